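"""Post hoc quantities extracted from a fitted model.

The point of modelling the whole conditional distribution is that any
categorized summary can be read off afterwards, at any cut-off:

* proportional odds ratios exp(beta) with Wald intervals — cut-off-free
  by construction;
* non-proportional stratum odds ratios exp(alpha(b)_A - alpha(b)_B) at
  arbitrary outcome values b, with delta-method intervals;
* per-stratum CDF tables at chosen cut-offs, distribution and density
  curves for plotting;
* probability-integral-transform residuals U = F(b | stratum, x),
  uniform under a correctly specified model (Cox–Snell style).

Remember the sign convention: the model is for P(Y <= b), so an odds
ratio above 1 means higher odds of LOWER outcome values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .likelihood_fit import FitResult
from .model_core import cdf, pdf

__all__ = [
    "OddsRatioEstimate",
    "proportional_or",
    "stratum_or",
    "cdf_table",
    "curve",
    "residuals",
    "ResidualDiagnostics",
]


@dataclass(frozen=True)
class OddsRatioEstimate:
    """Odds ratio with a two-sided Wald confidence interval."""

    value: float
    ci_lower: float
    ci_upper: float
    level: float = 0.95
    cutoff: object = "all"
    contrast: str = ""

    def __post_init__(self) -> None:
        if not self.ci_lower <= self.value <= self.ci_upper:
            raise ValueError("interval must contain the point estimate")

    def __str__(self) -> str:
        return (
            f"{self.value:.3f} ({self.ci_lower:.3f}–{self.ci_upper:.3f})"
        )


def _zcrit(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    return float(stats.norm.ppf(0.5 + level / 2.0))


def proportional_or(fit: FitResult, covariate: str,
                    level: float = 0.95) -> OddsRatioEstimate:
    """exp(beta_hat) for one covariate, Wald interval on the log scale.

    Valid for every cut-off simultaneously (the proportional-odds
    structure makes beta cut-off-free).
    """
    i = fit.beta_index(covariate)
    b = float(fit.free_params[i])
    se = fit.beta_se(covariate)
    z = _zcrit(level)
    return OddsRatioEstimate(
        value=float(np.exp(b)),
        ci_lower=float(np.exp(b - z * se)),
        ci_upper=float(np.exp(b + z * se)),
        level=level,
        cutoff="all",
        contrast=f"per unit {covariate}",
    )


def stratum_or(fit: FitResult, stratum_a, stratum_b, b: float,
               level: float = 0.95) -> OddsRatioEstimate:
    """Odds ratio of Y <= b comparing stratum_a to stratum_b.

    exp(alpha(b)_A - alpha(b)_B); the contrast is linear in the natural
    intercept coefficients, and its variance is propagated through the
    softplus chain rule from the free-parameterization covariance.
    Defined for any b strictly inside the hard bounds.
    """
    spec = fit.spec
    w = spec.window
    if not (w.hard_lower < b < w.hard_upper):
        raise ValueError("cut-off must lie strictly inside the hard bounds")
    ia = spec.stratum_index(stratum_a)
    ib = spec.stratum_index(stratum_b)
    row = spec.basis.eval(b)
    m = spec.n_coef
    c_nat = np.zeros(spec.n_strata * m + spec.n_cov)
    c_nat[ia * m : (ia + 1) * m] += row
    c_nat[ib * m : (ib + 1) * m] -= row
    theta = fit.params.theta
    log_or = float(row @ theta[ia] - row @ theta[ib])
    if ia == ib:
        return OddsRatioEstimate(1.0, 1.0, 1.0, level, b,
                                 f"{stratum_a} vs {stratum_b}")
    if fit.vcov is None:
        raise ValueError("fit was run without covariance computation")
    J = fit.free_parameterization.jacobian(fit.free_params)
    g = J.T @ c_nat
    var = float(g @ fit.vcov @ g)
    se = np.sqrt(max(var, 0.0))
    z = _zcrit(level)
    return OddsRatioEstimate(
        value=float(np.exp(log_or)),
        ci_lower=float(np.exp(log_or - z * se)),
        ci_upper=float(np.exp(log_or + z * se)),
        level=level,
        cutoff=b,
        contrast=f"{stratum_a} vs {stratum_b}",
    )


WHO_CUTOFFS = (18.5, 25.0, 30.0)


def cdf_table(fit: FitResult, cutoffs=WHO_CUTOFFS,
              baseline_x=None) -> pd.DataFrame:
    """P(Y <= cut-off | stratum, baseline_x), strata as rows.

    ``baseline_x`` defaults to the zero vector (reference categories and
    centered continuous covariates).
    """
    spec = fit.spec
    w = spec.window
    cutoffs = [float(c) for c in cutoffs]
    if any(not (w.hard_lower <= c <= w.hard_upper) for c in cutoffs):
        raise ValueError("cut-offs must lie inside the hard bounds")
    rows = {
        s: [cdf(c, s, baseline_x, fit.params, spec) for c in cutoffs]
        for s in spec.strata
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"P(Y<={c:g})" for c in cutoffs]
    )


def curve(fit: FitResult, stratum, baseline_x=None, kind: str = "distribution",
          grid=None) -> pd.DataFrame:
    """Distribution or density curve for one stratum at baseline covariates."""
    spec = fit.spec
    w = spec.window
    if grid is None:
        grid = np.linspace(w.lower, w.upper, 201)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < w.hard_lower) or np.any(grid > w.hard_upper):
        raise ValueError("grid must lie inside the hard bounds")
    if kind == "distribution":
        vals = cdf(grid, stratum, baseline_x, fit.params, spec)
    elif kind == "density":
        vals = pdf(grid, stratum, baseline_x, fit.params, spec)
    else:
        raise ValueError("kind must be 'distribution' or 'density'")
    return pd.DataFrame({"b": grid, kind: np.asarray(vals)})


@dataclass(frozen=True)
class ResidualDiagnostics:
    u: np.ndarray
    ks_statistic: float
    ks_pvalue: float
    n_approximate: int  # interval observations scored at their midpoint


def residuals(fit: FitResult, data) -> ResidualDiagnostics:
    """PIT residuals U_i = F(b_i | stratum_i, x_i) with a KS summary.

    Exact observations use their measured value; interval observations
    use the interval midpoint (finite endpoints clipped to the support
    window first) and are counted as approximate.
    """
    spec = fit.spec
    w = spec.window
    u = np.empty(len(data))
    n_approx = 0
    for i, obs in enumerate(data):
        if obs.is_exact:
            b = obs.exact
        else:
            lo = w.lower if obs.lower is None else max(obs.lower, w.lower)
            hi = w.upper if obs.upper is None else min(obs.upper, w.upper)
            b = 0.5 * (lo + hi)
            n_approx += 1
        u[i] = cdf(b, obs.stratum, obs.x, fit.params, spec)
    ks = stats.kstest(u, "uniform")
    return ResidualDiagnostics(
        u=u,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        n_approximate=n_approx,
    )
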