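"""The conditional-distribution model r(b | stratum, x) = alpha(b)_stratum + x'beta.

The model states that a link transform of the conditional CDF of the
outcome is additive in a stratum-specific monotone intercept function
``alpha(b)`` and a constant covariate shift ``x'beta``:

    g(P(Y <= b | stratum, x)) = alpha(b)_stratum + x' beta

With the logit link, differences of ``r`` are log-odds ratios of the
event ``Y <= b``; with the complementary log-log link the same structure
is a fully parameterized proportional-hazards model.

Sign convention
---------------
The model is for ``P(Y <= b)``: a positive coefficient beta_j (odds
ratio exp(beta_j) > 1) means *higher* odds of LOWER outcome values, i.e.
the covariate shifts the distribution towards smaller outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .basis import SupportWindow

__all__ = [
    "Link",
    "LOGIT",
    "CLOGLOG",
    "get_link",
    "ModelSpec",
    "ParameterVector",
    "transform",
    "cdf",
    "pdf",
    "quantile",
]


# --------------------------------------------------------------------------
# Links


@dataclass(frozen=True)
class Link:
    """Inverse-link (CDF scale) and its density, on the transform scale."""

    name: str

    def inv(self, eta):
        """F(eta): inverse link, a CDF value in [0, 1]."""
        eta = np.asarray(eta, dtype=float)
        if self.name == "logit":
            return expit(eta)
        eta = np.clip(eta, -700.0, 30.0)
        return -np.expm1(-np.exp(eta))

    def density(self, eta):
        """dF/deta evaluated at eta."""
        eta = np.asarray(eta, dtype=float)
        if self.name == "logit":
            return expit(eta) * expit(-eta)
        eta = np.clip(eta, -700.0, 30.0)
        return np.exp(eta - np.exp(eta))

    def log_density(self, eta):
        eta = np.asarray(eta, dtype=float)
        if self.name == "logit":
            return -np.logaddexp(0.0, eta) - np.logaddexp(0.0, -eta)
        eta = np.clip(eta, -700.0, 30.0)
        return eta - np.exp(eta)

    def dlog_density(self, eta):
        """d/deta log dF/deta (used in the likelihood gradient)."""
        eta = np.asarray(eta, dtype=float)
        if self.name == "logit":
            return 1.0 - 2.0 * expit(eta)
        eta = np.clip(eta, -700.0, 30.0)
        return 1.0 - np.exp(eta)

    def forward(self, p):
        """g(p): the link itself (logit or cloglog)."""
        p = np.asarray(p, dtype=float)
        if self.name == "logit":
            return np.log(p) - np.log1p(-p)
        return np.log(-np.log1p(-p))


LOGIT = Link("logit")
CLOGLOG = Link("cloglog")


def get_link(name) -> Link:
    if isinstance(name, Link):
        return name
    if name == "logit":
        return LOGIT
    if name == "cloglog":
        return CLOGLOG
    raise ValueError(f"unknown link {name!r}; expected 'logit' or 'cloglog'")


# --------------------------------------------------------------------------
# Model specification and parameters


@dataclass(frozen=True)
class ModelSpec:
    """Strata, covariate design and basis defining one model.

    ``strata`` are opaque labels (typically "smoking:sex" combinations);
    each stratum owns one block of intercept-function coefficients.
    ``covariate_names`` are the columns of the (already dummy-encoded)
    design; categorical covariates use first-level-reference encoding
    upstream.
    """

    strata: tuple
    covariate_names: tuple
    basis: object  # BernsteinBasis | StepBasis
    link: str = "logit"

    def __post_init__(self) -> None:
        object.__setattr__(self, "strata", tuple(self.strata))
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        if len(self.strata) < 1:
            raise ValueError("at least one stratum is required")
        if len(set(self.strata)) != len(self.strata):
            raise ValueError("duplicate stratum labels")
        get_link(self.link)

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    @property
    def n_coef(self) -> int:
        return self.basis.n_coef

    @property
    def n_cov(self) -> int:
        return len(self.covariate_names)

    @property
    def n_params(self) -> int:
        return self.n_strata * self.n_coef + self.n_cov

    @property
    def window(self) -> SupportWindow:
        return self.basis.window

    def stratum_index(self, stratum) -> int:
        try:
            return self.strata.index(stratum)
        except ValueError:
            raise KeyError(f"unknown stratum {stratum!r}; have {self.strata}")


@dataclass
class ParameterVector:
    """Per-stratum intercept coefficient blocks plus shared shifts beta.

    ``theta`` has shape (n_strata, n_coef) with each row non-decreasing;
    ``beta`` has one entry per covariate column.  The flat layout is
    [theta row 0, theta row 1, ..., beta].
    """

    theta: np.ndarray
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        self.beta = np.asarray(self.beta, dtype=float).ravel()

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.theta.ravel(), self.beta])

    @classmethod
    def from_flat(cls, flat, n_strata: int, n_coef: int) -> "ParameterVector":
        flat = np.asarray(flat, dtype=float)
        nt = n_strata * n_coef
        return cls(flat[:nt].reshape(n_strata, n_coef), flat[nt:])

    def is_monotone(self, tol: float = 1e-10) -> bool:
        return bool(np.all(np.diff(self.theta, axis=1) >= -tol))


# --------------------------------------------------------------------------
# Model evaluation


def _as_x(x, spec: ModelSpec) -> np.ndarray:
    if x is None:
        return np.zeros(spec.n_cov)
    x = np.asarray(x, dtype=float).ravel()
    if x.size != spec.n_cov:
        raise ValueError(
            f"covariate vector has length {x.size}, expected {spec.n_cov}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate vector must be finite")
    return x


def transform(b, stratum, x, params: ParameterVector, spec: ModelSpec):
    """r(b | stratum, x) = alpha(b)_stratum + x' beta.

    Non-decreasing in ``b`` for admissible (monotone) theta blocks.
    """
    s = spec.stratum_index(stratum)
    xv = _as_x(x, spec)
    rows = spec.basis.eval(b)
    shift = float(xv @ params.beta) if spec.n_cov else 0.0
    return rows @ params.theta[s] + shift


def transform_deriv(b, stratum, params: ParameterVector, spec: ModelSpec):
    """d r(b | stratum, x) / db = alpha'(b)_stratum (covariate-free)."""
    s = spec.stratum_index(stratum)
    return spec.basis.deriv(b) @ params.theta[s]


def cdf(b, stratum, x, params: ParameterVector, spec: ModelSpec):
    """P(Y <= b | stratum, x); pinned to 0/1 at the hard bounds."""
    b_arr = np.asarray(b, dtype=float)
    w = spec.window
    at_lo = b_arr <= w.hard_lower
    at_hi = b_arr >= w.hard_upper
    inner = np.where(at_lo | at_hi, w.lower, b_arr)  # placeholder, finite
    vals = get_link(spec.link).inv(transform(inner, stratum, x, params, spec))
    vals = np.where(at_lo, 0.0, np.where(at_hi, 1.0, vals))
    return float(vals) if np.isscalar(b) or np.ndim(b) == 0 else vals

def pdf(b, stratum, x, params: ParameterVector, spec: ModelSpec):
    """Conditional density: dF/deta at r(b) times alpha'(b).

    Zero on flat segments of the intercept function (tied coefficients).
    """
    b_arr = np.asarray(b, dtype=float)
    w = spec.window
    if np.any(b_arr <= w.hard_lower) or np.any(b_arr >= w.hard_upper):
        raise ValueError("density is only defined strictly inside the hard bounds")
    link = get_link(spec.link)
    eta = transform(b_arr, stratum, x, params, spec)
    slope = transform_deriv(b_arr, stratum, params, spec)
    vals = link.density(eta) * np.maximum(slope, 0.0)
    return float(vals) if np.isscalar(b) or np.ndim(b) == 0 else vals


def quantile(p, stratum, x, params: ParameterVector, spec: ModelSpec,
             tol: float = 1e-10) -> float:
    """Smallest b with P(Y <= b | stratum, x) ~ p, by bracketed root-finding."""
    p = float(p)
    if not 0.0 < p < 1.0:
        raise ValueError("quantile requires p strictly inside (0, 1)")
    w = spec.window

    def f(b):
        return cdf(b, stratum, x, params, spec) - p

    lo, hi = w.lower, w.upper
    eps = 1e-9 * max(1.0, abs(w.hard_lower))
    floor = w.hard_lower + max(eps, 1e-12)
    step = w.width
    for _ in range(200):
        if f(lo) <= 0.0:
            break
        lo = max(floor, lo - step)
        step *= 2.0
        if lo <= floor and f(lo) > 0.0:
            return floor
    step = w.width
    for _ in range(200):
        if f(hi) >= 0.0:
            break
        hi = min(w.hard_upper - eps, hi + step) if np.isfinite(w.hard_upper) else hi + step
        step *= 2.0
    else:
        raise RuntimeError("quantile bracket search failed (flat upper tail?)")
    return brentq(f, lo, hi, xtol=tol)
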