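"""Synthetic survey-like data from a known ground-truth model.

The real motivating data (a national health survey with self-reported
height and weight) is only available by application, so every other
module is exercised against simulated cohorts with the same structure:
five smoking levels crossed with two sexes as strata, continuous and
categorical covariates, and outcomes observable at four measurement
scales —

* ``who``          the four WHO BMI categories (cut-offs 18.5, 25, 30);
* ``fixed_width``  a 21-category grid of 2-unit intervals
                   (<=17, (17,19], ..., (35,37], >37);
* ``rounding``     the numeric interval of BMI values consistent with
                   height reported to 1 cm and weight to 1 kg;
* ``exact``        the ratio weight/height^2 taken as exact.

Outcomes are drawn by inverse-CDF sampling from a model of exactly the
fitted family (Bernstein intercept functions per stratum plus constant
covariate shifts), so parameter-recovery tests have a well-defined
truth.  The default intercept presets give right-skewed, sex-distinct
BMI distributions (means near 23 for females and 25.5 for males); they
are presets of this package, not estimates from any survey.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .basis import BernsteinBasis, SupportWindow
from .likelihood_fit import Observation
from .model_core import ModelSpec, ParameterVector, get_link

__all__ = [
    "CovariateSpec",
    "GeneratorConfig",
    "MeasurementScheme",
    "SimulatedData",
    "shs_like_config",
    "model_spec",
    "true_parameters",
    "encode_covariates",
    "generate",
    "who_categorize",
    "fixed_width_categorize",
    "rounding_interval",
    "apply_scheme",
    "to_observations",
]


SMOKING_LEVELS = ("Never", "Former", "Light", "Medium", "Heavy")
SEX_LEVELS = ("Female", "Male")

WHO_EDGES = (18.5, 25.0, 30.0)


# --------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate of the generating model.

    Continuous covariates (``kind='continuous'``) are drawn from a
    normal or exponential distribution and enter the design centered at
    ``center``.  Categorical covariates are drawn from ``levels`` with
    ``probs`` and dummy-encoded with the first level as reference;
    ``beta`` then holds one log-odds-ratio per non-reference level.
    """

    name: str
    kind: str  # 'continuous' | 'categorical'
    beta: tuple  # log-odds ratios (length 1 for continuous)
    levels: tuple = ()
    probs: tuple = ()
    mean: float = 0.0
    sd: float = 1.0
    dist: str = "normal"  # 'normal' | 'exponential'
    center: float = 0.0
    clip: tuple | None = None

    def __post_init__(self) -> None:
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "beta", tuple(beta))
        if self.kind == "categorical":
            if len(self.levels) < 2:
                raise ValueError(f"categorical covariate {self.name} needs >= 2 levels")
            if len(self.probs) != len(self.levels):
                raise ValueError(f"probs/levels length mismatch for {self.name}")
            if abs(sum(self.probs) - 1.0) > 1e-9:
                raise ValueError(f"level probabilities of {self.name} must sum to 1")
            if len(beta) != len(self.levels) - 1:
                raise ValueError(
                    f"{self.name}: need one beta per non-reference level"
                )
        elif self.kind == "continuous":
            if len(beta) != 1:
                raise ValueError(f"{self.name}: continuous covariate has one beta")
        else:
            raise ValueError(f"unknown covariate kind {self.kind!r}")

    @property
    def design_names(self) -> tuple:
        if self.kind == "continuous":
            return (self.name,)
        return tuple(f"{self.name}[{lv}]" for lv in self.levels[1:])


@dataclass(frozen=True)
class MeasurementScheme:
    """How exact outcomes are coarsened before entering the likelihood."""

    kind: str  # 'who' | 'fixed_width' | 'rounding' | 'exact'
    width: float = 2.0
    who_cutoffs: tuple = WHO_EDGES
    height_step: float = 0.01  # m
    weight_step: float = 1.0  # kg

    def __post_init__(self) -> None:
        if self.kind not in ("who", "fixed_width", "rounding", "exact"):
            raise ValueError(f"unknown measurement scheme {self.kind!r}")
        if self.width <= 0:
            raise ValueError("interval width must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground truth for one simulated cohort.

    ``strata_probs`` maps stratum labels (by default the ten
    smoking-by-sex combinations, labelled "Never:Female", ...) to
    sampling probabilities.  ``theta`` optionally overrides the
    intercept-coefficient preset per stratum.
    """

    n: int
    seed: int
    strata_probs: dict = field(default_factory=dict)
    covariates: tuple = ()
    window: SupportWindow = field(
        default_factory=lambda: SupportWindow(13.0, 45.0, 0.0, np.inf)
    )
    order: int = 5
    link: str = "logit"
    theta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.strata_probs:
            object.__setattr__(
                self, "strata_probs", _default_strata_probs()
            )
        p = np.array(list(self.strata_probs.values()), dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("stratum probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def strata(self) -> tuple:
        return tuple(self.strata_probs)


def _default_strata_probs() -> dict:
    smoking_p = dict(zip(SMOKING_LEVELS, (0.45, 0.25, 0.10, 0.10, 0.10)))
    return {
        f"{smk}:{sex}": smoking_p[smk] * 0.5
        for smk in SMOKING_LEVELS
        for sex in SEX_LEVELS
    }


def shs_like_config(n: int, seed: int) -> GeneratorConfig:
    """Full survey-like default: 10 strata, seven covariates.

    Effect sizes are plausible magnitudes for BMI epidemiology (odds
    ratios of the event Y <= b between roughly 0.77 and 1.8).
    """
    covariates = (
        CovariateSpec("age", "continuous", beta=(np.log(0.968),),
                      mean=47.0, sd=16.0, clip=(18.0, 74.0), center=40.0),
        CovariateSpec("alcohol", "continuous", beta=(np.log(1.002),),
                      mean=8.0, dist="exponential"),
        CovariateSpec("fruitveg", "categorical", beta=(np.log(0.93),),
                      levels=("High", "Low"), probs=(0.35, 0.65)),
        CovariateSpec("activity", "categorical",
                      beta=(np.log(0.86), np.log(0.77)),
                      levels=("High", "Moderate", "Low"),
                      probs=(0.45, 0.30, 0.25)),
        CovariateSpec("education", "categorical",
                      beta=(np.log(1.25), np.log(1.78)),
                      levels=("Mandatory", "Secondary", "Tertiary"),
                      probs=(0.15, 0.55, 0.30)),
        CovariateSpec("nationality", "categorical", beta=(np.log(0.81),),
                      levels=("Swiss", "Foreign"), probs=(0.75, 0.25)),
        CovariateSpec("region", "categorical",
                      beta=(np.log(1.13), np.log(1.23)),
                      levels=("German", "French", "Italian"),
                      probs=(0.70, 0.24, 0.06)),
    )
    return GeneratorConfig(n=n, seed=seed, covariates=covariates)


# --------------------------------------------------------------------------
# Ground-truth model


def _preset_theta(label: str, window: SupportWindow, order: int, link) -> np.ndarray:
    """Intercept coefficients from a right-skewed target distribution.

    The link transform of a skew-normal CDF is read off at the Bernstein
    knots, which places the true model exactly inside the fitted family
    while matching the qualitative shape of adult BMI distributions.
    """
    loc, scale, shape = 20.9, 4.4, 4.0  # male-like default, realized mean ~25.5
    parts = label.split(":")
    if "Female" in parts:
        loc = 18.4  # realized mean ~23
    smoking_shift = {"Never": 0.0, "Former": 0.6, "Light": -0.6,
                     "Medium": -0.2, "Heavy": -0.4}
    for p in parts:
        loc += smoking_shift.get(p, 0.0)
    knots = window.lower + np.arange(order + 1) / order * window.width
    f0 = np.clip(stats.skewnorm.cdf(knots, shape, loc=loc, scale=scale),
                 1e-4, 1.0 - 1e-4)
    theta = np.asarray(link.forward(f0), dtype=float)
    for k in range(1, theta.size):  # strictly increasing, no flat tails
        theta[k] = max(theta[k], theta[k - 1] + 0.05)
    return theta


def model_spec(config: GeneratorConfig) -> ModelSpec:
    names = [n for c in config.covariates for n in c.design_names]
    return ModelSpec(
        strata=config.strata,
        covariate_names=tuple(names),
        basis=BernsteinBasis(config.order, config.window),
        link=config.link,
    )


def true_parameters(config: GeneratorConfig) -> ParameterVector:
    link = get_link(config.link)
    theta = np.array(
        [
            np.asarray(config.theta[s], dtype=float)
            if s in config.theta
            else _preset_theta(s, config.window, config.order, link)
            for s in config.strata
        ]
    )
    beta = np.array([b for c in config.covariates for b in c.beta])
    return ParameterVector(theta, beta)


def encode_covariates(frame: pd.DataFrame, covariates) -> tuple:
    """Design matrix (centered continuous, first-level-reference dummies)."""
    cols, names = [], []
    for c in covariates:
        if c.kind == "continuous":
            cols.append(np.asarray(frame[c.name], dtype=float) - c.center)
            names.append(c.name)
        else:
            vals = frame[c.name].to_numpy()
            for lv in c.levels[1:]:
                cols.append((vals == lv).astype(float))
                names.append(f"{c.name}[{lv}]")
    X = np.column_stack(cols) if cols else np.zeros((len(frame), 0))
    return X, tuple(names)


# --------------------------------------------------------------------------
# Sampling


def _sample_outcomes(u, sidx, xshift, params, spec, grid_points: int = 4001):
    """Inverse-CDF sampling, vectorized per stratum.

    Solves alpha(b)_s = g(u) - x'beta on a dense grid inside the widened
    support window; outside the grid the transformation is exactly
    linear, so the solution is closed-form there.
    """
    w = spec.window
    link = get_link(spec.link)
    target = link.forward(u) - xshift
    b_lo = max(w.hard_lower + 1e-3, w.lower - 5.0)
    bgrid = np.linspace(b_lo, w.upper + 5.0, grid_points)
    rows = spec.basis.eval(bgrid)
    d_lo = spec.basis.deriv(np.array([bgrid[0]]))[0]
    d_hi = spec.basis.deriv(np.array([bgrid[-1]]))[0]
    out = np.empty_like(target)
    for s in range(spec.n_strata):
        mask = sidx == s
        if not np.any(mask):
            continue
        theta = params.theta[s]
        agrid = rows @ theta
        slope_lo = max(float(d_lo @ theta), 1e-12)
        slope_hi = max(float(d_hi @ theta), 1e-12)
        t = target[mask]
        b = np.interp(t, agrid, bgrid)
        low = t < agrid[0]
        high = t > agrid[-1]
        b[low] = np.maximum(
            w.hard_lower + 1e-6, bgrid[0] - (agrid[0] - t[low]) / slope_lo
        )
        b[high] = bgrid[-1] + (t[high] - agrid[-1]) / slope_hi
        out[mask] = b
    return out


@dataclass
class SimulatedData:
    """One simulated cohort plus its generating truth."""

    frame: pd.DataFrame
    spec: ModelSpec
    params: ParameterVector
    config: GeneratorConfig


_HEIGHT_BY_SEX = {"Female": (1.655, 0.065), "Male": (1.78, 0.07)}


def generate(config: GeneratorConfig) -> SimulatedData:
    """Draw a cohort: strata, covariates, exact outcomes, body measures.

    Draws happen in a fixed order (strata, then each covariate in
    declared order, then the outcome uniforms, then heights), so
    appending covariates to the configuration does not perturb earlier
    columns for the same seed.
    """
    rng = np.random.default_rng(config.seed)
    spec = model_spec(config)
    params = true_parameters(config)
    labels = list(config.strata)
    probs = np.array([config.strata_probs[s] for s in labels])
    sidx = rng.choice(len(labels), size=config.n, p=probs)

    frame = pd.DataFrame({"id": np.arange(config.n)})
    frame["stratum"] = [labels[i] for i in sidx]
    parts = [lab.split(":") for lab in labels]
    if all(len(p) == 2 for p in parts):
        frame["smoking"] = [parts[i][0] for i in sidx]
        frame["sex"] = [parts[i][1] for i in sidx]

    for c in config.covariates:
        if c.kind == "continuous":
            if c.dist == "exponential":
                col = rng.exponential(c.mean, size=config.n)
            else:
                col = rng.normal(c.mean, c.sd, size=config.n)
            if c.clip is not None:
                col = np.clip(col, *c.clip)
        else:
            col = rng.choice(c.levels, size=config.n, p=c.probs)
        frame[c.name] = col

    X, names = encode_covariates(frame, config.covariates)
    assert names == spec.covariate_names
    u = rng.uniform(size=config.n)
    xshift = X @ params.beta if names else np.zeros(config.n)
    bmi = _sample_outcomes(u, sidx, xshift, params, spec)
    frame["bmi"] = bmi

    if "sex" in frame:
        hm = np.array([_HEIGHT_BY_SEX[s][0] for s in frame["sex"]])
        hs = np.array([_HEIGHT_BY_SEX[s][1] for s in frame["sex"]])
    else:
        hm, hs = 1.72, 0.08
    height = np.clip(rng.normal(hm, hs, size=config.n), 1.45, 2.10)
    frame["height"] = height
    frame["weight"] = bmi * height**2
    frame["sampling_weight"] = 1.0
    return SimulatedData(frame=frame, spec=spec, params=params, config=config)


# --------------------------------------------------------------------------
# Coarsening to measurement scales


def who_categorize(b: float) -> tuple:
    """WHO category interval containing b: one of (0, 18.5], (18.5, 25],
    (25, 30], (30, inf].  Boundaries belong to the lower category."""
    if not b > 0:
        raise ValueError("BMI must be positive")
    edges = (0.0,) + WHO_EDGES + (np.inf,)
    k = int(np.searchsorted(WHO_EDGES, b, side="left"))
    return (edges[k], edges[k + 1])


def fixed_width_categorize(b: float, scheme: MeasurementScheme | None = None) -> tuple:
    """2-unit-interval category containing b, on the 21-category grid
    <=17, (17, 19], ..., (35, 37], > 37 (open-ended tails)."""
    if not b > 0:
        raise ValueError("BMI must be positive")
    scheme = scheme or MeasurementScheme("fixed_width")
    inner = np.arange(17.0, 37.0 + 0.5 * scheme.width, scheme.width)
    edges = (0.0,) + tuple(inner) + (np.inf,)
    k = int(np.searchsorted(inner, b, side="left"))
    return (edges[k], edges[k + 1])


def rounding_interval(height_m, weight_kg, height_step: float = 0.01,
                      weight_step: float = 1.0) -> tuple:
    """BMI interval consistent with rounded height/weight reports.

    A height reported as h and weight reported as w are compatible with
    true values in (h - hs/2, h + hs/2) and (w - ws/2, w + ws/2), hence
    with any BMI in ((w - ws/2)/(h + hs/2)^2, (w + ws/2)/(h - hs/2)^2].
    """
    height_m = np.asarray(height_m, dtype=float)
    weight_kg = np.asarray(weight_kg, dtype=float)
    if np.any(height_m <= 0) or np.any(weight_kg <= 0):
        raise ValueError("height and weight must be positive")
    if height_step <= 0 or weight_step <= 0:
        raise ValueError("rounding steps must be positive")
    lo = (weight_kg - weight_step / 2.0) / (height_m + height_step / 2.0) ** 2
    hi = (weight_kg + weight_step / 2.0) / (height_m - height_step / 2.0) ** 2
    if lo.ndim == 0:
        return (float(lo), float(hi))
    return (lo, hi)


def apply_scheme(frame: pd.DataFrame, scheme) -> pd.DataFrame:
    """Replace exact outcomes by their scheme-coarsened representation.

    ``scheme`` is one :class:`MeasurementScheme` for the whole frame or
    a sequence of per-row schemes (mixed-scale datasets).  Returns a
    copy with columns ``lower``/``upper``/``exact``; NaN in
    lower/upper marks a hard bound, NaN in exact marks an interval row.
    """
    out = frame.copy()
    n = len(out)
    lower = np.full(n, np.nan)
    upper = np.full(n, np.nan)
    exact = np.full(n, np.nan)
    if isinstance(scheme, MeasurementScheme):
        schemes = [scheme] * n
    else:
        schemes = list(scheme)
        if len(schemes) != n:
            raise ValueError("per-row scheme list length must match the frame")
    bmi = out["bmi"].to_numpy(dtype=float)
    for i, sch in enumerate(schemes):
        if sch.kind == "exact":
            exact[i] = bmi[i]
        elif sch.kind == "who":
            lo, hi = who_categorize(bmi[i])
            lower[i], upper[i] = lo, hi
        elif sch.kind == "fixed_width":
            lo, hi = fixed_width_categorize(bmi[i], sch)
            lower[i], upper[i] = lo, hi
        else:  # rounding
            if "height" not in out or "weight" not in out:
                raise ValueError(
                    "rounding scheme requires height and weight columns"
                )
            h = round(out["height"].iat[i] / sch.height_step) * sch.height_step
            w = round(out["weight"].iat[i] / sch.weight_step) * sch.weight_step
            lo, hi = rounding_interval(h, w, sch.height_step, sch.weight_step)
            lower[i], upper[i] = lo, hi
    lower[~np.isfinite(lower) | (lower <= 0.0)] = np.nan
    upper[~np.isfinite(upper)] = np.nan
    out["lower"], out["upper"], out["exact"] = lower, upper, exact
    out["scheme"] = [s.kind for s in schemes]
    return out


def to_observations(frame: pd.DataFrame, config: GeneratorConfig) -> list:
    """Convert a coarsened frame into likelihood-ready observations."""
    X, _ = encode_covariates(frame, config.covariates)
    obs = []
    weights = (
        frame["sampling_weight"].to_numpy(dtype=float)
        if "sampling_weight" in frame
        else np.ones(len(frame))
    )
    for i in range(len(frame)):
        ex = frame["exact"].iat[i]
        lo = frame["lower"].iat[i]
        hi = frame["upper"].iat[i]
        obs.append(
            Observation(
                stratum=frame["stratum"].iat[i],
                x=tuple(X[i]),
                lower=None if pd.isna(lo) else float(lo),
                upper=None if pd.isna(hi) else float(hi),
                exact=None if pd.isna(ex) else float(ex),
                weight=float(weights[i]),
            )
        )
    return obs
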