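"""Mixed-scale likelihood and constrained maximum-likelihood estimation.

Each subject contributes either

* an interval probability  ``F(r(upper)) - F(r(lower))``  for an
  outcome known only to lie in the half-open interval (lower, upper]
  (categories, rounding intervals), with the CDF pinned to 0/1 at the
  hard bounds; or
* a density  ``dF/deta(r(b)) * alpha'(b)``  for an "exact" measurement,
  the narrow-interval limit of the interval contribution.

Contributions from different measurement scales mix freely in one
likelihood, which is what makes joint fits across studies with
different outcome codings possible.

Monotonicity of each stratum's intercept coefficients is enforced
exactly by reparameterization: the first coefficient is free and each
increment is softplus-transformed, so any unconstrained optimizer can
be used.  The covariance of the estimates is reported in this free
parameterization; delta-method helpers map contrasts of the natural
coefficients back through the softplus chain rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .model_core import ModelSpec, ParameterVector, get_link
from .basis import StepBasis

__all__ = [
    "Observation",
    "FitOptions",
    "FitResult",
    "FreeParameterization",
    "loglik_contribution",
    "total_negloglik",
    "fit",
    "fit_binary_reduction",
]


# --------------------------------------------------------------------------
# Observations


@dataclass(frozen=True)
class Observation:
    """One subject: outcome (exact value or half-open interval), stratum,
    covariate vector, nonnegative weight.

    ``lower``/``upper`` of ``None`` mean the hard bounds of the outcome
    (0 and +infinity for BMI).  Exactly one of {interval, exact} is
    present; intervals follow the (lower, upper] convention.
    """

    stratum: object
    x: tuple = ()
    lower: float | None = None
    upper: float | None = None
    exact: float | None = None

    weight: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", tuple(float(v) for v in self.x))
        if self.exact is not None:
            if self.lower is not None or self.upper is not None:
                raise ValueError(
                    "observation cannot carry both an exact value and an interval"
                )
            if not np.isfinite(self.exact) or self.exact <= 0:
                raise ValueError("exact outcome must be finite and positive")
        else:
            lo = -np.inf if self.lower is None else float(self.lower)
            hi = np.inf if self.upper is None else float(self.upper)
            if not lo < hi:
                raise ValueError(f"interval ({lo}, {hi}] is empty")
        if not (np.isfinite(self.weight) and self.weight >= 0.0):
            raise ValueError("weight must be finite and nonnegative")

    @property
    def is_exact(self) -> bool:
        return self.exact is not None


@dataclass
class FitOptions:
    """Optimizer and numerics knobs.

    ``gtol`` is relative: convergence requires the inf-norm of the free
    gradient to be below ``gtol * (1 + |negloglik|)``.  ``prob_floor``
    guards the log of near-zero interval probabilities/densities; each
    floored contribution is counted and reported on the fit result.
    """

    gtol: float = 1e-6
    maxiter: int = 500
    newton_maxiter: int = 100
    prob_floor: float = 1e-12
    hessian_step: float = 1e-5
    compute_vcov: bool = True
    divergence_bound: float = 25.0


# --------------------------------------------------------------------------
# Free (unconstrained) parameterization


def _softplus(g):
    return np.logaddexp(0.0, g)


def _inv_softplus(d):
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(
            d > 1e-10, d + np.log1p(-np.exp(-np.maximum(d, 1e-10))), np.log(np.maximum(d, 1e-300))
        )
    return out


class FreeParameterization:
    """Bijection between constrained natural parameters and free ones.

    Per stratum block of m coefficients: theta_1 is free and
    theta_{k+1} = theta_k + softplus(gamma_k), so every free vector maps
    to a non-decreasing block (strictly increasing for finite gamma).
    beta passes through unchanged.
    """

    def __init__(self, spec: ModelSpec):
        self.n_strata = spec.n_strata
        self.n_coef = spec.n_coef
        self.n_cov = spec.n_cov
        self.n_free = self.n_strata * self.n_coef + self.n_cov

    def split(self, free):
        free = np.asarray(free, dtype=float)
        nt = self.n_strata * self.n_coef
        return free[:nt].reshape(self.n_strata, self.n_coef), free[nt:]

    def to_natural(self, free) -> ParameterVector:
        blocks, beta = self.split(free)
        theta = np.empty_like(blocks)
        theta[:, 0] = blocks[:, 0]
        if self.n_coef > 1:
            theta[:, 1:] = blocks[:, [0]] + np.cumsum(_softplus(blocks[:, 1:]), axis=1)
        return ParameterVector(theta, beta.copy())

    def to_free(self, params: ParameterVector, min_increment: float = 1e-6) -> np.ndarray:
        theta = np.asarray(params.theta, dtype=float)
        blocks = np.empty_like(theta)
        blocks[:, 0] = theta[:, 0]
        if self.n_coef > 1:
            incr = np.maximum(np.diff(theta, axis=1), min_increment)
            blocks[:, 1:] = _inv_softplus(incr)
        return np.concatenate([blocks.ravel(), np.asarray(params.beta, dtype=float)])

    def chain_gradient(self, g_theta, g_beta, free) -> np.ndarray:
        """Pull a gradient w.r.t. natural (theta, beta) back to free space."""
        blocks, _ = self.split(free)
        out = np.empty_like(blocks)
        # d theta_j / d theta1 = 1 for all j; d theta_j / d gamma_k = sigma(gamma_k), k<=j
        rev = np.cumsum(g_theta[:, ::-1], axis=1)[:, ::-1]
        out[:, 0] = rev[:, 0]
        if self.n_coef > 1:
            out[:, 1:] = expit(blocks[:, 1:]) * rev[:, 1:]
        return np.concatenate([out.ravel(), np.asarray(g_beta, dtype=float)])

    def jacobian(self, free) -> np.ndarray:
        """Dense d(natural)/d(free), for delta-method variance propagation.

        Natural layout matches ParameterVector.flatten(): theta blocks
        row-major, then beta.
        """
        blocks, _ = self.split(free)
        m, S, c = self.n_coef, self.n_strata, self.n_cov
        J = np.zeros((S * m + c, self.n_free))
        for s in range(S):
            r0 = s * m
            J[r0 : r0 + m, r0] = 1.0
            for k in range(1, m):
                J[r0 + k :, r0 + k][: m - k] = expit(blocks[s, k])
        if c:
            J[S * m :, S * m :] = np.eye(c)
        return J


# --------------------------------------------------------------------------
# Packed data and vectorized likelihood


class _Packed:
    """Precomputed basis rows / design matrices for fast likelihood evals."""

    def __init__(self, data, spec: ModelSpec):
        if len(data) == 0:
            raise ValueError("no observations")
        w = spec.window
        exact_rows, int_rows = [], []
        for i, obs in enumerate(data):
            if obs.is_exact:
                exact_rows.append((i, obs))
            else:
                int_rows.append((i, obs))
        if exact_rows and spec.basis.kind == "step":
            raise ValueError("exact-scale observations require a smooth basis")

        def xmat(rows):
            if spec.n_cov == 0:
                return np.zeros((len(rows), 0))
            X = np.array([obs.x for _, obs in rows], dtype=float)
            if X.shape[1] != spec.n_cov:
                raise ValueError("covariate length mismatch with model spec")
            return X

        sidx = {s: k for k, s in enumerate(spec.strata)}

        def smap(rows):
            try:
                return np.array([sidx[obs.stratum] for _, obs in rows], dtype=int)
            except KeyError as e:
                raise KeyError(f"observation stratum {e.args[0]!r} not in model spec")

        if exact_rows:
            be = np.array([obs.exact for _, obs in exact_rows])
            self.Be = spec.basis.eval(be)
            self.Bde = spec.basis.deriv(be)
            self.se = smap(exact_rows)
            self.Xe = xmat(exact_rows)
            self.we = np.array([obs.weight for _, obs in exact_rows])
        else:
            self.Be = np.zeros((0, spec.n_coef))
            self.Bde = self.Be
            self.se = np.zeros(0, dtype=int)
            self.Xe = np.zeros((0, spec.n_cov))
            self.we = np.zeros(0)

        if int_rows:
            lo = np.array(
                [w.hard_lower if obs.lower is None else obs.lower for _, obs in int_rows]
            )
            hi = np.array(
                [w.hard_upper if obs.upper is None else obs.upper for _, obs in int_rows]
            )
            self.lo_hard = lo <= w.hard_lower
            self.hi_hard = hi >= w.hard_upper
            self.Bl = np.zeros((len(int_rows), spec.n_coef))
            self.Bu = np.zeros((len(int_rows), spec.n_coef))
            if np.any(~self.lo_hard):
                self.Bl[~self.lo_hard] = spec.basis.eval(lo[~self.lo_hard])
            if np.any(~self.hi_hard):
                self.Bu[~self.hi_hard] = spec.basis.eval(hi[~self.hi_hard])
            self.si = smap(int_rows)
            self.Xi = xmat(int_rows)
            self.wi = np.array([obs.weight for _, obs in int_rows])
        else:
            self.lo_hard = np.zeros(0, dtype=bool)
            self.hi_hard = self.lo_hard
            self.Bl = np.zeros((0, spec.n_coef))
            self.Bu = self.Bl
            self.si = np.zeros(0, dtype=int)
            self.Xi = np.zeros((0, spec.n_cov))
            self.wi = np.zeros(0)

        self.n_obs = len(data)
        self.strata_counts = np.bincount(
            np.concatenate([self.se, self.si]), minlength=spec.n_strata
        )
        self.weight_sum = self.we.sum() + self.wi.sum()


def _negloglik_grad(free, packed: _Packed, spec: ModelSpec,
                    fp: FreeParameterization, floor: float):
    """Weighted negative log-likelihood, its free-space gradient, and the
    number of floored (near-zero probability) contributions."""
    params = fp.to_natural(free)
    theta, beta = params.theta, params.beta
    if not np.all(np.isfinite(theta)) or not np.all(np.isfinite(beta)):
        raise FloatingPointError("non-finite parameters in likelihood evaluation")
    link = get_link(spec.link)
    g_theta = np.zeros_like(theta)
    g_beta = np.zeros_like(beta)
    nll = 0.0
    n_floored = 0

    if packed.we.size:
        eta = np.einsum("ij,ij->i", packed.Be, theta[packed.se])
        if beta.size:
            eta = eta + packed.Xe @ beta
        dens_slope = np.einsum("ij,ij->i", packed.Bde, theta[packed.se])
        n_floored += int(np.sum(dens_slope < floor))
        slope = np.maximum(dens_slope, floor)
        nll -= float(packed.we @ (link.log_density(eta) + np.log(slope)))
        coef = packed.we * link.dlog_density(eta)
        np.add.at(
            g_theta,
            packed.se,
            coef[:, None] * packed.Be + (packed.we / slope)[:, None] * packed.Bde,
        )
        if beta.size:
            g_beta += packed.Xe.T @ coef

    if packed.wi.size:
        eta_u = np.einsum("ij,ij->i", packed.Bu, theta[packed.si])
        eta_l = np.einsum("ij,ij->i", packed.Bl, theta[packed.si])
        if beta.size:
            shift = packed.Xi @ beta
            eta_u = eta_u + shift
            eta_l = eta_l + shift
        Fu = np.where(packed.hi_hard, 1.0, link.inv(eta_u))
        Fl = np.where(packed.lo_hard, 0.0, link.inv(eta_l))
        p = Fu - Fl
        n_floored += int(np.sum(p < floor))
        p = np.maximum(p, floor)
        nll -= float(packed.wi @ np.log(p))
        fu = np.where(packed.hi_hard, 0.0, link.density(eta_u))
        fl = np.where(packed.lo_hard, 0.0, link.density(eta_l))
        coef = packed.wi / p
        np.add.at(
            g_theta,
            packed.si,
            coef[:, None] * (fu[:, None] * packed.Bu - fl[:, None] * packed.Bl),
        )
        if beta.size:
            g_beta += packed.Xi.T @ (coef * (fu - fl))

    grad = -fp.chain_gradient(g_theta, g_beta, free)
    return nll, grad, n_floored


# --------------------------------------------------------------------------
# Public likelihood surface


def loglik_contribution(obs: Observation, params: ParameterVector,
                        spec: ModelSpec, prob_floor: float = 1e-12) -> float:
    """Weighted log-likelihood contribution of one observation."""
    return -_negloglik_natural(params, _Packed([obs], spec), spec, prob_floor)


def _negloglik_natural(params: ParameterVector, packed: _Packed,
                       spec: ModelSpec, floor: float) -> float:
    link = get_link(spec.link)
    theta, beta = params.theta, params.beta
    if not np.all(np.isfinite(theta)) or not np.all(np.isfinite(beta)):
        raise FloatingPointError("non-finite parameters in likelihood evaluation")
    nll = 0.0
    if packed.we.size:
        eta = np.einsum("ij,ij->i", packed.Be, theta[packed.se])
        if beta.size:
            eta = eta + packed.Xe @ beta
        slope = np.maximum(np.einsum("ij,ij->i", packed.Bde, theta[packed.se]), floor)
        nll -= float(packed.we @ (link.log_density(eta) + np.log(slope)))
    if packed.wi.size:
        eta_u = np.einsum("ij,ij->i", packed.Bu, theta[packed.si])
        eta_l = np.einsum("ij,ij->i", packed.Bl, theta[packed.si])
        if beta.size:
            shift = packed.Xi @ beta
            eta_u = eta_u + shift
            eta_l = eta_l + shift
        Fu = np.where(packed.hi_hard, 1.0, link.inv(eta_u))
        Fl = np.where(packed.lo_hard, 0.0, link.inv(eta_l))
        nll -= float(packed.wi @ np.log(np.maximum(Fu - Fl, floor)))
    return nll


def total_negloglik(data, params: ParameterVector, spec: ModelSpec,
                    prob_floor: float = 1e-12) -> float:
    """Negative weighted sum of log-likelihood contributions."""
    packed = _Packed(list(data), spec)
    return _negloglik_natural(params, packed, spec, prob_floor)


# --------------------------------------------------------------------------
# Fit result and estimation


@dataclass
class FitResult:
    params: ParameterVector
    loglik: float
    vcov: np.ndarray | None
    converged: bool
    n_iter: int
    n_obs: int
    spec: ModelSpec
    free_params: np.ndarray = field(repr=False, default=None)
    n_floored: int = 0
    grad_norm: float = np.nan
    message: str = ""

    @property
    def free_parameterization(self) -> FreeParameterization:
        return FreeParameterization(self.spec)

    def beta_index(self, covariate: str) -> int:
        try:
            k = self.spec.covariate_names.index(covariate)
        except ValueError:
            raise KeyError(
                f"unknown covariate {covariate!r}; have {self.spec.covariate_names}"
            )
        return self.spec.n_strata * self.spec.n_coef + k

    def beta_se(self, covariate: str) -> float:
        """Wald standard error of one shift coefficient (free == natural)."""
        if self.vcov is None:
            raise ValueError("fit was run without covariance computation")
        i = self.beta_index(covariate)
        return float(np.sqrt(max(self.vcov[i, i], 0.0)))


def _initial_free(data, spec: ModelSpec, fp: FreeParameterization) -> np.ndarray:
    """Data-adaptive start: theta from the link transform of the pooled
    empirical CDF at the basis knots, beta at zero."""
    link = get_link(spec.link)
    vals = []
    w = spec.window
    for obs in data:
        if obs.is_exact:
            vals.append(obs.exact)
        else:
            lo = w.hard_lower if obs.lower is None else obs.lower
            hi = w.hard_upper if obs.upper is None else obs.upper
            lo = max(lo, w.lower)
            hi = min(hi, w.upper)
            vals.append(0.5 * (lo + hi) if lo < hi else min(lo, w.upper))
    vals = np.asarray(vals, dtype=float)
    m = spec.n_coef
    if spec.basis.kind == "step":
        knots = np.asarray(spec.basis.cutoffs)
    else:
        knots = w.lower + np.arange(m) / (m - 1) * w.width
    ecdf = np.clip(
        np.array([np.mean(vals <= k) for k in knots]), 1.0 / (len(vals) + 1), 0.99
    )
    theta0 = link.forward(ecdf)
    theta0 = np.maximum.accumulate(theta0) + 1e-3 * np.arange(m)
    params0 = ParameterVector(np.tile(theta0, (spec.n_strata, 1)), np.zeros(spec.n_cov))
    return fp.to_free(params0, min_increment=1e-3)


def _numeric_hessian(fun_grad, free, step_scale):
    p = free.size
    H = np.empty((p, p))
    for j in range(p):
        h = step_scale * (1.0 + abs(free[j]))
        fp_ = free.copy(); fp_[j] += h
        fm_ = free.copy(); fm_[j] -= h
        gp = fun_grad(fp_)[1]
        gm = fun_grad(fm_)[1]
        H[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit(data, spec: ModelSpec, init: ParameterVector | None = None,
        options: FitOptions | None = None) -> FitResult:
    """Constrained MLE of all parameters simultaneously.

    All intercept blocks and shift coefficients are estimated jointly in
    the softplus-free parameterization: quasi-Newton (L-BFGS) with the
    analytic gradient, followed by Newton polishing steps on the
    numerically differentiated Hessian.  Covariate columns are rescaled
    to unit spread internally for conditioning and mapped back before
    reporting.  Non-convergence is flagged on the result, not raised.
    """
    data = list(data)
    options = options or FitOptions()
    fp = FreeParameterization(spec)
    packed = _Packed(data, spec)
    if np.any(packed.strata_counts == 0):
        empty = [s for s, c in zip(spec.strata, packed.strata_counts) if c == 0]
        raise ValueError(f"strata with no observations: {empty}")
    _check_design_rank(packed, spec)

    # internal covariate scaling (undone below): X -> X / s, beta -> beta * s
    if spec.n_cov:
        scale = np.vstack([packed.Xe, packed.Xi]).std(axis=0)
        scale[~(scale > 1e-12)] = 1.0
        packed.Xe = packed.Xe / scale
        packed.Xi = packed.Xi / scale
    else:
        scale = np.zeros(0)

    if init is not None:
        free0 = fp.to_free(
            ParameterVector(init.theta, np.asarray(init.beta) * scale)
        )
    else:
        free0 = _initial_free(data, spec, fp)

    def fun(free):
        nll, grad, _ = _negloglik_grad(free, packed, spec, fp, options.prob_floor)
        return nll, grad

    res = minimize(
        fun,
        free0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": options.maxiter, "ftol": 1e-13, "gtol": 1e-9,
                 "maxcor": 30},
    )
    x = res.x
    nll, grad, _ = _negloglik_grad(x, packed, spec, fp, options.prob_floor)
    tol = options.gtol * (1.0 + abs(nll))

    # Newton polish: L-BFGS alone creeps on ill-conditioned problems
    H = None
    n_newton = 0
    for _ in range(options.newton_maxiter):
        if float(np.max(np.abs(grad), initial=0.0)) <= tol:
            break
        H = _numeric_hessian(fun, x, options.hessian_step)
        step = _newton_step(H, grad)
        if step is None:
            break
        new_x, new_nll, new_grad, ok = _line_search(fun, x, nll, grad, step)
        if not ok:
            break
        x, nll, grad = new_x, new_nll, new_grad
        tol = options.gtol * (1.0 + abs(nll))
        n_newton += 1

    nll, grad, n_floored = _negloglik_grad(x, packed, spec, fp, options.prob_floor)
    grad_norm = float(np.max(np.abs(grad))) if grad.size else 0.0
    # relative gradient criterion: an absolute inf-norm tolerance is not
    # attainable in double precision when the log-likelihood is O(n)
    converged = bool(grad_norm <= options.gtol * (1.0 + abs(nll)))
    params_scaled = fp.to_natural(x)
    # step intercepts escaping to +/-inf indicate separation (e.g. a
    # category with no events); for smooth bases, large tail
    # coefficients merely reflect weak identification beyond the data
    # and are not an error
    diverged = spec.basis.kind == "step" and bool(
        np.max(np.abs(params_scaled.theta)) > options.divergence_bound
    )
    if diverged:
        converged = False

    vcov = None
    if options.compute_vcov:
        if H is None or n_newton == 0:
            H = _numeric_hessian(fun, x, options.hessian_step)
        vcov = _psd_inverse(H)

    # undo the internal covariate scaling
    nb = spec.n_cov
    free_out = x.copy()
    if nb:
        free_out[-nb:] = free_out[-nb:] / scale
        if vcov is not None:
            T = np.ones(free_out.size)
            T[-nb:] = 1.0 / scale
            vcov = vcov * np.outer(T, T)
    params = fp.to_natural(free_out)

    return FitResult(
        params=params,
        loglik=-nll,
        vcov=vcov,
        converged=converged,
        n_iter=int(res.nit) + n_newton,
        n_obs=packed.n_obs,
        spec=spec,
        free_params=free_out,
        n_floored=n_floored,
        grad_norm=grad_norm,
        message=("divergence: intercept escaped to +/-inf (separation?); "
                 if diverged else "") + str(res.message),
    )


def _psd_inverse(H):
    """Inverse of the Hessian with eigenvalues floored at a small
    positive multiple of the largest one: weakly identified (flat or
    noise-negative) directions get large positive variances instead of
    corrupting the whole matrix."""
    lam, Q = np.linalg.eigh(0.5 * (H + H.T))
    top = float(lam.max(initial=0.0))
    if top <= 0.0:
        return np.full_like(H, np.nan)
    lam = np.maximum(lam, 1e-9 * top)
    return (Q / lam) @ Q.T


def _newton_step(H, grad, max_norm: float = 20.0):
    """Modified-Newton descent step: eigenvalues floored to keep the
    direction downhill even on flat or slightly indefinite Hessians
    (weakly identified tail coefficients), step length capped."""
    try:
        lam, Q = np.linalg.eigh(H)
    except np.linalg.LinAlgError:
        return None
    floor = max(1e-6 * float(lam.max(initial=0.0)), 1e-8)
    lam = np.maximum(lam, floor)
    step = -Q @ ((Q.T @ grad) / lam)
    norm = np.linalg.norm(step)
    if norm > max_norm:
        step = step * (max_norm / norm)
    if step @ grad >= 0:
        return None
    return step


def _line_search(fun, x, nll, grad, step, max_halvings: int = 30):
    """Backtracking (Armijo) line search along a descent direction."""
    slope = float(grad @ step)
    t = 1.0
    for _ in range(max_halvings):
        try:
            new_nll, new_grad = fun(x + t * step)
        except FloatingPointError:
            t *= 0.5
            continue
        if np.isfinite(new_nll) and new_nll <= nll + 1e-4 * t * slope:
            return x + t * step, new_nll, new_grad, True
        t *= 0.5
    return x, nll, grad, False


def _check_design_rank(packed: _Packed, spec: ModelSpec) -> None:
    if spec.n_cov == 0:
        return
    X = np.vstack([packed.Xe, packed.Xi])
    S = np.concatenate([packed.se, packed.si])
    D = np.zeros((X.shape[0], spec.n_strata))
    D[np.arange(X.shape[0]), S] = 1.0
    full = np.hstack([D, X])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError(
            "rank-deficient design: covariate columns are collinear with "
            "each other or with the stratum intercepts"
        )


def fit_binary_reduction(data, cutoff: float, spec: ModelSpec,
                         options: FitOptions | None = None) -> FitResult:
    """Binary logistic regression as the single-cutoff special case.

    Every observation is reduced to the indicator Y <= cutoff and the
    model refitted with a one-cutoff step intercept; coefficients agree
    with standard binary logistic regression on the dichotomized data.
    """
    w = spec.window
    if not (w.hard_lower < cutoff < w.hard_upper):
        raise ValueError("cutoff must lie strictly inside the hard bounds")
    reduced = []
    for obs in data:
        if obs.is_exact:
            below = obs.exact <= cutoff
        else:
            lo = w.hard_lower if obs.lower is None else obs.lower
            hi = w.hard_upper if obs.upper is None else obs.upper
            if hi <= cutoff:
                below = True
            elif lo >= cutoff:
                below = False
            else:
                raise ValueError(
                    f"interval ({lo}, {hi}] straddles the cutoff {cutoff} and "
                    "cannot be reduced to a binary outcome"
                )
        reduced.append(
            Observation(
                stratum=obs.stratum,
                x=obs.x,
                lower=None if below else cutoff,
                upper=cutoff if below else None,
                weight=obs.weight,
            )
        )
    step_spec = ModelSpec(
        strata=spec.strata,
        covariate_names=spec.covariate_names,
        basis=StepBasis((cutoff,), w),
        link=spec.link,
    )
    return fit(reduced, step_spec, options=options)
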