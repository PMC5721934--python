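"""Monotone bases over outcome values.

A transformation model parameterizes the conditional log-odds of
``Y <= b`` as a monotone function of the outcome ``b``.  Two bases are
provided:

* :class:`BernsteinBasis` — Bernstein polynomials of a given order on a
  finite support window.  With non-decreasing coefficients the resulting
  polynomial is non-decreasing, which is the constraint structure used
  for smooth intercept functions.
* :class:`StepBasis` — indicator (one-hot) functions at fixed category
  boundaries, the parameterization underlying proportional-odds
  regression on ad hoc categories.

Outside the support window the Bernstein response is continued linearly
(endpoint value plus endpoint slope), which keeps the transformation
monotone and defined for every positive outcome value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb

__all__ = [
    "SupportWindow",
    "BernsteinBasis",
    "StepBasis",
    "support_from_data",
]


@dataclass(frozen=True)
class SupportWindow:
    """Finite interval on which a basis is defined, inside hard bounds.

    ``hard_lower``/``hard_upper`` are the theoretical bounds of the
    outcome (0 and +inf for BMI); the CDF is pinned to 0 and 1 there.
    """

    lower: float
    upper: float
    hard_lower: float = 0.0
    hard_upper: float = np.inf

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("support window endpoints must be finite")
        if not self.lower < self.upper:
            raise ValueError(
                f"degenerate support window [{self.lower}, {self.upper}]"
            )
        if not (self.hard_lower <= self.lower and self.upper <= self.hard_upper):
            raise ValueError("support window must lie inside the hard bounds")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def support_from_data(
    values,
    prob: tuple[float, float] = (0.01, 0.99),
    add: tuple[float, float] = (-5.0, 5.0),
    hard_lower: float = 0.0,
    hard_upper: float = np.inf,
) -> SupportWindow:
    """Default support window: empirical quantiles of the observed
    outcome values widened by ``add`` units, clipped to the hard bounds.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite values to derive a support window from")
    lo, hi = np.quantile(values, prob)
    lo = max(lo + add[0], hard_lower)
    hi = min(hi + add[1], hard_upper)
    return SupportWindow(lo, hi, hard_lower, hard_upper)


def _bernstein_weights(t: np.ndarray, order: int) -> np.ndarray:
    """Bernstein basis B_{k,n}(t) = C(n,k) t^k (1-t)^(n-k), t in [0,1]."""
    k = np.arange(order + 1)
    t = t[..., None]
    return comb(order, k) * t**k * (1.0 - t) ** (order - k)


@dataclass(frozen=True)
class BernsteinBasis:
    """Bernstein polynomial basis of a given order on a support window.

    ``order + 1`` coefficients; non-decreasing coefficients imply a
    non-decreasing response.  Evaluation outside the window continues
    linearly from the nearest endpoint.
    """

    order: int
    window: SupportWindow

    kind = "bernstein"

    def __post_init__(self) -> None:
        if not (isinstance(self.order, (int, np.integer)) and self.order >= 1):
            raise ValueError("Bernstein order must be an integer >= 1")

    @property
    def n_coef(self) -> int:
        return self.order + 1

    def _scaled(self, b):
        b = np.asarray(b, dtype=float)
        if not np.all(np.isfinite(b)):
            raise ValueError("basis evaluation requires finite outcome values")
        return b, (b - self.window.lower) / self.window.width

    def eval(self, b) -> np.ndarray:
        """Basis weights at outcome value(s) ``b``; shape (..., order+1).

        Inside the window the weights are nonnegative and sum to one;
        outside, they are the linear continuation
        ``w(endpoint) + (b - endpoint) * w'(endpoint)``.
        """
        b, t = self._scaled(b)
        tc = np.clip(t, 0.0, 1.0)
        w = _bernstein_weights(tc, self.order)
        overshoot = b - np.clip(b, self.window.lower, self.window.upper)
        if np.any(overshoot != 0.0):
            w = w + overshoot[..., None] * self._deriv_clipped(tc)
        return w

    def _deriv_clipped(self, tc: np.ndarray) -> np.ndarray:
        n = self.order
        lower = _bernstein_weights(tc, n - 1) if n >= 1 else None
        k = np.arange(n + 1)
        d = np.zeros(tc.shape + (n + 1,))
        # d/dt B_{k,n} = n (B_{k-1,n-1} - B_{k,n-1})
        d[..., 1:] += n * lower
        d[..., :-1] -= n * lower
        return d / self.window.width

    def deriv(self, b) -> np.ndarray:
        """Derivative of each basis function w.r.t. ``b``.

        Constant (endpoint) derivative outside the window, so the linear
        continuation of :meth:`eval` is consistent.  Rows sum to zero.
        """
        _, t = self._scaled(b)
        return self._deriv_clipped(np.clip(t, 0.0, 1.0))

    def constraint_matrix(self) -> np.ndarray:
        """Rows c with c @ theta >= 0 encoding non-decreasing coefficients."""
        return _difference_matrix(self.n_coef)


@dataclass(frozen=True)
class StepBasis:
    """One-hot basis at fixed category boundaries (proportional odds).

    The step model is only defined at its cutoffs: evaluating anywhere
    else is a usage error, because between boundaries the categorical
    model carries no information.
    """

    cutoffs: tuple
    window: SupportWindow

    kind = "step"

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cutoffs)
        object.__setattr__(self, "cutoffs", cuts)
        if len(cuts) < 1:
            raise ValueError("step basis needs at least one cutoff")
        if not all(a < b for a, b in zip(cuts, cuts[1:])):
            raise ValueError("step cutoffs must be strictly increasing")
        w = self.window
        if not (w.hard_lower < cuts[0] and cuts[-1] < w.hard_upper):
            raise ValueError("cutoffs must lie strictly inside the hard bounds")

    @property
    def n_coef(self) -> int:
        return len(self.cutoffs)

    def eval(self, b) -> np.ndarray:
        b = np.asarray(b, dtype=float)
        if not np.all(np.isfinite(b)):
            raise ValueError("basis evaluation requires finite outcome values")
        cuts = np.asarray(self.cutoffs)
        match = np.isclose(b[..., None], cuts, rtol=0.0, atol=1e-9)
        if not np.all(match.any(axis=-1)):
            bad = np.asarray(b)[~match.any(axis=-1)]
            raise ValueError(
                f"step basis evaluated away from its cutoffs: {bad!r}; "
                "categorical models are only defined at category boundaries"
            )
        return match.astype(float)

    def deriv(self, b) -> np.ndarray:
        raise ValueError(
            "step basis has no derivative: densities are undefined for "
            "purely categorical intercept functions"
        )

    def constraint_matrix(self) -> np.ndarray:
        return _difference_matrix(self.n_coef)


def _difference_matrix(m: int) -> np.ndarray:
    d = np.zeros((m - 1, m))
    idx = np.arange(m - 1)
    d[idx, idx] = -1.0
    d[idx, idx + 1] = 1.0
    return d
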