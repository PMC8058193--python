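"""Closed-form algebra for polynomial-times-exponential curves.

Every continuous curve in this package -- the arterial input model, the
two-tissue compartment solutions, and the regional brain model -- is a finite
sum of terms ``c * u**n * exp(-lam*u)`` in the delayed time variable
``u = t - shift`` (zero before the delay).  This family is closed under

* running integration from zero,
* convolution with a decaying exponential,

which means every frame average the kinetic models need is an exact
antiderivative evaluation rather than a quadrature.  The optimizers call the
frame operators thousands of times, so this is also the performance core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

__all__ = ["ExpPolySum", "frame_average_numeric"]

# Rates closer than this (1/min) use the confluent t*exp limit instead of the
# generic partial-fraction form, which would otherwise lose all precision.
RATE_COLLISION_TOL = 1e-9


def _antiderivative_terms(c: float, n: int, lam: float) -> list[tuple[float, int, float]]:
    """Terms of ``int_0^u c s^n exp(-lam s) ds`` as an ExpPolySum term list."""
    if lam == 0.0:
        return [(c / (n + 1), n + 1, 0.0)]
    out: list[tuple[float, int, float]] = [(c * math.factorial(n) / lam ** (n + 1), 0, 0.0)]
    for j in range(n + 1):
        coef = -c * math.factorial(n) / (math.factorial(n - j) * lam ** (j + 1))
        out.append((coef, n - j, lam))
    return out


def _convolve_term_exp(c: float, n: int, lam: float, beta: float) -> list[tuple[float, int, float]]:
    """Terms of ``(c u^n e^{-lam u}) conv (e^{-beta u})`` on u >= 0."""
    mu = beta - lam
    if abs(mu) < RATE_COLLISION_TOL:
        # confluent limit: integrand exponentials cancel
        return [(c / (n + 1), n + 1, beta)]
    out: list[tuple[float, int, float]] = []
    for j in range(n + 1):
        coef = (-1.0) ** j * c * math.factorial(n) / (math.factorial(n - j) * mu ** (j + 1))
        out.append((coef, n - j, lam))
    out.append(((-1.0) ** (n + 1) * c * math.factorial(n) / mu ** (n + 1), 0, beta))
    return out


@dataclass(frozen=True)
class ExpPolySum:
    """Sum of ``c * u**n * exp(-lam*u)`` terms with ``u = t - shift``, zero for t < shift.

    Parameters
    ----------
    terms
        Sequence of ``(coefficient, power, rate)`` triples.  Powers are
        non-negative integers; rates are in 1/min and must be >= 0 for the
        closed-form integrals to stay finite at large t.
    shift
        Appearance delay in minutes (``tau`` for an arterial input).
    """

    terms: tuple[tuple[float, int, float], ...]
    shift: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "terms",
            tuple((float(c), int(n), float(lam)) for c, n, lam in self.terms),
        )

    # -- evaluation ---------------------------------------------------------

    def __call__(self, t: float | np.ndarray) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        u = np.maximum(t - self.shift, 0.0)
        out = np.zeros_like(u)
        for c, n, lam in self.terms:
            out += c * u**n * np.exp(-lam * u)
        out = np.where(t >= self.shift, out, 0.0)
        return out if out.ndim else float(out)

    def _F(self, u: np.ndarray) -> np.ndarray:
        """Antiderivative ``int_0^u`` of the u-domain sum, vectorized."""
        out = np.zeros_like(u)
        for c, n, lam in self.terms:
            for cc, nn, ll in _antiderivative_terms(c, n, lam):
                out += cc * u**nn * np.exp(-ll * u)
        return out

    def definite_integral(
        self, a: float | np.ndarray, b: float | np.ndarray
    ) -> np.ndarray | float:
        """Exact ``int_a^b f(t) dt`` (kBq/cc * min), vectorized over frame edges."""
        ua = np.maximum(np.asarray(a, dtype=float) - self.shift, 0.0)
        ub = np.maximum(np.asarray(b, dtype=float) - self.shift, 0.0)
        out = self._F(ub) - self._F(ua)
        return out if out.ndim else float(out)

    # -- calculus -----------------------------------------------------------

    def cumulative(self) -> "ExpPolySum":
        """The running integral ``t -> int_0^t f``, again an ExpPolySum."""
        terms: list[tuple[float, int, float]] = []
        for c, n, lam in self.terms:
            terms.extend(_antiderivative_terms(c, n, lam))
        return ExpPolySum(tuple(terms), self.shift)._compacted()

    def convolve_exp(self, beta: float) -> "ExpPolySum":
        """Convolution ``(f conv e^{-beta t})(t)`` for beta >= 0."""
        terms: list[tuple[float, int, float]] = []
        for c, n, lam in self.terms:
            terms.extend(_convolve_term_exp(c, n, lam, beta))
        return ExpPolySum(tuple(terms), self.shift)._compacted()

    # -- algebra ------------------------------------------------------------

    def __mul__(self, scalar: float) -> "ExpPolySum":
        return ExpPolySum(tuple((c * scalar, n, lam) for c, n, lam in self.terms), self.shift)

    __rmul__ = __mul__

    def __add__(self, other: "ExpPolySum") -> "ExpPolySum":
        if abs(other.shift - self.shift) > 1e-12:
            raise ValueError("cannot add curves with different appearance delays")
        return ExpPolySum(self.terms + other.terms, self.shift)._compacted()

    def _compacted(self) -> "ExpPolySum":
        merged: dict[tuple[int, float], float] = {}
        for c, n, lam in self.terms:
            merged[(n, lam)] = merged.get((n, lam), 0.0) + c
        terms = tuple((c, n, lam) for (n, lam), c in merged.items() if c != 0.0)
        return ExpPolySum(terms or ((0.0, 0, 0.0),), self.shift)

    # -- frame operators ----------------------------------------------------

    def frame_average(
        self, starts: Sequence[float] | np.ndarray, ends: Sequence[float] | np.ndarray
    ) -> np.ndarray:
        """Per-frame mean value: ``int_{tb}^{te} f / (te - tb)``."""
        starts = np.asarray(starts, dtype=float)
        ends = np.asarray(ends, dtype=float)
        return self.definite_integral(starts, ends) / (ends - starts)

    def auc(self, t_end: float, t_start: float = 0.0) -> float:
        """Area under the curve on ``[t_start, t_end]`` in value*min units."""
        return float(self.definite_integral(t_start, t_end))

    def peak(self, t_lo: float, t_hi: float, n_grid: int = 2001) -> tuple[float, float]:
        """(time, value) of the maximum on [t_lo, t_hi]: grid scan plus local refine."""
        grid = np.linspace(max(t_lo, self.shift), t_hi, n_grid)
        vals = self(grid)
        i = int(np.argmax(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, n_grid - 1)]
        if hi > lo:
            res = minimize_scalar(lambda t: -self(t), bounds=(lo, hi), method="bounded")
            if -res.fun >= vals[i]:
                return float(res.x), float(-res.fun)
        return float(grid[i]), float(vals[i])


def frame_average_numeric(f, t_b: float, t_e: float, tol: float = 1e-8) -> float:
    """Frame average of an arbitrary integrable callable by adaptive quadrature.

    Fallback for curves with no closed form; ``tol`` is the absolute
    quadrature tolerance on the integral before division by the frame width.
    """
    if t_b >= t_e:
        raise ValueError(f"invalid frame: t_b={t_b} >= t_e={t_e}")
    val, _ = quad(f, t_b, t_e, epsabs=tol, limit=200)
    return val / (t_e - t_b)
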