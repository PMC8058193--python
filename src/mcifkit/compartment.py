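"""Two-tissue compartment model: forward solutions, Ki, and graphical oracles.

Tracer exchanges between arterial blood (concentration Ca), a free/
transportable tissue pool C1 and a phosphorylated (trapped) pool C2:

    dC1/dt = K1*Ca - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2,          C_T = C1 + C2.

For FDG the dephosphorylation rate k4 is zero (irreversible trapping) and
the net uptake rate constant is Ki = K1*k3/(k2+k3): the fraction of
delivered tracer that is phosphorylated rather than washed out.  With a
sum-of-exponentials input the convolution solution is closed-form; a stiff
ODE integration and the Patlak graphical slope are provided as independent
numerical routes for validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .expsum import ExpPolySum, RATE_COLLISION_TOL
from .input_function import FengInput
from .tac import TimeActivityCurve

__all__ = [
    "TwoTissueParams",
    "tissue_curve",
    "solve_tissue",
    "solve_tissue_ode",
    "ki_from_micro",
    "patlak_slope",
]


@dataclass(frozen=True)
class TwoTissueParams:
    """Rate constants in 1/min (K1 formally ml/min/cc); k4 = 0 means irreversible."""

    K1: float
    k2: float
    k3: float
    k4: float = 0.0

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3, self.k4) < 0:
            raise ValueError("rate constants must be non-negative")


def _as_curve(input_model) -> ExpPolySum:
    if isinstance(input_model, ExpPolySum):
        return input_model
    if hasattr(input_model, "curve"):
        return input_model.curve()
    raise TypeError("input must be an ExpPolySum or expose .curve()")


def tissue_curve(params: TwoTissueParams, input_model) -> ExpPolySum:
    """Closed-form C_T(t) = (Ca conv h)(t) as an ExpPolySum.

    Irreversible branch (k4 = 0):
        C_T = [K1 k3/(k2+k3)] * int_0^t Ca  +  [K1 k2/(k2+k3)] * (Ca conv e^{-(k2+k3)t})
    with the degenerate k2+k3 = 0 case collapsing to pure accumulation
    C_T = K1 * int_0^t Ca.  Reversible branch uses the standard
    two-exponential impulse response with eigenvalues
    alpha_{1,2} = [(k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4 k2 k4)] / 2.
    """
    ca = _as_curve(input_model)
    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    if K1 == 0.0:
        return ExpPolySum(((0.0, 0, 0.0),), ca.shift)
    if k4 == 0.0:
        s = k2 + k3
        if s < RATE_COLLISION_TOL:
            return K1 * ca.cumulative()
        out = (K1 * k3 / s) * ca.cumulative()
        if k2 > 0.0:
            out = out + (K1 * k2 / s) * ca.convolve_exp(s)
        return out
    disc = (k2 + k3 + k4) ** 2 - 4.0 * k2 * k4
    alpha1 = 0.5 * ((k2 + k3 + k4) - np.sqrt(max(disc, 0.0)))
    alpha2 = 0.5 * ((k2 + k3 + k4) + np.sqrt(max(disc, 0.0)))
    if alpha2 - alpha1 < RATE_COLLISION_TOL:
        # equal-eigenvalue point is measure-zero; nudge off it
        return tissue_curve(TwoTissueParams(K1, k2, k3, k4 + 1e-9), input_model)
    c1 = K1 * (k3 + k4 - alpha1) / (alpha2 - alpha1)
    c2 = K1 * (alpha2 - k3 - k4) / (alpha2 - alpha1)
    return c1 * ca.convolve_exp(alpha1) + c2 * ca.convolve_exp(alpha2)


def solve_tissue(params: TwoTissueParams, input_model, t) -> np.ndarray | float:
    """Evaluate the closed-form tissue concentration C_T at times t (min)."""
    return tissue_curve(params, input_model)(t)


def solve_tissue_ode(
    params: TwoTissueParams, input_model, t, rtol: float = 1e-10, atol: float = 1e-12
) -> np.ndarray:
    """Reference C_T by stiff numerical integration of the compartment ODEs.

    Independent of the closed-form path (direct LSODA integration of the
    state equations); intended for validation, not production fitting.
    """
    ca = _as_curve(input_model)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4

    def rhs(tt, yy):
        c1, c2 = yy
        cin = ca(tt)
        return [K1 * cin - (k2 + k3) * c1 + k4 * c2, k3 * c1 - k4 * c2]

    t_end = float(t.max()) if t.size else 0.0
    sol = solve_ivp(
        rhs, (0.0, max(t_end, 1e-9)), [0.0, 0.0], t_eval=np.sort(t),
        method="LSODA", rtol=rtol, atol=atol, max_step=0.05,
    )
    if not sol.success:
        raise RuntimeError(f"ODE oracle failed: {sol.message}")
    ct = sol.y[0] + sol.y[1]
    return ct[np.argsort(np.argsort(t))]


def ki_from_micro(params: TwoTissueParams) -> float:
    """Net uptake rate constant Ki = K1*k3/(k2+k3) in 1/min."""
    s = params.k2 + params.k3
    if s <= 0:
        raise ValueError("Ki undefined: k2 + k3 must be positive")
    return params.K1 * params.k3 / s


def patlak_slope(tissue: TimeActivityCurve, input_model, t_star: float) -> float:
    """Patlak graphical influx slope from frames with midpoint >= t_star.

    Regresses C_T(t)/Ca(t) on [int_0^t Ca]/Ca(t) at frame midpoints; for an
    irreversible tracer the late-time slope equals Ki.  Requires at least
    three qualifying frames.
    """
    ca = _as_curve(input_model)
    mids = tissue.schedule.midpoints
    mask = mids >= t_star
    if int(mask.sum()) < 3:
        raise ValueError(f"need >= 3 frames with midpoint >= {t_star} min")
    t = mids[mask]
    ca_t = np.asarray(ca(t))
    x = np.asarray(ca.cumulative()(t)) / ca_t
    y = tissue.values[mask] / ca_t
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)
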