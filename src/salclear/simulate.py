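"""Trajectory simulation for the clearance models.

The first-order and M-M models have closed-form solutions and never touch
an integrator.  The enzyme scheme is stiff by construction: with
kon1 = 3 L/(mg*s) and ETOT = 1.5e-4 mg/L the binding/unbinding relaxation
is sub-second while clearance plays out over hours, so the default solver
is LSODA with an analytic Jacobian, rtol 1e-8 and a 1e-12 absolute floor
on the (tiny) complex concentration.  Observation times are evaluated by
the integrator's own continuous extension, so they need not coincide with
solver steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import (
    EnzymeParams,
    FirstOrderParams,
    MMParams,
    derive_mm_from_enzyme,
    first_order_solution,
    mm_rate,
    mm_solution,
)

__all__ = [
    "Trajectory",
    "IntegrationError",
    "simulate",
    "flux_curve",
    "occupancy_curve",
]

MODEL_IDS = ("first_order", "mm", "enzyme")


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to meet its tolerances."""


@dataclass
class Trajectory:
    """Model solution sampled on an ascending time grid.

    S is always present; SE, E and P only for the enzyme model (None
    otherwise, flagged not-applicable).
    """

    model_id: str
    times: np.ndarray
    S: np.ndarray
    SE: np.ndarray | None = None
    E: np.ndarray | None = None
    P: np.ndarray | None = None
    params: object = field(default=None, repr=False)

    @property
    def is_enzyme(self) -> bool:
        return self.model_id == "enzyme"

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_h": self.times, "S_mg_L": self.S}
        if self.is_enzyme:
            cols.update(SE_mg_L=self.SE, E_mg_L=self.E, P_mg_L=self.P)
        return pd.DataFrame(cols)


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if times[0] < 0:
        raise ValueError("times must start at >= 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return times


def _enzyme_system(p: EnzymeParams, strict: bool):
    a1, b1, b2, a2 = p.hourly_rates()
    ETOT, G = p.ETOT, p.G
    rebind = 0.0 if strict else 1.0

    def rhs(t, y):
        S, SE, P = y
        E = ETOT - SE
        bind = a1 * S * E
        rebindflux = a2 * P * E
        dS = -bind + b1 * SE
        dSE = bind - (b1 + b2) * SE + rebind * rebindflux
        dP = -rebindflux + b2 * SE - G * P
        return (dS, dSE, dP)

    def jac(t, y):
        S, SE, P = y
        E = ETOT - SE
        return np.array(
            [
                [-a1 * E, a1 * S + b1, 0.0],
                [a1 * E, -a1 * S - rebind * a2 * P - (b1 + b2), rebind * a2 * E],
                [0.0, a2 * P + b2, -a2 * E - G],
            ]
        )

    return rhs, jac


def simulate(
    model_id: str,
    params,
    times,
    *,
    rtol: float = 1e-8,
    atol_conc: float = 1e-10,
    atol_complex: float = 1e-12,
    method: str = "LSODA",
    strict_mass_balance: bool = False,
) -> Trajectory:
    """Integrate (or evaluate) a clearance model on an ascending time grid.

    Initial conditions are S(0) = S0, SE(0) = 0, P(0) = 0; the trajectory
    always starts from t = 0 even when the first requested time is later.
    Solver failure raises :class:`IntegrationError` rather than returning
    a partial trajectory.
    """
    times = _check_times(times)
    if model_id == "first_order":
        if not isinstance(params, FirstOrderParams):
            raise TypeError("first_order model requires FirstOrderParams")
        return Trajectory("first_order", times, first_order_solution(params, times), params=params)
    if model_id == "mm":
        if not isinstance(params, MMParams):
            raise TypeError("mm model requires MMParams")
        return Trajectory("mm", times, np.atleast_1d(mm_solution(params, times)), params=params)
    if model_id != "enzyme":
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")

    if not isinstance(params, EnzymeParams):
        raise TypeError("enzyme model requires EnzymeParams")
    y0 = np.array([params.S0, 0.0, 0.0])
    if times[-1] == 0.0:
        S = np.array([params.S0])
        SE = np.zeros(1)
        P = np.zeros(1)
    else:
        rhs, jac = _enzyme_system(params, strict_mass_balance)
        sol = solve_ivp(
            rhs,
            (0.0, times[-1]),
            y0,
            method=method,
            t_eval=times,
            jac=jac,
            rtol=rtol,
            atol=np.array([atol_conc, atol_complex, atol_conc]),
        )
        if not sol.success:
            raise IntegrationError(f"enzyme ODE integration failed: {sol.message}")
        S, SE, P = sol.y
        # solver overshoot below zero is tolerated only at noise level
        floor = -1e3 * max(atol_conc, rtol * params.S0)
        if S.min() < floor or SE.min() < floor or P.min() < floor:
            raise IntegrationError("integration produced significantly negative state")
        S, SE, P = (np.clip(v, 0.0, None) for v in (S, SE, P))
    return Trajectory(
        "enzyme", times, S, SE=SE, E=params.ETOT - SE, P=P, params=params
    )


def flux_curve(params, S_grid) -> tuple[np.ndarray, np.ndarray]:
    """Clearance flux magnitude |dS/dt| versus substrate concentration.

    For M-M parameters this is the rate law itself (crosses Vmax/2 exactly
    at S = Km); for enzyme parameters the effective M-M constants from
    :func:`derive_mm_from_enzyme` are used (product-free flux).
    """
    S_grid = np.asarray(S_grid, dtype=float)
    if np.any(S_grid < 0):
        raise ValueError("S_grid must be non-negative")
    if isinstance(params, EnzymeParams):
        d = derive_mm_from_enzyme(params)
        params = MMParams(Vmax=d.Vmax, Km=d.Km, S0=max(float(S_grid.max()), 1.0))
    if not isinstance(params, MMParams):
        raise TypeError("flux_curve needs MMParams or EnzymeParams")
    return S_grid, np.abs(mm_rate(S_grid, params))


def occupancy_curve(traj: Trajectory, ETOT: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(time, SE/ETOT, E/ETOT) for an enzyme trajectory; fractions sum to 1."""
    if not traj.is_enzyme or traj.SE is None:
        raise ValueError("occupancy_curve requires an enzyme-model trajectory")
    bound = traj.SE / ETOT
    return traj.times, bound, 1.0 - bound
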