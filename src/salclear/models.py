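"""Kinetic models of plasma salicylate clearance.

Three nested descriptions of the disappearance of salicylate (S) from
plasma after an oral aspirin dose:

1. a first-order washout, ``dS/dt = -k*S``, the standard single-exponential
   pharmacokinetic model;
2. the irreversible Briggs-Haldane / Michaelis-Menten (M-M) rate law,
   ``dS/dt = -Vmax*S/(Km+S)``, zero-order at high dose and first-order at
   low dose;
3. a mass-action enzyme scheme with reversible product binding,
   ``S + E <-> SE -> E + P`` with P able to rebind the enzyme and an
   optional first-order consumption of P at rate G.

Canonical internal units are mg/L for concentrations and hours for time.
Bimolecular and unimolecular rate constants (``kon1``, ``koff1``,
``koff2``, ``kon2``) are entered *per second*, as enzyme-kinetics tables
quote them, and converted exactly once at the type boundary (x3600); all
derived velocities are in mg/(L*hour).  This module is pure algebra and
right-hand sides: no integration, no file I/O.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Union

import numpy as np

__all__ = [
    "SECONDS_PER_HOUR",
    "MINUTES_PER_HOUR",
    "FirstOrderParams",
    "MMParams",
    "EnzymeParams",
    "EnzymeState",
    "DerivedParams",
    "HofmeyrParams",
    "first_order_solution",
    "half_life_from_k",
    "mm_rate",
    "mm_solution",
    "enzyme_rhs",
    "derive_mm_from_enzyme",
    "derive_rates_from_affinities",
    "hofmeyr_flux",
    "equilibrium_ratio",
    "estimate_vmax_two_point",
    "estimate_rate_log_slope",
    "occupancy_fraction",
    "round_sig",
]

SECONDS_PER_HOUR = 3600.0
MINUTES_PER_HOUR = 60.0

ArrayLike = Union[float, np.ndarray]


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


def round_sig(x: float, n_sig: int) -> float:
    """Round ``x`` to ``n_sig`` significant figures (0 stays 0).

    Used only for reporting; full precision is always retained internally.
    """
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, n_sig - 1 - int(math.floor(math.log10(abs(x)))))


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FirstOrderParams:
    """First-order washout: initial concentration S0 (mg/L), rate k (1/h)."""

    S0: float
    k: float

    def __post_init__(self) -> None:
        _require(self.S0 > 0, f"S0 must be > 0, got {self.S0}")
        _require(self.k > 0, f"k must be > 0, got {self.k}")

    @property
    def thalf_minutes(self) -> float:
        return half_life_from_k(self.k)


@dataclass(frozen=True)
class MMParams:
    """Michaelis-Menten: Vmax in mg/(L*h), Km in mg/L, S0 in mg/L."""

    Vmax: float
    Km: float
    S0: float

    def __post_init__(self) -> None:
        for name in ("Vmax", "Km", "S0"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")


@dataclass(frozen=True)
class EnzymeParams:
    """Reversible enzyme scheme S + E <-> SE -> E + P (+ P rebinding).

    Parameters
    ----------
    kon1 : float
        Substrate binding rate, L/(mg*sec).
    koff1 : float
        Complex dissociation back to free S, 1/sec.
    koff2 : float
        Catalytic release of product P, 1/sec.
    ETOT : float
        Total enzyme concentration, mg/L.
    S0 : float
        Initial substrate concentration of the simulated dose group, mg/L.
    kon2 : float
        Product rebinding rate, L/(mg*sec); 0 gives the irreversible limit.
    G : float
        First-order consumption of P (renal clearance surrogate), 1/hour.
        Defaults to 0: product accumulates.
    """

    kon1: float
    koff1: float
    koff2: float
    ETOT: float
    S0: float
    kon2: float = 0.0
    G: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kon1", "koff1", "koff2", "ETOT", "S0"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(self.kon2 >= 0, "kon2 must be >= 0")
        _require(self.G >= 0, "G must be >= 0")

    @property
    def KS(self) -> float:
        """Substrate dissociation constant koff1/kon1, mg/L."""
        return self.koff1 / self.kon1

    @property
    def KP(self) -> float:
        """Product dissociation constant koff2/kon2, mg/L (inf if kon2=0)."""
        if self.kon2 == 0:
            return math.inf
        return self.koff2 / self.kon2

    @classmethod
    def from_affinities(
        cls,
        KS: float,
        koff2: float,
        kon1: float,
        ETOT: float,
        S0: float,
        KP: float = math.inf,
        G: float = 0.0,
    ) -> "EnzymeParams":
        """Build from the fitted parameterisation (KS, KP, koff2).

        ``koff1 = KS*kon1`` and ``kon2 = koff2/KP``; an infinite KP gives
        the irreversible scheme (kon2 = 0).
        """
        _require(KS > 0, "KS must be > 0")
        _require(KP > 0, "KP must be > 0")
        kon2 = 0.0 if math.isinf(KP) else koff2 / KP
        return cls(
            kon1=kon1,
            koff1=KS * kon1,
            koff2=koff2,
            ETOT=ETOT,
            S0=S0,
            kon2=kon2,
            G=G,
        )

    def with_s0(self, S0: float) -> "EnzymeParams":
        return replace(self, S0=S0)

    def hourly_rates(self) -> tuple[float, float, float, float]:
        """(kon1, koff1, koff2, kon2) converted to per-hour units."""
        return (
            self.kon1 * SECONDS_PER_HOUR,
            self.koff1 * SECONDS_PER_HOUR,
            self.koff2 * SECONDS_PER_HOUR,
            self.kon2 * SECONDS_PER_HOUR,
        )


@dataclass(frozen=True)
class EnzymeState:
    """Instantaneous state (S, SE, P) in mg/L; free enzyme is algebraic."""

    S: float
    SE: float
    P: float

    def __post_init__(self) -> None:
        for name in ("S", "SE", "P"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")

    def free_enzyme(self, ETOT: float) -> float:
        """E = ETOT - SE (enzyme mass conservation)."""
        E = ETOT - self.SE
        _require(E >= 0, f"SE={self.SE} exceeds ETOT={ETOT}: corrupted state")
        return E


@dataclass(frozen=True)
class DerivedParams:
    """Michaelis-Menten constants and rate constants derived from a fit.

    ``Km = KS + koff2/kon1`` and ``Vmax = koff2*ETOT`` (converted to
    mg/(L*hour)); ``koff1 = KS*kon1`` and ``kon2 = koff2/KP`` invert the
    affinity definitions.  ``thalf_min`` only applies to the first-order
    model.
    """

    Km: float
    Vmax: float
    KS: float
    KP: float
    koff1: float
    kon2: float
    thalf_min: float | None = None


@dataclass(frozen=True)
class HofmeyrParams:
    """Reversible uni-uni rate law: Vfmax/Vrmax in mg/(L*h), Ks/Kp in mg/L."""

    Vfmax: float
    Vrmax: float
    Ks: float
    Kp: float

    def __post_init__(self) -> None:
        for name in ("Vfmax", "Vrmax", "Ks", "Kp"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def first_order_solution(p: FirstOrderParams, t: ArrayLike) -> ArrayLike:
    """S(t) = S0*exp(-k*t); t in hours, t >= 0."""
    t_arr = np.asarray(t, dtype=float)
    _require(bool(np.all(t_arr >= 0)), "t must be non-negative")
    out = p.S0 * np.exp(-p.k * t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def half_life_from_k(k: float) -> float:
    """Half-life in minutes from a first-order rate in 1/hour."""
    _require(k > 0, f"k must be > 0, got {k}")
    return MINUTES_PER_HOUR * math.log(2.0) / k


def mm_rate(S: ArrayLike, p: MMParams) -> ArrayLike:
    """dS/dt = -Vmax*S/(Km+S) in mg/(L*hour); magnitude < Vmax."""
    S_arr = np.asarray(S, dtype=float)
    _require(bool(np.all(S_arr >= 0)), "S must be non-negative")
    out = -p.Vmax * S_arr / (p.Km + S_arr)
    return float(out) if np.isscalar(S) or S_arr.ndim == 0 else out


def _mm_solution_scalar(S0: float, Vmax: float, Km: float, t: float) -> float:
    # exact implicit progress curve: S + Km*ln(S/S0) = S0 - Vmax*t,
    # monotone in S on (0, S0]; solved by bracketed root finding.
    from scipy.optimize import brentq

    if t == 0.0:
        return S0
    rhs = S0 - Vmax * t

    def phi(S: float) -> float:
        return S + Km * math.log(S / S0) - rhs

    lo = max(S0 * math.exp(-(S0 + Vmax * t) / Km), 1e-300)
    if phi(lo) >= 0.0:  # pragma: no cover - lo is constructed negative
        return lo
    return brentq(phi, lo, S0, xtol=1e-300, rtol=1e-15)


def mm_solution(p: MMParams, t: ArrayLike) -> ArrayLike:
    """Exact Michaelis-Menten progress curve S(t).

    Uses the implicit conservation form ``S + Km*ln(S/S0) = S0 - Vmax*t``
    (the closed-form integral of the rate law), solved per time point to
    near machine precision.  Exact zero-order and first-order limits fall
    out of the same expression.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    _require(bool(np.all(t_arr >= 0)), "t must be non-negative")
    out = np.array([_mm_solution_scalar(p.S0, p.Vmax, p.Km, ti) for ti in t_arr])
    return float(out[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else out


# ---------------------------------------------------------------------------
# enzyme scheme
# ---------------------------------------------------------------------------


def enzyme_rhs(
    state: EnzymeState, p: EnzymeParams, strict_mass_balance: bool = False
) -> tuple[float, float, float]:
    """Time derivatives (dS, dSE, dP) in mg/(L*hour).

    The default scheme includes the product-rebinding flux ``kon2*P*E`` in
    dSE/dt so that S + SE + P is exactly conserved when G = 0.  With
    ``strict_mass_balance=True`` the rebinding flux is removed from the
    complex balance (the literal published equation set), which leaks mass
    through product rebinding whenever kon2 > 0 and P > 0.
    """
    a1, b1, b2, a2 = p.hourly_rates()
    E = state.free_enzyme(p.ETOT)
    S, SE, P = state.S, state.SE, state.P
    dS = -a1 * S * E + b1 * SE
    dSE = a1 * S * E - (b1 + b2) * SE
    if not strict_mass_balance:
        dSE += a2 * P * E
    dP = -a2 * P * E + b2 * SE - p.G * P
    return (dS, dSE, dP)


def derive_mm_from_enzyme(p: EnzymeParams) -> DerivedParams:
    """Effective M-M constants: Km = KS + koff2/kon1, Vmax = koff2*ETOT.

    Vmax is converted to mg/(L*hour); Km stays in mg/L because kon1 and
    koff2 share the per-second time base.
    """
    _require(p.kon1 > 0, "kon1 must be > 0")
    return DerivedParams(
        Km=p.KS + p.koff2 / p.kon1,
        Vmax=p.koff2 * p.ETOT * SECONDS_PER_HOUR,
        KS=p.KS,
        KP=p.KP,
        koff1=p.koff1,
        kon2=p.kon2,
    )


def derive_rates_from_affinities(
    KS: float, KP: float, koff2: float, kon1: float
) -> tuple[float, float]:
    """(koff1, kon2) = (KS*kon1, koff2/KP), all in per-second units."""
    for name, val in (("KS", KS), ("KP", KP), ("koff2", koff2), ("kon1", kon1)):
        _require(val > 0, f"{name} must be > 0, got {val}")
    return KS * kon1, koff2 / KP


def hofmeyr_flux(S: ArrayLike, P: ArrayLike, h: HofmeyrParams) -> ArrayLike:
    """Net forward flux of the reversible uni-uni rate law, mg/(L*hour).

    ``-dS/dt = (Vfmax*S/Ks - Vrmax*P/Kp) / (1 + S/Ks + P/Kp)``: the
    denominator accounts for enzyme occupancy by both substrate and
    product.  Zero exactly when the unidirectional fluxes balance; reduces
    to the M-M form at P = 0.
    """
    S_arr = np.asarray(S, dtype=float)
    P_arr = np.asarray(P, dtype=float)
    _require(bool(np.all(S_arr >= 0)) and bool(np.all(P_arr >= 0)), "S, P must be >= 0")
    num = h.Vfmax * S_arr / h.Ks - h.Vrmax * P_arr / h.Kp
    den = 1.0 + S_arr / h.Ks + P_arr / h.Kp
    out = num / den
    scalar = np.isscalar(S) and np.isscalar(P)
    return float(out) if scalar else out


def equilibrium_ratio(p: EnzymeParams) -> float:
    """Equilibrium S/P ratio of the reversible scheme (G = 0).

    ``S/P = (koff1/koff2)*(KS/KP)``, algebraically identical to
    ``(koff1^2/kon1)/(koff2^2/kon2)``.  Undefined for the irreversible
    scheme: with kon2 = 0 the substrate is fully consumed.
    """
    if p.kon2 <= 0:
        raise ValueError("kon2 = 0: irreversible scheme, equilibrium S/P undefined")
    return (p.koff1 / p.koff2) * (p.KS / p.KP)


# ---------------------------------------------------------------------------
# two-point starting estimators
# ---------------------------------------------------------------------------


def estimate_vmax_two_point(S1: float, t1: float, S2: float, t2: float) -> float:
    """Vmax estimate -(S2-S1)/(t2-t1) from two points of a near-linear
    (zero-order regime) decay, mg/(L*hour)."""
    _require(t1 != t2, "t1 and t2 must differ")
    return -(S2 - S1) / (t2 - t1)


def estimate_rate_log_slope(S1: float, t1: float, S2: float, t2: float) -> float:
    """First-order rate ln(S1/S2)/(t2-t1) in 1/hour.

    In the low-concentration limit this is Vmax/Km; combined with the
    two-point Vmax it bootstraps a Km starting value for fitting.
    """
    _require(S1 > 0 and S2 > 0, "concentrations must be positive")
    _require(t1 != t2, "t1 and t2 must differ")
    return math.log(S1 / S2) / (t2 - t1)


def occupancy_fraction(state: EnzymeState, ETOT: float) -> float:
    """Fraction of enzyme bound, SE/ETOT, in [0, 1]."""
    _require(ETOT > 0, "ETOT must be > 0")
    if state.SE > ETOT * (1.0 + 1e-9):
        raise ValueError(f"SE={state.SE} exceeds ETOT={ETOT}: corrupted state")
    return min(state.SE / ETOT, 1.0)
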