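"""Synthetic dose-group data with the structure the analysis assumes.

The published concentration-time series were digitized from figures in
three unrelated clinical studies and are not printed anywhere, so every
stage of this package is exercised on generated data instead: three
group-averaged curves — low dose (~81 mg aspirin, S0 ~ 5 mg/L, 7 points),
mid dose (1000 mg, S0 ~ 65 mg/L, 11 points) and high dose (mild
overdose, S0 ~ 335 mg/L, 9 points) — simulated from a chosen truth model
and corrupted with seeded proportional noise.  Sampling grids are
log-spaced inside each group's observation window, approximating the
published figure abscissae without claiming the digitized values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import ConcentrationTimeSeries
from .models import EnzymeParams, FirstOrderParams, MMParams
from .simulate import simulate

__all__ = [
    "DoseGroupSpec",
    "generate_group",
    "default_scenario",
    "DEFAULT_TRUTH",
    "DEFAULT_S0",
    "DEFAULT_WINDOWS",
    "DEFAULT_SCENARIO_SEED",
]

#: Observation window (first hour, last hour, n points) per dose group.
DEFAULT_WINDOWS = {
    "low": (1.9, 12.0, 7),
    "mid": (0.75, 13.0, 11),
    "high": (0.95, 15.94, 9),
}

#: Initial concentrations (mg/L) of the three groups in the reference
#: simultaneous-fit truth.
DEFAULT_S0 = {"low": 5.67, "mid": 64.9, "high": 335.0}

#: Reference truth: the reversible enzyme scheme with the simultaneous-fit
#: estimates KS = 10.44 mg/L, KP = 273.5 mg/L, koff2 = 14.82/s at fixed
#: kon1 = 3 L/(mg*s) and ETOT = 1.5e-4 mg/L (G = 0).
DEFAULT_TRUTH = EnzymeParams.from_affinities(
    KS=10.44, KP=273.5, koff2=14.82, kon1=3.0, ETOT=1.5e-4, S0=DEFAULT_S0["mid"]
)

DEFAULT_SCENARIO_SEED = 2015


@dataclass
class DoseGroupSpec:
    """Sampling design and noise model for one synthetic dose group.

    noise "gaussian": multiplicative, ``conc * (1 + level*N(0,1))`` — the
    realistic default at level 0.02 (2% CV).  noise "uniform":
    multiplicative ``conc * (1 + U(-level, +level))``, the perturbation
    used by the Monte Carlo refit machinery.  level 0 returns exact model
    values.
    """

    label: str
    S0: float
    times: np.ndarray
    noise: str = "gaussian"
    noise_level: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(self.times < 0):
            raise ValueError("sampling times must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if self.noise not in ("gaussian", "uniform"):
            raise ValueError("noise must be 'gaussian' or 'uniform'")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.S0 <= 0:
            raise ValueError("S0 must be > 0")

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    @classmethod
    def default(cls, label: str, **overrides) -> "DoseGroupSpec":
        """The group's standard log-spaced window and reference S0."""
        t0, t1, n = DEFAULT_WINDOWS[label]
        kwargs = dict(
            label=label,
            S0=DEFAULT_S0[label],
            times=np.geomspace(t0, t1, n),
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def _with_s0(truth, S0: float):
    if isinstance(truth, EnzymeParams):
        return truth.with_s0(S0)
    if isinstance(truth, MMParams):
        return MMParams(Vmax=truth.Vmax, Km=truth.Km, S0=S0)
    if isinstance(truth, FirstOrderParams):
        return FirstOrderParams(S0=S0, k=truth.k)
    raise TypeError(f"unsupported truth type {type(truth).__name__}")


def generate_group(spec: DoseGroupSpec, truth) -> ConcentrationTimeSeries:
    """Simulate the truth model at the spec's times and apply its noise.

    Deterministic under ``spec.seed``; noise level 0 returns points lying
    exactly on the model curve.
    """
    truth = _with_s0(truth, spec.S0)
    model_id = {
        EnzymeParams: "enzyme",
        MMParams: "mm",
        FirstOrderParams: "first_order",
    }[type(truth)]
    traj = simulate(model_id, truth, spec.times)
    conc = np.asarray(traj.S, dtype=float).copy()
    if spec.noise_level > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.noise == "gaussian":
            factors = 1.0 + spec.noise_level * rng.standard_normal(spec.n_points)
        else:
            factors = 1.0 + rng.uniform(-spec.noise_level, spec.noise_level, spec.n_points)
        conc = conc * np.clip(factors, 1e-6, None)
    return ConcentrationTimeSeries(label=spec.label, times=spec.times.copy(), conc=conc)


def default_scenario(
    seed: int = DEFAULT_SCENARIO_SEED,
    noise_level: float = 0.01,
    noise: str = "gaussian",
    truth: EnzymeParams = DEFAULT_TRUTH,
) -> tuple[list[ConcentrationTimeSeries], dict]:
    """Three dose groups from the reference enzyme truth with 1% noise.

    Returns the series plus a plain-dict truth record (parameters, group
    S0s, noise model, per-group child seeds) suitable for a scenario
    manifest and for checking parameter recovery.
    """
    child_seeds = [
        int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(3)
    ]
    series = []
    record_groups = {}
    for child, label in zip(child_seeds, ("low", "mid", "high")):
        spec = DoseGroupSpec.default(
            label, noise=noise, noise_level=noise_level, seed=child
        )
        series.append(generate_group(spec, truth))
        record_groups[label] = {
            "S0": spec.S0,
            "times": spec.times.tolist(),
            "seed": child,
        }
    record = {
        "model": "enzyme",
        "truth": {
            "KS": truth.KS,
            "KP": truth.KP,
            "koff2": truth.koff2,
            "kon1": truth.kon1,
            "ETOT": truth.ETOT,
            "G": truth.G,
        },
        "groups": record_groups,
        "noise": {"kind": noise, "level": noise_level},
        "seed": seed,
    }
    return series, record
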