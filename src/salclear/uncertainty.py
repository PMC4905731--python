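"""Monte Carlo uncertainty quantification for fitted parameters.

Two tools: (1) refitting replicates of the data perturbed by proportional
uniform noise, giving empirical SDs for the optimized parameters; (2) a
sampling estimate of the SD of a ratio of two Gaussian quantities (e.g.
Vmax/Km from their individual means and SDs), where the delta method is
only a first-order guide.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .fitting import ConcentrationTimeSeries, FitConfig, FitResult, fit_model, replace_curve

__all__ = ["MonteCarloResult", "monte_carlo_refit", "gaussian_ratio_sd"]

#: Parameters screened by the replicate rejection rule, in their natural
#: units (mg/L for the affinities, 1/sec for the catalytic rate).
DEFAULT_MONITORED = ("KS", "KP", "koff2")


@dataclass
class MonteCarloResult:
    """Replicate estimates and their empirical summary.

    ``estimates`` holds one row per *accepted* replicate; rejected
    replicates (any monitored parameter above the threshold, a sign of a
    runaway fit) are excluded from the means and SDs.
    """

    estimates: pd.DataFrame
    n_requested: int
    n_rejected: int
    means: dict[str, float]
    sds: dict[str, float]
    seed: int
    noise_frac: float
    rejection_threshold: float
    baseline: FitResult

    @property
    def n_used(self) -> int:
        return self.n_requested - self.n_rejected


def monte_carlo_refit(
    data: list[ConcentrationTimeSeries],
    cfg: FitConfig,
    n_reps: int = 1000,
    noise_frac: float = 0.01,
    rejection_threshold: float = 1000.0,
    seed: int = 0,
    from_scratch: bool = False,
    monitored: tuple[str, ...] = DEFAULT_MONITORED,
) -> MonteCarloResult:
    """Empirical parameter SDs by refitting noise-perturbed replicates.

    Each replicate multiplies every observation independently by
    ``1 + U(-noise_frac, +noise_frac)`` and refits with the same masks.
    Replicates restart the simplex from the baseline optimum (single
    start) for speed; ``from_scratch=True`` instead redoes the full
    multi-start bootstrap per replicate, useful for bias checks.

    With ``noise_frac=0`` the perturbed data are identical to the
    original, so the refit is skipped and every replicate equals the
    baseline (empirical SDs exactly 0).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    baseline = fit_model(data, cfg)
    watch = [p for p in monitored if p in cfg.free]

    rng = np.random.default_rng(seed)
    rows = []
    n_rejected = 0
    for _ in range(n_reps):
        if noise_frac == 0.0:
            rows.append(dict(baseline.estimates))
            continue
        perturbed = [
            replace_curve(
                c, conc=c.conc * (1.0 + rng.uniform(-noise_frac, noise_frac, c.n))
            )
            for c in data
        ]
        if from_scratch:
            rep_cfg = cfg
            rep = fit_model(perturbed, rep_cfg, compute_sds=False)
        else:
            rep_cfg = dc_replace(cfg, n_starts=1)
            rep = fit_model(
                perturbed, rep_cfg, start=baseline.estimates, compute_sds=False
            )
        if any(rep.estimates[p] > rejection_threshold for p in watch):
            n_rejected += 1
            continue
        rows.append(dict(rep.estimates))

    if not rows:
        raise RuntimeError(
            f"all {n_reps} Monte Carlo replicates rejected "
            f"(monitored {watch} > {rejection_threshold}); "
            "the baseline fit is likely unstable"
        )
    table = pd.DataFrame(rows)[list(baseline.estimates)]
    free = list(cfg.free)
    means = {p: float(table[p].mean()) for p in free}
    sds = {
        p: (0.0 if len(table) < 2 else float(table[p].std(ddof=1))) for p in free
    }
    return MonteCarloResult(
        estimates=table,
        n_requested=n_reps,
        n_rejected=n_rejected,
        means=means,
        sds=sds,
        seed=seed,
        noise_frac=noise_frac,
        rejection_threshold=rejection_threshold,
        baseline=baseline,
    )


def gaussian_ratio_sd(
    num_mean: float,
    num_sd: float,
    den_mean: float,
    den_sd: float,
    n_samples: int = 10_000,
    seed: int = 0,
) -> float:
    """Empirical SD of X/Y with X, Y independent Gaussians.

    Well-defined in practice only when den_mean >> den_sd (the exact ratio
    distribution has no moments); to first order the delta method gives
    SD ~= |num/den| * sqrt(cv_num^2 + cv_den^2).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if num_sd < 0 or den_sd < 0:
        raise ValueError("SDs must be >= 0")
    if num_sd == 0 and den_sd == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    num = rng.normal(num_mean, num_sd, n_samples)
    den = rng.normal(den_mean, den_sd, n_samples)
    return float(np.std(num / den, ddof=1))
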