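"""Delimited-text I/O, fit reports and run manifests.

All artifacts are plain text: datasets and trajectories as CSV, fit and
Monte Carlo reports as TSV plus a human-readable rendering, manifests as
JSON.  Every result file can be regenerated from its manifest (command,
config snapshot, input digests, seeds, package version).
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import ConcentrationTimeSeries, FitResult
from .models import (
    EnzymeParams,
    derive_mm_from_enzyme,
    half_life_from_k,
    round_sig,
)
from .simulate import Trajectory
from .uncertainty import MonteCarloResult

__all__ = [
    "read_series",
    "write_series",
    "read_trajectory",
    "write_trajectory",
    "load_config",
    "file_digest",
    "write_manifest",
    "fit_report_frame",
    "render_fit_report",
    "write_fit_report",
    "write_mc_report",
    "write_scenario_manifest",
    "read_scenario_manifest",
]

SERIES_COLUMNS = ["time_h", "conc_mg_L"]


def write_series(series: ConcentrationTimeSeries, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_h": series.times, "conc_mg_L": series.conc}).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


def read_series(path, label: str | None = None, curve_weight: float = 1.0) -> ConcentrationTimeSeries:
    """Read a dose-group dataset (columns ``time_h,conc_mg_L``).

    The label defaults to the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:2]) != SERIES_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {SERIES_COLUMNS}, found {list(df.columns)}"
        )
    return ConcentrationTimeSeries(
        label=label or path.stem,
        times=df["time_h"].to_numpy(),
        conc=df["conc_mg_L"].to_numpy(),
        curve_weight=curve_weight,
    )


def write_trajectory(traj: Trajectory, path) -> Path:
    path = Path(path)
    traj.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def read_trajectory(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_h" not in df.columns or "S_mg_L" not in df.columns:
        raise ValueError(f"{path}: not a trajectory file (need time_h, S_mg_L)")
    return df


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, command: str, config: dict, inputs: list, seeds: dict) -> Path:
    """Record everything needed to regenerate the emitted result files."""
    path = Path(path)
    manifest = {
        "command": command,
        "config": config,
        "inputs": [
            {"path": str(p), "sha256": file_digest(p)} for p in inputs
        ],
        "seeds": seeds,
        "package": {"name": "salclear", "version": __version__},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path.write_text(json.dumps(manifest, indent=2, default=_json_default) + "\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# fit reports
# ---------------------------------------------------------------------------


def _derived_rows(result: FitResult) -> list[dict]:
    est = result.estimates
    rows = []
    if result.model_id == "first_order":
        rows.append(
            dict(
                parameter="thalf_min",
                estimate=half_life_from_k(est["k"]),
                sd=float("nan"),
                how_obtained="Calc",
            )
        )
    elif result.model_id == "mm":
        rows.append(
            dict(
                parameter="Vmax_over_Km",
                estimate=est["Vmax"] / est["Km"],
                sd=float("nan"),
                how_obtained="Calc",
            )
        )
    elif result.model_id == "enzyme":
        p = EnzymeParams.from_affinities(
            KS=est["KS"],
            KP=est["KP"],
            koff2=est["koff2"],
            kon1=est["kon1"],
            ETOT=est["ETOT"],
            S0=1.0,
            G=est.get("G", 0.0),
        )
        d = derive_mm_from_enzyme(p)
        for name, val in (
            ("Km", d.Km),
            ("Vmax", d.Vmax),
            ("koff1", d.koff1),
            ("kon2", d.kon2),
        ):
            rows.append(
                dict(parameter=name, estimate=val, sd=float("nan"), how_obtained="Calc")
            )
    return rows


def fit_report_frame(result: FitResult) -> pd.DataFrame:
    """Tabular report: parameter, estimate, SD, how_obtained (Opt/Fixed/Calc).

    Structural constants fixed at zero (e.g. G when product consumption is
    ignored) are omitted, matching how kinetics tables report only the
    quantities in play.
    """
    rows = []
    for name in result.free:
        rows.append(
            dict(
                parameter=name,
                estimate=result.estimates[name],
                sd=result.sds.get(name, float("nan")),
                how_obtained="Opt",
            )
        )
    for name, val in result.estimates.items():
        if name in result.free:
            continue
        if name == "G" and val == 0.0:
            continue
        rows.append(dict(parameter=name, estimate=val, sd=float("nan"), how_obtained="Fixed"))
    rows.extend(_derived_rows(result))
    return pd.DataFrame(rows, columns=["parameter", "estimate", "sd", "how_obtained"])


def render_fit_report(result: FitResult, sig: int = 3) -> str:
    """Human-readable fit report (estimates rounded to 3 significant
    figures, as kinetics tables print them; the TSV keeps full precision)."""
    lines = [
        f"model: {result.model_id}   datasets: {', '.join(result.labels)}",
        f"converged: {result.converged}   SSWR: {result.sswr:.6g}   "
        f"n_points: {result.n_points}   n_free: {result.n_free}",
        "",
        f"{'parameter':<12}{'estimate':>14}{'sd':>12}  how",
    ]
    for row in fit_report_frame(result).itertuples():
        sd = "-" if not np.isfinite(row.sd) else f"{round_sig(row.sd, sig):g}"
        lines.append(
            f"{row.parameter:<12}{round_sig(row.estimate, sig):>14g}{sd:>12}  {row.how_obtained}"
        )
    lines.append("")
    lines.append("per-curve weight / fractional residual error:")
    for lab in result.labels:
        lines.append(
            f"  {lab:<8} w={result.curve_weights[lab]:.6g}  "
            f"fre={result.per_curve_fre[lab]:.4g}"
        )
    if result.at_bounds:
        lines.append(f"parameters at bounds: {', '.join(result.at_bounds)}")
    if result.singular:
        lines.append("warning: singular information matrix; SDs unavailable")
    return "\n".join(lines) + "\n"


def write_fit_report(result: FitResult, out_dir, stem: str = "fit") -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / f"{stem}_report.tsv"
    fit_report_frame(result).to_csv(tsv, sep="\t", index=False, float_format="%.17g")
    txt = out_dir / f"{stem}_report.txt"
    txt.write_text(render_fit_report(result))
    js = out_dir / f"{stem}_result.json"
    js.write_text(
        json.dumps(
            {
                "model_id": result.model_id,
                "labels": list(result.labels),
                "estimates": result.estimates,
                "free": list(result.free),
                "sds": result.sds,
                "sswr": result.sswr,
                "per_curve_fre": result.per_curve_fre,
                "curve_weights": result.curve_weights,
                "n_points": result.n_points,
                "n_free": result.n_free,
                "converged": result.converged,
                "singular": result.singular,
                "seed": result.seed,
            },
            indent=2,
            default=_json_default,
        )
        + "\n"
    )
    return {"tsv": tsv, "txt": txt, "json": js}


def write_mc_report(mc: MonteCarloResult, out_dir, stem: str = "mc") -> dict[str, Path]:
    """Replicate table as CSV plus a summary block appended to the text report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = out_dir / f"{stem}_replicates.csv"
    mc.estimates.to_csv(table, index=False, float_format="%.17g")
    lines = [
        render_fit_report(mc.baseline),
        f"Monte Carlo: n_requested={mc.n_requested} n_rejected={mc.n_rejected} "
        f"noise_frac={mc.noise_frac} threshold={mc.rejection_threshold} seed={mc.seed}",
        f"{'parameter':<12}{'mean':>14}{'empirical sd':>16}",
    ]
    for p in mc.means:
        lines.append(f"{p:<12}{mc.means[p]:>14.6g}{mc.sds[p]:>16.6g}")
    txt = out_dir / f"{stem}_report.txt"
    txt.write_text("\n".join(lines) + "\n")
    return {"table": table, "txt": txt}


def write_scenario_manifest(record: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(record, indent=2, default=_json_default) + "\n")
    return path


def read_scenario_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
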