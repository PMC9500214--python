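"""Plain-text serialization: trial tables, breath tables, sidecars, summaries.

One trial is stored as three files sharing a prefix: ``<prefix>.tsv`` (the
columnar time series), ``<prefix>_breaths.tsv`` (t, vo2, vco2) and
``<prefix>.json`` (participant / clamp / intensity / mass / standing power).
Summary tables are TSV, one row per trial.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gait_processing import TrialSummary
from .metabolics import BreathSample
from .synthetic_gait import TrialRaw

__all__ = [
    "trial_prefix",
    "write_trial",
    "read_trial",
    "write_controller_trace",
    "write_summaries",
    "read_summaries",
]

_SERIES_COLS = [
    "time", "grfV_L", "grfV_R", "grfAP_L", "grfAP_R",
    "cop_ap", "heelAP_L", "heelAP_R", "belt_speed",
]


def trial_prefix(raw_or_summary) -> str:
    r = raw_or_summary
    return f"{r.participant_id}_{r.clamp_type}_{r.intensity:+.2f}"


def write_trial(raw: TrialRaw, outdir: Path, mass: float, standing_power: float) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = outdir / trial_prefix(raw)
    df = pd.DataFrame(
        dict(zip(_SERIES_COLS, [
            raw.time, raw.grf_vertical_l, raw.grf_vertical_r,
            raw.grf_ap_l, raw.grf_ap_r, raw.cop_ap,
            raw.heel_ap_l, raw.heel_ap_r, raw.belt_speed,
        ]))
    )
    df.to_csv(f"{prefix}.tsv", sep="\t", index=False, float_format="%.6g")
    bdf = pd.DataFrame(
        {"t": [b.t for b in raw.breaths],
         "vo2": [b.vo2 for b in raw.breaths],
         "vco2": [b.vco2 for b in raw.breaths]}
    )
    bdf.to_csv(f"{prefix}_breaths.tsv", sep="\t", index=False, float_format="%.8g")
    sidecar = {
        "participant_id": raw.participant_id,
        "clamp_type": raw.clamp_type,
        "intensity": raw.intensity,
        "mass": mass,
        "standing_power": standing_power,
    }
    Path(f"{prefix}.json").write_text(json.dumps(sidecar, indent=1))
    return Path(f"{prefix}.tsv")


def read_trial(prefix: str | Path) -> tuple[TrialRaw, dict]:
    """Inverse of :func:`write_trial`; returns (TrialRaw, sidecar dict)."""
    prefix = str(prefix)
    if prefix.endswith(".tsv"):
        prefix = prefix[:-4]
    sidecar = json.loads(Path(f"{prefix}.json").read_text())
    df = pd.read_csv(f"{prefix}.tsv", sep="\t")
    bdf = pd.read_csv(f"{prefix}_breaths.tsv", sep="\t")
    breaths = [BreathSample(t=float(r.t), vo2=float(r.vo2), vco2=float(r.vco2))
               for r in bdf.itertuples()]
    raw = TrialRaw(
        participant_id=sidecar["participant_id"],
        clamp_type=sidecar["clamp_type"],
        intensity=float(sidecar["intensity"]),
        time=df["time"].to_numpy(float),
        grf_vertical_l=df["grfV_L"].to_numpy(float),
        grf_vertical_r=df["grfV_R"].to_numpy(float),
        grf_ap_l=df["grfAP_L"].to_numpy(float),
        grf_ap_r=df["grfAP_R"].to_numpy(float),
        cop_ap=df["cop_ap"].to_numpy(float),
        heel_ap_l=df["heelAP_L"].to_numpy(float),
        heel_ap_r=df["heelAP_R"].to_numpy(float),
        belt_speed=df["belt_speed"].to_numpy(float),
        breaths=breaths,
        meta={},
    )
    return raw, sidecar


def write_controller_trace(raw: TrialRaw, path: Path) -> None:
    """Audit table for a self-paced trial: one row per double-support update."""
    trace = raw.meta.get("controller_trace", [])
    df = pd.DataFrame(trace, columns=["time", "cop_avg", "delta_speed", "belt_speed"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_summaries(summaries: list[TrialSummary], path: Path) -> pd.DataFrame:
    rows = []
    for s in summaries:
        d = asdict(s)
        d["flags"] = ";".join(d["flags"])
        rows.append(d)
    df = pd.DataFrame(rows)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_summaries(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["flags"] = df.get("flags", pd.Series([""] * len(df))).fillna("")
    return df
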