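"""Readers and writers for the package's interchange formats.

CSV for tabular data, JSON for structured results.  JSON artifacts are
written canonically (sorted keys, fixed float formatting, trailing newline)
and embed the sha256 hash of their own configuration block, so re-running
with an identical configuration reproduces byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .footprint import FootprintLane, ReactivityProfile
from .kinetic_model import ProgressCurve, Substrate, UnwindingMechanism
from .titration import TitrationSeries

__all__ = [
    "read_progress_curves",
    "write_progress_curves",
    "read_substrate",
    "write_substrate",
    "read_mechanism",
    "write_mechanism",
    "read_lanes",
    "write_profile",
    "read_titration",
    "canonical_json",
    "config_hash",
    "write_json_artifact",
]


# ---------------------------------------------------------------------------
# progress curves: CSV with header time_s,fraction_ss[,replicate]

def read_progress_curves(path: str | Path) -> list[ProgressCurve]:
    df = pd.read_csv(path)
    if "time_s" not in df.columns or "fraction_ss" not in df.columns:
        raise ValueError(f"{path}: expected columns time_s,fraction_ss[,replicate]")
    if "replicate" in df.columns:
        return [
            ProgressCurve(g.time_s.to_numpy(), g.fraction_ss.to_numpy(), replicate_id=str(rep))
            for rep, g in df.groupby("replicate", sort=False)
        ]
    return [ProgressCurve(df.time_s.to_numpy(), df.fraction_ss.to_numpy())]


def write_progress_curves(curves: Sequence[ProgressCurve], path: str | Path) -> None:
    frames = []
    any_rep = any(c.replicate_id is not None for c in curves)
    for i, c in enumerate(curves):
        d = {"time_s": c.times, "fraction_ss": c.fraction_ss}
        if any_rep:
            d["replicate"] = c.replicate_id if c.replicate_id is not None else f"rep{i + 1}"
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# substrates and mechanisms: JSON

def read_substrate(path: str | Path) -> Substrate:
    return Substrate.from_json(Path(path).read_text())


def write_substrate(sub: Substrate, path: str | Path) -> None:
    Path(path).write_text(sub.to_json() + "\n")


def read_mechanism(path: str | Path) -> UnwindingMechanism:
    return UnwindingMechanism.from_json(Path(path).read_text())


def write_mechanism(mech: UnwindingMechanism, path: str | Path) -> None:
    Path(path).write_text(mech.to_json() + "\n")


# ---------------------------------------------------------------------------
# footprint lanes: CSV lane_id,condition,position,intensity

def read_lanes(path: str | Path) -> list[FootprintLane]:
    df = pd.read_csv(path)
    required = {"lane_id", "condition", "position", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    lanes = []
    for lane_id, g in df.groupby("lane_id", sort=False):
        g = g.sort_values("position")
        lanes.append(
            FootprintLane(
                str(lane_id),
                str(g.condition.iloc[0]),
                g.position.to_numpy(),
                g.intensity.to_numpy(),
            )
        )
    return lanes


def write_profile(profile: ReactivityProfile, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "position": profile.positions,
            "relative_reactivity": profile.relative_reactivity,
            "sd": profile.sd if profile.sd is not None else np.nan,
            "call": profile.calls,
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# titrations: CSV protein_conc,F_raw,F_buffer_blank,F_protein_only

def read_titration(path: str | Path) -> TitrationSeries:
    df = pd.read_csv(path)
    required = ["protein_conc", "F_raw", "F_buffer_blank", "F_protein_only"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return TitrationSeries(*(df[c].to_numpy() for c in required))


def write_titration(series: TitrationSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "protein_conc": series.protein_conc,
            "F_raw": series.F_raw,
            "F_buffer_blank": series.F_buffer_blank,
            "F_protein_only": series.F_protein_only,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# canonical JSON artifacts with provenance

def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, float) and obj != obj:  # NaN -> null
        return None
    return obj


def canonical_json(obj) -> str:
    """Deterministic JSON text: sorted keys, no whitespace variation."""
    return json.dumps(_jsonify(obj), sort_keys=True, separators=(",", ":"))


def config_hash(config: dict) -> str:
    """sha256 of the canonical JSON of a configuration block."""
    return hashlib.sha256(canonical_json(config).encode()).hexdigest()


def write_json_artifact(payload: dict, config: dict, path: str | Path) -> None:
    """Write a result JSON embedding its configuration and config hash."""
    artifact = dict(payload)
    artifact["config"] = config
    artifact["config_sha256"] = config_hash(config)
    Path(path).write_text(
        json.dumps(_jsonify(artifact), sort_keys=True, indent=2) + "\n"
    )
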