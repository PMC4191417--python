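"""Quantification of permanganate (KMnO4) footprinting lanes.

KMnO4 oxidizes thymidines in single-stranded, unprotected DNA; piperidine
cleavage then yields one gel band per reactive thymidine.  Each band is
expressed as a fraction of its lane's total signal (so lanes with different
exposure compare correctly), and the relative reactivity at a position is
the with-protein fraction divided by the without-protein fraction.  Ratios
below ~0.8 indicate protection (protein bound or base paired), above ~1.2
enhancement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FootprintLane",
    "ReactivityProfile",
    "lane_fractions",
    "relative_reactivity",
    "call_protection",
    "compare_profiles",
]


@dataclass
class FootprintLane:
    """One gel lane: band intensities at ordered thymidine positions."""

    lane_id: str
    condition: str  # "no_protein" or "with_protein"
    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.condition not in ("no_protein", "with_protein"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.positions.shape != self.intensities.shape or self.positions.ndim != 1:
            raise ValueError("positions and intensities must be 1-D and equal length")
        if len(np.unique(self.positions)) != len(self.positions):
            raise ValueError("positions must be unique")
        if self.positions.size > 1 and np.any(np.diff(self.positions.astype(float)) <= 0):
            raise ValueError("positions must be in increasing order")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")
        if not np.any(self.intensities > 0):
            raise ValueError("lane must contain at least one nonzero band")


@dataclass
class ReactivityProfile:
    """Per-position relative reactivity (with protein / without protein)."""

    positions: np.ndarray
    relative_reactivity: np.ndarray
    sd: np.ndarray | None = None
    calls: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.relative_reactivity = np.asarray(self.relative_reactivity, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)


def lane_fractions(lane: FootprintLane) -> np.ndarray:
    """Band intensity as a fraction of the lane total; sums to 1."""
    return lane.intensities / lane.intensities.sum()


def _as_lane_list(lanes: "FootprintLane | Sequence[FootprintLane]") -> list[FootprintLane]:
    return [lanes] if isinstance(lanes, FootprintLane) else list(lanes)


def relative_reactivity(
    with_protein: "FootprintLane | Sequence[FootprintLane]",
    without_protein: "FootprintLane | Sequence[FootprintLane]",
) -> ReactivityProfile:
    """Ratio of lane fractions, with protein over without.

    Replicate lane lists are paired index-wise and reduced to mean and
    sample sd per position.  Positions where the without-protein fraction is
    zero get NaN (undefined, not infinite).
    """
    wl = _as_lane_list(with_protein)
    nl = _as_lane_list(without_protein)
    if len(wl) != len(nl):
        raise ValueError(f"replicate counts differ: {len(wl)} with vs {len(nl)} without")
    pos = wl[0].positions
    for lane in (*wl, *nl):
        if not np.array_equal(lane.positions, pos):
            raise ValueError(f"lane {lane.lane_id!r} position set does not match")

    ratios = []
    for w, n in zip(wl, nl):
        fw, fn = lane_fractions(w), lane_fractions(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(fn > 0, fw / fn, np.nan)
        ratios.append(r)
    stacked = np.vstack(ratios)
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0, ddof=1) if len(ratios) > 1 else None
    profile = ReactivityProfile(pos, mean, sd)
    profile.calls = call_protection(profile)
    return profile


def call_protection(
    profile: ReactivityProfile, low: float = 0.8, high: float = 1.2
) -> list[str]:
    """Classify each position: protected (< low), enhanced (> high),
    neutral otherwise (boundaries inclusive of neutral); NaN -> undefined."""
    if not 0 < low < high:
        raise ValueError(f"require 0 < low < high, got low={low}, high={high}")
    calls = []
    for r in profile.relative_reactivity:
        if np.isnan(r):
            calls.append("undefined")
        elif r < low:
            calls.append("protected")
        elif r > high:
            calls.append("enhanced")
        else:
            calls.append("neutral")
    return calls


def compare_profiles(a: ReactivityProfile, b: ReactivityProfile) -> ReactivityProfile:
    """Per-position difference a - b with sd propagated in quadrature.

    Used e.g. to contrast a fork footprint against a junction footprint:
    negative differences mark positions the fork protects more strongly.
    """
    if not np.array_equal(a.positions, b.positions):
        raise ValueError("profiles cover different position sets")
    diff = a.relative_reactivity - b.relative_reactivity
    if a.sd is not None and b.sd is not None:
        sd = np.sqrt(a.sd**2 + b.sd**2)
    elif a.sd is not None or b.sd is not None:
        sd = a.sd if a.sd is not None else b.sd
    else:
        sd = None
    return ReactivityProfile(a.positions, diff, sd)
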