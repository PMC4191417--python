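"""Synthetic data generator for every analysis stage.

Emulates the three experimental readouts with their characteristic noise
structure so the whole pipeline is testable end to end:

* single-turnover quench-flow progress curves — the sequential-mechanism
  model sampled at 20 log-spaced times over 5-500 ms with additive Gaussian
  quantification noise (sd 0.02 fraction units, 3 replicates);
* permanganate footprint lane pairs — per-position base reactivities scaled
  by protection factors under protein, multiplicative lognormal band noise,
  and a random overall lane exposure;
* 2-AP fluorescence titrations — a Hill-shaped signal plus linear protein
  autofluorescence and a dilution decay on all series, with Gaussian noise.

One integer seed expands into independent per-stage substreams via
``numpy.random.SeedSequence(seed, spawn_key=(stage,))``, so adding a new
generator never perturbs data produced by the existing ones.

Default truths follow the fork/junction study conditions: junction curves
need three kinetic steps and plateau near 0.25, fork curves need two steps
and plateau near 0.45; dissociation rate constants are set from those
plateaus via k_d = k_u * (A^(-1/n) - 1) since only amplitudes, not k_d
values, are reported for these substrates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from .kinetic_model import ProgressCurve, Substrate, UnwindingMechanism, closed_form_fraction
from .footprint import FootprintLane
from .titration import TitrationSeries, hill_equation

__all__ = [
    "SimulationSpec",
    "stage_rng",
    "gen_progress_curves",
    "gen_footprint_lanes",
    "gen_titration",
    "JUNCTION_16BP",
    "FORK_16BP",
    "junction_mechanism",
    "fork_mechanism",
]

# stage indices for seed substreams; append-only
_STAGES = {"progress": 0, "footprint": 1, "titration": 2}

JUNCTION_16BP = Substrate("7T16bp ss/ds junction", L=16, overhang5=7, overhang3=0, L0=8, LB=0)
FORK_16BP = Substrate("7T16bp fork", L=16, overhang5=7, overhang3=7, L0=8, LB=2)


def _kd_from_amplitude(n: int, k_u: float, amp: float) -> float:
    """Invert amplitude = (k_u/(k_u+k_d))^n for k_d."""
    return k_u * (amp ** (-1.0 / n) - 1.0)


def junction_mechanism(k_u: float = 78.4, amp: float = 0.25) -> UnwindingMechanism:
    """Three-step mechanism with the junction's observed plateau (~0.25)."""
    return UnwindingMechanism(3, k_u, _kd_from_amplitude(3, k_u, amp))


def fork_mechanism(k_u: float = 71.9, amp: float = 0.45) -> UnwindingMechanism:
    """Two-step mechanism with the fork's observed plateau (~0.45)."""
    return UnwindingMechanism(2, k_u, _kd_from_amplitude(2, k_u, amp))


@dataclass
class SimulationSpec:
    """Ground truth and design for all synthetic data; one seed fixes all
    outputs bit for bit."""

    seed: int = 0

    # --- progress curves -------------------------------------------------
    mechanism: UnwindingMechanism = field(default_factory=junction_mechanism)
    substrate: Substrate = field(default_factory=lambda: JUNCTION_16BP)
    n_times: int = 20
    t_min: float = 0.005  # s
    t_max: float = 0.5  # s
    time_spacing: Literal["log", "linear"] = "log"
    noise_sd: float = 0.02  # fraction units
    replicates: int = 3

    # --- footprint lanes -------------------------------------------------
    positions: tuple = tuple(range(1, 10))
    base_reactivity: tuple = (1.5, 1.0, 0.9, 0.8, 0.8, 0.9, 1.0, 1.0, 1.0)
    protection_factors: tuple = (0.9, 0.55, 0.45, 0.4, 0.4, 0.45, 0.8, 0.4, 0.4)
    lane_noise_cv: float = 0.05
    footprint_replicates: int = 3

    # --- titration -------------------------------------------------------
    K_half: float = 330.0
    hill_h: float = 1.9
    F_max: float = 1.0
    conc_max: float = 2000.0
    n_conc: int = 16
    protein_bg_slope: float = 2e-4  # a.u. per concentration unit
    dna_baseline: float = 0.2  # a.u., labeled-DNA fluorescence before protein
    dilution_per_point: float = 0.005  # fractional signal loss per addition
    titration_noise_cv: float = 0.02  # sd as fraction of F_max

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.lane_noise_cv < 0 or self.titration_noise_cv < 0:
            raise ValueError("noise parameters must be >= 0")
        if len(self.base_reactivity) != len(self.positions) or len(
            self.protection_factors
        ) != len(self.positions):
            raise ValueError("footprint truth vectors must match the position set")

    def times(self) -> np.ndarray:
        if self.time_spacing == "log":
            return np.geomspace(self.t_min, self.t_max, self.n_times)
        return np.linspace(self.t_min, self.t_max, self.n_times)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mechanism"] = self.mechanism.to_dict()
        d["substrate"] = self.substrate.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        if "mechanism" in d:
            d["mechanism"] = UnwindingMechanism.from_dict(d["mechanism"])
        if "substrate" in d:
            d["substrate"] = Substrate.from_dict(d["substrate"])
        for key in ("positions", "base_reactivity", "protection_factors"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent random substream for one generator stage."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES[stage],)))


def gen_progress_curves(spec: SimulationSpec) -> tuple[list[ProgressCurve], dict]:
    """Simulated replicate progress curves plus the generating truth."""
    rng = stage_rng(spec.seed, "progress")
    t = spec.times()
    clean = closed_form_fraction(spec.mechanism, t)
    curves = []
    for r in range(spec.replicates):
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=t.size) if spec.noise_sd > 0 else clean.copy()
        noisy = np.clip(noisy, -0.05, 1.05)
        curves.append(ProgressCurve(t, noisy, replicate_id=f"rep{r + 1}"))
    truth = {
        "mechanism": spec.mechanism.to_dict(),
        "substrate": spec.substrate.to_dict(),
        "noise_sd": spec.noise_sd,
        "replicates": spec.replicates,
    }
    return curves, truth


def gen_footprint_lanes(
    spec: SimulationSpec,
) -> tuple[list[FootprintLane], list[FootprintLane], dict]:
    """Paired with/without-protein lanes for each replicate, plus truth.

    Without-protein bands are proportional to the base reactivities; the
    with-protein lane multiplies in the protection factors.  Band noise is
    multiplicative lognormal with the given CV and each lane gets a random
    overall exposure, which the fraction-of-lane-total normalization must
    cancel.
    """
    rng = stage_rng(spec.seed, "footprint")
    base = np.asarray(spec.base_reactivity, dtype=float)
    prot = np.asarray(spec.protection_factors, dtype=float)
    pos = np.asarray(spec.positions)
    sigma = np.sqrt(np.log1p(spec.lane_noise_cv**2))

    def one_lane(expected: np.ndarray, lane_id: str, condition: str) -> FootprintLane:
        noise = rng.lognormal(-sigma**2 / 2.0, sigma, size=expected.size) if sigma > 0 else 1.0
        exposure = rng.uniform(0.5, 2.0)
        return FootprintLane(lane_id, condition, pos, exposure * expected * noise)

    without, with_ = [], []
    for r in range(spec.footprint_replicates):
        without.append(one_lane(base, f"no_protein_rep{r + 1}", "no_protein"))
        with_.append(one_lane(base * prot, f"with_protein_rep{r + 1}", "with_protein"))
    truth = {
        "positions": pos.tolist(),
        "base_reactivity": base.tolist(),
        "protection_factors": prot.tolist(),
        "expected_relative_reactivity": expected_relative_reactivity(base, prot).tolist(),
        "lane_noise_cv": spec.lane_noise_cv,
    }
    return with_, without, truth


def expected_relative_reactivity(base: np.ndarray, protection: np.ndarray) -> np.ndarray:
    """Noise-free relative reactivity implied by the generator.

    Lane-total normalization rescales the protection factors by the ratio of
    lane totals: ratio_i = p_i * sum(base) / sum(base * p)."""
    base = np.asarray(base, dtype=float)
    protection = np.asarray(protection, dtype=float)
    return protection * base.sum() / (base * protection).sum()


def gen_titration(spec: SimulationSpec) -> tuple[TitrationSeries, dict]:
    """Synthetic titration with its two control series, plus truth.

    Built so the standard correction recovers the pure Hill signal exactly
    at zero noise: the dilution decay enters the raw and blank series
    identically, and the protein background is zero at the first point.
    """
    rng = stage_rng(spec.seed, "titration")
    conc = np.linspace(0.0, spec.conc_max, spec.n_conc)
    signal = hill_equation(conc, spec.F_max, spec.K_half, spec.hill_h)
    dilution = (1.0 - spec.dilution_per_point) ** np.arange(conc.size)
    protein_bg = spec.protein_bg_slope * conc

    f_blank = spec.dna_baseline * dilution
    f_raw = f_blank + signal + protein_bg
    # unlabeled DNA fluoresces weakly and constantly, so this control isolates
    # the protein-added increment
    f_protein_only = 0.25 * spec.dna_baseline + protein_bg

    if spec.titration_noise_cv > 0:
        sd = spec.titration_noise_cv * spec.F_max
        f_raw = f_raw + rng.normal(0.0, sd, conc.size)
        f_blank = f_blank + rng.normal(0.0, sd, conc.size)
        f_protein_only = f_protein_only + rng.normal(0.0, sd, conc.size)

    series = TitrationSeries(conc, f_raw, f_blank, f_protein_only)
    truth = {
        "K_half": spec.K_half,
        "h": spec.hill_h,
        "F_max": spec.F_max,
        "noise_cv": spec.titration_noise_cv,
    }
    return series, truth
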