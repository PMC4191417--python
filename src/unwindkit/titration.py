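"""Background correction and Hill analysis of 2-aminopurine titrations.

2-aminopurine (2-AP) is a fluorescent adenine analog whose emission rises
when it loses base pairing/stacking, so titrating protein into 2-AP-labeled
DNA reports on duplex melting at the label.  Two backgrounds must be removed
before fitting: dilution of the sample by each addition (measured by
titrating buffer alone) and the protein's own fluorescence (measured by
titrating protein into unlabeled DNA).  The corrected signal is fit to the
Hill equation

    dF(c) = F_max * c^h / (K_half^h + c^h)

whose coefficient h > 1 indicates multiple coupled binding events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lmfit import Model

__all__ = ["TitrationSeries", "HillFit", "correct_series", "fit_hill", "hill_equation"]


@dataclass
class TitrationSeries:
    """Raw titration with its two control series.

    ``F_buffer_blank``: the labeled sample titrated with an equal volume of
    protein buffer (dilution control).  ``F_protein_only``: protein titrated
    into unlabeled DNA (protein autofluorescence control).
    """

    protein_conc: np.ndarray
    F_raw: np.ndarray
    F_buffer_blank: np.ndarray
    F_protein_only: np.ndarray

    def __post_init__(self) -> None:
        self.protein_conc = np.asarray(self.protein_conc, dtype=float)
        self.F_raw = np.asarray(self.F_raw, dtype=float)
        self.F_buffer_blank = np.asarray(self.F_buffer_blank, dtype=float)
        self.F_protein_only = np.asarray(self.F_protein_only, dtype=float)
        n = self.protein_conc.size
        for name in ("F_raw", "F_buffer_blank", "F_protein_only"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must match protein_conc in length")
        if np.any(self.protein_conc < 0):
            raise ValueError("protein concentrations must be >= 0")
        if np.any(np.diff(self.protein_conc) < 0):
            raise ValueError("protein concentrations must be non-decreasing")

    def __len__(self) -> int:
        return self.protein_conc.size


@dataclass
class HillFit:
    """Fitted Hill parameters with standard errors from the fit."""

    K_half: float
    h: float
    F_max: float
    K_half_stderr: float
    h_stderr: float
    F_max_stderr: float
    rss: float
    saturation_warning: bool = False

    def to_dict(self) -> dict:
        return {
            "K_half": self.K_half, "h": self.h, "F_max": self.F_max,
            "K_half_stderr": self.K_half_stderr, "h_stderr": self.h_stderr,
            "F_max_stderr": self.F_max_stderr, "rss": self.rss,
            "saturation_warning": self.saturation_warning,
        }


def correct_series(s: TitrationSeries) -> np.ndarray:
    """Background-corrected fluorescence change.

    dF = (F_raw - F_buffer_blank) - (F_protein_only - F_protein_only[0]).
    The protein-only control is anchored at its first point so only the
    protein-added increment is subtracted (no protein is present before the
    first addition).  The correction is exactly linear in the raw series.
    """
    return (s.F_raw - s.F_buffer_blank) - (s.F_protein_only - s.F_protein_only[0])


def hill_equation(c: np.ndarray, F_max: float, K_half: float, h: float) -> np.ndarray:
    """Hill isotherm F_max * c^h / (K_half^h + c^h); 0 at c = 0."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        # evaluate via the ratio (c/K)^h for scale stability
        x = np.where(c > 0, (c / K_half) ** h, 0.0)
    return F_max * x / (1.0 + x)


def fit_hill(conc: np.ndarray, dF: np.ndarray) -> HillFit:
    """Least-squares Hill fit of corrected fluorescence vs concentration.

    Deterministic initialization: F_max from the maximal signal, K_half from
    the concentration nearest half-maximal signal, h = 1.  A saturation
    warning is raised when the signal is still climbing steeply at the last
    titration point (the plateau was not approached, so F_max and K_half are
    extrapolations).
    """
    conc = np.asarray(conc, dtype=float)
    dF = np.asarray(dF, dtype=float)
    if conc.size < 5:
        raise ValueError("need at least 5 titration points")
    f_max0 = float(dF.max())
    if f_max0 <= 0:
        raise ValueError("no positive fluorescence change to fit")
    half_idx = int(np.argmin(np.abs(dF - f_max0 / 2.0)))
    k0 = float(conc[half_idx]) if conc[half_idx] > 0 else float(np.median(conc[conc > 0]))

    model = Model(hill_equation, independent_vars=["c"])
    params = model.make_params(F_max=f_max0, K_half=k0, h=1.0)
    params["F_max"].set(min=1e-12)
    params["K_half"].set(min=1e-12)
    params["h"].set(min=1e-3, max=20)
    out = model.fit(dF, params, c=conc)

    def se(name: str) -> float:
        s = out.params[name].stderr
        return float(s) if s is not None else math.nan

    # saturation check: max signal at the final point and the end slope
    # still above 10% of the steepest slope
    slopes = np.gradient(dF, conc, edge_order=1) if conc.size > 2 else np.zeros_like(dF)
    warn = bool(
        int(np.argmax(dF)) == conc.size - 1
        and abs(slopes[-1]) > 0.10 * np.max(np.abs(slopes))
    )

    return HillFit(
        K_half=float(out.params["K_half"].value),
        h=float(out.params["h"].value),
        F_max=float(out.params["F_max"].value),
        K_half_stderr=se("K_half"),
        h_stderr=se("h"),
        F_max_stderr=se("F_max"),
        rss=float(np.sum(out.residual**2)),
        saturation_warning=warn,
    )
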