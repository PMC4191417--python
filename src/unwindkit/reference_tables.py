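"""Published kinetic parameters for Dda unwinding of fork and junction DNA.

Fitted unwinding rate constants (k_u, s^-1) and tabulated velocities
(bp/s) for the T4 Dda helicase acting on ss/ds-junction and fork substrates,
under two designs: excess enzyme (150 nM Dda, 2 nM DNA; wild-type and the
K24A-K25A duplex-contact mutant) and a DNA titration (150 nM Dda, 75-300 nM
DNA).  All substrates share L0 = 8 bp of spontaneous thermal fraying;
forks additionally melt LB = 2 bp on helicase binding and need n = 2
kinetic steps, junctions have LB = 0 and need n = 3.

These rows are the input for velocity recomputation: the printed_velocity
column is the published value that V_un = k_u * (L - L0 - LB)/n should
reproduce.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["published_unwinding_parameters", "wt_excess_enzyme_step_sizes"]

_COLUMNS = [
    "dataset", "substrate", "enzyme", "dna_nM",
    "k_u", "k_u_err", "L", "L0", "LB", "n", "printed_velocity",
]

_ROWS = [
    # excess-enzyme design: 2 nM DNA
    ("excess_enzyme", "7T16bp ss/ds junction", "wtDda", 2, 78.4, 3.8, 16, 8, 0, 3, 209),
    ("excess_enzyme", "7T16bp fork", "wtDda", 2, 71.9, 8.9, 16, 8, 2, 2, 216),
    ("excess_enzyme", "7T16bp ss/ds junction", "K24A-K25A", 2, 62.5, 2.5, 16, 8, 0, 3, 166),
    ("excess_enzyme", "7T16bp fork", "K24A-K25A", 2, 50.7, 3.7, 16, 8, 2, 2, 152),
    ("excess_enzyme", "14T16bp ss/ds junction", "wtDda", 2, 63.5, 2.5, 16, 8, 0, 3, 171),
    ("excess_enzyme", "14T16bp fork", "wtDda", 2, 63.4, 8.9, 16, 8, 2, 2, 190),
    ("excess_enzyme", "7T20bp ss/ds junction", "wtDda", 2, 61.3, 4.3, 20, 8, 0, 3, 245),
    ("excess_enzyme", "7T20bp fork", "wtDda", 2, 61.9, 9.3, 20, 8, 2, 2, 310),
    # DNA-titration design: 75-300 nM DNA, wild-type enzyme
    ("dna_titration", "7T16bp ss/ds junction", "wtDda", 75, 104.0, 10.0, 16, 8, 0, 3, 277),
    ("dna_titration", "7T16bp fork", "wtDda", 75, 93.3, 17.0, 16, 8, 2, 2, 280),
    ("dna_titration", "7T16bp ss/ds junction", "wtDda", 150, 105.0, 5.0, 16, 8, 0, 3, 279),
    ("dna_titration", "7T16bp fork", "wtDda", 150, 103.0, 11.0, 16, 8, 2, 2, 309),
    ("dna_titration", "7T16bp ss/ds junction", "wtDda", 300, 114.0, 21.7, 16, 8, 0, 3, 305),
    ("dna_titration", "7T16bp fork", "wtDda", 300, 141.0, 6.8, 16, 8, 2, 2, 423),
]


def published_unwinding_parameters() -> pd.DataFrame:
    """All published rows as a DataFrame (one row per substrate/condition)."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def wt_excess_enzyme_step_sizes() -> pd.DataFrame:
    """The six wild-type excess-enzyme rows, the set over which the average
    kinetic step size is quoted."""
    df = published_unwinding_parameters()
    return df[(df.dataset == "excess_enzyme") & (df.enzyme == "wtDda")].reset_index(drop=True)
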