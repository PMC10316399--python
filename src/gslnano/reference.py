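"""Published reference values for GSL nanodomains in model membranes.

Atomistic-MD reference tables for DOPC/Chol/SM/GSL (65/25/10/5) bilayers:
per-moiety GSL-GSL hydrogen-bond counts, GSL interaction energies with
their per-partner normalisation, and headgroup/sialic-acid-water
hydrogen-bond counts, as reported for asialoGM1, GM3, GM1 and GD1a.  These
are inputs for cross-checking the package's bookkeeping (totals, ratios
and percentage changes), not quantities the package recomputes from
trajectories.

All hydrogen-bond counts are per GSL molecule; energies are kJ/mol per GSL.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "GSL_GSL_HBONDS",
    "GSL_INTERACTION_ENERGIES",
    "HEADGROUP_WATER_HBONDS",
    "SM_SM_HBONDS",
]

#: Average GSL-GSL hydrogen bonds per molecule, split by sugar moiety.
#: NaN marks moieties absent from the species.
GSL_GSL_HBONDS = pd.DataFrame(
    {
        "Sia6": [2.5, np.nan, np.nan, np.nan],
        "Gal5": [1.6, 2.0, np.nan, 1.0],
        "GalNAc4": [1.1, 1.1, np.nan, 0.9],
        "Sia3": [2.2, 2.1, 2.6, np.nan],
        "Gal2": [2.1, 0.4, 1.4, 0.4],
        "Glc1": [0.5, 0.6, 0.7, 0.5],
    },
    index=["GD1a", "GM1", "GM3", "asialoGM1"],
)

#: Reference SM-SM hydrogen-bond count per sphingomyelin molecule.
SM_SM_HBONDS = 1.0

#: Interaction energies (kJ/mol per GSL): totals per partner class and the
#: per-partner normalised values ("_norm").
GSL_INTERACTION_ENERGIES = pd.DataFrame(
    {
        "GSL_GSL": [-51.0, -56.0, -35.0],
        "GSL_GSL_norm": [-4.3, -4.7, -2.9],
        "DOPC": [-298.0, -247.0, -267.0],
        "DOPC_norm": [-3.3, -2.7, -3.0],
        "SM": [-86.0, -123.0, -101.0],
        "SM_norm": [-3.3, -4.7, -3.9],
        "Chol": [-78.0, -83.0, -88.0],
        "Chol_norm": [-1.2, -1.3, -1.4],
    },
    index=["GD1a", "GM1", "asialoGM1"],
)

#: Headgroup-water and per-sialic-moiety-water hydrogen bonds per GSL, for
#: GSLs inside nanodomains and for one isolated GSL molecule.
HEADGROUP_WATER_HBONDS = pd.DataFrame(
    [
        ("GD1a", "headgroup", 43.5, 44.6),
        ("GD1a", "Sia1", 12.1, 12.6),
        ("GD1a", "Sia2", 12.6, 13.5),
        ("GM1", "headgroup", 32.6, 34.3),
        ("GM1", "Sia1", 12.2, 13.1),
        ("asialoGM1", "headgroup", 22.0, 22.9),
        ("SM", "headgroup", 4.3, 4.5),
    ],
    columns=["species", "group", "nanodomain", "isolated"],
)
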