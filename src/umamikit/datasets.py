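"""Packaged reference datasets.

The only shipped dataset is the published species-mean table for the six
bivalve species (nucleotides with dispersions; amino acids either printed
directly or reconstructed as taste-activity value x threshold). It lets the
whole scoring pipeline run with zero external data.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["reference_means_path", "reference_species_means", "SPECIES"]

#: the six species, in the reference table's column order
SPECIES = (
    "M. meretrix",
    "C. sinensis",
    "M. mercenaria",
    "R. philippinarum",
    "C. sikamea",
    "S. constricta",
)


def reference_means_path() -> Path:
    return Path(str(resources.files("umamikit").joinpath("data/reference_means.csv")))


def reference_species_means() -> pd.DataFrame:
    """Species x compound summary: columns species, compound, mean, sd, n.

    sd is NaN where no dispersion was published; means are mg per 100 g dry
    weight throughout.
    """
    df = pd.read_csv(reference_means_path(), comment="#")
    return df[["species", "compound", "mean", "sd", "n"]]
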