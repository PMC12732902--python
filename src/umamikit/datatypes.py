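"""Core data model shared across the analysis stages.

All concentrations cross module boundaries in one canonical unit,
mg per 100 g dry weight, to avoid silent factor-of-ten mistakes between
the HPLC (µg/g), taste-activity (mg/100 g) and umami-synergy (g/100 g)
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._util import log

__all__ = [
    "SchemaError",
    "ValidationError",
    "ThresholdMissingError",
    "PotencyMissingError",
    "ConcentrationTable",
    "ThresholdRegistry",
    "PotencyConfig",
    "CANONICAL_COMPOUNDS",
    "canonical_compound",
]


class SchemaError(ValueError):
    """An input file is missing required columns."""


class ValidationError(ValueError):
    """An input violates a data-model invariant."""


class ThresholdMissingError(KeyError):
    """A taste-activity value was requested for a compound without a threshold."""


class PotencyMissingError(KeyError):
    """An umami potency coefficient was requested for an unconfigured compound."""


#: canonical labels for the compounds handled by the default configuration
CANONICAL_COMPOUNDS = (
    "Glu", "Asp", "Ala", "Gly", "Thr", "Ser", "Arg", "His", "Val",
    "Lys", "Pro", "Tau", "GMP", "AMP", "IMP",
)
_CANON = {c.lower(): c for c in CANONICAL_COMPOUNDS}


def canonical_compound(label: str) -> str:
    """Map a compound label case-insensitively onto its canonical code.

    Unknown labels pass through unchanged but are logged once.
    """
    name = label.strip()
    canon = _CANON.get(name.lower())
    if canon is None:
        log.warning("unknown compound label %r passed through unchanged", name)
        return name
    return canon


@dataclass
class ConcentrationTable:
    """Long-format species x replicate x compound concentrations.

    The wrapped frame has columns ``species, replicate, compound,
    concentration`` (mg per 100 g) plus a single shared ``basis``
    ("dry" or "wet"). A compound not measured in a sample is an absent
    row, never a stored NaN.
    """

    data: pd.DataFrame
    basis: str = "dry"

    REQUIRED = ("species", "replicate", "compound", "concentration")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        if self.basis not in ("dry", "wet"):
            raise ValidationError(f"basis must be 'dry' or 'wet', got {self.basis!r}")
        conc = pd.to_numeric(df["concentration"], errors="coerce")
        if conc.isna().any():
            bad = df.index[conc.isna()].tolist()
            raise ValidationError(f"non-numeric or NaN concentrations at rows {bad}")
        if (conc < 0).any():
            bad = df.index[conc < 0].tolist()
            raise ValidationError(f"negative concentrations at rows {bad}")
        dup = df.duplicated(subset=["species", "replicate", "compound"])
        if dup.any():
            bad = df.index[dup].tolist()
            raise ValidationError(
                f"duplicate (species, replicate, compound) triples at rows {bad}"
            )
        self.data = df.assign(concentration=conc.astype(float)).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    @property
    def compounds(self) -> list[str]:
        return sorted(self.data["compound"].unique())


@dataclass
class ThresholdRegistry:
    """Per-compound taste class and human detection threshold (mg/100 g).

    A compound may carry a class but no threshold (e.g. taurine, or IMP
    for which no threshold is configured by default); asking for such a
    threshold raises :class:`ThresholdMissingError` rather than returning 0.
    """

    classes: dict[str, str] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    VALID_CLASSES = ("umami", "sweet", "bitter", "unflavored", "nucleotide")

    def __post_init__(self) -> None:
        for compound, cls in self.classes.items():
            if cls not in self.VALID_CLASSES:
                raise ValidationError(f"{compound}: invalid taste class {cls!r}")
        for compound, thr in self.thresholds.items():
            if not thr > 0:
                raise ValidationError(f"{compound}: threshold must be > 0, got {thr}")

    def threshold(self, compound: str) -> float:
        compound = canonical_compound(compound)
        try:
            return self.thresholds[compound]
        except KeyError:
            raise ThresholdMissingError(
                f"no taste threshold configured for {compound!r}"
            ) from None

    def has_threshold(self, compound: str) -> bool:
        return canonical_compound(compound) in self.thresholds

    def taste_class(self, compound: str) -> str | None:
        return self.classes.get(canonical_compound(compound))


@dataclass
class PotencyConfig:
    """Umami potency coefficients relative to MSG and the synergy constant.

    Defaults follow the classical mixed-synergy model: glutamate 1.000 and
    aspartate 0.077 among amino acids; AMP 0.18, IMP 1.0 and GMP 2.3 among
    5'-nucleotides; interaction coefficient 1218.
    """

    amino_potency: dict[str, float] = field(
        default_factory=lambda: {"Glu": 1.000, "Asp": 0.077}
    )
    nucleotide_potency: dict[str, float] = field(
        default_factory=lambda: {"AMP": 0.18, "IMP": 1.0, "GMP": 2.3}
    )
    synergy_constant: float = 1218.0

    def __post_init__(self) -> None:
        if not self.synergy_constant > 0:
            raise ValidationError("synergy_constant must be > 0")
        for name, table in (
            ("amino", self.amino_potency),
            ("nucleotide", self.nucleotide_potency),
        ):
            for compound, b in table.items():
                if b < 0:
                    raise ValidationError(f"{name} potency for {compound} is negative")

    def amino(self, compound: str) -> float:
        compound = canonical_compound(compound)
        try:
            return self.amino_potency[compound]
        except KeyError:
            raise PotencyMissingError(
                f"no amino-acid umami potency configured for {compound!r}"
            ) from None

    def nucleotide(self, compound: str) -> float:
        compound = canonical_compound(compound)
        try:
            return self.nucleotide_potency[compound]
        except KeyError:
            raise PotencyMissingError(
                f"no nucleotide umami potency configured for {compound!r}"
            ) from None
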