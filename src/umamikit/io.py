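"""Reading/writing concentration tables and the threshold/potency configuration."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from ._util import log, to_mg_per_100g
from .datatypes import (
    ConcentrationTable,
    PotencyConfig,
    SchemaError,
    ThresholdRegistry,
    ValidationError,
    canonical_compound,
)

__all__ = [
    "read_concentration_table",
    "write_concentration_table",
    "summarize",
    "load_config",
    "default_config_path",
]

_DEFAULT_SCHEMA = {
    "species": "species",
    "replicate": "replicate",
    "compound": "compound",
    "concentration": "concentration",
    "unit": "unit",
    "basis": "basis",
}


def read_concentration_table(
    path: str | Path, schema: dict[str, str] | None = None
) -> ConcentrationTable:
    """Read a long-format CSV/TSV of per-replicate compound concentrations.

    ``schema`` maps logical column names (species, replicate, compound,
    concentration, unit, basis) onto the file's column headers. ``unit``
    (default mg/100g; µg/g and g/100 g accepted and converted) and
    ``basis`` (default dry) columns are optional.
    """
    path = Path(path)
    cols = dict(_DEFAULT_SCHEMA, **(schema or {}))
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep, comment="#")

    required = ["species", "replicate", "compound", "concentration"]
    missing = [cols[k] for k in required if cols[k] not in raw.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")

    df = pd.DataFrame(
        {
            "species": raw[cols["species"]].astype(str).str.strip(),
            "replicate": raw[cols["replicate"]],
            "compound": raw[cols["compound"]].map(canonical_compound),
        }
    )
    conc = pd.to_numeric(raw[cols["concentration"]], errors="coerce")
    if conc.isna().any():
        bad = raw.index[conc.isna()].tolist()
        raise ValidationError(f"{path.name}: unparseable concentrations at rows {bad}")

    if cols["unit"] in raw.columns:
        units = raw[cols["unit"]].fillna("mg/100g").astype(str)
        df["concentration"] = [to_mg_per_100g(v, u) for v, u in zip(conc, units)]
    else:
        df["concentration"] = conc

    if cols["basis"] in raw.columns:
        bases = set(raw[cols["basis"]].fillna("dry").astype(str).str.strip())
        if len(bases) > 1:
            raise ValidationError(f"{path.name}: mixed bases {sorted(bases)}")
        basis = bases.pop()
    else:
        basis = "dry"

    return ConcentrationTable(df, basis=basis)


def write_concentration_table(table: ConcentrationTable, path: str | Path) -> None:
    """Write a table back to CSV in canonical units (round-trips losslessly)."""
    out = table.data.copy()
    out["unit"] = "mg/100g"
    out["basis"] = table.basis
    out.to_csv(path, index=False)


def summarize(table: ConcentrationTable) -> pd.DataFrame:
    """Per species x compound mean, sample SD (n-1 denominator) and n.

    Single-replicate cells report sd = 0. Raises on an empty table.
    """
    if len(table) == 0:
        raise ValidationError("cannot summarize an empty concentration table")
    grouped = table.data.groupby(["species", "compound"], sort=True, observed=True)[
        "concentration"
    ]
    out = grouped.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out


def default_config_path() -> Path:
    return Path(str(resources.files("umamikit").joinpath("data/default_config.yaml")))


def load_config(path: str | Path | None = None) -> tuple[ThresholdRegistry, PotencyConfig]:
    """Load the threshold/potency YAML; with no path, the packaged defaults."""
    path = default_config_path() if path is None else Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)

    classes: dict[str, str] = {}
    thresholds: dict[str, float] = {}
    for compound, entry in (cfg.get("thresholds") or {}).items():
        compound = canonical_compound(compound)
        classes[compound] = entry["class"]
        thr = entry.get("threshold_mg_per_100g")
        if thr is not None:
            thresholds[compound] = float(thr)
    registry = ThresholdRegistry(classes=classes, thresholds=thresholds)

    pot = cfg.get("potencies") or {}
    potency = PotencyConfig(
        amino_potency={
            canonical_compound(k): float(v) for k, v in (pot.get("amino") or {}).items()
        },
        nucleotide_potency={
            canonical_compound(k): float(v)
            for k, v in (pot.get("nucleotide") or {}).items()
        },
        synergy_constant=float(pot.get("synergy_constant", 1218.0)),
    )

    if thresholds.get("Asp") == 100.0:
        log.info(
            "using the reconciled aspartate threshold of 100 mg/100 g "
            "(the literature also quotes 10 mg/100 g; see config comments)"
        )
    return registry, potency
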