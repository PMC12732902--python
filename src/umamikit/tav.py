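"""Taste-activity values (TAV) and flavor-class composition.

TAV = C / T: a compound's concentration over its human detection threshold,
both in mg per 100 g dry weight. TAV >= 1 marks a compound as contributing
perceptibly to taste. Internal math is full precision; reported values are
conventionally rounded half-up to 2 decimals via ``report_round``.
"""

from __future__ import annotations

import pandas as pd

from ._util import round_half_up
from .datatypes import ThresholdRegistry, ValidationError

__all__ = ["compute_tav", "tav_table", "mean_tav", "class_proportions", "report_round"]

#: conventional activity cutoff: TAV >= 1 means a perceptible contribution
TASTE_ACTIVE = 1.0

report_round = round_half_up


def compute_tav(concentration: float, threshold: float) -> float:
    """Ratio of concentration to detection threshold (both mg/100 g)."""
    if threshold is None or not threshold > 0:
        raise ValidationError(f"threshold must be > 0, got {threshold!r}")
    if concentration < 0:
        raise ValidationError("concentration must be >= 0")
    return concentration / threshold


def tav_table(
    summary: pd.DataFrame,
    registry: ThresholdRegistry,
    compounds: list[str] | None = None,
) -> pd.DataFrame:
    """Per species x compound TAVs on species-mean concentrations.

    ``summary`` is the species x compound frame produced by
    :func:`umamikit.io.summarize` (columns species, compound, mean).
    Restricts to ``compounds`` when given; a requested compound absent
    from a species' data scores 0 (absence, not missingness). Compounds
    with no configured threshold are skipped unless explicitly requested,
    in which case the registry raises.
    """
    species = sorted(summary["species"].unique())
    if compounds is None:
        compounds = [c for c in sorted(summary["compound"].unique())
                     if registry.has_threshold(c)]
    means = summary.set_index(["species", "compound"])["mean"]
    rows = []
    for sp in species:
        for comp in compounds:
            thr = registry.threshold(comp)
            conc = float(means.get((sp, comp), 0.0))
            rows.append(
                {
                    "species": sp,
                    "compound": comp,
                    "taste_class": registry.taste_class(comp),
                    "concentration": conc,
                    "threshold": thr,
                    "tav": compute_tav(conc, thr),
                }
            )
    return pd.DataFrame(rows)


def mean_tav(tavs) -> float:
    """Arithmetic mean of a non-empty collection of TAVs."""
    tavs = list(tavs)
    if not tavs:
        raise ValidationError("mean_tav of an empty collection")
    return float(sum(tavs) / len(tavs))


def class_proportions(
    summary: pd.DataFrame,
    registry: ThresholdRegistry,
    compounds: list[str] | None = None,
) -> pd.DataFrame:
    """Per-species fraction of total considered concentration by taste class.

    Fractions sum to 1 per species. Compounds without a class assignment
    are excluded; a species with zero total considered concentration is an
    error.
    """
    df = summary.copy()
    if compounds is not None:
        df = df[df["compound"].isin(compounds)]
    df = df.assign(taste_class=df["compound"].map(registry.taste_class))
    df = df[df["taste_class"].notna()]
    totals = df.groupby("species")["mean"].sum()
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValidationError(f"zero total considered concentration for {bad}")
    by_class = (
        df.groupby(["species", "taste_class"])["mean"].sum().reset_index(name="amount")
    )
    by_class["fraction"] = by_class.apply(
        lambda r: r["amount"] / totals[r["species"]], axis=1
    )
    return by_class[["species", "taste_class", "fraction"]]
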