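"""Equivalent umami concentration (EUC): the Yamaguchi synergy model.

EUC (g MSG / 100 g dry weight) = sum_i(a_i b_i)
                                + k * sum_i(a_i b_i) * sum_j(a_j b_j)

where a_i are umami amino-acid concentrations (g/100 g; Glu, Asp) with
potencies b_i relative to MSG (1.000, 0.077), a_j are flavor-nucleotide
concentrations (AMP, IMP, GMP) with potencies b_j (0.18, 1.0, 2.3), and
k = 1218 is the empirical amino-acid x nucleotide synergy coefficient.
The score is the MSG concentration with the same umami intensity as the
mixture; the synergy term means it can far exceed the total input mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .datatypes import PotencyConfig, ValidationError, canonical_compound

__all__ = ["EUCResult", "compute_euc", "euc_table", "decompose_contributions"]


@dataclass(frozen=True)
class EUCResult:
    """EUC and its decomposition, all in g per 100 g dry weight.

    ``euc = additive_term + synergy_term``; ``nucleotide_term`` is the
    nucleotide potency-weighted sum entering the synergy product.
    """

    euc: float
    additive_term: float
    nucleotide_term: float
    synergy_term: float


def _weighted_sum(conc_g: Mapping[str, float], potency_of) -> float:
    total = 0.0
    for compound, conc in conc_g.items():
        if conc < 0:
            raise ValidationError(f"negative concentration for {compound}")
        total += conc * potency_of(compound)
    return total


def compute_euc(
    amino: Mapping[str, float],
    nucleotide: Mapping[str, float],
    potency: PotencyConfig | None = None,
    unit: str = "mg/100g",
) -> EUCResult:
    """Evaluate the synergy model on compound concentration maps.

    ``amino`` maps umami amino acids (Glu, Asp) and ``nucleotide`` maps
    flavor nucleotides (AMP, IMP, GMP) to concentrations in ``unit``
    ("mg/100g", the package canonical, or "g/100g", the model's native
    unit). Every keyed compound must have a configured potency.
    """
    potency = potency or PotencyConfig()
    if unit == "mg/100g":
        scale = 1e-3
    elif unit == "g/100g":
        scale = 1.0
    else:
        raise ValueError(f"unit must be 'mg/100g' or 'g/100g', got {unit!r}")

    amino_g = {canonical_compound(k): v * scale for k, v in amino.items()}
    nuc_g = {canonical_compound(k): v * scale for k, v in nucleotide.items()}

    additive = _weighted_sum(amino_g, potency.amino)
    nuc_term = _weighted_sum(nuc_g, potency.nucleotide)
    synergy = potency.synergy_constant * additive * nuc_term
    return EUCResult(
        euc=additive + synergy,
        additive_term=additive,
        nucleotide_term=nuc_term,
        synergy_term=synergy,
    )


def euc_table(
    summary: pd.DataFrame,
    potency: PotencyConfig | None = None,
    replicates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-species EUC on species-mean concentrations (mg/100 g).

    ``summary`` is a species x compound frame (columns species, compound,
    mean). Only compounds with configured potencies enter; absent compounds
    contribute 0. When ``replicates`` (long frame with columns species,
    replicate, compound, concentration) is supplied, per-replicate EUCs are
    also aggregated into mean and sample SD columns — the model is
    nonlinear, so the mean of per-replicate EUCs differs from the EUC of
    mean concentrations, and both are reported.
    """
    potency = potency or PotencyConfig()
    aminos = set(potency.amino_potency)
    nucs = set(potency.nucleotide_potency)

    def split(conc_by_compound: Mapping[str, float]):
        a = {c: v for c, v in conc_by_compound.items() if c in aminos}
        n = {c: v for c, v in conc_by_compound.items() if c in nucs}
        return a, n

    rows = []
    for sp, grp in summary.groupby("species", sort=True, observed=True):
        conc = dict(zip(grp["compound"], grp["mean"]))
        a, n = split(conc)
        res = compute_euc(a, n, potency)
        rows.append(
            {
                "species": sp,
                "euc_g_msg_per_100g": res.euc,
                "additive_term": res.additive_term,
                "synergy_term": res.synergy_term,
            }
        )
    out = pd.DataFrame(rows)

    if replicates is not None:
        per_rep = []
        for (sp, rep), grp in replicates.groupby(["species", "replicate"], observed=True):
            conc = dict(zip(grp["compound"], grp["concentration"]))
            a, n = split(conc)
            per_rep.append({"species": sp, "euc": compute_euc(a, n, potency).euc})
        agg = (
            pd.DataFrame(per_rep)
            .groupby("species")["euc"]
            .agg(euc_replicate_mean="mean", euc_replicate_sd=lambda s: s.std(ddof=1), n="count")
            .reset_index()
        )
        out = out.merge(agg, on="species", how="left")
    return out


def decompose_contributions(result: EUCResult) -> dict[str, float]:
    """Percent shares of the additive and synergy terms in the EUC."""
    if not result.euc > 0:
        raise ValidationError("cannot decompose an EUC of 0")
    return {
        "additive_pct": 100.0 * result.additive_term / result.euc,
        "synergy_pct": 100.0 * result.synergy_term / result.euc,
    }
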