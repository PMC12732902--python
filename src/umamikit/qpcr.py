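"""Relative gene expression by the 2^-ddCt method and primer-efficiency QC.

Per replicate, dCt = Ct(target) - Ct(reference); per group (species x gene)
the mean dCt is referenced to a calibrator group, and fold change is
2^-ddCt, assuming perfect per-cycle doubling. Dilution-series standard
curves validate that assumption: efficiency = 10^(-1/slope) - 1, which is
1.0 for exact doubling (slope -1/log10(2) ~= -3.3219).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import log
from .datatypes import ValidationError

__all__ = ["EfficiencyCurve", "relative_expression", "fit_efficiency"]

CT_RANGE = (0.0, 45.0)
DEFAULT_EFFICIENCY_WINDOW = (0.9, 1.1)


@dataclass(frozen=True)
class EfficiencyCurve:
    gene: str
    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    acceptable: bool


def _validate_ct(records: pd.DataFrame) -> pd.DataFrame:
    required = ["species", "replicate", "gene", "ct_target", "ct_reference"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValidationError(f"Ct records missing columns {missing}")
    for col in ("ct_target", "ct_reference"):
        vals = pd.to_numeric(records[col], errors="coerce")
        if vals.isna().any():
            bad = records.index[vals.isna()].tolist()
            raise ValidationError(f"missing/unparseable {col} at rows {bad}")
        lo, hi = CT_RANGE
        out = ~vals.between(lo, hi, inclusive="neither")
        if out.any():
            bad = records.index[out].tolist()
            raise ValidationError(f"{col} outside ({lo}, {hi}) at rows {bad}")
    return records


def relative_expression(
    records: pd.DataFrame, calibrator: str = "auto"
) -> pd.DataFrame:
    """Group-level relative expression from per-replicate Ct pairs.

    ``records`` has columns species, replicate, gene, ct_target,
    ct_reference. Per gene, ddCt is taken against ``calibrator`` (a species
    label, or "auto" = the species with the largest mean dCt, i.e. lowest
    expression, so every displayed fold is >= 1). Returns a frame with
    species, gene, delta_ct, delta_delta_ct, fold.

    Reference genes may legitimately differ between species; cross-species
    fold comparisons then carry a normalization caveat (logged, not fatal).
    """
    records = _validate_ct(records)
    df = records.assign(delta_ct=records["ct_target"] - records["ct_reference"])
    grouped = (
        df.groupby(["gene", "species"], sort=True, observed=True)["delta_ct"]
        .mean()
        .reset_index()
    )

    out_rows = []
    for gene, grp in grouped.groupby("gene", sort=True, observed=True):
        if calibrator == "auto":
            cal_species = grp.loc[grp["delta_ct"].idxmax(), "species"]
        else:
            if calibrator not in set(grp["species"]):
                raise ValidationError(
                    f"calibrator {calibrator!r} absent for gene {gene!r}"
                )
            cal_species = calibrator
        cal_dct = float(grp.loc[grp["species"] == cal_species, "delta_ct"].iloc[0])
        for _, row in grp.iterrows():
            ddct = row["delta_ct"] - cal_dct
            out_rows.append(
                {
                    "species": row["species"],
                    "gene": gene,
                    "delta_ct": row["delta_ct"],
                    "delta_delta_ct": ddct,
                    "fold": 2.0 ** (-ddct),
                    "calibrator": cal_species,
                }
            )
    log.info(
        "relative expression normalized per species-specific reference genes; "
        "cross-species folds assume comparable reference stability"
    )
    return pd.DataFrame(out_rows)


def fit_efficiency(
    dilutions,
    gene: str = "",
    window: tuple[float, float] = DEFAULT_EFFICIENCY_WINDOW,
) -> EfficiencyCurve:
    """Fit Ct against log10(dilution) and derive amplification efficiency.

    ``dilutions`` is an iterable of (log10_dilution, ct) pairs or dicts with
    those keys; at least 3 points are required. Efficiency outside
    ``window`` is flagged (``acceptable = False``) and logged.
    """
    arr = np.asarray(
        [
            (d["log10_dilution"], d["ct"]) if isinstance(d, dict) else tuple(d)
            for d in dilutions
        ],
        dtype=float,
    )
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("efficiency fit needs at least 3 dilution points")
    x, y = arr[:, 0], arr[:, 1]
    if np.unique(x).size < 3:
        raise ValueError("efficiency fit needs at least 3 distinct dilutions")
    res = stats.linregress(x, y)
    slope = float(res.slope)
    if slope == 0:
        raise ValueError("zero slope: Ct does not respond to dilution")
    efficiency = 10.0 ** (-1.0 / slope) - 1.0
    acceptable = window[0] <= efficiency <= window[1]
    if not acceptable:
        log.warning(
            "%s: amplification efficiency %.3f outside window [%.2f, %.2f]",
            gene or "<unnamed>", efficiency, *window,
        )
    return EfficiencyCurve(
        gene=gene,
        slope=slope,
        intercept=float(res.intercept),
        efficiency=float(efficiency),
        r_squared=float(res.rvalue**2),
        acceptable=acceptable,
    )
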