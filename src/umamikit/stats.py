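"""Group comparisons and expression-metabolite correlation.

One-way ANOVA with Tukey HSD post hoc tests (Tukey-Kramer under unbalanced
group sizes) summarized as a compact letter display — the machine twin of
the superscript letters in species-comparison tables — plus the Pearson
correlation matrix between gene expression and compound content/TAV with
significance stars (* p<0.05, ** p<0.01, *** p<0.001, unadjusted).
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._util import log
from .datatypes import ValidationError

__all__ = [
    "ANOVAResult",
    "anova_oneway",
    "tukey_hsd",
    "compact_letter_display",
    "pearson_matrix",
    "strong_associations",
]

DEFAULT_ALPHA = 0.05
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class ANOVAResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


def _check_groups(groups) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValidationError("every group needs at least 2 replicates")
    return arrays


def anova_oneway(groups) -> ANOVAResult:
    """Classical one-way fixed-effects ANOVA across replicate vectors.

    The fully degenerate case (zero within-group variance and equal means)
    is reported as F = 0, p = 1; zero within-group variance with unequal
    means as F = inf, p = 0.
    """
    arrays = _check_groups(groups)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0.0:
        means = [a.mean() for a in arrays]
        if np.ptp(means) == 0.0:
            return ANOVAResult(0.0, k - 1, n - k, 1.0)
        return ANOVAResult(np.inf, k - 1, n - k, 0.0)
    f, p = sps.f_oneway(*arrays)
    return ANOVAResult(float(f), k - 1, n - k, float(p))


def tukey_hsd(groups) -> np.ndarray:
    """All-pairs Tukey HSD p-value matrix (symmetric, unit diagonal).

    Uses the studentized-range distribution with the Tukey-Kramer
    adjustment when group sizes differ. With zero pooled within-group
    variance, pairs with equal means get p = 1 and unequal means p = 0.
    """
    arrays = _check_groups(groups)
    k = len(arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0.0:
        means = np.array([a.mean() for a in arrays])
        p = (means[:, None] == means[None, :]).astype(float)
        return p
    res = sps.tukey_hsd(*arrays)
    p = np.asarray(res.pvalue, dtype=float)
    np.fill_diagonal(p, 1.0)
    return np.clip(p, 0.0, 1.0)


def _absorb(columns: list[frozenset]) -> list[frozenset]:
    """Deduplicate and drop letter columns that are proper subsets of another."""
    uniq: list[frozenset] = []
    for col in columns:
        if col not in uniq:
            uniq.append(col)
    return [c for c in uniq if not any(c < other for other in uniq)]


def compact_letter_display(
    pairwise_p: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    labels: list[str] | None = None,
    means: np.ndarray | None = None,
) -> dict[str, str]:
    """Letter codes from a pairwise p-value matrix (insert-and-absorb).

    Two groups share at least one letter iff their pairwise p >= alpha.
    Letters are assigned a, b, c, ... with 'a' attached to the column
    containing the largest group mean when ``means`` is given (the usual
    table convention), otherwise by first group index. Minimal letter
    count is not guaranteed; the sharing invariant always holds.
    """
    P = np.asarray(pairwise_p, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValidationError("pairwise p matrix must be square")
    if not np.allclose(P, P.T, atol=1e-12, equal_nan=True):
        raise ValidationError("pairwise p matrix must be symmetric")
    k = P.shape[0]
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    if len(labels) != k:
        raise ValidationError("labels length must match matrix size")

    columns: list[frozenset] = [frozenset(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if P[i, j] < alpha:
                split: list[frozenset] = []
                for col in columns:
                    if i in col and j in col:
                        split.append(col - {i})
                        split.append(col - {j})
                    else:
                        split.append(col)
                columns = _absorb([c for c in split if c])

    # deterministic letter order: column holding the best-ranked group first
    if means is not None:
        rank = np.argsort(np.argsort(-np.asarray(means, dtype=float), kind="stable"))
    else:
        rank = np.arange(k)
    columns.sort(key=lambda col: min(rank[g] for g in col))

    alphabet = list(string.ascii_lowercase)
    while len(alphabet) < len(columns):  # beyond 26 columns: aa, ab, ...
        alphabet += [a + b for a in string.ascii_lowercase for b in string.ascii_lowercase]

    out: dict[str, str] = {}
    for g in range(k):
        letters = sorted(
            alphabet[pos] for pos, col in enumerate(columns) if g in col
        )
        out[labels[g]] = "".join(letters)
    if any(not v for v in out.values()):
        raise AssertionError("letter assignment left a group unlabelled")
    return out


def _stars(p: float) -> str:
    for cut, mark in STAR_THRESHOLDS:
        if p < cut:
            return mark
    return ""


def pearson_matrix(
    expression: pd.DataFrame, variables: pd.DataFrame, min_n: int = 3
) -> pd.DataFrame:
    """Pearson r between each expression column and each variable column.

    Both frames are indexed by the shared observational unit (species);
    rows are aligned on the intersection of indices. p-values are two-sided
    from the t transform with n-2 df and deliberately unadjusted for
    multiplicity (exploratory screen); stars follow the 0.05/0.01/0.001
    convention. Zero-variance vectors yield an absent (NaN) r with a
    warning rather than a silent 0.
    """
    common = expression.index.intersection(variables.index)
    if len(common) < min_n:
        raise ValidationError(
            f"need at least {min_n} shared observations, found {len(common)}"
        )
    ex = expression.loc[common]
    va = variables.loc[common]
    rows = []
    for gene in ex.columns:
        for var in va.columns:
            x = ex[gene].to_numpy(dtype=float)
            y = va[var].to_numpy(dtype=float)
            if np.std(x) == 0.0 or np.std(y) == 0.0:
                log.warning("zero variance for (%s, %s): r undefined", gene, var)
                r, p = np.nan, np.nan
            else:
                r, p = sps.pearsonr(x, y)
            rows.append(
                {
                    "gene": gene,
                    "variable": var,
                    "r": float(r),
                    "p_value": float(p),
                    "stars": "" if np.isnan(p) else _stars(p),
                    "n": len(common),
                }
            )
    return pd.DataFrame(rows)


def strong_associations(
    matrix: pd.DataFrame, r_min: float = 0.8, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Report filter for the headline associations: |r| > r_min and p < alpha."""
    m = matrix.dropna(subset=["r", "p_value"])
    return m[(m["r"].abs() > r_min) & (m["p_value"] < alpha)].reset_index(drop=True)
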