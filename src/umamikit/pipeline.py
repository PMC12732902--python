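"""End-to-end orchestration: quantify -> TAV -> EUC -> expression -> stats.

``run_pipeline`` composes the individual modules with no hidden state, so
its outputs are identical to calling each stage by hand, and writes a
diffable Markdown report plus the CSV tables behind it. ``reproduce``
runs the scoring stages on the packaged reference species-mean dataset.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._util import log, round_half_up
from .datasets import reference_means_path, reference_species_means
from .datatypes import PotencyConfig, ThresholdRegistry
from .euc import euc_table
from .io import load_config, read_concentration_table, summarize
from .qpcr import relative_expression
from .stats import anova_oneway, compact_letter_display, pearson_matrix, tukey_hsd
from .tav import tav_table

__all__ = ["AnalysisReport", "run_pipeline", "reproduce", "group_letters"]


@dataclass
class AnalysisReport:
    tav: pd.DataFrame
    euc: pd.DataFrame
    stats: pd.DataFrame | None
    correlations: pd.DataFrame | None
    provenance: dict = field(default_factory=dict)


def _sha256(path: str | Path | None) -> str | None:
    if path is None:
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def group_letters(table: pd.DataFrame, compound: str, alpha: float = 0.05) -> dict:
    """ANOVA + Tukey HSD letters across species for one compound's replicates.

    ``table`` is a long replicate-level frame (species, replicate, compound,
    concentration). Returns {species: letters} plus the ANOVA row under the
    key ``"_anova"``.
    """
    sub = table[table["compound"] == compound]
    species = sorted(sub["species"].unique())
    groups = [sub.loc[sub["species"] == sp, "concentration"].to_numpy() for sp in species]
    res = anova_oneway(groups)
    letters = compact_letter_display(
        tukey_hsd(groups),
        alpha=alpha,
        labels=species,
        means=[g.mean() for g in groups],
    )
    letters["_anova"] = res
    return letters


def _stats_table(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    rows = []
    for compound in sorted(table["compound"].unique()):
        sub = table[table["compound"] == compound]
        counts = sub.groupby("species").size()
        if len(counts) < 2 or (counts < 2).any():
            log.warning("skipping group stats for %s: needs >=2 replicates per species", compound)
            continue
        letters = group_letters(table, compound, alpha=alpha)
        anova = letters.pop("_anova")
        for sp, lett in letters.items():
            grp = sub[sub["species"] == sp]["concentration"]
            rows.append(
                {
                    "compound": compound,
                    "species": sp,
                    "mean": grp.mean(),
                    "sd": grp.std(ddof=1),
                    "n": len(grp),
                    "letters": lett,
                    "anova_f": anova.f_statistic,
                    "anova_p": anova.p_value,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    compounds_path: str | Path,
    ct_path: str | Path | None = None,
    config_path: str | Path | None = None,
    outdir: str | Path | None = None,
    calibrator: str = "auto",
    alpha: float = 0.05,
) -> AnalysisReport:
    """Run the full analysis on a replicate-level concentration CSV.

    Stages: summary statistics, taste-activity values, umami-equivalent
    scores (species-mean and per-replicate), per-compound ANOVA/Tukey
    letters, and — when Ct records are supplied — relative expression and
    the expression x compound/TAV Pearson matrix. Writes tav.csv, euc.csv,
    stats.csv, correlations.csv and report.md into ``outdir`` when given.
    """
    registry, potency = load_config(config_path)
    table = read_concentration_table(compounds_path)
    summary = summarize(table)

    tav = tav_table(summary, registry)
    euc = euc_table(summary, potency, replicates=table.data)
    stats_df = _stats_table(table.data, alpha=alpha)

    correlations = None
    if ct_path is not None:
        ct = pd.read_csv(ct_path, comment="#")
        rel = relative_expression(ct, calibrator=calibrator)
        expr_wide = rel.pivot(index="species", columns="gene", values="fold")
        conc_wide = summary.pivot(index="species", columns="compound", values="mean")
        tav_wide = tav.pivot(index="species", columns="compound", values="tav")
        tav_wide.columns = [f"TAV:{c}" for c in tav_wide.columns]
        variables = pd.concat([conc_wide, tav_wide], axis=1)
        correlations = pearson_matrix(expr_wide, variables)

    report = AnalysisReport(
        tav=tav,
        euc=euc,
        stats=stats_df if not stats_df.empty else None,
        correlations=correlations,
        provenance={
            "package_version": __version__,
            "compounds_sha256": _sha256(compounds_path),
            "ct_sha256": _sha256(ct_path),
            "config_sha256": _sha256(config_path) if config_path else "default",
            "calibrator": calibrator,
            "alpha": alpha,
        },
    )
    if outdir is not None:
        write_report(report, outdir)
    return report


def reproduce(config_path: str | Path | None = None) -> AnalysisReport:
    """Score the packaged reference species-mean dataset (no external data).

    Replicate-level statistics are unavailable (the dataset holds means
    only), so the report carries TAV and EUC tables alone.
    """
    registry, potency = load_config(config_path)
    summary = reference_species_means()
    tav = tav_table(summary, registry)
    euc = euc_table(summary, potency)
    return AnalysisReport(
        tav=tav,
        euc=euc,
        stats=None,
        correlations=None,
        provenance={
            "package_version": __version__,
            "compounds_sha256": _sha256(reference_means_path()),
            "config_sha256": _sha256(config_path) if config_path else "default",
        },
    )


def write_report(report: AnalysisReport, outdir: str | Path) -> None:
    """Write the CSV tables and a Markdown digest of an analysis."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.tav.to_csv(outdir / "tav.csv", index=False)
    report.euc.to_csv(outdir / "euc.csv", index=False)
    if report.stats is not None:
        report.stats.to_csv(outdir / "stats.csv", index=False)
    if report.correlations is not None:
        report.correlations.to_csv(outdir / "correlations.csv", index=False)

    lines = ["# umamikit analysis report", ""]
    lines += ["## Provenance", ""]
    for k, v in report.provenance.items():
        lines.append(f"- {k}: {v}")
    lines += ["", "## Equivalent umami concentration (g MSG/100 g dry weight)", ""]
    for _, row in report.euc.iterrows():
        lines.append(
            f"- {row['species']}: {round_half_up(row['euc_g_msg_per_100g'])}"
        )
    lines += ["", "## Taste-activity values (TAV >= 1 is taste-active)", ""]
    for _, row in report.tav.sort_values(["compound", "species"]).iterrows():
        lines.append(
            f"- {row['species']} {row['compound']}: {round_half_up(row['tav'])}"
        )
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
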