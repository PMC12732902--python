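"""Synthetic study generator.

Emulates the measurements the analysis consumes, with the statistical
structure the downstream methods assume:

* replicate compound concentrations: lognormal per species x compound,
  moment-matched so the configured means/SDs are hit in expectation
  (lognormal rather than Gaussian to guarantee positivity);
* paired gene expression: a latent Gaussian coupling at the species level,
  z_gene = rho * z_compound + sqrt(1 - rho^2) * noise, so the population
  Pearson correlation between expression level and species-mean compound
  content is exactly the configured rho (both margins are kept Gaussian;
  a nonlinear margin would distort Pearson r);
* qPCR Ct records derived from the drawn expression levels so the
  2^-ddCt chain recovers them (dCt = -log2(expression) + noise);
* HPLC standard series: areas linear in concentration plus Gaussian noise.

One global seed is split into fixed, named substreams so adding a new
generator never perturbs existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ConcentrationTable, ValidationError
from .datasets import SPECIES, reference_species_means

__all__ = [
    "GeneratorConfig",
    "SimulatedStudy",
    "default_compound_params",
    "generate_compound_table",
    "generate_expression_and_compounds",
    "generate_hplc_standards",
]

_STREAMS = {"compounds": 0, "expression": 1, "standards": 2}

#: default latent couplings gene -> (compound, rho). The GLUD1-Glu value is
#: the study system's headline coefficient; the rest are plausible signs and
#: magnitudes for the remaining umami-metabolism genes (synthetic choices).
DEFAULT_COUPLINGS: dict[str, tuple[str, float]] = {
    "GLUD1": ("Glu", 0.90),
    "GOT1": ("Asp", 0.60),
    "ADSS": ("Glu", 0.60),
    "HPRT1": ("Glu", -0.60),
}

_FALLBACK_CV = 0.10  # within-species CV where no SD was published
_SYNTHETIC_ASP = (150.0, 22.5)  # stand-in for species whose Asp mean is unpublished


def default_compound_params() -> dict[str, dict[str, tuple[float, float]]]:
    """Per-species (mean, sd) keyed to the packaged reference means.

    Where no SD was published, a 10% CV is assumed; species with no
    published aspartate mean receive a synthetic stand-in so every species
    carries the full umami compound set.
    """
    ref = reference_species_means()
    params: dict[str, dict[str, tuple[float, float]]] = {sp: {} for sp in SPECIES}
    for _, row in ref.iterrows():
        mean = float(row["mean"])
        sd = float(row["sd"]) if pd.notna(row["sd"]) else mean * _FALLBACK_CV
        params[row["species"]][row["compound"]] = (mean, sd)
    for sp in SPECIES:
        params[sp].setdefault("Asp", _SYNTHETIC_ASP)
    return params


@dataclass
class GeneratorConfig:
    """Stated world for the synthetic study.

    Defaults: six species with the published compound means/SDs, ten
    biological replicates per species, four umami-metabolism genes with the
    couplings in :data:`DEFAULT_COUPLINGS`, species-level expression levels
    ~ N(10, 2) in arbitrary units, reference Ct ~ N(20, 0.15) and 0.25
    cycles of technical Ct noise.
    """

    species: tuple[str, ...] = SPECIES
    compound_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=default_compound_params
    )
    n_replicates: int = 10
    couplings: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_COUPLINGS)
    )
    expression_mean: float = 10.0
    expression_sd: float = 2.0
    ct_reference_mean: float = 20.0
    ct_reference_sd: float = 0.15
    ct_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValidationError("n_replicates must be >= 2")
        for sp, comps in self.compound_params.items():
            for comp, (mean, sd) in comps.items():
                if mean < 0 or sd < 0:
                    raise ValidationError(f"{sp}/{comp}: mean and sd must be >= 0")
        for gene, (comp, rho) in self.couplings.items():
            if not -1.0 <= rho <= 1.0:
                raise ValidationError(f"{gene}: rho must lie in [-1, 1], got {rho}")
        if self.expression_sd < 0 or self.ct_reference_sd < 0 or self.ct_noise_sd < 0:
            raise ValidationError("dispersion parameters must be >= 0")


@dataclass
class SimulatedStudy:
    """Paired synthetic outputs of one simulated study."""

    ct_records: pd.DataFrame
    compounds: ConcentrationTable
    #: species-level truth: expression level per gene (index = species)
    expression_truth: pd.DataFrame
    #: species-level truth: mean concentration per compound (index = species)
    compound_truth: pd.DataFrame


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


def _lognormal_moment_matched(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Lognormal draws with the requested arithmetic mean and SD."""
    if mean == 0.0:
        return np.zeros(size)
    if sd == 0.0:
        return np.full(size, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def generate_compound_table(config: GeneratorConfig, seed: int = 0) -> ConcentrationTable:
    """Replicate-level concentration table for the configured species."""
    rng = _rng(seed, "compounds")
    rows = []
    for sp in config.species:
        for comp in sorted(config.compound_params[sp]):
            mean, sd = config.compound_params[sp][comp]
            draws = _lognormal_moment_matched(rng, mean, sd, config.n_replicates)
            for rep, value in enumerate(draws, start=1):
                rows.append(
                    {
                        "species": sp,
                        "replicate": rep,
                        "compound": comp,
                        "concentration": float(value),
                    }
                )
    return ConcentrationTable(pd.DataFrame(rows))


def _between_species_population(
    config: GeneratorConfig,
) -> dict[str, tuple[float, float]]:
    """Grand mean and between-species SD per compound, from configured means."""
    out: dict[str, tuple[float, float]] = {}
    compounds = sorted({c for comps in config.compound_params.values() for c in comps})
    for comp in compounds:
        means = [
            config.compound_params[sp][comp][0]
            for sp in config.species
            if comp in config.compound_params[sp]
        ]
        if len(means) < 2:
            continue
        out[comp] = (float(np.mean(means)), float(np.std(means, ddof=1)))
    return out


def generate_expression_and_compounds(
    config: GeneratorConfig, seed: int = 0, n_species: int | None = None
) -> SimulatedStudy:
    """Paired expression and compound data with the configured couplings.

    With ``n_species`` beyond the configured list, pseudo-species are drawn
    from the between-species population implied by the configured means
    (grand mean, between-species SD per compound) — this is how correlation
    recovery is checked at large n, since the real design only offers six
    species-level points.
    """
    n = n_species if n_species is not None else len(config.species)
    if n < 3:
        raise ValidationError("need at least 3 species for correlation structure")
    if n == len(config.species):
        labels = list(config.species)
    else:
        labels = [f"sim{idx:06d}" for idx in range(1, n + 1)]

    pop = _between_species_population(config)
    compounds = sorted(pop)
    rng = _rng(seed, "expression")

    z_comp = {comp: rng.standard_normal(n) for comp in compounds}
    comp_means = {
        comp: np.maximum(pop[comp][0] + pop[comp][1] * z_comp[comp], 1e-9)
        for comp in compounds
    }

    expression = {}
    for gene, (comp, rho) in sorted(config.couplings.items()):
        if comp not in z_comp:
            raise ValidationError(f"{gene} is coupled to unknown compound {comp!r}")
        eps = rng.standard_normal(n)
        z_gene = rho * z_comp[comp] + np.sqrt(1.0 - rho**2) * eps
        expression[gene] = np.maximum(
            config.expression_mean + config.expression_sd * z_gene, 1e-9
        )

    expression_truth = pd.DataFrame(expression, index=pd.Index(labels, name="species"))
    compound_truth = pd.DataFrame(
        {c: comp_means[c] for c in compounds}, index=pd.Index(labels, name="species")
    )

    # replicate-level concentrations around each species-level mean, with a
    # within-species CV borrowed from the configured dispersions
    cv_by_comp = {}
    for comp in compounds:
        cvs = [
            sd / mean
            for sp in config.species
            for c, (mean, sd) in config.compound_params[sp].items()
            if c == comp and mean > 0 and sd > 0
        ]
        cv_by_comp[comp] = float(np.mean(cvs)) if cvs else _FALLBACK_CV

    # categorical label columns: orders of magnitude cheaper than object
    # strings to build and to check for duplicate triples at large n
    n_rep = config.n_replicates
    species_codes = np.repeat(np.arange(n), n_rep)
    rep_ids = np.tile(np.arange(1, n_rep + 1), n)

    def species_col() -> pd.Categorical:
        return pd.Categorical.from_codes(species_codes, categories=labels)

    conc_frames = []
    for comp in compounds:
        means_vec = comp_means[comp]
        cv = cv_by_comp[comp]
        sigma2 = np.log1p(cv**2)
        mu = np.log(means_vec) - sigma2 / 2.0
        draws = rng.lognormal(
            mean=mu[:, None], sigma=np.sqrt(sigma2), size=(n, n_rep)
        ) if cv > 0 else np.repeat(means_vec[:, None], n_rep, axis=1)
        conc_frames.append(
            pd.DataFrame(
                {
                    "species": species_col(),
                    "replicate": rep_ids,
                    "compound": pd.Categorical([comp] * (n * n_rep), categories=compounds),
                    "concentration": draws.ravel(),
                }
            )
        )
    compounds_table = ConcentrationTable(
        pd.concat(conc_frames, ignore_index=True)
    )

    # Ct records reproducing the drawn expression through the 2^-ddCt chain
    genes = sorted(config.couplings)
    ct_frames = []
    for gene in genes:
        true_dct = -np.log2(expression_truth[gene].to_numpy())
        ct_ref = rng.normal(
            config.ct_reference_mean, config.ct_reference_sd, size=(n, n_rep)
        )
        ct_tgt = ct_ref + true_dct[:, None] + rng.normal(
            0.0, config.ct_noise_sd, size=(n, n_rep)
        )
        ct_frames.append(
            pd.DataFrame(
                {
                    "species": species_col(),
                    "replicate": rep_ids,
                    "gene": pd.Categorical([gene] * (n * n_rep), categories=genes),
                    "ct_target": ct_tgt.ravel(),
                    "ct_reference": ct_ref.ravel(),
                }
            )
        )
    ct_records = pd.concat(ct_frames, ignore_index=True)

    return SimulatedStudy(ct_records, compounds_table, expression_truth, compound_truth)


def generate_hplc_standards(
    slope: float = 100.0,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    levels: list[float] | None = None,
    seed: int = 0,
) -> list[dict[str, float]]:
    """Standard series: area = slope * conc + intercept + N(0, noise_sd).

    Default levels are six points spanning the 0.1-50 µg/mL working range
    of a 5'-nucleotide assay, geometrically spaced.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if levels is None:
        levels = list(np.geomspace(0.1, 50.0, 6))
    rng = _rng(seed, "standards")
    noise = rng.normal(0.0, noise_sd, len(levels)) if noise_sd > 0 else np.zeros(len(levels))
    return [
        {"conc": float(c), "area": float(slope * c + intercept + e)}
        for c, e in zip(levels, noise)
    ]
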