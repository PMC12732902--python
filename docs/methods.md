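# Methods

## Scope and data model

`umamikit` operates on three kinds of input: long-format per-replicate
compound concentration tables (species × replicate × compound), qPCR cycle
thresholds (target and reference gene per replicate), and HPLC standard
series (concentration vs. peak area). All concentrations cross module
boundaries in a single canonical unit, **mg per 100 g dry weight**; µg/g
(×0.1) and g/100 g (×1000) inputs are converted on read. The literature
this field draws on mixes µg/g (HPLC), mg/100 g (thresholds) and g/100 g
(synergy model) — a single canonical unit removes the silent factor-of-ten
errors that conversion-at-use invites.

A compound not measured in a sample is an **absent row**, never a stored
NaN; downstream scoring treats absence as concentration 0 (e.g. IMP, which
is typically undetectable in fresh bivalve tissue because phosphatases
degrade it rapidly post-sampling).

## HPLC quantification

Calibration standards are fit by **unweighted ordinary least squares**
(area on concentration). No weighting scheme is used because acceptance of
a curve is defined by a plain R² criterion (R² > 0.995 over the
0.1–50 µg/mL working range); a weighted fit would change the estimator
without changing the acceptance semantics. Inverse predictions below the
intercept floor to 0 with a warning (trace-level noise), and predictions
beyond 1.2× the calibrated maximum warn about extrapolation. Tissue
content is `C·V/W` (µg/g), where the extract volume V represents the
pooled supernatant of the extraction; multi-step extraction is a
sample-preparation fact, not a computation.

## Taste-activity values

`TAV = C/T` with full-precision internals; reported values round
half-away-from-zero to 2 decimals (the table convention; banker's rounding
would disagree on exact halves). Requesting a TAV for a compound without a
configured threshold is an **error naming the compound**, never a silent
zero — a missing threshold is a configuration gap, not evidence of
tastelessness.

Default thresholds (mg/100 g): Glu 30, Asp 100, Ala 6, Gly 13, Thr 26,
Ser 15, Arg 50, His 20, Val 15, Lys 5, Pro 30, GMP 12.5, AMP 50.
**Aspartate is the one deliberate deviation from the common literature
list**, which quotes 10 mg/100 g: the published per-species Asp TAVs and
umami-equivalent scores this package reproduces are mutually consistent
only with T = 100 (e.g. a Venus-clam Asp TAV of 0.86 together with an EUC
of 283.23). The 10 mg/100 g alternative is kept, commented, in the shipped
YAML, and loading the default logs a note. IMP carries an umami potency
but no invented threshold; taurine is classed unflavored with no
threshold and appears only in composition breakdowns.

Lysine's "unflavored" class label is kept as conventionally printed even
though it carries a threshold; class labels are configuration, not
chemistry.

## Equivalent umami concentration

The Yamaguchi mixed-synergy model:

EUC = Σᵢ aᵢbᵢ + k·(Σᵢ aᵢbᵢ)(Σⱼ aⱼbⱼ),  k = 1218

with potencies Glu 1.000, Asp 0.077, AMP 0.18, IMP 1.0, GMP 2.3, all
relative to MSG, and concentrations in g/100 g. Useful identities the
tests enforce: pure glutamate at c g/100 g gives EUC = c (MSG identity);
scaling every concentration by κ scales the additive term by κ and the
synergy term by κ²; EUC is monotone non-decreasing in every concentration.
No cap is applied — the bilinear synergy term legitimately pushes EUC far
above 100 g/100 g for nucleotide-rich tissue.

Because the model is nonlinear, **EUC of mean concentrations ≠ mean of
per-replicate EUCs**. The headline per-species score is computed on
species-mean concentrations (this is what reproduces published
species-level values); `euc_table(..., replicates=...)` additionally
reports the per-replicate mean ± SD so users can quantify the gap.

## Relative expression (2^−ΔΔCt)

Per replicate, ΔCt = Ct(target) − Ct(reference); group ΔCt is the mean
over replicates; ΔΔCt references a calibrator group; fold = 2^−ΔΔCt with
amplification efficiency **assumed exactly 2.0**. Measured efficiencies
from dilution-series curves (efficiency = 10^(−1/slope) − 1, acceptance
window 0.9–1.1 by default) are validation-only and are not folded into an
efficiency-corrected model — the classic method is what it is, and mixing
correction schemes silently would change the estimand.

Calibrator `"auto"` picks the group with the largest mean ΔCt (lowest
expression), making all displayed folds ≥ 1. Reference genes legitimately
differ between species (ribosomal, actin and elongation-factor controls);
cross-species fold comparisons therefore carry a logged caveat rather than
an error.

## Group statistics

- One-way ANOVA (scipy); the fully degenerate case (zero within-group
  variance, equal means) is defined as F = 0, p = 1.
- Tukey HSD via the studentized-range distribution, with the Tukey–Kramer
  adjustment under unequal group sizes (replicate counts vary in practice).
- **Compact letter display** by insert-and-absorb: start with one column
  holding all groups; for each significant pair, split every column
  containing both; absorb columns that became subsets. The algorithm
  guarantees the defining invariant — *two groups share a letter iff their
  pairwise p ≥ α* — in both directions, but not minimal letter count.
  Letter 'a' attaches to the column containing the largest group mean,
  matching table convention. α defaults to 0.05.
- Pearson correlations between expression folds and compound
  content/TAVs: two-sided p from the t transform with n−2 df,
  **deliberately unadjusted** for multiplicity (exploratory screen; the
  report filter instead emphasizes |r| > 0.8 with p < 0.05). Zero-variance
  vectors yield an absent r with a warning.

## Synthetic data generator

The generator emulates a six-species, ten-replicate study (ten biological
individuals per species is the sampling design emulated):

- **Replicate concentrations** are lognormal, moment-matched so the
  configured per-species mean and SD are hit in expectation; lognormality
  guarantees positivity. Defaults are keyed to the packaged reference
  means; where no SD was published a 10% CV is assumed. Aspartate means
  for the three species where none was published use a synthetic stand-in
  (150 ± 22.5 mg/100 g).
- **Gene–metabolite coupling** is imposed at the species level through a
  latent Gaussian construction: z_gene = ρ·z_compound + √(1−ρ²)·ε, with
  both margins affine-Gaussian (species-mean concentration, expression
  level ~ N(10, 2) arbitrary units). Keeping both margins Gaussian makes
  the *population Pearson correlation exactly ρ*; a lognormal expression
  margin would attenuate it. Default couplings: GLUD1–Glu ρ = 0.90 (the
  study system's headline coefficient); GOT1–Asp 0.60, ADSS–Glu 0.60,
  HPRT1–Glu −0.60 are plausible synthetic choices for the remaining
  umami-metabolism genes, not published estimates.
- **Ct records** are derived from the drawn expression levels
  (ΔCt = −log2(expression) plus N(0, 0.25) cycles of technical noise,
  reference Ct ~ N(20, 0.15)), so the 2^−ΔΔCt chain recovers the drawn
  folds up to calibrator scale.
- **Correlation recovery at large n** uses pseudo-species drawn from the
  between-species population implied by the configured means (grand mean,
  between-species SD per compound): the real design offers only six
  species-level points, so convergence of r̂ to ρ is checked on simulated
  species.
- A single global seed is split into fixed named substreams (compounds,
  expression, standards), so adding a generator never perturbs existing
  draws; identical config + seed gives byte-identical output.

What a green synthetic test does **not** establish: the generator draws
compounds independently across compounds (no amino-acid covariance
structure), uses one dispersion term (no biological/technical variance
split — the underlying design does not distinguish them), and has no
seasonal or environmental covariates. Recovery of ρ on pseudo-species says
the estimator and the generator agree, not that six real species give a
stable estimate — at n = 6 the sampling error of r is large, which is why
exploratory screens at that scale emphasize |r| > 0.8.

## Numerical conventions and degenerate inputs

- Reporting rounds half-away-from-zero at 2 decimals; all internal math is
  double precision.
- Empty tables, zero totals in composition fractions, missing thresholds
  or potencies, mixed dry/wet bases, duplicate (species, replicate,
  compound) triples, and Ct values outside (0, 45) are hard errors with
  row references; unknown compound labels pass through with a logged
  warning.
- Negative inverse predictions floor at 0 (warned); lognormal
  moment-matching returns a constant when SD = 0 and zeros when mean = 0.

## Known limitations

- Published mean Glu/Asp TAV aggregates (14.23 / 1.99) are not exactly
  reproducible from the six published per-species values (the printed
  per-species Glu TAVs average 13.73); the package computes aggregates
  from its inputs and does not force published aggregate values.
- The hard-clam (M. mercenaria) EUC recomputed from 2-decimal published
  activity ratios prints 284.94 vs. the published 284.93 — input rounding
  propagates ~0.1 through the synergy term, so agreement is to one
  reporting ulp.
- Three species' EUC cannot be fully recovered from published values
  (their aspartate means were never printed); the packaged dataset scores
  them without Asp, as explicit lower bounds.
- No wet↔dry basis conversion (moisture contents unavailable), no
  chromatogram/peak-integration handling (peak areas enter as numbers),
  no multivariate (PERMANOVA-style) species comparison, and no
  psychophysical saturation modeling — EUC is a chemical index of umami
  potential, not a prediction of perceived intensity.
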