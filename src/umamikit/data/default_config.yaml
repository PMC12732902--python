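# Default taste thresholds (mg per 100 g dry weight) and umami potency
# coefficients for the bivalve umami-profiling pipeline.
#
# Thresholds follow the classical human-gustation literature values used
# for shellfish taste-activity scoring. The aspartate entry is 100 mg/100 g:
# some sources quote 10 mg/100 g, but the reported per-species Asp
# taste-activity values and umami-equivalent scores this package reproduces
# are mutually consistent only with 100. Swap in the commented alternative
# to use the stricter value.
thresholds:
  Glu: {class: umami, threshold_mg_per_100g: 30}
  Asp: {class: umami, threshold_mg_per_100g: 100}
  # Asp: {class: umami, threshold_mg_per_100g: 10}   # alternative literature value
  Ala: {class: sweet, threshold_mg_per_100g: 6}
  Gly: {class: sweet, threshold_mg_per_100g: 13}
  Thr: {class: sweet, threshold_mg_per_100g: 26}
  Ser: {class: sweet, threshold_mg_per_100g: 15}
  Arg: {class: bitter, threshold_mg_per_100g: 50}
  His: {class: bitter, threshold_mg_per_100g: 20}
  Val: {class: bitter, threshold_mg_per_100g: 15}
  Lys: {class: unflavored, threshold_mg_per_100g: 5}
  Pro: {class: unflavored, threshold_mg_per_100g: 30}
  # Taurine is abundant in bivalve tissue but tasteless; it appears in
  # composition breakdowns yet never in taste-activity or umami scoring.
  Tau: {class: unflavored}
  GMP: {class: nucleotide, threshold_mg_per_100g: 12.5}
  AMP: {class: nucleotide, threshold_mg_per_100g: 50}
  # IMP has an umami potency but no configured threshold (it is typically
  # undetectable in fresh bivalve tissue); supply one to score its TAV.
  IMP: {class: nucleotide}

potencies:
  amino:
    Glu: 1.000
    Asp: 0.077
  nucleotide:
    AMP: 0.18
    IMP: 1.0
    GMP: 2.3
  synergy_constant: 1218
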