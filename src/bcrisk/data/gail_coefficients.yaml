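# Relative-risk coefficient bundle for the Gail breast-cancer model.
#
# log_rr terms follow the Gail et al. (1989) model-2 parameterization
# (per-category log relative risks; the biopsy term gains an extra
# per-level term in the >=50 age segment; first-birth and relatives
# interact multiplicatively on the log scale per category level).
# The atypical-hyperplasia multiplier applies only to women with at
# least one biopsy.
#
# The per-group attributable-risk deflation fractions (1 - AR) and the
# companion rates table are ILLUSTRATIVE values in the published range,
# not an officially calibrated set; the engine is data-driven so a
# calibrated bundle can be swapped in without code changes.
provenance: "log-RR terms transcribed from Gail et al. (1989) model 2; (1-AR) fractions illustrative"
log_rr:
  menarche:
    GE_14: 0.0
    FROM_12_TO_13: 0.0940103
    LT_12: 0.1880206
    UNKNOWN: 0.0
  first_birth:
    LT_20: 0.0
    FROM_20_TO_24: 0.2186262
    FROM_25_TO_29_OR_NULLIPAROUS: 0.4372524
    GE_30: 0.6558786
    UNKNOWN: 0.0
  relatives:
    NONE: 0.0
    ONE: 0.9583028
    TWO_PLUS: 1.9166056
    UNKNOWN: 0.0
  biopsies:
    NONE: 0.0
    ONE: 0.5292642
    TWO_PLUS: 1.0585284
    UNKNOWN: 0.0
interactions:
  # added once per biopsy category level, in the >=50 age segment only
  biopsy_age_ge50_per_level: -0.2880425
  # multiplied by the category levels of first birth (0-3) and relatives (0-2)
  first_birth_x_relatives_per_level: -0.1908114
hyperplasia_multiplier:
  "YES": 1.82
  "NO": 0.93
  "UNKNOWN": 1.0
groups:
  asian:
    one_minus_ar_under_50: 0.4752
    one_minus_ar_50_plus: 0.5032
  white:
    one_minus_ar_under_50: 0.5788
    one_minus_ar_50_plus: 0.5788
default_group: asian
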