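# Published cohort composition and index-locus carrier counts.
# These are inputs (printed summary numbers), consumed by the acceptance
# script and by tests that rebuild the published contingency tables.
cohort1:
  n_sle: 101
  n_non_sle: 163
  n_sporadic_sle: 24
  n_families: 62
  n_familial_sle: 77
  n_familial_non_sle: 157
  n_hc: 6
  index_controls_above: 0
cohort2:
  n_sle: 80
  n_hc: 87
  index_controls_above: 14
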