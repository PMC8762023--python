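# Demo pipeline configuration: a familial discovery cohort of 101 patients
# (24 sporadic + 77 familial in 62 families) and 163 individuals without
# disease (6 healthy controls + 157 unaffected relatives), screened at the
# index 3'-UTR locus. family_structure lists (affected, unaffected) per
# family; families 7 and 26 are multi-case, so the germline carrier pairs
# below are patient pairs that family-deduplication collapses to one.
simulate: true
index_locus: T635C
out_dir: vafscreen_out
seed: 0
tails: 2
sim:
  n_sporadic_sle: 24
  n_families: 62
  n_familial_sle: 77
  n_familial_non_sle: 157
  n_hc: 6
  family_structure: [
    [2, 3], [2, 3], [2, 3], [2, 3], [2, 3], [2, 3], [2, 3],
    [2, 3], [2, 3], [2, 3], [2, 3], [2, 3], [2, 3], [2, 3],
    [1, 3], [1, 3], [1, 3], [1, 3], [1, 3], [1, 3], [1, 3],
    [1, 3], [1, 3], [1, 3], [1, 3], [2, 3], [1, 3], [1, 3],
    [1, 3], [1, 3], [1, 3], [1, 3], [1, 3], [1, 2], [1, 2],
    [1, 2], [1, 2], [1, 2], [1, 2], [1, 2], [1, 2], [1, 2],
    [1, 2], [1, 2], [1, 2], [1, 2], [1, 2], [1, 2], [1, 2],
    [1, 2], [1, 2], [1, 2], [1, 2], [1, 2], [1, 2], [1, 2],
    [1, 2], [1, 2], [1, 2], [1, 2], [1, 2], [1, 2]
  ]
  depth_range: [100000, 300000]
  control_error_mean: 0.010
  control_error_sd: 0.0058
  somatic_carrier_fraction_sle: 0.16831683168316833
  somatic_fraction_range: [0.027, 0.053]
  germline_carriers:
    - [S10, A410T, het]
    - [F7-01, A410T, het]
    - [F7-02, A410T, het]
    - [F52-01, A644C, het]
    - [F52-02, A644C, het]
    - [F26-01, K650R, het]
    - [F26-02, K650R, het]
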