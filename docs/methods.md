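# Methods

This note documents the statistical model behind `vafscreen`, the
synthetic-data generator's assumptions and defaults, the numerical
choices, and what the package's tests do and do not establish about real
data.

## 1. Read-fraction model and zygosity bands

The atomic observation is a read count pair (depth *D*, alternate reads
*k*) at one locus in one individual; the variant read fraction is
*f = k/D*.  At the depths this pipeline targets (1e5–3e5 reads), binomial
noise around a true fraction *p* has standard deviation
√(p(1−p)/D) ≤ 0.16% — small enough that fixed bands classify zygosity
reliably:

| class              | band (default)       | rationale                                   |
|--------------------|----------------------|---------------------------------------------|
| germline_hom       | f ≥ 0.90             | nearly all reads alternate                  |
| germline_het       | 0.35 ≤ f ≤ 0.65      | at D ≥ 1e5 a true 0.5 never leaves [0.49, 0.51] |
| candidate_somatic  | 0.001 < f < 0.35     | a mutant clone above the background floor   |
| background         | otherwise            | sequencing/PCR error                        |

All four boundaries are configurable (`ZygosityBands`).  Frequencies in
the gap (0.65, 0.90) fall back to `background`: values there are
inconsistent with every modelled state, and flagging them as background
rather than guessing is deliberate.

## 2. Control-derived cut-off (Westgard mean + 3 SD)

Somatic carrier status at the index locus is defined against the control
population (all individuals without the disease):

    cutoff_raw     = mean(f_controls) + 3 × sd(f_controls)      (sample SD, n−1)
    cutoff_applied = cutoff_raw truncated to 0.1% (default) or raw

The n−1 convention is the QC convention behind Westgard rules.
Truncation to one decimal of a percent reflects how such thresholds are
quoted in practice (a raw 2.74% is applied as "2.7%"); both values are
reported, and truncation can be disabled.  Classification is strict
`f > cutoff_applied` by default, with an inclusive `>=` mode, because
both phrasings occur in practice for threshold rules; the boundary case
is surfaced, not hidden.

Note that mean + 3·SD is **not** monotone in each control value — raising
a low outlier shrinks the SD faster than it raises the mean — so the
property tests assert scale/shift equivariance instead.

## 3. Exact association test

Carrier status × case status forms a 2×2 table with margins
(r₁, r₂, c₁).  Under independence the top-left count follows the
hypergeometric law; the two-tailed p-value is the probability-mass
definition:

    p = Σ  P(x)   over all x with P(x) ≤ P(a_obs) · (1 + 1e-7)

The 1e-7 relative tolerance absorbs floating-point ties, the convention
of standard exact-test implementations.  Probabilities are computed in
log space (`lgamma`) so that cohort-scale deep tails (p ≈ 3×10⁻⁸ for a
17/101 vs 0/163 split) remain accurate.  The implementation is
first-principles; `scipy.stats.fisher_exact` and an exact
integer-arithmetic enumeration serve as independent oracles in the test
suite (exhaustively for every table with total ≤ 40).  An all-zero table
is degenerate and returns p = 1.

## 4. Family de-duplication and allele frequencies

Allele frequencies of germline variants are computed over *unrelated*
individuals: all sporadic patients and non-familial controls, plus
exactly one affected and one unaffected member per family.  The family
representative is the lexicographically smallest ID — the source study
does not state which member it kept, and with germline carriers shared
within a family the choice affects only the excluded-ID report, not the
counts.  Each heterozygous carrier contributes 1 allele (homozygotes 2)
out of 2 × |unrelated set|.  With 24 sporadic patients and 62 families
the unrelated patient set has 86 members (172 alleles) regardless of
family sizes; a deduplicated A410T carrier pair plus one sporadic carrier
gives 2/172 = 1.163%.

## 5. Minus-strand gene model and annotation

The screened gene is transcribed from the minus strand, so cDNA positions
run opposite to genomic positions and cDNA alleles are reverse
complements of the forward-strand genomic alleles.  The model is a list
of colinear anchor blocks; the packaged fixture has a CDS length of
2685 nt (pinned by the published pairs c.3320 ↔ 3'-UTR 635 and
c.3329 ↔ 3'-UTR 644, which both imply CDS = 3320 − 635 = 2685, an exact
multiple of 3) and a single 700-nt 3'-UTR block anchored at
chr2:39,477,758 ↔ UTR position 1.  The anchor is verified by the
round-trip identity genomic → cDNA → genomic on every in-model position.
Real exon structure is not modelled; coding sites outside the fixture
blocks carry an explicit cDNA position in the locus table.

Labels emitted per variant:

* cDNA: `c.3320T>C` (1-based, minus-strand alleles),
* 3'-UTR continuation dialect: `U635C` (RNA alphabet, position = cDNA −
  CDS length) plus the HGVS starred form `c.*635T>C`,
* protein: `p.Ala410Thr` from the standard codon table given the
  reference codon context; stop gains use `Ter`; synonymous changes are
  `p.(=)`; frameshifting insertions between adjacent cDNA positions get
  `p.<AA><codon>fs` at the first affected codon.  In-frame insertions are
  outside the supported grammar and raise a typed error, as are
  deletions and intronic offsets.

One published inconsistency is handled explicitly: the pair
"c.1635G>A / p.Ala546Thr" is internally contradictory (position 1635 is
the third base of codon 545, where G>A is synonymous); the packaged locus
table keeps the printed name and genomic position but carries cDNA 1636
so the annotation is consistent.

## 6. AU-rich element scan

AU-rich elements (AREs) destabilise mRNAs; variants inside one can
stabilise the transcript.  `scan_are` reports maximal A/U-dense segments:
scanning left to right, the first window of `min_length` (default 50 nt)
whose A+U fraction reaches `min_au` (default 0.65) seeds a segment; the
seed is trimmed of leading non-A/U bases, extended rightward while the
fraction constraint holds, then trimmed of trailing non-A/U bases.
Reported segments never overlap and each satisfies both thresholds.  The
leading trim matters: without it, a seed window carrying a G/C prefix
can stall the extension before the element ends.  There is no canonical
ARE-calling rule in the literature; this maximal-window definition is the
package's own, and the packaged synthetic UTR carries one 62-nt element
of 69.4% AU (positions 603–664) between pure-G/C pads so any reasonable
rule finds the same boundaries.

## 7. Synthetic cohort generator

The generator produces the three tables the pipeline consumes — roster,
read counts, clinical covariates — with the statistical structure of the
emulated two-cohort study.  Defaults (all configurable in `SimConfig`):

* **Cohort composition**: 24 sporadic patients, 62 families totalling 77
  affected and 157 unaffected members (one affected index per family,
  extra affected/unaffected members dealt round-robin to the
  lowest-numbered families; an explicit per-family structure can be
  supplied, e.g. to emulate multi-case families), 6 unrelated healthy
  controls.  The validation-cohort preset is 80 sporadic patients vs 87
  controls.  Patients are 90% female; ages are drawn around medians 31
  (patients) / 40 (others) and are reporting-only.
* **Sequencing**: depth ~ Uniform{1e5 … 3e5} per individual × locus.
  Each individual has a latent background error rate drawn from a normal
  distribution truncated at zero whose *underlying* parameters are
  moment-matched (via `scipy.optimize.fsolve` on the truncated-normal
  moments) so the truncated distribution has exactly the configured
  mean 1.0% and SD 0.58% — the published values are moments of observed
  control fractions, so the generator must reproduce them after
  truncation, not before.  Alternate counts are Binomial(depth, p).
* **Somatic carriers**: a configurable fraction of patients (default
  17/101) at the index locus add a clone fraction ~ Uniform(2.7%, 5.3%)
  to their background rate.  A single clone per carrier; no clonal
  mixture structure is modelled (none is published).
* **Germline carriers**: named (individual, locus, zygosity) triples;
  heterozygotes sequence at p = 0.5, homozygotes at 1 − error.
* **Clinical covariates**: per-patient normal draws with a carrier-group
  mean shift whose default signs follow the emulated study's directions —
  anti-dsDNA up (+70 IU/mL on a 120 ± 90 baseline), C3 −14 (85 ± 22
  mg/dL), C4 −4 (16 ± 7 mg/dL), WBC −1100 (6200 ± 2100 /µL), lymphocytes
  −320 (1400 ± 600 /µL), platelets −45,000 (230,000 ± 65,000 /µL), and a
  mild SLEDAI shift of +1 (6 ± 4) sized to stay mostly non-significant at
  n ≈ 100.  Values are floored at 0; SLEDAI is an integer; 5% of entries
  per parameter are missing at random (the emulated figures report
  different n per parameter).
* **Determinism**: one integer seed; all draws flow from a single
  `numpy.random.Generator` in documented order (roster demographics;
  background rates; somatic carrier selection and clone fractions; per
  locus, depths then binomial counts).  Identical (config, seed) give
  byte-identical output tables.

What the generator does **not** emulate: raw reads, alignment artifacts,
strand bias, PCR duplicates, batch effects, age-dependent clonal
haematopoiesis, within-family genetic correlation beyond shared carrier
labels, or any correlation structure among clinical parameters.  Passing
tests therefore demonstrate that the *inference machinery* recovers known
parameters under the stated sampling model — not that the pipeline is
robust to real-world sequencing artifacts.

## 8. Clinical comparisons

Patients are split at the cut-off and each laboratory parameter is
compared with a two-sample Student's t-test (pooled variance,
df = n₁ + n₂ − 2), the test named by the emulated study; Welch's
unequal-variance form is available behind a flag.  One-tailed tests
require an explicit per-parameter direction (default direction vector:
anti-dsDNA and SLEDAI up in carriers, the rest down); the one-tailed p is
half the two-tailed p on the observed side and 1 − p/2 otherwise.
Missing values are dropped per parameter (pairwise deletion) and each
comparison reports its own group sizes.  No multiplicity adjustment is
applied across the seven parameters, matching the emulated presentation;
reports should be read accordingly.  Binary outcomes (organ involvement,
treatments) are tested against carrier status with the same exact test as
the main association.

## 9. Numerical and degenerate-input choices

* Zero depth → typed undefined-frequency error; alt > depth → input error.
* Fewer than 2 control values → insufficient-data error; a constant
  control vector yields SD 0 and cut-off = mean.
* Cut-off truncation adds 1e-12 before flooring to keep 0.0274 → 0.027
  stable against floating-point representation.
* Zero pooled variance with equal means → t = 0, p = 1; with unequal
  means the p-value is clamped to the smallest positive float so p ∈ (0, 1].
* Fisher ties use a 1 + 1e-7 relative gate; p is clamped to ≤ 1.
* `control_error_mean = 0` short-circuits to an exact zero error rate
  (no truncated normal has mean 0).
* All tables are written as TSV (IDs like `F7-01` and labels like
  `3'-UTR U635C` survive untouched) with `#`-comment headers recording
  version, seed and a config digest (the digest excludes the output
  directory, so identical analyses are byte-identical wherever written).

## 10. Problem sizes used in the checks

The shipped verification uses desk-scale problems chosen to make the
statistical assertions sharp: 10,000-control calibration of the
background model, 10,000 heterozygote draws for band classification,
exhaustive Fisher-oracle agreement over all 2×2 tables with total ≤ 40,
and 200 seeded end-to-end replicates of the discovery cohort (264
individuals at one locus each), which recover a cut-off in [2.4%, 3.1%]
and association p < 10⁻⁴ in ≥ 95% of replicates.
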