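# vafscreen

Deep-sequencing **variant-read-fraction screening** for case–control
cohorts: derive a control-based outlier threshold, classify somatic
carriers, test case–control association with an exact test, compute
family-deduplicated germline allele frequencies, and annotate variants on
a minus-strand gene — with a synthetic-cohort generator standing in for
patient sequencing data.

## The problem

Very deep amplicon sequencing (10⁵–3×10⁵ reads per locus) can detect
somatic variants carried by only a few percent of a patient's blood
cells.  At such depths the read fraction *f = alt/depth* cleanly separates
three regimes: germline heterozygotes (~50%), germline homozygotes
(~100%), and low-fraction somatic clones sitting just above the
sequencing background.  The motivating application is a lupus (SLE)
screening study of the kinase gene *MAP4K3* (*GLK*) on the minus strand
of chromosome 2, where a recurrent somatic variant in the 3'-UTR
(chr2:39,477,124 A>G, i.e. c.3320T>C or 3'-UTR U635C) marks a patient
subgroup with more active disease.

The screening logic is a clinical-laboratory QC convention (Westgard
rules): the control population defines normality, and an individual whose
variant read fraction exceeds

> cut-off = x̄₍control₎ + 3·s₍control₎   (≈ 99.7% of a normal distribution)

is called a carrier.  With control mean 1.0% and SD 0.58% this gives
2.74%, applied as 2.7%.  Carrier status is then cross-classified against
case/control status in a 2×2 table and tested with a **two-tailed Fisher
exact test** (probability-mass definition, implemented from first
principles with log-factorial accumulation so p ~ 10⁻⁸ tails stay exact).
Germline variants are reported as **allele frequencies over unrelated
individuals**: every sporadic patient plus exactly one affected and one
unaffected member per family, one allele per heterozygote out of 2N.

## Worked example

Run the packaged demo — a familial discovery cohort of 101 patients (24
sporadic + 77 familial in 62 families) and 163 individuals without
disease, with 17 patients carrying somatic clones at 2.7–5.3% and three
germline variant families spiked in:

```bash
python -m vafscreen.cli run \
    --config src/vafscreen/data/demo_config.yaml --out demo_out --seed 0
```

prints

```
cutoff 2.7000% (raw 2.7052%); cases above 18/101, controls above 0/163; fisher p = 1.114e-08
reports in demo_out
```

The cut-off recomputed from the 163 simulated controls lands at 2.7%; the
17 spiked carriers (plus one background clone that crossed the threshold
for this seed) are recovered in patients and none in controls, so the
exact test is decisive.  `demo_out/allele_frequencies.tsv` shows the
family-deduplication arithmetic — the A410T patient pair from family F7
collapses to one unrelated carrier:

```
locus   group    carriers_total  carriers_unrelated  allele_count  denominator  allele_frequency
A410T   SLE      3               2                   2             172          0.0116279...
A644C   SLE      1               1                   1             172          0.0058139...
K650R   SLE      2               1                   1             172          0.0058139...
A644C   non_SLE  1               1                   1             136          0.0073529...
```

`demo_out/calls.vcf` carries every call with forward-strand alleles and
INFO fields for read fraction, zygosity band, and the cDNA / protein /
3'-UTR labels (`c.3320T>C`, `3'-UTR U635C`, `p.Ala410Thr`, …).

The same stages are available as library functions
(`westgard_cutoff`, `fisher_exact_two_tailed`, `dedup_unrelated`,
`allele_frequency`, `genomic_to_cdna`, `scan_are`, …) and as CLI
subcommands `simulate`, `quantify`, `screen`, `associate`, `report`.

## What is synthetic

No patient-level data are included.  The cohort generator
(`vafscreen.cohort`) emulates the study's statistical structure
(cohort composition, sequencing depth, control background error with
mean 1.0% / SD 0.58%, somatic clone fractions, germline heterozygotes,
carrier-shifted clinical covariates); the gene model and 3'-UTR sequence
are compact synthetic fixtures pinned to the published coordinate pairs.
See `docs/methods.md` for the model, its defaults, and its limits.
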