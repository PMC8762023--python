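"""Variant read fractions, zygosity bands, and minus-strand annotation.

A variant's *read frequency* is simply alternate-supporting reads over
total depth at the locus.  At depths of 1e5-3e5 reads the binomial noise
around a heterozygous germline variant (true fraction 0.5) is a fraction
of a percent, so read frequency separates three regimes cleanly:

* germline heterozygous: ~50% of reads,
* germline homozygous: ~100% of reads,
* somatic (a mutant cell clone): a low fraction, here 0-5.3%.

Annotation covers the gene's two coordinate dialects: genomic (forward
strand, hg19-style ``chr2:39477124 A>G``) and cDNA on the minus strand
(``c.3320T>C``), with 3'-UTR positions numbered both as a continuation of
the cDNA ("U635C" for cDNA 3320 when the CDS is 2685 nt) and as HGVS
``c.*635T>C``.  Coding changes get ``p.`` labels from the standard codon
table; frameshifting insertions get ``p.<AA><codon>fs``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.SeqUtils import seq3

from .errors import (
    ConfigurationError,
    InputError,
    OutOfModelError,
    ReferenceMismatchError,
    UndefinedFrequencyError,
    UnsupportedAnnotationError,
)
from .genemodel import CODON_TO_AA, GeneModel, complement

_BASES = {"A", "C", "G", "T"}
_AU = {"A", "T", "U"}

ZYG_GERMLINE_HET = "germline_het"
ZYG_GERMLINE_HOM = "germline_hom"
ZYG_CANDIDATE_SOMATIC = "candidate_somatic"
ZYG_BACKGROUND = "background"


@dataclass(frozen=True)
class Locus:
    """One screened genomic site (forward-strand reference allele)."""

    name: str
    chrom: str
    pos: int
    ref_fwd: str
    region: str  # "CDS" or "UTR3"
    alt_fwd: str | None = None
    cdna_pos: int | None = None  # explicit override for sites outside model blocks
    codon_context: str | None = None  # reference codon containing the site (CDS only)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ConfigurationError(f"locus {self.name}: pos must be >= 1")
        if self.ref_fwd not in _BASES:
            raise ConfigurationError(f"locus {self.name}: ref_fwd must be one of ACGT")
        if self.region not in {"CDS", "UTR3"}:
            raise ConfigurationError(f"locus {self.name}: region must be CDS or UTR3")


@dataclass(frozen=True)
class ZygosityBands:
    """Read-frequency bands separating background, somatic and germline calls."""

    background_floor: float = 0.001
    het_low: float = 0.35
    het_high: float = 0.65
    hom_floor: float = 0.90

    def __post_init__(self) -> None:
        ordered = (
            0.0 <= self.background_floor < self.het_low < self.het_high <= self.hom_floor <= 1.0
        )
        if not ordered:
            raise ConfigurationError(
                "zygosity bands must satisfy 0 <= background_floor < het_low "
                f"< het_high <= hom_floor <= 1, got {self}"
            )


def variant_frequency(alt: int, depth: int) -> float:
    """Alternate-read fraction alt/depth at a single locus."""
    if depth == 0:
        raise UndefinedFrequencyError("variant frequency undefined at depth 0")
    if depth < 0 or alt < 0 or alt > depth:
        raise InputError(f"need 0 <= alt <= depth, got alt={alt}, depth={depth}")
    return alt / depth


def classify_zygosity(frequency: float, bands: ZygosityBands = ZygosityBands()) -> str:
    """Assign a read frequency to a zygosity class.

    Homozygous at/above ``hom_floor``; heterozygous within the het band;
    candidate somatic strictly between the background floor and the het
    band; background otherwise.
    """
    if not 0.0 <= frequency <= 1.0:
        raise InputError(f"frequency must be in [0, 1], got {frequency}")
    if frequency >= bands.hom_floor:
        return ZYG_GERMLINE_HOM
    if bands.het_low <= frequency <= bands.het_high:
        return ZYG_GERMLINE_HET
    if bands.background_floor < frequency < bands.het_low:
        return ZYG_CANDIDATE_SOMATIC
    return ZYG_BACKGROUND


# ---------------------------------------------------------------------------
# Coordinate mapping
# ---------------------------------------------------------------------------

def genomic_to_cdna(
    pos: int, ref_fwd: str, alt_fwd: str, model: GeneModel
) -> tuple[int, str, str]:
    """Map a forward-strand genomic substitution into cDNA space.

    On the minus strand both alleles are complemented, e.g. the genomic
    chr2:39,477,124 A>G becomes c.3320 T>C.
    """
    cdna_pos = model.genomic_to_cdna_pos(pos)
    if model.strand == "-":
        return cdna_pos, complement(ref_fwd), complement(alt_fwd)
    return cdna_pos, ref_fwd.upper(), alt_fwd.upper()


def cdna_to_genomic(
    cdna_pos: int, ref: str, alt: str, model: GeneModel
) -> tuple[int, str, str]:
    """Inverse of :func:`genomic_to_cdna`."""
    pos = model.cdna_to_genomic_pos(cdna_pos)
    if model.strand == "-":
        return pos, complement(ref), complement(alt)
    return pos, ref.upper(), alt.upper()


def cdna_to_utr3(cdna_pos: int, model: GeneModel) -> int:
    """3'-UTR position of a cDNA coordinate past the stop codon."""
    if cdna_pos <= model.cds_length:
        raise InputError(
            f"cDNA position {cdna_pos} is within the CDS (length {model.cds_length}), "
            "not in the 3'-UTR"
        )
    return cdna_pos - model.cds_length


def utr3_label(utr_pos: int, ref: str, alt: str) -> str:
    """UTR continuation-style label, RNA alphabet: e.g. U635C."""
    to_rna = {"T": "U"}
    return f"{to_rna.get(ref.upper(), ref.upper())}{utr_pos}{to_rna.get(alt.upper(), alt.upper())}"


def utr3_hgvs(utr_pos: int, ref: str, alt: str) -> str:
    """HGVS starred form of the same change: e.g. c.*635T>C."""
    return f"c.*{utr_pos}{ref.upper()}>{alt.upper()}"


def cdna_label(cdna_pos: int, ref: str, alt: str) -> str:
    return f"c.{cdna_pos}{ref.upper()}>{alt.upper()}"


# ---------------------------------------------------------------------------
# Protein consequences
# ---------------------------------------------------------------------------

def _normalize_codon(codon: str) -> str:
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise InputError(f"codon context must be 3 DNA bases, got {codon!r}")
    return codon


def _aa3(codon: str) -> str:
    return seq3(CODON_TO_AA[codon])  # "*" -> "Ter"


def annotate_codon_change(
    cdna_pos: int, ref: str, alt: str, codon_context: str, model: GeneModel
) -> str:
    """Protein label for a CDS substitution, e.g. c.1228 GCA G>A -> p.Ala410Thr.

    ``codon_context`` is the reference codon containing ``cdna_pos``; the
    stated reference base must match it at the in-codon offset.
    """
    if not 1 <= cdna_pos <= model.cds_length:
        raise InputError(
            f"cDNA position {cdna_pos} outside the CDS (1..{model.cds_length})"
        )
    codon = _normalize_codon(codon_context)
    ref = ref.upper().replace("U", "T")
    alt = alt.upper().replace("U", "T")
    offset = (cdna_pos - 1) % 3
    index = (cdna_pos - 1) // 3 + 1
    if codon[offset] != ref:
        raise ReferenceMismatchError(
            f"reference base {ref} does not match codon {codon} at offset {offset}"
        )
    alt_codon = codon[:offset] + alt + codon[offset + 1 :]
    ref_aa, alt_aa = CODON_TO_AA[codon], CODON_TO_AA[alt_codon]
    if ref_aa == alt_aa:
        return "p.(=)"
    return f"p.{seq3(ref_aa)}{index}{seq3(alt_aa)}"


def annotate_insertion(
    cdna_left: int,
    cdna_right: int,
    inserted: str,
    codon_context: str,
    model: GeneModel,
) -> str:
    """Frameshift label for an insertion between two adjacent cDNA positions.

    ``codon_context`` is the reference codon containing the first affected
    position (the right flank); in-frame insertions are outside the
    supported grammar and raise :class:`UnsupportedAnnotationError`.
    """
    if cdna_right != cdna_left + 1:
        raise InputError(
            f"insertion flanks must be adjacent, got {cdna_left}_{cdna_right}"
        )
    if not 1 <= cdna_right <= model.cds_length:
        raise InputError(f"insertion at c.{cdna_left}_{cdna_right} outside the CDS")
    if len(inserted) % 3 == 0:
        raise UnsupportedAnnotationError(
            "in-frame insertions are not annotated (length divisible by 3)"
        )
    codon = _normalize_codon(codon_context)
    index = (cdna_right - 1) // 3 + 1
    return f"p.{_aa3(codon)}{index}fs"


# ---------------------------------------------------------------------------
# AU-rich element scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AreSegment:
    """One AU-rich segment, 1-based inclusive coordinates."""

    start: int
    end: int
    length: int
    au_fraction: float


def scan_are(
    sequence: str, min_length: int = 50, min_au: float = 0.65
) -> list[AreSegment]:
    """Find AU-rich elements: maximal segments of A/U-dense sequence.

    Scanning left to right, the first window of ``min_length`` whose A+U
    fraction reaches ``min_au`` seeds a segment.  The seed is trimmed of
    leading non-A/U bases (the fraction can only rise), extended rightward
    one base at a time while the fraction constraint still holds, and
    finally trimmed of trailing non-A/U bases.  Reported segments never
    overlap and each satisfies both thresholds.
    """
    if not 0 < min_au <= 1:
        raise ConfigurationError(f"min_au must be in (0, 1], got {min_au}")
    if min_length < 1:
        raise ConfigurationError(f"min_length must be >= 1, got {min_length}")
    seq = sequence.upper()
    for ch in seq:
        if ch not in _BASES and ch != "U":
            raise InputError(f"non-nucleotide character in sequence: {ch!r}")
    n = len(seq)
    is_au = [1 if c in _AU else 0 for c in seq]
    prefix = [0] * (n + 1)
    for i, v in enumerate(is_au):
        prefix[i + 1] = prefix[i] + v

    def au(i: int, j: int) -> int:  # 1-based inclusive
        return prefix[j] - prefix[i - 1]

    def dense(i: int, j: int) -> bool:
        return au(i, j) >= min_au * (j - i + 1) - 1e-9

    segments: list[AreSegment] = []
    i = 1
    while i + min_length - 1 <= n:
        j = i + min_length - 1
        if not dense(i, j):
            i += 1
            continue
        lo = i
        while lo < j and not is_au[lo - 1]:
            lo += 1
        while j + 1 <= n and dense(lo, j + 1):
            j += 1
        hi = j
        while hi >= lo and not is_au[hi - 1]:
            hi -= 1
        length = hi - lo + 1
        if length >= min_length:
            segments.append(AreSegment(lo, hi, length, au(lo, hi) / length))
        i = j + 1
    return segments


# ---------------------------------------------------------------------------
# Per-call annotation table
# ---------------------------------------------------------------------------

def annotate_locus(locus: Locus, model: GeneModel) -> dict[str, str]:
    """Resolve all labels for a locus: cDNA, protein or UTR, and HGVS.

    The cDNA position comes from the gene model when the site lies inside a
    model block; a locus may instead carry an explicit ``cdna_pos`` (used
    for coding sites whose exon is not part of the compact fixture model).
    """
    if locus.alt_fwd is None:
        raise InputError(f"locus {locus.name} has no alternate allele to annotate")
    try:
        cdna_pos, ref_c, alt_c = genomic_to_cdna(
            locus.pos, locus.ref_fwd, locus.alt_fwd, model
        )
        if locus.cdna_pos is not None and locus.cdna_pos != cdna_pos:
            raise InputError(
                f"locus {locus.name}: stated cDNA position {locus.cdna_pos} "
                f"disagrees with the gene model ({cdna_pos})"
            )
    except OutOfModelError:
        if locus.cdna_pos is None:
            raise
        cdna_pos = locus.cdna_pos
        ref_c = complement(locus.ref_fwd) if model.strand == "-" else locus.ref_fwd
        alt_c = complement(locus.alt_fwd) if model.strand == "-" else locus.alt_fwd
    out = {"cdna_pos": str(cdna_pos), "cdna_label": cdna_label(cdna_pos, ref_c, alt_c)}
    if locus.region == "UTR3":
        utr_pos = cdna_to_utr3(cdna_pos, model)
        out["label"] = f"3'-UTR {utr3_label(utr_pos, ref_c, alt_c)}"
        out["hgvs"] = utr3_hgvs(utr_pos, ref_c, alt_c)
    else:
        if locus.codon_context is None:
            raise InputError(f"CDS locus {locus.name} needs a codon context")
        out["label"] = annotate_codon_change(cdna_pos, ref_c, alt_c, locus.codon_context, model)
        out["hgvs"] = out["label"]
    return out


def quantify_calls(
    counts,
    loci: Sequence[Locus],
    model: GeneModel,
    bands: ZygosityBands = ZygosityBands(),
):
    """Turn a read-count table into an annotated per-call table.

    ``counts`` is a DataFrame with columns individual_id, locus, depth, alt;
    the result adds frequency, zygosity and the locus annotation columns.
    """
    import pandas as pd

    by_name = {locus.name: locus for locus in loci}
    unknown = set(counts["locus"]) - set(by_name)
    if unknown:
        raise InputError(f"read counts reference unknown loci: {sorted(unknown)}")
    annotations = {
        name: annotate_locus(locus, model) if locus.alt_fwd is not None else
        {"cdna_pos": "", "cdna_label": "", "label": "", "hgvs": ""}
        for name, locus in by_name.items()
    }
    rows = []
    for rec in counts.itertuples(index=False):
        freq = variant_frequency(int(rec.alt), int(rec.depth))
        locus = by_name[rec.locus]
        ann = annotations[rec.locus]
        rows.append(
            {
                "individual_id": rec.individual_id,
                "locus": rec.locus,
                "chrom": locus.chrom,
                "pos": locus.pos,
                "ref": locus.ref_fwd,
                "alt_allele": locus.alt_fwd or "",
                "depth": int(rec.depth),
                "alt": int(rec.alt),
                "frequency": freq,
                "zygosity": classify_zygosity(freq, bands),
                "cdna_label": ann["cdna_label"],
                "label": ann["label"],
                "hgvs": ann["hgvs"],
            }
        )
    return pd.DataFrame(rows)
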