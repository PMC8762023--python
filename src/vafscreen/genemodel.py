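"""Minus-strand gene model: genomic <-> cDNA coordinate mapping.

The screened kinase gene (MAP4K3/GLK) is transcribed from the minus strand
of chromosome 2, so cDNA positions *increase* as hg19 genomic positions
*decrease*, and alleles reported in cDNA space are the reverse complement
of the forward-strand genomic alleles.  The model is a list of colinear
blocks, each anchoring one cDNA position to one genomic position; within a
block the mapping is ``genomic = g_anchor - (cdna - c_anchor)`` on the
minus strand (``+`` strand models use the same anchors with a positive
slope).

The default model is a compact fixture: it carries the 3'-UTR as a single
block plus small coding blocks around the codons that the screening
pipeline annotates.  Real multi-exon structure is deliberately out of
scope; the fixture is synthetic and exists so that every coordinate and
label the pipeline emits can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from Bio.Data import CodonTable

from .errors import ConfigurationError, OutOfModelError

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}

#: Standard genetic code, codon -> 1-letter amino acid; "*" marks stop.
_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TO_AA.update({codon: "*" for codon in _STANDARD.stop_codons})


def complement(base: str) -> str:
    """Complement a single nucleotide (DNA alphabet; U treated as T)."""
    try:
        return COMPLEMENT[base.upper()]
    except KeyError:
        raise ConfigurationError(f"not a nucleotide: {base!r}") from None


@dataclass(frozen=True)
class Block:
    """One colinear anchor: cDNA positions [c_anchor, c_anchor+length-1]."""

    g_anchor: int  # genomic position (1-based) of cDNA position c_anchor
    c_anchor: int  # cDNA position (1-based)
    length: int

    def contains_cdna(self, cdna_pos: int) -> bool:
        return self.c_anchor <= cdna_pos < self.c_anchor + self.length

    def genomic_range(self, strand: str) -> tuple[int, int]:
        if strand == "-":
            return (self.g_anchor - self.length + 1, self.g_anchor)
        return (self.g_anchor, self.g_anchor + self.length - 1)

    def contains_genomic(self, pos: int, strand: str) -> bool:
        lo, hi = self.genomic_range(strand)
        return lo <= pos <= hi


@dataclass
class GeneModel:
    """Coordinate system of one gene: strand, CDS length and anchor blocks."""

    chrom: str
    strand: str
    cds_length: int
    blocks: list[Block] = field(default_factory=list)
    name: str = "gene"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ConfigurationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.cds_length % 3 != 0:
            raise ConfigurationError(
                f"cds_length must be divisible by 3, got {self.cds_length}"
            )
        spans_c = sorted((b.c_anchor, b.c_anchor + b.length - 1) for b in self.blocks)
        spans_g = sorted(b.genomic_range(self.strand) for b in self.blocks)
        for spans, system in ((spans_c, "cDNA"), (spans_g, "genomic")):
            for (_, hi), (lo, _) in zip(spans, spans[1:]):
                if lo <= hi:
                    raise ConfigurationError(f"gene model blocks overlap in {system} space")

    def block_for_cdna(self, cdna_pos: int) -> Block:
        for block in self.blocks:
            if block.contains_cdna(cdna_pos):
                return block
        raise OutOfModelError(f"cDNA position {cdna_pos} outside every model block")

    def block_for_genomic(self, pos: int) -> Block:
        for block in self.blocks:
            if block.contains_genomic(pos, self.strand):
                return block
        raise OutOfModelError(f"genomic position {pos} outside every model block")

    def genomic_to_cdna_pos(self, pos: int) -> int:
        block = self.block_for_genomic(pos)
        if self.strand == "-":
            return block.c_anchor + (block.g_anchor - pos)
        return block.c_anchor + (pos - block.g_anchor)

    def cdna_to_genomic_pos(self, cdna_pos: int) -> int:
        block = self.block_for_cdna(cdna_pos)
        if self.strand == "-":
            return block.g_anchor - (cdna_pos - block.c_anchor)
        return block.g_anchor + (cdna_pos - block.c_anchor)


# ---------------------------------------------------------------------------
# Default fixture model
# ---------------------------------------------------------------------------

#: CDS length implied by the UTR continuation numbering of the screened gene:
#: cDNA 3320 is 3'-UTR position 635 and cDNA 3329 is 3'-UTR position 644, so
#: the CDS ends at 3320 - 635 = 2685 (an exact multiple of 3: 895 codons).
DEFAULT_CDS_LENGTH = 2685

#: Length of the synthetic 3'-UTR fixture sequence.
UTR_LENGTH = 700

#: Genomic anchor of 3'-UTR position 1 (cDNA 2686) on the minus strand.
#: Pinned by the published pair chr2:39,477,124 <-> cDNA 3320 (UTR 635):
#: 39,477,124 + (3320 - 2686) = 39,477,758; the companion pair
#: chr2:39,477,115 <-> cDNA 3329 checks out against the same anchor.
UTR_GENOMIC_ANCHOR = 39_477_758

# Inside the synthetic UTR, the AU-rich element spans positions 603..664
# (62 nt, 43 of them A/U -> 69.35% AU), flanked by 20-nt G/C pads so the
# element boundaries are unambiguous for any scanning rule.
ARE_START = 603
ARE_END = 664
_ARE_GC_IDX = frozenset(
    [2, 5, 8, 11, 14, 17, 20, 23, 26, 29, 33, 36, 39, 44, 47, 50, 53, 56, 59]
)


def synthetic_utr_sequence() -> str:
    """Deterministically build the 700-nt synthetic 3'-UTR fixture.

    Layout: neutral background (repeating ACGT, 50% AU) everywhere except a
    62-nt AU-rich element at positions 603..664 bracketed by pure-G/C pads.
    UTR position 635 carries T and 644 carries A, matching the forward-strand
    genomic reference alleles (A at chr2:39,477,124; T at chr2:39,477,115).
    """
    background = "ACGT"
    seq = [background[i % 4] for i in range(UTR_LENGTH)]
    for i in range(ARE_START - 21, ARE_START - 1):  # left pad, UTR 583..602
        seq[i] = "GC"[i % 2]
    for i in range(ARE_END, ARE_END + 20):  # right pad, UTR 665..684
        seq[i] = "GC"[i % 2]
    au = "AT"
    for i in range(62):
        pos = ARE_START - 1 + i
        seq[pos] = "GC"[i % 2] if i in _ARE_GC_IDX else au[i % 2]
    seq[635 - 1] = "T"
    seq[644 - 1] = "A"
    return "".join(seq)


def default_gene_model() -> GeneModel:
    """The packaged minus-strand fixture model for the screened kinase gene.

    Blocks: the whole synthetic 3'-UTR, plus coding mini-blocks around the
    codons whose genomic loci appear in the default locus table (codon 267,
    codons 648-650, codon 410).
    """
    return GeneModel(
        chrom="chr2",
        strand="-",
        cds_length=DEFAULT_CDS_LENGTH,
        name="GLK",
        blocks=[
            # 3'-UTR: cDNA 2686..3385 <-> chr2:39,477,758 down to 39,477,059
            Block(g_anchor=UTR_GENOMIC_ANCHOR, c_anchor=DEFAULT_CDS_LENGTH + 1, length=UTR_LENGTH),
            # codon 410 (c.1228-1230), anchored by chr2:39,519,957 <-> c.1228
            Block(g_anchor=39_519_957, c_anchor=1228, length=3),
            # codons 648-650 (c.1942-1950), anchored by chr2:39,499,448 <-> c.1949
            Block(g_anchor=39_499_455, c_anchor=1942, length=9),
            # codon 267 (c.799-801), anchored by chr2:39,552,878 <-> c.800
            Block(g_anchor=39_552_879, c_anchor=799, length=3),
        ],
    )


def load_packaged_utr() -> str:
    """Read the packaged synthetic UTR FASTA and return its sequence."""
    from Bio import SeqIO

    ref = resources.files("vafscreen.data").joinpath("utr_synthetic.fa")
    with resources.as_file(ref) as path:
        record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()
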