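"""Table and VCF input/output.

All tables are tab-separated UTF-8 text with a one-line column header;
report files are prefixed with ``#``-comment lines recording the tool
version, the seed and a digest of the configuration, so that two runs
with the same configuration are byte-identical.  Labels in machine-
readable columns use the ASCII apostrophe form ("3'-UTR").
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import InputError, SchemaError
from .genemodel import GeneModel, complement
from .variants import Locus

ROSTER_COLUMNS = ["individual_id", "group", "family_id", "sex", "age"]
COUNT_COLUMNS = ["individual_id", "locus", "depth", "alt"]
LOCI_COLUMNS = ["name", "chrom", "pos", "ref", "region"]
_GROUPS = {"SLE", "HC", "family_non_SLE"}


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    return table


def _line_numbers(table: pd.DataFrame, mask) -> list[int]:
    # +2: header line plus 1-based numbering (comment lines shift these,
    # but tables written by this package carry no comments above the header)
    return [int(i) + 2 for i in table.index[mask]]


def read_roster(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort roster table."""
    table = _read_tsv(path, ROSTER_COLUMNS)
    dup = table["individual_id"].duplicated(keep=False)
    if dup.any():
        ids = sorted(set(table.loc[dup, "individual_id"]))
        raise SchemaError(f"duplicate individual_id: {ids}")
    bad = ~table["group"].isin(_GROUPS)
    if bad.any():
        raise SchemaError(
            f"unknown group value(s) {sorted(set(table.loc[bad, 'group']))}; "
            f"expected one of {sorted(_GROUPS)}"
        )
    familial = table["family_id"] != ""
    if (familial & (table["group"] == "HC")).any():
        raise SchemaError("healthy controls must not carry a family_id")
    if ((~familial) & (table["group"] == "family_non_SLE")).any():
        raise SchemaError("family_non_SLE members must carry a family_id")
    table["age"] = pd.to_numeric(table["age"], errors="coerce")
    return table


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-individual x per-locus read-count table."""
    table = _read_tsv(path, COUNT_COLUMNS)
    for col in ("depth", "alt"):
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            raise SchemaError(
                f"non-integer {col} value at line(s) {_line_numbers(table, bad)[:5]}"
            )
        table[col] = numeric.astype(int)
    bad = (table["alt"] < 0) | (table["depth"] < 1) | (table["alt"] > table["depth"])
    if bad.any():
        raise SchemaError(
            f"alt must satisfy 0 <= alt <= depth (depth >= 1); "
            f"violated at line(s) {_line_numbers(table, bad)[:5]}"
        )
    dup = table.duplicated(subset=["individual_id", "locus"], keep=False)
    if dup.any():
        raise SchemaError(
            f"duplicate (individual, locus) rows at line(s) {_line_numbers(table, dup)[:5]}"
        )
    return table


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical table: individual_id plus numeric parameter columns."""
    table = _read_tsv(path, ["individual_id"])
    dup = table["individual_id"].duplicated(keep=False)
    if dup.any():
        ids = sorted(set(table.loc[dup, "individual_id"]))
        raise SchemaError(f"duplicate individual_id in clinical table: {ids}")
    for col in table.columns:
        if col == "individual_id":
            continue
        table[col] = pd.to_numeric(table[col].replace("", None), errors="coerce")
    return table


def read_loci(path: str | Path) -> list[Locus]:
    """Read a locus table into :class:`~vafscreen.variants.Locus` records."""
    table = _read_tsv(path, LOCI_COLUMNS)
    loci = []
    for row in table.itertuples(index=False):
        cdna = getattr(row, "cdna_pos", "")
        codon = getattr(row, "codon_context", "")
        alt = getattr(row, "alt", "")
        loci.append(
            Locus(
                name=row.name,
                chrom=row.chrom,
                pos=int(row.pos),
                ref_fwd=row.ref,
                region=row.region,
                alt_fwd=alt or None,
                cdna_pos=int(cdna) if cdna else None,
                codon_context=codon or None,
            )
        )
    if len({locus.name for locus in loci}) != len(loci):
        raise SchemaError("duplicate locus names in locus table")
    return loci


def packaged_loci() -> list[Locus]:
    """The default locus table shipped with the package."""
    ref = resources.files("vafscreen.data").joinpath("loci.tsv")
    with resources.as_file(ref) as path:
        return read_loci(path)


def packaged_cohorts() -> dict:
    """Published cohort composition and index-locus carrier counts."""
    ref = resources.files("vafscreen.data").joinpath("cohorts.yaml")
    with resources.as_file(ref) as path, open(path, encoding="utf-8") as handle:
        return yaml.safe_load(handle)


def packaged_carriers() -> pd.DataFrame:
    """The published carrier-ID table shipped with the package."""
    ref = resources.files("vafscreen.data").joinpath("carriers.tsv")
    with resources.as_file(ref) as path:
        return _read_tsv(path, ["cohort", "variant", "individual_id", "kind", "zygosity"])


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def config_digest(config_mapping) -> str:
    """Short stable digest of a configuration mapping."""
    canonical = yaml.safe_dump(config_mapping, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def write_tsv(
    table: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    digest: str | None = None,
) -> None:
    """Write a table as TSV with a reproducibility comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write(f"# vafscreen {__version__}\n")
        if seed is not None:
            handle.write(f"# seed={seed}\n")
        if digest is not None:
            handle.write(f"# config_digest={digest}\n")
        table.to_csv(handle, sep="\t", index=False, lineterminator="\n")


def write_vcf(
    calls: pd.DataFrame,
    model: GeneModel,
    path: str | Path,
    seed: int | None = None,
    reference_check: dict[int, str] | None = None,
) -> None:
    """Write annotated calls as a minimal VCF 4.2 file.

    One record per call, forward-strand REF/ALT, sorted by position, with
    INFO keys IND (individual), VF (read frequency), ZYG (zygosity class),
    CDNA and LABEL (cDNA and protein/UTR labels).  ``reference_check``
    optionally maps genomic positions to the expected forward-strand base;
    a contradiction raises :class:`InputError`.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    required = {"chrom", "pos", "ref", "alt_allele", "individual_id",
                "frequency", "zygosity", "cdna_label", "label"}
    missing = required - set(calls.columns)
    if missing:
        raise InputError(f"call table is missing columns: {sorted(missing)}")
    if reference_check:
        for pos, expected in reference_check.items():
            stated = calls.loc[calls["pos"] == pos, "ref"]
            if len(stated) and (stated != expected).any():
                raise InputError(
                    f"REF at {model.chrom}:{pos} contradicts the gene model "
                    f"(expected {expected})"
                )
    header = [
        "##fileformat=VCFv4.2",
        f"##source=vafscreen {__version__}" + (f" seed={seed}" if seed is not None else ""),
        f"##reference=hg19 ({model.name} on the {model.strand} strand; "
        "POS/REF/ALT are forward-strand, 1-based)",
        f"##contig=<ID={model.chrom}>",
        '##INFO=<ID=IND,Number=1,Type=String,Description="Individual ID">',
        '##INFO=<ID=VF,Number=1,Type=Float,Description="Variant read frequency">',
        '##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity class">',
        '##INFO=<ID=CDNA,Number=1,Type=String,Description="cDNA label (minus-strand coding)">',
        '##INFO=<ID=LABEL,Number=1,Type=String,Description="Protein or 3-prime UTR label">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    body = []
    ordered = calls.sort_values(["pos", "individual_id"], kind="stable")
    for row in ordered.itertuples(index=False):
        if not row.alt_allele:
            continue
        info = (
            f"IND={row.individual_id};VF={row.frequency:.6g};ZYG={row.zygosity};"
            f"CDNA={row.cdna_label};LABEL={row.label.replace(' ', '_')}"
        )
        body.append(
            f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt_allele}\t.\tPASS\t{info}"
        )
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("\n".join(header + body) + "\n")


def write_fasta(name: str, sequence: str, path: str | Path, width: int = 70) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            handle.write(sequence[i : i + width] + "\n")


def reference_check_from_model(loci, model: GeneModel, utr_sequence: str) -> dict[int, str]:
    """Expected forward-strand base per UTR locus, from the UTR sequence."""
    expected = {}
    for locus in loci:
        if locus.region != "UTR3":
            continue
        cdna = model.genomic_to_cdna_pos(locus.pos)
        utr_pos = cdna - model.cds_length
        if 1 <= utr_pos <= len(utr_sequence):
            expected[locus.pos] = complement(utr_sequence[utr_pos - 1])
    return expected
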