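"""Pipeline configuration and orchestration: simulate -> quantify -> screen
-> associate, with a report bundle written to an output directory."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .clinical import compare_clinical
from .cohort import (
    GROUP_SLE,
    SimConfig,
    simulate_clinical,
    simulate_cohort,
    simulate_read_counts,
)
from .errors import ConfigurationError, InputError, VafScreenError
from .genemodel import default_gene_model, load_packaged_utr
from .screen import ScreenResult, allele_frequency, dedup_unrelated, screen_locus
from .variants import ZYG_GERMLINE_HET, ZYG_GERMLINE_HOM, ZygosityBands, quantify_calls

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, options and the seed for a full screening run."""

    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    roster_path: str | None = None
    counts_path: str | None = None
    clinical_path: str | None = None
    loci_path: str | None = None
    index_locus: str = "T635C"
    inclusive_cutoff: bool = False
    round_cutoff: bool = True
    tails: int = 2
    welch: bool = False
    out_dir: str = "vafscreen_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        sim_raw = raw.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        sim_known = {f.name for f in dataclasses.fields(SimConfig)}
        sim_unknown = set(sim_raw) - sim_known
        if sim_unknown:
            raise ConfigurationError(f"unknown sim config field(s): {sorted(sim_unknown)}")
        for key in ("depth_range", "somatic_fraction_range"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        if "germline_carriers" in sim_raw:
            sim_raw["germline_carriers"] = [tuple(t) for t in sim_raw["germline_carriers"]]
        if "clinical_effects" in sim_raw:
            sim_raw["clinical_effects"] = {
                k: tuple(v) for k, v in sim_raw["clinical_effects"].items()
            }
        if "family_structure" in sim_raw and sim_raw["family_structure"] is not None:
            sim_raw["family_structure"] = [tuple(t) for t in sim_raw["family_structure"]]
        return cls(sim=SimConfig(**sim_raw), **raw)

    def as_mapping(self) -> dict:
        """Mapping of everything that determines the report content.

        ``out_dir`` is excluded so the digest identifies the analysis, not
        where its files happen to land.
        """
        out = dataclasses.asdict(self)
        out.pop("out_dir", None)
        return out


@dataclass
class ReportBundle:
    """Paths and in-memory results of one pipeline run."""

    out_dir: Path
    screen: ScreenResult
    association_path: Path
    allele_path: Path
    clinical_path: Path | None
    vcf_path: Path
    log_path: Path


def _association_table(result: ScreenResult) -> pd.DataFrame:
    t = result.table
    return pd.DataFrame(
        [
            {
                "locus": result.locus,
                "cutoff_raw": result.cutoff.cutoff_raw,
                "cutoff_applied": result.cutoff.cutoff_applied,
                "n_controls_for_cutoff": result.cutoff.n_controls,
                "cases_above": t.a,
                "cases_below": t.b,
                "controls_above": t.c,
                "controls_below": t.d,
                "case_carrier_fraction": result.case_carrier_fraction,
                "control_carrier_fraction": result.control_carrier_fraction,
                "fisher_p_two_tailed": result.p_value,
                "case_carrier_ids": ",".join(result.carrier_ids_case),
            }
        ]
    )


def _allele_table(calls: pd.DataFrame, roster: pd.DataFrame) -> pd.DataFrame:
    """Family-deduplicated allele frequencies for germline calls per locus."""
    dedup = dedup_unrelated(roster)
    germline = calls[calls["zygosity"].isin([ZYG_GERMLINE_HET, ZYG_GERMLINE_HOM])]
    rows = []
    group_of = dict(zip(roster["individual_id"], roster["group"]))
    for locus, sub in germline.groupby("locus", sort=True):
        carriers = [
            (row.individual_id, "hom" if row.zygosity == ZYG_GERMLINE_HOM else "het")
            for row in sub.itertuples(index=False)
        ]
        sle_carriers = [c for c in carriers if group_of.get(c[0]) == GROUP_SLE]
        ctl_carriers = [c for c in carriers if group_of.get(c[0]) != GROUP_SLE]
        for label, subset, unrelated in (
            ("SLE", sle_carriers, dedup.unrelated_sle),
            ("non_SLE", ctl_carriers, dedup.unrelated_non_sle),
        ):
            res = allele_frequency(locus, subset, unrelated, roster["individual_id"])
            rows.append(
                {
                    "locus": locus,
                    "group": label,
                    "carriers_total": len(subset),
                    "carriers_unrelated": res.unrelated_carriers,
                    "allele_count": res.allele_count,
                    "denominator": res.denominator,
                    "allele_frequency": res.frequency,
                    "excluded_duplicates": ",".join(res.excluded_duplicates),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "locus", "group", "carriers_total", "carriers_unrelated",
            "allele_count", "denominator", "allele_frequency", "excluded_duplicates",
        ],
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the whole screen and write the report bundle.

    Stages: (optionally) simulate the cohort, read counts and clinical
    table; quantify and annotate calls; screen the index locus against the
    control-derived cut-off; compute family-deduplicated allele
    frequencies; compare clinical parameters between carrier groups.  Any
    stage error aborts the run and removes partial outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digest = io.config_digest(config.as_mapping())
    written: list[Path] = []

    def emit(table: pd.DataFrame, name: str) -> Path:
        path = out_dir / name
        io.write_tsv(table, path, seed=config.seed, digest=digest)
        written.append(path)
        return path

    try:
        model = default_gene_model()
        loci = io.packaged_loci() if config.loci_path is None else io.read_loci(config.loci_path)
        locus_names = [locus.name for locus in loci]
        if config.index_locus not in locus_names:
            raise ConfigurationError(
                f"index locus {config.index_locus!r} not in the locus table"
            )
        if config.simulate:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            rng = np.random.default_rng(config.seed)
            roster = simulate_cohort(sim, rng)
            counts = simulate_read_counts(roster, locus_names, sim, rng)
            emit(roster, "roster.tsv")
            emit(counts, "counts.tsv")
        else:
            if config.roster_path is None or config.counts_path is None:
                raise ConfigurationError(
                    "simulation disabled: roster_path and counts_path are required"
                )
            roster = io.read_roster(config.roster_path)
            counts = io.read_counts(config.counts_path)

        calls = quantify_calls(counts, loci, model, ZygosityBands())
        emit(calls, "calls.tsv")

        result = screen_locus(
            counts,
            roster,
            config.index_locus,
            strict=not config.inclusive_cutoff,
            rounded_cutoff=config.round_cutoff,
        )
        association_path = emit(_association_table(result), "association.tsv")
        allele_path = emit(_allele_table(calls, roster), "allele_frequencies.tsv")

        carrier_flags = pd.Series(False, index=roster["individual_id"])
        carrier_flags.loc[list(result.carrier_ids_case + result.carrier_ids_control)] = True
        clinical_path: Path | None = None
        if config.simulate:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            clinical = simulate_clinical(roster, carrier_flags, sim, rng)
            emit(clinical, "clinical.tsv")
        elif config.clinical_path is not None:
            clinical = io.read_clinical(config.clinical_path)
        else:
            clinical = None
        if clinical is not None and not clinical.empty:
            patient_flags = carrier_flags
            comparisons = compare_clinical(
                clinical, patient_flags, tails=config.tails, welch=config.welch
            )
            comparison_table = pd.DataFrame(
                [
                    {
                        "parameter": c.parameter,
                        "n_low": c.n_low,
                        "n_high": c.n_high,
                        "mean_low": c.mean_low,
                        "mean_high": c.mean_high,
                        "t": c.t_statistic,
                        "df": c.df,
                        "tails": c.tails,
                        "p_value": c.p_value,
                        "significance": c.stars,
                    }
                    for c in comparisons
                ]
            )
            clinical_path = emit(comparison_table, "clinical_comparisons.tsv")

        vcf_path = out_dir / "calls.vcf"
        utr = load_packaged_utr()
        io.write_vcf(
            calls[calls["alt_allele"] != ""],
            model,
            vcf_path,
            seed=config.seed,
            reference_check=io.reference_check_from_model(loci, model, utr),
        )
        written.append(vcf_path)

        log_path = out_dir / "run_log.txt"
        from . import __version__

        log_path.write_text(
            "\n".join(
                [
                    f"vafscreen {__version__}",
                    f"seed={config.seed}",
                    f"config_digest={digest}",
                    f"index_locus={config.index_locus}",
                    f"cutoff_raw={result.cutoff.cutoff_raw:.6g}",
                    f"cutoff_applied={result.cutoff.cutoff_applied:.6g}",
                    f"fisher_p={result.p_value:.6g}",
                    "",
                ]
            ),
            encoding="utf-8",
        )
        written.append(log_path)
    except VafScreenError:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return ReportBundle(
        out_dir=out_dir,
        screen=result,
        association_path=association_path,
        allele_path=allele_path,
        clinical_path=clinical_path,
        vcf_path=vcf_path,
        log_path=log_path,
    )
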