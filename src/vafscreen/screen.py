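"""Control-derived cut-off, carrier classification, exact association, and
family-deduplicated allele frequencies.

The screening logic is the laboratory-QC idea behind the Westgard rules:
the distribution of a quantity in a control population defines normality,
and an observation beyond mean + 3 SD (99.7% of a normal distribution)
is flagged.  Here the quantity is the variant read fraction at the index
locus in individuals without disease; patients whose fraction exceeds the
cut-off are carriers of an expanded somatic clone, and carrier status is
tested against case/control status with a two-tailed Fisher exact test.

Germline allele frequencies use only unrelated individuals: all sporadic
patients and non-familial controls, plus exactly one affected and one
unaffected member per family, each heterozygous carrier contributing one
of the 2N alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import GROUP_FAMILY, GROUP_HC, GROUP_SLE
from .errors import InputError, InsufficientDataError
from .variants import ZYG_GERMLINE_HOM


@dataclass(frozen=True)
class CutoffResult:
    """Mean + 3 SD control threshold, raw and as applied."""

    control_mean: float
    control_sd: float
    cutoff_raw: float
    cutoff_applied: float
    n_controls: int

    @classmethod
    def from_summary(cls, mean: float, sd: float, n: int, rounded: bool = True) -> "CutoffResult":
        """Build the threshold from an already-computed control mean and SD."""
        if n < 2:
            raise InsufficientDataError(f"need >= 2 controls, got {n}")
        raw = mean + 3.0 * sd
        return cls(mean, sd, raw, _truncate_percent_decimal(raw) if rounded else raw, n)


def _truncate_percent_decimal(value: float) -> float:
    """Truncate a fraction to one decimal of a percent (0.0274 -> 0.027)."""
    return math.floor(value * 1000.0 + 1e-12) / 1000.0


def westgard_cutoff(control_frequencies, rounded: bool = True) -> CutoffResult:
    """Mean + 3·SD of the control variant frequencies (sample SD, n-1).

    ``rounded`` truncates the applied threshold to one decimal of a percent
    (so a raw 2.74% is applied as 2.7%), the convention used when a QC
    threshold is quoted to the precision of the assay; the raw value is
    always reported alongside.
    """
    values = np.asarray(list(control_frequencies), dtype=float)
    if values.size < 2:
        raise InsufficientDataError(
            f"need >= 2 control frequencies, got {values.size}"
        )
    if np.any((values < 0) | (values > 1)):
        raise InputError("control frequencies must be fractions in [0, 1]")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return CutoffResult.from_summary(mean, sd, int(values.size), rounded=rounded)


def classify_above_cutoff(
    frequencies, cutoff: CutoffResult, strict: bool = True
) -> np.ndarray:
    """Boolean carrier flags: frequency above the applied cut-off.

    Strict ``>`` by default; ``strict=False`` uses ``>=`` ("at or above").
    """
    values = np.asarray(list(frequencies), dtype=float)
    if np.any((values < 0) | (values > 1)):
        raise InputError("frequencies must be fractions in [0, 1]")
    threshold = cutoff.cutoff_applied
    return values > threshold if strict else values >= threshold


# ---------------------------------------------------------------------------
# Exact association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows = case/control, columns = above/below cut-off."""

    a: int  # cases above
    b: int  # cases below
    c: int  # controls above
    d: int  # controls below

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def build_contingency(groups, above) -> ContingencyTable:
    """Cross-classify case/control status against carrier flags.

    ``groups`` is an iterable of group labels (cases are ``SLE``) or of
    booleans (True = case), aligned with the carrier flags.
    """
    groups = list(groups)
    above = list(above)
    if len(groups) != len(above):
        raise InputError(
            f"groups ({len(groups)}) and flags ({len(above)}) are not aligned"
        )
    is_case = [g is True or g == GROUP_SLE for g in groups]
    a = sum(1 for case, hi in zip(is_case, above) if case and hi)
    b = sum(1 for case, hi in zip(is_case, above) if case and not hi)
    c = sum(1 for case, hi in zip(is_case, above) if not case and hi)
    d = sum(1 for case, hi in zip(is_case, above) if not case and not hi)
    return ContingencyTable(a, b, c, d)


_TIE_TOLERANCE = math.log1p(1e-7)


def fisher_exact_two_tailed(table: ContingencyTable) -> float:
    """Two-tailed Fisher exact p via the probability-mass definition.

    Fixing both margins, the table count ``a`` follows a hypergeometric
    law; p is the total probability of every table whose point probability
    does not exceed the observed one (a relative tolerance of 1e-7 absorbs
    floating-point ties).  Log-probabilities are accumulated with
    ``lgamma`` so deep tails (p ~ 1e-8 at cohort scale) stay accurate.
    An all-zero table is degenerate and returns p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    if n == 0:
        return 1.0
    r1, r2, c1 = a + b, c + d, a + c

    def log_choose(m: int, k: int) -> float:
        return math.lgamma(m + 1) - math.lgamma(k + 1) - math.lgamma(m - k + 1)

    log_denominator = log_choose(n, c1)

    def log_pmf(x: int) -> float:
        return log_choose(r1, x) + log_choose(r2, c1 - x) - log_denominator

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    observed = log_pmf(a)
    p = sum(
        math.exp(lp)
        for x in range(lo, hi + 1)
        if (lp := log_pmf(x)) <= observed + _TIE_TOLERANCE
    )
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Family de-duplication and allele frequencies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DedupResult:
    """Unrelated subsets per group and the familial IDs that were dropped."""

    unrelated_sle: tuple[str, ...]
    unrelated_non_sle: tuple[str, ...]
    excluded: tuple[str, ...]


def dedup_unrelated(roster: pd.DataFrame) -> DedupResult:
    """Reduce a familial roster to unrelated individuals.

    Keeps every sporadic patient and every non-familial control; from each
    family keeps exactly one affected and one unaffected member (the
    lexicographically smallest ID of each, a deterministic and reportable
    choice).  A family with no member of a given group contributes none to
    that group.
    """
    _validate_roster(roster)
    family = roster["family_id"].fillna("").astype(str)
    sporadic_sle = roster.loc[(roster["group"] == GROUP_SLE) & (family == ""), "individual_id"]
    hc = roster.loc[roster["group"] == GROUP_HC, "individual_id"]
    keep_sle = list(sporadic_sle)
    keep_non = list(hc)
    excluded: list[str] = []
    familial = roster[family != ""]
    for _, members in familial.groupby(family[family != ""], sort=True):
        for group, keep in ((GROUP_SLE, keep_sle), (GROUP_FAMILY, keep_non)):
            ids = sorted(members.loc[members["group"] == group, "individual_id"])
            if ids:
                keep.append(ids[0])
                excluded.extend(ids[1:])
    return DedupResult(
        unrelated_sle=tuple(sorted(keep_sle)),
        unrelated_non_sle=tuple(sorted(keep_non)),
        excluded=tuple(sorted(excluded)),
    )


@dataclass(frozen=True)
class AlleleFrequencyResult:
    """Carrier alleles over 2N alleles in an unrelated set."""

    variant: str
    unrelated_carriers: int
    allele_count: int
    denominator: int
    frequency: float
    excluded_duplicates: tuple[str, ...] = field(default_factory=tuple)


def allele_frequency(
    variant: str,
    carriers: list[tuple[str, str]],
    unrelated_ids,
    roster_ids=None,
) -> AlleleFrequencyResult:
    """Allele frequency of a germline variant in an unrelated set.

    ``carriers`` is a list of (individual_id, zygosity); heterozygotes
    contribute one allele, homozygotes two.  Carriers outside the
    unrelated set (family duplicates) are reported as excluded, not
    counted.
    """
    unrelated = set(unrelated_ids)
    if roster_ids is not None:
        known = set(roster_ids)
        unknown = [iid for iid, _ in carriers if iid not in known]
        if unknown:
            raise InputError(f"carriers not present in the roster: {unknown}")
    denominator = 2 * len(unrelated)
    allele_count = 0
    counted = 0
    excluded = []
    for iid, zygosity in carriers:
        if iid in unrelated:
            counted += 1
            allele_count += 2 if zygosity in {"hom", ZYG_GERMLINE_HOM} else 1
        else:
            excluded.append(iid)
    frequency = allele_count / denominator if denominator else 0.0
    return AlleleFrequencyResult(
        variant=variant,
        unrelated_carriers=counted,
        allele_count=allele_count,
        denominator=denominator,
        frequency=frequency,
        excluded_duplicates=tuple(excluded),
    )


def _validate_roster(roster: pd.DataFrame) -> None:
    required = {"individual_id", "group", "family_id"}
    missing = required - set(roster.columns)
    if missing:
        raise InputError(f"roster is missing columns: {sorted(missing)}")


# ---------------------------------------------------------------------------
# One-locus screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenResult:
    """Everything the screen derives for one locus."""

    locus: str
    cutoff: CutoffResult
    table: ContingencyTable
    p_value: float
    carrier_ids_case: tuple[str, ...]
    carrier_ids_control: tuple[str, ...]
    case_carrier_fraction: float
    control_carrier_fraction: float


def screen_locus(
    counts: pd.DataFrame,
    roster: pd.DataFrame,
    locus: str,
    strict: bool = True,
    rounded_cutoff: bool = True,
) -> ScreenResult:
    """Run the whole screen at one locus.

    The cut-off is derived from the variant frequencies of all non-case
    individuals (healthy controls and unaffected family members), then
    every individual is classified against it and carrier status is tested
    for association with case status.
    """
    _validate_roster(roster)
    at_locus = counts[counts["locus"] == locus]
    if at_locus.empty:
        raise InputError(f"no read counts at locus {locus!r}")
    merged = at_locus.merge(roster, on="individual_id", how="left", validate="one_to_one")
    if merged["group"].isna().any():
        orphans = merged.loc[merged["group"].isna(), "individual_id"].tolist()
        raise InputError(f"read counts for individuals absent from the roster: {orphans[:5]}")
    merged = merged.assign(frequency=merged["alt"] / merged["depth"])
    is_case = merged["group"] == GROUP_SLE
    controls = merged.loc[~is_case, "frequency"]
    cutoff = westgard_cutoff(controls, rounded=rounded_cutoff)
    above = classify_above_cutoff(merged["frequency"], cutoff, strict=strict)
    table = build_contingency(is_case, above)
    p = fisher_exact_two_tailed(table)
    case_ids = tuple(merged.loc[is_case & above, "individual_id"])
    ctrl_ids = tuple(merged.loc[~is_case & above, "individual_id"])
    n_case = int(is_case.sum())
    n_ctrl = int((~is_case).sum())
    return ScreenResult(
        locus=locus,
        cutoff=cutoff,
        table=table,
        p_value=p,
        carrier_ids_case=case_ids,
        carrier_ids_control=ctrl_ids,
        case_carrier_fraction=len(case_ids) / n_case if n_case else 0.0,
        control_carrier_fraction=len(ctrl_ids) / n_ctrl if n_ctrl else 0.0,
    )
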