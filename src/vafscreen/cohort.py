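"""Synthetic cohorts, deep-sequencing read counts, and clinical covariates.

The generator emulates the statistical structure of a two-cohort lupus
screening study so that every downstream stage (cut-off, classification,
exact test, allele frequencies, clinical comparisons) can be exercised
without patient data:

* cohort composition: sporadic patients, multi-member families (each with
  at least one affected index), and unrelated healthy controls; the
  default mirrors a 101-patient / 163-non-patient familial cohort (24
  sporadic + 77 familial patients in 62 families, 6 healthy controls +
  157 unaffected relatives),
* sequencing: per-locus depths of 1e5-3e5 reads, a per-individual
  background error rate whose population mean/SD across observed control
  read fractions is 1.0% / 0.58%, somatic clones adding 2.7-5.3% to the
  background in a configurable fraction of patients, and germline
  heterozygotes at a true fraction of 0.5,
* clinical covariates: normal draws per patient, with a configurable
  mean shift in somatic-carrier patients (autoantibody up; complement,
  blood counts down; disease-activity score mildly up).

The background error rate is drawn from a normal distribution truncated
at zero whose *underlying* parameters are moment-matched so the truncated
distribution has exactly the configured mean and SD -- the configured
values are the moments a control population would show, not the raw
normal parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError, InputError

GROUP_SLE = "SLE"
GROUP_HC = "HC"
GROUP_FAMILY = "family_non_SLE"

#: Default per-parameter (baseline mean, SD, carrier shift); units per field.
DEFAULT_CLINICAL_EFFECTS: dict[str, tuple[float, float, float]] = {
    "anti_dsDNA": (120.0, 90.0, 70.0),     # IU/mL, up in carriers
    "C3": (85.0, 22.0, -14.0),             # mg/dL, down
    "C4": (16.0, 7.0, -4.0),               # mg/dL, down
    "WBC": (6200.0, 2100.0, -1100.0),      # cells/uL, down
    "lymphocytes": (1400.0, 600.0, -320.0),  # cells/uL, down
    "platelets": (230_000.0, 65_000.0, -45_000.0),  # /uL, down
    "SLEDAI": (6.0, 4.0, 1.0),             # integer score, mildly up
}


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the emulated cohort as default."""

    n_sporadic_sle: int = 24
    n_families: int = 62
    n_familial_sle: int = 77
    n_familial_non_sle: int = 157
    n_hc: int = 6
    family_structure: list[tuple[int, int]] | None = None  # per family (affected, unaffected)
    depth_range: tuple[int, int] = (100_000, 300_000)
    control_error_mean: float = 0.010
    control_error_sd: float = 0.0058
    somatic_carrier_fraction_sle: float = 17 / 101
    somatic_fraction_range: tuple[float, float] = (0.027, 0.053)
    somatic_locus: str | None = None  # default: first locus passed to the simulator
    germline_carriers: list[tuple[str, str, str]] = field(default_factory=list)
    clinical_effects: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_EFFECTS)
    )
    clinical_missing_rate: float = 0.05
    female_fraction_sle: float = 0.9
    female_fraction_other: float = 0.5
    median_age_sle: float = 31.0
    median_age_other: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sporadic_sle", "n_families", "n_familial_sle",
                     "n_familial_non_sle", "n_hc"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.depth_range[0] < 1 or self.depth_range[0] > self.depth_range[1]:
            raise ConfigurationError("depth_range must be an interval with lower bound >= 1")
        for name in ("control_error_mean", "control_error_sd",
                     "somatic_carrier_fraction_sle", "clinical_missing_rate",
                     "female_fraction_sle", "female_fraction_other"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be a fraction in [0, 1], got {value}")
        lo, hi = self.somatic_fraction_range
        if not (self.control_error_mean < lo <= hi < 1.0):
            raise ConfigurationError(
                "somatic_fraction_range must lie within (control_error_mean, 1), "
                f"got {self.somatic_fraction_range}"
            )
        if self.n_families > 0:
            if self.n_familial_sle < self.n_families:
                raise ConfigurationError(
                    "n_familial_sle must give every family at least one affected member"
                )
            if self.n_familial_sle + self.n_familial_non_sle < 2 * self.n_families:
                raise ConfigurationError("family sizes must be >= 2 members")
        elif self.n_familial_sle or self.n_familial_non_sle:
            raise ConfigurationError("familial members require n_families > 0")
        if self.family_structure is not None:
            if len(self.family_structure) != self.n_families:
                raise ConfigurationError("family_structure length must equal n_families")
            for aff, unaff in self.family_structure:
                if aff < 1 or aff + unaff < 2:
                    raise ConfigurationError(
                        "each family needs >= 1 affected member and >= 2 members in total"
                    )

    def resolved_families(self) -> list[tuple[int, int]]:
        """Per-family (affected, unaffected) counts.

        With no explicit structure, every family gets one affected index and
        the remaining affected/unaffected members are dealt round-robin to
        the lowest-numbered families, so the totals are met exactly and the
        allocation is deterministic.
        """
        if self.family_structure is not None:
            return list(self.family_structure)
        if self.n_families == 0:
            return []
        affected = [1] * self.n_families
        for i in range(self.n_familial_sle - self.n_families):
            affected[i % self.n_families] += 1
        unaffected = [0] * self.n_families
        for i in range(self.n_familial_non_sle):
            unaffected[i % self.n_families] += 1
        # guarantee >= 2 members even in corner allocations
        for i in range(self.n_families):
            if affected[i] + unaffected[i] < 2:
                donor = max(range(self.n_families), key=lambda j: affected[j] + unaffected[j])
                unaffected[donor] -= 1
                unaffected[i] += 1
        return list(zip(affected, unaffected))


# ---------------------------------------------------------------------------
# Roster
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the cohort roster: IDs, group labels, family IDs, sex, age.

    Sporadic patients are ``S1..``, healthy controls ``H1..`` and family
    members ``F<k>-<m>`` with affected members numbered first (``F7-01`` is
    family 7's index patient).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rows: list[dict] = []

    def draw_person(group: str) -> tuple[str, float]:
        if group == GROUP_SLE:
            p_female, med = config.female_fraction_sle, config.median_age_sle
        else:
            p_female, med = config.female_fraction_other, config.median_age_other
        sex = "F" if rng.random() < p_female else "M"
        age = float(np.clip(np.round(rng.normal(med, 12.0), 1), 5.0, 95.0))
        return sex, age

    for i in range(config.n_sporadic_sle):
        sex, age = draw_person(GROUP_SLE)
        rows.append(dict(individual_id=f"S{i + 1}", group=GROUP_SLE,
                         family_id="", sex=sex, age=age))
    for fam_idx, (n_aff, n_unaff) in enumerate(config.resolved_families(), start=1):
        fam = f"F{fam_idx}"
        member = 0
        for _ in range(n_aff):
            member += 1
            sex, age = draw_person(GROUP_SLE)
            rows.append(dict(individual_id=f"{fam}-{member:02d}", group=GROUP_SLE,
                             family_id=fam, sex=sex, age=age))
        for _ in range(n_unaff):
            member += 1
            sex, age = draw_person(GROUP_FAMILY)
            rows.append(dict(individual_id=f"{fam}-{member:02d}", group=GROUP_FAMILY,
                             family_id=fam, sex=sex, age=age))
    for i in range(config.n_hc):
        sex, age = draw_person(GROUP_HC)
        rows.append(dict(individual_id=f"H{i + 1}", group=GROUP_HC,
                         family_id="", sex=sex, age=age))
    roster = pd.DataFrame(
        rows, columns=["individual_id", "group", "family_id", "sex", "age"]
    )
    if roster["individual_id"].duplicated().any():
        raise ConfigurationError("generated duplicate individual IDs")
    return roster


# ---------------------------------------------------------------------------
# Read counts
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _matched_truncnorm(mean: float, sd: float) -> tuple[float, float, float]:
    """Underlying (mu, sigma, a) of a zero-truncated normal with given moments."""

    def residual(params: np.ndarray) -> list[float]:
        mu, sigma = params
        sigma = abs(sigma)
        a = (0.0 - mu) / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    solution, _, status, message = optimize.fsolve(
        residual, [mean, sd], full_output=True
    )
    if status != 1:
        raise ConfigurationError(
            f"cannot match a zero-truncated normal to mean={mean}, sd={sd}: {message}"
        )
    mu, sigma = float(solution[0]), float(abs(solution[1]))
    return mu, sigma, (0.0 - mu) / sigma


def _background_rates(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if config.control_error_mean == 0.0:
        return np.zeros(n)
    if config.control_error_sd == 0.0:
        return np.full(n, config.control_error_mean)
    mu, sigma, a = _matched_truncnorm(config.control_error_mean, config.control_error_sd)
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)


def simulate_read_counts(
    roster: pd.DataFrame,
    loci: list[str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate (depth, alt) for every individual x locus.

    Draw order (all from one generator): per-individual background error
    rates; somatic carrier selection among patients, then their clone
    fractions; then per locus, depths followed by binomial alternate
    counts.  Somatic clones are added to the background at the designated
    somatic locus only; germline carriers named in the config sequence at
    probability 0.5 (het) or 1 - error (hom).
    """
    if roster.empty:
        raise InputError("roster is empty")
    if not loci:
        raise InputError("no loci to simulate")
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    ids = roster["individual_id"].to_numpy()
    index_of = {iid: k for k, iid in enumerate(ids)}
    known_loci = set(loci)
    for iid, locus, zygosity in config.germline_carriers:
        if iid not in index_of:
            raise InputError(f"germline carrier references unknown individual {iid!r}")
        if locus not in known_loci:
            raise InputError(f"germline carrier references unknown locus {locus!r}")
        if zygosity not in {"het", "hom"}:
            raise InputError(f"germline zygosity must be het or hom, got {zygosity!r}")

    n = len(ids)
    background = _background_rates(config, n, rng)

    somatic_locus = config.somatic_locus or loci[0]
    if somatic_locus not in known_loci:
        raise InputError(f"somatic locus {somatic_locus!r} not among the simulated loci")
    sle_positions = np.flatnonzero((roster["group"] == GROUP_SLE).to_numpy())
    n_somatic = int(round(config.somatic_carrier_fraction_sle * len(sle_positions)))
    somatic_idx = (
        rng.choice(sle_positions, size=n_somatic, replace=False)
        if n_somatic > 0
        else np.array([], dtype=int)
    )
    lo, hi = config.somatic_fraction_range
    clone_fractions = rng.uniform(lo, hi, size=len(somatic_idx))

    germline_at: dict[str, dict[int, str]] = {}
    for iid, locus, zygosity in config.germline_carriers:
        germline_at.setdefault(locus, {})[index_of[iid]] = zygosity

    frames = []
    depth_lo, depth_hi = config.depth_range
    for locus in loci:
        depths = rng.integers(depth_lo, depth_hi + 1, size=n)
        p = background.copy()
        if locus == somatic_locus and len(somatic_idx):
            p[somatic_idx] = np.minimum(p[somatic_idx] + clone_fractions, 1.0)
        for k, zygosity in germline_at.get(locus, {}).items():
            p[k] = 0.5 if zygosity == "het" else 1.0 - background[k]
        alts = rng.binomial(depths, np.clip(p, 0.0, 1.0))
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": ids,
                    "locus": locus,
                    "depth": depths.astype(np.int64),
                    "alt": alts.astype(np.int64),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Clinical covariates
# ---------------------------------------------------------------------------

def simulate_clinical(
    roster: pd.DataFrame,
    carrier_flags: pd.Series | dict[str, bool],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate per-patient clinical parameters with carrier-group shifts.

    One row per patient (group SLE); each parameter is a normal draw around
    its baseline, shifted by the configured amount for somatic carriers,
    floored at zero, with SLEDAI rounded to a non-negative integer.  A
    configurable fraction of entries per parameter is missing.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if isinstance(carrier_flags, dict):
        carrier_flags = pd.Series(carrier_flags)
    patients = roster[roster["group"] == GROUP_SLE]["individual_id"]
    missing = set(patients) - set(carrier_flags.index)
    if missing:
        raise InputError(
            f"carrier flags missing for {len(missing)} patients, e.g. {sorted(missing)[:3]}"
        )
    flags = carrier_flags.loc[patients].to_numpy(dtype=bool)
    n = len(patients)
    out = pd.DataFrame({"individual_id": patients.to_numpy()})
    for name, (baseline, sd, shift) in config.clinical_effects.items():
        values = rng.normal(baseline + shift * flags, sd, size=n)
        values = np.maximum(values, 0.0)
        if name == "SLEDAI":
            values = np.round(values)
        if config.clinical_missing_rate > 0:
            values = np.where(
                rng.random(n) < config.clinical_missing_rate, np.nan, values
            )
        out[name] = values
    return out


def cohort2_config(seed: int = 0) -> SimConfig:
    """Convenience preset: the sporadic validation cohort (80 SLE vs 87 HC)."""
    return SimConfig(
        n_sporadic_sle=80,
        n_families=0,
        n_familial_sle=0,
        n_familial_non_sle=0,
        n_hc=87,
        somatic_carrier_fraction_sle=37 / 80,
        median_age_sle=43.5,
        median_age_other=42.0,
        seed=seed,
    )


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """A copy of the config with a different seed."""
    return replace(config, seed=int(seed))
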