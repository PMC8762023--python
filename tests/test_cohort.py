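"""Synthetic cohort generator: composition, determinism, calibration."""

import numpy as np
import pandas as pd
import pytest

from vafscreen.cohort import (
    GROUP_FAMILY,
    GROUP_HC,
    GROUP_SLE,
    SimConfig,
    cohort2_config,
    simulate_clinical,
    simulate_cohort,
    simulate_read_counts,
)
from vafscreen.errors import ConfigurationError, InputError


class TestSimulateCohort:
    def test_familial_cohort_composition(self, cohort1_roster):
        counts = cohort1_roster["group"].value_counts()
        assert counts[GROUP_SLE] == 101
        assert counts[GROUP_FAMILY] == 157
        assert counts[GROUP_HC] == 6
        familial = cohort1_roster[cohort1_roster["family_id"] != ""]
        assert familial["family_id"].nunique() == 62
        # every family has >= 2 members and >= 1 affected member
        sizes = familial.groupby("family_id").size()
        assert (sizes >= 2).all()
        affected = familial[familial["group"] == GROUP_SLE].groupby("family_id").size()
        assert len(affected) == 62

    def test_sporadic_cohort_has_no_families(self):
        roster = simulate_cohort(cohort2_config(seed=5))
        counts = roster["group"].value_counts()
        assert counts[GROUP_SLE] == 80
        assert counts[GROUP_HC] == 87
        assert (roster["family_id"] == "").all()

    def test_empty_cohort(self):
        config = SimConfig(
            n_sporadic_sle=0, n_families=0, n_familial_sle=0,
            n_familial_non_sle=0, n_hc=0,
        )
        assert simulate_cohort(config).empty

    def test_ids_unique_and_deterministic(self, cohort1_config, cohort1_roster):
        assert cohort1_roster["individual_id"].is_unique
        again = simulate_cohort(cohort1_config)
        pd.testing.assert_frame_equal(again, cohort1_roster)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_sporadic_sle", -1),
            ("control_error_mean", 1.5),
            ("somatic_fraction_range", (0.005, 0.05)),  # below the error mean
            ("depth_range", (0, 100)),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        with pytest.raises(ConfigurationError):
            SimConfig(**{field: value})

    def test_family_structure_override(self):
        config = SimConfig(
            n_sporadic_sle=0, n_families=2, n_familial_sle=3,
            n_familial_non_sle=3, n_hc=0,
            family_structure=[(2, 1), (1, 2)], seed=1,
        )
        roster = simulate_cohort(config)
        f1 = roster[roster["family_id"] == "F1"]
        assert (f1["group"] == GROUP_SLE).sum() == 2


class TestSimulateReadCounts:
    def test_conservation_and_bounds(self, cohort1_roster, cohort1_config):
        counts = simulate_read_counts(cohort1_roster, ["T635C", "A410T"], cohort1_config)
        # every individual exactly once per locus
        assert len(counts) == 2 * len(cohort1_roster)
        per_locus = counts.groupby("locus")["individual_id"].apply(set)
        expected = set(cohort1_roster["individual_id"])
        assert all(ids == expected for ids in per_locus)
        assert (counts["alt"] <= counts["depth"]).all()
        assert (counts["depth"] >= cohort1_config.depth_range[0]).all()
        assert (counts["depth"] <= cohort1_config.depth_range[1]).all()

    def test_deterministic_for_fixed_seed(self, cohort1_roster, cohort1_config):
        a = simulate_read_counts(cohort1_roster, ["T635C"], cohort1_config)
        b = simulate_read_counts(cohort1_roster, ["T635C"], cohort1_config)
        pd.testing.assert_frame_equal(a, b)

    def test_control_frequency_calibration(self):
        """Simulated control read fractions recover the configured moments.

        The configured control mean/SD (1.0% / 0.58%) are the moments of
        the observed control distribution; with 10,000 controls the
        empirical mean and SD must match within 3 standard errors.
        """
        n = 10_000
        config = SimConfig(
            n_sporadic_sle=0, n_families=0, n_familial_sle=0,
            n_familial_non_sle=0, n_hc=n, seed=42,
        )
        roster = simulate_cohort(config)
        counts = simulate_read_counts(roster, ["T635C"], config)
        freq = counts["alt"] / counts["depth"]
        mean, sd = freq.mean(), freq.std(ddof=1)
        se_mean = config.control_error_sd / np.sqrt(n)
        se_sd = config.control_error_sd / np.sqrt(2 * n)
        assert abs(mean - config.control_error_mean) < 3 * se_mean
        assert abs(sd - config.control_error_sd) < 3 * se_sd

    def test_control_tail_below_mean_plus_3sd(self):
        """~99.7% of control fractions fall below mean + 3 SD (2.74%)."""
        config = SimConfig(
            n_sporadic_sle=0, n_families=0, n_familial_sle=0,
            n_familial_non_sle=0, n_hc=10_000, seed=7,
        )
        roster = simulate_cohort(config)
        counts = simulate_read_counts(roster, ["T635C"], config)
        freq = counts["alt"] / counts["depth"]
        below = (freq < 0.0274).mean()
        assert below > 0.99

    def test_germline_het_concentration(self):
        """A heterozygote at depth 1e5 shows 49-51% of alternate reads."""
        config = SimConfig(
            n_sporadic_sle=1, n_families=0, n_familial_sle=0,
            n_familial_non_sle=0, n_hc=0,
            somatic_carrier_fraction_sle=0.0,
            germline_carriers=[("S1", "A410T", "het")], seed=3,
        )
        roster = simulate_cohort(config)
        freqs = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            counts = simulate_read_counts(roster, ["A410T"], config, rng)
            freqs.append(counts["alt"].iloc[0] / counts["depth"].iloc[0])
        assert all(0.49 <= f <= 0.51 for f in freqs)

    def test_zero_error_rate_gives_zero_alt(self):
        config = SimConfig(
            n_sporadic_sle=5, n_families=0, n_familial_sle=0,
            n_familial_non_sle=0, n_hc=5,
            control_error_mean=0.0, control_error_sd=0.0,
            somatic_carrier_fraction_sle=0.0, seed=0,
        )
        roster = simulate_cohort(config)
        counts = simulate_read_counts(roster, ["T635C"], config)
        assert (counts["alt"] == 0).all()

    def test_unknown_carrier_rejected(self, cohort1_roster, cohort1_config):
        import dataclasses

        bad = dataclasses.replace(
            cohort1_config, germline_carriers=[("NOBODY", "T635C", "het")]
        )
        with pytest.raises(InputError, match="NOBODY"):
            simulate_read_counts(cohort1_roster, ["T635C"], bad)


class TestSimulateClinical:
    def test_default_shift_directions(self):
        """Carriers shift up in anti-dsDNA and SLEDAI, down elsewhere."""
        config = SimConfig(
            n_sporadic_sle=2000, n_families=0, n_familial_sle=0,
            n_familial_non_sle=0, n_hc=0, clinical_missing_rate=0.0, seed=9,
        )
        roster = simulate_cohort(config)
        ids = roster["individual_id"]
        flags = pd.Series([i % 2 == 0 for i in range(len(ids))], index=ids.to_numpy())
        clinical = simulate_clinical(roster, flags, config)
        merged = clinical.set_index("individual_id")
        expected_sign = {
            "anti_dsDNA": 1, "C3": -1, "C4": -1, "WBC": -1,
            "lymphocytes": -1, "platelets": -1, "SLEDAI": 1,
        }
        for name, sign in expected_sign.items():
            diff = merged.loc[flags, name].mean() - merged.loc[~flags, name].mean()
            assert np.sign(diff) == sign, name

    def test_zero_shift_gives_identical_distributions(self):
        config = SimConfig(
            n_sporadic_sle=400, n_families=0, n_familial_sle=0,
            n_familial_non_sle=0, n_hc=0, clinical_missing_rate=0.0,
            clinical_effects={"anti_dsDNA": (120.0, 90.0, 0.0)}, seed=2,
        )
        roster = simulate_cohort(config)
        ids = roster["individual_id"]
        flags = pd.Series([i % 2 == 0 for i in range(len(ids))], index=ids.to_numpy())
        clinical = simulate_clinical(roster, flags, config)
        from scipy import stats

        values = clinical.set_index("individual_id")["anti_dsDNA"]
        _, p = stats.ks_2samp(values[flags], values[~flags])
        assert p > 0.01

    def test_misaligned_flags_rejected(self, cohort1_roster, cohort1_config):
        with pytest.raises(InputError):
            simulate_clinical(cohort1_roster, {"S1": True}, cohort1_config)
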