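"""Cut-off derivation, carrier classification, exact association, and
family-deduplicated allele frequencies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vafscreen.cohort import SimConfig, simulate_cohort
from vafscreen.errors import InputError, InsufficientDataError
from vafscreen.screen import (
    ContingencyTable,
    CutoffResult,
    allele_frequency,
    build_contingency,
    classify_above_cutoff,
    dedup_unrelated,
    fisher_exact_two_tailed,
    westgard_cutoff,
)


def enumeration_oracle(a: int, b: int, c: int, d: int) -> float:
    """Literal two-tailed Fisher p: exact binomial-coefficient enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {x: math.comb(r1, x) * math.comb(r2, c1 - x) / denom for x in range(lo, hi + 1)}
    observed = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= observed * (1 + 1e-7)))


class TestWestgardCutoff:
    def test_published_summary(self):
        """Control mean 1.0% and SD 0.58% give 2.74% raw, applied as 2.7%."""
        result = CutoffResult.from_summary(0.010, 0.0058, 163)
        assert result.cutoff_raw == pytest.approx(0.0274, abs=1e-12)
        assert result.cutoff_applied == pytest.approx(0.027, abs=1e-12)

    def test_from_values_with_exact_moments(self):
        # two values engineered to have mean 0.010 and sample SD 0.0058
        d = 0.0058 / math.sqrt(2)
        result = westgard_cutoff([0.010 - d, 0.010 + d])
        assert result.control_mean == pytest.approx(0.010)
        assert result.control_sd == pytest.approx(0.0058)
        assert result.cutoff_raw == pytest.approx(0.0274)
        assert result.cutoff_applied == pytest.approx(0.027)

    def test_constant_vector(self):
        result = westgard_cutoff([0.01] * 100)
        assert result.control_sd == pytest.approx(0.0, abs=1e-15)
        assert result.cutoff_raw == pytest.approx(0.01)

    def test_against_two_pass_oracle(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 0.05, size=1000)
        result = westgard_cutoff(values, rounded=False)
        mean = sum(values) / len(values)
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (len(values) - 1))
        assert result.control_mean == pytest.approx(mean, rel=1e-12)
        assert result.control_sd == pytest.approx(sd, rel=1e-12)
        assert result.cutoff_raw == pytest.approx(mean + 3 * sd, rel=1e-12)

    def test_insufficient_controls(self):
        with pytest.raises(InsufficientDataError):
            westgard_cutoff([0.01])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.001, max_value=0.9), min_size=2, max_size=30),
        st.floats(min_value=0.1, max_value=1.0),
        st.floats(min_value=0.0, max_value=0.1),
    )
    def test_scale_and_shift_equivariance(self, values, scale, shift):
        """mean + 3 SD transforms like the data: scaling the control values
        scales the raw cut-off; adding a constant shifts it by that constant.
        (Note: the cut-off is *not* monotone in each single control value --
        raising a low outlier shrinks the SD faster than it raises the mean.)
        """
        base = westgard_cutoff(values, rounded=False).cutoff_raw
        scaled = westgard_cutoff([v * scale for v in values], rounded=False).cutoff_raw
        assert scaled == pytest.approx(base * scale, rel=1e-9, abs=1e-12)
        shifted = westgard_cutoff(
            [min(v + shift, 1.0) for v in values], rounded=False
        ).cutoff_raw
        if max(values) + shift <= 1.0:
            assert shifted == pytest.approx(base + shift, rel=1e-9, abs=1e-12)
        assert base >= sum(values) / len(values) - 1e-12


class TestClassifyAboveCutoff:
    def test_boundary_semantics(self):
        cutoff = CutoffResult.from_summary(0.010, 0.0058, 163)
        assert classify_above_cutoff([0.053], cutoff).tolist() == [True]
        assert classify_above_cutoff([0.027], cutoff, strict=True).tolist() == [False]
        assert classify_above_cutoff([0.027], cutoff, strict=False).tolist() == [True]


class TestContingency:
    def test_published_tables(self):
        groups = ["SLE"] * 101 + ["HC"] * 6 + ["family_non_SLE"] * 157
        above = [True] * 17 + [False] * 84 + [False] * 163
        table = build_contingency(groups, above)
        assert (table.a, table.b, table.c, table.d) == (17, 84, 0, 163)

    def test_empty(self):
        table = build_contingency([], [])
        assert table.total == 0

    def test_misaligned(self):
        with pytest.raises(InputError):
            build_contingency(["SLE"], [True, False])


class TestFisherExact:
    def test_worked_example(self):
        """[[1,9],[11,3]]: classic enumeration over 11 admissible tables."""
        p = fisher_exact_two_tailed(ContingencyTable(1, 9, 11, 3))
        assert p == pytest.approx(enumeration_oracle(1, 9, 11, 3), rel=1e-10)
        assert p == pytest.approx(0.0027594561852, rel=1e-9)

    def test_empty_column_gives_one(self):
        assert fisher_exact_two_tailed(ContingencyTable(0, 5, 0, 9)) == 1.0

    def test_all_zero_table(self):
        assert fisher_exact_two_tailed(ContingencyTable(0, 0, 0, 0)) == 1.0

    def test_cohort_scale_deep_tail(self):
        p1 = fisher_exact_two_tailed(ContingencyTable(17, 84, 0, 163))
        p2 = fisher_exact_two_tailed(ContingencyTable(37, 43, 14, 73))
        assert p1 < 1e-4 and p2 < 1e-4
        assert p1 == pytest.approx(stats.fisher_exact([[17, 84], [0, 163]])[1], rel=1e-9)
        assert p2 == pytest.approx(stats.fisher_exact([[37, 43], [14, 73]])[1], rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.tuples(*[st.integers(min_value=0, max_value=25)] * 4))
    def test_matches_enumeration_and_scipy(self, cells):
        a, b, c, d = cells
        p = fisher_exact_two_tailed(ContingencyTable(a, b, c, d))
        assert p == pytest.approx(enumeration_oracle(a, b, c, d), rel=1e-9)
        if a + b + c + d > 0:
            assert p == pytest.approx(
                float(stats.fisher_exact([[a, b], [c, d]])[1]), rel=1e-7
            )

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.tuples(*[st.integers(min_value=0, max_value=20)] * 4))
    def test_symmetry_and_range(self, cells):
        a, b, c, d = cells
        p = fisher_exact_two_tailed(ContingencyTable(a, b, c, d))
        assert 0 < p <= 1
        # invariant under simultaneous row and column swaps
        assert p == pytest.approx(
            fisher_exact_two_tailed(ContingencyTable(d, c, b, a)), rel=1e-12
        )


class TestDedupUnrelated:
    def test_familial_cohort_denominators(self, cohort1_roster):
        """24 sporadic + 62 family indices = 86 unrelated patients (172
        alleles); 6 HCs + 62 family representatives = 68 (136 alleles)."""
        result = dedup_unrelated(cohort1_roster)
        assert len(result.unrelated_sle) == 86
        assert len(result.unrelated_non_sle) == 68
        assert "S10" in result.unrelated_sle
        assert "F7-01" in result.unrelated_sle  # smallest ID per family

    def test_all_sporadic_is_identity(self):
        from vafscreen.cohort import cohort2_config

        roster = simulate_cohort(cohort2_config(seed=1))
        result = dedup_unrelated(roster)
        assert len(result.unrelated_sle) == 80
        assert len(result.unrelated_non_sle) == 87
        assert result.excluded == ()

    def test_denominator_independent_of_family_sizes(self):
        """The unrelated count depends only on sporadic and family counts."""
        sizes = []
        for structure in ([(1, 2)] * 4, [(2, 3), (1, 1), (3, 2), (1, 4)]):
            total_aff = sum(a for a, _ in structure)
            total_unaff = sum(u for _, u in structure)
            config = SimConfig(
                n_sporadic_sle=5, n_families=4, n_familial_sle=total_aff,
                n_familial_non_sle=total_unaff, n_hc=3,
                family_structure=structure, seed=0,
            )
            result = dedup_unrelated(simulate_cohort(config))
            sizes.append((len(result.unrelated_sle), len(result.unrelated_non_sle)))
        assert sizes[0] == sizes[1] == (9, 7)


class TestAlleleFrequency:
    def test_published_a410t(self, cohort1_roster):
        """Three heterozygous carriers, two from one family, give 2/172."""
        dedup = dedup_unrelated(cohort1_roster)
        result = allele_frequency(
            "A410T",
            [("S10", "het"), ("F7-01", "het"), ("F7-04", "het")],
            dedup.unrelated_sle,
            cohort1_roster["individual_id"],
        )
        assert result.allele_count == 2
        assert result.denominator == 172
        assert result.frequency == pytest.approx(0.01163, abs=5e-6)
        assert result.excluded_duplicates == ("F7-04",)

    def test_published_a644c(self, cohort1_roster):
        dedup = dedup_unrelated(cohort1_roster)
        result = allele_frequency(
            "A644C", [("F52-01", "het")], dedup.unrelated_sle,
            cohort1_roster["individual_id"],
        )
        assert result.frequency == pytest.approx(1 / 172)
        assert result.frequency == pytest.approx(0.00581, abs=5e-6)

    def test_homozygote_counts_two_alleles(self):
        result = allele_frequency("X", [("P1", "hom")], ["P1", "P2"])
        assert result.allele_count == 2
        assert result.denominator == 4

    def test_no_carriers(self):
        result = allele_frequency("X", [], ["P1", "P2"])
        assert result.frequency == 0.0

    def test_unknown_carrier_rejected(self):
        with pytest.raises(InputError):
            allele_frequency("X", [("GHOST", "het")], ["P1"], roster_ids=["P1"])
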