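import math

import pytest
from hypothesis import given, strategies as st

from probefit.ingest import AggregatedPairActivity
from probefit.scoring import (
    ScoreVector,
    SelectivityBreakdown,
    Weights,
    build_selectivity_breakdown,
    cell_score,
    danger_flag,
    first_factor,
    global_score,
    normalize_second_factor,
    potency_score,
    rank_compounds,
    second_factor_raw,
    selectivity_information_richness,
    selectivity_score,
    third_factor,
)


def agg(median, active=True, conflicting=False, compound="C1", target="T1"):
    return AggregatedPairActivity(
        compound_id=compound, target_accession=target, median_pactivity=median,
        mad=0.0, n_measurements=1, has_equal=True, has_greater=False,
        conflicting=conflicting, active=active,
    )


def vector(compound="C1", potency=0.5, selectivity=0.5, cell=1, sar=0, ia=0, pains=1,
           weights=Weights()):
    return ScoreVector(
        compound_id=compound, target_accession="T1", potency=potency,
        selectivity=selectivity, cell=cell, sar=sar, inactive_analog=ia, pains=pains,
        global_=global_score(potency, selectivity, cell, sar, ia, pains, weights),
    )


class TestPotencyScore:
    def test_cap_maps_to_one(self):
        assert potency_score(agg(10.0)) == 1.0

    def test_threshold_maps_to_zero(self):
        # pActivity 5 is the formula's lower anchor (limit case: a pair at
        # exactly 5 is never classified active, so force the flag).
        assert potency_score(agg(5.0)) == 0.0

    def test_midpoint(self):
        assert potency_score(agg(7.5)) == pytest.approx(0.5)

    def test_inactive_pair_is_contract_violation(self):
        with pytest.raises(ValueError):
            potency_score(agg(4.0, active=False))

    @given(st.floats(min_value=5.000001, max_value=10.0))
    def test_linear_on_scale(self, p):
        assert potency_score(agg(p)) == pytest.approx((p - 5) / 5)

    @given(
        st.floats(min_value=5.000001, max_value=10.0),
        st.floats(min_value=0, max_value=4.999),
    )
    def test_monotone_nondecreasing(self, p, dec):
        lower = max(5.000001, p - dec)
        assert potency_score(agg(lower)) <= potency_score(agg(p))


class TestFirstFactor:
    def test_all_selective(self):
        ff, n_off, n_sel = first_factor({"R": 8.0, "A": 6.5, "B": 5.0}, "R")
        assert (ff, n_off, n_sel) == (1.0, 2, 2)

    def test_half_selective(self):
        ff, n_off, n_sel = first_factor({"R": 8.0, "A": 7.5, "B": 5.0}, "R")
        assert ff == 0.5 and n_sel == 1

    def test_no_off_targets(self):
        assert first_factor({"R": 8.0}, "R") == (0.0, 0, 0)

    def test_boundary_delta_exactly_one_is_selective(self):
        ff, _, n_sel = first_factor({"R": 8.0, "A": 7.0}, "R")
        assert ff == 1.0 and n_sel == 1

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            first_factor({"A": 6.0}, "R")

    @given(
        st.dictionaries(st.text(min_size=1, max_size=4), st.floats(0, 10),
                        min_size=0, max_size=20),
        st.floats(0, 10),
        st.floats(0, 10),
    )
    def test_adding_selective_never_decreases(self, offs, ref, extra_margin):
        offs.pop("R", None)
        profile = {"R": ref, **offs}
        before, n_before, _ = first_factor(profile, "R")
        profile2 = {**profile, "NEW": ref - 1 - extra_margin}
        after, n_after, _ = first_factor(profile2, "R")
        assert n_after == n_before + 1
        if n_before > 0:
            assert after >= before

    @given(
        st.dictionaries(st.text(min_size=1, max_size=4), st.floats(0, 10),
                        min_size=1, max_size=20),
        st.floats(0, 10),
        st.floats(min_value=0, max_value=0.999),
    )
    def test_adding_unselective_never_increases(self, offs, ref, margin):
        offs.pop("R", None)
        profile = {"R": ref, **offs}
        before, _, _ = first_factor(profile, "R")
        profile2 = {**profile, "NEW": ref - margin}
        after, _, _ = first_factor(profile2, "R")
        if profile != profile2 and len(profile) > 1:
            assert after <= before


class TestSic:
    def test_hand_summation(self):
        assert selectivity_information_richness({"R": 8.0, "A": 6.0, "B": 7.5}, "R") == \
            pytest.approx(0.5)

    def test_boundary_zero(self):
        assert selectivity_information_richness({"R": 8.0, "A": 7.0}, "R") == pytest.approx(0.0)

    def test_empty_sum(self):
        assert selectivity_information_richness({"R": 8.0}, "R") == 0.0

    @given(
        st.floats(0, 10),
        st.lists(st.floats(0, 10), min_size=0, max_size=50),
    )
    def test_brute_force_oracle(self, ref, offs):
        profile = {"R": ref}
        profile.update({f"T{i}": p for i, p in enumerate(offs)})
        expected = 0.0
        for p in offs:  # independent per-off-target summation
            expected += ref - p - 1
        assert selectivity_information_richness(profile, "R") == pytest.approx(expected)


class TestSecondFactor:
    @pytest.mark.parametrize(
        "sic,n_unsel,expected",
        [(0.5, 1, 0.25), (6.0, 0, 6.0), (-2.0, 2, -2 / 3)],
    )
    def test_raw(self, sic, n_unsel, expected):
        assert second_factor_raw(sic, n_unsel) == pytest.approx(expected)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            second_factor_raw(1.0, -1)

    def test_minmax_normalization(self):
        cohort = {"a": -1.0, "b": 0.0, "c": 3.0}
        assert normalize_second_factor(cohort) == pytest.approx(
            {"a": 0.0, "b": 0.25, "c": 1.0}
        )

    def test_singleton_cohort_maps_to_zero(self):
        assert normalize_second_factor({"a": 7.0}) == {"a": 0.0}

    def test_zero_range_cohort(self):
        assert normalize_second_factor({"a": 2.0, "b": 2.0}) == {"a": 0.0, "b": 0.0}

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            normalize_second_factor({})

    @given(st.dictionaries(st.integers(0, 50), st.floats(-100, 100), min_size=1, max_size=30))
    def test_normalized_values_in_unit_interval(self, cohort):
        normed = normalize_second_factor(cohort)
        assert all(0.0 <= v <= 1.0 for v in normed.values())


class TestThirdFactor:
    def test_paper_scale_example(self):
        assert third_factor(2, 2220) == pytest.approx(3 / 2220)

    def test_full_coverage_clamped(self):
        assert third_factor(2219, 2220) == 1.0
        assert third_factor(5000, 2220) == 1.0

    def test_no_off_targets(self):
        assert third_factor(0, 100) == pytest.approx(0.01)

    def test_invalid_liganded_count(self):
        with pytest.raises(ValueError):
            third_factor(1, 0)


class TestSelectivityScore:
    def breakdown(self, first=1.0, norm=1.0, third=1.0, n_off=2, n_sel=2):
        return SelectivityBreakdown(
            n_off_targets=n_off, n_selective_off_targets=n_sel, first_factor=first,
            sic=0.0, second_factor_raw=0.0, second_factor_norm=norm, third_factor=third,
        )

    def test_maximum(self):
        assert selectivity_score(self.breakdown()) == 1.0

    def test_no_off_target_information(self):
        bd = self.breakdown(first=0.0, norm=0.0, third=0.5, n_off=0, n_sel=0)
        assert selectivity_score(bd) == 0.0

    def test_direct_arithmetic(self):
        bd = self.breakdown(first=1.0, norm=0.0, third=3 / 2220)
        assert selectivity_score(bd) == pytest.approx((1 + 0 + 3 / 2220) / 3)

    def test_invariant_counts(self):
        with pytest.raises(ValueError):
            SelectivityBreakdown(
                n_off_targets=1, n_selective_off_targets=2, first_factor=1.0,
                sic=0.0, second_factor_raw=0.0, second_factor_norm=0.0, third_factor=0.0,
            )


class TestCellScore:
    def test_one_active_cell_line(self):
        assert cell_score([agg(6.0, target="CL1")]) == 1

    def test_no_cell_data(self):
        assert cell_score([]) == 0

    def test_exactly_ten_micromolar_is_inactive(self):
        assert cell_score([agg(5.0, active=False, target="CL1")]) == 0

    def test_conflicting_cell_data_does_not_count(self):
        assert cell_score([agg(6.0, active=False, conflicting=True, target="CL1")]) == 0


class TestGlobalScore:
    def test_all_ones(self):
        assert global_score(1, 1, 1, 1, 1, 1) == pytest.approx(1.0)

    def test_default_weights_hand_value(self):
        # selectivity, potency and cell at 1; binaries at 0 -> (8+4+2)/17
        assert global_score(1, 1, 1, 0, 0, 0) == pytest.approx(14 / 17)

    def test_all_zero(self):
        assert global_score(0, 0, 0, 0, 0, 0) == 0.0

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            Weights(a=0, b=0, c=0, d=0, e=0, f=0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            Weights(a=-1)

    @given(
        st.lists(st.floats(0, 1), min_size=6, max_size=6),
        st.floats(min_value=0.01, max_value=100),
    )
    def test_invariant_under_uniform_weight_rescaling(self, comps, scale):
        p, s, c, sar, ia, pains = comps
        w = Weights()
        scaled = Weights(**{k: getattr(w, k) * scale for k in "abcdef"})
        assert global_score(p, s, c, sar, ia, pains, w) == pytest.approx(
            global_score(p, s, c, sar, ia, pains, scaled)
        )

    @given(st.lists(st.floats(0, 1), min_size=6, max_size=6))
    def test_bounded(self, comps):
        assert 0.0 <= global_score(*comps) <= 1.0

    def test_weights_from_mapping_rejects_unknown(self):
        with pytest.raises(ValueError):
            Weights.from_mapping({"g": 1.0})


class TestDangerFlag:
    def bd(self, n_off, n_sel):
        return SelectivityBreakdown(
            n_off_targets=n_off, n_selective_off_targets=n_sel, first_factor=0.0,
            sic=0.0, second_factor_raw=0.0, second_factor_norm=0.0, third_factor=0.0,
        )

    def test_one_unselective(self):
        assert danger_flag(self.bd(5, 4)) is True

    def test_fully_selective(self):
        assert danger_flag(self.bd(5, 5)) is False

    def test_no_evidence(self):
        assert danger_flag(self.bd(0, 0)) is False


class TestRankCompounds:
    def test_two_element_sort(self):
        ranked = rank_compounds([vector("A", potency=0.9), vector("B", potency=0.7)],
                                "potency")
        assert [(e.rank, e.compound_id) for e in ranked] == [(1, "A"), (2, "B")]

    def test_tie_breaks_by_compound_id(self):
        ranked = rank_compounds([vector("B", potency=0.5), vector("A", potency=0.5)],
                                "potency")
        assert [e.compound_id for e in ranked] == ["A", "B"]
        assert [e.rank for e in ranked] == [1, 2]

    def test_singleton(self):
        assert rank_compounds([vector("A")])[0].rank == 1

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            rank_compounds([vector("A")], "charisma")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_compounds([])


class TestBuildBreakdown:
    def test_assembles_consistent_intermediates(self):
        profile = {"R": 8.0, "A": 6.0, "B": 7.5}
        bd = build_selectivity_breakdown(profile, "R", 100)
        assert bd.n_off_targets == 2
        assert bd.n_selective_off_targets == 1  # only A at delta 2
        assert bd.first_factor == 0.5
        assert bd.sic == pytest.approx(0.5)
        assert bd.second_factor_raw == pytest.approx(0.5 / 2)
        assert bd.third_factor == pytest.approx(3 / 100)
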