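"""Mass balance, cross-source agreement, heterogeneity and mixture checks."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from fcdbaudit.composition import (
    cross_source_agreement,
    mass_balance,
    mixture_average_check,
    relative_difference,
    resolve_class_components,
    sample_heterogeneity,
    scan_cross_source,
)
from fcdbaudit.errors import DomainError, ScopeError
from fcdbaudit.model import ComponentValue, FCDBPanel, ValueStatus
from oracles import max_pairwise_reldiff_naive


def _profile_panel(class_sums: dict[str, float], food="palm", db="db1"):
    records = [
        ComponentValue(food, db, comp, ValueStatus.QUANTIFIED, qty)
        for comp, qty in class_sums.items()
    ]
    return FCDBPanel(records)


class TestMassBalance:
    def test_overshooting_profile(self):
        # class breakdown synthetic; the total is the interesting part
        panel = _profile_panel({"SFA": 49.44, "MUFA": 40.00, "PUFA": 11.50})
        rep = mass_balance(panel, "palm", "db1")
        assert rep.class_sum == pytest.approx(100.94)
        assert rep.residual == pytest.approx(-0.94)
        assert rep.overshoot is True

    def test_undershooting_profile_has_other_compounds_residual(self):
        panel = _profile_panel({"SFA": 46.4, "MUFA": 38.0, "PUFA": 11.0})
        rep = mass_balance(panel, "palm", "db1")
        assert rep.class_sum == pytest.approx(95.4)
        assert rep.residual == pytest.approx(4.6)
        assert rep.overshoot is False

    def test_residual_is_exactly_100_minus_sum(self):
        panel = _profile_panel({"SFA": 33.333, "MUFA": 33.333, "PUFA": 33.333})
        rep = mass_balance(panel, "palm", "db1")
        assert rep.residual == 100.0 - rep.class_sum  # exact float identity

    def test_empty_class(self):
        panel = _profile_panel({"vitamin_e": 0.02})
        rep = mass_balance(panel, "palm", "db1", component_class=["SFA", "MUFA", "PUFA"])
        assert rep.class_sum == 0.0 and rep.residual == 100.0

    def test_scope_error_for_unknown_food(self):
        panel = _profile_panel({"SFA": 50.0})
        with pytest.raises(ScopeError):
            mass_balance(panel, "nosuchfood", "db1")

    def test_aggregate_preferred_over_leaves(self):
        # both the SFA aggregate and its member FA16:0 present: use the
        # aggregate only, never both
        panel = _profile_panel({"SFA": 49.0, "FA16:0": 43.5, "MUFA": 37.0, "PUFA": 9.4})
        comps = resolve_class_components(panel, "palm", "db1")
        assert "SFA" in comps and "FA16:0" not in comps
        rep = mass_balance(panel, "palm", "db1")
        assert rep.class_sum == pytest.approx(95.4)

    def test_leaves_used_when_aggregate_absent(self):
        panel = _profile_panel({"FA16:0": 43.5, "FA18:0": 5.5, "MUFA": 37.0})
        comps = resolve_class_components(panel, "palm", "db1")
        assert {"FA16:0", "FA18:0", "MUFA"} == comps

    def test_mixed_aggregate_and_member_rejected(self):
        panel = _profile_panel({"SFA": 49.0, "FA16:0": 43.5})
        with pytest.raises(DomainError):
            mass_balance(panel, "palm", "db1", component_class=["SFA", "FA16:0"])

    def test_overshoot_tolerance_configurable(self):
        panel = _profile_panel({"SFA": 100.5})
        assert mass_balance(panel, "palm", "db1").overshoot is True
        assert mass_balance(panel, "palm", "db1", tolerance=1.0).overshoot is False


class TestRelativeDifference:
    def test_identity_and_sign(self):
        assert relative_difference(3.7, 3.7) == 0.0
        assert relative_difference(1.78, 1.00) == pytest.approx(0.78)
        assert relative_difference(0.5, 1.0) == pytest.approx(-0.5)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(DomainError):
            relative_difference(1.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(min_value=0.01, max_value=100, allow_nan=False),
        st.floats(min_value=0.01, max_value=100, allow_nan=False),
        st.floats(min_value=0.01, max_value=10, allow_nan=False),
    )
    def test_scale_invariance(self, a, b, k):
        assert relative_difference(k * a, k * b) == pytest.approx(
            relative_difference(a, b), rel=1e-9, abs=1e-12
        )


class TestCrossSourceAgreement:
    def test_close_database_triple(self):
        values = {"USDA": 43.50, "FRIDA": 43.68, "BEDCA": 43.04}
        rep = cross_source_agreement(values)
        assert rep.max_pairwise_reldiff == pytest.approx(
            max_pairwise_reldiff_naive(values), abs=1e-15
        )
        assert rep.max_pairwise_reldiff == pytest.approx(0.64 / 43.04)
        assert rep.suspicious_shared_source is False

    def test_regional_sample_triple_is_wider(self):
        close = cross_source_agreement({"USDA": 43.50, "FRIDA": 43.68, "BEDCA": 43.04})
        regional = cross_source_agreement({"zaire": 42.0, "indonesia": 48.6, "malaysia": 49.2})
        assert regional.max_pairwise_reldiff == pytest.approx(7.2 / 42.0)
        assert regional.max_pairwise_reldiff > 10 * close.max_pairwise_reldiff

    def test_identical_values_are_suspicious(self):
        rep = cross_source_agreement({"a": 10.0, "b": 10.0, "c": 10.0})
        assert rep.suspicious_shared_source is True
        assert rep.max_pairwise_reldiff == 0.0

    def test_needs_two_sources(self):
        with pytest.raises(ScopeError):
            cross_source_agreement({"only": 1.0})

    @settings(derandomize=True, max_examples=60)
    @given(
        st.dictionaries(
            st.sampled_from(["d1", "d2", "d3", "d4", "d5"]),
            st.floats(min_value=0.1, max_value=100, allow_nan=False),
            min_size=2,
        )
    )
    def test_matches_brute_force(self, values):
        rep = cross_source_agreement(values)
        assert rep.max_pairwise_reldiff == pytest.approx(
            max_pairwise_reldiff_naive(values), abs=1e-12
        )

    def test_scan_panel_values(self, mini_panel):
        rep = scan_cross_source(mini_panel, "oilA", "SFA")
        assert rep.values == {"db1": 5.0, "db2": 4.5}
        assert rep.max_pairwise_reldiff == pytest.approx(0.5 / 4.5)


class TestSampleHeterogeneity:
    def test_bimodal_sample_pool(self):
        # two conventional samples near 20, six high-oleic near 75-80:
        # the pooled mean lands far from either cluster
        samples = [20, 20, 75, 76, 78, 79, 80, 80]
        rep = sample_heterogeneity(samples, gap_threshold=25)
        assert rep.cluster_means == (pytest.approx(20.0), pytest.approx(78.0))
        assert rep.pooled_mean == pytest.approx(63.5)
        assert rep.heterogeneous is True

    def test_constant_samples(self):
        rep = sample_heterogeneity([55.0, 55.0, 55.0], gap_threshold=10)
        assert rep.split_gap == 0.0 and rep.heterogeneous is False

    def test_two_close_samples(self):
        assert sample_heterogeneity([1, 2], gap_threshold=10).heterogeneous is False

    def test_insufficient_samples(self):
        rep = sample_heterogeneity([42.0])
        assert rep.heterogeneous is False and rep.note == "insufficient-samples"

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(st.floats(min_value=0, max_value=100, allow_nan=False), min_size=2, max_size=12),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariant(self, samples, rnd):
        shuffled = list(samples)
        rnd.shuffle(shuffled)
        a = sample_heterogeneity(samples, gap_threshold=20)
        b = sample_heterogeneity(shuffled, gap_threshold=20)
        assert a.cluster_means == b.cluster_means
        assert a.heterogeneous == b.heterogeneous


class TestMixtureAverage:
    def test_pooled_pair_detected(self):
        rep = mixture_average_check(
            25.8, {"palm": 43.5, "palm_kernel": 8.1}, eps=0.5, statistic="mean"
        )
        assert rep.flagged is True
        assert rep.pair == ("palm", "palm_kernel")
        assert rep.pair_statistic == pytest.approx(25.8)

    def test_value_matching_single_candidate_not_flagged(self):
        rep = mixture_average_check(43.5, {"palm": 43.5, "palm_kernel": 8.1}, eps=0.5)
        assert rep.flagged is False

    def test_single_candidate_not_flagged(self):
        assert mixture_average_check(25.8, {"palm": 43.5}).flagged is False

    def test_median_statistic_supported(self):
        rep = mixture_average_check(
            25.8, {"palm": 43.5, "palm_kernel": 8.1}, eps=0.5, statistic="median"
        )
        assert rep.flagged is True  # median of a pair equals its mean
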