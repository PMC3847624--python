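"""Residual mortality engine: multipliers, decompositions, microsim oracle."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from listlite.impact import (
    CauseStructure,
    DecompositionMode,
    EffectivenessEntry,
    ImpactError,
    ProjectionResult,
    attributable_reduction,
    cause_multiplier,
    decompose_by_intervention,
    microsim_oracle,
    percent_reduction,
)


def entry(iid, cause, eff, af=1.0):
    return EffectivenessEntry(
        intervention_id=iid, cause=cause, effectiveness=eff, affected_fraction=af
    )


@pytest.fixture
def single_cause():
    return CauseStructure(fractions={"malaria": 1.0})


@pytest.fixture
def burkina_causes():
    return CauseStructure.with_residual(
        {"malaria": 0.24, "pneumonia": 0.18, "diarrhea": 0.12, "neonatal": 0.22}
    )


class TestCauseStructure:
    def test_residual_closes_sum(self, burkina_causes):
        assert sum(burkina_causes.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert burkina_causes.fractions["other"] == pytest.approx(0.24)

    def test_non_unit_sum_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            CauseStructure(fractions={"malaria": 0.5})


class TestCauseMultiplier:
    def test_empty_product_is_one(self):
        assert cause_multiplier("malaria", {"x": 0.2}, {"x": 0.6}, []) == 1.0

    def test_hand_computed_ratio(self):
        eff = [entry("x", "malaria", 0.5)]
        m = cause_multiplier("malaria", {"x": 0.2}, {"x": 0.6}, eff)
        assert m == pytest.approx(0.7 / 0.9, abs=1e-12)

    def test_identity_when_coverage_unchanged(self):
        eff = [entry("x", "malaria", 0.5)]
        assert cause_multiplier("malaria", {"x": 0.4}, {"x": 0.4}, eff) == 1.0

    def test_baseline_saturation_rejected(self):
        eff = [entry("x", "malaria", 1.0, 1.0)]
        with pytest.raises(ImpactError, match="saturation"):
            cause_multiplier("malaria", {"x": 1.0}, {"x": 1.0}, eff)

    def test_order_invariance_under_shuffle(self):
        rng = random.Random(7)
        eff = [entry(f"i{k}", "malaria", 0.1 + 0.05 * k) for k in range(6)]
        base = {f"i{k}": 0.1 * k for k in range(6)}
        scen = {f"i{k}": min(0.1 * k + 0.2, 1.0) for k in range(6)}
        reference = cause_multiplier("malaria", base, scen, eff)
        for _ in range(10):
            shuffled = eff[:]
            rng.shuffle(shuffled)
            assert cause_multiplier("malaria", base, scen, shuffled) == pytest.approx(
                reference, abs=1e-12
            )


class TestPercentReduction:
    def test_zero_at_baseline(self, burkina_causes):
        eff = [entry("x", "malaria", 0.5)]
        assert percent_reduction(burkina_causes, {"x": 0.3}, {"x": 0.3}, eff) == 0.0

    def test_single_cause_chain(self, single_cause):
        eff = [entry("x", "malaria", 0.5)]
        r = percent_reduction(single_cause, {"x": 0.2}, {"x": 0.6}, eff)
        assert r == pytest.approx(100 * (1 - 0.7 / 0.9), abs=1e-9)

    def test_negative_when_coverage_declines(self, single_cause):
        eff = [entry("x", "malaria", 0.5)]
        assert percent_reduction(single_cause, {"x": 0.6}, {"x": 0.2}, eff) < 0

    @given(
        cov_base=st.floats(0, 0.9, allow_nan=False),
        cov_up=st.floats(0, 1, allow_nan=False),
        potency=st.floats(0.05, 0.9, allow_nan=False),
    )
    def test_monotone_in_scenario_coverage(self, cov_base, cov_up, potency):
        cs = CauseStructure.with_residual({"malaria": 0.24})
        eff = [entry("x", "malaria", potency)]
        r_lo = percent_reduction(cs, {"x": cov_base}, {"x": cov_base}, eff)
        r_hi = percent_reduction(cs, {"x": cov_base}, {"x": max(cov_base, cov_up)}, eff)
        assert r_hi >= r_lo - 1e-12

    @given(
        f_mal=st.floats(0.05, 0.5, allow_nan=False),
        covs=st.tuples(st.floats(0, 0.8), st.floats(0, 1)),
    )
    def test_bounded_by_addressed_cause_share(self, f_mal, covs):
        cs = CauseStructure.with_residual({"malaria": f_mal})
        eff = [entry("x", "malaria", 0.9)]
        r = percent_reduction(cs, {"x": covs[0]}, {"x": covs[1]}, eff)
        assert r <= 100 * f_mal + 1e-9


class TestAttributableReduction:
    @pytest.mark.parametrize("su, sec, expected", [(22, 8, 14), (5, 5, 0), (10, 15, -5)])
    def test_scenario_differencing(self, su, sec, expected):
        assert attributable_reduction(su, sec) == expected


class TestDecomposition:
    def test_single_intervention_both_modes_equal_joint(self, single_cause):
        eff = [entry("x", "malaria", 0.5)]
        base, scen = {"x": 0.2}, {"x": 0.6}
        joint = percent_reduction(single_cause, base, scen, eff)
        for mode in DecompositionMode:
            out = decompose_by_intervention(single_cause, base, scen, eff, mode)
            assert out["x"] == pytest.approx(joint, abs=1e-9)

    def test_disjoint_causes_make_modes_agree(self, burkina_causes):
        eff = [entry("a", "malaria", 0.5), entry("b", "diarrhea", 0.7)]
        base = {"a": 0.2, "b": 0.1}
        scen = {"a": 0.6, "b": 0.5}
        iso = decompose_by_intervention(burkina_causes, base, scen, eff, "isolation")
        sim = decompose_by_intervention(burkina_causes, base, scen, eff, "simultaneous")
        for iid in base:
            assert sim[iid] == pytest.approx(iso[iid], abs=1e-9)

    def test_unchanged_coverage_gives_zero_map(self, burkina_causes):
        eff = [entry("a", "malaria", 0.5)]
        out = decompose_by_intervention(burkina_causes, {"a": 0.3}, {"a": 0.3}, eff)
        assert out == {"a": 0.0}

    @given(
        potencies=st.lists(st.floats(0.05, 0.8), min_size=2, max_size=4),
        data=st.data(),
    )
    def test_simultaneous_shares_conserve_joint_reduction(self, potencies, data):
        cs = CauseStructure.with_residual({"malaria": 0.24, "diarrhea": 0.12})
        causes = ["malaria", "diarrhea"]
        eff, base, scen = [], {}, {}
        for k, p in enumerate(potencies):
            iid = f"i{k}"
            eff.append(entry(iid, causes[k % 2], p))
            base[iid] = data.draw(st.floats(0, 0.8))
            scen[iid] = data.draw(st.floats(0, 1))
        joint = percent_reduction(cs, base, scen, eff)
        shares = decompose_by_intervention(cs, base, scen, eff, "simultaneous")
        assert sum(shares.values()) == pytest.approx(joint, abs=1e-9)

    def test_joint_subadditive_vs_isolation_sum(self, single_cause):
        # Two interventions competing for the same deaths: isolation sums
        # double-count the overlap.
        eff = [entry("a", "malaria", 0.6), entry("b", "malaria", 0.5)]
        base = {"a": 0.1, "b": 0.2}
        scen = {"a": 0.7, "b": 0.8}
        joint = percent_reduction(single_cause, base, scen, eff)
        iso = decompose_by_intervention(single_cause, base, scen, eff, "isolation")
        assert joint <= sum(iso.values()) + 1e-9


class TestMicrosimOracle:
    def test_seeded_bit_reproducibility(self, single_cause):
        eff = [entry("x", "malaria", 0.5)]
        args = (single_cause, {"x": 0.2}, {"x": 0.6}, eff)
        assert microsim_oracle(*args, n_children=10, seed=3) == microsim_oracle(
            *args, n_children=10, seed=3
        )

    def test_null_scenario_within_three_se_of_zero(self, burkina_causes):
        eff = [entry("x", "malaria", 0.5)]
        r, se = microsim_oracle(
            burkina_causes, {"x": 0.3}, {"x": 0.3}, eff, n_children=50_000, seed=11
        )
        assert abs(r) <= 3 * se

    def test_converges_to_analytic_value(self, single_cause):
        eff = [entry("x", "malaria", 0.5)]
        base, scen = {"x": 0.2}, {"x": 0.6}
        analytic = percent_reduction(single_cause, base, scen, eff)
        r, se = microsim_oracle(single_cause, base, scen, eff, n_children=10**6, seed=5)
        assert r == pytest.approx(analytic, abs=3 * se)

    def test_multi_cause_multi_intervention_agreement(self, burkina_causes):
        eff = [
            entry("act", "malaria", 0.55),
            entry("ors", "diarrhea", 0.93, 0.8),
            entry("zinc", "diarrhea", 0.23),
            entry("abx", "pneumonia", 0.7, 0.8),
        ]
        base = {"act": 0.26, "ors": 0.23, "zinc": 0.04, "abx": 0.33}
        scen = {"act": 0.70, "ors": 0.60, "zinc": 0.60, "abx": 0.60}
        analytic = percent_reduction(burkina_causes, base, scen, eff)
        r, se = microsim_oracle(burkina_causes, base, scen, eff, n_children=400_000, seed=9)
        assert r == pytest.approx(analytic, abs=3 * se)


class TestProjectionResult:
    def test_reduction_multiplier_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ProjectionResult(
                unit_id="all", scenario="fixed", mortality_multiplier=0.9, percent_reduction=5.0
            )

    def test_valid_result_roundtrip(self):
        p = ProjectionResult(
            unit_id="all", scenario="scale_up", mortality_multiplier=0.78,
            percent_reduction=100 * (1 - 0.78),
        )
        assert p.percent_reduction == pytest.approx(22.0)
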