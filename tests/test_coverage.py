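"""Survey harmonization: reference preference, conflict rule, interpolation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from listlite.coverage import (
    BirthAttendanceBreakdown,
    HarmonizationError,
    Source,
    SurveyEstimate,
    build_trajectory,
    harmonize_unit_intervention,
    interpolate,
    proxy_coverage,
    recompute_sba,
    resolve_decline,
    select_reference,
)


def est(source, coverage, year=None, unit="all", iid="itn"):
    years = {Source.DHS2003: 2003, Source.MICS2006: 2006, Source.BASELINE2010: 2010}
    return SurveyEstimate(
        intervention_id=iid,
        unit_id=unit,
        year=year or years[source],
        coverage=coverage,
        source=source,
    )


class TestSelectReference:
    def test_mics_preferred_over_dhs(self):
        chosen = select_reference([est(Source.DHS2003, 0.30), est(Source.MICS2006, 0.40)])
        assert chosen.source is Source.MICS2006
        assert chosen.coverage == 0.40

    def test_dhs_used_when_only_candidate(self):
        chosen = select_reference([est(Source.DHS2003, 0.30)])
        assert chosen.source is Source.DHS2003

    def test_order_invariant(self):
        pair = [est(Source.MICS2006, 0.40), est(Source.DHS2003, 0.30)]
        assert select_reference(pair) == select_reference(pair[::-1])

    def test_empty_list_rejected(self):
        with pytest.raises(HarmonizationError, match="no reference data"):
            select_reference([])

    def test_duplicate_source_is_ambiguous(self):
        with pytest.raises(HarmonizationError, match="ambiguous"):
            select_reference([est(Source.DHS2003, 0.30), est(Source.DHS2003, 0.35)])

    def test_baseline_survey_not_a_candidate(self):
        with pytest.raises(HarmonizationError):
            select_reference([est(Source.BASELINE2010, 0.5)])


class TestRecomputeSba:
    def test_skilled_categories_only(self):
        b = BirthAttendanceBreakdown(doctor=0.05, nurse=0.10, midwife=0.15, matrone=0.20)
        assert recompute_sba(b) == pytest.approx(0.30)

    def test_all_zero(self):
        assert recompute_sba(BirthAttendanceBreakdown()) == 0.0

    def test_impossible_fractions_rejected(self):
        with pytest.raises(ValueError):
            BirthAttendanceBreakdown(doctor=0.6, nurse=0.6)

    def test_unknown_category_rejected(self):
        with pytest.raises(HarmonizationError, match="unknown provider"):
            recompute_sba(BirthAttendanceBreakdown(doctor=0.1), included_categories=["shaman"])


class TestResolveDecline:
    def test_apparent_decline_flattened_at_2010_value(self):
        anchors = resolve_decline(est(Source.MICS2006, 0.50), est(Source.BASELINE2010, 0.30))
        assert anchors == ((2006, 0.30), (2010, 0.30))

    def test_increase_passes_through(self):
        anchors = resolve_decline(est(Source.MICS2006, 0.20), est(Source.BASELINE2010, 0.30))
        assert anchors == ((2006, 0.20), (2010, 0.30))

    def test_equality_is_not_a_conflict(self):
        anchors = resolve_decline(est(Source.DHS2003, 0.30), est(Source.BASELINE2010, 0.30))
        assert anchors == ((2003, 0.30), (2010, 0.30))

    @given(
        ref=st.floats(0, 1, allow_nan=False),
        base=st.floats(0, 1, allow_nan=False),
    )
    def test_output_non_decreasing_and_in_range(self, ref, base):
        anchors = resolve_decline(est(Source.MICS2006, ref), est(Source.BASELINE2010, base))
        (y0, c0), (y1, c1) = anchors
        assert y0 < y1 and c0 <= c1
        assert 0.0 <= c0 <= 1.0 and 0.0 <= c1 <= 1.0


class TestInterpolate:
    def test_midpoint_of_segment(self):
        assert interpolate([(2006, 0.20), (2010, 0.40)], 2008) == pytest.approx(0.30)

    def test_exact_at_anchor(self):
        assert interpolate([(2006, 0.20), (2010, 0.40)], 2010) == 0.40

    def test_extrapolation_refused(self):
        with pytest.raises(HarmonizationError, match="outside anchor span"):
            interpolate([(2006, 0.20), (2010, 0.40)], 2012)

    @given(
        covs=st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=5),
        data=st.data(),
    )
    def test_anchor_exactness_and_betweenness(self, covs, data):
        years = list(range(2003, 2003 + 2 * len(covs), 2))
        anchors = list(zip(years, covs))
        for y, c in anchors:
            assert interpolate(anchors, y) == c
        q = data.draw(st.integers(years[0], years[-1]))
        v = interpolate(anchors, q)
        for (y0, c0), (y1, c1) in zip(anchors, anchors[1:]):
            if y0 <= q <= y1:
                assert min(c0, c1) - 1e-12 <= v <= max(c0, c1) + 1e-12


class TestProxyCoverage:
    @pytest.mark.parametrize(
        "value, link, factor, expected",
        [(0.71, "SBA", 1.0, 0.71), (0.80, "ANC4plus", 0.5, 0.40), (0.0, "SBA", 0.7, 0.0)],
    )
    def test_scaling_contract(self, value, link, factor, expected):
        assert proxy_coverage(value, link, factor) == pytest.approx(expected)

    def test_unknown_link_rejected(self):
        with pytest.raises(HarmonizationError, match="unknown proxy link"):
            proxy_coverage(0.5, "TT2plus")


class TestHarmonizeUnitIntervention:
    def _surveys(self):
        return [
            est(Source.DHS2003, 0.10),
            est(Source.MICS2006, 0.20),
            est(Source.BASELINE2010, 0.40, unit="district_a"),
            est(Source.BASELINE2010, 0.15, unit="district_b"),
        ]

    def test_national_reference_borrowed_by_district(self):
        traj = harmonize_unit_intervention("itn", "district_a", self._surveys())
        assert traj.at(2006) == 0.20
        assert traj.at(2010) == 0.40
        assert traj.at(2008) == pytest.approx(0.30)

    def test_conflict_with_borrowed_reference_goes_flat(self):
        traj = harmonize_unit_intervention("itn", "district_b", self._surveys())
        assert all(traj.at(y) == 0.15 for y in range(2003, 2011))

    def test_no_reference_at_all_is_flat_at_2010(self):
        surveys = [est(Source.BASELINE2010, 0.33, unit="district_a")]
        traj = harmonize_unit_intervention("itn", "district_a", surveys)
        assert all(traj.at(y) == 0.33 for y in range(2003, 2011))

    def test_missing_baseline_is_an_error(self):
        with pytest.raises(HarmonizationError, match="no 2010 baseline"):
            harmonize_unit_intervention("itn", "district_c", self._surveys())


def test_trajectory_flat_extension_outside_anchors():
    traj = build_trajectory("itn", "all", [(2006, 0.2), (2010, 0.4)], 2003, 2013)
    assert traj.at(2003) == 0.2 and traj.at(2013) == 0.4
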