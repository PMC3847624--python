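"""Harmonization of intervention-coverage survey anchors.

Coverage point estimates arrive from heterogeneous household surveys — a
DHS-style national survey (2003), a MICS-style national survey (2006) and a
program baseline survey (2010). This module represents those estimates,
applies the preference and conflict-resolution rules that turn them into a
single per-intervention annual time series, and exposes the small coverage
arithmetic the rules need (skilled-birth-attendance recomputation from
provider categories, proxy coverage for interventions that household surveys
cannot measure directly).

Coverage is a fraction in [0, 1] everywhere inside the engine; file I/O and
reports use percent (0-100).
"""

from __future__ import annotations

import enum
from bisect import bisect_right
from typing import Iterable, Mapping, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

YEAR_MIN = 2000
YEAR_MAX = 2015
#: First and last calendar year of the modeled horizon.
HORIZON_START = 2003
HORIZON_END = 2013
BASELINE_YEAR = 2010


class HarmonizationError(ValueError):
    """A survey set violates the harmonization contract."""


class Source(str, enum.Enum):
    """Which survey family an estimate came from."""

    DHS2003 = "DHS2003"
    MICS2006 = "MICS2006"
    BASELINE2010 = "BASELINE2010"


class Stratum(str, enum.Enum):
    RURAL = "rural"
    URBAN = "urban"
    ALL = "all"


#: Later-collected surveys are preferred as the pre-2010 reference.
DEFAULT_PREFER_SOURCE_ORDER: tuple[Source, ...] = (Source.MICS2006, Source.DHS2003)


class SurveyEstimate(BaseModel):
    """One coverage point estimate for one intervention in one unit."""

    model_config = ConfigDict(frozen=True)

    intervention_id: str
    unit_id: str
    year: int = Field(ge=YEAR_MIN, le=YEAR_MAX)
    coverage: float = Field(ge=0.0, le=1.0)
    source: Source
    stratum: Stratum = Stratum.RURAL


class BirthAttendanceBreakdown(BaseModel):
    """Births attended, by provider category, as population fractions.

    ``matrone`` is a trained traditional birth attendant; the current
    skilled-birth-attendance definition excludes that category, so the
    indicator is recomputed as doctor + nurse + midwife.
    """

    model_config = ConfigDict(frozen=True)

    doctor: float = Field(0.0, ge=0.0, le=1.0)
    nurse: float = Field(0.0, ge=0.0, le=1.0)
    midwife: float = Field(0.0, ge=0.0, le=1.0)
    auxiliary_midwife: float = Field(0.0, ge=0.0, le=1.0)
    matrone: float = Field(0.0, ge=0.0, le=1.0)
    other: float = Field(0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _total_at_most_one(self) -> "BirthAttendanceBreakdown":
        total = (
            self.doctor
            + self.nurse
            + self.midwife
            + self.auxiliary_midwife
            + self.matrone
            + self.other
        )
        if total > 1.0 + 1e-9:
            raise ValueError(f"provider fractions sum to {total:.4f} > 1")
        return self


#: Provider categories counted as "skilled" under the current definition.
SKILLED_CATEGORIES: tuple[str, ...] = ("doctor", "nurse", "midwife")


class ProxyLink(str, enum.Enum):
    """Measured indicator whose coverage stands in for an unmeasured one."""

    ANC4plus = "ANC4plus"
    SBA = "SBA"


class CoverageTrajectory(BaseModel):
    """Per-intervention coverage as a function of calendar year.

    ``anchors`` are the surveyed (or scenario-constructed) support points;
    ``values`` holds the annual series obtained by linear interpolation
    between consecutive anchors and flat extension outside their span.
    """

    model_config = ConfigDict(frozen=True)

    intervention_id: str
    unit_id: str
    anchors: tuple[tuple[int, float], ...]
    values: Mapping[int, float]

    @model_validator(mode="after")
    def _check(self) -> "CoverageTrajectory":
        years = [y for y, _ in self.anchors]
        if years != sorted(set(years)):
            raise ValueError("anchor years must be strictly increasing")
        for year, cov in self.anchors:
            if not 0.0 <= cov <= 1.0:
                raise ValueError(f"anchor coverage {cov} outside [0,1]")
            got = self.values.get(year)
            if got is None or abs(got - cov) > 1e-12:
                raise ValueError(f"values[{year}]={got!r} does not match anchor {cov}")
        if any(not 0.0 <= v <= 1.0 for v in self.values.values()):
            raise ValueError("interpolated value outside [0,1]")
        return self

    def at(self, year: int) -> float:
        return self.values[year]


def select_reference(estimates: Sequence[SurveyEstimate]) -> SurveyEstimate:
    """Pick the pre-2010 reference estimate for one intervention and unit.

    MICS (2006) values are used preferentially to DHS (2003) values because
    they were collected more recently; DHS is the fallback when the
    indicator was only measured there. The 2010 baseline survey never serves
    as the reference. Order of the input is irrelevant.
    """
    if not estimates:
        raise HarmonizationError("no reference data: empty estimate list")
    keys = {(e.intervention_id, e.unit_id) for e in estimates}
    if len(keys) > 1:
        raise HarmonizationError(f"mixed intervention/unit in reference set: {sorted(keys)}")
    if any(e.source is Source.BASELINE2010 for e in estimates):
        raise HarmonizationError("2010 baseline estimates are not reference candidates")
    by_source: dict[Source, list[SurveyEstimate]] = {}
    for e in estimates:
        by_source.setdefault(e.source, []).append(e)
    for source, group in by_source.items():
        if len(group) > 1:
            raise HarmonizationError(f"ambiguous reference: {len(group)} estimates from {source.value}")
    for source in DEFAULT_PREFER_SOURCE_ORDER:
        if source in by_source:
            return by_source[source][0]
    raise HarmonizationError(f"no usable reference source among {sorted(s.value for s in by_source)}")


def recompute_sba(
    breakdown: BirthAttendanceBreakdown,
    included_categories: Iterable[str] = SKILLED_CATEGORIES,
) -> float:
    """Recompute skilled birth attendance as a sum of provider categories.

    The shipped configuration includes doctor, nurse and midwife — excluding
    auxiliary midwives and matrones, whose inclusion in survey reports is
    inconsistent with the current indicator definition. The category list is
    configurable so the same recomputation applies to any provider-breakdown
    indicator.
    """
    included = tuple(included_categories)
    unknown = [c for c in included if c not in BirthAttendanceBreakdown.model_fields]
    if unknown:
        raise HarmonizationError(f"unknown provider categories: {unknown}")
    total = sum(getattr(breakdown, c) for c in included)
    if total > 1.0 + 1e-9:
        raise HarmonizationError(f"selected provider categories sum to {total:.4f} > 1")
    return min(total, 1.0)


def resolve_decline(
    reference: SurveyEstimate, baseline2010: SurveyEstimate
) -> tuple[tuple[int, float], ...]:
    """Apply the flat-trend conflict rule to a (reference, 2010) anchor pair.

    An apparent coverage decline from the 2003/2006 national-rural reference
    to the 2010 program-area baseline is treated as an artifact of the
    differing sampling frames, not a real decline: the 2010 value replaces
    the reference value, yielding a flat pre-2010 trend. Otherwise both
    anchors pass through unchanged.
    """
    if reference.year >= BASELINE_YEAR:
        raise HarmonizationError(f"reference year {reference.year} must precede {BASELINE_YEAR}")
    if baseline2010.year != BASELINE_YEAR:
        raise HarmonizationError(f"baseline anchor must be {BASELINE_YEAR}, got {baseline2010.year}")
    if reference.coverage > baseline2010.coverage:
        return ((reference.year, baseline2010.coverage), (BASELINE_YEAR, baseline2010.coverage))
    return ((reference.year, reference.coverage), (BASELINE_YEAR, baseline2010.coverage))


def interpolate(anchors: Sequence[tuple[int, float]], query_year: int) -> float:
    """Linear interpolation between the bracketing anchors; exact at anchors.

    Queries outside the anchor span raise — extrapolation beyond 2010 is the
    scenario builder's job and follows different rules.
    """
    if len(anchors) < 2:
        raise HarmonizationError("need at least two anchors to interpolate")
    years = [y for y, _ in anchors]
    if any(b <= a for a, b in zip(years, years[1:])):
        raise HarmonizationError(f"anchor years must be strictly increasing: {years}")
    if not years[0] <= query_year <= years[-1]:
        raise HarmonizationError(
            f"query year {query_year} outside anchor span [{years[0]}, {years[-1]}]"
        )
    hi = bisect_right(years, query_year)
    if hi == len(years):
        return anchors[-1][1]
    lo = hi - 1
    (y0, c0), (y1, c1) = anchors[lo], anchors[hi]
    if query_year == y0:
        return c0
    return c0 + (c1 - c0) * (query_year - y0) / (y1 - y0)


def proxy_coverage(
    linked_indicator_value: float, link: ProxyLink | str, factor: float = 1.0
) -> float:
    """Coverage assigned to an intervention not measurable in surveys.

    Interventions such as magnesium sulfate for pre-eclampsia or active
    management of the third stage of labor are proxied from a measured
    contact indicator (ANC4+ or skilled birth attendance), optionally scaled
    by a per-intervention factor in [0, 1]. The default factor is the
    identity: the linkage coefficients of the reference implementation are
    not public.
    """
    try:
        ProxyLink(link)
    except ValueError:
        raise HarmonizationError(f"unknown proxy link {link!r}") from None
    if not 0.0 <= linked_indicator_value <= 1.0:
        raise HarmonizationError(f"linked indicator value {linked_indicator_value} outside [0,1]")
    if not 0.0 <= factor <= 1.0:
        raise HarmonizationError(f"proxy scaling factor {factor} outside [0,1]")
    return factor * linked_indicator_value


def build_trajectory(
    intervention_id: str,
    unit_id: str,
    anchors: Sequence[tuple[int, float]],
    year_start: int = HORIZON_START,
    year_end: int = HORIZON_END,
) -> CoverageTrajectory:
    """Annualize a set of anchors into a full trajectory over the horizon.

    Years between anchors are linearly interpolated; years outside the
    anchor span are held flat at the nearest anchor (the conservative
    no-information extension used before the reference year and after the
    last constructed anchor).
    """
    anchors = tuple(sorted(anchors))
    values: dict[int, float] = {}
    for year in range(year_start, year_end + 1):
        if year < anchors[0][0]:
            values[year] = anchors[0][1]
        elif year > anchors[-1][0]:
            values[year] = anchors[-1][1]
        else:
            values[year] = interpolate(anchors, year)
    return CoverageTrajectory(
        intervention_id=intervention_id, unit_id=unit_id, anchors=anchors, values=values
    )


def harmonize_unit_intervention(
    intervention_id: str,
    unit_id: str,
    estimates: Sequence[SurveyEstimate],
    national_unit_id: str = "all",
) -> CoverageTrajectory:
    """Full harmonization for one (unit, intervention): reference selection,
    conflict resolution, annual interpolation up to 2010.

    Pre-2010 references are national-rural surveys; when the unit itself has
    no pre-2010 estimate the national (``national_unit_id``) reference is
    used with the unit's own 2010 baseline, mirroring how district
    projections borrow the national trend. With no reference at all the
    trajectory is flat at the 2010 value.
    """
    baselines = [
        e
        for e in estimates
        if e.intervention_id == intervention_id
        and e.unit_id == unit_id
        and e.source is Source.BASELINE2010
    ]
    if not baselines:
        raise HarmonizationError(f"no 2010 baseline for {intervention_id!r} in unit {unit_id!r}")
    if len(baselines) > 1:
        raise HarmonizationError(f"multiple 2010 baselines for {intervention_id!r}/{unit_id!r}")
    baseline = baselines[0]

    def _refs(uid: str) -> list[SurveyEstimate]:
        return [
            e
            for e in estimates
            if e.intervention_id == intervention_id
            and e.unit_id == uid
            and e.source is not Source.BASELINE2010
        ]

    candidates = _refs(unit_id) or _refs(national_unit_id)
    if not candidates:
        anchors: tuple[tuple[int, float], ...] = (
            (HORIZON_START, baseline.coverage),
            (BASELINE_YEAR, baseline.coverage),
        )
    else:
        if candidates[0].unit_id != unit_id:
            # National reference borrowed for a sub-unit: re-key it.
            candidates = [e.model_copy(update={"unit_id": unit_id}) for e in candidates]
        reference = select_reference(candidates)
        anchors = resolve_decline(reference, baseline)
    return build_trajectory(intervention_id, unit_id, anchors, year_end=BASELINE_YEAR)
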