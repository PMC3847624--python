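"""Counterfactual coverage scenarios for the 2010-2013 projection horizon.

Three scenarios are constructed from the harmonized trajectories:

* **fixed** — every intervention stays at its 2010 coverage through 2013;
  the null scenario against which the engine's multiplier is exactly 1.
* **scale_up** — program interventions move linearly from their 2010
  coverage to their 2013 targets; non-program interventions stay at 2010
  levels. Interventions that already meet their target continue at the
  pre-2010 annual rate of change (never decreasing), under the same
  ceiling as the secular scenario.
* **secular_trend** — every intervention continues its pre-2010 annual
  rate of change; once coverage reaches the cap (default 90%) it stops
  rising. An intervention whose own pre-2010 history is uninformative can
  borrow another intervention's rate (rate substitution — ACT borrows the
  oral-antibiotics rate, because chloroquine was being phased out while
  ACT use was still negligible in 2006).

All coverage changes are linear in calendar time.
"""

from __future__ import annotations

import enum
from typing import Mapping, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .coverage import BASELINE_YEAR, CoverageTrajectory, build_trajectory

DEFAULT_CAP = 0.90
HORIZON = (2010, 2013)


class ScenarioError(ValueError):
    """Scenario construction received inconsistent inputs."""


class ScenarioKind(str, enum.Enum):
    FIXED = "fixed"
    SCALE_UP = "scale_up"
    SECULAR_TREND = "secular_trend"


#: Deterministic rendering order for scenarios in reports and job lists.
SCENARIO_ORDER: tuple[ScenarioKind, ...] = (
    ScenarioKind.FIXED,
    ScenarioKind.SCALE_UP,
    ScenarioKind.SECULAR_TREND,
)


class ScenarioSpec(BaseModel):
    """Which counterfactual rule to apply, with its parameters.

    ``targets`` maps program interventions to their 2013 target coverage
    (fractions); interventions absent from the map are non-program and are
    held at 2010 levels in the scale-up scenario. ``cap`` is the ceiling at
    which secular growth stops. ``rate_substitutions`` maps an intervention
    to the donor whose pre-2010 annual rate it borrows.
    """

    model_config = ConfigDict(frozen=True)

    kind: ScenarioKind
    targets: Mapping[str, float] = Field(default_factory=dict)
    cap: float = Field(DEFAULT_CAP, gt=0.0, le=1.0)
    rate_substitutions: Mapping[str, str] = Field(default_factory=dict)
    horizon_start: int = HORIZON[0]
    horizon_end: int = HORIZON[1]

    @model_validator(mode="after")
    def _check(self) -> "ScenarioSpec":
        if self.horizon_start >= self.horizon_end:
            raise ValueError("horizon_start must precede horizon_end")
        for iid, t in self.targets.items():
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"target for {iid!r} is {t}, outside [0,1]")
        if self.kind is ScenarioKind.SCALE_UP and not self.targets:
            raise ValueError("scale_up scenario requires a target map")
        return self


class AnnualRate(BaseModel):
    """Pre-2010 annual rate of coverage change, in fraction per year."""

    model_config = ConfigDict(frozen=True)

    intervention_id: str
    rate: float
    reference_year: int
    baseline_year: int = BASELINE_YEAR


def annual_rate(
    intervention_id: str,
    reference: tuple[int, float],
    baseline: tuple[int, float],
) -> AnnualRate:
    """Annual rate of change between the reference anchor and 2010.

    A flat pre-2010 series (as produced by the conflict rule) yields rate 0.
    """
    ref_year, ref_cov = reference
    base_year, base_cov = baseline
    if base_year != BASELINE_YEAR:
        raise ScenarioError(f"baseline anchor must be {BASELINE_YEAR}, got {base_year}")
    if ref_year >= base_year:
        raise ScenarioError(f"reference year {ref_year} must precede baseline {base_year}")
    rate = (base_cov - ref_cov) / (base_year - ref_year)
    return AnnualRate(intervention_id=intervention_id, rate=rate, reference_year=ref_year)


def _segment(
    intervention_id: str,
    unit_id: str,
    values_by_year: Mapping[int, float],
    spec: ScenarioSpec,
) -> CoverageTrajectory:
    anchors = tuple(sorted(values_by_year.items()))
    return build_trajectory(
        intervention_id,
        unit_id,
        anchors,
        year_start=spec.horizon_start,
        year_end=spec.horizon_end,
    )


def build_fixed(
    baseline2010: float,
    spec: ScenarioSpec,
    intervention_id: str = "",
    unit_id: str = "",
) -> CoverageTrajectory:
    """Constant coverage at the 2010 level over the whole horizon."""
    if not 0.0 <= baseline2010 <= 1.0:
        raise ScenarioError(f"baseline coverage {baseline2010} outside [0,1]")
    values = {y: baseline2010 for y in range(spec.horizon_start, spec.horizon_end + 1)}
    return _segment(intervention_id, unit_id, values, spec)


def _continuation(baseline: float, rate: float, spec: ScenarioSpec) -> dict[int, float]:
    # Linear continuation at `rate`, stopped at max(cap, baseline), floored at 0.
    ceiling = max(spec.cap, baseline)
    return {
        y: min(max(baseline + rate * (y - spec.horizon_start), 0.0), ceiling)
        for y in range(spec.horizon_start, spec.horizon_end + 1)
    }


def build_scale_up(
    baseline2010: float,
    target: float,
    prior_rate: AnnualRate | None,
    spec: ScenarioSpec,
    unit_id: str = "",
) -> CoverageTrajectory:
    """Scale-up trajectory for one program intervention.

    Below target: a straight line from the 2010 baseline to exactly the
    target in 2013. At or above target: coverage keeps growing at the
    pre-2010 annual rate (floored at zero so pre-achieved coverage never
    declines), under the same max(cap, baseline) ceiling as the secular
    scenario.
    """
    if not 0.0 <= baseline2010 <= 1.0:
        raise ScenarioError(f"baseline coverage {baseline2010} outside [0,1]")
    if not 0.0 <= target <= 1.0:
        raise ScenarioError(f"target {target} outside [0,1]")
    iid = prior_rate.intervention_id if prior_rate is not None else ""
    if baseline2010 < target:
        span = spec.horizon_end - spec.horizon_start
        values = {
            y: baseline2010 + (target - baseline2010) * (y - spec.horizon_start) / span
            for y in range(spec.horizon_start, spec.horizon_end + 1)
        }
        values[spec.horizon_end] = target  # exact, no float drift
    else:
        rate = max(prior_rate.rate, 0.0) if prior_rate is not None else 0.0
        values = _continuation(baseline2010, rate, spec)
    return _segment(iid, unit_id, values, spec)


def build_secular(
    baseline2010: float,
    rate: AnnualRate,
    spec: ScenarioSpec,
    unit_id: str = "",
) -> CoverageTrajectory:
    """Secular-trend trajectory: pre-2010 rate continued, capped.

    c(t) = clamp(c2010 + rate * (t - 2010), 0, max(cap, c2010)).
    Negative rates are allowed and floor at zero coverage.
    """
    if not 0.0 <= baseline2010 <= 1.0:
        raise ScenarioError(f"baseline coverage {baseline2010} outside [0,1]")
    values = _continuation(baseline2010, rate.rate, spec)
    return _segment(rate.intervention_id, unit_id, values, spec)


def substitute_rate(
    rates: Mapping[str, AnnualRate], spec: ScenarioSpec
) -> dict[str, AnnualRate]:
    """Replace each substituted intervention's rate with its donor's rate.

    Idempotent; interventions outside the substitution map pass through
    unchanged. The shipped configuration contains exactly one entry,
    ACT <- oral antibiotics.
    """
    out: dict[str, AnnualRate] = dict(rates)
    for iid, donor in spec.rate_substitutions.items():
        if donor not in rates:
            raise ScenarioError(f"rate substitution for {iid!r} names missing donor {donor!r}")
        donated = rates[donor]
        out[iid] = AnnualRate(
            intervention_id=iid,
            rate=donated.rate,
            reference_year=donated.reference_year,
        )
    return out


def enumerate_projections(
    units: Sequence[str], scenarios: Sequence[ScenarioSpec]
) -> list[tuple[str, ScenarioSpec]]:
    """Cartesian product of units and scenarios, in deterministic order.

    Units keep their input order; scenarios run fixed, scale_up,
    secular_trend. The study's 14 units (9 districts, 2 regions, 2
    intervention-group strata, all districts pooled) times 3 scenarios give
    the 42 projections of the full analysis.
    """
    if not units:
        raise ScenarioError("no units to project")
    if not scenarios:
        raise ScenarioError("no scenarios to project")
    order = {k: i for i, k in enumerate(SCENARIO_ORDER)}
    ordered = sorted(scenarios, key=lambda s: order[s.kind])
    return [(u, s) for u in units for s in ordered]
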