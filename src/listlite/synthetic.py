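"""Synthetic study generator with known ground truth.

Generates complete studies — units, survey anchors, targets, effectiveness
tables, cause structures — shaped like the real evaluation design: a set of
districts in a small number of regions, two intervention-group strata and
an all-districts pool, each with three survey anchors (2003 DHS-like, 2006
MICS-like, 2010 baseline-like) per intervention.

For every unit the generator draws a 2010 baseline coverage and a pre-2010
secular rate, back-computes the 2003/2006 anchors from them, and (with a
configurable probability) inverts an anchor above the 2010 value so the
flat-trend conflict rule is routinely exercised. Ground-truth percent
reductions for all three scenarios are computed here with self-contained
closed-form arithmetic — deliberately not by calling the scenario or
impact modules — so a pipeline run over the generated files is a genuine
two-route consistency check.

Sample sizes and survey noise are not simulated: like the analysis it
emulates, the pipeline consumes point estimates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .coverage import Source, Stratum, SurveyEstimate
from .impact import CORE_CAUSES, CauseStructure, EffectivenessEntry
from .study import (
    Study,
    write_causes_csv,
    write_effectiveness_csv,
    write_surveys_csv,
    write_targets_csv,
)

_MICS_YEAR = 2006
_DHS_YEAR = 2003
_BASE_YEAR = 2010
_END_YEAR = 2013

#: Default cause structure: the high-burden setting the generator emulates.
DEFAULT_CAUSE_FRACTIONS = {
    "malaria": 0.24,
    "pneumonia": 0.18,
    "diarrhea": 0.12,
    "neonatal": 0.22,
    "other": 0.24,
}

DEFAULT_INTERVENTIONS = tuple(f"intervention_{i:02d}" for i in range(1, 9))


class SyntheticStudySpec(BaseModel):
    """Parameters of a generated study.

    Defaults mirror the emulated evaluation: 9 program districts in 2
    regions, plus two pooled intervention-group strata and an all-districts
    unit (14 units in total), three survey anchors per unit, modest
    positive secular trends, and a 20% chance per (unit, intervention) of
    an apparent pre-2010 decline that triggers the flat-trend rule.
    """

    model_config = ConfigDict(frozen=True)

    n_districts: int = Field(9, ge=1)
    n_regions: int = Field(2, ge=1)
    include_pooled_units: bool = True
    interventions: tuple[str, ...] = DEFAULT_INTERVENTIONS
    baseline_coverage_range: tuple[float, float] = (0.10, 0.60)
    secular_rate_range: tuple[float, float] = (0.0, 0.05)
    target_range: tuple[float, float] = (0.50, 0.90)
    conflict_probability: float = Field(0.2, ge=0.0, le=1.0)
    cap: float = Field(0.90, gt=0.0, le=1.0)
    rate_substitutions: Mapping[str, str] = Field(default_factory=dict)
    cause_fractions: Mapping[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_CAUSE_FRACTIONS)
    )
    true_effectiveness: tuple[EffectivenessEntry, ...] = ()
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticStudySpec":
        for name in ("baseline_coverage_range", "target_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} {lo, hi} is not a valid sub-interval of [0,1]")
        lo, hi = self.secular_rate_range
        if lo > hi:
            raise ValueError("secular_rate_range is inverted")
        if not self.interventions:
            raise ValueError("need at least one intervention")
        return self

    def unit_ids(self) -> tuple[str, ...]:
        units = [f"district_{i:02d}" for i in range(1, self.n_districts + 1)]
        if self.include_pooled_units:
            units = (
                ["all"]
                + [f"region_{j}" for j in range(1, self.n_regions + 1)]
                + units
                + ["stratum_with_ccm", "stratum_without_ccm"]
            )
        return tuple(units)


class SyntheticStudy(BaseModel):
    """A generated study and its ground-truth percent reductions."""

    model_config = ConfigDict(frozen=True)

    spec: SyntheticStudySpec
    study: Study
    #: (unit_id, scenario) -> true percent reduction, computed closed-form.
    ground_truth: Mapping[tuple[str, str], float]

    def write(self, out_dir: Path | str) -> dict[str, Path]:
        """Write the same CSV dialects the pipeline reads."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "surveys": out / "coverage_surveys.csv",
            "targets": out / "targets.csv",
            "effectiveness": out / "effectiveness.csv",
            "causes": out / "cause_structure.csv",
        }
        write_surveys_csv(self.study.surveys, paths["surveys"])
        write_targets_csv(self.study.targets, paths["targets"])
        write_effectiveness_csv(self.study.effectiveness, paths["effectiveness"])
        write_causes_csv(self.study.cause_structure, paths["causes"])
        return paths


def _default_effectiveness(
    spec: SyntheticStudySpec, rng: np.random.Generator
) -> tuple[EffectivenessEntry, ...]:
    entries = []
    for i, iid in enumerate(spec.interventions):
        cause = CORE_CAUSES[i % len(CORE_CAUSES)]
        entries.append(
            EffectivenessEntry(
                intervention_id=iid,
                cause=cause,
                effectiveness=float(rng.uniform(0.3, 0.7)),
                affected_fraction=float(rng.uniform(0.5, 1.0)),
            )
        )
    return tuple(entries)


def _true_reduction(
    cause_fractions: Mapping[str, float],
    effectiveness: tuple[EffectivenessEntry, ...],
    baseline: Mapping[str, float],
    scenario: Mapping[str, float],
) -> float:
    # Closed-form residual arithmetic, self-contained on purpose (the
    # pipeline's impact module is the thing being checked against this).
    m_total = 0.0
    for cause, frac in cause_fractions.items():
        m_c = 1.0
        for e in effectiveness:
            if e.cause != cause or e.intervention_id not in baseline:
                continue
            p = e.effectiveness * e.affected_fraction
            m_c *= (1.0 - p * scenario[e.intervention_id]) / (
                1.0 - p * baseline[e.intervention_id]
            )
        m_total += frac * m_c
    return 100.0 * (1.0 - m_total)


def generate_study(spec: SyntheticStudySpec) -> SyntheticStudy:
    """Generate a full study with ground truth; bit-reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    effectiveness = spec.true_effectiveness or _default_effectiveness(spec, rng)
    cause_structure = CauseStructure(fractions=dict(spec.cause_fractions))
    targets = {
        iid: float(rng.uniform(*spec.target_range)) for iid in spec.interventions
    }
    units = spec.unit_ids()

    surveys: list[SurveyEstimate] = []
    ground_truth: dict[tuple[str, str], float] = {}
    horizon = _END_YEAR - _BASE_YEAR

    for unit in units:
        baseline_cov: dict[str, float] = {}
        eff_rate: dict[str, float] = {}
        for iid in spec.interventions:
            c2010 = float(rng.uniform(*spec.baseline_coverage_range))
            rate = float(rng.uniform(*spec.secular_rate_range))
            conflict = bool(rng.random() < spec.conflict_probability)
            if conflict:
                bump = float(rng.uniform(0.05, 0.20))
                a2006 = min(c2010 + bump, 1.0)
                a2003 = min(c2010 + bump, 1.0)
            else:
                a2006 = float(np.clip(c2010 - rate * (_BASE_YEAR - _MICS_YEAR), 0.0, 1.0))
                a2003 = float(np.clip(c2010 - rate * (_BASE_YEAR - _DHS_YEAR), 0.0, 1.0))
            for year, src, cov in (
                (_DHS_YEAR, Source.DHS2003, a2003),
                (_MICS_YEAR, Source.MICS2006, a2006),
                (_BASE_YEAR, Source.BASELINE2010, c2010),
            ):
                surveys.append(
                    SurveyEstimate(
                        unit_id=unit,
                        intervention_id=iid,
                        year=year,
                        source=src,
                        stratum=Stratum.RURAL,
                        coverage=cov,
                    )
                )
            baseline_cov[iid] = c2010
            # The MICS anchor is the preferred reference; an anchor at or
            # above the 2010 value is flattened by the conflict rule.
            if a2006 >= c2010:
                eff_rate[iid] = 0.0
            else:
                eff_rate[iid] = (c2010 - a2006) / (_BASE_YEAR - _MICS_YEAR)

        for iid, donor in spec.rate_substitutions.items():
            eff_rate[iid] = eff_rate[donor]

        fixed_cov = dict(baseline_cov)
        secular_cov = {
            iid: min(
                max(baseline_cov[iid] + eff_rate[iid] * horizon, 0.0),
                max(spec.cap, baseline_cov[iid]),
            )
            for iid in spec.interventions
        }
        scale_cov = {}
        for iid in spec.interventions:
            base, tgt = baseline_cov[iid], targets[iid]
            if base < tgt:
                scale_cov[iid] = tgt
            else:
                scale_cov[iid] = min(
                    max(base + max(eff_rate[iid], 0.0) * horizon, 0.0),
                    max(spec.cap, base),
                )

        for scen, cov in (
            ("fixed", fixed_cov),
            ("scale_up", scale_cov),
            ("secular_trend", secular_cov),
        ):
            ground_truth[(unit, scen)] = _true_reduction(
                spec.cause_fractions, effectiveness, baseline_cov, cov
            )

    study = Study(
        name=f"synthetic_seed{spec.seed}",
        units=units,
        interventions=spec.interventions,
        surveys=tuple(surveys),
        targets=targets,
        cap=spec.cap,
        rate_substitutions=dict(spec.rate_substitutions),
        effectiveness=effectiveness,
        cause_structure=cause_structure,
    )
    return SyntheticStudy(spec=spec, study=study, ground_truth=ground_truth)
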