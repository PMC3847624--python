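"""End-to-end orchestration: harmonize -> scenarios -> project -> decompose.

`run_study` executes the full analysis for a `Study` in memory;
`run_pipeline` wraps it with file I/O, a YAML run configuration and a JSON
run manifest. Outputs mirror the published result artifacts: a
scenario-comparison table (per unit: scale-up reduction, secular-trend
reduction, and their difference — the program-attributable reduction) and
an intervention table (baseline, target, gap, and per-intervention
mortality reductions for the pooled unit).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .coverage import (
    BASELINE_YEAR,
    CoverageTrajectory,
    harmonize_unit_intervention,
)
from .impact import (
    CauseStructure,
    DecompositionMode,
    EffectivenessEntry,
    ProjectionResult,
    attributable_reduction,
    decompose_by_intervention,
    percent_reduction,
)
from .scenarios import (
    SCENARIO_ORDER,
    AnnualRate,
    ScenarioKind,
    ScenarioSpec,
    annual_rate,
    build_fixed,
    build_scale_up,
    build_secular,
    enumerate_projections,
    substitute_rate,
)
from .study import (
    Study,
    read_causes_csv,
    read_effectiveness_csv,
    read_surveys_csv,
    read_targets_csv,
)

logger = logging.getLogger("listlite")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the unit/intervention."""


class RunConfig(BaseModel):
    """File-based run configuration (loaded from YAML).

    All referenced files must exist and parse before any computation
    starts.
    """

    model_config = ConfigDict(frozen=True)

    surveys: Path
    targets: Path
    effectiveness: Path
    causes: Path
    out_dir: Path = Path("out")
    units: tuple[str, ...] = ()
    cap_percent: float = Field(90.0, gt=0.0, le=100.0)
    rate_substitutions: Mapping[str, str] = Field(default_factory=dict)
    horizon: tuple[int, int] = (2010, 2013)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        scen = raw.pop("scenarios", {})
        raw.setdefault("cap_percent", scen.get("cap_percent", 90.0))
        raw.setdefault("rate_substitutions", scen.get("rate_substitutions", {}))
        raw.setdefault("horizon", tuple(scen.get("horizon", (2010, 2013))))
        return cls(**raw)


def load_study(config: RunConfig) -> Study:
    """Read and validate every input file; fail fast before computing."""
    for label in ("surveys", "targets", "effectiveness", "causes"):
        path = getattr(config, label)
        if not Path(path).is_file():
            raise PipelineError(f"{label} file not found: {path}")
    surveys = read_surveys_csv(config.surveys)
    units = config.units or tuple(
        dict.fromkeys(e.unit_id for e in surveys if e.year == BASELINE_YEAR)
    )
    interventions = tuple(dict.fromkeys(e.intervention_id for e in surveys))
    return Study(
        name="run",
        units=units,
        interventions=interventions,
        surveys=tuple(surveys),
        targets=read_targets_csv(config.targets),
        cap=config.cap_percent / 100.0,
        rate_substitutions=dict(config.rate_substitutions),
        effectiveness=read_effectiveness_csv(config.effectiveness),
        cause_structure=read_causes_csv(config.causes),
    )


def scenario_specs(study: Study) -> dict[ScenarioKind, ScenarioSpec]:
    common = dict(
        targets=dict(study.targets),
        cap=study.cap,
        rate_substitutions=dict(study.rate_substitutions),
    )
    return {kind: ScenarioSpec(kind=kind, **common) for kind in SCENARIO_ORDER}


def harmonize_unit(study: Study, unit: str) -> dict[str, CoverageTrajectory]:
    """Pre-2010 trajectories for every intervention in one unit."""
    out: dict[str, CoverageTrajectory] = {}
    for iid in study.interventions:
        try:
            out[iid] = harmonize_unit_intervention(iid, unit, study.surveys)
        except Exception as exc:
            raise PipelineError(f"harmonization failed for {iid!r} in {unit!r}: {exc}") from exc
    return out


def unit_rates(
    study: Study, trajectories: Mapping[str, CoverageTrajectory]
) -> dict[str, AnnualRate]:
    """Pre-2010 annual rates from resolved anchors, substitutions applied."""
    rates = {}
    for iid, traj in trajectories.items():
        first, last = traj.anchors[0], traj.anchors[-1]
        rates[iid] = annual_rate(iid, first, last)
    spec = ScenarioSpec(
        kind=ScenarioKind.SECULAR_TREND,
        cap=study.cap,
        rate_substitutions=dict(study.rate_substitutions),
    )
    substituted = substitute_rate(rates, spec)
    for iid in substituted:
        if substituted[iid].rate != rates[iid].rate:
            logger.info(
                "rate substitution applied: %s <- %s", iid, study.rate_substitutions[iid]
            )
    return substituted


def scenario_trajectories(
    study: Study,
    unit: str,
    baseline_cov: Mapping[str, float],
    rates: Mapping[str, AnnualRate],
    spec: ScenarioSpec,
) -> dict[str, CoverageTrajectory]:
    """2010-2013 trajectory per intervention under one scenario."""
    out: dict[str, CoverageTrajectory] = {}
    for iid in study.interventions:
        base = baseline_cov[iid]
        if spec.kind is ScenarioKind.FIXED:
            traj = build_fixed(base, spec, intervention_id=iid, unit_id=unit)
        elif spec.kind is ScenarioKind.SCALE_UP:
            if iid in spec.targets:
                traj = build_scale_up(base, spec.targets[iid], rates[iid], spec, unit_id=unit)
            else:
                # Non-program interventions stay at 2010 coverage.
                traj = build_fixed(base, spec, intervention_id=iid, unit_id=unit)
        else:
            traj = build_secular(base, rates[iid], spec, unit_id=unit)
        out[iid] = traj
    return out


def scenario_coverage_frame(study: Study) -> pd.DataFrame:
    """Annual scenario coverage for every unit, as the pipeline's CSV dialect."""
    specs = scenario_specs(study)
    rows = []
    for unit in study.units:
        trajs = harmonize_unit(study, unit)
        baseline_cov = {iid: t.at(BASELINE_YEAR) for iid, t in trajs.items()}
        rates = unit_rates(study, trajs)
        for kind, spec in specs.items():
            for iid, traj in scenario_trajectories(
                study, unit, baseline_cov, rates, spec
            ).items():
                for year, cov in sorted(traj.values.items()):
                    rows.append(
                        {
                            "unit_id": unit,
                            "scenario": kind.value,
                            "intervention_id": iid,
                            "year": year,
                            "coverage_percent": 100.0 * cov,
                        }
                    )
    return pd.DataFrame(rows)


def project_from_coverage(
    coverage: pd.DataFrame,
    effectiveness: Sequence[EffectivenessEntry],
    cause_structure: CauseStructure,
    mode: DecompositionMode | str = DecompositionMode.SIMULTANEOUS,
) -> pd.DataFrame:
    """Percent reductions from a scenario-coverage table.

    Every scenario shares its own 2010 row as the baseline, so the fixed
    scenario reduces mortality by exactly zero.
    """
    mode = DecompositionMode(mode)
    rows = []
    for (unit, scenario), grp in coverage.groupby(["unit_id", "scenario"], sort=False):
        by_year = {
            int(year): {
                str(r.intervention_id): float(r.coverage_percent) / 100.0
                for r in sub.itertuples()
            }
            for year, sub in grp.groupby("year")
        }
        base, scen = by_year[min(by_year)], by_year[max(by_year)]
        row = {
            "unit_id": unit,
            "scenario": scenario,
            "percent_reduction": percent_reduction(cause_structure, base, scen, effectiveness),
        }
        shares = decompose_by_intervention(cause_structure, base, scen, effectiveness, mode)
        row.update({f"r_{iid}": v for iid, v in sorted(shares.items())})
        rows.append(row)
    return pd.DataFrame(rows)


class StudyResult(BaseModel):
    """Everything `run_study` computes, ready for rendering or file output."""

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    projections: tuple[ProjectionResult, ...]
    scenario_coverage: pd.DataFrame  # unit_id, scenario, intervention_id, year, coverage_percent
    table2: pd.DataFrame  # unit x (scale_up, secular, difference)
    table3: pd.DataFrame  # intervention x (baseline, target, gap, isolation/simultaneous R)
    manifest: dict

    def projection(self, unit: str, scenario: str) -> ProjectionResult:
        for p in self.projections:
            if p.unit_id == unit and p.scenario == scenario:
                return p
        raise KeyError((unit, scenario))


def run_study(study: Study, pooled_unit: str | None = None) -> StudyResult:
    """Run all scenarios for all units of a study.

    ``pooled_unit`` names the unit whose per-intervention table is rendered
    (default: the first unit). Requires the study to carry an effectiveness
    table and a cause structure.
    """
    if study.cause_structure is None or not study.effectiveness:
        raise PipelineError("study lacks an effectiveness table or cause structure")
    if not study.units:
        raise PipelineError("study has no units")
    pooled_unit = pooled_unit or study.units[0]
    specs = scenario_specs(study)
    jobs = enumerate_projections(list(study.units), list(specs.values()))

    projections: list[ProjectionResult] = []
    cov_rows: list[dict] = []
    per_unit: dict[str, dict[str, float]] = {}
    unit_baselines: dict[str, dict[str, float]] = {}
    unit_scenario_2013: dict[tuple[str, str], dict[str, float]] = {}

    for unit in study.units:
        trajs = harmonize_unit(study, unit)
        baseline_cov = {iid: t.at(BASELINE_YEAR) for iid, t in trajs.items()}
        unit_baselines[unit] = baseline_cov
        rates = unit_rates(study, trajs)
        for kind, spec in specs.items():
            scen_trajs = scenario_trajectories(study, unit, baseline_cov, rates, spec)
            for iid, traj in scen_trajs.items():
                for year, cov in sorted(traj.values.items()):
                    cov_rows.append(
                        {
                            "unit_id": unit,
                            "scenario": kind.value,
                            "intervention_id": iid,
                            "year": year,
                            "coverage_percent": 100.0 * cov,
                        }
                    )
            scenario_cov = {iid: t.at(spec.horizon_end) for iid, t in scen_trajs.items()}
            unit_scenario_2013[(unit, kind.value)] = scenario_cov
            r = percent_reduction(
                study.cause_structure, baseline_cov, scenario_cov, study.effectiveness
            )
            shares = decompose_by_intervention(
                study.cause_structure,
                baseline_cov,
                scenario_cov,
                study.effectiveness,
                mode=DecompositionMode.SIMULTANEOUS,
            )
            projections.append(
                ProjectionResult(
                    unit_id=unit,
                    scenario=kind.value,
                    mortality_multiplier=1.0 - r / 100.0,
                    percent_reduction=r,
                    per_intervention=shares,
                )
            )
            per_unit.setdefault(unit, {})[kind.value] = r

    table2 = pd.DataFrame(
        [
            {
                "unit_id": unit,
                "scale_up_percent_reduction": rs[ScenarioKind.SCALE_UP.value],
                "secular_percent_reduction": rs[ScenarioKind.SECULAR_TREND.value],
                "difference": attributable_reduction(
                    rs[ScenarioKind.SCALE_UP.value], rs[ScenarioKind.SECULAR_TREND.value]
                ),
            }
            for unit, rs in per_unit.items()
        ]
    )

    pooled_base = unit_baselines[pooled_unit]
    pooled_scale = unit_scenario_2013[(pooled_unit, ScenarioKind.SCALE_UP.value)]
    isolation = decompose_by_intervention(
        study.cause_structure,
        pooled_base,
        pooled_scale,
        study.effectiveness,
        mode=DecompositionMode.ISOLATION,
    )
    simultaneous = next(
        p for p in projections
        if p.unit_id == pooled_unit and p.scenario == ScenarioKind.SCALE_UP.value
    ).per_intervention
    table3 = pd.DataFrame(
        [
            {
                "intervention_id": iid,
                "baseline_percent": 100.0 * pooled_base[iid],
                "target_percent": 100.0 * study.targets[iid]
                if iid in study.targets
                else float("nan"),
                "scenario_2013_percent": 100.0 * pooled_scale[iid],
                "gap_percent": 100.0 * (pooled_scale[iid] - pooled_base[iid]),
                "isolation_percent_reduction": isolation[iid],
                "simultaneous_percent_reduction": simultaneous[iid],
            }
            for iid in study.interventions
        ]
    )

    manifest = {
        "study": study.name,
        "version": __version__,
        "n_units": len(study.units),
        "n_scenarios": len(specs),
        "n_projections": len(jobs),
        "config_hash": hashlib.sha256(
            study.model_dump_json(exclude={"surveys"}).encode()
        ).hexdigest()[:16],
    }
    return StudyResult(
        projections=tuple(projections),
        scenario_coverage=pd.DataFrame(cov_rows),
        table2=table2,
        table3=table3,
        manifest=manifest,
    )


def write_outputs(result: StudyResult, out_dir: Path | str) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "scenario_coverage": out / "scenario_coverage.csv",
        "projection_results": out / "projection_results.csv",
        "attribution": out / "attribution.csv",
        "table2_like": out / "table2_like.csv",
        "table3_like": out / "table3_like.csv",
        "manifest": out / "manifest.json",
    }
    result.scenario_coverage.to_csv(paths["scenario_coverage"], index=False)

    proj_rows = []
    for p in result.projections:
        row = {
            "unit_id": p.unit_id,
            "scenario": p.scenario,
            "percent_reduction": p.percent_reduction,
        }
        row.update({f"r_{iid}": v for iid, v in sorted(p.per_intervention.items())})
        proj_rows.append(row)
    pd.DataFrame(proj_rows).to_csv(paths["projection_results"], index=False)
    result.table2.rename(columns={"difference": "attributable_percent_reduction"}).to_csv(
        paths["attribution"], index=False
    )
    result.table2.to_csv(paths["table2_like"], index=False)
    result.table3.to_csv(paths["table3_like"], index=False)
    paths["manifest"].write_text(json.dumps(result.manifest, indent=2, sort_keys=True) + "\n")
    return paths


def run_pipeline(config: RunConfig) -> StudyResult:
    """Load inputs per the config, run the study, write the report bundle."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    study = load_study(config)
    result = run_study(study)
    write_outputs(result, config.out_dir)
    return result


def sensitivity_all_to_cap(
    study: Study,
    cap: float = 0.90,
    exempt: Sequence[str] = ("vitamin_a",),
    pooled_unit: str | None = None,
) -> dict[str, float]:
    """Scale-up sensitivity: every program target raised to ``cap``.

    Interventions in ``exempt`` (vitamin A, whose original target already
    equals the cap) keep their original targets. Returns the joint
    percent reduction under the original targets and under the raised
    targets for the pooled unit.
    """
    if not 0.0 < cap <= 1.0:
        raise PipelineError(f"cap {cap} outside (0, 1]")
    pooled_unit = pooled_unit or study.units[0]
    original = run_study(study, pooled_unit=pooled_unit)
    raised = {
        iid: (t if iid in exempt else cap) for iid, t in study.targets.items()
    }
    raised_study = study.model_copy(update={"targets": raised})
    sens = run_study(raised_study, pooled_unit=pooled_unit)
    kind = ScenarioKind.SCALE_UP.value
    return {
        "original_percent_reduction": original.projection(pooled_unit, kind).percent_reduction,
        "sensitivity_percent_reduction": sens.projection(pooled_unit, kind).percent_reduction,
        "cap_percent": 100.0 * cap,
    }
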