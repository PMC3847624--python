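"""Study container and plain-CSV I/O.

A *study* bundles everything one projection run needs: the ordered unit
list (districts, regions, pooled strata, all-districts), the survey point
estimates, the 2013 targets for program interventions, the effectiveness
table and the cause-of-death structure. All tabular files are UTF-8 CSV
with headers; coverage and cause fractions are percent (0-100) on disk and
fractions in memory.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .coverage import Source, Stratum, SurveyEstimate
from .impact import CauseStructure, EffectivenessEntry

SURVEY_COLUMNS = ["unit_id", "intervention_id", "year", "source", "stratum", "coverage_percent"]


class Study(BaseModel):
    """All inputs for one end-to-end projection run."""

    model_config = ConfigDict(frozen=True)

    name: str
    units: tuple[str, ...]
    interventions: tuple[str, ...]
    surveys: tuple[SurveyEstimate, ...]
    targets: Mapping[str, float]  # program interventions -> 2013 target fraction
    cap: float = 0.90
    rate_substitutions: Mapping[str, str] = Field(default_factory=dict)
    effectiveness: tuple[EffectivenessEntry, ...] = ()
    cause_structure: CauseStructure | None = None


def surveys_to_frame(surveys: Sequence[SurveyEstimate]) -> pd.DataFrame:
    rows = [
        {
            "unit_id": e.unit_id,
            "intervention_id": e.intervention_id,
            "year": e.year,
            "source": e.source.value,
            "stratum": e.stratum.value,
            "coverage_percent": 100.0 * e.coverage,
        }
        for e in surveys
    ]
    return pd.DataFrame(rows, columns=SURVEY_COLUMNS)


def write_surveys_csv(surveys: Sequence[SurveyEstimate], path: Path | str) -> None:
    surveys_to_frame(surveys).to_csv(path, index=False)


def read_surveys_csv(path: Path | str) -> list[SurveyEstimate]:
    df = pd.read_csv(path)
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"surveys file {path} missing columns {sorted(missing)}")
    return [
        SurveyEstimate(
            unit_id=str(r.unit_id),
            intervention_id=str(r.intervention_id),
            year=int(r.year),
            source=Source(r.source),
            stratum=Stratum(r.stratum),
            coverage=float(r.coverage_percent) / 100.0,
        )
        for r in df.itertuples()
    ]


def read_effectiveness_csv(path: Path | str) -> list[EffectivenessEntry]:
    df = pd.read_csv(path)
    return [
        EffectivenessEntry(
            intervention_id=str(r.intervention_id),
            cause=str(r.cause),
            effectiveness=float(r.effectiveness),
            affected_fraction=float(r.affected_fraction),
        )
        for r in df.itertuples()
    ]


def write_effectiveness_csv(entries: Sequence[EffectivenessEntry], path: Path | str) -> None:
    pd.DataFrame(
        [
            {
                "intervention_id": e.intervention_id,
                "cause": e.cause,
                "effectiveness": e.effectiveness,
                "affected_fraction": e.affected_fraction,
            }
            for e in entries
        ]
    ).to_csv(path, index=False)


def read_causes_csv(path: Path | str) -> CauseStructure:
    df = pd.read_csv(path)
    fractions = {str(r.cause): float(r.fraction_percent) / 100.0 for r in df.itertuples()}
    return CauseStructure(fractions=fractions)


def write_causes_csv(structure: CauseStructure, path: Path | str) -> None:
    pd.DataFrame(
        [{"cause": c, "fraction_percent": 100.0 * f} for c, f in structure.fractions.items()]
    ).to_csv(path, index=False)


def read_targets_csv(path: Path | str) -> dict[str, float]:
    """Targets file: intervention_id, target_percent, program (0/1).

    Only program interventions (program=1) carry targets into the scale-up
    scenario; non-program rows are tolerated and ignored.
    """
    df = pd.read_csv(path)
    out: dict[str, float] = {}
    for r in df.itertuples():
        program = bool(int(getattr(r, "program", 1)))
        if program:
            out[str(r.intervention_id)] = float(r.target_percent) / 100.0
    return out


def write_targets_csv(targets: Mapping[str, float], path: Path | str) -> None:
    pd.DataFrame(
        [
            {"intervention_id": iid, "target_percent": 100.0 * t, "program": 1}
            for iid, t in targets.items()
        ]
    ).to_csv(path, index=False)
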