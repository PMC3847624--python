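"""Bundled Burkina Faso 2010-2013 study fixture.

Transcribes the published pooled baselines, 2013 targets, and the
cause-of-death structure (malaria 24%, pneumonia 18%, diarrhea 12%,
neonatal 22%, residual 24%) into a ready-to-run 14-unit study: nine
program districts in two regions, the two regions pooled, two
intervention-group strata (community case management of pneumonia present
or absent), and all districts together.

Three parts of the fixture are synthetic, because the underlying numbers
were never published at desk scale:

* the 2003/2006 national-rural anchor values (constructed to give mild
  positive pre-2010 trends, plus one deliberate apparent decline for
  vitamin A that exercises the flat-trend conflict rule);
* the ANC4+ and skilled-birth-attendance pooled baselines;
* per-district variation around the pooled baselines (deterministic
  draws from a fixed internal seed).

The effectiveness table is likewise a synthetic, literature-magnitude
approximation — NOT the CHERG-derived database the reference software
carries — so mortality results on this fixture reproduce the published
analysis structurally (signs, rankings), not numerically.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from ..coverage import Source, Stratum, SurveyEstimate
from ..impact import CauseStructure, EffectivenessEntry
from ..study import Study

POOLED_UNIT = "all"

#: 9 program districts by region, then pooled pseudo-units.
CENTER_NORTH = ("barsalogho", "boulsa", "kaya", "kongoussi")
NORTH = ("gourcy", "ouahigouya", "seguenega", "yako", "titao")
REGIONS = ("center_north", "north")
STRATA = ("pmnch_with_ccm", "pmnch_without_ccm")
UNITS: tuple[str, ...] = (POOLED_UNIT,) + REGIONS + CENTER_NORTH + NORTH + STRATA

#: Rate donor for ACT: chloroquine phase-out made pre-2010 ACT trends
#: uninformative, so the oral-antibiotics rate is borrowed.
RATE_SUBSTITUTIONS = {"act_malaria": "antibiotics_pneumonia"}

_JITTER_SEED = 20100531  # fixed: the fixture is deterministic by construction
_JITTER_SD = 0.06


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def burkina_targets() -> dict[str, float]:
    df = _read("burkina_targets.csv")
    return {str(r.intervention_id): float(r.target_percent) / 100.0 for r in df.itertuples()}


def burkina_causes() -> CauseStructure:
    df = _read("burkina_causes.csv")
    return CauseStructure(
        fractions={str(r.cause): float(r.fraction_percent) / 100.0 for r in df.itertuples()}
    )


def burkina_effectiveness() -> tuple[EffectivenessEntry, ...]:
    df = _read("effectiveness_synthetic.csv")
    return tuple(
        EffectivenessEntry(
            intervention_id=str(r.intervention_id),
            cause=str(r.cause),
            effectiveness=float(r.effectiveness),
            affected_fraction=float(r.affected_fraction),
        )
        for r in df.itertuples()
    )


def burkina_fixture() -> Study:
    """The packaged 14-unit study, ready for the full pipeline.

    The pooled ``all`` unit carries the published baselines exactly;
    district, region and stratum units get deterministic synthetic
    variation around them.
    """
    base = _read("burkina_baseline.csv")
    interventions = tuple(str(i) for i in base.intervention_id)
    surveys: list[SurveyEstimate] = []

    # National rural pre-2010 anchors, shared by all units via fallback.
    for r in base.itertuples():
        iid = str(r.intervention_id)
        surveys.append(
            SurveyEstimate(
                unit_id=POOLED_UNIT,
                intervention_id=iid,
                year=2003,
                source=Source.DHS2003,
                stratum=Stratum.RURAL,
                coverage=float(r.dhs_2003_percent) / 100.0,
            )
        )
        surveys.append(
            SurveyEstimate(
                unit_id=POOLED_UNIT,
                intervention_id=iid,
                year=2006,
                source=Source.MICS2006,
                stratum=Stratum.RURAL,
                coverage=float(r.mics_2006_percent) / 100.0,
            )
        )

    rng = np.random.default_rng(_JITTER_SEED)
    for unit in UNITS:
        for r in base.itertuples():
            iid = str(r.intervention_id)
            pooled = float(r.baseline_2010_percent) / 100.0
            if unit == POOLED_UNIT:
                cov = pooled
            else:
                cov = float(np.clip(pooled + rng.normal(0.0, _JITTER_SD), 0.01, 0.95))
            surveys.append(
                SurveyEstimate(
                    unit_id=unit,
                    intervention_id=iid,
                    year=2010,
                    source=Source.BASELINE2010,
                    stratum=Stratum.RURAL,
                    coverage=cov,
                )
            )

    return Study(
        name="burkina_2010_2013",
        units=UNITS,
        interventions=interventions,
        surveys=tuple(surveys),
        targets=burkina_targets(),
        cap=0.90,
        rate_substitutions=dict(RATE_SUBSTITUTIONS),
        effectiveness=burkina_effectiveness(),
        cause_structure=burkina_causes(),
    )
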