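"""Cause-structured residual engine for under-five mortality impact.

The model follows the standard Lives-Saved-Tool convention. Under-five
deaths are partitioned by cause (malaria, pneumonia, diarrhea, neonatal,
and a residual "other"). Each intervention i acting on cause c has a
potency p_ic = effectiveness * affected_fraction: the share of that cause's
deaths it averts among children it reaches. At coverage C_i the cause's
mortality is multiplied by the residual factor (1 - p_ic * C_i);
interventions on the same cause act independently, so residual factors
multiply. Moving coverage from a baseline to a scenario therefore scales
cause-c mortality by

    M_c = prod_i (1 - p_ic * C_i_scenario) / (1 - p_ic * C_i_baseline)

and total mortality by M = sum_c f_c * M_c, where f_c is the cause-of-death
fraction. The headline quantity is the percent reduction

    R = 100 * (1 - M),

which is exactly 0 when scenario coverage equals baseline coverage, and can
be negative when coverage declines.

A seeded microsimulation (`microsim_oracle`) embodies the same independent-
action assumptions child by child and provides an independent Monte Carlo
check on the closed-form engine.
"""

from __future__ import annotations

import enum
import math
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

CORE_CAUSES = ("malaria", "pneumonia", "diarrhea", "neonatal")
RESIDUAL_CAUSE = "other"

#: Under-five mortality rate anchor (deaths per 1,000 live births); used only
#: to express absolute deaths averted, never in percent reductions.
DEFAULT_U5MR_2010 = 184.0


class ImpactError(ValueError):
    """Engine inputs violate the model's preconditions."""


class CauseStructure(BaseModel):
    """Cause-of-death fractions for under-five mortality; must sum to 1.

    An explicit residual cause absorbs whatever the named causes leave.
    """

    model_config = ConfigDict(frozen=True)

    fractions: Mapping[str, float]

    @model_validator(mode="after")
    def _check(self) -> "CauseStructure":
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("cause fractions must be non-negative")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cause fractions sum to {total!r}, not 1")
        return self

    @classmethod
    def with_residual(cls, named: Mapping[str, float]) -> "CauseStructure":
        """Close the structure with an ``other`` residual."""
        total = sum(named.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"named cause fractions sum to {total} > 1")
        fractions = dict(named)
        fractions[RESIDUAL_CAUSE] = max(0.0, 1.0 - total)
        return cls(fractions=fractions)


class EffectivenessEntry(BaseModel):
    """(intervention, cause) potency: effectiveness x affected fraction."""

    model_config = ConfigDict(frozen=True)

    intervention_id: str
    cause: str
    effectiveness: float = Field(ge=0.0, le=1.0)
    affected_fraction: float = Field(ge=0.0, le=1.0)

    @property
    def potency(self) -> float:
        return self.effectiveness * self.affected_fraction


class DecompositionMode(str, enum.Enum):
    ISOLATION = "isolation"
    SIMULTANEOUS = "simultaneous"


class ProjectionResult(BaseModel):
    """Mortality outcome of one (unit, scenario) projection."""

    model_config = ConfigDict(frozen=True)

    unit_id: str
    scenario: str
    mortality_multiplier: float = Field(gt=0.0)
    percent_reduction: float
    per_intervention: Mapping[str, float] = Field(default_factory=dict)
    u5mr_2010: float | None = None

    @model_validator(mode="after")
    def _consistent(self) -> "ProjectionResult":
        if abs(self.percent_reduction - 100.0 * (1.0 - self.mortality_multiplier)) > 1e-9:
            raise ValueError("percent_reduction inconsistent with mortality_multiplier")
        return self


def _entries_on_cause(
    effectiveness: Sequence[EffectivenessEntry], cause: str
) -> list[EffectivenessEntry]:
    return [e for e in effectiveness if e.cause == cause]


def _residual(entry: EffectivenessEntry, coverage: float) -> float:
    return 1.0 - entry.potency * coverage


def cause_multiplier(
    cause: str,
    baseline_cov: Mapping[str, float],
    scenario_cov: Mapping[str, float],
    effectiveness: Sequence[EffectivenessEntry],
) -> float:
    """Ratio of scenario to baseline mortality for one cause.

    Empty product (no intervention acts on the cause) is 1. Baseline
    coverage so high that an intervention's residual factor vanishes is a
    saturation error: the ratio is undefined there.
    """
    m = 1.0
    for entry in _entries_on_cause(effectiveness, cause):
        iid = entry.intervention_id
        if iid not in baseline_cov:
            continue
        base = _residual(entry, baseline_cov[iid])
        scen = _residual(entry, scenario_cov.get(iid, baseline_cov[iid]))
        if base <= 0.0:
            raise ImpactError(
                f"baseline saturation: {iid!r} on {cause!r} has residual {base} <= 0"
            )
        m *= scen / base
    return m


def mortality_multiplier(
    cause_structure: CauseStructure,
    baseline_cov: Mapping[str, float],
    scenario_cov: Mapping[str, float],
    effectiveness: Sequence[EffectivenessEntry],
) -> float:
    return sum(
        frac * cause_multiplier(cause, baseline_cov, scenario_cov, effectiveness)
        for cause, frac in cause_structure.fractions.items()
    )


def percent_reduction(
    cause_structure: CauseStructure,
    baseline_cov: Mapping[str, float],
    scenario_cov: Mapping[str, float],
    effectiveness: Sequence[EffectivenessEntry],
) -> float:
    """Percent reduction in under-five mortality, scenario vs baseline."""
    return 100.0 * (
        1.0 - mortality_multiplier(cause_structure, baseline_cov, scenario_cov, effectiveness)
    )


def attributable_reduction(scale_up_r: float, secular_r: float) -> float:
    """Program-attributable reduction: scale-up R minus secular-trend R.

    In percentage points; negative when secular trends alone outperform the
    program targets.
    """
    return scale_up_r - secular_r


def decompose_by_intervention(
    cause_structure: CauseStructure,
    baseline_cov: Mapping[str, float],
    scenario_cov: Mapping[str, float],
    effectiveness: Sequence[EffectivenessEntry],
    mode: DecompositionMode | str = DecompositionMode.SIMULTANEOUS,
) -> dict[str, float]:
    """Per-intervention contributions to the joint percent reduction.

    *isolation*: each intervention moves to its scenario coverage alone,
    all others pinned at baseline; contributions need not sum to the joint
    reduction (interventions on a shared cause compete for the same deaths).

    *simultaneous*: each cause's log-multiplier — exactly additive over
    interventions — is shared out proportionally to each intervention's own
    log-multiplier on that cause, and the cause's contribution to the joint
    reduction is split by those shares. Shares sum to the joint R exactly.
    """
    mode = DecompositionMode(mode)
    interventions = sorted(baseline_cov)
    if mode is DecompositionMode.ISOLATION:
        out: dict[str, float] = {}
        for iid in interventions:
            solo = dict(baseline_cov)
            solo[iid] = scenario_cov.get(iid, baseline_cov[iid])
            out[iid] = percent_reduction(cause_structure, baseline_cov, solo, effectiveness)
        return out

    shares = {iid: 0.0 for iid in interventions}
    for cause, frac in cause_structure.fractions.items():
        logs: dict[str, float] = {}
        for entry in _entries_on_cause(effectiveness, cause):
            iid = entry.intervention_id
            if iid not in baseline_cov:
                continue
            base = _residual(entry, baseline_cov[iid])
            scen = _residual(entry, scenario_cov.get(iid, baseline_cov[iid]))
            if base <= 0.0:
                raise ImpactError(
                    f"baseline saturation: {iid!r} on {cause!r} has residual {base} <= 0"
                )
            logs[iid] = logs.get(iid, 0.0) + math.log(scen / base)
        total_log = sum(logs.values())
        if total_log == 0.0:
            continue
        cause_deficit = 100.0 * frac * (1.0 - math.exp(total_log))
        for iid, l in logs.items():
            shares[iid] += cause_deficit * (l / total_log)
    return shares


def microsim_oracle(
    cause_structure: CauseStructure,
    baseline_cov: Mapping[str, float],
    scenario_cov: Mapping[str, float],
    effectiveness: Sequence[EffectivenessEntry],
    n_children: int,
    seed: int,
) -> tuple[float, float]:
    """Monte Carlo estimate of the percent reduction, with its standard error.

    Simulates ``n_children`` potential under-five death events per arm,
    allocated to causes by the cause-of-death fractions (a multinomial
    draw). Within a cause, each intervention acting on it is received
    independently with probability equal to its coverage, and each received
    intervention independently averts the death with probability
    effectiveness x affected_fraction; the child dies only if no received
    intervention averts the event. The cause fractions describe baseline
    deaths, so the arms are compared cause by cause — the estimate is
    100 * (1 - sum_c f_c * ratio_c) with ratio_c the simulated
    scenario/baseline death ratio for cause c — and converges to the
    closed-form R as n grows. Identical seeds give bit-identical output.
    """
    if n_children < 1:
        raise ImpactError("n_children must be >= 1")
    rng = np.random.default_rng(seed)
    causes = sorted(cause_structure.fractions)
    probs = np.array([cause_structure.fractions[c] for c in causes])
    counts = rng.multinomial(n_children, probs)

    def _death_rate(cause: str, cov: Mapping[str, float], n_c: int) -> float:
        averted = np.zeros(n_c, dtype=bool)
        for entry in _entries_on_cause(effectiveness, cause):
            iid = entry.intervention_id
            if iid not in cov and iid not in baseline_cov:
                continue
            c_i = cov.get(iid, baseline_cov[iid])
            received = rng.random(n_c) < c_i
            averts = rng.random(n_c) < entry.potency
            averted |= received & averts
        return float((~averted).mean())

    multiplier = 0.0
    variance = 0.0
    for ci, cause in enumerate(causes):
        f_c = float(probs[ci])
        n_c = int(counts[ci])
        active = [
            e
            for e in _entries_on_cause(effectiveness, cause)
            if e.intervention_id in baseline_cov or e.intervention_id in scenario_cov
        ]
        if not active or n_c == 0 or f_c == 0.0:
            # Untouched cause: every simulated event is a death in both
            # arms, so the ratio is exactly 1 with zero Monte Carlo error.
            multiplier += f_c
            continue
        p_base = _death_rate(cause, baseline_cov, n_c)
        p_scen = _death_rate(cause, scenario_cov, n_c)
        # Floor at one pseudo-event so the ratio and its delta-method SE
        # stay finite on small samples.
        pb = max(p_base, 1.0 / n_c)
        ps = max(p_scen, 1.0 / n_c)
        multiplier += f_c * (p_scen / pb)
        variance += (f_c * ps / pb) ** 2 * (
            (1.0 - ps) / (n_c * ps) + (1.0 - pb) / (n_c * pb)
        )

    r_hat = 100.0 * (1.0 - multiplier)
    se = 100.0 * math.sqrt(max(variance, 0.0))
    return r_hat, se
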