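"""The seven relevance rules.

Each rule is a predicate over one pathway that emits *verdicts*: sub-intervals
of stages judged level 0 (should not be hospitalized) or level 1 (wrong
unit).  Absence of verdicts means level 2.  Rules only flag problems; the
labeler merges verdicts into a phase tiling and the corrector consumes the
optional ``correction_target``.

The ED stage is the entry point of every unscheduled pathway, so it is exempt
from the destination-ward rules (4-7); rule 1 is the only rule that judges
the ED stay itself.

Rules 1 and 2 could not be validated by the expert panel (no consensus on the
ideal ED stay or ideal length of stay), hence the shipped ``validated``
profile enables rules 3-7 only and the ``full`` profile all seven.  Rules 2
and 7 are reconstructions from the main-text pattern descriptions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Callable, Optional

from .io import (
    BUFFER_CATEGORIES,
    SPECIALIZED_CATEGORIES,
    RuleConfig,
    UnitCategory,
    UnitRegistry,
)
from .model import PatientPathway, RelevanceLevel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RuleVerdict:
    """A phase-level relevance finding of one rule on one stage."""

    case_id: str
    stage_index: int
    from_ts: datetime
    to_ts: datetime
    level: int  # 0 or 1; level 2 is the absence of verdicts
    rule_id: int
    correction_target: Optional[str] = None

    def __post_init__(self):
        if self.level not in (0, 1):
            raise ValueError("verdicts only carry level 0 or 1")
        if not self.from_ts < self.to_ts:
            raise ValueError("verdict interval must have positive length")


def _is_ed(pathway: PatientPathway, idx: int, registry: Optional[UnitRegistry]) -> bool:
    stage = pathway.trace.stages[idx]
    if registry is not None and stage.activity in registry:
        return registry.category(stage.activity) == UnitCategory.ED
    return idx == 0  # by the framework invariant the trace begins at the ED


def rule1_ed_boarding(
    pathway: PatientPathway, config: RuleConfig
) -> list[RuleVerdict]:
    """Rule 1 — the ED stay is too long (boarding).

    Strict threshold: an ED stage of exactly ``ed_los_max`` is compliant.
    The verdict covers the excess interval only; no correction target is
    attached — the corrector resolves the excess to the first relevant
    destination ward, which is robust when the following stage is itself
    flagged by another rule.
    """
    stages = pathway.trace.stages
    if not stages:
        return []
    ed = stages[0]
    if ed.duration <= config.ed_los_max:
        return []
    return [
        RuleVerdict(
            case_id=pathway.case_id,
            stage_index=0,
            from_ts=ed.start_ts + config.ed_los_max,
            to_ts=ed.end_ts,
            level=1,
            rule_id=1,
        )
    ]


def rule2_excess_los(
    pathway: PatientPathway, config: RuleConfig
) -> list[RuleVerdict]:
    """Rule 2 — the whole stay exceeds the national per-DRG reference LoS.

    The trailing excess of the last stage is flagged level 0.  Skipped with a
    logged warning when the pathway carries no reference LoS.
    """
    stages = pathway.trace.stages
    if not stages:
        return []
    if pathway.reference_los_days is None:
        logger.warning(
            "rule 2 enabled but case %s has no reference LoS; skipped",
            pathway.case_id,
        )
        return []
    threshold_days = config.los_excess_factor * pathway.reference_los_days
    if not math.isfinite(threshold_days):
        return []  # an infinite factor disables the rule for any trace
    threshold = timedelta(days=threshold_days)
    duration = pathway.trace.end_ts - pathway.trace.start_ts
    if duration <= threshold:
        return []
    last = stages[-1]
    from_ts = max(last.start_ts, pathway.trace.end_ts - (duration - threshold))
    if not from_ts < last.end_ts:
        return []
    return [
        RuleVerdict(
            case_id=pathway.case_id,
            stage_index=len(stages) - 1,
            from_ts=from_ts,
            to_ts=last.end_ts,
            level=0,
            rule_id=2,
        )
    ]


def rule3_delayed_discharge(pathway: PatientPathway) -> list[RuleVerdict]:
    """Rule 3 — the patient stays past the fit-for-discharge instant.

    Everything from that instant to the trace end is level 0, clipped per
    overlapped stage.  A fit-for-discharge timestamp after the trace end is a
    data error.
    """
    fit = pathway.fit_for_discharge_ts
    stages = pathway.trace.stages
    if fit is None or not stages:
        return []
    end = stages[-1].end_ts
    if fit > end:
        raise ValueError(
            f"case {pathway.case_id}: fit-for-discharge {fit} after trace end {end}"
        )
    if fit == end:
        return []
    verdicts = []
    for i, stage in enumerate(stages):
        lo = max(stage.start_ts, fit)
        if lo < stage.end_ts:
            verdicts.append(
                RuleVerdict(
                    case_id=pathway.case_id,
                    stage_index=i,
                    from_ts=lo,
                    to_ts=stage.end_ts,
                    level=0,
                    rule_id=3,
                )
            )
    return verdicts


def rule4_overflow_bed(
    pathway: PatientPathway, registry: Optional[UnitRegistry] = None
) -> list[RuleVerdict]:
    """Rule 4 — overflow bed: the patient lies in one unit while another unit
    is medically responsible.  The whole stage is level 1 and corrects to the
    responsible unit."""
    verdicts = []
    for i, stage in enumerate(pathway.trace.stages):
        if _is_ed(pathway, i, registry):
            continue
        if stage.responsible_unit and stage.responsible_unit != stage.activity:
            verdicts.append(
                RuleVerdict(
                    case_id=pathway.case_id,
                    stage_index=i,
                    from_ts=stage.start_ts,
                    to_ts=stage.end_ts,
                    level=1,
                    rule_id=4,
                    correction_target=stage.responsible_unit,
                )
            )
    return verdicts


def rule5_buffer_unit(
    pathway: PatientPathway, registry: UnitRegistry, config: RuleConfig
) -> list[RuleVerdict]:
    """Rule 5 — a short stay in a polyvalent/post-emergency/observation unit
    immediately followed by a transfer is a buffer stay.

    Trigger: buffer-stage duration <= ``buffer_window`` (7.5 days — one week
    plus transfer time) and a different successor unit.  When
    ``require_specialized_successor`` is set the successor must be a
    specialized ward (specialized medicine, surgery, ICU or CCU)."""
    stages = pathway.trace.stages
    verdicts = []
    for i in range(len(stages) - 1):
        if _is_ed(pathway, i, registry):
            continue
        stage, nxt = stages[i], stages[i + 1]
        if stage.activity not in registry or nxt.activity not in registry:
            continue
        if registry.category(stage.activity) not in BUFFER_CATEGORIES:
            continue
        if nxt.activity == stage.activity:
            continue
        if stage.duration > config.buffer_window:
            continue
        if (
            config.require_specialized_successor
            and registry.category(nxt.activity) not in SPECIALIZED_CATEGORIES
        ):
            continue
        verdicts.append(
            RuleVerdict(
                case_id=pathway.case_id,
                stage_index=i,
                from_ts=stage.start_ts,
                to_ts=stage.end_ts,
                level=1,
                rule_id=5,
                correction_target=nxt.activity,
            )
        )
    return verdicts


def rule6_ou_awaiting_bed(
    pathway: PatientPathway, registry: UnitRegistry, config: RuleConfig
) -> list[RuleVerdict]:
    """Rule 6 — an observation-unit stay whose transfer label says the patient
    was awaiting a bed.  Corrects to the next stage's unit; with no next
    stage the verdict is target-less and the corrector deletes the stay."""
    stages = pathway.trace.stages
    verdicts = []
    for i, stage in enumerate(stages):
        if _is_ed(pathway, i, registry):
            continue
        if stage.activity not in registry:
            continue
        if registry.category(stage.activity) != UnitCategory.OBSERVATION:
            continue
        if stage.transfer_label != config.awaiting_bed_label:
            continue
        target = stages[i + 1].activity if i + 1 < len(stages) else None
        verdicts.append(
            RuleVerdict(
                case_id=pathway.case_id,
                stage_index=i,
                from_ts=stage.start_ts,
                to_ts=stage.end_ts,
                level=1,
                rule_id=6,
                correction_target=target,
            )
        )
    return verdicts


def rule7_day_week_before_full(
    pathway: PatientPathway, registry: UnitRegistry
) -> list[RuleVerdict]:
    """Rule 7 — a day/week-hospitalization stay immediately followed by the
    full-hospitalization unit of the same specialty betrays a missing bed in
    the full unit."""
    stages = pathway.trace.stages
    verdicts = []
    for i in range(len(stages) - 1):
        if _is_ed(pathway, i, registry):
            continue
        stage, nxt = stages[i], stages[i + 1]
        if stage.activity not in registry or nxt.activity not in registry:
            continue
        if registry.mode(stage.activity) not in ("day", "week"):
            continue
        if registry.mode(nxt.activity) != "full":
            continue
        if registry.specialty(stage.activity) != registry.specialty(nxt.activity):
            continue
        verdicts.append(
            RuleVerdict(
                case_id=pathway.case_id,
                stage_index=i,
                from_ts=stage.start_ts,
                to_ts=stage.end_ts,
                level=1,
                rule_id=7,
                correction_target=nxt.activity,
            )
        )
    return verdicts


def run_rules(
    pathway: PatientPathway, registry: UnitRegistry, config: RuleConfig
) -> list[RuleVerdict]:
    """Concatenate the verdicts of every enabled rule (order-independent)."""
    dispatch: dict[int, Callable[[], list[RuleVerdict]]] = {
        1: lambda: rule1_ed_boarding(pathway, config),
        2: lambda: rule2_excess_los(pathway, config),
        3: lambda: rule3_delayed_discharge(pathway),
        4: lambda: rule4_overflow_bed(pathway, registry),
        5: lambda: rule5_buffer_unit(pathway, registry, config),
        6: lambda: rule6_ou_awaiting_bed(pathway, registry, config),
        7: lambda: rule7_day_week_before_full(pathway, registry),
    }
    verdicts: list[RuleVerdict] = []
    for rule_id in sorted(config.enabled_rules):
        verdicts.extend(dispatch[rule_id]())
    return verdicts
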