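"""Pathway labeling: from rule verdicts to a phase tiling.

A historical trace of stages becomes a labeled trace of *phases*: every
instant of every stage is covered by exactly one phase carrying a relevance
level.  An instant covered by several verdicts takes the minimum level
(0 beats 1 beats 2 — the worst label has priority) and the union of the
firing rule ids; intervals untouched by any verdict are level 2.  Stages are
split at verdict boundaries, so the labeled trace has at least as many
phase-stages per activity as the historical trace had stages (the labeling
function can only refine, never coarsen).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Iterator, Optional

from .io import RuleConfig, UnitRegistry
from .model import EventLog, PatientPathway
from .rules import RuleVerdict, run_rules


@dataclass(frozen=True)
class LabeledPhase:
    """A maximal constant-level sub-interval of one stage."""

    activity: str
    level: int
    start_ts: datetime
    end_ts: datetime
    stage_index: int
    rule_ids: frozenset[int] = frozenset()
    correction_target: Optional[str] = None

    def __post_init__(self):
        if (self.level == 2) != (not self.rule_ids):
            raise ValueError("level 2 iff no rule fired")


@dataclass
class LabeledTrace:
    case_id: str
    phases: list[LabeledPhase] = field(default_factory=list)

    def __iter__(self) -> Iterator[LabeledPhase]:
        return iter(self.phases)

    def __len__(self) -> int:
        return len(self.phases)

    def stage_levels(self) -> dict[int, int]:
        """Per-stage relevance: the minimum level among the stage's phases."""
        levels: dict[int, int] = {}
        for ph in self.phases:
            levels[ph.stage_index] = min(levels.get(ph.stage_index, 2), ph.level)
        return levels

    @property
    def is_irrelevant(self) -> bool:
        return any(ph.level < 2 for ph in self.phases)


def _pick_target(covering: list[RuleVerdict]) -> Optional[str]:
    # Precedence: the overflow rule's responsible unit beats the
    # successor-derived targets of the sequence rules; then lowest rule id.
    with_target = [v for v in covering if v.correction_target]
    if not with_target:
        return None
    with_target.sort(key=lambda v: (v.rule_id != 4, v.rule_id))
    return with_target[0].correction_target


def tile_phases(
    pathway: PatientPathway, verdicts: Iterable[RuleVerdict]
) -> LabeledTrace:
    """Merge verdict intervals into the phase tiling of one trace.

    Usable with any verdict source (the production rules or ad-hoc rules);
    :func:`label_trace` wires it to :func:`wardpath.rules.run_rules`.
    Zero-length phases are dropped.
    """
    by_stage: dict[int, list[RuleVerdict]] = {}
    for v in verdicts:
        by_stage.setdefault(v.stage_index, []).append(v)

    phases: list[LabeledPhase] = []
    for idx, stage in enumerate(pathway.trace.stages):
        vs = []
        for v in by_stage.get(idx, ()):
            lo = max(v.from_ts, stage.start_ts)
            hi = min(v.to_ts, stage.end_ts)
            if lo < hi:
                vs.append((lo, hi, v))
        if not vs:
            # a whole untouched stage stays one level-2 phase, even when
            # instantaneous; only split artifacts of zero length are dropped
            phases.append(
                LabeledPhase(
                    activity=stage.activity,
                    level=2,
                    start_ts=stage.start_ts,
                    end_ts=stage.end_ts,
                    stage_index=idx,
                )
            )
            continue
        cuts = sorted({stage.start_ts, stage.end_ts} | {lo for lo, _, _ in vs} | {hi for _, hi, _ in vs})
        runs: list[list] = []  # [level, ids, target, start, end]
        for a, b in zip(cuts, cuts[1:]):
            covering = [v for lo, hi, v in vs if lo < b and hi > a]
            level = min((v.level for v in covering), default=2)
            ids = frozenset(v.rule_id for v in covering)
            target = _pick_target(covering) if level == 1 else None
            if runs and runs[-1][0] == level and runs[-1][2] == target:
                runs[-1][1] |= ids
                runs[-1][4] = b
            else:
                runs.append([level, set(ids), target, a, b])
        for level, ids, target, a, b in runs:
            if a == b:
                continue
            phases.append(
                LabeledPhase(
                    activity=stage.activity,
                    level=level,
                    start_ts=a,
                    end_ts=b,
                    stage_index=idx,
                    rule_ids=frozenset(ids),
                    correction_target=target if level == 1 else None,
                )
            )
    return LabeledTrace(case_id=pathway.case_id, phases=phases)


def label_trace(
    pathway: PatientPathway, registry: UnitRegistry, config: RuleConfig
) -> LabeledTrace:
    """Run the enabled rules on one pathway and tile the verdicts."""
    return tile_phases(pathway, run_rules(pathway, registry, config))


@dataclass
class LabeledPathway:
    pathway: PatientPathway
    labeled: LabeledTrace


@dataclass
class LabeledLog:
    entries: list[LabeledPathway] = field(default_factory=list)

    def __iter__(self) -> Iterator[LabeledPathway]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def by_case(self) -> dict[str, LabeledTrace]:
        return {e.labeled.case_id: e.labeled for e in self.entries}

    def to_event_rows(self) -> list[dict]:
        """Phase events for export: each phase yields a start and a complete
        row carrying the relevance level and firing rules."""
        rows = []
        for entry in self.entries:
            for ph in entry.labeled.phases:
                for trans, when in (("start", ph.start_ts), ("complete", ph.end_ts)):
                    rows.append(
                        {
                            "case_id": entry.pathway.case_id,
                            "patient_id": entry.pathway.patient_id,
                            "activity": ph.activity,
                            "transaction": trans,
                            "timestamp": when.isoformat(),
                            "level": ph.level,
                            "rule_ids": ";".join(str(r) for r in sorted(ph.rule_ids)),
                            "stage_index": ph.stage_index,
                        }
                    )
        return rows


@dataclass
class LabelSummary:
    n_pathways: int = 0
    n_irrelevant_pathways: int = 0
    phase_counts: dict[int, int] = field(default_factory=lambda: {0: 0, 1: 0, 2: 0})
    rule_firings: dict[int, int] = field(default_factory=dict)
    errors: list[tuple[str, str]] = field(default_factory=list)

    @property
    def irrelevant_share(self) -> float:
        """Fraction of evaluated pathways containing any level-0/1 phase."""
        if self.n_pathways == 0:
            return 0.0
        return self.n_irrelevant_pathways / self.n_pathways

    def to_dict(self) -> dict:
        return {
            "n_pathways": self.n_pathways,
            "n_irrelevant_pathways": self.n_irrelevant_pathways,
            "irrelevant_share": self.irrelevant_share,
            "phase_counts": {str(k): v for k, v in self.phase_counts.items()},
            "rule_firings": {str(k): v for k, v in sorted(self.rule_firings.items())},
            "errors": [list(e) for e in self.errors],
        }


def label_log(
    log: EventLog, registry: UnitRegistry, config: RuleConfig
) -> tuple[LabeledLog, LabelSummary]:
    """Label every pathway; per-case errors are collected, not fatal."""
    out = LabeledLog()
    summary = LabelSummary()
    for pathway in log:
        try:
            labeled = label_trace(pathway, registry, config)
        except ValueError as exc:
            summary.errors.append((pathway.case_id, str(exc)))
            continue
        out.entries.append(LabeledPathway(pathway, labeled))
        summary.n_pathways += 1
        if labeled.is_irrelevant:
            summary.n_irrelevant_pathways += 1
        for ph in labeled.phases:
            summary.phase_counts[ph.level] = summary.phase_counts.get(ph.level, 0) + 1
            for rid in ph.rule_ids:
                summary.rule_firings[rid] = summary.rule_firings.get(rid, 0) + 1
    return out, summary


def read_labeled_log(path) -> dict[str, LabeledTrace]:
    """Re-read a labeled CSV (written by ``write_event_log(...,
    include_labels=True)``) into per-case labeled traces."""
    import pandas as pd

    df = pd.read_csv(path, dtype={"case_id": str, "rule_ids": str})
    traces: dict[str, LabeledTrace] = {}
    for case_id, group in df.groupby("case_id", sort=True):
        phases = []
        starts = group[group["transaction"] == "start"].reset_index(drop=True)
        ends = group[group["transaction"] == "complete"].reset_index(drop=True)
        for (_, srow), (_, erow) in zip(starts.iterrows(), ends.iterrows()):
            ids = frozenset(
                int(float(x))
                for x in str(srow.get("rule_ids", "")).split(";")
                if x and x != "nan"
            )
            phases.append(
                LabeledPhase(
                    activity=srow["activity"],
                    level=int(srow["level"]),
                    start_ts=pd.to_datetime(srow["timestamp"]).to_pydatetime(),
                    end_ts=pd.to_datetime(erow["timestamp"]).to_pydatetime(),
                    stage_index=int(srow["stage_index"]),
                    rule_ids=ids,
                )
            )
        traces[str(case_id)] = LabeledTrace(case_id=str(case_id), phases=phases)
    return traces
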