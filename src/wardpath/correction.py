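"""Pathway correction: from a labeled trace to the ideal trace.

The corrected trace is the pathway the patient would have followed with
unlimited beds:

* level-1 phases (wrong unit) keep their time but change activity — to the
  rule-supplied correction target when present, else to the activity of the
  next level-2 phase, else the phase is deleted;
* level-0 phases (should not be hospitalized) are deleted — a trailing
  deletion discharges the patient at the presumed discharge instant, an
  interior deletion leaves a timestamp gap (later admissions are never
  re-timed, which would fabricate data);
* consecutive phases with the same activity are then merged by extending the
  first phase's end to the last's.  The merge is unconditional: it also
  bridges inter-site transfer gaps, so a relabeled buffer stay fuses with the
  destination stay it fed into.

Corrections never add hospital time, so the corrected log has at most as
many trace variants as its source.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .model import COMPLETE, START, Event, EventLog, PatientPathway, Stage, Trace
from .labeling import LabeledLog, LabeledTrace


@dataclass
class CorrectionOps:
    """Per-trace tally of what the correction did."""

    deleted: int = 0  # phases removed (level 0, or target-less level 1)
    relabeled: int = 0  # level-1 phases whose activity changed
    merged: int = 0  # phases absorbed into a predecessor
    emptied: bool = False  # nothing survived


def _synth_events(case_id: str, patient_id: str, activity: str, start, end):
    return (
        Event(case_id, patient_id, activity, START, start),
        Event(case_id, patient_id, activity, COMPLETE, end),
    )


def correct_trace(
    labeled: LabeledTrace, patient_id: str = ""
) -> tuple[Trace, CorrectionOps]:
    """Apply relabel / delete / merge to one labeled trace."""
    ops = CorrectionOps()
    segments: list[list] = []  # [activity, start, end]
    phases = labeled.phases
    for i, ph in enumerate(phases):
        if ph.level == 0:
            ops.deleted += 1
            continue
        activity = ph.activity
        if ph.level == 1:
            if ph.correction_target:
                activity = ph.correction_target
            else:
                nxt = next((q for q in phases[i + 1 :] if q.level == 2), None)
                if nxt is None:
                    ops.deleted += 1
                    continue
                activity = nxt.activity
            if activity != ph.activity:
                ops.relabeled += 1
        if segments and segments[-1][0] == activity:
            segments[-1][2] = ph.end_ts
            ops.merged += 1
        else:
            segments.append([activity, ph.start_ts, ph.end_ts])
    stages = [
        Stage(
            activity=act,
            start_ts=start,
            end_ts=end,
            events=_synth_events(labeled.case_id, patient_id, act, start, end),
        )
        for act, start, end in segments
    ]
    ops.emptied = not stages
    return Trace(case_id=labeled.case_id, stages=stages), ops


@dataclass
class DiffReport:
    """Log-level tally of the correction, with variant counts before/after."""

    n_pathways: int = 0
    stages_removed: int = 0
    stages_relabeled: int = 0
    stages_merged: int = 0
    variants_before: int = 0
    variants_after: int = 0
    empty_trace_warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_pathways": self.n_pathways,
            "stages_removed": self.stages_removed,
            "stages_relabeled": self.stages_relabeled,
            "stages_merged": self.stages_merged,
            "variants_before": self.variants_before,
            "variants_after": self.variants_after,
            "empty_trace_warnings": list(self.empty_trace_warnings),
        }


def correct_log(labeled_log: LabeledLog) -> tuple[EventLog, DiffReport]:
    """Correct every labeled pathway and report the aggregate diff.

    Pathways whose correction leaves no stage (everything was judged
    irrelevant and nothing had a target) stay in the log with an empty trace
    and are listed in ``empty_trace_warnings``.
    """
    report = DiffReport()
    corrected = []
    for entry in labeled_log:
        src = entry.pathway
        trace, ops = correct_trace(entry.labeled, patient_id=src.patient_id)
        report.n_pathways += 1
        report.stages_removed += ops.deleted
        report.stages_relabeled += ops.relabeled
        report.stages_merged += ops.merged
        if ops.emptied:
            report.empty_trace_warnings.append(src.case_id)
        fit = src.fit_for_discharge_ts
        if fit is not None and trace.stages:
            fit = min(fit, trace.end_ts)
        elif not trace.stages:
            fit = None
        corrected.append(
            PatientPathway(
                patient_id=src.patient_id,
                stay_id=src.stay_id,
                trace=trace,
                discharge_disposition=src.discharge_disposition,
                fit_for_discharge_ts=fit,
                reference_los_days=src.reference_los_days,
                drg_code=src.drg_code,
            )
        )
    log = EventLog(corrected)
    before = {tuple(e.pathway.trace.activities) for e in labeled_log}
    after = {tuple(p.trace.activities) for p in log}
    report.variants_before = len(before)
    report.variants_after = len(after)
    return log, report
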