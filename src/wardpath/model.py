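"""Formal model of unscheduled hospital pathways.

A pathway is the process-mining view of one acute-care (MCO) stay: a trace of
*stages*, each stage being one contiguous visit to one medical unit delimited
by a ``start`` and a ``complete`` lifecycle event.  Traces begin at the
emergency department (ED) and end at the unit from which the patient is
discharged.  Gaps between stages (inter-site transfer time) are legal; a
patient occupies no unit during a gap.

Relevance levels grade each (sub-)interval of a stay:

* level 2 — the patient is in the right unit and the hospitalization is
  justified;
* level 1 — hospitalization justified, wrong unit (overflow bed, buffer stay);
* level 0 — no remaining medical reason to be hospitalized (delayed
  discharge).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Iterable, Iterator, Optional, Sequence

START = "start"
COMPLETE = "complete"
TRANSITIONS = frozenset({START, COMPLETE})


class RelevanceLevel(enum.IntEnum):
    """Three-level relevance scale; lower is worse (0 < 1 < 2)."""

    SHOULD_NOT_BE_HOSPITALIZED = 0
    WRONG_UNIT = 1
    RELEVANT = 2


class MalformedLogError(ValueError):
    """Raised when lifecycle events of a case cannot be paired into stages."""

    def __init__(self, message: str, case_id: str = "", activity: str = ""):
        self.case_id = case_id
        self.activity = activity
        super().__init__(
            f"{message} (case={case_id!r}, activity={activity!r})"
            if case_id or activity
            else message
        )


@dataclass(frozen=True)
class Event:
    """A single lifecycle event: a patient entering or leaving a unit."""

    case_id: str
    patient_id: str
    activity: str
    transaction: str
    timestamp: datetime
    responsible_unit: Optional[str] = None
    transfer_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.transaction not in TRANSITIONS:
            raise ValueError(
                f"transaction must be one of {sorted(TRANSITIONS)}, "
                f"got {self.transaction!r}"
            )


@dataclass
class Stage:
    """One contiguous visit to one medical unit (paired start/complete)."""

    activity: str
    start_ts: datetime
    end_ts: datetime
    events: tuple[Event, ...] = ()
    responsible_unit: Optional[str] = None
    transfer_label: Optional[str] = None
    open: bool = False  # permissive mode: complete event missing

    def __post_init__(self) -> None:
        if self.end_ts < self.start_ts:
            raise ValueError(
                f"stage {self.activity!r} ends before it starts "
                f"({self.start_ts} > {self.end_ts})"
            )

    @property
    def duration(self) -> timedelta:
        return self.end_ts - self.start_ts


@dataclass
class Trace:
    """The ordered stages of one stay."""

    case_id: str
    stages: list[Stage] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.stages)

    def __iter__(self) -> Iterator[Stage]:
        return iter(self.stages)

    @property
    def start_ts(self) -> datetime:
        if not self.stages:
            raise ValueError(f"empty trace {self.case_id!r} has no start")
        return self.stages[0].start_ts

    @property
    def end_ts(self) -> datetime:
        if not self.stages:
            raise ValueError(f"empty trace {self.case_id!r} has no end")
        return self.stages[-1].end_ts

    @property
    def activities(self) -> tuple[str, ...]:
        return tuple(s.activity for s in self.stages)

    def events(self) -> list[Event]:
        """Flatten stages back to the chronological event list."""
        out: list[Event] = []
        for stage in self.stages:
            out.extend(stage.events)
        return out


def trace_duration(trace: Trace) -> timedelta:
    """Total elapsed time: last complete minus first start.

    Raises ``ValueError`` on an empty trace.
    """
    if not trace.stages:
        raise ValueError(f"cannot compute duration of empty trace {trace.case_id!r}")
    return trace.end_ts - trace.start_ts


@dataclass
class PatientPathway:
    """One MCO stay: the trace plus its administrative attributes."""

    patient_id: str
    stay_id: str
    trace: Trace
    discharge_disposition: str = ""
    fit_for_discharge_ts: Optional[datetime] = None
    reference_los_days: Optional[float] = None
    drg_code: Optional[str] = None

    @property
    def case_id(self) -> str:
        return self.stay_id


@dataclass
class EventLog:
    """A set of pathways; one trace per stay, case ids unique."""

    pathways: list[PatientPathway] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self) -> Iterator[PatientPathway]:
        return iter(self.pathways)

    @property
    def units(self) -> set[str]:
        """The unit universe implied by the activities of the log."""
        return {s.activity for p in self.pathways for s in p.trace.stages}

    def by_case(self) -> dict[str, PatientPathway]:
        return {p.case_id: p for p in self.pathways}


def _sorted_for_pairing(events: Sequence[Event]) -> list[Event]:
    # Stable sort by timestamp only; tie order among equal timestamps is
    # resolved during the pairing scan.
    return sorted(events, key=lambda e: e.timestamp)


def build_stages(
    events: Sequence[Event], *, permissive: bool = False
) -> list[Stage]:
    """Pair start/complete events of one case into stages.

    Per activity, the earliest unmatched ``start`` is paired with the next
    ``complete`` of the same activity with no intervening event of that
    activity (the unique non-crossing pairing).  Repeated visits to the same
    unit yield distinct stages.

    A ``complete`` without a prior ``start``, or a dangling ``start`` (unless
    ``permissive``), raises :class:`MalformedLogError`.  In permissive mode a
    dangling start becomes an open stage ending at its own timestamp with
    ``open=True``.
    """
    if not events:
        return []
    ordered = _sorted_for_pairing(events)
    case_id = ordered[0].case_id

    # Group per activity, preserving time order; within equal timestamps,
    # close an open stage before opening the next one.
    per_activity: dict[str, list[Event]] = {}
    for ev in ordered:
        per_activity.setdefault(ev.activity, []).append(ev)

    stages: list[Stage] = []
    for activity, evs in per_activity.items():
        # Resolve timestamp ties: when a stage is open, a complete at the tied
        # instant precedes a start; otherwise the start comes first.
        evs = sorted(evs, key=lambda e: e.timestamp)
        i = 0
        open_start: Optional[Event] = None
        while i < len(evs):
            # gather the tie group
            j = i
            while j < len(evs) and evs[j].timestamp == evs[i].timestamp:
                j += 1
            group = evs[i:j]
            if len(group) > 1:
                want_first = COMPLETE if open_start is not None else START
                group.sort(key=lambda e: 0 if e.transaction == want_first else 1)
            for ev in group:
                if ev.transaction == START:
                    if open_start is not None:
                        raise MalformedLogError(
                            "start while a stage of the same activity is open",
                            case_id,
                            activity,
                        )
                    open_start = ev
                else:
                    if open_start is None:
                        raise MalformedLogError(
                            "complete without prior start", case_id, activity
                        )
                    stages.append(
                        Stage(
                            activity=activity,
                            start_ts=open_start.timestamp,
                            end_ts=ev.timestamp,
                            events=(open_start, ev),
                            responsible_unit=open_start.responsible_unit
                            or ev.responsible_unit,
                            transfer_label=open_start.transfer_label
                            or ev.transfer_label,
                        )
                    )
                    open_start = None
            i = j
        if open_start is not None:
            if not permissive:
                raise MalformedLogError(
                    "start without complete", case_id, activity
                )
            stages.append(
                Stage(
                    activity=activity,
                    start_ts=open_start.timestamp,
                    end_ts=open_start.timestamp,
                    events=(open_start,),
                    responsible_unit=open_start.responsible_unit,
                    transfer_label=open_start.transfer_label,
                    open=True,
                )
            )
    stages.sort(key=lambda s: (s.start_ts, s.end_ts, s.activity))
    return stages


@dataclass(frozen=True)
class Violation:
    """One well-formedness defect found by :func:`validate_log`."""

    case_id: str
    kind: str
    detail: str


def validate_log(log: EventLog, registry=None) -> list[Violation]:
    """Diagnose well-formedness; returns one record per violated invariant.

    Never raises.  Checks: duplicate case ids, unknown units (when a registry
    is supplied), a first stage that is not ED-category, overlapping stages,
    duplicate events within a trace, and a fit-for-discharge timestamp after
    the trace end.
    """
    violations: list[Violation] = []
    seen_cases: set[str] = set()
    for pathway in log:
        cid = pathway.case_id
        if cid in seen_cases:
            violations.append(Violation(cid, "duplicate_case", "case id not unique"))
        seen_cases.add(cid)
        stages = pathway.trace.stages
        if not stages:
            violations.append(Violation(cid, "empty_trace", "trace has no stages"))
            continue
        if registry is not None:
            for s in stages:
                if s.activity not in registry:
                    violations.append(
                        Violation(cid, "unknown_unit", f"activity {s.activity!r} not in registry")
                    )
            first = stages[0]
            if first.activity in registry and registry.category(first.activity) != "ED":
                violations.append(
                    Violation(
                        cid,
                        "first_stage_not_ed",
                        f"trace begins at {first.activity!r}, not an ED unit",
                    )
                )
        for a, b in itertools.pairwise(stages):
            if b.start_ts < a.end_ts:
                violations.append(
                    Violation(
                        cid,
                        "overlapping_stages",
                        f"{b.activity!r} starts {b.start_ts} before "
                        f"{a.activity!r} ends {a.end_ts}",
                    )
                )
        events = pathway.trace.events()
        if len(events) != len(
            set((e.activity, e.transaction, e.timestamp) for e in events)
        ):
            violations.append(
                Violation(cid, "duplicate_event", "an event appears more than once")
            )
        if (
            pathway.fit_for_discharge_ts is not None
            and pathway.fit_for_discharge_ts > stages[-1].end_ts
        ):
            violations.append(
                Violation(
                    cid,
                    "fit_after_discharge",
                    "fit-for-discharge timestamp lies after the trace end",
                )
            )
    return violations
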