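"""Synthetic unscheduled-pathway logs with planted ground truth.

The generator emulates the mechanisms that bias real hospital event logs —
ED boarding, overflow beds (location differs from the medically responsible
unit), buffer stays in polyvalent/post-emergency units before a specialized
ward, observation-unit stays that are really bed waits, and delayed
discharges after the fit-for-discharge instant — and emits three aligned
artifacts per run: the *historical* log (with the bias), the planted *truth*
labeling, and the *ideal* log (the pathway under unlimited beds, sharing the
discharge instants the correction semantics preserve).

Mechanism and signature are separable: the attribute dropout rate removes
the detectable signature (responsible unit, transfer label, fit-for-
discharge timestamp) while leaving the planted irrelevance in the truth,
which is how detector-invisible bias — the gap between a rule engine and an
expert — is emulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional

import numpy as np

from .io import Unit, UnitCategory, UnitRegistry, SPECIALIZED_CATEGORIES
from .labeling import LabeledLog, LabeledPathway, LabeledTrace, tile_phases
from .model import (
    COMPLETE,
    START,
    Event,
    EventLog,
    PatientPathway,
    Stage,
    Trace,
)
from .rules import RuleVerdict

AWAITING_BED = "awaiting bed"
OBSERVATION_LABELS = ("observation", "back home within 24 h")


def default_registry() -> UnitRegistry:
    """A mid-size general-hospital group: one ED, an observation unit, two
    polyvalent-type wards, eight specialized medicine wards, two surgery
    wards, intensive/continuing care, a week-hospitalization unit and a
    seasonal ward."""
    S = "scorff"
    mk = lambda uid, cat, spec="", mode="full", site=S: Unit(
        uid, uid.replace("_", " ").title(), site, cat, spec, mode
    )
    return UnitRegistry(
        [
            mk("ED", UnitCategory.ED, "emergency"),
            mk("OU", UnitCategory.OBSERVATION, "emergency"),
            mk("POLYVALENT_MEDICINE", UnitCategory.POLYVALENT),
            mk("POST_EMERGENCY", UnitCategory.POST_EMERGENCY),
            mk("CARDIOLOGY", UnitCategory.SPECIALIZED_MED, "cardiology"),
            mk("GERIATRICS", UnitCategory.SPECIALIZED_MED, "geriatrics"),
            mk("PULMONOLOGY", UnitCategory.SPECIALIZED_MED, "pulmonology"),
            mk("NEUROLOGY", UnitCategory.SPECIALIZED_MED, "neurology"),
            mk("HEPATOGASTRO", UnitCategory.SPECIALIZED_MED, "hepatogastroenterology"),
            mk("ONCOLOGY", UnitCategory.SPECIALIZED_MED, "oncology"),
            mk("RHEUMATOLOGY", UnitCategory.SPECIALIZED_MED, "rheumatology"),
            mk("NEPHROLOGY", UnitCategory.SPECIALIZED_MED, "nephrology"),
            mk("ORTHO_SURGERY", UnitCategory.SURGERY, "orthopedics"),
            mk("VISCERAL_SURGERY", UnitCategory.SURGERY, "visceral"),
            mk("ICU", UnitCategory.ICU, "intensive care"),
            mk("CCU", UnitCategory.CCU, "continuing care"),
            mk("CARDIOLOGY_WEEK", UnitCategory.DAY_WEEK, "cardiology", "week"),
            mk("SEASONAL_UNIT", UnitCategory.SEASONAL),
        ]
    )


#: per-unit log-normal LoS parameters (mu, sigma) on log-days
DEFAULT_LOS_PARAMS: dict[str, tuple[float, float]] = {
    "ED": (math.log(0.15), 0.35),  # ~3.6 h median
    "OU": (math.log(0.5), 0.4),
    "POLYVALENT_MEDICINE": (math.log(6.0), 0.5),
    "POST_EMERGENCY": (math.log(4.0), 0.5),
    "CARDIOLOGY": (math.log(5.0), 0.5),
    "GERIATRICS": (math.log(8.0), 0.5),
    "PULMONOLOGY": (math.log(6.0), 0.5),
    "NEUROLOGY": (math.log(5.0), 0.5),
    "HEPATOGASTRO": (math.log(5.5), 0.5),
    "ONCOLOGY": (math.log(6.0), 0.5),
    "RHEUMATOLOGY": (math.log(5.0), 0.5),
    "NEPHROLOGY": (math.log(5.0), 0.5),
    "ORTHO_SURGERY": (math.log(4.0), 0.5),
    "VISCERAL_SURGERY": (math.log(4.0), 0.5),
    "ICU": (math.log(3.0), 0.6),
    "CCU": (math.log(2.5), 0.6),
    "CARDIOLOGY_WEEK": (math.log(2.0), 0.4),
    "SEASONAL_UNIT": (math.log(5.0), 0.5),
}

#: pathway shapes after the ED visit and their mix; shapes whose first
#: inpatient stage is a specialized ward can host insertion mechanisms
_SHAPES: list[tuple[str, float]] = [
    ("ED_OU", 0.22),
    ("ED_SPEC", 0.40),
    ("ED_SURG", 0.09),
    ("ED_POLY", 0.08),
    ("ED_POSTEM", 0.06),
    ("ED_SEASONAL", 0.02),
    ("ED_CCU", 0.01),
    ("ED_ICU_SPEC", 0.07),
    ("ED_SPEC_SPEC", 0.05),
]
_INSERTABLE = {"ED_SPEC", "ED_SURG", "ED_CCU", "ED_ICU_SPEC", "ED_SPEC_SPEC"}

_SPEC_UNITS = [
    "CARDIOLOGY",
    "GERIATRICS",
    "PULMONOLOGY",
    "NEUROLOGY",
    "HEPATOGASTRO",
    "ONCOLOGY",
    "RHEUMATOLOGY",
    "NEPHROLOGY",
]
_SPEC_WEIGHTS = [0.18, 0.20, 0.14, 0.10, 0.11, 0.09, 0.09, 0.09]
_SURG_UNITS = ["ORTHO_SURGERY", "VISCERAL_SURGERY"]

_WEEKDAY_WEIGHTS = np.array([1.25, 1.05, 1.0, 0.95, 0.95, 0.8, 1.0])  # Mon..Sun
_HOUR_WEIGHTS = np.array(
    [0.5, 0.4, 0.3, 0.3, 0.3, 0.4, 0.6, 1.0, 1.4, 1.6, 1.7, 1.7,
     1.6, 1.5, 1.5, 1.5, 1.5, 1.6, 1.5, 1.3, 1.1, 0.9, 0.7, 0.6]
)

_DISPOSITIONS = ["home", "rehabilitation", "psychiatric center", "death", "transfer"]
_DISPOSITION_W = [0.72, 0.16, 0.02, 0.04, 0.06]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic year of unscheduled pathways.

    Defaults emulate a mid-size hospital group over twelve months: 13,366
    simulated stays, a Monday-peaked / night-troughed arrival profile, and
    mechanism probabilities sized so that roughly 14% of pathways carry at
    least one planted irrelevance detectable by rules 3-7.
    """

    n_pathways: int = 13366
    duration_days: float = 365.0
    start: datetime = datetime(2021, 1, 4)
    registry: UnitRegistry = field(default_factory=default_registry)
    los_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LOS_PARAMS)
    )
    p_overflow: float = 0.03
    p_buffer: float = 0.03
    p_awaiting_bed: float = 0.04
    p_week_full: float = 0.01
    p_delayed_discharge: float = 0.04
    p_ed_boarding: float = 0.04
    ed_los_max_days: float = 10.0 / 24.0
    buffer_window_days: float = 7.5
    attribute_dropout: float = 0.0
    arrival_modulation: bool = True
    seed: int = 0

    def __post_init__(self):
        probs = [
            self.p_overflow,
            self.p_buffer,
            self.p_awaiting_bed,
            self.p_week_full,
            self.p_delayed_discharge,
            self.p_ed_boarding,
            self.attribute_dropout,
        ]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.p_overflow + self.p_buffer + self.p_awaiting_bed + self.p_week_full > 1:
            raise ValueError("insertion-mechanism probabilities must sum to <= 1")
        if self.n_pathways < 1:
            raise ValueError("n_pathways must be >= 1")
        cats = {u.category for u in self.registry}
        if self.p_buffer > 0 and not (
            {UnitCategory.POLYVALENT, UnitCategory.POST_EMERGENCY} & cats
        ):
            raise ValueError("p_buffer > 0 needs a polyvalent/post-emergency unit")
        if (self.p_overflow > 0 or self.p_buffer > 0) and not (
            SPECIALIZED_CATEGORIES & cats
        ):
            raise ValueError("insertion mechanisms need a specialized unit")
        if self.p_week_full > 0 and UnitCategory.DAY_WEEK not in cats:
            raise ValueError("p_week_full > 0 needs a day/week-mode unit")


@dataclass
class SynthResult:
    historical: EventLog
    truth: LabeledLog  # planted labels, aligned to the historical pathways
    ideal: EventLog  # the pathway with no mechanism applied
    registry: UnitRegistry
    mechanism_counts: dict[str, int] = field(default_factory=dict)


def _td(days: float) -> timedelta:
    return timedelta(seconds=int(round(days * 86400.0)))


class _Builder:
    def __init__(self, config: SynthConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.shape_names = [s for s, _ in _SHAPES]
        self.shape_p = np.array([p for _, p in _SHAPES])
        self.shape_p = self.shape_p / self.shape_p.sum()
        ins = np.array([s in _INSERTABLE for s, _ in _SHAPES])
        self.shape_p_ins = np.where(ins, self.shape_p, 0.0)
        self.shape_p_ins /= self.shape_p_ins.sum()

    def los_days(self, unit: str, lo: float = 0.0, hi: float = 28.0) -> float:
        mu, sigma = self.cfg.los_params[unit]
        for _ in range(1000):
            d = float(np.exp(self.rng.normal(mu, sigma)))
            if lo < d < hi:
                return d
        raise RuntimeError(f"LoS rejection sampling stuck for {unit}")

    def pick(self, options, weights=None) -> str:
        if weights is not None:
            weights = np.asarray(weights, dtype=float)
            weights = weights / weights.sum()
        return str(self.rng.choice(options, p=weights))

    def mechanism(self) -> Optional[str]:
        r = float(self.rng.random())
        cum = 0.0
        for name, p in (
            ("overflow", self.cfg.p_overflow),
            ("buffer", self.cfg.p_buffer),
            ("awaiting", self.cfg.p_awaiting_bed),
            ("week_full", self.cfg.p_week_full),
        ):
            cum += p
            if r < cum:
                return name
        return None

    def shape(self, mech: Optional[str]) -> str:
        if mech == "week_full":
            return "ED_SPEC"
        p = self.shape_p_ins if mech in ("overflow", "buffer") else self.shape_p
        return self.shape_names[int(self.rng.choice(len(self.shape_names), p=p))]

    def destination_units(self, shape: str, mech: Optional[str]) -> list[str]:
        if shape == "ED_OU":
            return ["OU"]
        if shape == "ED_SPEC":
            if mech == "week_full":
                return ["CARDIOLOGY"]
            return [self.pick(_SPEC_UNITS, _SPEC_WEIGHTS)]
        if shape == "ED_SURG":
            return [self.pick(_SURG_UNITS)]
        if shape == "ED_POLY":
            return ["POLYVALENT_MEDICINE"]
        if shape == "ED_POSTEM":
            return ["POST_EMERGENCY"]
        if shape == "ED_SEASONAL":
            return ["SEASONAL_UNIT"]
        if shape == "ED_CCU":
            return ["CCU"]
        if shape == "ED_ICU_SPEC":
            return [self.pick(["ICU", "CCU"], [0.75, 0.25]),
                    self.pick(_SPEC_UNITS, _SPEC_WEIGHTS)]
        if shape == "ED_SPEC_SPEC":
            first = self.pick(_SPEC_UNITS, _SPEC_WEIGHTS)
            second = first
            while second == first:
                second = self.pick(_SPEC_UNITS, _SPEC_WEIGHTS)
            return [first, second]
        raise AssertionError(shape)


def _arrivals(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Arrival offsets in days, sorted; weekday/hour modulated unless
    disabled."""
    n = config.n_pathways
    days = int(math.ceil(config.duration_days))
    if config.arrival_modulation:
        start_wd = config.start.weekday()
        day_w = _WEEKDAY_WEIGHTS[(start_wd + np.arange(days)) % 7].astype(float)
        day_w /= day_w.sum()
        day = rng.choice(days, size=n, p=day_w)
        hour_w = _HOUR_WEIGHTS / _HOUR_WEIGHTS.sum()
        hour = rng.choice(24, size=n, p=hour_w)
    else:
        day = rng.integers(0, days, size=n)
        hour = rng.integers(0, 24, size=n)
    minute = rng.integers(0, 60, size=n)
    offsets = day + hour / 24.0 + minute / 1440.0
    offsets.sort()
    return offsets


def generate(config: SynthConfig) -> SynthResult:
    """Generate aligned historical / truth / ideal logs.

    Every trace starts at the ED; each planted mechanism carries exactly the
    attribute signature its rule needs (unless dropped out); the ideal log
    keeps the timestamps the correction semantics preserve, so correcting
    the historical log with matching rules reproduces it exactly.
    """
    rng = np.random.default_rng(config.seed)
    b = _Builder(config, rng)
    arrivals = _arrivals(config, rng)
    width = len(str(config.n_pathways))

    historical, ideal, truth_entries = [], [], []
    mech_counts: dict[str, int] = {
        "overflow": 0, "buffer": 0, "awaiting": 0, "week_full": 0,
        "delayed_discharge": 0, "ed_boarding": 0, "none": 0,
    }

    for i in range(config.n_pathways):
        case_id = f"S{i + 1:0{width}d}"
        patient_id = f"P{i + 1:0{width}d}"
        t0 = config.start + _td(float(arrivals[i]))

        mech = b.mechanism()
        shape = b.shape(mech)
        dest = b.destination_units(shape, mech)
        terminal_awaiting = mech == "awaiting" and shape == "ED_OU"
        boarding = (
            not terminal_awaiting
            and float(rng.random()) < config.p_ed_boarding
        )
        last_is_inpatient = not (shape == "ED_OU")
        delayed = last_is_inpatient and float(rng.random()) < config.p_delayed_discharge

        dropout = lambda: float(rng.random()) < config.attribute_dropout

        # --- historical stage chain: (unit, duration_days, responsible, label, planted)
        chain: list[dict] = []
        ed_days = b.los_days("ED", hi=config.ed_los_max_days * 0.999)
        if boarding:
            excess = b.los_days("ED", lo=0.01)  # reuse the ED scale for excess
            chain.append(
                dict(unit="ED", days=config.ed_los_max_days + excess,
                     resp=None, label=None, planted="ed_boarding")
            )
        else:
            chain.append(dict(unit="ED", days=ed_days, resp=None, label=None, planted=None))

        if terminal_awaiting:
            d = b.los_days("OU", hi=0.999)
            label = OBSERVATION_LABELS[0] if dropout() else AWAITING_BED
            chain.append(dict(unit="OU", days=d, resp=None, label=label,
                              planted="awaiting_terminal"))
        else:
            inserted = None
            if mech == "overflow":
                intended = dest[0] if shape != "ED_ICU_SPEC" else dest[0]
                pool = [u for u in _SPEC_UNITS + _SURG_UNITS if u != intended]
                wrong = b.pick(pool)
                inserted = dict(
                    unit=wrong,
                    days=b.los_days(wrong, hi=min(5.0, 27.0)),
                    resp=None if dropout() else intended,
                    label=None,
                    planted="overflow",
                )
            elif mech == "buffer":
                buf = b.pick(["POLYVALENT_MEDICINE", "POST_EMERGENCY"])
                inserted = dict(
                    unit=buf,
                    days=b.los_days(buf, hi=config.buffer_window_days * 0.98),
                    resp=None,
                    label=None,
                    planted="buffer",
                )
            elif mech == "awaiting":
                inserted = dict(
                    unit="OU",
                    days=b.los_days("OU", hi=0.999),
                    resp=None,
                    label=OBSERVATION_LABELS[0] if dropout() else AWAITING_BED,
                    planted="awaiting",
                )
            elif mech == "week_full":
                inserted = dict(
                    unit="CARDIOLOGY_WEEK",
                    days=b.los_days("CARDIOLOGY_WEEK", hi=6.0),
                    resp=None,
                    label=None,
                    planted="week_full",
                )
            if inserted is not None:
                chain.append(inserted)
            for j, unit in enumerate(dest):
                label = None
                if unit == "OU":
                    label = b.pick(list(OBSERVATION_LABELS), [0.6, 0.4])
                    d = b.los_days("OU", hi=0.999)
                else:
                    d = b.los_days(unit)
                chain.append(dict(unit=unit, days=d, resp=None if unit in ("OU",) else unit,
                                  label=label, planted=None))

        delay_days = 0.0
        if delayed:
            last_d = chain[-1]["days"]
            delay_days = min(b.los_days("CCU", lo=0.05), 0.9 * last_d)
            chain[-1]["days"] += delay_days
            chain[-1]["planted"] = (chain[-1]["planted"] or "") + "+delayed"

        # --- materialize historical stages (contiguous chain)
        stages: list[Stage] = []
        cursor = t0
        for item in chain:
            end = cursor + _td(item["days"])
            stages.append(
                Stage(
                    activity=item["unit"],
                    start_ts=cursor,
                    end_ts=end,
                    events=(
                        Event(case_id, patient_id, item["unit"], START, cursor,
                              item["resp"], item["label"]),
                        Event(case_id, patient_id, item["unit"], COMPLETE, end,
                              item["resp"], item["label"]),
                    ),
                    responsible_unit=item["resp"],
                    transfer_label=item["label"],
                )
            )
            cursor = end
        trace_end = stages[-1].end_ts

        fit_ts = None
        if delayed:
            fit_true = trace_end - _td(delay_days)
            fit_ts = None if dropout() else fit_true
        else:
            fit_true = None

        disposition = b.pick(_DISPOSITIONS, _DISPOSITION_W)
        ref_los = round(float(np.exp(rng.normal(math.log(6.0), 0.4))), 1)
        pathway = PatientPathway(
            patient_id=patient_id,
            stay_id=case_id,
            trace=Trace(case_id=case_id, stages=stages),
            discharge_disposition=disposition,
            fit_for_discharge_ts=fit_ts,
            reference_los_days=ref_los,
        )
        historical.append(pathway)

        # --- planted truth, via the phase-tiling machinery
        verdicts: list[RuleVerdict] = []
        rule_of = {"overflow": 4, "buffer": 5, "awaiting": 6,
                   "awaiting_terminal": 6, "week_full": 7}
        for idx, item in enumerate(chain):
            planted = item["planted"] or ""
            if planted.startswith("ed_boarding"):
                verdicts.append(RuleVerdict(
                    case_id, idx,
                    stages[idx].start_ts + _td(config.ed_los_max_days),
                    stages[idx].end_ts, 1, 1))
            base = planted.split("+")[0]
            if base in rule_of:
                verdicts.append(RuleVerdict(
                    case_id, idx, stages[idx].start_ts, stages[idx].end_ts, 1,
                    rule_of[base]))
        if delayed:
            verdicts.append(RuleVerdict(
                case_id, len(chain) - 1, fit_true, trace_end, 0, 3))
        truth_entries.append(LabeledPathway(pathway, tile_phases(pathway, verdicts)))

        # --- ideal log: drop inserted stages, cap the boarding ED, truncate
        # the delayed end; absorbed intervals extend the following stage
        ideal_stages: list[Stage] = []
        cursor = t0
        for idx, item in enumerate(chain):
            planted = (item["planted"] or "").split("+")[0]
            if planted in ("overflow", "buffer", "awaiting", "week_full",
                           "awaiting_terminal"):
                continue  # absorbed by the next kept stage (or dropped)
            if planted == "ed_boarding":
                end = cursor + _td(config.ed_los_max_days)
            else:
                end = stages[idx].end_ts
            if delayed and idx == len(chain) - 1:
                end = fit_true
            label = item["label"]
            ideal_stages.append(
                Stage(
                    activity=item["unit"],
                    start_ts=cursor,
                    end_ts=end,
                    events=(
                        Event(case_id, patient_id, item["unit"], START, cursor,
                              item["resp"], label),
                        Event(case_id, patient_id, item["unit"], COMPLETE, end,
                              item["resp"], label),
                    ),
                    responsible_unit=item["resp"],
                    transfer_label=label,
                )
            )
            cursor = end
        ideal.append(
            PatientPathway(
                patient_id=patient_id,
                stay_id=case_id,
                trace=Trace(case_id=case_id, stages=ideal_stages),
                discharge_disposition=disposition,
                fit_for_discharge_ts=None,
                reference_los_days=ref_los,
            )
        )

        if mech:
            key = "awaiting" if mech == "awaiting" else mech
            mech_counts[key] += 1
        else:
            mech_counts["none"] += 1
        if delayed:
            mech_counts["delayed_discharge"] += 1
        if boarding:
            mech_counts["ed_boarding"] += 1

    return SynthResult(
        historical=EventLog(historical),
        truth=LabeledLog(truth_entries),
        ideal=EventLog(ideal),
        registry=config.registry,
        mechanism_counts=mech_counts,
    )


# ---------------------------------------------------------------------------
# packaged mini fixture


def _fixture_case(
    case_id: str,
    patient_id: str,
    stage_specs: list[tuple],
    disposition: str = "home",
    fit: Optional[datetime] = None,
    ref_los: Optional[float] = None,
) -> PatientPathway:
    stages = []
    for unit, start, end, resp, label in stage_specs:
        s, e = datetime.fromisoformat(start), datetime.fromisoformat(end)
        stages.append(
            Stage(
                activity=unit,
                start_ts=s,
                end_ts=e,
                events=(
                    Event(case_id, patient_id, unit, START, s, resp, label),
                    Event(case_id, patient_id, unit, COMPLETE, e, resp, label),
                ),
                responsible_unit=resp,
                transfer_label=label,
            )
        )
    return PatientPathway(
        patient_id=patient_id,
        stay_id=case_id,
        trace=Trace(case_id=case_id, stages=stages),
        discharge_disposition=disposition,
        fit_for_discharge_ts=fit,
        reference_los_days=ref_los,
    )


def fixture_ghbs_mini() -> tuple[EventLog, UnitRegistry, LabeledLog]:
    """A deterministic 20-case log covering every rule at least once,
    together with its planted truth labeling.

    Case ``00000056098`` reproduces the canonical worked pathway: ED arrival
    Jan 4 5:36 AM, observation unit awaiting a bed, inter-site transfer to
    geriatrics (with a 30-minute travel gap), medically fit Jan 10 2 PM,
    discharged home Jan 12 1:30 PM.
    """
    registry = default_registry()
    fig2_fit = datetime(2021, 1, 10, 14, 0)
    specs: list[tuple] = [
        # (case, stages, disposition, fit, ref_los, planted verdicts)
        ("00000056098", [
            ("ED", "2021-01-04T05:36", "2021-01-04T10:13", None, None),
            ("OU", "2021-01-04T10:13", "2021-01-05T09:45", None, AWAITING_BED),
            ("GERIATRICS", "2021-01-05T10:15", "2021-01-12T13:30", "GERIATRICS", None),
        ], "home", fig2_fit, 9.0,
            [(1, "full", 1, 6, None), (2, "tail", 0, 3, fig2_fit)]),
        ("C02", [
            ("ED", "2021-01-05T08:00", "2021-01-06T00:00", None, None),
            ("CARDIOLOGY", "2021-01-06T00:00", "2021-01-09T00:00", "CARDIOLOGY", None),
        ], "home", None, 5.0,
            [(0, "from", 1, 1, datetime(2021, 1, 5, 18, 0))]),
        ("C03", [
            ("ED", "2021-01-06T09:00", "2021-01-06T13:00", None, None),
            ("PULMONOLOGY", "2021-01-06T13:00", "2021-01-12T13:00", "PULMONOLOGY", None),
        ], "home", None, 4.0,
            [(1, "from", 0, 2, datetime(2021, 1, 10, 9, 0))]),
        ("C04", [
            ("ED", "2021-01-07T10:00", "2021-01-07T15:00", None, None),
            ("VISCERAL_SURGERY", "2021-01-07T15:00", "2021-01-08T15:00", "CARDIOLOGY", None),
            ("CARDIOLOGY", "2021-01-08T15:00", "2021-01-12T15:00", "CARDIOLOGY", None),
        ], "home", None, 6.0,
            [(1, "full", 1, 4, None)]),
        ("C05", [
            ("ED", "2021-01-08T07:30", "2021-01-08T12:30", None, None),
            ("POLYVALENT_MEDICINE", "2021-01-08T12:30", "2021-01-11T12:30", None, None),
            ("PULMONOLOGY", "2021-01-11T12:30", "2021-01-16T12:30", "PULMONOLOGY", None),
        ], "home", None, 9.0,
            [(1, "full", 1, 5, None)]),
        ("C06", [
            ("ED", "2021-01-09T20:00", "2021-01-10T02:00", None, None),
            ("OU", "2021-01-10T02:00", "2021-01-10T20:00", None, AWAITING_BED),
        ], "home", None, 2.0,
            [(1, "full", 1, 6, None)]),
        ("C07", [
            ("ED", "2021-01-10T11:00", "2021-01-10T16:00", None, None),
            ("CARDIOLOGY_WEEK", "2021-01-10T16:00", "2021-01-12T16:00", None, None),
            ("CARDIOLOGY", "2021-01-12T16:00", "2021-01-16T16:00", "CARDIOLOGY", None),
        ], "home", None, 7.0,
            [(1, "full", 1, 7, None)]),
    ]
    relevant: list[tuple] = [
        ("C08", [("ED", "2021-01-11T06:00", "2021-01-11T10:00", None, None),
                 ("OU", "2021-01-11T10:00", "2021-01-11T22:00", None, "observation")],
         "home", None, 1.0, []),
        ("C09", [("ED", "2021-01-12T14:00", "2021-01-12T19:00", None, None),
                 ("GERIATRICS", "2021-01-12T19:00", "2021-01-20T19:00", "GERIATRICS", None)],
         "rehabilitation", None, 9.0, []),
        ("C10", [("ED", "2021-01-13T03:00", "2021-01-13T07:00", None, None),
                 ("ICU", "2021-01-13T07:00", "2021-01-16T07:00", "ICU", None),
                 ("NEUROLOGY", "2021-01-16T07:00", "2021-01-21T07:00", "NEUROLOGY", None)],
         "home", None, 9.0, []),
        ("C11", [("ED", "2021-01-14T12:00", "2021-01-14T17:00", None, None),
                 ("ORTHO_SURGERY", "2021-01-14T17:00", "2021-01-18T17:00", "ORTHO_SURGERY", None)],
         "home", None, 5.0, []),
        ("C12", [("ED", "2021-01-15T09:00", "2021-01-15T13:00", None, None),
                 ("POLYVALENT_MEDICINE", "2021-01-15T13:00", "2021-01-24T13:00", None, None)],
         "home", None, 10.0, []),
        ("C13", [("ED", "2021-01-16T10:00", "2021-01-16T14:00", None, None),
                 ("HEPATOGASTRO", "2021-01-16T14:00", "2021-01-21T14:00", "HEPATOGASTRO", None)],
         "home", None, 6.0, []),
        ("C14", [("ED", "2021-01-17T22:00", "2021-01-18T02:00", None, None),
                 ("CCU", "2021-01-18T02:00", "2021-01-20T02:00", "CCU", None)],
         "transfer", None, 3.0, []),
        ("C15", [("ED", "2021-01-18T08:00", "2021-01-18T12:00", None, None),
                 ("NEPHROLOGY", "2021-01-18T12:00", "2021-01-22T12:00", "NEPHROLOGY", None),
                 ("ONCOLOGY", "2021-01-22T12:00", "2021-01-28T12:00", "ONCOLOGY", None)],
         "home", None, 11.0, []),
        ("C16", [("ED", "2021-01-19T15:00", "2021-01-19T19:00", None, None),
                 ("POST_EMERGENCY", "2021-01-19T19:00", "2021-01-23T19:00", None, None)],
         "home", None, 5.0, []),
        ("C17", [("ED", "2021-01-20T07:00", "2021-01-20T11:00", None, None),
                 ("SEASONAL_UNIT", "2021-01-20T11:00", "2021-01-25T11:00", None, None)],
         "home", None, 6.0, []),
        ("C18", [("ED", "2021-01-21T13:00", "2021-01-21T17:00", None, None),
                 ("RHEUMATOLOGY", "2021-01-21T17:00", "2021-01-26T17:00", "RHEUMATOLOGY", None)],
         "home", None, 6.0, []),
        ("C19", [("ED", "2021-01-22T05:00", "2021-01-22T09:00", None, None),
                 ("OU", "2021-01-22T09:00", "2021-01-22T20:00", None, "back home within 24 h")],
         "home", None, 1.0, []),
        ("C20", [("ED", "2021-01-23T18:00", "2021-01-23T22:00", None, None),
                 ("PULMONOLOGY", "2021-01-23T22:00", "2021-01-29T22:00", "PULMONOLOGY", None)],
         "home", None, 7.0, []),
    ]
    pathways, truth_entries = [], []
    for case_id, stage_specs, dispo, fit, ref, planted in specs + relevant:
        pw = _fixture_case(case_id, f"P{case_id}", stage_specs, dispo, fit, ref)
        verdicts = []
        for idx, kind, level, rule_id, anchor in planted:
            stage = pw.trace.stages[idx]
            if kind == "full":
                lo, hi = stage.start_ts, stage.end_ts
            elif kind == "tail":
                lo, hi = anchor, stage.end_ts
            else:  # "from": anchor is the split instant
                lo, hi = anchor, stage.end_ts
            verdicts.append(RuleVerdict(case_id, idx, lo, hi, level, rule_id))
        truth_entries.append(LabeledPathway(pw, tile_phases(pw, verdicts)))
        pathways.append(pw)
    return EventLog(pathways), registry, LabeledLog(truth_entries)
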