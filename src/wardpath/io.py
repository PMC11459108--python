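"""Readers and writers for event logs, stay attributes, unit registries and
rule configuration.

CSV is the canonical interchange format (a hospital information system
extract is tabular by nature); XES is export-only, for interoperability with
process-mining suites.  Stay attributes live in a separate CSV keyed by
case id, mirroring the three administrative data sources the pipeline
consumes (patient record extract, billing attributes, discharge planning).
"""

from __future__ import annotations

import enum
import importlib.resources
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import timedelta
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
import yaml

from .model import (
    COMPLETE,
    START,
    Event,
    EventLog,
    PatientPathway,
    Trace,
    build_stages,
)


class ParseError(ValueError):
    """Schema or value error in an input file, pointing at the offending row."""


class UnitCategory(str, enum.Enum):
    ED = "ED"
    OBSERVATION = "OBSERVATION"
    POLYVALENT = "POLYVALENT"
    POST_EMERGENCY = "POST_EMERGENCY"
    SPECIALIZED_MED = "SPECIALIZED_MED"
    SURGERY = "SURGERY"
    ICU = "ICU"
    DAY_WEEK = "DAY_WEEK"
    SEASONAL = "SEASONAL"
    CCU = "CCU"


#: categories that can act as a buffer in front of a specialized unit
BUFFER_CATEGORIES = frozenset(
    {UnitCategory.POLYVALENT, UnitCategory.POST_EMERGENCY, UnitCategory.OBSERVATION}
)
#: categories counting as a specialized destination ward
SPECIALIZED_CATEGORIES = frozenset(
    {UnitCategory.SPECIALIZED_MED, UnitCategory.SURGERY, UnitCategory.ICU, UnitCategory.CCU}
)


@dataclass(frozen=True)
class Unit:
    unit_id: str
    name: str = ""
    site: str = ""
    category: UnitCategory = UnitCategory.SPECIALIZED_MED
    specialty: str = ""
    mode: str = "full"  # full | day | week

    def __post_init__(self):
        if self.mode not in ("full", "day", "week"):
            raise ValueError(f"unit {self.unit_id!r}: mode must be full/day/week")


class UnitRegistry:
    """Maps unit ids to category, specialty, site and hospitalization mode."""

    def __init__(self, units: Iterable[Unit] = ()):
        self._units: dict[str, Unit] = {}
        for u in units:
            if u.unit_id in self._units:
                raise ValueError(f"duplicate unit id {u.unit_id!r}")
            self._units[u.unit_id] = u

    def __contains__(self, unit_id: str) -> bool:
        return unit_id in self._units

    def __iter__(self):
        return iter(self._units.values())

    def __len__(self) -> int:
        return len(self._units)

    def __getitem__(self, unit_id: str) -> Unit:
        try:
            return self._units[unit_id]
        except KeyError:
            raise KeyError(f"unit {unit_id!r} not in registry") from None

    def category(self, unit_id: str) -> UnitCategory:
        return self[unit_id].category

    def mode(self, unit_id: str) -> str:
        return self[unit_id].mode

    def specialty(self, unit_id: str) -> str:
        return self[unit_id].specialty

    def site(self, unit_id: str) -> str:
        return self[unit_id].site

    def resolve(self, activities: Iterable[str]) -> list[str]:
        """Return the activities that do NOT resolve to a registry entry."""
        return sorted({a for a in activities if a not in self._units})

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "UnitRegistry":
        df = pd.read_csv(path, dtype=str).fillna("")
        required = {"unit_id", "category"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"unit registry {path}: missing columns {sorted(missing)}")
        units = []
        for i, row in df.iterrows():
            try:
                cat = UnitCategory(row["category"])
            except ValueError:
                raise ParseError(
                    f"unit registry {path} row {i + 2}: unknown category "
                    f"{row['category']!r}"
                ) from None
            units.append(
                Unit(
                    unit_id=row["unit_id"],
                    name=row.get("name", ""),
                    site=row.get("site", ""),
                    category=cat,
                    specialty=row.get("specialty", ""),
                    mode=row.get("mode", "full") or "full",
                )
            )
        return cls(units)

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            [
                {
                    "unit_id": u.unit_id,
                    "name": u.name,
                    "site": u.site,
                    "category": u.category.value,
                    "specialty": u.specialty,
                    "mode": u.mode,
                }
                for u in self
            ]
        ).to_csv(path, index=False)


@dataclass
class RuleConfig:
    """Thresholds and switches for the relevance rules.

    ``ed_los_max`` — maximum acceptable ED stay (experts bound it at 5-10 h;
    default the permissive end, 10 h).  ``buffer_window`` — a buffer-unit stay
    transferred onward within this window is flagged (7.5 days: one week plus
    half a day of transfer time).  ``los_excess_factor`` — multiplier on the
    national per-DRG reference length of stay for the excess-stay rule.
    """

    ed_los_max: timedelta = timedelta(hours=10)
    buffer_window: timedelta = timedelta(days=7.5)
    awaiting_bed_label: str = "awaiting bed"
    los_excess_factor: float = 1.0
    enabled_rules: frozenset[int] = frozenset({3, 4, 5, 6, 7})
    require_specialized_successor: bool = True
    profile: str = "validated"

    def __post_init__(self):
        self.enabled_rules = frozenset(self.enabled_rules)
        if not self.enabled_rules <= frozenset(range(1, 8)):
            raise ValueError("enabled_rules must be a subset of {1..7}")
        if self.ed_los_max <= timedelta(0) or self.buffer_window <= timedelta(0):
            raise ValueError("rule thresholds must be positive durations")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RuleConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RuleConfig":
        kwargs = {}
        if "ed_los_max_hours" in raw:
            kwargs["ed_los_max"] = timedelta(hours=float(raw["ed_los_max_hours"]))
        if "buffer_window_days" in raw:
            kwargs["buffer_window"] = timedelta(days=float(raw["buffer_window_days"]))
        for key in (
            "awaiting_bed_label",
            "los_excess_factor",
            "require_specialized_successor",
            "profile",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "enabled_rules" in raw:
            kwargs["enabled_rules"] = frozenset(int(r) for r in raw["enabled_rules"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "profile": self.profile,
            "ed_los_max_hours": self.ed_los_max / timedelta(hours=1),
            "buffer_window_days": self.buffer_window / timedelta(days=1),
            "awaiting_bed_label": self.awaiting_bed_label,
            "los_excess_factor": self.los_excess_factor,
            "enabled_rules": sorted(self.enabled_rules),
            "require_specialized_successor": self.require_specialized_successor,
        }


def load_profile(name: str) -> RuleConfig:
    """Load a shipped rule profile: ``validated`` (rules 3-7) or ``full``."""
    res = importlib.resources.files("wardpath") / "profiles" / f"{name}.yaml"
    if not res.is_file():
        raise FileNotFoundError(f"no shipped rule profile named {name!r}")
    return RuleConfig.from_dict(yaml.safe_load(res.read_text()))


EVENT_COLUMNS = [
    "case_id",
    "patient_id",
    "activity",
    "transaction",
    "timestamp",
    "responsible_unit",
    "transfer_label",
]
STAY_COLUMNS = [
    "case_id",
    "patient_id",
    "discharge_disposition",
    "fit_for_discharge_ts",
    "reference_los_days",
    "drg_code",
]


def _opt(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return str(value)


def read_event_log(
    path: Union[str, Path],
    stays_path: Optional[Union[str, Path]] = None,
    registry: Optional[UnitRegistry] = None,
    *,
    permissive: bool = False,
) -> EventLog:
    """Read an event CSV (and optional stay-attribute CSV) into an EventLog.

    Every activity must resolve against ``registry`` when one is given.
    Raises :class:`ParseError` naming the offending row on schema errors.
    """
    df = pd.read_csv(path, dtype=str)
    missing = {"case_id", "activity", "transaction", "timestamp"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad = df[~df["transaction"].isin([START, COMPLETE])]
    if len(bad):
        row = int(bad.index[0]) + 2  # header + 1-based
        raise ParseError(
            f"{path} row {row}: transaction must be start/complete, "
            f"got {bad.iloc[0]['transaction']!r}"
        )
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: unparseable timestamp ({exc})") from None
    df = df.assign(_ts=ts)

    stays: dict[str, dict] = {}
    if stays_path is not None:
        sdf = pd.read_csv(stays_path, dtype=str)
        if "case_id" not in sdf.columns:
            raise ParseError(f"{stays_path}: missing column 'case_id'")
        for _, row in sdf.iterrows():
            fit = _opt(row.get("fit_for_discharge_ts"))
            ref = _opt(row.get("reference_los_days"))
            stays[row["case_id"]] = {
                "patient_id": _opt(row.get("patient_id")) or "",
                "discharge_disposition": _opt(row.get("discharge_disposition")) or "",
                "fit_for_discharge_ts": pd.to_datetime(fit).to_pydatetime()
                if fit
                else None,
                "reference_los_days": float(ref) if ref else None,
                "drg_code": _opt(row.get("drg_code")),
            }

    pathways = []
    for case_id, group in df.groupby("case_id", sort=True):
        events = [
            Event(
                case_id=str(case_id),
                patient_id=_opt(row.get("patient_id")) or "",
                activity=row["activity"],
                transaction=row["transaction"],
                timestamp=row["_ts"].to_pydatetime(),
                responsible_unit=_opt(row.get("responsible_unit")),
                transfer_label=_opt(row.get("transfer_label")),
            )
            for _, row in group.iterrows()
        ]
        stages = build_stages(events, permissive=permissive)
        attrs = stays.get(str(case_id), {})
        pathways.append(
            PatientPathway(
                patient_id=attrs.get("patient_id") or (events[0].patient_id if events else ""),
                stay_id=str(case_id),
                trace=Trace(case_id=str(case_id), stages=stages),
                discharge_disposition=attrs.get("discharge_disposition", ""),
                fit_for_discharge_ts=attrs.get("fit_for_discharge_ts"),
                reference_los_days=attrs.get("reference_los_days"),
                drg_code=attrs.get("drg_code"),
            )
        )
    log = EventLog(pathways)
    if registry is not None:
        unknown = registry.resolve(log.units)
        if unknown:
            raise ParseError(f"{path}: activities not in unit registry: {unknown}")
    return log


def _event_rows(log: EventLog) -> list[dict]:
    rows = []
    for pathway in log:
        for stage in pathway.trace.stages:
            for trans, when in ((START, stage.start_ts), (COMPLETE, stage.end_ts)):
                rows.append(
                    {
                        "case_id": pathway.case_id,
                        "patient_id": pathway.patient_id,
                        "activity": stage.activity,
                        "transaction": trans,
                        "timestamp": when.isoformat(),
                        "responsible_unit": stage.responsible_unit or "",
                        "transfer_label": stage.transfer_label or "",
                    }
                )
    return rows


def write_event_log(log, path: Union[str, Path], include_labels: bool = False) -> None:
    """Serialize a log to CSV.

    With ``include_labels`` the argument must be a labeled log (see
    :mod:`wardpath.labeling`); each phase contributes a start and a complete
    row carrying the relevance level and the semicolon-joined firing rules.
    """
    if include_labels:
        rows = log.to_event_rows()  # LabeledLog
        cols = ["case_id", "patient_id", "activity", "transaction", "timestamp",
                "level", "rule_ids", "stage_index"]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    else:
        pd.DataFrame(_event_rows(log), columns=EVENT_COLUMNS).to_csv(path, index=False)


def write_stays(log: EventLog, path: Union[str, Path]) -> None:
    rows = [
        {
            "case_id": p.case_id,
            "patient_id": p.patient_id,
            "discharge_disposition": p.discharge_disposition,
            "fit_for_discharge_ts": p.fit_for_discharge_ts.isoformat()
            if p.fit_for_discharge_ts
            else "",
            "reference_los_days": p.reference_los_days
            if p.reference_los_days is not None
            else "",
            "drg_code": p.drg_code or "",
        }
        for p in log
    ]
    pd.DataFrame(rows, columns=STAY_COLUMNS).to_csv(path, index=False)


_XES_NS = "http://www.xes-standard.org/"


def write_xes(log, path: Union[str, Path], labels: Optional[Mapping] = None) -> None:
    """Export to XES 2.0 (concept:name = unit, lifecycle:transition,
    time:timestamp; relevance as custom attribute ``relevance:level``)."""
    root = ET.Element("log", {"xes.version": "2.0", "xmlns": _XES_NS})
    for uri, prefix in (
        ("http://www.xes-standard.org/concept.xesext", "concept"),
        ("http://www.xes-standard.org/lifecycle.xesext", "lifecycle"),
        ("http://www.xes-standard.org/time.xesext", "time"),
    ):
        ET.SubElement(root, "extension", {"name": prefix, "prefix": prefix, "uri": uri})
    for pathway in log:
        tr = ET.SubElement(root, "trace")
        ET.SubElement(tr, "string", {"key": "concept:name", "value": pathway.case_id})
        levels = labels.get(pathway.case_id) if labels else None
        for stage in pathway.trace.stages:
            for trans, when in ((START, stage.start_ts), (COMPLETE, stage.end_ts)):
                ev = ET.SubElement(tr, "event")
                ET.SubElement(ev, "string", {"key": "concept:name", "value": stage.activity})
                ET.SubElement(ev, "string", {"key": "lifecycle:transition", "value": trans})
                ET.SubElement(ev, "date", {"key": "time:timestamp", "value": when.isoformat()})
                if levels is not None:
                    ET.SubElement(
                        ev, "int", {"key": "relevance:level", "value": str(int(levels))}
                    )
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)
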