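"""Variant and structure tables, and algorithm-vs-expert agreement.

The confusion matrix treats *relevant* (level 2) as the positive class, at
either stage or pathway granularity.  The first ED stage is the entry point
and is excluded at both granularities: a pathway is positive iff every stage
after the first ED visit is level 2.  Rows are the predicted labels, columns
the actual ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Union

import pandas as pd

from .io import UnitCategory, UnitRegistry
from .labeling import LabeledLog, LabeledTrace
from .model import EventLog


def variant_table(log: EventLog) -> pd.DataFrame:
    """Trace variants (exact activity sequences) with counts and percentages,
    sorted by count descending, ties broken lexicographically."""
    counts: dict[tuple[str, ...], int] = {}
    for pathway in log:
        key = tuple(pathway.trace.activities)
        counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    rows = [
        {
            "variant": ",".join(variant),
            "count": count,
            "percentage": 100.0 * count / total if total else 0.0,
        }
        for variant, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["variant", "count", "percentage"])


#: collapse of the registry categories onto the four coarse pathway groups
STRUCTURE_MAP = {
    UnitCategory.ED: "ED",
    UnitCategory.OBSERVATION: "MEDICINE",
    UnitCategory.POLYVALENT: "MEDICINE",
    UnitCategory.POST_EMERGENCY: "MEDICINE",
    UnitCategory.SEASONAL: "MEDICINE",
    UnitCategory.SPECIALIZED_MED: "MEDICINE",
    UnitCategory.DAY_WEEK: "MEDICINE",
    UnitCategory.SURGERY: "SURGERY",
    UnitCategory.ICU: "ICU",
    UnitCategory.CCU: "ICU",
}


def map_to_structure(activity: str, registry: UnitRegistry) -> str:
    if activity not in registry:
        raise KeyError(f"activity {activity!r} not in registry")
    return STRUCTURE_MAP[registry.category(activity)]


def structure_table(log: EventLog, registry: UnitRegistry) -> pd.DataFrame:
    """Variant table over the coarse category sequences (ED / MEDICINE /
    SURGERY / ICU)."""
    counts: dict[tuple[str, ...], int] = {}
    for pathway in log:
        key = tuple(map_to_structure(a, registry) for a in pathway.trace.activities)
        counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    rows = [
        {
            "variant": ",".join(variant),
            "count": count,
            "percentage": 100.0 * count / total if total else 0.0,
        }
        for variant, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["variant", "count", "percentage"])


@dataclass(frozen=True)
class ConfusionMatrix:
    """Predicted-vs-actual agreement; positive = relevant (level 2)."""

    tp: int
    fp: int
    fn: int
    tn: int
    granularity: str = "stage"

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


LabelSource = Union[LabeledLog, Mapping[str, LabeledTrace]]


def _as_mapping(source: LabelSource) -> Mapping[str, LabeledTrace]:
    if isinstance(source, LabeledLog):
        return source.by_case()
    return source


def confusion(
    pred: LabelSource, truth: LabelSource, granularity: str = "stage"
) -> ConfusionMatrix:
    """Tally predicted vs actual relevance over matching cases.

    Stage granularity: each non-first stage is one observation, positive iff
    its minimum phase level is 2.  Pathway granularity: a pathway is positive
    iff all its assessed stages are.  The case sets (and, per case, the
    assessed stage sets) must coincide.
    """
    if granularity not in ("stage", "pathway"):
        raise ValueError("granularity must be 'stage' or 'pathway'")
    pred_map, truth_map = _as_mapping(pred), _as_mapping(truth)
    if set(pred_map) != set(truth_map):
        raise ValueError(
            "prediction and truth cover different case sets: "
            f"{sorted(set(pred_map) ^ set(truth_map))[:5]} ..."
        )
    tp = fp = fn = tn = 0
    for case_id, p in pred_map.items():
        t = truth_map[case_id]
        p_levels, t_levels = p.stage_levels(), t.stage_levels()
        assessed = sorted(set(p_levels) - {0})
        if sorted(set(t_levels) - {0}) != assessed:
            raise ValueError(
                f"case {case_id}: prediction and truth disagree on the stage set"
            )
        if granularity == "stage":
            for idx in assessed:
                pp, tt = p_levels[idx] == 2, t_levels[idx] == 2
                tp += pp and tt
                fp += pp and not tt
                fn += (not pp) and tt
                tn += (not pp) and (not tt)
        else:
            pp = all(p_levels[i] == 2 for i in assessed)
            tt = all(t_levels[i] == 2 for i in assessed)
            tp += pp and tt
            fp += pp and not tt
            fn += (not pp) and tt
            tn += (not pp) and (not tt)
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn, granularity=granularity)


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    accuracy: float
    error_rate: float

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "error_rate": self.error_rate,
        }


def metrics(cm: ConfusionMatrix) -> Metrics:
    """Precision, recall, accuracy and error rate; a zero denominator yields
    NaN (undefined), never an exception."""

    def ratio(num: int, den: int) -> float:
        return num / den if den else math.nan

    accuracy = ratio(cm.tp + cm.tn, cm.total)
    return Metrics(
        precision=ratio(cm.tp, cm.tp + cm.fp),
        recall=ratio(cm.tp, cm.tp + cm.fn),
        accuracy=accuracy,
        error_rate=1.0 - accuracy if not math.isnan(accuracy) else math.nan,
    )
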