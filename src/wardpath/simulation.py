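"""Infinite-capacity occupancy simulation of patient flow.

The model replays the log's admissions against sampled lengths of stay
(LoS): every patient arrives at their logged arrival instant, visits their
trace's units in order with no transfer delay, and each visit's LoS is drawn
from the unit's fitted distribution, truncated by resampling at a cap (28
days in a ward, 24 hours in the ED) so the heavy log-normal tail cannot
produce implausible stays.  Capacities are infinite — the question answered
is *how many beds would have been needed*, not who gets blocked — which
makes the system an infinite-server queue per unit: no event calendar is
needed and occupancy reduces to interval-overlap arithmetic, computed
exactly as the time-weighted mean number of patients present after the
warm-up period.

Replications differ only in the LoS draws (arrivals are fixed, as in the
source data); reports carry 95% t-based confidence intervals across
replications.  Scenario comparisons reuse the same replication seeds and
draw each unit's samples in a fixed visit order (common random numbers), so
paired deltas are tighter than independent runs would give.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from datetime import timedelta
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import scipy.stats

from .analytics import variant_table
from .io import UnitCategory, UnitRegistry
from .model import EventLog

logger = logging.getLogger(__name__)

DAY_SECONDS = 86400.0


@dataclass(frozen=True)
class LosSpec:
    """A fitted (or imposed) per-unit length-of-stay distribution.

    ``family`` is a ``scipy.stats`` distribution name (``lognorm``,
    ``gamma``, ...) with ``params`` the full ``fit`` parameter tuple, or
    ``fixed`` with a single constant duration in days.
    """

    family: str
    params: tuple[float, ...]
    n: int = 0
    empirical_mean_days: float = math.nan

    def frozen(self):
        if self.family == "fixed":
            return None
        return getattr(scipy.stats, self.family)(*self.params)

    def sample(self, size: int, rng: np.random.Generator, cap: float) -> np.ndarray:
        """Draw ``size`` values truncated at ``cap`` by resampling (no atom
        at the cap)."""
        if self.family == "fixed":
            return np.full(size, min(self.params[0], cap))
        dist = self.frozen()
        out = np.asarray(dist.rvs(size=size, random_state=rng), dtype=float)
        for _ in range(1000):
            bad = (out > cap) | (out <= 0)
            if not bad.any():
                break
            out[bad] = dist.rvs(size=int(bad.sum()), random_state=rng)
        else:
            raise RuntimeError(
                f"LoS resampling did not converge below cap {cap} for {self.family}"
            )
        return out


#: candidate families compared by maximum likelihood + AIC
_CANDIDATES: dict[str, dict] = {
    "norm": {},
    "gamma": {"floc": 0},
    "lognorm": {"floc": 0},
    "weibull_min": {"floc": 0},
    "exponweib": {"floc": 0},
    "beta": {"floc": 0},
}


def aic(dist_name: str, params: tuple[float, ...], data: np.ndarray, k: int) -> float:
    """Akaike information criterion 2k − 2·logL for a fitted family."""
    dist = getattr(scipy.stats, dist_name)
    loglik = np.sum(dist.logpdf(data, *params))
    if not np.isfinite(loglik):
        return math.inf
    return 2 * k - 2 * float(loglik)


def _fit_family(name: str, data: np.ndarray) -> Optional[tuple[tuple, float]]:
    kwargs = dict(_CANDIDATES[name])
    if name == "beta":
        kwargs["fscale"] = float(data.max()) * 1.001
    try:
        with np.errstate(all="ignore"):
            params = getattr(scipy.stats, name).fit(data, **kwargs)
        k = len(params) - len(kwargs)  # free parameters only
        return params, aic(name, params, data, k)
    except Exception:  # a family that cannot fit the sample is just skipped
        return None


def fit_one(data: np.ndarray) -> LosSpec:
    """Select the best family for one duration sample by AIC."""
    data = np.asarray(data, dtype=float)
    data = data[data > 0]
    if len(data) == 0:
        raise ValueError("no positive durations to fit")
    if float(np.std(data)) == 0.0:
        raise ValueError("degenerate variance: all durations identical")
    best_name, best_params, best_aic = None, None, math.inf
    for name in _CANDIDATES:
        fitted = _fit_family(name, data)
        if fitted is None:
            continue
        params, score = fitted
        if score < best_aic:
            best_name, best_params, best_aic = name, params, score
    if best_name is None:
        raise ValueError("no candidate distribution could be fitted")
    return LosSpec(
        family=best_name,
        params=tuple(float(p) for p in best_params),
        n=len(data),
        empirical_mean_days=float(np.mean(data)),
    )


def stage_durations_by_unit(log: EventLog) -> dict[str, np.ndarray]:
    """Per-unit stage durations in days."""
    per_unit: dict[str, list[float]] = {}
    for pathway in log:
        for stage in pathway.trace.stages:
            d = stage.duration.total_seconds() / DAY_SECONDS
            if d > 0:
                per_unit.setdefault(stage.activity, []).append(d)
    return {u: np.asarray(v) for u, v in per_unit.items()}


def fit_los(log: EventLog, min_samples: int = 30) -> dict[str, LosSpec]:
    """Fit every unit's LoS distribution by maximum likelihood and AIC
    ranking; units with fewer than ``min_samples`` positive durations fall
    back to a pooled fit (with a logged warning)."""
    per_unit = stage_durations_by_unit(log)
    pooled_spec: Optional[LosSpec] = None
    specs: dict[str, LosSpec] = {}
    for unit, durations in sorted(per_unit.items()):
        if len(durations) < min_samples:
            if pooled_spec is None:
                pooled = np.concatenate(list(per_unit.values()))
                pooled_spec = fit_one(pooled)
            logger.warning(
                "unit %s has %d LoS samples (<%d); using pooled fit",
                unit, len(durations), min_samples,
            )
            specs[unit] = replace(
                pooled_spec,
                n=len(durations),
                empirical_mean_days=float(np.mean(durations)),
            )
        else:
            specs[unit] = fit_one(durations)
    return specs


@dataclass
class SimConfig:
    """Run settings for the occupancy simulation.

    Durations are in days.  ``horizon_days`` defaults to the span of the
    input log.  ``los_model`` may impose per-unit distributions; otherwise
    they are fitted from the simulated log itself.
    """

    warmup_days: float = 60.0
    replications: int = 15
    los_cap_days: float = 28.0
    ed_cap_days: float = 1.0
    seed: int = 0
    horizon_days: Optional[float] = None
    los_model: Optional[Mapping[str, LosSpec]] = None
    daily_sampling: bool = False  # midnight census instead of time average

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if self.los_cap_days <= 0 or self.ed_cap_days <= 0:
            raise ValueError("LoS caps must be positive")


@dataclass
class OccupancyReport:
    """Per-unit mean patients present (post-warm-up) with replication CIs."""

    per_unit: pd.DataFrame  # index unit; mean, sd, ci_low, ci_high, ...
    replications: int
    warmup_days: float
    horizon_days: float
    seed: int

    @property
    def total_mean(self) -> float:
        return float(self.per_unit["mean"].sum())

    @property
    def max_rel_half_width(self) -> float:
        return float(self.per_unit["rel_half_width"].max())

    @property
    def mean_rel_half_width(self) -> float:
        return float(self.per_unit["rel_half_width"].mean())

    def to_csv(self, path) -> None:
        self.per_unit.to_csv(path, index_label="unit")


def filter_for_sim(
    log: EventLog,
    registry: UnitRegistry,
    max_stages: int = 3,
    min_variant_coverage: float = 0.001,
    site: Optional[str] = None,
) -> EventLog:
    """Apply the simulation inclusion criteria: at most ``max_stages``
    stages, no day/week-mode unit, variant coverage at or above the
    threshold, and (optionally) every unit on the given site."""
    vt = variant_table(log)
    coverage = dict(zip(vt["variant"], vt["percentage"] / 100.0))
    kept = []
    for pathway in log:
        acts = pathway.trace.activities
        if not acts or len(acts) > max_stages:
            continue
        if any(a in registry and registry.mode(a) in ("day", "week") for a in acts):
            continue
        if site is not None and any(
            a not in registry or registry.site(a) != site for a in acts
        ):
            continue
        if coverage.get(",".join(acts), 0.0) < min_variant_coverage:
            continue
        kept.append(pathway)
    return EventLog(kept)


def _visit_arrays(log: EventLog):
    """Flatten the log to padded (unit_code, arrival_day) arrays; t=0 at the
    earliest admission."""
    if not len(log):
        raise ValueError("cannot simulate an empty log")
    origin = min(p.trace.start_ts for p in log if p.trace.stages)
    units = sorted({a for p in log for a in p.trace.activities})
    code = {u: i for i, u in enumerate(units)}
    k = max(len(p.trace.stages) for p in log)
    n = len(log)
    unit_mat = np.full((n, k), -1, dtype=np.int64)
    arrivals = np.zeros(n)
    for i, pathway in enumerate(sorted(log, key=lambda p: p.case_id)):
        arrivals[i] = (pathway.trace.start_ts - origin).total_seconds() / DAY_SECONDS
        for j, stage in enumerate(pathway.trace.stages):
            unit_mat[i, j] = code[stage.activity]
    return units, unit_mat, arrivals


def simulate(
    log: EventLog, registry: UnitRegistry, config: SimConfig
) -> OccupancyReport:
    """Run the infinite-capacity replication study on one log.

    Returns the per-unit time-averaged occupancy over the post-warm-up
    horizon with 95% confidence intervals across replications.  Fully
    reproducible from ``config.seed``.
    """
    units, unit_mat, arrivals = _visit_arrays(log)
    specs = dict(config.los_model) if config.los_model is not None else fit_los(log)
    missing = [u for u in units if u not in specs]
    if missing:
        raise ValueError(f"no LoS model for units {missing}")
    horizon = config.horizon_days
    if horizon is None:
        end = max(p.trace.end_ts for p in log if p.trace.stages)
        start = min(p.trace.start_ts for p in log if p.trace.stages)
        horizon = (end - start).total_seconds() / DAY_SECONDS
    if horizon <= config.warmup_days:
        raise ValueError(
            f"horizon ({horizon:.1f} d) must exceed warm-up ({config.warmup_days} d)"
        )

    def cap_for(unit: str) -> float:
        if unit in registry and registry.category(unit) == UnitCategory.ED:
            return config.ed_cap_days
        return config.los_cap_days

    n, k = unit_mat.shape
    window = horizon - config.warmup_days
    occ = np.zeros((config.replications, len(units)))
    sim_los = np.zeros((config.replications, len(units)))
    for rep in range(config.replications):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, rep]))
        los = np.zeros((n, k))
        # per-unit draws in fixed visit order: common random numbers across
        # scenarios sharing the seed
        for ui, unit in enumerate(units):
            mask = unit_mat == ui
            m = int(mask.sum())
            if m == 0:
                continue
            draws = specs[unit].sample(m, rng, cap_for(unit))
            los[mask] = draws
            sim_los[rep, ui] = float(np.mean(draws))
        starts = arrivals[:, None] + np.cumsum(los, axis=1) - los
        ends = starts + los
        if config.daily_sampling:
            days = np.arange(math.ceil(config.warmup_days), math.floor(horizon) + 1)
            for ui in range(len(units)):
                mask = unit_mat == ui
                s, e = starts[mask], ends[mask]
                present = (s[None, :] <= days[:, None]) & (e[None, :] > days[:, None])
                occ[rep, ui] = present.sum(axis=1).mean()
        else:
            overlap = np.clip(
                np.minimum(ends, horizon) - np.maximum(starts, config.warmup_days),
                0.0,
                None,
            )
            for ui in range(len(units)):
                occ[rep, ui] = overlap[unit_mat == ui].sum() / window

    mean = occ.mean(axis=0)
    if config.replications > 1:
        sd = occ.std(axis=0, ddof=1)
        tcrit = scipy.stats.t.ppf(0.975, config.replications - 1)
        half = tcrit * sd / math.sqrt(config.replications)
    else:
        sd = np.full(len(units), math.nan)
        half = np.full(len(units), math.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, half / mean, np.nan)
    per_unit = pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "ci_low": mean - half,
            "ci_high": mean + half,
            "half_width": half,
            "rel_half_width": rel,
            "sim_mean_los_days": sim_los.mean(axis=0),
        },
        index=pd.Index(units, name="unit"),
    )
    return OccupancyReport(
        per_unit=per_unit,
        replications=config.replications,
        warmup_days=config.warmup_days,
        horizon_days=float(horizon),
        seed=config.seed,
    )


def compare_scenarios(
    historical: EventLog,
    corrected: EventLog,
    registry: UnitRegistry,
    config: SimConfig,
) -> tuple[OccupancyReport, OccupancyReport, pd.DataFrame]:
    """Simulate both scenarios with common random numbers and report
    per-unit occupancy deltas (corrected − historical)."""
    r1 = simulate(historical, registry, config)
    r2 = simulate(corrected, registry, config)
    units = sorted(set(r1.per_unit.index) | set(r2.per_unit.index))
    m1 = r1.per_unit["mean"].reindex(units).fillna(0.0)
    m2 = r2.per_unit["mean"].reindex(units).fillna(0.0)
    deltas = pd.DataFrame(
        {"historical": m1, "corrected": m2, "delta": m2 - m1},
        index=pd.Index(units, name="unit"),
    )
    return r1, r2, deltas


def validate_sim(report: OccupancyReport, log: EventLog) -> float:
    """Mean absolute error (days) between simulated and empirical mean LoS
    per unit; the unit sets must coincide."""
    empirical = {u: float(np.mean(d)) for u, d in stage_durations_by_unit(log).items()}
    sim_units = set(report.per_unit.index)
    if sim_units != set(empirical):
        raise ValueError(
            "report and log cover different unit sets: "
            f"{sorted(sim_units ^ set(empirical))}"
        )
    errors = [
        abs(report.per_unit.loc[u, "sim_mean_los_days"] - empirical[u])
        for u in sorted(sim_units)
    ]
    return float(np.mean(errors))
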