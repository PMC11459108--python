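"""The seven relevance rules, each against its oracle or boundary cases."""

from datetime import datetime, timedelta

import pytest

from wardpath import RuleConfig, run_rules
from wardpath.rules import (
    rule1_ed_boarding,
    rule2_excess_los,
    rule3_delayed_discharge,
    rule4_overflow_bed,
    rule5_buffer_unit,
    rule6_ou_awaiting_bed,
    rule7_day_week_before_full,
)

from conftest import make_pathway

T0 = datetime(2021, 3, 1, 8, 0)
H = timedelta(hours=1)
D = timedelta(days=1)
CFG = RuleConfig()


class TestRule1:
    def test_below_threshold(self):
        p = make_pathway([("ED", T0, T0 + timedelta(hours=4, minutes=37))])
        assert rule1_ed_boarding(p, CFG) == []

    def test_exact_threshold_compliant(self):
        p = make_pathway([("ED", T0, T0 + 10 * H)])
        assert rule1_ed_boarding(p, CFG) == []

    def test_excess_flagged(self):
        p = make_pathway([("ED", T0, T0 + 16 * H),
                          ("CARDIOLOGY", T0 + 16 * H, T0 + 16 * H + 2 * D)])
        (v,) = rule1_ed_boarding(p, CFG)
        assert v.level == 1 and v.rule_id == 1
        assert v.from_ts == T0 + 10 * H and v.to_ts == T0 + 16 * H
        assert v.to_ts - v.from_ts == 6 * H


class TestRule2:
    def test_under_reference(self):
        p = make_pathway([("ED", T0, T0 + 4 * H),
                          ("GERIATRICS", T0 + 4 * H, T0 + 6 * D)], ref=8.0)
        assert rule2_excess_los(p, CFG) == []

    def test_trailing_excess(self):
        p = make_pathway([("ED", T0, T0 + 4 * H),
                          ("GERIATRICS", T0 + 4 * H, T0 + 10 * D)], ref=8.0)
        (v,) = rule2_excess_los(p, CFG)
        assert v.level == 0 and v.stage_index == 1
        assert v.to_ts == T0 + 10 * D
        assert v.to_ts - v.from_ts == 2 * D

    def test_infinite_factor_disables(self):
        cfg = RuleConfig(los_excess_factor=float("inf"))
        p = make_pathway([("ED", T0, T0 + 4 * H),
                          ("GERIATRICS", T0 + 4 * H, T0 + 40 * D)], ref=1.0)
        assert rule2_excess_los(p, cfg) == []

    def test_missing_reference_skips(self, caplog):
        p = make_pathway([("ED", T0, T0 + 40 * D)])
        assert rule2_excess_los(p, CFG) == []


class TestRule3:
    def test_worked_pathway(self, fig2_pathway):
        """Fit Jan 10 2 PM, discharge Jan 12 1:30 PM: a 47.5 h level-0 phase
        on the geriatrics stage."""
        (v,) = rule3_delayed_discharge(fig2_pathway)
        assert v.level == 0 and v.stage_index == 2
        assert v.to_ts - v.from_ts == timedelta(hours=47, minutes=30)

    def test_absent_fit(self):
        p = make_pathway([("ED", T0, T0 + 4 * H)])
        assert rule3_delayed_discharge(p) == []

    def test_fit_at_end_boundary(self):
        p = make_pathway([("ED", T0, T0 + 4 * H)], fit=T0 + 4 * H)
        assert rule3_delayed_discharge(p) == []

    def test_fit_after_end_raises(self):
        p = make_pathway([("ED", T0, T0 + 4 * H)], fit=T0 + 5 * H)
        with pytest.raises(ValueError, match="after trace end"):
            rule3_delayed_discharge(p)

    def test_fit_before_last_stage_clips_per_stage(self):
        p = make_pathway(
            [("ED", T0, T0 + 4 * H),
             ("ICU", T0 + 4 * H, T0 + 2 * D),
             ("CARDIOLOGY", T0 + 2 * D, T0 + 5 * D)],
            fit=T0 + 1 * D,
        )
        verdicts = rule3_delayed_discharge(p)
        assert [(v.stage_index, v.from_ts, v.to_ts) for v in verdicts] == [
            (1, T0 + 1 * D, T0 + 2 * D),
            (2, T0 + 2 * D, T0 + 5 * D),
        ]


class TestRule4:
    def test_mismatch_flagged(self):
        p = make_pathway([("ED", T0, T0 + 4 * H),
                          ("VISCERAL_SURGERY", T0 + 4 * H, T0 + 2 * D, "CARDIOLOGY")])
        (v,) = rule4_overflow_bed(p)
        assert v.level == 1 and v.correction_target == "CARDIOLOGY"
        assert (v.from_ts, v.to_ts) == (T0 + 4 * H, T0 + 2 * D)

    def test_equal_responsible_clean(self):
        p = make_pathway([("ED", T0, T0 + 4 * H),
                          ("CARDIOLOGY", T0 + 4 * H, T0 + 2 * D, "CARDIOLOGY")])
        assert rule4_overflow_bed(p) == []

    def test_planted_count(self):
        pathways = []
        for i in range(7):
            pathways.append(make_pathway(
                [("ED", T0, T0 + 4 * H),
                 ("ONCOLOGY", T0 + 4 * H, T0 + 2 * D, "CARDIOLOGY")],
                case=f"C{i}",
            ))
        assert sum(len(rule4_overflow_bed(p)) for p in pathways) == 7


class TestRule5:
    def test_buffer_flagged(self, registry):
        p = make_pathway([("ED", T0, T0 + 4 * H),
                          ("POLYVALENT_MEDICINE", T0 + 4 * H, T0 + 3 * D),
                          ("CARDIOLOGY", T0 + 3 * D, T0 + 8 * D)])
        (v,) = rule5_buffer_unit(p, registry, CFG)
        assert v.level == 1 and v.correction_target == "CARDIOLOGY"

    def test_long_stay_not_a_buffer(self, registry):
        p = make_pathway([("ED", T0, T0 + 4 * H),
                          ("POLYVALENT_MEDICINE", T0 + 4 * H, T0 + 4 * H + 9 * D),
                          ("CARDIOLOGY", T0 + 4 * H + 9 * D, T0 + 15 * D)])
        assert rule5_buffer_unit(p, registry, CFG) == []

    def test_nonspecialized_successor_requires_flag(self, registry):
        p = make_pathway([("ED", T0, T0 + 4 * H),
                          ("POST_EMERGENCY", T0 + 4 * H, T0 + 2 * D),
                          ("POLYVALENT_MEDICINE", T0 + 2 * D, T0 + 6 * D)])
        assert rule5_buffer_unit(p, registry, CFG) == []
        lax = RuleConfig(require_specialized_successor=False)
        assert len(rule5_buffer_unit(p, registry, lax)) == 1

    def test_pairwise_scan_oracle(self, registry):
        """Randomized sequences match a brute-force scan over consecutive
        stage pairs."""
        import random

        from wardpath.io import BUFFER_CATEGORIES, SPECIALIZED_CATEGORIES

        rnd = random.Random(7)
        units = ["OU", "POLYVALENT_MEDICINE", "POST_EMERGENCY", "CARDIOLOGY",
                 "ICU", "ORTHO_SURGERY", "GERIATRICS"]
        for trial in range(30):
            seq, t = [], T0
            for _ in range(rnd.randint(1, 5)):
                unit = rnd.choice(units)
                dur = timedelta(days=rnd.choice([0.5, 2, 8, 10]))
                seq.append((unit, t + 4 * H if not seq else seq[-1][2], None))
                start = seq[-1][1]
                seq[-1] = (unit, start, start + dur)
            specs = [("ED", T0, T0 + 4 * H)] + list(seq)
            p = make_pathway(specs, case=f"T{trial}")
            expected = []
            stages = p.trace.stages
            for i in range(1, len(stages) - 1):
                a, b = stages[i], stages[i + 1]
                if (
                    registry.category(a.activity) in BUFFER_CATEGORIES
                    and b.activity != a.activity
                    and a.duration <= CFG.buffer_window
                    and registry.category(b.activity) in SPECIALIZED_CATEGORIES
                ):
                    expected.append(i)
            got = [v.stage_index for v in rule5_buffer_unit(p, registry, CFG)]
            assert got == expected


class TestRule6:
    def test_awaiting_bed_flagged(self, registry, fig2_pathway):
        (v,) = rule6_ou_awaiting_bed(fig2_pathway, registry, CFG)
        assert v.level == 1 and v.correction_target == "GERIATRICS"

    def test_observation_label_clean(self, registry):
        p = make_pathway([("ED", T0, T0 + 4 * H),
                          ("OU", T0 + 4 * H, T0 + 18 * H, None, "observation")])
        assert rule6_ou_awaiting_bed(p, registry, CFG) == []

    def test_trailing_stay_has_no_target(self, registry):
        p = make_pathway([("ED", T0, T0 + 4 * H),
                          ("OU", T0 + 4 * H, T0 + 18 * H, None, "awaiting bed")])
        (v,) = rule6_ou_awaiting_bed(p, registry, CFG)
        assert v.correction_target is None


class TestRule7:
    def test_week_before_full_flagged(self, registry):
        p = make_pathway([("ED", T0, T0 + 4 * H),
                          ("CARDIOLOGY_WEEK", T0 + 4 * H, T0 + 2 * D),
                          ("CARDIOLOGY", T0 + 2 * D, T0 + 6 * D)])
        (v,) = rule7_day_week_before_full(p, registry)
        assert v.correction_target == "CARDIOLOGY"

    def test_mode_specialty_grid(self, registry):
        """Only (week-mode, full-mode, same specialty) fires."""
        from wardpath.io import Unit, UnitCategory, UnitRegistry

        reg = UnitRegistry([
            Unit("ED", category=UnitCategory.ED),
            Unit("CARD_WEEK", category=UnitCategory.DAY_WEEK, specialty="cardio", mode="week"),
            Unit("CARD_FULL", category=UnitCategory.SPECIALIZED_MED, specialty="cardio"),
            Unit("PNEUMO_WEEK", category=UnitCategory.DAY_WEEK, specialty="pneumo", mode="week"),
            Unit("PNEUMO_FULL", category=UnitCategory.SPECIALIZED_MED, specialty="pneumo"),
        ])
        for first in ("CARD_WEEK", "CARD_FULL", "PNEUMO_WEEK", "PNEUMO_FULL"):
            for second in ("CARD_FULL", "PNEUMO_FULL"):
                if first == second:
                    continue
                p = make_pathway([("ED", T0, T0 + 4 * H),
                                  (first, T0 + 4 * H, T0 + 2 * D),
                                  (second, T0 + 2 * D, T0 + 6 * D)])
                fired = bool(rule7_day_week_before_full(p, reg))
                should = first.endswith("WEEK") and first[:4] == second[:4]
                assert fired == should, (first, second)


class TestRunRules:
    def test_worked_pathway_two_verdicts(self, registry, fig2_pathway):
        cfg = RuleConfig(enabled_rules={3, 6})
        verdicts = run_rules(fig2_pathway, registry, cfg)
        assert sorted(v.rule_id for v in verdicts) == [3, 6]

    def test_all_disabled(self, registry, fig2_pathway):
        assert run_rules(fig2_pathway, registry, RuleConfig(enabled_rules=frozenset())) == []

    def test_union_of_individual_rules(self, registry):
        """run_rules equals the multiset union of each rule run separately."""
        from wardpath.synth import SynthConfig, generate

        res = generate(SynthConfig(n_pathways=150, seed=5))
        cfg = RuleConfig(enabled_rules={1, 3, 4, 5, 6, 7})
        for pathway in res.historical:
            combined = run_rules(pathway, registry := res.registry, cfg)
            separate = []
            for rid in cfg.enabled_rules:
                separate.extend(
                    run_rules(pathway, registry, RuleConfig(enabled_rules={rid}))
                )
            key = lambda v: (v.rule_id, v.stage_index, v.from_ts, v.to_ts, v.level)
            assert sorted(map(key, combined)) == sorted(map(key, separate))

    def test_disabling_removes_exactly_that_rule(self, registry, fig2_pathway):
        full = run_rules(fig2_pathway, registry, RuleConfig(enabled_rules={3, 5, 6}))
        without6 = run_rules(fig2_pathway, registry, RuleConfig(enabled_rules={3, 5}))
        assert [v for v in full if v.rule_id != 6] == without6
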