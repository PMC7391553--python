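"""Ruleset grammar, packaged expert rules, prediction, assessment,
mutual exclusivity."""

import pytest

from reefrules import (
    ConstraintSet,
    assess,
    check_exclusivity,
    parse_ruleset,
    predict,
    predict_all,
    render_ruleset,
)
from reefrules.engine import ParseError, render_rule
from reefrules.mining import ClassRule, Condition

from conftest import make_station

# The 26 expert rule conditions in canonical grammar form, frozen from the
# published rule tables (golden reference for the packaged ruleset).
EXPECTED_CONDITIONS = {
    "MA1": "algae > 80 AND algal_turf < 20",
    "MA2": "60 <= algae < 80 AND algal_turf <= 20 AND dead_coral < 5",
    "MA3": "40 <= algae < 60 AND algal_turf < 20 AND hard_coral <= 20",
    "MA4": "20 <= algae < 40 AND algal_turf < 5 AND seagrass < 40 AND hard_coral < 5",
    "SG1": "seagrass >= 80",
    "SG2": "60 <= seagrass < 80",
    "SG3": "40 <= seagrass < 60 AND algae < 40",
    "SG4": "20 <= seagrass < 40 AND algae < 40 AND depth >= 10",
    "SA1": "sand >= 80 AND seagrass < 20 AND algae < 20",
    "SA2": "sand >= 80 AND seagrass < 20 AND algae >= 20 AND algal_turf > 5",
    "SA3": "60 <= sand < 80 AND seagrass < 5 AND erect_algae < 20",
    "SA4": "40 <= sand < 60 AND 5 <= live_coral < 40 AND complexity < 2 "
           "AND hard_substrate < 40",
    "SA5": "40 <= sand < 60 AND 5 <= live_coral < 40 AND 2 <= complexity < 3 "
           "AND hard_substrate < 40",
    "LC1": "live_coral >= 60",
    "LC2": "40 <= live_coral < 60 AND hard_coral >= 60",
    "LC3": "40 <= live_coral < 60 AND hard_coral < 60",
    "LC4": "20 <= live_coral < 40 AND hard_coral >= 60",
    "LC5": "20 <= live_coral < 40 AND hard_coral < 60 AND hard_substrate < 40 "
           "AND complexity > 2 AND topography > 2",
    "LC6": "15 <= live_coral < 20 AND dead_coral >= 20 AND algal_turf >= 5",
    "D1": "debris >= 60",
    "D2": "40 <= debris < 60 AND boulder >= 1",
    "D3": "40 <= debris < 60 AND boulder < 1 AND sand < 40",
    "D4": "40 <= debris < 60 AND boulder < 1 AND sand >= 40 AND complexity > 1.5",
    "D5": "20 <= debris < 40 AND sand < 60 AND (slab + boulder + rock) >= 20",
    "D6": "20 <= debris < 40 AND sand < 60 AND 5 < (slab + boulder + rock) < 20 "
          "AND complexity > 2",
    "D7": "5 <= debris < 20 AND (slab + boulder + rock) >= 20 AND sand < 60 "
          "AND hard_coral < 40",
}

EXPECTED_COUNTS = {
    "Macroalgae": 4, "Seagrass": 4, "Sandy": 5, "Live Coral": 6, "Debris": 7,
}


class TestPackagedRuleset:
    def test_26_rules_with_expected_per_habitat_counts(self, expert_rules):
        assert len(expert_rules) == 26
        by_habitat = expert_rules.by_habitat()
        assert {h: len(rs) for h, rs in by_habitat.items()} == EXPECTED_COUNTS

    def test_conditions_match_golden_strings(self, expert_rules):
        rendered = {
            r.rule_id: " AND ".join(c.render() for c in r.antecedent)
            for r in expert_rules
        }
        assert rendered == EXPECTED_CONDITIONS

    def test_printed_confidences_preserved(self, expert_rules):
        by_id = {r.rule_id: r for r in expert_rules}
        assert by_id["SG1"].confidence == 100 and by_id["SG1"].support == 93
        assert by_id["LC1"].confidence == 100 and by_id["LC1"].support == 217
        assert by_id["SA5"].confidence == 46
        assert by_id["SA3"].confusion == {"Live Coral": 2.5, "Debris": 0.7}


class TestGrammar:
    def test_render_parse_round_trip(self, expert_rules):
        text = render_ruleset(expert_rules)
        back = parse_ruleset(text, name=expert_rules.name)
        assert len(back) == len(expert_rules)
        for a, b in zip(expert_rules, back):
            assert a.rule_id == b.rule_id
            assert a.consequent == b.consequent
            assert render_rule(a) == render_rule(b)
            assert a.confusion == b.confusion

    def test_empty_file_warns_and_gives_empty_ruleset(self):
        with pytest.warns(UserWarning, match="empty"):
            rs = parse_ruleset("", name="none")
        assert len(rs) == 0

    def test_malformed_condition_reports_line(self):
        with pytest.raises(ParseError, match="line 2"):
            parse_ruleset("R1: sand >= 80 => Sandy\nR2: sand >>> => Sandy\n")

    def test_unknown_attribute_rejected(self):
        with pytest.raises(ParseError, match="kelp"):
            parse_ruleset("R1: kelp >= 80 => Sandy\n")

    def test_duplicate_rule_ids_rejected(self):
        with pytest.raises(ParseError, match="duplicate"):
            parse_ruleset("R1: sand >= 80 => Sandy\nR1: sand < 80 => Debris\n")

    def test_interval_with_strict_lower_bound(self):
        rs = parse_ruleset("R1: 5 < (slab + boulder + rock) < 20 => Debris\n")
        cond = rs.rules[0].antecedent[0]
        assert cond.lower == 5 and cond.lower_strict
        assert cond.upper == 20 and cond.upper_strict


class TestPredict:
    def test_dense_seagrass_fires_sg1(self, expert_rules):
        p = predict(make_station("S1", seagrass=85.0), expert_rules)
        assert p.habitat == "Seagrass"
        assert p.fired_rule_ids == ["SG1"]
        assert p.confidence == 100
        assert not p.conflict

    def test_high_live_coral_fires_lc1(self, expert_rules):
        station = make_station(
            "S1", live_coral=65.0, sand=60.0, debris=20.0, boulder=10.0,
            rock=5.0, slab=5.0, complexity=3.5, topography=3.0,
        )
        p = predict(station, expert_rules)
        assert p.habitat == "Live Coral"
        assert "LC1" in p.fired_rule_ids
        assert p.confidence == 100

    def test_intermediate_sand_station_unclassified(self, expert_rules):
        # Sand cover between 20 and 40% with low biotic covers falls in the
        # gap the ruleset deliberately leaves open.
        station = make_station(
            "S1", sand=30.0, debris=10.0, boulder=20.0, rock=20.0, slab=20.0,
            seagrass=0.0, live_coral=10.0, dead_coral=30.0, complexity=1.8,
        )
        p = predict(station, expert_rules)
        assert p.habitat is None
        assert p.fired_rule_ids == []

    def test_boundary_operators_exact(self, expert_rules):
        # seagrass >= 80 fires SG1 at exactly 80, not at 79.999.
        assert predict(make_station("S", seagrass=80.0), expert_rules).habitat \
            == "Seagrass"
        p = predict(make_station("S", seagrass=79.999), expert_rules)
        assert "SG1" not in p.fired_rule_ids

    def test_conflict_flag_and_confidence_priority(self):
        rs = parse_ruleset(
            "A: sand >= 50 => Sandy [conf=70]\n"
            "B: sand >= 60 => Debris [conf=95]\n"
        )
        p = predict(make_station("S", sand=100.0), rs)
        assert p.conflict
        assert set(p.fired_rule_ids) == {"A", "B"}
        assert p.habitat == "Debris"  # higher-confidence rule wins


class TestAssess:
    def test_perfect_ruleset_scores_100_100(self):
        rs = parse_ruleset(
            "S: sand >= 80 => Sandy [conf=100]\n"
            "G: seagrass >= 80 => Seagrass [conf=100]\n"
        )
        stations = [
            make_station(f"A{i}", habitat="Sandy", sand=90.0) for i in range(5)
        ] + [
            make_station(f"B{i}", habitat="Seagrass", seagrass=90.0, sand=10.0)
            for i in range(5)
        ]
        a = assess(stations, rs)
        assert a.overall_classified_pct == pytest.approx(100.0)
        assert a.overall_confidence == pytest.approx(100.0)
        for pct, cl in a.per_habitat.values():
            assert pct == pytest.approx(100.0)
            assert cl == pytest.approx(100.0)

    def test_no_rule_fired_confidence_not_evaluable(self):
        rs = parse_ruleset("S: sand >= 99.5 => Sandy\n")
        stations = [make_station("A", habitat="Debris", sand=50.0, debris=50.0)]
        a = assess(stations, rs)
        assert a.overall_classified_pct == pytest.approx(0.0)
        assert a.overall_confidence is None

    def test_absent_habitat_row_omitted_with_note(self, expert_rules):
        stations = [make_station("A", habitat="Sandy", sand=90.0)]
        a = assess(stations, expert_rules)
        assert "Seagrass" not in a.per_habitat
        assert any("Seagrass" in n for n in a.notes)

    def test_confidence_consistent_with_predict(self, synthetic_stations,
                                                expert_rules):
        a = assess(synthetic_stations, expert_rules)
        preds = predict_all(synthetic_stations, expert_rules)
        classified = [
            (s, p) for s, p in zip(synthetic_stations, preds) if p.classified
        ]
        correct = sum(1 for s, p in classified if p.habitat == s.habitat)
        assert a.overall_confidence == pytest.approx(
            correct / len(classified) * 100.0
        )


class TestExclusivity:
    def test_rule_with_itself_satisfiable(self, expert_rules):
        reports = {
            (r.rule_a, r.rule_b): r for r in check_exclusivity(expert_rules)
        }
        for rule in expert_rules:
            assert reports[(rule.rule_id, rule.rule_id)].status == "SATISFIABLE"

    def test_ma1_sg1_exclusive_under_biotic_sum(self, expert_rules):
        reports = {
            frozenset((r.rule_a, r.rule_b)): r.status
            for r in check_exclusivity(expert_rules)
        }
        assert reports[frozenset(("MA1", "SG1"))] == "EXCLUSIVE"

    def test_witnesses_refire_both_rules(self, expert_rules):
        by_id = {r.rule_id: r for r in expert_rules}
        reports = check_exclusivity(expert_rules)
        satisfiable = [r for r in reports if r.status == "SATISFIABLE"]
        assert satisfiable  # at least the self-pairs
        for rep in satisfiable:
            assert by_id[rep.rule_a].matches(rep.witness)
            assert by_id[rep.rule_b].matches(rep.witness)

    def test_disabling_biotic_constraint_relaxes_pairs(self, expert_rules):
        loose = ConstraintSet(biotic_sum_max=None)
        strict_n = sum(
            r.status == "EXCLUSIVE" for r in check_exclusivity(expert_rules)
        )
        loose_n = sum(
            r.status == "EXCLUSIVE"
            for r in check_exclusivity(expert_rules, loose)
        )
        assert loose_n <= strict_n
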