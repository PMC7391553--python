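"""Discretization, top-K rule mining vs the brute-force oracle,
rule evaluation semantics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefrules import (
    MiningConstraints,
    brute_force_rules,
    discretize,
    evaluate_rule,
    mine_topk,
)
from reefrules.mining import (
    Atom,
    ClassRule,
    Condition,
    MiningError,
    TransactionSet,
)

from conftest import make_station

ATTRS = ("sand", "debris", "seagrass", "live_coral", "erect_algae")


def random_instance(rng, n_trans, n_attrs, n_cuts):
    """A random discretized instance over uniform covers, 3 labels."""
    atoms = []
    for a in range(n_attrs):
        cuts = sorted(rng.choice(np.arange(5, 100, 5), size=n_cuts, replace=False))
        for t in cuts:
            atoms.append(Atom((ATTRS[a],), "ge", float(t)))
            atoms.append(Atom((ATTRS[a],), "lt", float(t)))
    vals = rng.uniform(0, 100, size=(n_trans, n_attrs))
    inc = np.zeros((n_trans, len(atoms)), dtype=bool)
    for j, at in enumerate(atoms):
        ai = ATTRS.index(at.components[0])
        inc[:, j] = (
            vals[:, ai] >= at.threshold if at.kind == "ge"
            else vals[:, ai] < at.threshold
        )
    labels = [f"H{l}" for l in rng.integers(0, 3, size=n_trans)]
    return TransactionSet(atoms, inc, labels)


def rule_key(r):
    return (
        tuple((c.components, c.lower, c.upper) for c in r.antecedent),
        r.consequent,
        r.support,
        round(r.confidence, 9),
        r.antecedent_count,
    )


class TestDiscretize:
    def test_high_seagrass_station_satisfies_top_cut(self):
        ts = discretize([make_station("S1", habitat="Seagrass", seagrass=85.0)])
        satisfied = {
            ts.atoms[j].render() for j in np.flatnonzero(ts.incidence[0])
        }
        assert "seagrass >= 80" in satisfied

    def test_all_zero_covers_only_below_lowest_cut(self):
        ts = discretize([make_station("S1", habitat="Sandy", sand=100.0)])
        satisfied = [ts.atoms[j] for j in np.flatnonzero(ts.incidence[0])]
        for a in satisfied:
            if a.components == ("seagrass",) and a.kind == "ge":
                pytest.fail("zero cover should satisfy no lower bound")

    def test_station_matching_sandy_rule_atoms(self):
        # sand >= 80, seagrass < 20, algae < 20 are all grid atoms.
        ts = discretize(
            [make_station("S1", habitat="Sandy", sand=92.0, seagrass=2.0)]
        )
        satisfied = {
            ts.atoms[j].render() for j in np.flatnonzero(ts.incidence[0])
        }
        assert {"sand >= 80", "seagrass < 20", "algae < 20"} <= satisfied

    def test_empty_grid_rejected(self, synthetic_stations):
        with pytest.raises(MiningError, match="grid"):
            discretize(synthetic_stations[:3], grid={})

    def test_unlabeled_station_rejected(self):
        with pytest.raises(MiningError, match="unlabeled"):
            discretize([make_station("S1", habitat=None)])


class TestBruteForce:
    def test_combinatorial_count_one_transaction(self):
        atoms = [Atom(("sand",), "ge", 20.0), Atom(("debris",), "ge", 20.0)]
        inc = np.ones((1, 2), dtype=bool)
        ts = TransactionSet(atoms, inc, ["H"])
        rules = brute_force_rules(
            ts, MiningConstraints(k=100, min_conf=50, max_conditions=2)
        )
        # 2 singletons + 1 pair of distinct attributes.
        assert len(rules) == 3

    def test_max_conditions_one_gives_singletons(self):
        rng = np.random.default_rng(1)
        ts = random_instance(rng, 50, 3, 2)
        rules = brute_force_rules(
            ts, MiningConstraints(k=10**6, min_conf=10, max_conditions=1)
        )
        assert all(r.n_conditions() == 1 for r in rules)

    def test_guard_refuses_large_instance(self):
        rng = np.random.default_rng(2)
        ts = random_instance(rng, 600, 3, 2)
        with pytest.raises(MiningError, match="guard"):
            brute_force_rules(ts, MiningConstraints(k=10, min_conf=50))


class TestMineTopK:
    def test_single_dominant_condition(self):
        # One atom present in 5 transactions, all labeled H; 5 others lack it.
        atoms = [Atom(("sand",), "ge", 80.0)]
        inc = np.array([[True]] * 5 + [[False]] * 5)
        ts = TransactionSet(atoms, inc, ["H"] * 5 + ["G"] * 5)
        rules = mine_topk(ts, MiningConstraints(k=1, min_conf=80))
        assert len(rules) == 1
        assert rules[0].support == 5
        assert rules[0].confidence == pytest.approx(100.0)
        assert rules[0].consequent == "H"

    def test_min_conf_100_with_counterexamples_is_empty(self):
        atoms = [Atom(("sand",), "ge", 50.0)]
        # Every candidate antecedent matches both labels.
        inc = np.array([[True], [True]])
        ts = TransactionSet(atoms, inc, ["H", "G"])
        assert mine_topk(ts, MiningConstraints(k=10, min_conf=100)) == []

    def test_k_larger_than_valid_rules_saturates(self):
        rng = np.random.default_rng(3)
        ts = random_instance(rng, 60, 2, 2)
        mc_all = MiningConstraints(k=10**6, min_conf=60)
        everything = brute_force_rules(ts, mc_all)
        got = mine_topk(ts, MiningConstraints(k=10**5, min_conf=60))
        assert len(got) == len(everything)

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        ts = random_instance(
            rng, int(rng.integers(20, 300)), int(rng.integers(2, 5)), 2
        )
        mc = MiningConstraints(
            k=10**6,
            min_conf=float(rng.choice([50, 70, 80, 90])),
            max_conditions=int(rng.integers(1, 4)),
        )
        assert [rule_key(r) for r in mine_topk(ts, mc)] == [
            rule_key(r) for r in brute_force_rules(ts, mc)
        ]

    @pytest.mark.parametrize("k", [1, 5, 25])
    def test_topk_is_prefix_of_oracle(self, k):
        rng = np.random.default_rng(42)
        ts = random_instance(rng, 200, 3, 2)
        mc_all = MiningConstraints(k=10**6, min_conf=60)
        oracle = brute_force_rules(ts, mc_all)
        got = mine_topk(ts, MiningConstraints(k=k, min_conf=60))
        assert [rule_key(r) for r in got] == [rule_key(r) for r in oracle[:k]]

    def test_invalid_constraints_rejected(self):
        with pytest.raises(MiningError):
            MiningConstraints(k=0)
        with pytest.raises(MiningError):
            MiningConstraints(min_conf=0)


@given(data=st.data())
@settings(max_examples=25, deadline=None, derandomize=True)
def test_support_anti_monotone(data):
    """Adding a condition to an antecedent never increases support."""
    rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
    ts = random_instance(rng, 80, 2, 2)
    mc = MiningConstraints(k=10**6, min_conf=1, max_conditions=2)
    rules = brute_force_rules(ts, mc)
    by_ant = {}
    for r in rules:
        key = frozenset(
            (c.components, c.lower, c.upper) for c in r.antecedent
        )
        by_ant[(key, r.consequent)] = r.support
    for (key, cls), support in by_ant.items():
        for (other_key, other_cls), other_support in by_ant.items():
            if cls == other_cls and key < other_key:
                assert other_support <= support


class TestEvaluateRule:
    def rule(self, **kw):
        defaults = dict(
            rule_id="T1",
            antecedent=[Condition(components=("seagrass",), lower=80.0)],
            consequent="Seagrass",
        )
        defaults.update(kw)
        return ClassRule(**defaults)

    def test_direct_ratio(self):
        stations = [
            make_station(f"S{i}", habitat="Seagrass", seagrass=85.0)
            for i in range(9)
        ] + [make_station("S9", habitat="Sandy", seagrass=85.0)]
        r = evaluate_rule(self.rule(), stations)
        assert r.antecedent_count == 10
        assert r.support == 9
        assert r.confidence == pytest.approx(90.0)
        assert r.confusion == {"Sandy": pytest.approx(10.0)}
        assert r.confidence + sum(r.confusion.values()) == pytest.approx(100.0)

    def test_no_match_is_not_evaluable(self):
        stations = [make_station("S1", habitat="Sandy", seagrass=10.0)]
        r = evaluate_rule(self.rule(), stations)
        assert not r.evaluable
        assert r.confidence is None

    def test_pure_separation_gives_confidence_100(self, synthetic_stations):
        # No non-Seagrass synthetic station reaches seagrass >= 80.
        competitors = [
            s for s in synthetic_stations
            if s.habitat != "Seagrass" and s.profile.seagrass >= 80
        ]
        assert not competitors
        r = evaluate_rule(self.rule(), synthetic_stations)
        if r.evaluable:
            assert r.confidence == pytest.approx(100.0)

    def test_support_confidence_consistency(self, synthetic_stations):
        r = evaluate_rule(
            self.rule(antecedent=[Condition(components=("sand",), lower=60.0)],
                      consequent="Sandy"),
            synthetic_stations,
        )
        assert r.support <= r.antecedent_count
        assert r.confidence == pytest.approx(
            r.support / r.antecedent_count * 100.0
        )
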