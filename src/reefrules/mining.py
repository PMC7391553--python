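"""Top-K class-association-rule mining over discretized station attributes.

A *classification rule* is a conjunction of threshold conditions on
(possibly composite) habitat attributes implying a habitat label, with

* support    = number of stations satisfying antecedent AND consequent,
* confidence = support / number of stations satisfying the antecedent.

Stations are first discretized against a cutpoint grid into transactions:
per-station sets of satisfied atomic conditions (``x >= t`` / ``x < t``
per cutpoint) plus the habitat label.  The miner returns the K rules of
maximum support among those with confidence at least ``min_conf`` and at
most ``max_conditions`` conditions, where a two-sided interval
(``t1 <= x < t2``) counts as a single condition on its attribute.

The search is a best-first expansion of the antecedent lattice in
canonical atom order with support-based pruning and a dynamic minimum
support raised as the K-th best rule improves (TopKRules-style);
:func:`brute_force_rules` enumerates the same space exhaustively on
small instances and serves as the independent oracle.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .stations import (
    BASE_ATTRIBUTES,
    COMPOSITE_ATTRIBUTES,
    COVER_ATTRIBUTES,
    ORDINAL_ATTRIBUTES,
    StationRecord,
)

#: Default discretization cutpoints, chosen to span the thresholds that
#: recur in expert habitat rules.
DEFAULT_COVER_CUTPOINTS = (1.0, 5.0, 15.0, 20.0, 40.0, 60.0, 80.0)
DEFAULT_ORDINAL_CUTPOINTS = (1.5, 2.0, 3.0)
DEFAULT_DEPTH_CUTPOINTS = (10.0,)

#: Attributes discretized by default: base covers plus the composites.
DEFAULT_MINED_ATTRIBUTES = (
    COVER_ATTRIBUTES + tuple(COMPOSITE_ATTRIBUTES) + ORDINAL_ATTRIBUTES + ("depth",)
)


class MiningError(ValueError):
    pass


def resolve_components(attribute) -> tuple[str, ...]:
    """Resolve an attribute name or explicit sum to its base components."""
    if isinstance(attribute, (tuple, list)):
        comps = tuple(attribute)
    elif attribute in COMPOSITE_ATTRIBUTES:
        return COMPOSITE_ATTRIBUTES[attribute]
    else:
        comps = (attribute,)
    for c in comps:
        if c not in BASE_ATTRIBUTES:
            raise MiningError(f"unknown attribute {c!r}")
    return comps


def display_name(components: tuple[str, ...]) -> str:
    if len(components) == 1:
        return components[0]
    for name, comps in COMPOSITE_ATTRIBUTES.items():
        if tuple(comps) == components:
            return name
    return "(" + " + ".join(components) + ")"


@dataclass(frozen=True)
class Condition:
    """A threshold or interval condition on one (composite) attribute."""

    components: tuple[str, ...]
    lower: float | None = None
    lower_strict: bool = False
    upper: float | None = None
    upper_strict: bool = True

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise MiningError("condition needs at least one bound")
        if self.lower is not None and self.upper is not None:
            if self.lower >= self.upper:
                raise MiningError(
                    f"empty interval [{self.lower}, {self.upper}) on "
                    f"{display_name(self.components)}"
                )

    @property
    def attribute(self) -> str:
        return display_name(self.components)

    def value_of(self, profile) -> float:
        return float(sum(profile.value(c) for c in self.components))

    def matches(self, profile) -> bool:
        v = self.value_of(profile)
        if self.lower is not None:
            if self.lower_strict:
                if not v > self.lower:
                    return False
            elif not v >= self.lower:
                return False
        if self.upper is not None:
            if self.upper_strict:
                if not v < self.upper:
                    return False
            elif not v <= self.upper:
                return False
        return True

    def render(self) -> str:
        name = self.attribute

        def num(x: float) -> str:
            return f"{x:g}"

        if self.lower is not None and self.upper is not None:
            lo_op = "<" if self.lower_strict else "<="
            hi_op = "<" if self.upper_strict else "<="
            return f"{num(self.lower)} {lo_op} {name} {hi_op} {num(self.upper)}"
        if self.lower is not None:
            return f"{name} {'>' if self.lower_strict else '>='} {num(self.lower)}"
        return f"{name} {'<' if self.upper_strict else '<='} {num(self.upper)}"


@dataclass
class ClassRule:
    """Antecedent conditions implying a habitat, with optional statistics.

    ``support`` counts stations satisfying antecedent and consequent;
    ``antecedent_count`` counts stations satisfying the antecedent alone;
    ``confidence`` is their ratio in percent; ``confusion`` maps each
    other habitat to its percentage of antecedent-matching stations.
    """

    rule_id: str
    antecedent: list[Condition]
    consequent: str
    confidence: float | None = None
    support: int | None = None
    antecedent_count: int | None = None
    confusion: dict[str, float] = field(default_factory=dict)
    evaluable: bool = True
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.antecedent:
            raise MiningError(f"rule {self.rule_id}: empty antecedent")

    def matches(self, profile) -> bool:
        return all(c.matches(profile) for c in self.antecedent)

    def n_conditions(self) -> int:
        return len(self.antecedent)


@dataclass
class MiningConstraints:
    k: int = 1000
    min_conf: float = 90.0  # percent
    max_conditions: int = 3

    def __post_init__(self) -> None:
        if self.k < 1:
            raise MiningError("K must be >= 1")
        if not 0 < self.min_conf <= 100:
            raise MiningError("min_conf must be in (0, 100]")
        if self.max_conditions < 1:
            raise MiningError("max_conditions must be >= 1")


@dataclass(frozen=True)
class Atom:
    """One atomic grid condition: components >= t ('ge') or < t ('lt')."""

    components: tuple[str, ...]
    kind: str  # "ge" or "lt"
    threshold: float

    def render(self) -> str:
        op = ">=" if self.kind == "ge" else "<"
        return f"{display_name(self.components)} {op} {self.threshold:g}"


@dataclass
class TransactionSet:
    """Discretized stations: the atom vocabulary, a boolean incidence
    matrix (transaction x atom), and the habitat label per transaction."""

    atoms: list[Atom]
    incidence: np.ndarray  # bool, shape (n_transactions, n_atoms)
    labels: list[str]

    @property
    def n_transactions(self) -> int:
        return self.incidence.shape[0]


def default_grid(attributes=DEFAULT_MINED_ATTRIBUTES) -> dict:
    grid = {}
    for a in attributes:
        if a in ORDINAL_ATTRIBUTES:
            grid[a] = list(DEFAULT_ORDINAL_CUTPOINTS)
        elif a == "depth":
            grid[a] = list(DEFAULT_DEPTH_CUTPOINTS)
        else:
            grid[a] = list(DEFAULT_COVER_CUTPOINTS)
    return grid


def discretize(stations: list[StationRecord], grid: dict | None = None
               ) -> TransactionSet:
    """Map labeled stations to transactions over grid atoms.

    For each attribute and cutpoint ``t`` two atoms exist, ``x >= t`` and
    ``x < t``; a station's transaction is the set of atoms it satisfies.
    """
    if grid is None:
        grid = default_grid()
    if not grid or not any(grid.values()):
        raise MiningError("empty discretization grid")
    atoms: list[Atom] = []
    for attr in grid:
        comps = resolve_components(attr)
        for t in sorted(grid[attr]):
            atoms.append(Atom(comps, "ge", float(t)))
            atoms.append(Atom(comps, "lt", float(t)))
    unlabeled = [s.station_id for s in stations if s.habitat is None]
    if unlabeled:
        raise MiningError(f"unlabeled stations: {unlabeled[:5]}")
    inc = np.zeros((len(stations), len(atoms)), dtype=bool)
    for i, s in enumerate(stations):
        for j, a in enumerate(atoms):
            v = sum(s.profile.value(c) for c in a.components)
            inc[i, j] = v >= a.threshold if a.kind == "ge" else v < a.threshold
    return TransactionSet(
        atoms=atoms, incidence=inc, labels=[s.habitat for s in stations]
    )


# ---------------------------------------------------------------------------
# Antecedent lattice shared by the miner and the oracle
# ---------------------------------------------------------------------------

def _atom_structure(atoms: list[Atom]):
    """Group atom indices by attribute; return (attr_of, is_lower)."""
    attr_of = [a.components for a in atoms]
    is_lower = [a.kind == "ge" for a in atoms]
    return attr_of, is_lower


def _antecedent_valid(atom_idx: tuple[int, ...], atoms: list[Atom],
                      max_conditions: int) -> bool:
    """A canonical antecedent has, per attribute, at most one lower and
    one upper bound (lower < upper), and at most ``max_conditions``
    distinct attributes."""
    per_attr: dict[tuple[str, ...], dict[str, float]] = {}
    for i in atom_idx:
        a = atoms[i]
        slot = per_attr.setdefault(a.components, {})
        if a.kind in slot:
            return False  # two bounds of the same direction are redundant
        slot[a.kind] = a.threshold
    if len(per_attr) > max_conditions:
        return False
    for slot in per_attr.values():
        if "ge" in slot and "lt" in slot and slot["ge"] >= slot["lt"]:
            return False  # empty interval
    return True


def _antecedent_conditions(atom_idx: tuple[int, ...],
                           atoms: list[Atom]) -> list[Condition]:
    per_attr: dict[tuple[str, ...], dict[str, float]] = {}
    order: list[tuple[str, ...]] = []
    for i in atom_idx:
        a = atoms[i]
        if a.components not in per_attr:
            order.append(a.components)
        per_attr.setdefault(a.components, {})[a.kind] = a.threshold
    conds = []
    for comps in order:
        slot = per_attr[comps]
        conds.append(
            Condition(
                components=comps,
                lower=slot.get("ge"),
                lower_strict=False,
                upper=slot.get("lt"),
                upper_strict=True,
            )
        )
    return conds


def _rule_sort_key(support: int, confidence: float, atom_idx: tuple[int, ...],
                   consequent: str):
    return (-support, -confidence, atom_idx, consequent)


def _finalize(found: list, atoms: list[Atom], k: int) -> list[ClassRule]:
    found.sort(key=lambda r: _rule_sort_key(r[0], r[1], r[3], r[4]))
    out = []
    for rank, (support, conf, ant_count, atom_idx, label) in enumerate(
        found[:k], start=1
    ):
        out.append(
            ClassRule(
                rule_id=f"R{rank:04d}",
                antecedent=_antecedent_conditions(atom_idx, atoms),
                consequent=label,
                confidence=conf,
                support=support,
                antecedent_count=ant_count,
                provenance="mined",
            )
        )
    return out


def brute_force_rules(transactions: TransactionSet,
                      constraints: MiningConstraints) -> list[ClassRule]:
    """Exhaustively enumerate every valid rule on a small instance.

    Guarded to <= 20 atoms and <= 500 transactions; identical support and
    confidence semantics as :func:`mine_topk`, with no top-K truncation
    (every rule meeting ``min_conf`` and the length cap is returned,
    sorted by the documented tie order).
    """
    n_atoms = len(transactions.atoms)
    if n_atoms > 20 or transactions.n_transactions > 500:
        raise MiningError(
            f"brute force guard: {n_atoms} atoms x "
            f"{transactions.n_transactions} transactions exceeds 20 x 500"
        )
    atoms = transactions.atoms
    inc = transactions.incidence
    labels = np.array(transactions.labels)
    classes = sorted(set(transactions.labels))
    found = []
    # Max antecedent size in atoms: max_conditions attributes x 2 bounds.
    max_atoms = 2 * constraints.max_conditions
    for size in range(1, max_atoms + 1):
        for combo in itertools.combinations(range(n_atoms), size):
            if not _antecedent_valid(combo, atoms, constraints.max_conditions):
                continue
            mask = inc[:, combo].all(axis=1)
            ant_count = int(mask.sum())
            if ant_count == 0:
                continue
            for cls in classes:
                support = int((mask & (labels == cls)).sum())
                if support == 0:
                    continue
                conf = support / ant_count * 100.0
                if conf >= constraints.min_conf:
                    found.append((support, conf, ant_count, combo, cls))
    return _finalize(found, atoms, len(found))


def mine_topk(transactions: TransactionSet,
              constraints: MiningConstraints) -> list[ClassRule]:
    """Mine the K maximum-support rules above the confidence floor.

    Best-first expansion of the canonical antecedent lattice: nodes are
    ordered by their best achievable rule support (the largest per-class
    count inside the antecedent's match set, an anti-monotone bound), and
    the minimum support rises to the K-th best support found so far,
    pruning every branch whose bound falls below it.  Exact: returns the
    same rules as :func:`brute_force_rules` truncated to K in the
    documented tie order.
    """
    atoms = transactions.atoms
    n_atoms = len(atoms)
    inc = transactions.incidence
    labels = np.array(transactions.labels)
    classes = sorted(set(transactions.labels))
    class_masks = {c: labels == c for c in classes}
    k = constraints.k
    max_atoms = 2 * constraints.max_conditions

    found: list = []
    top_heap: list[int] = []  # min-heap of the K best supports

    def minsup() -> int:
        return top_heap[0] if len(top_heap) >= k else 1

    def record(support, conf, ant_count, combo, cls):
        found.append((support, conf, ant_count, combo, cls))
        if len(top_heap) < k:
            heapq.heappush(top_heap, support)
        elif support > top_heap[0]:
            heapq.heapreplace(top_heap, support)

    # Priority queue of (negative bound, antecedent atoms, match mask).
    pq: list = []
    counter = itertools.count()
    root_mask = np.ones(transactions.n_transactions, dtype=bool)
    heapq.heappush(pq, (-transactions.n_transactions, next(counter), (), root_mask))

    while pq:
        neg_bound, _, combo, mask = heapq.heappop(pq)
        if -neg_bound < minsup():
            break  # no remaining node can beat the K-th best support
        last = combo[-1] if combo else -1
        if len(combo) >= max_atoms:
            continue
        for j in range(last + 1, n_atoms):
            new_combo = combo + (j,)
            if not _antecedent_valid(new_combo, atoms, constraints.max_conditions):
                continue
            new_mask = mask & inc[:, j]
            ant_count = int(new_mask.sum())
            if ant_count == 0:
                continue
            per_class = {c: int((new_mask & class_masks[c]).sum()) for c in classes}
            bound = max(per_class.values())
            if bound < minsup():
                continue
            for cls, support in per_class.items():
                if support < minsup() or support == 0:
                    continue
                conf = support / ant_count * 100.0
                if conf >= constraints.min_conf:
                    record(support, conf, ant_count, new_combo, cls)
            if len(new_combo) < max_atoms:
                heapq.heappush(pq, (-bound, next(counter), new_combo, new_mask))

    # Drop rules that fell below the final threshold, keeping ties with
    # the K-th support, then truncate deterministically.
    thr = minsup()
    found = [r for r in found if r[0] >= thr]
    return _finalize(found, atoms, k)


def evaluate_rule(rule: ClassRule, stations: list[StationRecord]) -> ClassRule:
    """Fill a rule's support, confidence and confusion map on labeled data.

    The confusion map gives, per non-consequent habitat, the percentage of
    antecedent-matching stations carrying that habitat; together with the
    confidence these percentages sum to 100 (up to rounding).  A rule whose
    antecedent matches no station is returned with ``evaluable=False``.
    """
    unlabeled = [s.station_id for s in stations if s.habitat is None]
    if unlabeled:
        raise MiningError(f"unlabeled stations: {unlabeled[:5]}")
    matching = [s for s in stations if rule.matches(s.profile)]
    ant_count = len(matching)
    if ant_count == 0:
        return replace(
            rule, evaluable=False, confidence=None, support=0,
            antecedent_count=0, confusion={},
        )
    support = sum(1 for s in matching if s.habitat == rule.consequent)
    confusion: dict[str, float] = {}
    for s in matching:
        if s.habitat != rule.consequent:
            confusion[s.habitat] = confusion.get(s.habitat, 0.0) + 1
    confusion = {h: c / ant_count * 100.0 for h, c in confusion.items()}
    return replace(
        rule,
        evaluable=True,
        confidence=support / ant_count * 100.0,
        support=support,
        antecedent_count=ant_count,
        confusion=confusion,
    )


def rules_to_frame(rules: list[ClassRule]):
    """Tabulate rules (id, antecedent, consequent, stats) as a DataFrame."""
    import pandas as pd

    rows = []
    for r in rules:
        rows.append(
            {
                "rule_id": r.rule_id,
                "antecedent": " AND ".join(c.render() for c in r.antecedent),
                "consequent": r.consequent,
                "confidence_pct": r.confidence,
                "support": r.support,
                "antecedent_count": r.antecedent_count,
                "n_conditions": r.n_conditions(),
            }
        )
    return pd.DataFrame(rows)
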