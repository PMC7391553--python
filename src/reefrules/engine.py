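"""Rule-based habitat prediction: ruleset grammar, the packaged expert
ruleset, prediction, coverage/confidence assessment, and pairwise
mutual-exclusivity checking under cover constraints.

Ruleset grammar (UTF-8 text, one rule per line, ``#`` comments)::

    rule       = id ":" antecedent "=>" habitat [ "[" meta "]" ]
    antecedent = condition { "AND" condition }
    condition  = number relop expr relop number   ; interval
               | expr relop number
    expr       = attribute | "(" attribute { "+" attribute } ")"
    relop      = "<=" | "<" | ">=" | ">"
    meta       = "conf=" number [ ", n=" number ]
                 [ ", confusion=" habitat ":" number { "; " habitat ":" number } ]

Attributes are the thirteen base attributes or the composites ``algae``,
``hard_coral``, ``hard_substrate``; explicit sums like
``(slab + boulder + rock)`` are also conditions on a single composite.
Thresholds compare exactly as written (``>= 80`` vs ``> 80``), with no
tolerance band, so rule firing is bit-reproducible.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .mining import ClassRule, Condition, MiningError, resolve_components
from .stations import (
    BASE_ATTRIBUTES,
    SUBSTRATE_SUM_TOLERANCE,
    BIOTIC_ATTRIBUTES,
    HABITATS,
    SUBSTRATE_ATTRIBUTES,
    AttributeProfile,
    StationRecord,
)

PACKAGED_RULESET = "expert_rules_nc_v1"


class ParseError(ValueError):
    pass


@dataclass
class RuleSet:
    name: str
    rules: list[ClassRule]
    version: str = "1"
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ParseError(f"duplicate rule ids: {dup}")
        for r in self.rules:
            if r.consequent not in HABITATS:
                raise ParseError(
                    f"rule {r.rule_id}: unknown habitat {r.consequent!r}"
                )

    def by_habitat(self) -> dict[str, list[ClassRule]]:
        out: dict[str, list[ClassRule]] = {}
        for r in self.rules:
            out.setdefault(r.consequent, []).append(r)
        return out

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


@dataclass
class Prediction:
    station_id: str
    habitat: str | None  # None == UNCLASSIFIED
    fired_rule_ids: list[str]
    confidence: float | None
    conflict: bool = False

    @property
    def classified(self) -> bool:
        return self.habitat is not None


@dataclass
class RuleSetAssessment:
    """Per-habitat classification coverage and confidence, plus the
    pooled overall row (station-weighted by default)."""

    per_habitat: dict[str, tuple[float, float | None]]  # (% classified, CL)
    overall_classified_pct: float
    overall_confidence: float | None
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Grammar
# ---------------------------------------------------------------------------

_NUM = r"[-+]?\d+(?:\.\d+)?"
_RELOP = r"<=|>=|<|>"
_EXPR = r"\(\s*\w+(?:\s*\+\s*\w+)*\s*\)|\w+"

_INTERVAL_RE = re.compile(
    rf"^\s*({_NUM})\s*(<=|<)\s*({_EXPR})\s*(<=|<)\s*({_NUM})\s*$"
)
_SIMPLE_RE = re.compile(rf"^\s*({_EXPR})\s*({_RELOP})\s*({_NUM})\s*$")
_RULE_RE = re.compile(
    r"^\s*(?P<id>[A-Za-z0-9_]+)\s*:\s*(?P<ant>.+?)\s*=>\s*"
    r"(?P<habitat>[A-Za-z][A-Za-z ]*?)\s*(?:\[(?P<meta>.*)\])?\s*$"
)


def _parse_expr(text: str) -> tuple[str, ...]:
    text = text.strip()
    if text.startswith("("):
        parts = [p.strip() for p in text.strip("() ").split("+")]
    else:
        parts = [text]
    return resolve_components(tuple(parts) if len(parts) > 1 else parts[0])


def parse_condition(text: str) -> Condition:
    m = _INTERVAL_RE.match(text)
    if m:
        lo, lo_op, expr, hi_op, hi = m.groups()
        return Condition(
            components=_parse_expr(expr),
            lower=float(lo),
            lower_strict=(lo_op == "<"),
            upper=float(hi),
            upper_strict=(hi_op == "<"),
        )
    m = _SIMPLE_RE.match(text)
    if m:
        expr, op, num = m.groups()
        comps = _parse_expr(expr)
        v = float(num)
        if op in (">=", ">"):
            return Condition(components=comps, lower=v, lower_strict=(op == ">"))
        return Condition(components=comps, upper=v, upper_strict=(op == "<"))
    raise ParseError(f"malformed condition: {text!r}")


def _parse_meta(meta: str, rule_id: str):
    conf = n = None
    confusion: dict[str, float] = {}
    for part in [p.strip() for p in meta.split(",") if p.strip()]:
        if part.startswith("conf="):
            conf = float(part[5:])
        elif part.startswith("n="):
            n = int(float(part[2:]))
        elif part.startswith("confusion="):
            for pair in part[len("confusion="):].split(";"):
                hab, _, pct = pair.partition(":")
                hab = hab.strip()
                if hab not in HABITATS:
                    raise ParseError(
                        f"rule {rule_id}: unknown confusion habitat {hab!r}"
                    )
                confusion[hab] = float(pct)
        else:
            raise ParseError(f"rule {rule_id}: unknown metadata {part!r}")
    if conf is not None and confusion:
        # Published tables round each percentage independently; sums can
        # land a few points off 100.
        if conf + sum(confusion.values()) > 100.0 + 5.0:
            raise ParseError(
                f"rule {rule_id}: confidence + confusion exceeds 100"
            )
    return conf, n, confusion


def parse_ruleset(text: str, name: str = "ruleset") -> RuleSet:
    """Parse a ruleset from the documented grammar.

    ``parse(render(ruleset))`` is the identity on structure and metadata.
    Parse errors carry the 1-based line number.
    """
    rules: list[ClassRule] = []
    provenance_lines: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            provenance_lines.append(line.lstrip("# "))
            continue
        m = _RULE_RE.match(line)
        if not m:
            raise ParseError(f"line {lineno}: malformed rule: {line!r}")
        try:
            conditions = [
                parse_condition(c)
                for c in re.split(r"\s+AND\s+", m.group("ant"), flags=re.I)
            ]
            conf, n, confusion = _parse_meta(m.group("meta") or "", m.group("id"))
        except (ParseError, MiningError) as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        rules.append(
            ClassRule(
                rule_id=m.group("id"),
                antecedent=conditions,
                consequent=m.group("habitat").strip(),
                confidence=conf,
                support=n,
                confusion=confusion,
                provenance="parsed",
            )
        )
    if not rules:
        warnings.warn(f"ruleset {name!r} is empty", stacklevel=2)
    return RuleSet(name=name, rules=rules, provenance="\n".join(provenance_lines))


def render_rule(rule: ClassRule) -> str:
    text = " AND ".join(c.render() for c in rule.antecedent)
    meta = []
    if rule.confidence is not None:
        meta.append(f"conf={rule.confidence:g}")
    if rule.support is not None:
        meta.append(f"n={rule.support}")
    if rule.confusion:
        pairs = "; ".join(f"{h}:{p:g}" for h, p in rule.confusion.items())
        meta.append(f"confusion={pairs}")
    suffix = f" [{', '.join(meta)}]" if meta else ""
    return f"{rule.rule_id}: {text} => {rule.consequent}{suffix}"


def render_ruleset(ruleset: RuleSet) -> str:
    lines = [f"# ruleset: {ruleset.name}"]
    lines += [render_rule(r) for r in ruleset.rules]
    return "\n".join(lines) + "\n"


def load_ruleset(path=None) -> RuleSet:
    """Load a ruleset file; the packaged 26 expert rules when path is None."""
    if path is None:
        text = (
            resources.files("reefrules")
            .joinpath(f"data/{PACKAGED_RULESET}.rules")
            .read_text()
        )
        return parse_ruleset(text, name=PACKAGED_RULESET)
    with open(path) as fh:
        return parse_ruleset(fh.read(), name=str(path))


def expert_ruleset() -> RuleSet:
    return load_ruleset(None)


# ---------------------------------------------------------------------------
# Prediction and assessment
# ---------------------------------------------------------------------------

def predict(station: StationRecord, ruleset: RuleSet) -> Prediction:
    """Evaluate every rule on one station.

    UNCLASSIFIED (habitat None) iff no rule fires.  When several rules
    fire the conflict flag is set and the habitat is taken from the
    highest-confidence fired rule (ties broken by rule order); all fired
    rule ids are reported so conflicts remain diagnosable.
    """
    fired = [r for r in ruleset if r.matches(station.profile)]
    if not fired:
        return Prediction(station.station_id, None, [], None)
    best = max(
        enumerate(fired),
        key=lambda t: (t[1].confidence if t[1].confidence is not None else -1, -t[0]),
    )[1]
    return Prediction(
        station_id=station.station_id,
        habitat=best.consequent,
        fired_rule_ids=[r.rule_id for r in fired],
        confidence=best.confidence,
        conflict=len(fired) > 1,
    )


def predict_all(stations: list[StationRecord], ruleset: RuleSet) -> list[Prediction]:
    return [predict(s, ruleset) for s in stations]


def assess(stations: list[StationRecord], ruleset: RuleSet,
           *, habitat_averaged: bool = False) -> RuleSetAssessment:
    """Coverage and confidence of a ruleset on labeled stations.

    Per habitat: % classified = stations firing any rule / stations of
    that habitat; confidence = correctly labeled / classified.  The
    overall row pools stations across habitats (station-weighted) unless
    ``habitat_averaged`` is set.
    """
    unlabeled = [s.station_id for s in stations if s.habitat is None]
    if unlabeled:
        raise MiningError(f"unlabeled stations: {unlabeled[:5]}")
    notes: list[str] = []
    per_habitat: dict[str, tuple[float, float | None]] = {}
    preds = predict_all(stations, ruleset)
    rows = pd.DataFrame(
        {
            "habitat": [s.habitat for s in stations],
            "classified": [p.classified for p in preds],
            "correct": [p.classified and p.habitat == s.habitat
                        for s, p in zip(stations, preds)],
        }
    )
    for habitat in HABITATS:
        grp = rows[rows["habitat"] == habitat]
        if grp.empty:
            notes.append(f"habitat {habitat!r} absent from data; row omitted")
            continue
        n_cls = int(grp["classified"].sum())
        pct = n_cls / len(grp) * 100.0
        cl = float(grp["correct"].sum()) / n_cls * 100.0 if n_cls else None
        per_habitat[habitat] = (pct, cl)
    n_cls = int(rows["classified"].sum())
    if habitat_averaged and per_habitat:
        pcts = [v[0] for v in per_habitat.values()]
        cls_ = [v[1] for v in per_habitat.values() if v[1] is not None]
        overall_pct = float(np.mean(pcts))
        overall_cl = float(np.mean(cls_)) if cls_ else None
    else:
        overall_pct = n_cls / len(rows) * 100.0 if len(rows) else 0.0
        overall_cl = (
            float(rows["correct"].sum()) / n_cls * 100.0 if n_cls else None
        )
    return RuleSetAssessment(
        per_habitat=per_habitat,
        overall_classified_pct=overall_pct,
        overall_confidence=overall_cl,
        notes=notes,
    )


def assessment_frame(a: RuleSetAssessment) -> pd.DataFrame:
    rows = [
        {"habitat": h, "classified_pct": pct, "overall_cl_pct": cl}
        for h, (pct, cl) in a.per_habitat.items()
    ]
    rows.append(
        {
            "habitat": "Overall",
            "classified_pct": a.overall_classified_pct,
            "overall_cl_pct": a.overall_confidence,
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mutual exclusivity under cover constraints
# ---------------------------------------------------------------------------

@dataclass
class ConstraintSet:
    """Linear constraints a physically possible station satisfies.

    The substrate partition is constrained to 100 within the same
    annotation tolerance the ingest validator allows (0.5 points): some
    published rules (e.g. a sand cover below 60 together with a combined
    debris-related cover below 40) are only satisfiable inside that slack.
    """

    substrate_sum_100: bool = True
    substrate_tolerance: float = SUBSTRATE_SUM_TOLERANCE
    biotic_sum_max: float | None = 100.0
    depth_max: float = 50.0

    def bounds(self) -> list[tuple[float, float]]:
        out = []
        for a in BASE_ATTRIBUTES:
            if a == "depth":
                out.append((0.0, self.depth_max))
            elif a in ("topography", "complexity"):
                out.append((1.0, 5.0))
            else:
                out.append((0.0, 100.0))
        return out


@dataclass
class PairReport:
    rule_a: str
    rule_b: str
    status: str  # "SATISFIABLE", "EXCLUSIVE", "INCONCLUSIVE"
    witness: AttributeProfile | None = None


_STRICT_EPS = 1e-4
_ATTR_INDEX = {a: i for i, a in enumerate(BASE_ATTRIBUTES)}


def _condition_rows(cond: Condition):
    """Yield (coefficients, upper_bound) rows encoding the condition as
    A x <= b; strict bounds are shrunk by a small epsilon."""
    coef = np.zeros(len(BASE_ATTRIBUTES))
    for c in cond.components:
        coef[_ATTR_INDEX[c]] = 1.0
    if cond.lower is not None:
        b = -(cond.lower + (_STRICT_EPS if cond.lower_strict else 0.0))
        yield -coef, b
    if cond.upper is not None:
        b = cond.upper - (_STRICT_EPS if cond.upper_strict else 0.0)
        yield coef, b


def _pair_feasible(rule_a: ClassRule, rule_b: ClassRule,
                   constraints: ConstraintSet):
    A_ub, b_ub = [], []
    for cond in rule_a.antecedent + rule_b.antecedent:
        for coef, b in _condition_rows(cond):
            A_ub.append(coef)
            b_ub.append(b)
    if constraints.substrate_sum_100:
        coef = np.zeros(len(BASE_ATTRIBUTES))
        for a in SUBSTRATE_ATTRIBUTES:
            coef[_ATTR_INDEX[a]] = 1.0
        A_ub.append(coef)
        b_ub.append(100.0 + constraints.substrate_tolerance)
        A_ub.append(-coef)
        b_ub.append(-(100.0 - constraints.substrate_tolerance))
    if constraints.biotic_sum_max is not None:
        coef = np.zeros(len(BASE_ATTRIBUTES))
        for a in BIOTIC_ATTRIBUTES:
            coef[_ATTR_INDEX[a]] = 1.0
        A_ub.append(coef)
        b_ub.append(constraints.biotic_sum_max)
    res = linprog(
        c=np.zeros(len(BASE_ATTRIBUTES)),
        A_ub=np.array(A_ub),
        b_ub=np.array(b_ub),
        bounds=constraints.bounds(),
        method="highs",
    )
    return res


def check_exclusivity(ruleset: RuleSet,
                      constraints: ConstraintSet | None = None,
                      *, include_same_habitat: bool = True,
                      seed: int = 0) -> list[PairReport]:
    """Decide, for every rule pair, whether one station can satisfy both
    antecedents under the cover constraints.

    Decided by linear-programming feasibility (all conditions are linear
    in the base attributes); every witness is verified by re-evaluating
    both antecedents, with a randomized perturbation search as fallback,
    and reported INCONCLUSIVE when feasibility cannot be certified either
    way.  A rule is always SATISFIABLE with itself when its antecedent is
    feasible at all.
    """
    if constraints is None:
        constraints = ConstraintSet()
    rng = np.random.default_rng(seed)
    reports: list[PairReport] = []
    rules = list(ruleset)
    for i, ra in enumerate(rules):
        for rb in rules[i:]:
            if not include_same_habitat and ra.consequent == rb.consequent \
                    and ra.rule_id != rb.rule_id:
                continue
            res = _pair_feasible(ra, rb, constraints)
            if res.status == 2:  # infeasible
                reports.append(PairReport(ra.rule_id, rb.rule_id, "EXCLUSIVE"))
                continue
            if not res.success:
                reports.append(PairReport(ra.rule_id, rb.rule_id, "INCONCLUSIVE"))
                continue
            witness = AttributeProfile(
                **dict(zip(BASE_ATTRIBUTES, np.clip(res.x, 0, None)))
            )
            if ra.matches(witness) and rb.matches(witness):
                reports.append(
                    PairReport(ra.rule_id, rb.rule_id, "SATISFIABLE", witness)
                )
                continue
            # LP vertex may sit on a strict boundary; nudge randomly inside.
            found = None
            for _ in range(50):
                x = res.x + rng.uniform(-_STRICT_EPS, _STRICT_EPS, size=len(res.x))
                cand = AttributeProfile(**dict(zip(BASE_ATTRIBUTES, np.clip(x, 0, None))))
                if ra.matches(cand) and rb.matches(cand):
                    found = cand
                    break
            reports.append(
                PairReport(
                    ra.rule_id, rb.rule_id,
                    "SATISFIABLE" if found else "INCONCLUSIVE", found,
                )
            )
    return reports
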