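"""Mine top-K classification rules from labeled stations.

Discretizes 60 synthetic stations per habitat against the default cutpoint
grid and mines the 10 maximum-support rules with confidence >= 90% and at
most 3 conditions.  Support counts stations satisfying antecedent and
consequent; confidence is support over antecedent matches.
"""

from reefrules import (
    GeneratorConfig,
    MiningConstraints,
    default_archetypes,
    discretize,
    generate_stations,
    mine_topk,
)

archetypes = default_archetypes()
stations = generate_stations(
    archetypes, GeneratorConfig(n_per_habitat={h: 60 for h in archetypes}, seed=3)
)
transactions = discretize(stations)
rules = mine_topk(transactions, MiningConstraints(k=10, min_conf=90.0))
print(f"{len(rules)} rules (of K=10 requested), sorted by support:\n")
for r in rules:
    ant = " AND ".join(c.render() for c in r.antecedent)
    print(
        f"  {r.rule_id}: {ant} => {r.consequent}"
        f"   [support={r.support}, conf={r.confidence:.0f}%]"
    )
print(
    "\nHigh-support rules pick out each habitat's archetype cover band;"
    " lower-support rules describe within-habitat facies."
)
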