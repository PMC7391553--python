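"""Predict habitat with the packaged 26 expert rules and assess coverage.

Applies the packaged ruleset to 100 synthetic stations per habitat and
prints, per habitat, the percentage of stations that fire at least one
rule and the confidence (share of classified stations whose fired rule
names their generating habitat).
"""

from reefrules import (
    GeneratorConfig,
    assess,
    default_archetypes,
    expert_ruleset,
    generate_stations,
    predict,
)
from reefrules.stations import AttributeProfile

rules = expert_ruleset()
print(f"ruleset {rules.name}: {len(rules)} rules\n")

archetypes = default_archetypes()
stations = generate_stations(
    archetypes, GeneratorConfig(n_per_habitat={h: 100 for h in archetypes}, seed=4)
)
result = assess(stations, rules)
print(f"{'habitat':<12} {'% classified':>12} {'confidence %':>13}")
for habitat, (pct, cl) in result.per_habitat.items():
    print(f"{habitat:<12} {pct:>11.1f} {cl:>13.1f}")
print(f"{'Overall':<12} {result.overall_classified_pct:>11.1f} "
      f"{result.overall_confidence:>13.1f}")

# A single dense seagrass station fires SG1 (seagrass >= 80) at conf 100.
station = stations[0]
dense = AttributeProfile(
    depth=8, topography=1.5, complexity=1.5, sand=100, debris=0, boulder=0,
    rock=0, slab=0, live_coral=0, dead_coral=0, erect_algae=0, algal_turf=0,
    seagrass=85,
)
from reefrules import StationRecord

p = predict(StationRecord("demo", dense), rules)
print(f"\ndemo station, seagrass=85% -> {p.habitat} via {p.fired_rule_ids} "
      f"(conf {p.confidence}%)")
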