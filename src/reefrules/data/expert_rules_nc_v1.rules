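# ruleset: expert_rules_nc_v1
# Expert-selected habitat classification rules for New Caledonia reef and
# lagoon stations (26 rules across 5 habitats).  Confidence (conf, %) and
# support (n, stations fulfilling the rule) were computed on the original
# 3,145-station survey and are provenance metadata, not recomputed here;
# confusion lists the other habitats observed among antecedent-matching
# stations (% of those stations).
# Composite covers: algae = erect_algae + algal_turf;
# hard_coral = live_coral + dead_coral.
MA1: algae > 80 AND algal_turf < 20 => Macroalgae [conf=100, n=20]
MA2: 60 <= algae < 80 AND algal_turf <= 20 AND dead_coral < 5 => Macroalgae [conf=100, n=35]
MA3: 40 <= algae < 60 AND algal_turf < 20 AND hard_coral <= 20 => Macroalgae [conf=79, n=64, confusion=Sandy:7; Seagrass:11; Debris:2]
MA4: 20 <= algae < 40 AND algal_turf < 5 AND seagrass < 40 AND hard_coral < 5 => Macroalgae [conf=66, n=48, confusion=Sandy:25; Seagrass:8; Debris:1]
SG1: seagrass >= 80 => Seagrass [conf=100, n=93]
SG2: 60 <= seagrass < 80 => Seagrass [conf=98, n=100, confusion=Macroalgae:1; Debris:1]
SG3: 40 <= seagrass < 60 AND algae < 40 => Seagrass [conf=93, n=92, confusion=Macroalgae:4; Debris:2; Sandy:1]
SG4: 20 <= seagrass < 40 AND algae < 40 AND depth >= 10 => Seagrass [conf=81, n=34, confusion=Macroalgae:12; Debris:2; Sandy:5]
SA1: sand >= 80 AND seagrass < 20 AND algae < 20 => Sandy [conf=99, n=393, confusion=Seagrass:1]
SA2: sand >= 80 AND seagrass < 20 AND algae >= 20 AND algal_turf > 5 => Sandy [conf=97, n=69, confusion=Macroalgae:3]
SA3: 60 <= sand < 80 AND seagrass < 5 AND erect_algae < 20 => Sandy [conf=97, n=417, confusion=Live Coral:2.5; Debris:0.7]
SA4: 40 <= sand < 60 AND 5 <= live_coral < 40 AND complexity < 2 AND (debris + boulder + rock + slab) < 40 => Sandy [conf=87, n=88, confusion=Debris:8; Live Coral:4; Macroalgae:1]
SA5: 40 <= sand < 60 AND 5 <= live_coral < 40 AND 2 <= complexity < 3 AND (debris + boulder + rock + slab) < 40 => Sandy [conf=46, n=91, confusion=Live Coral:33; Debris:21]
LC1: live_coral >= 60 => Live Coral [conf=100, n=217]
LC2: 40 <= live_coral < 60 AND hard_coral >= 60 => Live Coral [conf=100, n=121]
LC3: 40 <= live_coral < 60 AND hard_coral < 60 => Live Coral [conf=73, n=61, confusion=Debris:15; Sandy:12]
LC4: 20 <= live_coral < 40 AND hard_coral >= 60 => Live Coral [conf=99, n=105, confusion=Debris:1]
LC5: 20 <= live_coral < 40 AND hard_coral < 60 AND (debris + boulder + rock + slab) < 40 AND complexity > 2 AND topography > 2 => Live Coral [conf=86, n=108, confusion=Sandy:11; Debris:3]
LC6: 15 <= live_coral < 20 AND dead_coral >= 20 AND algal_turf >= 5 => Live Coral [conf=89, n=41, confusion=Sandy:7; Debris:4]
D1: debris >= 60 => Debris [conf=100, n=107]
D2: 40 <= debris < 60 AND boulder >= 1 => Debris [conf=100, n=98]
D3: 40 <= debris < 60 AND boulder < 1 AND sand < 40 => Debris [conf=89, n=42, confusion=Live Coral:11]
D4: 40 <= debris < 60 AND boulder < 1 AND sand >= 40 AND complexity > 1.5 => Debris [conf=75, n=6, confusion=Sandy:12.5; Macroalgae:12.5]
D5: 20 <= debris < 40 AND sand < 60 AND (slab + boulder + rock) >= 20 => Debris [conf=97, n=113, confusion=Live Coral:3]
D6: 20 <= debris < 40 AND sand < 60 AND 5 < (slab + boulder + rock) < 20 AND complexity > 2 => Debris [conf=87, n=71, confusion=Live Coral:12; Sandy:1]
D7: 5 <= debris < 20 AND (slab + boulder + rock) >= 20 AND sand < 60 AND hard_coral < 40 => Debris [conf=87, n=103, confusion=Live Coral:7; Sandy:9]
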