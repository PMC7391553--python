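# Default habitat archetypes, version 1.
#
# One entry per habitat.  Substrate concentrations are Dirichlet parameters
# for the five-part substrate composition (scaled to percent covers summing
# to 100); biotic covers, ordinal scores and depth are (mean, sd) of
# truncated normals; fish gives per-family occurrence probability and mean
# abundance (individuals per station when the family is present).
#
# The parameterization places most stations inside the high-confidence
# bands of the packaged expert ruleset (dominant archetype cover, low
# confusion covers), which is what makes the end-to-end
# simulate -> predict check meaningful.
version: 1
archetype_minimum: 15.0
archetypes:
  Seagrass:
    archetype_attribute: seagrass
    substrate_alpha: {sand: 24.0, debris: 2.4, boulder: 1.2, rock: 1.2, slab: 1.2}
    biotic:
      live_coral: [2.0, 2.0]
      dead_coral: [1.0, 1.5]
      erect_algae: [3.0, 2.5]
      algal_turf: [3.0, 2.5]
      seagrass: [60.0, 18.0]
    topography: [1.5, 0.4]
    complexity: [1.5, 0.4]
    depth: [12.5, 2.5]
    fish:
      Acanthuridae: {occurrence: 0.20, abundance: 2.0}
      Scaridae: {occurrence: 0.25, abundance: 2.5}
      Labridae: {occurrence: 0.50, abundance: 3.0}
      Chaetodontidae: {occurrence: 0.15, abundance: 1.5}
      Lethrinidae: {occurrence: 0.80, abundance: 5.0}
      Mullidae: {occurrence: 0.70, abundance: 4.0}
      Balistidae: {occurrence: 0.60, abundance: 2.0}
      Dasyatidae: {occurrence: 0.30, abundance: 1.0}
      Elapidae: {occurrence: 0.25, abundance: 1.0}
      Carcharhinidae: {occurrence: 0.05, abundance: 1.0}
  Macroalgae:
    archetype_attribute: algae
    substrate_alpha: {sand: 19.5, debris: 4.5, boulder: 2.1, rock: 1.8, slab: 2.1}
    biotic:
      live_coral: [2.0, 2.0]
      dead_coral: [1.0, 1.5]
      erect_algae: [55.0, 14.0]
      algal_turf: [8.0, 5.0]
      seagrass: [4.0, 4.0]
    topography: [1.7, 0.5]
    complexity: [1.8, 0.5]
    depth: [10.0, 3.0]
    fish:
      Acanthuridae: {occurrence: 0.25, abundance: 2.0}
      Scaridae: {occurrence: 0.30, abundance: 2.5}
      Labridae: {occurrence: 0.55, abundance: 3.0}
      Chaetodontidae: {occurrence: 0.20, abundance: 1.5}
      Lethrinidae: {occurrence: 0.75, abundance: 4.5}
      Mullidae: {occurrence: 0.65, abundance: 3.5}
      Balistidae: {occurrence: 0.60, abundance: 2.0}
      Dasyatidae: {occurrence: 0.25, abundance: 1.0}
      Elapidae: {occurrence: 0.20, abundance: 1.0}
      Carcharhinidae: {occurrence: 0.05, abundance: 1.0}
  Sandy:
    archetype_attribute: sand
    substrate_alpha: {sand: 25.5, debris: 2.1, boulder: 0.9, rock: 0.6, slab: 0.9}
    biotic:
      live_coral: [3.0, 3.0]
      dead_coral: [2.0, 2.0]
      erect_algae: [2.0, 2.0]
      algal_turf: [4.0, 3.0]
      seagrass: [1.0, 2.0]
    topography: [1.3, 0.3]
    complexity: [1.3, 0.3]
    depth: [9.0, 4.0]
    fish:
      Acanthuridae: {occurrence: 0.50, abundance: 3.0}
      Scaridae: {occurrence: 0.45, abundance: 3.0}
      Labridae: {occurrence: 0.60, abundance: 4.0}
      Chaetodontidae: {occurrence: 0.40, abundance: 2.0}
      Lethrinidae: {occurrence: 0.45, abundance: 2.5}
      Mullidae: {occurrence: 0.50, abundance: 2.5}
      Balistidae: {occurrence: 0.40, abundance: 1.5}
      Dasyatidae: {occurrence: 0.35, abundance: 1.0}
      Elapidae: {occurrence: 0.30, abundance: 1.0}
      Carcharhinidae: {occurrence: 0.15, abundance: 1.0}
  Debris:
    archetype_attribute: debris
    substrate_alpha: {sand: 5.6, debris: 13.0, boulder: 2.8, rock: 2.2, slab: 3.4}
    biotic:
      live_coral: [5.0, 4.0]
      dead_coral: [10.0, 6.0]
      erect_algae: [4.0, 3.0]
      algal_turf: [10.0, 6.0]
      seagrass: [1.0, 1.5]
    topography: [2.4, 0.5]
    complexity: [2.6, 0.5]
    depth: [8.0, 4.0]
    fish:
      Acanthuridae: {occurrence: 0.80, abundance: 6.0}
      Scaridae: {occurrence: 0.75, abundance: 5.5}
      Labridae: {occurrence: 0.85, abundance: 6.0}
      Chaetodontidae: {occurrence: 0.70, abundance: 3.5}
      Lethrinidae: {occurrence: 0.30, abundance: 1.5}
      Mullidae: {occurrence: 0.30, abundance: 1.5}
      Balistidae: {occurrence: 0.30, abundance: 1.5}
      Dasyatidae: {occurrence: 0.05, abundance: 1.0}
      Elapidae: {occurrence: 0.08, abundance: 1.0}
      Carcharhinidae: {occurrence: 0.30, abundance: 1.0}
  Live Coral:
    archetype_attribute: live_coral
    substrate_alpha: {sand: 20.0, debris: 3.5, boulder: 1.2, rock: 1.1, slab: 1.2}
    biotic:
      live_coral: [48.0, 16.0]
      dead_coral: [18.0, 8.0]
      erect_algae: [3.0, 3.0]
      algal_turf: [8.0, 5.0]
      seagrass: [0.5, 1.0]
    topography: [3.2, 0.7]
    complexity: [3.4, 0.6]
    depth: [10.0, 4.0]
    fish:
      Acanthuridae: {occurrence: 0.90, abundance: 8.0}
      Scaridae: {occurrence: 0.85, abundance: 7.0}
      Labridae: {occurrence: 0.90, abundance: 8.0}
      Chaetodontidae: {occurrence: 0.90, abundance: 5.0}
      Lethrinidae: {occurrence: 0.25, abundance: 1.5}
      Mullidae: {occurrence: 0.25, abundance: 1.5}
      Balistidae: {occurrence: 0.30, abundance: 1.5}
      Dasyatidae: {occurrence: 0.02, abundance: 1.0}
      Elapidae: {occurrence: 0.05, abundance: 1.0}
      Carcharhinidae: {occurrence: 0.35, abundance: 1.5}
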