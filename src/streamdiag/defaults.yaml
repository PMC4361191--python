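# Default study conditions for the synthetic mesocosm experiment and the
# gradient survey. Control means are per-Surber-sample abundances (counts),
# except chlorophyll_a (mg/m^2) and familial_richness (families per sample).
# Effect entries are multiplicative factors applied at the high level of the
# treatment (low level = factor 1). Values absent from an effect map default
# to 1 (no response).
mesocosm:
  n_per_combination: 16
  years: 2
  noise_cv: 0.30
  control_means:
    chlorophyll_a: 2.5
    familial_richness: 18.0
    total_abundance: 400.0
    Oligochaeta: 30.0
    Leptoperla_varia: 12.0
    Nousia: 40.0
    Austrophlebioides: 25.0
    Orthocladiinae: 80.0
    Tanypodinae: 10.0
    Tipulidae: 4.0
    Scirtidae_larvae: 8.0
  # Nutrient enrichment strongly boosts algal biomass and mildly boosts
  # collector/grazer taxa; fine sediments strongly favour burrowing
  # Orthocladiinae midges and mildly depress sediment-sensitive mayflies,
  # stoneflies and familial richness. Only the two strong effects are
  # clearly significant in a 2-way ANOVA at 16 replicates.
  nutrient_effect:
    chlorophyll_a: 2.4
    Scirtidae_larvae: 1.16
    total_abundance: 1.12
    Austrophlebioides: 1.12
    Orthocladiinae: 1.1
    Oligochaeta: 1.1
    familial_richness: 1.08
    Tipulidae: 1.06
  sediment_effect:
    Orthocladiinae: 2.2
    Nousia: 0.88
    Leptoperla_varia: 0.88
    familial_richness: 0.9
    Austrophlebioides: 0.9
    Oligochaeta: 1.12
    Tanypodinae: 1.1
    Tipulidae: 1.08
    chlorophyll_a: 0.95
  light_effect:
    # shade cloth mildly reduces algal biomass and biofilm grazers
    chlorophyll_a: 0.9
    Orthocladiinae: 0.92
    Scirtidae_larvae: 0.92
  # optional between-year multipliers (off by default; the two leptophlebiid
  # mayflies are the taxa that differed between years in practice)
  year_effect: {}
survey:
  n_sites: 27
  grazing_range: [0.0, 0.8]
  sediment_coupling: 1.2
  nutrient_coupling: 0.0
  latent_noise_sd: 0.05
  site_noise_cv: 0.30
pipeline:
  standardization_mode: ratio
  k_discard: 2
  n_priority: 3
  n_members: 50
  mse_goal: 0.2
  max_epochs: 1000
  classification_threshold: 1.5
  field_control_grazing_cutoff: 0.01
  alpha: 0.05
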