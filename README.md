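# streamdiag

Diagnosing *which* stressor mediates land-use impacts on river
macroinvertebrate communities — deposited fine sediments or dissolved
nutrients — by training ensembles of small feed-forward neural networks on
stream-mesocosm experiment data and applying them to field survey sites
along a catchment-grazing gradient.

Field surveys are correlative: grazing intensity, sediment delivery and
nutrient runoff co-vary, so a weak correlation between a hypothesised
driver and river condition does not rule the driver out, and a strong one
does not prove causation. A mesocosm experiment breaks that confounding: a
balanced 2×2 nutrient × fine-sediment factorial (16 replicate flow-through
channels per combination, 64 records over two years) quantifies the
*community fingerprint* of each stressor in isolation. `streamdiag` learns
those fingerprints and looks for them in the field.

The package is aimed at freshwater ecologists and eco-informaticians who
want a fully reproducible, seeded implementation of this cross-scale
pattern-recognition pipeline, including a synthetic-data generator so every
stage is testable without any field data.

## Method

1. **Standardize & code.** Each of 11 biological responses (chlorophyll
   *a*, familial richness, total abundance, 8 taxon abundances) is divided
   by its control mean (low/low mesocosm channels of the same year; <1 %-
   grazing sites in the field), rounded to the nearest integer and clipped
   to [−2, +3].
2. **Screen & split.** Per stressor, the 2 variables least |Pearson-r|-
   correlated with the treatment level are discarded; the 64 records are
   split 32/32 so that the training half spans the observed levels of the
   3 strongest correlates ("priority inputs").
3. **Train ensembles.** 50 networks per stressor, each 9 inputs → 6 tan-sig
   → 3 tan-sig → 1 linear output, y = f(Σwᵢxᵢ + b), batch Levenberg–
   Marquardt to an MSE goal of 0.2 (loose on purpose — 85 parameters vs 32
   records). The ensemble prediction is the mean ± SD of the 50 outputs;
   mean ≥ 1.5 classifies a record as high-stress.
4. **Validate.** Error rate (%) on the held-out 32 records.
5. **Diagnose.** Survey sites are standardized against field controls,
   scored by each ensemble on the clipped 1–2 stress scale, and the scores
   are regressed on the grazing proportion: F = (R²/1)/((1−R²)/(n−2)),
   p from the upper F tail. A significant sediment regression with a null
   nutrient regression yields the verdict **sediment-mediated**.

See `docs/methods.md` for the model, parameter and calibration details.

## Worked example

```bash
streamdiag run-all --seed 0 -o out/
```

prints:

```
nutrient: validation error 9.4% | slope=-0.123 R^2=0.087 F(1,25)=2.39 p=0.135
sediment: validation error 18.8% | slope=+0.617 R^2=0.434 F(1,25)=19.14 p=0.000
verdict: sediment-mediated
```

Reading: both ensembles learned their mesocosm fingerprint well enough to
generalise (validation errors of 9.4 % and 18.8 % against a 50 % chance
level). Applied to the 27 survey sites, the predicted *sediment* level
rises significantly with the proportion of catchment under grazing
(slope +0.62 on the 1–2 stress scale per unit grazing proportion,
R² = 0.43, p < 0.001) while the predicted *nutrient* level does not
(p = 0.135) — communities at heavily grazed sites resemble the
high-sediment, not the high-nutrient, mesocosm communities. Individual
replicates vary: across 200 re-simulated studies the sediment regression
is significant in ~79 % and the nutrient one in ~14 % (the residual
nutrient rate reflects cross-talk through taxa that respond to both
stressors; see `docs/methods.md`).

`out/` contains every intermediate artifact: `mesocosm.csv`, `survey.csv`
(+ `survey_truth.csv` with the latent stress levels), the standardized
feature table, per-stressor splits, 2 × 50 serialized networks with
manifests, per-record prediction tables, `scores.csv`, `report.json`
(ANOVA table, error rates, regressions, verdict) and `manifest.json`
(config hash + seeds). Rerunning with the same seed reproduces every file
byte-identically. The stages are also available separately
(`simulate-mesocosm`, `simulate-survey`, `train`, `validate`, `diagnose`),
each reading the files the previous stage wrote.

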