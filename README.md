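# rowseg

Row-segment selection and plot-trimming analysis for UAV plant-phenotyping
trials.

## The problem

Breeding trials plant genotypes in small multi-row plots (here: four rows,
3.05 m long, 0.76 m row spacing, 0.76 m alleys). Plants in a plot's outer
rows compete with neighboring genotypes and plants near the alleys enjoy
extra light and space, so remote-sensing traits measured on border rows and
row ends carry systematic bias and extra noise. When canopy traits are
extracted from UAV imagery and LiDAR per *row segment* (RS), the analyst must
decide which rows to pool — all four (RS1234), the inner pair (RS23), the
outer pair (RS14), or single rows (RS1–RS4) — and whether to *trim* 40 cm
off each row end. `rowseg` quantifies how those choices affect:

1. **Entry-mean repeatability** (broad-sense H²) of each trait, from the
   mixed model `y_ij = mu + H_i + R_j + e_ij` (hybrid random, replicate
   fixed, REML variance components):

   `H² = sigma²_H / (sigma²_H + sigma²_e / rep)`

2. **End-season yield prediction** accuracy (Pearson r between predicted and
   observed yield) with epsilon-SVR (RBF kernel `exp(-sigma·||u-v||²)`) under
   repeated k-fold cross-validation with subpopulation-balanced folds and a
   per-fold grid search over (sigma, cost).

3. **Scheme comparison** via factorial ANOVA (trim + year + selection +
   selection:year, sequential sums of squares) with LSD letter groupings at
   alpha = 0.05.

Because real multi-year UAV campaigns are not portable, the package ships a
first-class synthetic trial generator (`rowseg.synthetic_field`) with known
ground truth: genotype/replicate effects, border-row mean shift and extra
noise, alley-end effects, growth driven by growing degree days (GDD, base
10 °C, caps at 10/30 °C), LiDAR-like point clouds, RGB and 15-band
hyperspectral rasters, and yield generated from the *inner* rows only — the
configuration under which every claim here is tested.

## Worked example

```python
from rowseg import (TrialConfig, simulate_trial, simulate_trait_observations,
                    repeatability_sweep)
from rowseg.factor_analysis import anova_factorial, lsd_test, lsd_report

trial = simulate_trial(TrialConfig(n_genotypes=50, n_reps=2, rng_seed=1))
obs = simulate_trait_observations(trial, [300., 500., 750., 1000.])
h2 = repeatability_sweep(obs)
print(h2.groupby("selection")["H2"].mean().round(3).sort_values(ascending=False))
```

```
selection
RS1234    0.959
RS23      0.952
RS3       0.900
RS14      0.884
RS2       0.880
RS4       0.802
RS1       0.651
```

Pooling more rows raises repeatability; the inner pair RS23 is statistically
indistinguishable from all four rows, while single border rows (RS1, RS4)
are markedly less repeatable — the border effect at work. The factorial
ANOVA and LSD make that precise:

```python
print(anova_factorial(h2, terms=("trimmed", "selection"))[["term", "df", "F", "p"]])
print(lsd_report(lsd_test(h2, "selection", response="H2"), "selection"))
```

```
     term  df        F     p
  trimmed   1   0.3340 0.566
selection   6 208.1724 0.000
 Residual  48      NaN   NaN

selection  mean letters
   RS1234 0.959       a
     RS23 0.952       a
      RS3 0.900       b
     RS14 0.884       b
      RS2 0.880       b
      RS4 0.802       c
      RS1 0.651       d
```

The row-selection effect is overwhelming (p < 0.001) while end trimming
changes nothing (p = 0.57) — trimming removes material that the
early-season bounding boxes exclude anyway. The same comparison for yield
prediction (RS23 features vs RS14 features) is run by
`rowseg.studies.prediction_direction_study`.

The full pipeline — simulate, build the row-segment grid, render and extract
traits, sweep repeatability, predict yield, compare schemes — runs from the
shell:

```sh
rowseg run-all --seed 42 --out runs/demo
rowseg make-fixtures --kind tiny_cloud --seed 3 --out fixtures/
```

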