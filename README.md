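# oncolysis

Susceptibility scoring and molecular-correlate analysis for oncolytic-virus
cell-line screens.

## The problem

Oncolytic-virus programs screen panels of tumor cell lines by live-cell
imaging: each line is infected at a grid of multiplicities of infection
(MOI, in PFU per cell — here {0.001, 0.01, 0.1, 1, 10} plus an untreated
control), and confluence is scanned every 2 h for up to 170 h in triplicate
wells across three biological repeats.  The analysis questions are:

1. **How susceptible is each line?**  Per well, confluence is normalized to
   its first scan (fold change), integrated over time (trapezoidal AUC),
   averaged over technical triplicates, and divided by the untreated AUC of
   the same repeat.  Significance per MOI comes from a one-way ANOVA with
   Dunnett's many-to-one comparison against the untreated condition.  The
   composite score is

   `score = (Σ_m AUC_norm(m)) × r`,

   where the rank multiplier `r` is the rank of the lowest significant MOI
   (1 for the lowest MOI up to 5 for the highest; 6 if nothing reaches
   p ≤ 0.05).  Lower score = more susceptible; lines are ranked 1..N.

2. **What predicts susceptibility?**  Bulk RNA-seq counts from the
   uninfected lines are normalized with the median-of-ratios size-factor
   estimator, log2-transformed and z-scored per gene; per-line mean
   expression of candidate viral-entry receptors and antiviral genes is then
   correlated (Spearman `ρ = 1 − 6Σd²/(n(n²−1))` for untied ranks, with
   exact permutation inference at small n) against the susceptibility rank.

The package also covers the surrounding assay arithmetic — 4PL and
hyperbolic standard-curve calibration with detection-limit substitution
(below fit: LLOD/√2; above: upper limit), and plaque-assay titers
`PFU/mL = mean countable plaques × dilution / volume` with the 5–50
countable window — plus a synthetic-data generator (logistic growth with
delayed Hill-type killing, negative-binomial counts with planted receptor
effects) so the whole pipeline is testable with known ground truth.

## Worked example

```python
from oncolysis import (SimulationDesign, SusceptibilityScorer, auc_table,
                       default_panel, simulate_counts, simulate_panel,
                       normalize_expression, correlate_with_susceptibility)

design = SimulationDesign(seed=1)                 # 2 h grid to 170 h, 5 MOIs + UT
wells = simulate_panel(default_panel(), design)   # 11-line synthetic screen
scorer = SusceptibilityScorer(alpha=0.05).fit(auc_table(wells))
print(scorer.summary()[["cell_line", "susceptibility_rank", "score",
                        "rank_multiplier", "auc_sum"]].to_string(index=False))
```

```
cell_line  susceptibility_rank     score  rank_multiplier  auc_sum
    BXPC3                    1  0.788833                1 0.788833
    ASPC1                    2  0.974706                1 0.974706
   SW1990                    3  1.647117                1 1.647117
  Capan-1                    4  1.662253                1 1.662253
      U87                    5  4.682649                2 2.341325
  938-mel                    6  8.612868                3 2.870956
PaTu8988t                    7  9.022784                3 3.007595
  624-mel                    8  9.992264                3 3.330755
    SUIT2                    9 15.848897                4 3.962224
    LN229                   10 17.230006                4 4.307502
 MiaPaca2                   11 29.731183                6 4.955197
```

BXPC3 is already inhibited at the lowest MOI (multiplier 1) and loses most
of its growth (AUC sum 0.79 of untreated across five MOIs), so it ranks
most susceptible; MiaPaca2 never reaches significance (multiplier 6) and
barely responds (AUC sum 4.96 out of a maximal 5), ranking last.

```python
cm, truth = simulate_counts(default_panel(), scorer.scores_.to_dict(), seed=2)
corr = correlate_with_susceptibility(normalize_expression(cm),
                                     scorer.ranks_.to_dict())
print(corr.head(6)[["gene", "estimate", "p", "p_bh"]].to_string(index=False))
```

```
   gene  estimate            p     p_bh
   RIGI -0.990909 3.762572e-09 0.000002
NECTIN2 -0.981818 8.403066e-08 0.000011
  ITGB6 -0.981818 8.403066e-08 0.000011
   OAS1 -0.981818 8.403066e-08 0.000011
  ISG15 -0.945455 1.118304e-05 0.001163
NECTIN1 -0.900000 1.599714e-04 0.013864
```

The planted receptor genes come out with strongly negative Spearman
estimates — high expression in low-rank (susceptible) lines — exactly the
signature the correlation stage is built to detect.

The same stages are scriptable from the shell:

```bash
oncolysis simulate --seed 1 --outdir synthetic
oncolysis auc synthetic/timeseries.csv --out auc.csv
oncolysis score auc.csv --out dose_response.csv
oncolysis correlate synthetic/counts.tsv synthetic/sample_map.csv ranking.csv
oncolysis titer 20 30 --dilution-factor 1e5 --volume-ml 0.5
oncolysis report --outdir results --seed 1
```

## Layout

| module | contents |
| --- | --- |
| `oncolysis.kinetics` | `WellSeries`, baseline/untreated normalization, trapezoid AUC, death index |
| `oncolysis.doseresp` | one-way ANOVA, Dunnett quadrature, rank multiplier, `SusceptibilityScorer`, type-III two-way ANOVA, Sidák/Tukey/Fisher-LSD |
| `oncolysis.expression` | median-of-ratios size factors, log/scale transforms, Spearman/Pearson with exact small-n inference, `MedianOfRatiosNormalizer` |
| `oncolysis.assays` | `FourPLCurve`, `HyperbolicCurve`, detection-limit substitution, plaque titer |
| `oncolysis.simulate` | growth/kill/secretion simulators, negative-binomial count generator, study-shaped default panel |
| `oncolysis.io` / `oncolysis.cli` | CSV/TSV/MTX readers and writers, `PipelineConfig`, `run_pipeline`, `oncolysis` CLI |

See `docs/methods.md` for the models, defaults and design choices.
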