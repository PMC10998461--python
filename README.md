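# flexms

Neuronal-avalanche analysis of brain flexibility, built for studies that
relate resting-state MEG/EEG dynamics to clinical disability in multiple
sclerosis (and usable for any cohort with source-reconstructed ROI time
series and clinical scores).

Resting-state large-scale brain activity is not stationary: it unfolds in
aperiodic bursts — *neuronal avalanches* — that transiently recruit sets
of brain regions. The set of regions recruited during one avalanche is its
*pattern*, and the number of **unique** patterns a person expresses over a
recording, the **functional repertoire**, is a compact summary of how
flexible their brain dynamics are. In relapsing–remitting multiple
sclerosis (RRMS) flexibility is elevated relative to healthy controls and
tracks disability, while in the secondary-progressive phenotype (SPMS) it
does not — so the repertoire–disability relationship is phenotype-
dependent, and a regression predicting disability needs the phenotype ×
repertoire interaction.

## What the package computes

Given an ROI × time matrix `x` (n_rois × n_samples):

1. z-transform each ROI; mark events where |z| > 3 (two-tailed, strict);
2. bin the event raster (OR within bins of length L samples);
3. segment avalanches: maximal runs of bins with ≥ 1 active ROI;
4. estimate the branching ratio
   σᵢ = ∏ⱼ (n(j+1)/n(j))^(1/(N−1)) per avalanche (geometric mean of
   successive recruitment-count ratios) and σ = geometric mean of the σᵢ;
   choose L so σ is closest to 1 (criticality);
5. count the functional repertoire (unique avalanche patterns, union over
   a subject's recordings);
6. cohort statistics: HC-vs-patient rank-sum and 3-group Kruskal–Wallis
   with Benjamini–Hochberg FDR, phenotype-wise Spearman correlations, the
   5-fold cross-validated OLS
   `EDSS ~ repertoire + phenotype + repertoire×phenotype`
   (standardized continuous predictor, VIF diagnostics, NRMSE =
   out-of-fold RMSE / response range), and a 10,000-iteration permutation
   test comparing the phenotypes' absolute standardized residuals.

Synthetic generators with exact ground truth back every stage: a
Galton–Watson branching process on the ROI set (known branching parameter
and segmentation, embeddable in Gaussian noise) and a clinical cohort with
a known repertoire–disability model. See `docs/methods.md` for models,
conventions, and known estimator biases.

## Worked example

```python
from flexms import (SyntheticSeriesSpec, simulate_branching_raster,
                    events_to_timeseries, zscore_transform, binarize,
                    select_bin_length, bin_raster, extract_avalanches,
                    branching_ratio_overall, functional_repertoire)

spec = SyntheticSeriesSpec(n_rois=90, n_bins=6000, sigma_true=1.0,
                           drive_rate=0.02, samples_per_bin=3, seed=42)
raster, truth = simulate_branching_raster(spec)     # critical avalanches
series = events_to_timeseries(raster, spec)         # embed in noise

z = zscore_transform(series)
events = binarize(z, 3.0)
bin_length, sigma_table = select_bin_length(events, (1, 2, 3, 4, 5))
avalanches = extract_avalanches(bin_raster(events, bin_length))
sigma = branching_ratio_overall(avalanches)
repertoire = functional_repertoire(avalanches, subject_id="demo")

print(f"sigma by bin length: { {k: round(v, 3) for k, v in sigma_table.items()} }")
print(f"chosen bin length: {bin_length}")
print(f"avalanches: {avalanches.n_avalanches}, sigma = {sigma:.3f}")
print(f"functional repertoire: {repertoire.size} unique patterns")
```

prints

```
sigma by bin length: {1: 1.012, 2: 0.999, 3: 1.058, 4: 1.013, 5: 1.003}
chosen bin length: 2
avalanches: 1579, sigma = 0.999
functional repertoire: 670 unique patterns
```

The simulated process is critical (true branching parameter 1.0), and the
estimated σ sits near 1 at every bin length — the signature the bin-length
selection keys on; bin length 2 wins with σ = 0.999. The subject expressed
1,579 avalanches of which 670 had distinct recruitment patterns: that 670
is the flexibility statistic carried into the cohort analyses.

## Analysis scripts

Numbered drivers under `analysis/` run the package end to end on synthetic
data and write tables to `results/`:

- `01_branching_recovery.py` — how the σ estimator behaves versus the true
  branching parameter under sparse and dense avalanche seeding
  (`results/estimator_recovery.csv`);
- `02_subject_dynamics.py` — the full per-subject pipeline on 20 simulated
  subjects × 2 recordings, with union pooling
  (`results/subject_dynamics.csv`);
- `03_cohort_stats.py` — the cohort battery on a study-sized synthetic
  cohort (`results/group_tests.csv`, `correlations.csv`,
  `regression.json`, `permutation.json`);
- `04_robustness_sweeps.py` — stability of the group difference over the
  threshold × bin-length grid (`results/sweeps.csv`).

A thin CLI covers the same ground on files:
`flexms subject --series s.h5`, `flexms cohort --cohort-csv cohort.csv`,
`flexms sweep --config run.yaml`, `flexms synth series|cohort --out ...`.

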