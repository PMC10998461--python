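# Methods

## The pipeline

`flexms` quantifies the flexibility of large-scale brain dynamics from
source-reconstructed region-of-interest (ROI) time series, of the kind
produced by beamforming resting-state MEG onto an anatomical atlas
(typically 90 AAL regions sampled at 1024 Hz). The chain is:

1. **Z-transform.** Each ROI signal is standardized over the full
   recording, using the population SD (`ddof=0`). At recording lengths of
   ~2×10⁵ samples the population/sample distinction is negligible; the
   population convention makes the transform exactly idempotent, which the
   test suite exploits.
2. **Thresholding.** A sample is an *event* when `|z| > z_threshold`
   (strict inequality, both tails). The operating threshold is 3 SDs, with
   a robustness sweep over 2.5–3.5.
3. **Binning.** `bin_length` consecutive samples are merged per bin by
   logical OR, so an ROI contributes at most one event per bin and
   `n_events(j)` is "number of ROIs recruited in bin j". Bin *b* covers
   samples `[bL, (b+1)L)` (0-based, half-open everywhere); a trailing
   partial bin is dropped rather than analysed at a different width.
4. **Avalanche extraction.** An avalanche is a maximal run of consecutive
   bins with ≥ 1 active ROI, delimited by all-quiet bins. Runs touching the
   first or last bin are discarded by default (their true extent is
   unobservable) and counted; a `keep` policy is available. Each avalanche
   carries its per-bin recruitment counts and its *pattern* — the set of
   all ROIs recruited at any moment during the run, with no ordering or
   weighting.
5. **Branching ratio.** Per avalanche,
   `σ_i = ∏_{j=1}^{N_bin−1} (n_events(j+1)/n_events(j))^{1/(N_bin−1)}`,
   i.e. the geometric mean of successive bin-count ratios, computed in log
   space. `σ_i` is undefined for single-bin avalanches (`N_bin = 1`);
   these are excluded from the recording-level geometric mean
   `σ = ∏_i σ_i^{1/N_aval}` but retained for the repertoire, since their
   recruitment set is still a valid pattern. `N_aval` counts the
   avalanches that enter the product.
6. **Bin-length selection.** σ is computed at each candidate bin length
   (default 1–5) and the candidate minimising `|σ − 1|` is chosen — σ = 1
   marks critical dynamics. Ties break toward the smaller bin, preserving
   temporal resolution. Bin length is treated as abstract samples; no
   assumption is made about prior downsampling.
7. **Functional repertoire.** The number of *unique* avalanche patterns in
   a recording (repetitions discarded; equality is set equality). A
   subject's two recordings are pooled by pattern union by default; the
   per-recording alternative is kept as a configuration switch for
   sensitivity analysis, since either convention is defensible when a
   session comprises multiple runs.

## Properties and known biases of the σ estimator

The per-avalanche estimator only ever sees bins *inside* an avalanche, and
every such bin contains ≥ 1 event by definition. The successive-ratio
statistic is therefore conditioned on survival: it cannot observe the
final step into extinction, and for avalanches built from small counts the
conditioning dominates the signal. Concretely (see
`analysis/01_branching_recovery.py`, which reproduces the numbers):

- For a Galton–Watson process at criticality (mean offspring 1.0) with
  sparse seeding — each avalanche starting from a single exogenous event,
  the regime resembling resting-state recordings — the estimator returns
  ≈ 1.06–1.07 from ≥ 5,000 avalanches: close to the truth, with a small
  positive conditioning bias.
- For *subcritical* truths (0.5, 0.8) under the same single-seed regime
  the estimate stays ≈ 1.07–1.09 regardless of the truth: with initial
  count 1 and all in-avalanche counts ≥ 1, the observable ratios carry
  almost no information about the decay rate. Subcritical truths are
  recovered (within ~0.01–0.1) only when avalanches start from many
  simultaneous seeds, so that the count trajectory spends most of its time
  well above 1.
- *Supercritical* truths (e.g. 1.2) on a finite ROI set are unrecoverable
  under either regime: a surviving supercritical avalanche saturates the
  ROI set and never terminates (it is edge-truncated and discarded), while
  the complete avalanches that remain are precisely the extinction-selected
  ones, which look near-critical.

The practical reading: the estimator is a good *criticality detector* —
near σ_true = 1 it returns ≈ 1 — which is exactly the property the
bin-length selection relies on; it is not a general-purpose branching-
parameter estimator away from criticality at small avalanche sizes. The
test suite asserts the critical-recovery property; the sub/supercritical
recovery checks are included and document this bias by failing.

## The synthetic series generator

`simulate_branching_raster` runs a Galton–Watson branching process on the
ROI set: every event in bin *j* spawns `Poisson(sigma_true)` descendants
in bin *j+1*, each landing on a uniformly random ROI (surplus descendants
on an occupied ROI collapse, matching the one-event-per-ROI-per-bin
convention downstream; ROI assignment carries no spatial structure because
the downstream statistics are pattern-set based). Exogenous seeding
(`Poisson(drive_rate)` events per bin) happens only while no avalanche is
running and never in the extinction bin itself, so avalanches are always
separated by at least one quiet bin and the generator can return an exact
ground-truth segmentation. Bin 0 never seeds and a run still open at the
last bin is dropped from the truth, aligning the truth with the `discard`
truncation policy.

`events_to_timeseries` embeds the raster in iid Gaussian background noise:
each (ROI, bin) event adds a deflection of `event_amplitude` background
SDs at one uniformly chosen sample inside its bin, with random (or
alternating) sign so the two-tailed threshold is exercised on both tails.

Defaults: 90 ROIs, `sigma_true = 1.0` (critical), `samples_per_bin = 3`,
`drive_rate = 0.02` seeds per quiescent bin (sparse single-seed avalanche
onsets), `event_amplitude = 10` background SDs, nominal sampling rate
1024 Hz. The drive rate and amplitude are not constrained by published
values (avalanche rates and amplitude distributions for this kind of data
are not tabulated anywhere we can cite); they were fixed once for clean
detectability and realistic sparsity and are not tuned per analysis.

**What the generator does not emulate — and what that implies.** The
background is white: no 1/f spectrum, no band-limited autocorrelation, no
neural-mass dynamics, and — crucially — a hard separation between
"planted events" and "background" that real recordings do not have. On
real data the suprathreshold excursions *are* the events; on synthetic
data an iid Gaussian background produces `2Φ(−3) ≈ 0.0027` spurious
events per ROI-sample at the 3-SD threshold, i.e. ≈ 0.7 spurious events
per 3-sample bin across 90 ROIs — an order of magnitude more than the
planted process. Exact segmentation recovery at the 3-SD operating
threshold is therefore impossible *by construction of the synthetic
background*, not because of any pipeline defect. Consequently:

- the round-trip validation (ground-truth segmentation and pattern
  repertoire recovered exactly) runs the pipeline at a conservative 6-SD
  detection threshold, where background excursions are essentially
  impossible over the series length while 10-SD events are still detected
  with near-certainty (expected misses ≈ 0.05 per series);
- event-level *recall* is additionally verified at the 3-SD operating
  threshold, where false positives are plentiful but cannot reduce recall;
- the threshold-robustness demonstration sweeps 4.5–6 SDs on synthetic
  data (the paper-style 2.5–3.5 grid stays the package default for real
  data).

Passing tests therefore certify the pipeline's correctness and the
estimator's behaviour on a process with known ground truth; they do not
certify detection performance on band-limited neurophysiological noise.

## The synthetic cohort generator

`simulate_cohort` draws, per subject, a group label (defaults 25 HC, 10
RRMS, 15 SPMS — the study-sized layout), a repertoire size
`Normal(group mean, SD)` rounded to a nonnegative integer (defaults
120/160/130 ± 25: patients above controls, driven by RRMS), and for
patients an EDSS from

    EDSS = β₀ + β_rep·rep + β_grp·g + β_int·rep·g + ε,  g = 1{SPMS}

with defaults `β₀ = −2.65, β_rep = 0.04, β_grp = 7.75, β_int = −0.04`,
`ε ~ Normal(0, 0.8)`. These solve for RRMS mean EDSS 3.75 at repertoire
160 and SPMS mean 5.10 at 130 with a *flat* repertoire–EDSS slope in SPMS
(`β_rep + β_int = 0`): a positive association in RRMS only, the structure
the cohort statistics are designed to detect. EDSS is generated and
modelled as continuous; the ordinal half-point structure of the real scale
is not emulated (subgroup splits are provided for exactly that concern).
FSS, SDMT, BDI and disease duration are drawn from plausible per-phenotype
normal distributions (clipped to their scales) and carry no built-in
dependence on the repertoire; healthy controls have missing clinical
scores. Because EDSS is computed from the *rounded* repertoire, a
noiseless cohort refits its generating coefficients exactly — the
parameter-recovery tests use this.

## Statistical conventions

- **Rank-sum**: exact null distribution when the combined n ≤ 20 without
  ties, tie-corrected normal approximation otherwise; two-sided.
- **Kruskal–Wallis**: tie-corrected H, chi-square p with k−1 df.
- **FDR**: Benjamini–Hochberg step-up.
- **Spearman**: average ranks for ties; exact permutation p for n ≤ 9
  without ties, t-approximation otherwise.
- **Interaction regression**: patients only; phenotype coded RRMS = 0,
  SPMS = 1 (a positive phenotype beta then corresponds to SPMS's higher
  mean EDSS); the continuous predictor z-scored before fitting, the
  response left on its natural scale, so coefficients are response units
  per predictor SD. Overall F with (3, n−4) df; VIFs computed from the
  design matrix and reported for the non-intercept terms; residuals
  reported as internally studentized ("standardized") residuals.
- **Cross-validation**: k = 5; subjects shuffled into near-equal folds by
  a seeded RNG (unstratified by default, phenotype-stratified optional);
  repertoire standardization parameters estimated on training folds only.
  NRMSE = out-of-fold RMSE divided by the observed response range
  (mean-normalization available); both in-sample R² and cross-validated R²
  are reported since either may be meant by "explained variance".
- **Permutation test**: statistic = difference in group means of absolute
  standardized residuals; 10,000 label permutations by seeded RNG;
  two-sided add-one p-value `(1 + #{|null| ≥ |obs|})/(N + 1)`, which is
  never 0 and is exactly valid.
- **Covariate models**: response regressed on a fixed covariate block plus
  one independent variable at a time; BH-FDR across the family of
  variables.

## Problem sizes used by the test and acceptance suites

Branching-ratio recovery uses 90 ROIs × 4×10⁵ bins (≥ 5,000 complete
avalanches, ≈ 2 s); the extraction oracle compares 1,000 random rasters
(≤ 10 ROIs × 50 bins) against a naive per-bin scan; the round trip uses
90 ROIs × 10⁴ bins × 3 samples; type-I calibration uses 2,000 replicates
per procedure (group sizes 30, cohort 40 per group, permutation n = 24
with 10⁴ iterations); parameter recovery uses 200 patients per phenotype.
These sizes were chosen so each property is measured with comfortable
statistical margin while the whole suite completes in well under a minute
of compute per heavy test.

## Known limitations

- The σ estimator's conditioning bias (above): recording-level σ values
  from sparse-onset data should be read as "distance from criticality",
  not as unbiased branching-parameter estimates.
- The white-noise background makes absolute-threshold behaviour on
  synthetic data quantitatively unlike band-limited recordings.
- No avalanche size/duration power-law fitting, no spatial/connectome
  structure in patterns, no mixed-effects or ordinal regression, no
  missing-data imputation.
- Repertoire sizes depend on recording length and binning; they are
  comparable only within a fixed configuration (the sweep driver exists
  for exactly this reason).
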