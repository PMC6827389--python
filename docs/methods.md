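# Methods

## Problem and data model

The pipeline predicts, for every 30 m grid cell containing mature host trees
and every year, the probability that the cell is attacked by bark beetles in
that year, given (a) the spatial arrangement of hosts and of attacks in the
two preceding years within a 19×19-cell window around the focal cell, (b) the
cell's long-term mean annual temperature, and (c) the regional outbreak stage
of the previous year. The 19×19 window (±9 cells, 270 m) covers the dispersal
range of most beetles, so the window plus the two auxiliary covariates —
361 + 2 = 363 variables — is treated as a sufficient summary of the locally
available information.

A landscape series consists of a binary host map, one binary attack map per
calendar year (consecutive years), a temperature surface aligned to the same
grid, and an annual regional disturbed-timber volume series covering at least
the same years. NODATA cells are excluded from the host set, never imputed.

## Window encoding and example construction

Cell codes: 0 non-host (or outside the landscape — windows are zero-padded at
boundaries), 1 host not recently attacked, 2 attacked two years before the
target year, 3 attacked one year before (the more recent attack wins). Target
years are all years with two predecessors. By default a cell attacked in any
earlier year is removed from the eligible focal set for later years
(beetle-killed trees are no longer hosts); `mortality=False` restores the
behaviour of keeping them. The stage covariate attached to an example is the
stage of the year before the target year, keeping the printed 363-variable
arithmetic; temperature is z-scored with training-set statistics when it
enters a model.

Outbreak stages partition years by terciles of the regional volume series:
at or below the 33rd percentile (linear interpolation between order
statistics) is *background*, at or below the 66th is *gradation*, above it
*culmination* — i.e. ties at a cutoff resolve to the lower class, and the
middle tercile is read as the build-up phase per ecological convention. The
source literature is internally inconsistent about which elevated stage name
belongs to which tercile; the mapping here is a pinned convention and is
configurable in spirit (stages are plain labels; swapping names does not
change any computation).

## Classifier

The network has two branches: a stack of same-padded (optionally strided)
convolutions over the window — by default the codes are expanded into three
binary planes (host, attacked year−1, attacked year−2) — whose flattened
output is concatenated with the auxiliary covariates (z-scored temperature,
one-hot stage) before a stack of fully connected layers and a final two-unit
softmax. Training minimizes categorical cross-entropy with AdamW-style
decoupled weight decay; batch normalization follows each convolution/dense
layer and inverted dropout follows each dense activation. The layers,
backpropagation and optimizer are implemented directly in numpy (float32
training, float64 metric arithmetic), which keeps the package dependency-free
at this scale and fully deterministic: all randomness (initialization,
shuffling, dropout) derives from one config seed, so fixed seed ⇒
bit-identical training history.

Protocol choices replicated deliberately:

- **Epoch selection.** The weights kept are those of the epoch with the
  highest evaluation-set accuracy (first epoch on ties). When the evaluation
  set is the test set this leaks the test set into model selection; it is
  replicated because it is the published protocol. Passing a genuine
  validation split to `train()` gives the leak-free variant.
- **Threshold calibration.** The continuous probability is binarized at the
  grid threshold (0 to 1, step 0.001) maximizing F1 on the *training* set;
  ties break toward the larger threshold, and `probability ≥ threshold`
  counts as positive.
- **No imbalance correction by default** (≈3.5% positives); an optional
  class-weight switch exists.

The full published architecture (five convolutions, five dense layers, 60
epochs) is the `ModelConfig()` default; its exact widths were never printed
and are free configuration here. `ModelConfig.small()` — two convolutions,
two dense layers, batch 512, learning rate 2·10⁻³, dropout 0.1, 8 epochs —
is the desk-scale configuration used throughout the tests; it was tuned once
on simulated landscapes and then frozen. The linear baseline is logistic
regression on the 363 flattened inputs (stage one-hot expanded).

## Evaluation suite

With disturbed as the positive class and N = tp+tn+fp+fn:

| statistic | definition |
|---|---|
| accuracy | (tp+tn)/N |
| precision | tp/(tp+fp) |
| recall | tp/(tp+fn) |
| F1 | 2·precision·recall/(precision+recall) |
| Conditional Kappa | (precision − (tp+fn)/N)/(1 − (tp+fn)/N) |
| True Skill Statistic | precision + tn/(tn+fn) − 1 |

The TSS definition above (precision plus negative predictive value minus one)
is the form this pipeline is built around and reproduces the published
results; note it differs from the classical sensitivity + specificity − 1,
which is exposed separately as `tss_conventional`. Undefined ratios (zero
denominators, e.g. recall in a year without attacks) are returned as NaN,
never raised.

Gleichläufigkeit scores each year-over-year step of each series +1/2, 0 or
−1/2 by the sign of the difference and averages |G_i(x)+G_i(y)| over the
n−1 steps (the printed source formula lists "> 0" twice; the third case is
read as "< 0", the evident intent). It is symmetric and shift-invariant.

`backsolve_confusion` inverts the metric definitions: from
(N, accuracy, precision, recall) the observed positives are
P = N(1−accuracy) / ((1−recall) + recall(1−precision)/precision), whence tp,
fn, fp and tn follow; results are rounded to integers and verified against
the forward formulas (tolerance 10⁻³). This turns published summary tables
into exact testable matrices. Error-free inputs (precision = recall =
accuracy = 1) do not determine prevalence; the solver then returns an even
split with fp = fn = 0 by convention.

## Experiment designs

*Year holdout* withholds entire calendar years (forward-prediction analog):
train on the remaining years, calibrate the threshold on training data, score
the held-out years pooled and per year, and emit per-year probability and
binary maps (sentinel −1 on unscored cells). *Random holdout* withholds a
random unstratified fraction (default 20%) and additionally aggregates
observed and predicted annual disturbed areas (positive cells × 0.09 ha) and
their Gleichläufigkeit. The annual series uses the test examples by default;
`annual_on="all"` scores every eligible cell-year instead — on small
simulated landscapes the 20% subsample of a few hundred attacked cells per
year is dominated by binomial subsampling noise, so the package's end-to-end
tests use the full-series switch for the temporal-agreement check while
keeping all pooled metrics strictly out of sample. Experiments are
bit-reproducible given (config, seed).

## Synthetic outbreak generator

The simulator emulates the statistical structure the analysis assumes, not
beetle biology. Host maps are thresholded smoothed Gaussian noise (spatially
autocorrelated, fraction 0.6 by default); temperature is a linear
north–south gradient (5–9 °C) with white noise. Attacks follow a logistic
contagion process: for each eligible host cell and year,

    logit p = baseline + w_recent·K1 + w_older·K2 + w_temp·(T − T̄) + forcing(year)

where K1, K2 are truncated-exponential-kernel-weighted counts of cells
attacked one and two years earlier (radius 9 cells = the window radius,
e-folding 1.5 cells), and the forcing is a two-pulse Gaussian train (pulse
centres at 27% and 76% of the series, width 1.8 yr, amplitude 3.1) standing
in for the regional population wave. The first two years are spin-up without
neighbour terms. Attacked cells leave the host pool (`kill_hosts`), so no
cell is attacked twice. The regional volume series is attacked cells × 25 m³
with lognormal observation noise (σ = 0.08), so stage classification is
exercised end to end. All streams (host, temperature, attacks, volume noise)
are independent substreams of one root seed.

Default parameters (baseline −7.5, w_recent 3.0, w_older 1.0, w_temp 0.25)
were calibrated once so that the `two_wave` preset (100×100 cells, 14 years)
yields ≈3.5% attacked cell-years — the class imbalance typical of this kind
of survey data — with strong local contagion over a very low background
rate: that contrast is what makes attacks predictable from the window, and
matches the predictability regime the method is designed for. Realized
attack waves peak one to two years after the forcing pulses (contagion
momentum), and with some seeds the two waves partially merge; structural
tests therefore pin seeds and allow ±2 years on peak positions.

What the simulator does **not** emulate: temperature-driven beetle phenology
and voltinism, wind-throw triggers, management interventions (sanitation
felling), observation error in the attack maps, and multi-scale host
heterogeneity. Tests passing on these landscapes show the pipeline recovers
a known contagious signal at realistic imbalance; they do not certify
performance on real survey data.

## Problem sizes and numerical choices

Desk-scale settings used by the test suite: the two-wave acceptance landscape
is 100×100 cells × 14 years (≈60,000 examples), trained 6 epochs with
`ModelConfig.small()`; unit tests use 30×30 to 80×80 landscapes and a
miniature one-convolution network. Metric computation is double precision;
training is single precision. The max-F1 threshold grid step is 0.001.
Windows are stored as int8 codes and expanded per batch, keeping memory flat.

## Known limitations

- The published architecture's exact dimensions are not reproduced (never
  printed); the defaults are this package's own.
- Full-scale training (≈1.9 M examples, 60 epochs) is supported by the same
  code paths but is CPU-bound in this pure-numpy implementation; expect hours
  rather than the published ~1 GPU-hour.
- The back-solver requires an error-free-consistent summary; inconsistent
  (mistyped) table values raise rather than being repaired.
- Gleichläufigkeit on short series (here 12 annual steps) has a broad
  permutation null; temporal-agreement conclusions at this scale are
  correspondingly weak.
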