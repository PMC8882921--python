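# Methods

## Model and procedure

EEG microstate analysis assumes that spontaneous scalp EEG passes through a
small number K of quasi-stable potential topographies, each persisting for
roughly 80–120 ms, and that the instantaneous map's *shape* (not its
polarity or strength) identifies the active state. The pipeline follows the
standard four stages:

1. **Candidate extraction.** Trials are common-average referenced; the GFP
   curve (per-sample spatial SD) is computed and the topographies at its
   strict local maxima — the high-SNR moments — become candidate maps.
   Candidates are normalized to unit GFP on entry to clustering (config
   `normalize=False` keeps raw microvolts; the choice is exposed because
   either convention is defensible and published work rarely states it).
2. **Template detection.** Polarity-invariant modified k-means: assignment
   by maximal squared spatial correlation, template update by the dominant
   eigenvector of the assigned maps' scatter matrix. The eigenvector is the
   exact maximizer of the within-cluster sum of squared projections, which
   makes the objective (total R²) non-decreasing across iterations; the
   sign-aligned mean is available as a config alternative. Each fit runs
   `restarts` (default 20) random initializations seeded from distinct
   candidate maps and keeps the best total explained variance.
3. **Segmentation.** Every sample is assigned to the template of highest
   |R| (signed R available for ERP-style polarity-aware data). Zero-variance
   samples inherit the previous label. No temporal smoothing by default; a
   minimum-segment rejection (`min_segment_ms`) is available but off.
4. **Features.** Per state: mean segment duration (ms), coverage (fraction
   of samples), occurrence (segments/s), and the segment-boundary transition
   matrix (row-normalized, diagonal 0). Truncated first/last segments count
   toward duration and occurrence. These definitions satisfy
   `occurrence × duration = coverage` exactly, which the tests exploit.

## Clustering strategies

The five orchestrations differ only in grouping. Step-1 fits use
`max_iterations = 1000`; the final pooled fit uses 5000. Each grouping unit
contributes its K templates to the next stage. The final K is fixed at 4 by
default (the canonical microstate count); unsetting `k_fixed` scans K = 2..8
and selects by the cross-validation criterion
`CV = σ̂² ((N−1)/(N−1−K))²` (minimized; ties at numerical zero — which arise
on noiseless data — resolve to the smallest K), or by a GEV-gain elbow rule.
Case 5 reuses Case 3's cached per-trial templates for its first step, so the
strategies' timing differences reflect clustering arrangement only; its
final step pools the low- and high-level templates of one rating dimension
into a single clustering (`separate_levels=True` fits them separately for
sensitivity analysis). Rating binarization is an exhaustive 1-D 2-means over
sorted split points (globally optimal), thresholding at the centroid
midpoint with ties labeled low.

## Synthetic data generator

Each trial is a semi-Markov sequence of K templates: successive states drawn
proportional to occurrence weights with no immediate self-transition, dwell
times a rounded normal (mean 100 ms, SD 20% of the mean, floor 2 samples).
The instantaneous signal is `s·a(t)·template[state]` with
`a(t) = |sin(2πf t)| + 0.1` (f = 10 Hz, the alpha band; the rectified
envelope guarantees two GFP peaks per cycle), `s = ±1` per segment
(exercising polarity invariance), plus white Gaussian noise scaled so
RMS(signal)/RMS(noise) equals the configured SNR; the result is
average-referenced. Templates are low-order circular harmonics on a ring
montage (dipolar/quadrupolar patterns akin to the canonical left-right,
anterior-posterior, and center-surround microstate maps) with a small seeded
higher-order admixture; they are zero-mean, unit-GFP, pairwise |R| < 0.95.
Subject topographies perturb the group templates (SD 0.05) and renormalize.
Conditions attach to videos (balanced low/high); every subject watches every
video once in randomized order. The high condition multiplies one designated
state's occurrence weight by (1 − effect_size), default 0.15 on the last
state, and drives the 9-point valence/arousal ratings (clipped rounded
normals, mean 3 low / 7 high, SD 1).

What the generator does *not* emulate: volume-conducted 1/f spectra,
artifacts, channel covariance of a real 10–20 montage, non-stationary dwell
distributions, or rating noise decoupled from the condition. Passing tests
therefore demonstrate correctness of the algorithms under the model's
assumptions, not robustness to real-data violations of them.

## Default study conditions and problem sizes

The reference synthetic study is 8 subjects × 10 trials, 32 channels,
250 Hz, 20 s trials, K = 4, SNR 5. At these settings all five strategies
recover the generative templates with mean matched |R| > 0.99, and backfit
mean durations land near the generative 100 ms dwell. The statistical
calibration uses generator state sequences directly (the tested procedure —
features → Lilliefors gate → Welch t / rank-sum → Benjamini–Hochberg —
consumes label sequences, so EEG synthesis adds nothing): 200 null datasets
of 32 + 32 trials for the false-positive rate, and 20 repeats of
32 subjects × 40 trials for power against a 15% occurrence reduction.

## Numerical choices

- Spatial correlation is computed on mean-centered, unit-RMS maps;
  zero-variance maps raise errors in metrics but are skipped (counted)
  during candidate extraction.
- GFP peaks are strict local maxima; plateaus yield no peak. A
  `min_peak_distance_ms` config (default 0) thins peaks greedily by height.
- Assignment ties break to the lowest template index; empty clusters are
  re-seeded from the worst-fit map of a multi-member cluster, which cannot
  empty another cluster and preserves objective monotonicity.
- Template matching is exhaustive over permutations (K ≤ 8), maximizing
  total |R|, with signs flipped so matched R ≥ 0.
- The Benjamini–Hochberg adjustment is `p₍ᵢ₎·m/i` with a reverse cumulative
  minimum and cap at 1; the FDR family is all state × feature comparisons
  within one rating dimension.
- Lilliefors gating requires *both* groups to pass at α = 0.05; groups with
  zero range are routed to the rank-sum branch. Welch (unequal-variance)
  t-test is used on the normal branch.
- Cronbach's α uses unbiased variances with trials as observations and
  strategies as items; zero total variance raises a degenerate-α error.
- All randomness flows from integer seeds through `numpy.random.default_rng`;
  identical configs reproduce datasets and fits bit-for-bit.

## Known limitations

- The modified k-means is a local optimizer. On *structured* inputs (maps
  drawn from distinct templates plus noise) it attains the global partition
  optimum found by exhaustive search; on isotropic, structure-free random
  maps local optima are plentiful and no restart budget guarantees the
  global optimum. The oracle tests therefore use structured instances and
  only bound (not equate) the objective on unstructured ones.
- I/O supports delimited channels × samples matrices with JSON sidecars;
  binary EEG interchange formats are out of scope (convert upstream).
- Hierarchical (AAHC/TAAHC) clustering is not implemented; published
  comparisons find it equivalent for microstate detection.
- Case 5 requires at least two distinct rating values per subject; subjects
  with constant or missing ratings are excluded from that dimension with a
  warning.
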