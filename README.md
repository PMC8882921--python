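# microstates

Detection and comparison of **EEG microstates** — the quasi-stable scalp
potential topographies (~80–120 ms) into which continuous multichannel EEG
can be segmented — with a focus on *task-state* recordings, where the choice
of topographic clustering strategy matters.

The package is for EEG researchers who want to (a) detect microstate
templates from multi-subject, multi-trial recordings with any of five
clustering strategies, (b) backfit templates and extract the standard
temporal features, and (c) compare strategies on quality, task efficacy and
computational cost. A built-in synthetic-data generator with known ground
truth makes every stage testable without access to restricted databases.

## The method

For average-referenced EEG `V(t)` over `N` electrodes, the **global field
power** is the spatial standard deviation

    GFP(t) = sqrt( (1/N) Σᵢ (Vᵢ(t) − V̄(t))² )

Topographies at GFP local maxima are high-SNR candidate maps. Similarity of
two maps `p, q` is measured by the **global map dissimilarity** (each map
centered and scaled to unit GFP before differencing) and the **spatial
correlation** `R = 1 − GMD²/2`, numerically the Pearson correlation of the
channel vectors.

Templates come from a **polarity-invariant modified k-means**: maps are
assigned to the template maximizing `R²` (sign ignored), and each template
is updated as the dominant eigenvector of the scatter matrix of its
assigned (centered, normalized) maps; multiple random restarts keep the run
with the highest explained variance.

Five orchestrations of this primitive are implemented:

| strategy | grouping for step-1 clustering | final step |
|---|---|---|
| Case 1 | per subject (all trials pooled) | pooled subject templates |
| Case 2 | per video (all subjects pooled) | pooled video templates |
| Case 3 | per single trial | pooled trial templates |
| Case 4 | random near-equal trial groups | pooled group templates |
| Case 5 | per trial, then per subject × rating level (low/high by adaptive 2-means binarization of valence or arousal ratings) | pooled level templates |

Backfitting assigns each sample to the template of highest `|R|`; the
resulting label sequence yields duration, coverage, occurrence, transition
probabilities, and the **global explained variance**

    GEV = Σₜ (Corr(V(t), V_c(t)) · GFP(t))² / Σₜ GFP(t)²

Strategy evaluation covers |R| correlation matrices against a reference set
(with row/column/overall diagonal ratios), per-trial GEV with Cronbach's α
consistency across strategies, normality-gated group statistics (Lilliefors
→ Welch t-test or Wilcoxon rank-sum, two-sided, Benjamini–Hochberg FDR),
and per-stage wall-clock timings.

## Worked example

```python
import microstates as m
from microstates.strategies import Dataset, extract_all_candidates

cfg = m.SimulationConfig(n_subjects=4, n_trials_per_subject=6,
                         trial_duration=10.0, snr=5.0, seed=42)
sim = m.simulate_dataset(cfg)
ds = Dataset(sim.recordings, sim.manifest)
candidates = extract_all_candidates(ds)
params = m.ClusteringParams(seed=42)
truth = m.MicrostateSet(sim.truth.templates)

for name in ("case1", "case3", "case5_valence"):
    res = m.run_strategy(name, ds, params, candidates)
    match = m.match_templates(res.final, truth)
    print(f"{name:14s} mean matched |R| vs truth = {match.mean_r:.4f} "
          f"(step-1 time {res.timings['step1']:.2f} s)")

res = m.run_strategy("case3", ds, params, candidates)
seq = m.backfit(ds.recordings[0], res.final)
feats = m.microstate_features(seq)
gev = m.compute_gev(ds.recordings[0], seq)
print(f"trial S01/T01: total GEV = {gev['total']:.3f}")
for k in range(4):
    print(f"  MS{k+1}: duration {feats.duration_ms[k]:6.1f} ms, "
          f"coverage {feats.coverage[k]:.3f}, occurrence {feats.occurrence[k]:.2f}/s")
```

prints

```
case1          mean matched |R| vs truth = 0.9998 (step-1 time 0.34 s)
case3          mean matched |R| vs truth = 0.9998 (step-1 time 0.95 s)
case5_valence  mean matched |R| vs truth = 0.9998 (step-1 time 1.02 s)
trial S01/T01: total GEV = 0.963
  MS1: duration   93.2 ms, coverage 0.252, occurrence 2.70/s
  MS2: duration   89.8 ms, coverage 0.242, occurrence 2.70/s
  MS3: duration  106.6 ms, coverage 0.309, occurrence 2.90/s
  MS4: duration   93.7 ms, coverage 0.197, occurrence 2.10/s
```

All three strategies recover the four generative templates nearly exactly
(`|R| ≈ 1`), trial-based step-1 clustering costs more wall-clock time than
subject-based, the backfit explains ~96% of GFP-weighted topographic
variance, and mean state durations sit near the generative 100 ms dwell.

A command-line interface mirrors the library:

```bash
microstates simulate --subjects 8 --trials 10 --seed 1 --out ds/
microstates detect --manifest ds/manifest.csv --strategy case3 --seed 1 --out out/
microstates features --manifest ds/manifest.csv --templates out/templates.csv --out features.csv
microstates run --seed 1 --out full_run/     # full pipeline + report.json
```

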