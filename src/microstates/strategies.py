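"""The five topographic clustering strategies over a multi-trial dataset.

All five orchestrations share the same primitive (polarity-invariant
modified k-means over GFP-peak candidate maps) and differ only in how the
data are grouped before the first clustering step and how intermediate
candidate templates are pooled afterwards:

* Case 1 (trial-subject sequence): step 1 clusters each subject's pooled
  trials; step 2 clusters the pooled subject templates.
* Case 2 (subject-trial sequence): step 1 clusters each video's pooled
  subjects; step 2 clusters the pooled video templates.
* Case 3 (single trial): step 1 clusters every trial separately; step 2
  clusters all trial templates.
* Case 4 (random grouping): trials are dealt into near-equal random groups,
  each group clustered, then the group templates clustered.
* Case 5 (task guided, top down): per-trial templates (as Case 3 step 1)
  are regrouped by a per-subject binarization of the chosen rating dimension
  (1-D 2-means, threshold at the centroid midpoint), clustered per
  subject x level, and the pooled level templates clustered once per
  dimension.

Every clustering step is wall-clock timed so the strategies' computational
cost can be compared on equal inputs (all consume the same cached per-trial
candidate maps).
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusteringParams, MicrostateSet, select_cluster_number
from .core import Recording, extract_candidate_maps, stack_maps
from .exceptions import ConfigError, InvalidInputError, NoSplitError

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "CandidateBank",
    "StrategyResult",
    "extract_all_candidates",
    "random_grouping",
    "binarize_ratings",
    "run_case1",
    "run_case2",
    "run_case3",
    "run_case4",
    "run_case5",
    "run_strategy",
]


@dataclass
class Dataset:
    """Recordings plus their manifest (subject, trial, video, ratings)."""

    recordings: list[Recording]
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        keys = {(r.subject_id, r.trial_id) for r in self.recordings}
        mkeys = set(zip(self.manifest["subject_id"], self.manifest["trial_id"]))
        if len(keys) != len(self.recordings):
            raise InvalidInputError("duplicate (subject, trial) among recordings")
        if keys != mkeys:
            raise InvalidInputError("manifest rows do not match recordings one-to-one")
        names = {tuple(r.channel_names) for r in self.recordings}
        if len(names) > 1:
            raise InvalidInputError("all recordings must share one channel set")

    def recording(self, subject_id, trial_id) -> Recording:
        for r in self.recordings:
            if r.subject_id == subject_id and r.trial_id == trial_id:
                return r
        raise KeyError((subject_id, trial_id))


@dataclass
class CandidateBank:
    """Step-1 clustering outputs: one MicrostateSet per grouping unit."""

    units: dict  # grouping key -> MicrostateSet
    step_name: str = "step1"

    @property
    def pooled_maps(self) -> np.ndarray:
        """All unit templates flattened into one (sum K, N) matrix."""
        return np.vstack([ms.templates for ms in self.units.values()])


@dataclass
class StrategyResult:
    """Final templates, intermediate bank(s), per-stage wall-clock timings."""

    strategy: str
    final: MicrostateSet
    banks: dict = field(default_factory=dict)  # step name -> CandidateBank
    timings: dict = field(default_factory=dict)  # step name -> seconds (+ total)
    config: dict = field(default_factory=dict)


def extract_all_candidates(
    ds: Dataset, normalize: bool = True, min_peak_distance_ms: float = 0.0
) -> dict:
    """Per-trial candidate maps, keyed by (subject_id, trial_id).

    Cached per dataset by the caller; every strategy consumes the same bank
    so timing differences reflect the clustering arrangement only.
    """
    out = {}
    for rec in ds.recordings:
        maps = extract_candidate_maps(
            rec, normalize=normalize, min_peak_distance_ms=min_peak_distance_ms
        )
        out[(rec.subject_id, rec.trial_id)] = stack_maps(maps) if maps else np.empty((0, rec.n_channels))
    return out


def _timed_cluster(
    maps: np.ndarray,
    params: ClusteringParams,
    max_iterations: int,
    seed: int,
) -> tuple[MicrostateSet, float]:
    t0 = time.perf_counter()
    ms = select_cluster_number(maps, params, max_iterations=max_iterations, seed=seed)
    return ms, time.perf_counter() - t0


def _step1(
    groups: dict,
    params: ClusteringParams,
    min_maps: int,
    label: str,
) -> tuple[CandidateBank, float]:
    """Cluster each group of maps; skip groups with too few maps (warning)."""
    units = {}
    elapsed = 0.0
    for i, (key, maps) in enumerate(groups.items()):
        if maps.shape[0] < min_maps:
            warnings.warn(f"{label} unit {key!r} has {maps.shape[0]} candidate maps; skipped")
            continue
        ms, dt = _timed_cluster(maps, params, params.max_iterations, seed=params.seed + i)
        ms.provenance["unit"] = key
        units[key] = ms
        elapsed += dt
    if not units:
        raise InvalidInputError(f"{label}: no unit had enough candidate maps")
    return CandidateBank(units=units, step_name=label), elapsed


def _min_maps(params: ClusteringParams) -> int:
    return params.k_fixed if params.k_fixed is not None else params.k_range[0]


def _final_step(
    bank: CandidateBank, params: ClusteringParams
) -> tuple[MicrostateSet, float]:
    return _timed_cluster(
        bank.pooled_maps, params, params.final_max_iterations, seed=params.seed + 10_000
    )


def _result(strategy, final, banks, timings, params) -> StrategyResult:
    timings = dict(timings)
    timings["total"] = sum(timings.values())
    final.provenance["strategy"] = strategy
    return StrategyResult(
        strategy=strategy,
        final=final,
        banks=banks,
        timings=timings,
        config={"params": params.__dict__.copy()},
    )


def run_case1(
    ds: Dataset, params: ClusteringParams | None = None, candidates: dict | None = None
) -> StrategyResult:
    """Trial-subject sequence: per-subject clustering, then across subjects."""
    params = params or ClusteringParams()
    candidates = candidates if candidates is not None else extract_all_candidates(ds)
    groups: dict = {}
    for (subject, _trial), maps in candidates.items():
        groups.setdefault(subject, []).append(maps)
    groups = {s: np.vstack(m) for s, m in groups.items()}
    bank, t1 = _step1(groups, params, _min_maps(params), "per-subject")
    final, t2 = _final_step(bank, params)
    return _result("case1", final, {"step1": bank}, {"step1": t1, "step2": t2}, params)


def run_case2(
    ds: Dataset, params: ClusteringParams | None = None, candidates: dict | None = None
) -> StrategyResult:
    """Subject-trial sequence: per-video clustering, then across videos."""
    params = params or ClusteringParams()
    if ds.manifest["video_id"].isna().any():
        raise InvalidInputError("case 2 requires video_id for every trial")
    candidates = candidates if candidates is not None else extract_all_candidates(ds)
    video_of = {
        (r.subject_id, r.trial_id): r.video_id
        for r in ds.recordings
    }
    groups: dict = {}
    for key, maps in candidates.items():
        groups.setdefault(video_of[key], []).append(maps)
    groups = {v: np.vstack(m) for v, m in groups.items()}
    bank, t1 = _step1(groups, params, _min_maps(params), "per-video")
    final, t2 = _final_step(bank, params)
    return _result("case2", final, {"step1": bank}, {"step1": t1, "step2": t2}, params)


def run_case3(
    ds: Dataset, params: ClusteringParams | None = None, candidates: dict | None = None
) -> StrategyResult:
    """Single-trial based: every trial clustered separately, then pooled."""
    params = params or ClusteringParams()
    candidates = candidates if candidates is not None else extract_all_candidates(ds)
    bank, t1 = _step1(dict(candidates), params, _min_maps(params), "per-trial")
    final, t2 = _final_step(bank, params)
    return _result("case3", final, {"step1": bank}, {"step1": t1, "step2": t2}, params)


def random_grouping(trial_keys: list, n_groups: int, rng: np.random.Generator) -> list[list]:
    """Deal shuffled trials into n_groups near-equal partitions (sizes differ <= 1)."""
    if n_groups < 1:
        raise ConfigError("n_groups must be >= 1")
    if n_groups > len(trial_keys):
        raise ConfigError("n_groups exceeds the number of trials")
    order = rng.permutation(len(trial_keys))
    shuffled = [trial_keys[i] for i in order]
    parts = np.array_split(np.arange(len(shuffled)), n_groups)
    return [[shuffled[i] for i in part] for part in parts]


def run_case4(
    ds: Dataset,
    n_groups: int = 40,
    params: ClusteringParams | None = None,
    candidates: dict | None = None,
) -> StrategyResult:
    """Random grouping: trials dealt into groups, clustered, then pooled."""
    params = params or ClusteringParams()
    candidates = candidates if candidates is not None else extract_all_candidates(ds)
    keys = list(candidates.keys())
    rng = np.random.default_rng(params.seed)
    partition = random_grouping(keys, n_groups, rng)
    groups = {
        f"group{g + 1:03d}": np.vstack([candidates[k] for k in part])
        for g, part in enumerate(partition)
    }
    bank, t1 = _step1(groups, params, _min_maps(params), "per-group")
    final, t2 = _final_step(bank, params)
    return _result("case4", final, {"step1": bank}, {"step1": t1, "step2": t2}, params)


def binarize_ratings(ratings: np.ndarray | list) -> tuple[np.ndarray, float]:
    """Adaptive low/high split of one subject's 9-point ratings.

    Exhaustive 1-D 2-means over the sorted split points (globally optimal);
    the threshold is the midpoint of the two cluster centroids; a rating is
    "high" iff it exceeds the threshold (ties labeled low).

    Returns (boolean high-mask aligned with the input, threshold).
    """
    r = np.asarray(ratings, dtype=float)
    if np.unique(r).size < 2:
        raise NoSplitError("all ratings identical; cannot binarize")
    s = np.sort(r)
    best_cost, best_thr = np.inf, None
    for i in range(1, s.size):
        lo, hi = s[:i], s[i:]
        if lo[-1] == hi[0]:
            continue  # identical values cannot straddle a split
        cost = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if cost < best_cost:
            best_cost = cost
            best_thr = (lo.mean() + hi.mean()) / 2.0
    return r > best_thr, float(best_thr)


def run_case5(
    ds: Dataset,
    dimension: str = "valence",
    params: ClusteringParams | None = None,
    candidates: dict | None = None,
    trial_bank: CandidateBank | None = None,
    separate_levels: bool = False,
) -> StrategyResult:
    """Task-guided top-down clustering along one rating dimension.

    Step 1 reuses (or fits) the per-trial templates of Case 3; step 2
    binarizes each subject's ratings; step 3 clusters each subject x level
    cell of trial templates; step 4 pools all low- and high-level templates
    of the dimension into one final clustering (or one per level with
    ``separate_levels``, for sensitivity analysis).
    """
    if dimension not in ("valence", "arousal"):
        raise ConfigError("dimension must be 'valence' or 'arousal'")
    params = params or ClusteringParams()
    candidates = candidates if candidates is not None else extract_all_candidates(ds)
    t1 = 0.0
    if trial_bank is None:
        trial_bank, t1 = _step1(dict(candidates), params, _min_maps(params), "per-trial")

    level_groups: dict = {"low": {}, "high": {}}
    for subject, sub_df in ds.manifest.groupby("subject_id", sort=True):
        ratings = sub_df[dimension].to_numpy(dtype=float)
        if np.isnan(ratings).any():
            warnings.warn(f"subject {subject!r} has missing {dimension} ratings; excluded")
            continue
        try:
            high, _thr = binarize_ratings(ratings)
        except NoSplitError:
            warnings.warn(f"subject {subject!r} has constant {dimension} ratings; excluded")
            continue
        for (_, row), is_high in zip(sub_df.iterrows(), high):
            key = (row["subject_id"], row["trial_id"])
            if key not in trial_bank.units:
                continue
            level = "high" if is_high else "low"
            level_groups[level].setdefault(subject, []).append(trial_bank.units[key].templates)

    banks = {"step1": trial_bank}
    timings = {"step1": t1}
    level_templates: dict = {}
    min_maps = _min_maps(params)
    for level in ("low", "high"):
        groups = {
            s: np.vstack(ts) for s, ts in level_groups[level].items() if np.vstack(ts).shape[0] >= min_maps
        }
        skipped = set(level_groups[level]) - set(groups)
        for s in skipped:
            warnings.warn(f"subject {s!r} {level}-{dimension} cell has < K templates; skipped")
        if groups:
            bank, dt = _step1(groups, params, min_maps, f"per-subject-{level}")
            banks[f"step2_{level}"] = bank
            timings[f"step2_{level}"] = dt
            level_templates[level] = bank.pooled_maps
    if not level_templates:
        raise InvalidInputError("case 5: no subject x level cell had enough templates")

    if separate_levels:
        finals = {}
        t3 = 0.0
        for level, maps in level_templates.items():
            ms, dt = _timed_cluster(maps, params, params.final_max_iterations, params.seed + 20_000)
            finals[level] = ms
            t3 += dt
        final = finals.get("high") or finals.get("low")
        final.provenance["per_level"] = {lvl: m.templates for lvl, m in finals.items()}
    else:
        pooled = np.vstack(list(level_templates.values()))
        final, t3 = _timed_cluster(pooled, params, params.final_max_iterations, params.seed + 20_000)
    timings["step3"] = t3
    final.provenance["dimension"] = dimension
    return _result(f"case5_{dimension}", final, banks, timings, params)


def run_strategy(
    name: str,
    ds: Dataset,
    params: ClusteringParams | None = None,
    candidates: dict | None = None,
    **kwargs,
) -> StrategyResult:
    """Dispatch by strategy name: case1..case4, case5_valence, case5_arousal."""
    if name == "case1":
        return run_case1(ds, params, candidates)
    if name == "case2":
        return run_case2(ds, params, candidates)
    if name == "case3":
        return run_case3(ds, params, candidates)
    if name == "case4":
        return run_case4(ds, kwargs.pop("n_groups", 40), params, candidates)
    if name in ("case5_valence", "case5_arousal", "case5"):
        dim = kwargs.pop("dimension", name.split("_", 1)[1] if "_" in name else "valence")
        return run_case5(ds, dim, params, candidates, **kwargs)
    raise ConfigError(f"unknown strategy {name!r}")
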