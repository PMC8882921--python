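"""Backfitting templates to continuous EEG and microstate time-series features.

Backfitting assigns every EEG sample to the template with the highest
absolute spatial correlation (polarity-blind, matching the clustering
convention). From the resulting label sequence the four standard microstate
features are computed per state: mean duration (ms), coverage (fraction of
samples), occurrence (segments per second) and the transition probability
matrix. Global explained variance (GEV) quantifies how much of the
GFP-weighted topographic variance the assigned templates capture:

    GEV = sum_t (Corr(V(t), V_c(t)) * GFP(t))^2 / sum_t GFP(t)^2
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import MicrostateSet
from .core import Recording, average_reference, compute_gfp, is_average_referenced
from .exceptions import DegenerateMapError, InvalidInputError

__all__ = [
    "LabelSequence",
    "TrialFeatures",
    "backfit",
    "compute_gev",
    "microstate_features",
    "features_table",
]


@dataclass
class LabelSequence:
    """Per-sample microstate assignment for one trial.

    labels are 0-based state indices in [0, K); fit_correlation holds the
    per-sample |R| (or signed R in polarity-aware mode) to the assigned
    template.
    """

    labels: np.ndarray
    fit_correlation: np.ndarray
    fs: float
    K: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.fit_correlation = np.asarray(self.fit_correlation, dtype=float)
        if self.labels.shape != self.fit_correlation.shape:
            raise InvalidInputError("labels and fit_correlation must align")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.K):
            raise InvalidInputError("labels out of range [0, K)")


@dataclass
class TrialFeatures:
    """Per-state temporal features of one trial's label sequence."""

    duration_ms: np.ndarray  # mean segment length per state; 0 if never visited
    coverage: np.ndarray  # fraction of samples per state, sums to 1
    occurrence: np.ndarray  # segments per second per state
    transitions: np.ndarray  # (K, K) row-normalized counts, diagonal 0
    n_segments: int


def _segments(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode: (state per segment, length per segment)."""
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [labels.size]))
    return labels[starts], stops - starts


def backfit(
    rec: Recording,
    ms: MicrostateSet,
    polarity_invariant: bool = True,
    min_segment_ms: float = 0.0,
) -> LabelSequence:
    """Assign every sample of a trial to its best-fitting template.

    label(t) = argmax_k |R(V(t), template_k)| (ties -> lowest index; drop the
    absolute value with ``polarity_invariant=False`` for ERP-style data).
    Zero-variance samples inherit the previous sample's label (first sample:
    lowest index). With ``min_segment_ms`` > 0, segments shorter than that are
    relabeled to the neighboring label with the higher fit.
    """
    if rec.n_channels != ms.n_channels:
        raise InvalidInputError("recording and templates have different channel counts")
    rec = rec if is_average_referenced(rec.data) else average_reference(rec)
    X = rec.data - rec.data.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(X, axis=0)
    ok = norms > 0
    T = ms.templates  # rows centered, unit L2 norm
    C = np.zeros((ms.K, rec.n_samples))
    C[:, ok] = (T @ X[:, ok]) / norms[ok]
    score = np.abs(C) if polarity_invariant else C
    labels = np.argmax(score, axis=0)  # ties -> lowest template index
    fit = score[labels, np.arange(rec.n_samples)]
    if not ok.all():
        for i in np.flatnonzero(~ok):
            labels[i] = labels[i - 1] if i > 0 else 0
            fit[i] = 0.0
    if min_segment_ms > 0:
        min_len = int(round(min_segment_ms / 1000.0 * rec.fs))
        labels = _reject_short_segments(labels, fit, min_len)
        fit = score[labels, np.arange(rec.n_samples)]
    return LabelSequence(labels=labels, fit_correlation=fit, fs=rec.fs, K=ms.K)


def _reject_short_segments(labels: np.ndarray, fit: np.ndarray, min_len: int) -> np.ndarray:
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        seg_states, seg_lens = _segments(labels)
        if seg_states.size <= 1:
            break
        starts = np.concatenate(([0], np.cumsum(seg_lens)[:-1]))
        for i, (start, length) in enumerate(zip(starts, seg_lens)):
            if length >= min_len:
                continue
            left = labels[start - 1] if start > 0 else None
            right_idx = start + length
            right = labels[right_idx] if right_idx < labels.size else None
            if left is None and right is None:
                continue
            if left is None:
                new = right
            elif right is None:
                new = left
            else:
                # neighbor whose template fits this stretch better on average
                new = left if fit[start - 1] >= fit[right_idx] else right
            if new != labels[start]:
                labels[start : start + length] = new
                changed = True
                break
    return labels


def compute_gev(rec: Recording, seq: LabelSequence) -> dict:
    """Total and per-state GEV of a backfit, plus per-state proportions.

    Per-state GEV restricts the numerator to that state's samples while
    keeping the full denominator, so the per-state values sum to the total.
    """
    if seq.labels.size != rec.n_samples:
        raise InvalidInputError("label sequence does not match the recording length")
    gfp = compute_gfp(rec).values
    denom = float((gfp**2).sum())
    if denom <= 0:
        raise DegenerateMapError("all-zero GFP: GEV undefined")
    contrib = (seq.fit_correlation * gfp) ** 2
    total = float(contrib.sum() / denom)
    per_state = np.array(
        [float(contrib[seq.labels == k].sum() / denom) for k in range(seq.K)]
    )
    proportions = per_state / total if total > 0 else np.full(seq.K, np.nan)
    return {"total": total, "per_state": per_state, "proportions": proportions}


def microstate_features(seq: LabelSequence) -> TrialFeatures:
    """Duration, coverage, occurrence and transition probabilities of a trial.

    Segments are maximal runs of one label; truncated first/last segments
    count. States never visited get zeros. Transition probabilities are
    segment-boundary counts row-normalized by departures (diagonal 0); a
    single-segment trial yields an all-zero matrix.
    """
    if seq.labels.size == 0:
        raise InvalidInputError("empty label sequence")
    K = seq.K
    n = seq.labels.size
    seg_states, seg_lens = _segments(seq.labels)
    duration = np.zeros(K)
    occurrence = np.zeros(K)
    coverage = np.zeros(K)
    trial_seconds = n / seq.fs
    for k in range(K):
        mask = seg_states == k
        if mask.any():
            duration[k] = seg_lens[mask].mean() / seq.fs * 1000.0
            occurrence[k] = mask.sum() / trial_seconds
        coverage[k] = (seq.labels == k).sum() / n
    trans = np.zeros((K, K))
    for a, b in zip(seg_states[:-1], seg_states[1:]):
        trans[a, b] += 1
    departures = trans.sum(axis=1)
    nonzero = departures > 0
    trans[nonzero] /= departures[nonzero, None]
    return TrialFeatures(
        duration_ms=duration,
        coverage=coverage,
        occurrence=occurrence,
        transitions=trans,
        n_segments=int(seg_states.size),
    )


def features_table(
    items: list[tuple[dict, LabelSequence]],
    recordings: list[Recording] | None = None,
) -> pd.DataFrame:
    """Long-format feature table: one row per trial x state.

    `items` pairs trial metadata dicts (subject_id, trial_id, ...) with label
    sequences. When matching recordings are given, per-trial GEV columns are
    included.
    """
    rows = []
    for i, (meta, seq) in enumerate(items):
        feats = microstate_features(seq)
        gev = None
        if recordings is not None:
            gev = compute_gev(recordings[i], seq)
        for k in range(seq.K):
            row = dict(meta)
            row.update(
                state=k,
                state_name=f"MS{k + 1}",
                duration_ms=feats.duration_ms[k],
                coverage=feats.coverage[k],
                occurrence=feats.occurrence[k],
            )
            if gev is not None:
                row["gev"] = gev["per_state"][k]
                row["gev_total"] = gev["total"]
            rows.append(row)
    return pd.DataFrame(rows)
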