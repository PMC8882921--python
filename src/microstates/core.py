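"""Scalp-topography primitives.

Everything downstream of raw multichannel EEG rests on four operations:
common average referencing, global field power (GFP), extraction of the
candidate topographies at GFP local maxima, and the pair of topographic
metrics — global map dissimilarity (GMD) and the spatial correlation R.

GFP at time t is the spatial standard deviation of the average-referenced
potential across the N electrodes:

    GFP(t) = sqrt( (1/N) * sum_i (V_i(t) - Vbar(t))^2 )

GMD between maps p and q first mean-centers each map and scales it to unit
RMS (unit GFP), then takes the RMS of the difference; it lives in [0, 2]
and relates to the spatial correlation R by R = 1 - GMD^2 / 2, which is
numerically the Pearson correlation of the two raw channel vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import DegenerateMapError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "TopographyMap",
    "GfpCurve",
    "average_reference",
    "is_average_referenced",
    "compute_gfp",
    "extract_candidate_maps",
    "gmd",
    "spatial_correlation",
]


@dataclass
class Recording:
    """One trial of multichannel EEG.

    data is a channels x samples matrix in microvolts; metadata identifies
    the trial within a dataset. Valence/arousal are 9-point self-assessment
    ratings (may be None when not collected).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    subject_id: object = None
    trial_id: object = None
    video_id: object = None
    valence: float | None = None
    arousal: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidInputError("data must be a 2-D channels x samples matrix")
        if self.data.shape[0] < 2:
            raise InvalidInputError("a Recording needs at least 2 channels")
        if self.data.shape[1] < 1:
            raise InvalidInputError("a Recording needs at least 1 sample")
        if self.fs <= 0:
            raise InvalidInputError("sampling rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise InvalidInputError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.fs


@dataclass
class TopographyMap:
    """One instantaneous scalp potential vector over N channels."""

    values: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    sample_index: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.values.size)]
        if len(self.channel_names) != self.values.size:
            raise InvalidInputError("channel_names length must match value count")


@dataclass
class GfpCurve:
    """Per-sample GFP values plus the indices of its strict local maxima."""

    values: np.ndarray
    peak_indices: np.ndarray
    fs: float


def is_average_referenced(data: np.ndarray, rtol: float = 1e-9) -> bool:
    """True if every sample's channel mean is ~0 relative to the column RMS."""
    col_mean = data.mean(axis=0)
    col_rms = np.sqrt((data**2).mean(axis=0))
    scale = np.maximum(col_rms, np.finfo(float).tiny)
    return bool(np.all(np.abs(col_mean) <= rtol * np.maximum(scale, 1.0)))


def average_reference(rec: Recording) -> Recording:
    """Re-reference to the common average: subtract the per-sample channel mean.

    Idempotent; shape, sampling rate and metadata are unchanged.
    """
    if rec.n_channels < 2:
        raise InvalidInputError("average reference needs at least 2 channels")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))


def _strict_local_maxima(values: np.ndarray) -> np.ndarray:
    """Interior indices i with values[i-1] < values[i] > values[i+1]."""
    if values.size < 3:
        return np.empty(0, dtype=int)
    interior = (values[1:-1] > values[:-2]) & (values[1:-1] > values[2:])
    return np.flatnonzero(interior) + 1


def compute_gfp(rec: Recording, min_peak_distance_ms: float = 0.0) -> GfpCurve:
    """GFP curve of a trial with strict local maxima as peak indices.

    The recording is re-referenced internally if it is not already
    average-referenced (logged). Peaks exclude the first/last sample; plateaus
    of equal values yield no peak. ``min_peak_distance_ms`` > 0 additionally
    enforces a minimum spacing between retained peaks (greedy by height).
    """
    data = rec.data
    if np.isnan(data).any():
        raise InvalidInputError("recording contains NaN values")
    if not is_average_referenced(data):
        logger.info("compute_gfp: input not average-referenced; re-referencing")
        data = data - data.mean(axis=0, keepdims=True)
    gfp = data.std(axis=0)  # population sd == sqrt(mean squared deviation)
    peaks = _strict_local_maxima(gfp)
    if min_peak_distance_ms > 0 and peaks.size > 1:
        min_dist = int(round(min_peak_distance_ms / 1000.0 * rec.fs))
        if min_dist > 1:
            keep: list[int] = []
            for idx in peaks[np.argsort(gfp[peaks])[::-1]]:
                if all(abs(idx - j) >= min_dist for j in keep):
                    keep.append(int(idx))
            peaks = np.array(sorted(keep), dtype=int)
    return GfpCurve(values=gfp, peak_indices=peaks, fs=rec.fs)


def extract_candidate_maps(
    rec: Recording,
    normalize: bool = True,
    min_peak_distance_ms: float = 0.0,
) -> list[TopographyMap]:
    """Topographies at the GFP peaks of a trial, in temporal order.

    Each map carries its source sample index. With ``normalize`` (default) maps
    are scaled to unit GFP so that clustering is strength-independent.
    Zero-variance maps at peaks are skipped (count logged); a trial with no
    GFP local maxima yields an empty list with a warning, not an error.
    """
    rec = rec if is_average_referenced(rec.data) else average_reference(rec)
    curve = compute_gfp(rec, min_peak_distance_ms=min_peak_distance_ms)
    maps: list[TopographyMap] = []
    n_skipped = 0
    for idx in curve.peak_indices:
        col = rec.data[:, idx]
        g = curve.values[idx]
        if g <= 0 or not np.isfinite(g):
            n_skipped += 1
            continue
        values = col / g if normalize else col.copy()
        maps.append(
            TopographyMap(values=values, channel_names=rec.channel_names, sample_index=int(idx))
        )
    if n_skipped:
        logger.info("extract_candidate_maps: skipped %d zero-variance peaks", n_skipped)
    if not maps:
        logger.warning(
            "extract_candidate_maps: no GFP local maxima in trial %s/%s",
            rec.subject_id,
            rec.trial_id,
        )
    return maps


def _as_values(m: TopographyMap | np.ndarray) -> np.ndarray:
    if isinstance(m, TopographyMap):
        return m.values
    return np.asarray(m, dtype=float).ravel()


def _normalize_map(v: np.ndarray) -> np.ndarray:
    """Mean-center and scale to unit RMS (unit GFP)."""
    v = v - v.mean()
    rms = np.sqrt((v**2).mean())
    if rms == 0 or not np.isfinite(rms):
        raise DegenerateMapError("zero-variance topography")
    return v / rms


def gmd(p: TopographyMap | np.ndarray, q: TopographyMap | np.ndarray) -> float:
    """Global map dissimilarity between two topographies, in [0, 2]."""
    return spatial_correlation(p, q)[1]


def spatial_correlation(
    p: TopographyMap | np.ndarray, q: TopographyMap | np.ndarray
) -> tuple[float, float]:
    """Spatial correlation R and GMD between two maps on the same montage.

    Returns ``(R, GMD)`` with R = 1 - GMD^2/2; R equals the Pearson correlation
    of the raw channel vectors. Raises on zero-variance maps or mismatched
    channel counts.
    """
    if isinstance(p, TopographyMap) and isinstance(q, TopographyMap):
        if p.channel_names != q.channel_names:
            raise InvalidInputError("maps are on different channel sets/orders")
    pv, qv = _as_values(p), _as_values(q)
    if pv.size != qv.size:
        raise InvalidInputError("maps have different channel counts")
    pn, qn = _normalize_map(pv), _normalize_map(qv)
    d = float(np.sqrt(((pn - qn) ** 2).mean()))
    r = 1.0 - d**2 / 2.0
    return r, d


def stack_maps(maps: Sequence[TopographyMap] | np.ndarray) -> np.ndarray:
    """Stack maps into an (n_maps, n_channels) float array."""
    if isinstance(maps, np.ndarray):
        arr = np.asarray(maps, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        return arr
    return np.array([_as_values(m) for m in maps], dtype=float)
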