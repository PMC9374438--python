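"""Whiff/blank segmentation and the five odor-signal features.

A short concentration record is binarized with an adaptive detection
threshold (half the mean of its strictly positive samples) and segmented
into whiffs — maximal runs above threshold — and blanks. Five scalar
summaries are computed:

``x1``  mean concentration during whiffs (intensity)
``x2``  peak forward-difference slope per whiff, averaged across whiffs
        (intensity)
``x3``  mean blank duration (timing)
``x4``  mean whiff duration (timing)
``x5``  intermittency factor: fraction of samples above threshold (timing)

Because the threshold is adaptive, the timing features are exactly
invariant under rescaling of the signal, while the intensity features scale
linearly with it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OdorTimeSeries",
    "WhiffSegmentation",
    "FeatureVector",
    "adaptive_threshold",
    "segment",
    "compute_features",
    "FEATURE_NAMES",
    "INTENSITY_FEATURES",
    "TIMING_FEATURES",
]

FEATURE_NAMES = ("x1", "x2", "x3", "x4", "x5")
INTENSITY_FEATURES = ("x1", "x2")
TIMING_FEATURES = ("x3", "x4", "x5")


@dataclass(frozen=True)
class OdorTimeSeries:
    """A sampled concentration record at one location.

    ``values`` are non-negative concentrations at ``dt`` spacing; the memory
    of the record is ``len(values) * dt``. ``location`` is the sampling
    point with the source at the origin (downwind coordinate first).
    """

    values: np.ndarray
    dt: float = 1.0
    location: tuple[float, ...] = (0.0, 0.0)
    t0: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("series must be one-dimensional with >= 2 samples")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if np.any(v < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def memory(self) -> float:
        return self.n_samples * self.dt


@dataclass(frozen=True)
class WhiffSegmentation:
    """Maximal above/below-threshold runs of one series.

    ``whiffs`` and ``blanks`` are ``(start, length)`` pairs; together they
    partition the record and alternate in type. Boundary-truncated runs are
    kept.
    """

    threshold: float
    detection: np.ndarray
    whiffs: tuple[tuple[int, int], ...]
    blanks: tuple[tuple[int, int], ...]

    @property
    def n_detected(self) -> int:
        return int(self.detection.sum())


def adaptive_threshold(series: OdorTimeSeries) -> float:
    """Adaptive detection threshold: half the mean of the strictly positive
    samples.

    Returns ``nan`` (the invalid sentinel) when the record has no positive
    sample, in which case no feature is defined.
    """
    v = series.values
    pos = v[v > 0]
    if pos.size == 0:
        return float("nan")
    return 0.5 * float(pos.mean())


def segment(series: OdorTimeSeries, cthr: float) -> WhiffSegmentation:
    """Binarize at a threshold (strictly greater-than) and extract maximal
    whiff and blank runs."""
    if not cthr >= 0:  # also rejects nan
        raise ValueError("threshold must be a non-negative number")
    det = series.values > cthr
    whiffs: list[tuple[int, int]] = []
    blanks: list[tuple[int, int]] = []
    # run boundaries where the binary state changes
    edges = np.flatnonzero(np.diff(det.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [det.size]])
    for s, e in zip(starts, ends):
        (whiffs if det[s] else blanks).append((int(s), int(e - s)))
    return WhiffSegmentation(
        threshold=float(cthr),
        detection=det,
        whiffs=tuple(whiffs),
        blanks=tuple(blanks),
    )


@dataclass(frozen=True)
class FeatureVector:
    """The five features of one series; all-nan with ``valid=False`` when no
    sample exceeds the detection threshold."""

    x1: float
    x2: float
    x3: float
    x4: float
    x5: float
    valid: bool
    threshold: float = float("nan")

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3, self.x4, self.x5])

    @classmethod
    def invalid(cls, threshold: float = float("nan")) -> "FeatureVector":
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, valid=False, threshold=threshold)


def _peak_slopes(values: np.ndarray, whiffs, dt: float) -> float:
    """Average over whiffs of the peak forward-difference slope.

    The per-whiff peak is the maximum forward difference over the whiff
    samples, including the onset step from the sample preceding the whiff
    when one exists. A length-1 whiff starting the record contributes no
    candidate and is skipped.
    """
    peaks = []
    for s, L in whiffs:
        cands = []
        if s > 0:
            cands.append(values[s] - values[s - 1])
        if L > 1:
            seg = values[s : s + L]
            cands.append(float(np.max(np.diff(seg))))
        if cands:
            peaks.append(max(cands) / dt)
    return float(np.mean(peaks)) if peaks else 0.0


def compute_features(
    series: OdorTimeSeries, cthr: float | None = None
) -> FeatureVector:
    """Compute the five features of one series.

    The threshold defaults to the adaptive rule; passing ``cthr=0`` recovers
    features of the raw on/off state. A series with no sample above
    threshold yields an invalid (all-nan) vector, never silent zeros.
    """
    if cthr is None:
        cthr = adaptive_threshold(series)
    if not np.isfinite(cthr):
        return FeatureVector.invalid()
    seg = segment(series, cthr)
    if seg.n_detected == 0:
        return FeatureVector.invalid(threshold=cthr)
    v = series.values
    dt = series.dt
    x1 = float(v[seg.detection].mean())
    x2 = _peak_slopes(v, seg.whiffs, dt)
    whiff_lengths = np.array([L for _, L in seg.whiffs])
    blank_lengths = np.array([L for _, L in seg.blanks])
    x3 = dt * float(blank_lengths.mean()) if blank_lengths.size else 0.0
    x4 = dt * float(whiff_lengths.mean())
    x5 = seg.n_detected / series.n_samples
    return FeatureVector(x1, x2, x3, x4, x5, valid=True, threshold=float(cthr))


def features_from_values(values: np.ndarray, dt: float) -> np.ndarray:
    """Fast path: five features of a raw array (adaptive threshold).

    Returns an all-nan vector for records never exceeding threshold; used by
    the dataset sampler where constructing dataclasses per window would
    dominate runtime.
    """
    pos = values[values > 0]
    if pos.size == 0:
        return np.full(5, np.nan)
    cthr = 0.5 * pos.mean()
    det = values > cthr
    n_det = int(det.sum())
    if n_det == 0:
        return np.full(5, np.nan)
    edges = np.flatnonzero(np.diff(det.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [det.size]])
    is_whiff = det[starts]
    lengths = ends - starts
    whiff_lengths = lengths[is_whiff]
    blank_lengths = lengths[~is_whiff]
    x1 = float(values[det].mean())
    x2 = _peak_slopes(values, list(zip(starts[is_whiff], whiff_lengths)), dt)
    x3 = dt * float(blank_lengths.mean()) if blank_lengths.size else 0.0
    x4 = dt * float(whiff_lengths.mean())
    x5 = n_det / values.size
    return np.array([x1, x2, x3, x4, x5])
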