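"""Trial segmentation and per-channel time-domain features.

Each one-minute trial is cut (after discarding the pre-trial baseline) into
non-overlapping 6-s windows, and six scalar features are computed per channel
per window: mean, population variance, mean absolute first difference, mean
absolute second difference, standard deviation, and fuzzy entropy.

Fuzzy entropy (FuzzyEn, after Chen et al.) measures signal irregularity by
comparing baseline-removed templates of length ``m`` and ``m + 1`` under a
smooth exponential similarity kernel::

    X_i^L   = (s_i, ..., s_{i+L-1}) - mean(s_i, ..., s_{i+L-1})
    d_ij^L  = max_k | X_i^L[k] - X_j^L[k] |            (Chebyshev)
    D_ij^L  = exp( - (d_ij^L / r)^n )
    phi^L   = mean_i  (N - m - 1)^{-1} sum_{j != i} D_ij^L
    FuzzyEn = ln phi^m - ln phi^{m+1}

Both template lengths use the same N - m template positions so the two
averages are over identical index sets.  Removing the per-template mean makes
the measure invariant to baseline shifts; deriving ``r`` from the segment's
standard deviation makes it invariant to amplitude rescaling.  A constant
signal is assigned entropy 0 by convention (all similarities are 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._fuzzy_kernels import HAVE_NUMBA, chebyshev_pairs_generic, chebyshev_pairs_m2

__all__ = [
    "TrialRecording",
    "Segment",
    "FuzzyEnConfig",
    "FEATURE_NAMES",
    "segment_trial",
    "basic_features",
    "fuzzy_entropy",
    "extract_features",
    "extract_features_batch",
]

FEATURE_NAMES: Tuple[str, ...] = (
    "mean",
    "variance",
    "first_difference",
    "second_difference",
    "standard_deviation",
    "fuzzy_entropy",
)


class SegmentationError(ValueError):
    pass


class FeatureError(ValueError):
    pass


@dataclass
class TrialRecording:
    """One trial of raw multi-channel signal (channels x samples)."""

    signal: np.ndarray
    fs: float = 128.0
    baseline_samples: int = 384  # 3 s pre-trial baseline at 128 Hz
    subject: int = 0
    trial: int = 0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError(f"signal must be channels x samples, got shape {self.signal.shape}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signal.shape[1] <= self.baseline_samples:
            raise ValueError("trial has no samples after the baseline")


@dataclass
class Segment:
    """A non-overlapping window cut from one trial, with provenance."""

    signal: np.ndarray  # channels x window samples
    fs: float
    window_seconds: float
    subject: int
    trial: int
    window_index: int


@dataclass
class FuzzyEnConfig:
    """Fuzzy-entropy parameters.

    ``r`` is the absolute similarity width; when ``None`` it is derived per
    channel and per segment as ``r_coef`` times that channel-segment's
    population standard deviation (field-standard 0.2*SD).
    """

    m: int = 2
    r: Optional[float] = None
    r_coef: float = 0.2
    n_exp: float = 2.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("template length m must be >= 1")
        if self.r is not None and self.r <= 0:
            raise ValueError("similarity width r must be positive")
        if self.r_coef <= 0 or self.n_exp <= 0:
            raise ValueError("r_coef and n_exp must be positive")


def segment_trial(rec: TrialRecording, window_seconds: float = 6.0) -> List[Segment]:
    """Cut a trial into consecutive non-overlapping windows.

    The first ``baseline_samples`` samples are discarded, then
    ``floor(remaining / window)`` full windows are emitted; a partial tail is
    dropped.  Every retained sample index is used exactly once.
    """
    window = int(round(window_seconds * rec.fs))
    if window <= 0:
        raise SegmentationError("window must contain at least one sample")
    post = rec.signal[:, rec.baseline_samples :]
    n_windows = post.shape[1] // window
    if n_windows == 0:
        raise SegmentationError(
            f"empty segmentation: window of {window} samples exceeds the "
            f"{post.shape[1]} post-baseline samples"
        )
    return [
        Segment(
            signal=post[:, i * window : (i + 1) * window],
            fs=rec.fs,
            window_seconds=window_seconds,
            subject=rec.subject,
            trial=rec.trial,
            window_index=i,
        )
        for i in range(n_windows)
    ]


def basic_features(x: Sequence[float]) -> Tuple[float, float, float, float, float]:
    """Mean, population variance, mean |1st diff|, mean |2nd diff|, SD."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 3:
        raise FeatureError("signal too short: need a 1-D signal of length >= 3")
    mean = float(x.mean())
    var = float(x.var())  # population (divide by N), so SD**2 == var exactly
    first = float(np.abs(np.diff(x, 1)).mean())
    second = float(np.abs(x[2:] - x[:-2]).mean())
    return mean, var, first, second, float(np.sqrt(var))


def _mean_similarity(d: np.ndarray, r: float, n_exp: float, n_templates: int) -> float:
    """Self-excluded mean of exp(-(d/r)^n) from packed upper-triangle distances."""
    z = d / d.dtype.type(r)
    if n_exp == 2.0:
        np.multiply(z, z, out=z)
    else:
        np.power(z, n_exp, out=z)
    np.negative(z, out=z)
    np.exp(z, out=z)
    # the packed triangle holds each unordered pair once; self-pairs (D=1) excluded
    return 2.0 * float(z.sum(dtype=np.float64)) / (n_templates * (n_templates - 1))


def _phi_numpy(x: np.ndarray, length: int, n_templates: int, r: float, n_exp: float) -> float:
    """Full-matrix numpy fallback for one template length (no numba)."""
    y = sliding_window_view(x, length)[:n_templates]
    y = y - y.mean(axis=1, keepdims=True)
    d: Optional[np.ndarray] = None
    for k in range(length):
        col = np.ascontiguousarray(y[:, k])
        dk = np.abs(col[:, None] - col[None, :])
        d = dk if d is None else np.maximum(d, dk, out=d)
    assert d is not None
    d /= d.dtype.type(r)
    if n_exp == 2.0:
        np.multiply(d, d, out=d)
    else:
        np.power(d, n_exp, out=d)
    np.negative(d, out=d)
    np.exp(d, out=d)
    total = float(d.sum(dtype=np.float64)) - n_templates  # drop the D_ii = 1 diagonal
    return total / (n_templates * (n_templates - 1))


def _phi_pair(x: np.ndarray, m: int, r: float, n_exp: float) -> Tuple[float, float]:
    """(phi_m, phi_{m+1}) over the shared N - m template positions."""
    n_templates = x.size - m
    if not HAVE_NUMBA:  # pragma: no cover - numba is a hard dependency in practice
        return (
            _phi_numpy(x, m, n_templates, r, n_exp),
            _phi_numpy(x, m + 1, n_templates, r, n_exp),
        )
    n_pairs = n_templates * (n_templates - 1) // 2
    d_m = np.empty(n_pairs, dtype=x.dtype)
    d_m1 = np.empty(n_pairs, dtype=x.dtype)
    if m == 2:
        chebyshev_pairs_m2(x, d_m, d_m1)
    else:
        chebyshev_pairs_generic(x, m, d_m, d_m1)
    return (
        _mean_similarity(d_m, r, n_exp, n_templates),
        _mean_similarity(d_m1, r, n_exp, n_templates),
    )


def fuzzy_entropy(x: Sequence[float], cfg: FuzzyEnConfig = FuzzyEnConfig()) -> float:
    """Fuzzy entropy of a single-channel signal.

    Computation follows the input dtype (float32 pipelines stay in float32);
    pass float64 input for reference-precision results.
    """
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float64)
    n = x.size
    if x.ndim != 1 or n < cfg.m + 2:
        raise FeatureError(f"signal too short for FuzzyEn: need length >= {cfg.m + 2}")
    r = cfg.r
    if r is None:
        sd = float(x.std())
        if sd == 0.0:
            return 0.0  # constant signal: all distances 0, phi_m = phi_{m+1} = 1
        r = cfg.r_coef * sd
    phi_m, phi_m1 = _phi_pair(x, cfg.m, r, cfg.n_exp)
    if phi_m <= 0.0 or phi_m1 <= 0.0:  # similarities underflowed to zero
        return 0.0
    return float(np.log(phi_m) - np.log(phi_m1))


def extract_features(seg: Segment, cfg: FuzzyEnConfig = FuzzyEnConfig()) -> np.ndarray:
    """Per-channel feature table of a segment: channels x 6.

    Row order follows the segment's channel order (= montage acquisition
    order); column order is :data:`FEATURE_NAMES`.
    """
    sig = np.asarray(seg.signal)
    out = np.empty((sig.shape[0], 6), dtype=sig.dtype if np.issubdtype(sig.dtype, np.floating) else np.float64)
    for ch in range(sig.shape[0]):
        try:
            out[ch, :5] = basic_features(sig[ch])
            out[ch, 5] = fuzzy_entropy(sig[ch], cfg)
        except (FeatureError, ValueError) as exc:
            raise FeatureError(f"channel index {ch}: {exc}") from exc
    if not np.all(np.isfinite(out)):
        raise FeatureError("non-finite feature value")
    return out


def extract_features_batch(
    segments: Sequence[Segment], cfg: FuzzyEnConfig = FuzzyEnConfig()
) -> np.ndarray:
    """Stack :func:`extract_features` over segments -> (n_segments, channels, 6)."""
    if len(segments) == 0:
        raise FeatureError("no segments to extract features from")
    return np.stack([extract_features(s, cfg) for s in segments])
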