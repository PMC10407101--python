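"""Labeled-sample assembly: feature images, graph samples, labels, containers.

Continuous 0-9 self-assessment ratings are binarized at the conventional
threshold: strictly greater than 5 is the "high" class, everything else
(including exactly 5) is "low"; the same rule serves both the arousal and the
valence dimension.

A per-segment 32 x 6 feature table feeds both network branches: dropped into
the 9 x 9 electrode grid it becomes the sparse 9 x 9 x 6 feature image for
the convolutional branch, and paired with the channel adjacency it is the
node-feature table of the graph branch.  Features are z-scored per feature
column with statistics fitted on the training split only; unmapped image
cells stay exactly zero.

Cohorts (raw signals + ratings) and derived datasets (features + labels +
provenance) round-trip through HDF5 or NPZ containers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .features import (  # noqa: F401 - FEATURE_NAMES re-exported for users
    FEATURE_NAMES,
    FuzzyEnConfig,
    TrialRecording,
    extract_features,
    segment_trial,
)
from .montage import GridMapping, Montage, get_montage

__all__ = [
    "RATING_DIMENSIONS",
    "label_from_rating",
    "build_feature_image",
    "build_feature_images",
    "GraphSample",
    "LabeledSample",
    "build_graph_sample",
    "NormalizationStats",
    "fit_normalization",
    "apply_normalization",
    "Cohort",
    "SegmentDataset",
    "assemble_dataset",
    "write_cohort",
    "read_cohort",
    "write_dataset",
    "read_dataset",
]

# DEAP rating order within the per-trial rating vector
RATING_DIMENSIONS: Tuple[str, ...] = ("valence", "arousal", "dominance", "liking")


class SchemaError(ValueError):
    """A container is missing required arrays."""


def label_from_rating(rating: float, dimension: str = "arousal") -> int:
    """Binarize a 0-9 rating: > 5 -> 1 (high), <= 5 -> 0 (low)."""
    if dimension not in ("arousal", "valence"):
        raise ValueError(f"unknown rating dimension {dimension!r}")
    if not (0.0 <= rating <= 9.0):
        raise ValueError(f"rating {rating} outside the 0-9 self-assessment scale")
    return int(rating > 5.0)


def build_feature_image(
    feats: np.ndarray, mapping: GridMapping, channels: Sequence[str]
) -> np.ndarray:
    """Place per-channel features into the sparse grid -> (rows, cols, 6)."""
    feats = np.asarray(feats)
    if feats.shape[0] != len(channels):
        raise ValueError(f"{feats.shape[0]} feature rows for {len(channels)} channels")
    rows, cols = mapping.grid_shape
    img = np.zeros((rows, cols, feats.shape[1]), dtype=feats.dtype)
    for i, label in enumerate(channels):
        if label not in mapping.entries:
            raise KeyError(f"channel {label!r} has no grid cell in the mapping")
        r, c = mapping[label]
        img[r, c, :] = feats[i]
    return img


def build_feature_images(
    feats: np.ndarray, mapping: GridMapping, channels: Sequence[str]
) -> np.ndarray:
    """Vectorized image construction: (n, C, F) -> (n, rows, cols, F)."""
    feats = np.asarray(feats)
    rows, cols = mapping.grid_shape
    imgs = np.zeros((feats.shape[0], rows, cols, feats.shape[2]), dtype=feats.dtype)
    rr = [mapping[c][0] for c in channels]
    cc = [mapping[c][1] for c in channels]
    imgs[:, rr, cc, :] = feats
    return imgs


@dataclass
class GraphSample:
    """Node-feature table plus the shared channel adjacency."""

    node_features: np.ndarray  # n_channels x n_features
    adjacency: np.ndarray  # n_channels x n_channels

    def __post_init__(self) -> None:
        if self.node_features.shape[0] != self.adjacency.shape[0]:
            raise ValueError(
                f"{self.node_features.shape[0]} node rows vs "
                f"adjacency of order {self.adjacency.shape[0]}"
            )


@dataclass
class LabeledSample:
    image: np.ndarray  # rows x cols x features
    graph: GraphSample
    label: int
    dimension: str
    provenance: Tuple[int, int, int]  # (subject, trial, window)


@dataclass
class NormalizationStats:
    """Per-feature mean/SD fitted on a training split.

    A constant feature column gets SD 1 so it centres to zero instead of
    dividing by zero.
    """

    mean: np.ndarray  # (n_features,)
    sd: np.ndarray  # (n_features,)


def fit_normalization(train_features: np.ndarray) -> NormalizationStats:
    """Fit per-feature stats over all (segment, channel) entries of the train split."""
    feats = np.asarray(train_features)
    if feats.size == 0:
        raise ValueError("empty training split")
    flat = feats.reshape(-1, feats.shape[-1])
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0).astype(feats.dtype)
    return NormalizationStats(mean=mean.astype(feats.dtype), sd=sd)


def apply_normalization(features: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Z-score feature tables (any leading shape, last axis = features)."""
    return (np.asarray(features) - stats.mean) / stats.sd


def build_graph_sample(feats: np.ndarray, adj: np.ndarray) -> GraphSample:
    """Package a channel-feature table with the shared adjacency (no reordering)."""
    return GraphSample(node_features=np.asarray(feats), adjacency=np.asarray(adj))


@dataclass
class Cohort:
    """Raw study container: per-trial signals and self-assessment ratings."""

    signals: np.ndarray  # subjects x trials x channels x samples
    ratings: np.ndarray  # subjects x trials x 4 (valence, arousal, dominance, liking)
    fs: float = 128.0
    baseline_samples: int = 384
    montage_name: str = "deap32"
    latent_class: Optional[np.ndarray] = None  # subjects x trials, synthetic only
    metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return self.signals.shape[0]

    @property
    def n_trials(self) -> int:
        return self.signals.shape[1]


@dataclass
class SegmentDataset:
    """Per-segment features, binary labels for both dimensions, provenance."""

    features: np.ndarray  # n x channels x 6
    labels_arousal: np.ndarray  # n
    labels_valence: np.ndarray  # n
    provenance: np.ndarray  # n x 3 (subject, trial, window)
    montage_name: str = "deap32"
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.features.shape[0]
        if not (len(self.labels_arousal) == len(self.labels_valence) == len(self.provenance) == n):
            raise ValueError("dataset arrays disagree on sample count")
        prov = [tuple(p) for p in np.asarray(self.provenance)]
        if len(set(prov)) != n:
            raise ValueError("provenance (subject, trial, window) must be unique")

    def __len__(self) -> int:
        return self.features.shape[0]

    def labels(self, dimension: str) -> np.ndarray:
        if dimension == "arousal":
            return self.labels_arousal
        if dimension == "valence":
            return self.labels_valence
        raise ValueError(f"unknown rating dimension {dimension!r}")


def assemble_dataset(
    cohort: Cohort,
    window_seconds: float = 6.0,
    fuzzy_cfg: FuzzyEnConfig = FuzzyEnConfig(),
    montage: Optional[Montage] = None,
    progress: bool = False,
) -> SegmentDataset:
    """Segment every trial of a cohort and extract per-segment features.

    Deterministic given (cohort, window, fuzzy config, montage).  EEG channels
    beyond the montage's channel count (DEAP stores 8 peripheral channels
    after the 32 EEG ones) are ignored.
    """
    montage = montage or get_montage(cohort.montage_name)
    n_ch = montage.n_channels
    feats: List[np.ndarray] = []
    labels_a: List[int] = []
    labels_v: List[int] = []
    prov: List[Tuple[int, int, int]] = []
    n_total = cohort.n_subjects * cohort.n_trials
    done = 0
    for s in range(cohort.n_subjects):
        for t in range(cohort.n_trials):
            rec = TrialRecording(
                signal=cohort.signals[s, t, :n_ch],
                fs=cohort.fs,
                baseline_samples=cohort.baseline_samples,
                subject=s,
                trial=t,
            )
            lab_v = label_from_rating(float(cohort.ratings[s, t, 0]), "valence")
            lab_a = label_from_rating(float(cohort.ratings[s, t, 1]), "arousal")
            for seg in segment_trial(rec, window_seconds):
                feats.append(extract_features(seg, fuzzy_cfg))
                labels_a.append(lab_a)
                labels_v.append(lab_v)
                prov.append((s, t, seg.window_index))
            done += 1
            if progress and done % 20 == 0:
                print(f"  features: {done}/{n_total} trials", flush=True)
    return SegmentDataset(
        features=np.stack(feats),
        labels_arousal=np.asarray(labels_a, dtype=np.int64),
        labels_valence=np.asarray(labels_v, dtype=np.int64),
        provenance=np.asarray(prov, dtype=np.int64),
        montage_name=montage.name,
        metadata={"window_seconds": window_seconds, "r_coef": fuzzy_cfg.r_coef, "m": fuzzy_cfg.m},
    )


# ---------------------------------------------------------------------------
# container I/O (HDF5 preferred; NPZ by file extension)
# ---------------------------------------------------------------------------

_COHORT_REQUIRED = ("signals", "ratings")
_DATASET_REQUIRED = ("features", "labels_arousal", "labels_valence", "provenance")


def _is_npz(path: Union[str, Path]) -> bool:
    return str(path).endswith(".npz")


def write_cohort(path: Union[str, Path], cohort: Cohort) -> None:
    attrs = {
        "fs": cohort.fs,
        "baseline_samples": cohort.baseline_samples,
        "montage_name": cohort.montage_name,
        "metadata": json.dumps(cohort.metadata),
    }
    arrays = {"signals": cohort.signals, "ratings": cohort.ratings}
    if cohort.latent_class is not None:
        arrays["latent_class"] = cohort.latent_class
    _write_container(path, arrays, attrs)


def read_cohort(path: Union[str, Path]) -> Cohort:
    arrays, attrs = _read_container(path, _COHORT_REQUIRED)
    return Cohort(
        signals=arrays["signals"],
        ratings=arrays["ratings"],
        fs=float(attrs.get("fs", 128.0)),
        baseline_samples=int(attrs.get("baseline_samples", 384)),
        montage_name=str(attrs.get("montage_name", "deap32")),
        latent_class=arrays.get("latent_class"),
        metadata=json.loads(attrs.get("metadata", "{}")),
    )


def write_dataset(path: Union[str, Path], ds: SegmentDataset) -> None:
    attrs = {"montage_name": ds.montage_name, "metadata": json.dumps(ds.metadata)}
    arrays = {
        "features": ds.features,
        "labels_arousal": ds.labels_arousal,
        "labels_valence": ds.labels_valence,
        "provenance": ds.provenance,
    }
    _write_container(path, arrays, attrs)


def read_dataset(path: Union[str, Path]) -> SegmentDataset:
    arrays, attrs = _read_container(path, _DATASET_REQUIRED)
    return SegmentDataset(
        features=arrays["features"],
        labels_arousal=arrays["labels_arousal"],
        labels_valence=arrays["labels_valence"],
        provenance=arrays["provenance"],
        montage_name=str(attrs.get("montage_name", "deap32")),
        metadata=json.loads(attrs.get("metadata", "{}")),
    )


def _write_container(path, arrays: Dict[str, np.ndarray], attrs: Dict[str, object]) -> None:
    if _is_npz(path):
        meta = {f"attr_{k}": np.asarray(v) for k, v in attrs.items()}
        np.savez(path, **arrays, **meta)
        return
    import h5py

    with h5py.File(path, "w") as f:
        for name, arr in arrays.items():
            f.create_dataset(name, data=arr)
        for k, v in attrs.items():
            f.attrs[k] = v


def _read_container(path, required: Tuple[str, ...]):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_npz(path):
        with np.load(path, allow_pickle=False) as z:
            arrays = {k: z[k] for k in z.files if not k.startswith("attr_")}
            attrs = {k[5:]: z[k][()] for k in z.files if k.startswith("attr_")}
            attrs = {k: v.item() if getattr(v, "ndim", 1) == 0 else v for k, v in attrs.items()}
    else:
        import h5py

        with h5py.File(path, "r") as f:
            arrays = {k: f[k][()] for k in f.keys()}
            attrs = {k: (v.decode() if isinstance(v, bytes) else v) for k, v in f.attrs.items()}
    missing = [k for k in required if k not in arrays]
    if missing:
        raise SchemaError(f"container {path} is missing required arrays: {missing}")
    return arrays, attrs
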