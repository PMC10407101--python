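"""Cross-validated training and evaluation.

The default protocol pools the 6-s segments of all subjects and assigns them
to stratified folds at segment level — the subject-dependent protocol.  Note
the optimistic bias this implies: segments cut from the same trial can land
in different folds, so validation segments share trial-level context with
training segments.  ``group_by_trial=True`` keeps all segments of a trial in
one fold for the stricter protocol.

Per fold, feature normalization statistics are fitted on the training split
only, a model is trained with Adam on cross-entropy, and validation metrics
(accuracy, positive-class F1, ROC points, trapezoidal AUC, confusion counts)
plus the mean first-layer attention matrix are reported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score, roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .dataset import (
    NormalizationStats,
    SegmentDataset,
    apply_normalization,
    build_feature_images,
    fit_normalization,
)
from .model import FusionModel, ModelConfig
from .montage import build_adjacency, build_grid_mapping, get_montage
from .nn import Adam
from .nn.layers import softmax_cross_entropy

__all__ = [
    "TrainConfig",
    "FoldMetrics",
    "CVResult",
    "make_folds",
    "compute_metrics",
    "train_fold",
    "cross_validate",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 64
    folds: int = 10
    seed: int = 0
    dimension: str = "arousal"  # or "valence"
    mode: str = "fused"  # or "resnet-only" / "gat-only"
    group_by_trial: bool = False
    shuffle_labels: bool = False  # permutation control

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class FoldMetrics:
    fold: int
    accuracy: float
    f1: float
    auc: float
    roc_points: np.ndarray  # (k, 2) columns (FPR, TPR)
    confusion: Tuple[int, int, int, int]  # (tn, fp, fn, tp)
    mean_attention: Optional[np.ndarray] = None
    train_losses: List[float] = field(default_factory=list)


@dataclass
class CVResult:
    folds: List[FoldMetrics]
    summary: dict

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"fold": m.fold, "accuracy": m.accuracy, "f1": m.f1, "auc": m.auc}
                for m in self.folds
            ]
        )


def make_folds(
    labels: Sequence[int],
    k: int = 10,
    seed: int = 0,
    groups: Optional[Sequence[int]] = None,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold split -> list of (train_idx, val_idx) pairs.

    With ``groups`` (e.g. trial identifiers) the split keeps each group in a
    single fold while still balancing labels.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("single-class dataset: stratified folding is undefined")
    if len(labels) < k:
        raise ValueError(f"cannot make {k} folds from {len(labels)} samples")
    if groups is None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(labels)), labels)
    else:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(labels)), labels, groups=np.asarray(groups))
    return [(np.asarray(tr), np.asarray(va)) for tr, va in split]


def compute_metrics(
    labels: Sequence[int],
    probabilities: np.ndarray,
    fold: int = 0,
    mean_attention: Optional[np.ndarray] = None,
) -> FoldMetrics:
    """Accuracy / F1 / ROC / trapezoidal AUC from class probabilities.

    ``probabilities`` is (n, 2) softmax output or (n,) positive-class scores.
    A single-class validation set yields AUC = NaN with a warning.
    """
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities)
    scores = probabilities[:, 1] if probabilities.ndim == 2 else probabilities
    if probabilities.ndim == 2:
        pred = probabilities.argmax(axis=1)
    else:
        pred = (scores > 0.5).astype(int)
    accuracy = float((pred == labels).mean())
    f1 = float(f1_score(labels, pred, pos_label=1, zero_division=0))
    tn, fp, fn, tp = confusion_matrix(labels, pred, labels=[0, 1]).ravel()
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class labels: AUC is undefined, reporting NaN")
        auc = float("nan")
        roc = np.empty((0, 2))
    else:
        fpr, tpr, _ = roc_curve(labels, scores)
        auc = float(np.trapezoid(tpr, fpr))
        roc = np.column_stack([fpr, tpr])
    return FoldMetrics(
        fold=fold,
        accuracy=accuracy,
        f1=f1,
        auc=auc,
        roc_points=roc,
        confusion=(int(tn), int(fp), int(fn), int(tp)),
        mean_attention=mean_attention,
    )


def _prepare_inputs(
    features: np.ndarray, stats: NormalizationStats, montage_name: str, mode: str
):
    """Normalized (images NCHW, node tables) for the requested mode."""
    normed = apply_normalization(features, stats).astype(np.float32)
    images = nodes = None
    if mode != "gat-only":
        montage = get_montage(montage_name)
        mapping = build_grid_mapping(montage)
        imgs = build_feature_images(normed, mapping, montage.channels)  # (n, 9, 9, 6)
        images = np.ascontiguousarray(imgs.transpose(0, 3, 1, 2))
    if mode != "resnet-only":
        nodes = normed
    return images, nodes


def train_fold(
    features: np.ndarray,
    labels: Sequence[int],
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    model_cfg: ModelConfig = ModelConfig(),
    train_cfg: TrainConfig = TrainConfig(),
    montage_name: str = "deap32",
    fold: int = 0,
    verbose: bool = False,
) -> Tuple[FusionModel, FoldMetrics, NormalizationStats]:
    """Train one fold; returns the fitted model, validation metrics and stats.

    Normalization statistics are fitted on the training indices only and
    applied unchanged to the validation split.
    """
    labels = np.asarray(labels)
    stats = fit_normalization(features[train_idx])
    images, nodes = _prepare_inputs(features, stats, montage_name, train_cfg.mode)

    adjacency = build_adjacency(model_cfg.n_channels)
    model = FusionModel(
        model_cfg, mode=train_cfg.mode, adjacency=adjacency,
        seed=train_cfg.seed * 1000 + fold,
    )
    opt = Adam(model.params(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed * 1000 + fold + 500_000)

    y_train = labels[train_idx]
    if train_cfg.shuffle_labels:
        y_train = rng.permutation(y_train)

    epoch_losses: List[float] = []
    order = np.arange(len(train_idx))
    for epoch in range(train_cfg.epochs):
        rng.shuffle(order)
        losses = []
        for lo in range(0, len(order), train_cfg.batch_size):
            sel = train_idx[order[lo : lo + train_cfg.batch_size]]
            ysel = y_train[order[lo : lo + train_cfg.batch_size]]
            logits = model.forward(
                images[sel] if images is not None else None,
                nodes[sel] if nodes is not None else None,
                training=True,
            )
            loss, _, dlogits = softmax_cross_entropy(logits, ysel)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at fold {fold}, epoch {epoch}"
                )
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        epoch_losses.append(float(np.mean(losses)))
        if verbose:
            print(f"  fold {fold} epoch {epoch}: loss {epoch_losses[-1]:.4f}", flush=True)

    probs, mean_att = model.predict_proba(
        images[val_idx] if images is not None else None,
        nodes[val_idx] if nodes is not None else None,
        collect_attention=train_cfg.mode != "resnet-only",
    )
    metrics = compute_metrics(labels[val_idx], probs, fold=fold, mean_attention=mean_att)
    metrics.train_losses = epoch_losses
    return model, metrics, stats


def cross_validate(
    dataset: SegmentDataset,
    model_cfg: ModelConfig = ModelConfig(),
    train_cfg: TrainConfig = TrainConfig(),
    out_dir: Optional[Path] = None,
    verbose: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation over a segment dataset."""
    labels = dataset.labels(train_cfg.dimension)
    groups = None
    if train_cfg.group_by_trial:
        # one group per (subject, trial)
        groups = dataset.provenance[:, 0] * 10_000 + dataset.provenance[:, 1]
    folds = make_folds(labels, k=train_cfg.folds, seed=train_cfg.seed, groups=groups)
    fold_metrics: List[FoldMetrics] = []
    for i, (tr, va) in enumerate(folds):
        _, metrics, _ = train_fold(
            dataset.features, labels, tr, va, model_cfg, train_cfg,
            montage_name=dataset.montage_name, fold=i, verbose=verbose,
        )
        fold_metrics.append(metrics)
        if verbose:
            print(f"fold {i}: acc {metrics.accuracy:.3f} f1 {metrics.f1:.3f} "
                  f"auc {metrics.auc:.3f}", flush=True)
    accs = np.array([m.accuracy for m in fold_metrics])
    f1s = np.array([m.f1 for m in fold_metrics])
    aucs = np.array([m.auc for m in fold_metrics])
    summary = {
        "mode": train_cfg.mode,
        "dimension": train_cfg.dimension,
        "folds": train_cfg.folds,
        "accuracy_mean": float(accs.mean()),
        "accuracy_sd": float(accs.std()),
        "f1_mean": float(f1s.mean()),
        "f1_sd": float(f1s.std()),
        "auc_mean": float(np.nanmean(aucs)),
        "auc_sd": float(np.nanstd(aucs)),
    }
    result = CVResult(folds=fold_metrics, summary=summary)
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: CVResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(out_dir / "metrics.csv", index=False)
    (out_dir / "summary.json").write_text(json.dumps(result.summary, indent=2))
    for m in result.folds:
        np.savetxt(
            out_dir / f"roc_fold{m.fold}.csv", m.roc_points,
            delimiter=",", header="fpr,tpr", comments="",
        )
    atts = [m.mean_attention for m in result.folds if m.mean_attention is not None]
    if atts:
        np.savetxt(out_dir / "mean_attention.csv", np.mean(atts, axis=0), delimiter=",")
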