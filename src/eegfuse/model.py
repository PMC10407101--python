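"""The dual-branch fusion network.

One branch is a residual CNN over the sparse 9 x 9 x 6 feature image: four
residual blocks (two with 64 filters, two with 128, all 3 x 3 kernels,
stride 1, same padding — the 9 x 9 plane is never downsampled), each block
two conv -> batch-norm stages with an identity skip (1 x 1 projection when
the channel count changes) added before the final ReLU.  Its output is
flattened to a 9*9*128 = 10368 vector.

The other branch runs multi-head graph attention over the 32-node channel
graph (fully connected, no self-loops): two GAT layers with K = 2 heads of
16 dims each (outputs concatenated, ELU inside), flattened to 32*32 = 1024
and batch-normalized.

The two flattened branch outputs are concatenated (10368 + 1024 = 11392) and
classified by a fully connected head (hidden ReLU layer, then softmax).
Single-branch ablation modes route only one branch's features to the head.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .nn import Adam  # noqa: F401  (re-export for callers)
from .nn.gat import GATLayer
from .nn.layers import (
    BatchNorm,
    Conv1x1,
    Conv3x3Same,
    Dense,
    Layer,
    Param,
    ReLU,
    softmax,
)

__all__ = ["ModelConfig", "ResidualBlock", "FusionModel", "MODES", "mean_attention"]

MODES = ("fused", "resnet-only", "gat-only")


@dataclass
class ModelConfig:
    """Architectural hyperparameters of the fusion network."""

    res_blocks: Tuple[Tuple[int, int], ...] = ((64, 2), (128, 2))  # (filters, count)
    gat_layers: int = 2
    gat_heads: int = 2
    gat_hidden: int = 16  # output dims per head
    leaky_slope: float = 0.2
    n_classes: int = 2
    fusion_hidden: int = 128
    dropout: float = 0.0
    self_loops: bool = False
    grid_shape: Tuple[int, int] = (9, 9)
    n_channels: int = 32
    n_features: int = 6

    def __post_init__(self) -> None:
        if self.gat_heads < 1 or self.gat_hidden < 1:
            raise ValueError("gat_heads and gat_hidden must be >= 1")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")

    @property
    def resnet_out_dim(self) -> int:
        last_filters = self.res_blocks[-1][0]
        return self.grid_shape[0] * self.grid_shape[1] * last_filters

    @property
    def gat_out_dim(self) -> int:
        return self.n_channels * self.gat_heads * self.gat_hidden

    def fused_dim(self, mode: str) -> int:
        if mode == "resnet-only":
            return self.resnet_out_dim
        if mode == "gat-only":
            return self.gat_out_dim
        return self.resnet_out_dim + self.gat_out_dim


class ResidualBlock(Layer):
    """conv3x3 -> BN -> ReLU -> conv3x3 -> BN, identity skip, final ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        self.conv1 = Conv3x3Same(c_in, c_out, rng, dtype)
        self.bn1 = BatchNorm(c_out, axes=(0, 2, 3), dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv3x3Same(c_out, c_out, rng, dtype)
        self.bn2 = BatchNorm(c_out, axes=(0, 2, 3), dtype=dtype)
        self.proj = Conv1x1(c_in, c_out, rng, dtype) if c_in != c_out else None
        self.relu_out = ReLU()

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training))
        h = self.bn2.forward(self.conv2.forward(h, training), training)
        skip = self.proj.forward(x, training) if self.proj is not None else x
        return self.relu_out.forward(h + skip, training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dout)
        dh = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(d)))))
        dskip = self.proj.backward(d) if self.proj is not None else d
        return dh + dskip

    def params(self) -> List[Param]:
        out = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.proj is not None:
            out += self.proj.params()
        return out


class FusionModel:
    """Dual-branch classifier over (feature image, graph sample) pairs.

    ``mode`` selects the forward routing: "fused" concatenates both branch
    outputs; "resnet-only" / "gat-only" send a single branch to the head
    (the single-network ablations).
    """

    def __init__(
        self,
        cfg: ModelConfig = ModelConfig(),
        mode: str = "fused",
        adjacency: Optional[np.ndarray] = None,
        seed: int = 0,
        dtype=np.float32,
    ):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
        self.cfg = cfg
        self.mode = mode
        self.dtype = dtype
        self.seed = seed
        rng = np.random.default_rng(seed)
        if adjacency is None:
            from .montage import build_adjacency

            adjacency = build_adjacency(cfg.n_channels)
        adjacency = np.asarray(adjacency, dtype=dtype)
        if cfg.self_loops:
            adjacency = adjacency + np.eye(cfg.n_channels, dtype=dtype)
        self.adjacency = adjacency

        self.blocks: List[ResidualBlock] = []
        if mode != "gat-only":
            c_prev = cfg.n_features
            for filters, count in cfg.res_blocks:
                for _ in range(count):
                    self.blocks.append(ResidualBlock(c_prev, filters, rng, dtype))
                    c_prev = filters

        self.gat: List[GATLayer] = []
        self.bn_gat: Optional[BatchNorm] = None
        if mode != "resnet-only":
            d_in = cfg.n_features
            for _ in range(cfg.gat_layers):
                layer = GATLayer(
                    d_in, cfg.gat_hidden, cfg.gat_heads, rng,
                    leaky_slope=cfg.leaky_slope, dtype=dtype,
                )
                self.gat.append(layer)
                d_in = layer.d_out
            self.bn_gat = BatchNorm(cfg.gat_out_dim, axes=(0,), dtype=dtype)

        self.fc1 = Dense(cfg.fused_dim(mode), cfg.fusion_hidden, rng, dtype)
        self.relu_head = ReLU()
        self.fc2 = Dense(cfg.fusion_hidden, cfg.n_classes, rng, dtype)
        self.dropout = cfg.dropout
        self._drop_rng = np.random.default_rng(seed + 1)
        self._cache_shapes = None

    # -- forward / backward -------------------------------------------------

    def forward(self, images: Optional[np.ndarray], nodes: Optional[np.ndarray],
                training: bool = True) -> np.ndarray:
        """(B, 6, 9, 9) images + (B, 32, 6) node features -> (B, n_classes) logits."""
        parts = []
        if self.mode != "gat-only":
            h = np.asarray(images, dtype=self.dtype)
            B = h.shape[0]
            for block in self.blocks:
                h = block.forward(h, training)
            parts.append(h.reshape(B, -1))
        if self.mode != "resnet-only":
            g = np.asarray(nodes, dtype=self.dtype)
            B = g.shape[0]
            for layer in self.gat:
                g = layer.forward(g, self.adjacency, training)
            g = g.reshape(B, -1)
            g = self.bn_gat.forward(g, training)
            parts.append(g)
        self._cache_shapes = [p.shape for p in parts]
        fused = parts[0] if len(parts) == 1 else np.concatenate(parts, axis=1)
        h = self.relu_head.forward(self.fc1.forward(fused, training), training)
        if training and self.dropout > 0:
            mask = self._drop_rng.random(h.shape) >= self.dropout
            h = h * mask / (1.0 - self.dropout)
            self._drop_mask = mask
        else:
            self._drop_mask = None
        return self.fc2.forward(h, training)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc2.backward(dlogits)
        if self._drop_mask is not None:
            d = d * self._drop_mask / (1.0 - self.dropout)
        d = self.fc1.backward(self.relu_head.backward(d))
        if self.mode == "fused":
            split = self._cache_shapes[0][1]
            d_res, d_gat = d[:, :split], d[:, split:]
        elif self.mode == "resnet-only":
            d_res, d_gat = d, None
        else:
            d_res, d_gat = None, d
        if d_res is not None:
            B = d_res.shape[0]
            h = d_res.reshape(B, self.cfg.res_blocks[-1][0], *self.cfg.grid_shape)
            for block in reversed(self.blocks):
                h = block.backward(h)
        if d_gat is not None:
            B = d_gat.shape[0]
            g = self.bn_gat.backward(d_gat)
            g = g.reshape(B, self.cfg.n_channels, -1)
            for layer in reversed(self.gat):
                g = layer.backward(g)

    def params(self) -> List[Param]:
        out: List[Param] = []
        for block in self.blocks:
            out += block.params()
        for layer in self.gat:
            out += layer.params()
        if self.bn_gat is not None:
            out += self.bn_gat.params()
        out += self.fc1.params() + self.fc2.params()
        return out

    # -- inference ----------------------------------------------------------

    def predict_proba(
        self,
        images: Optional[np.ndarray],
        nodes: Optional[np.ndarray],
        batch_size: int = 256,
        collect_attention: bool = False,
    ) -> Tuple[np.ndarray, Optional[np.ndarray]]:
        """Evaluation-mode class probabilities (+ summed first-layer attention)."""
        n = (images if images is not None else nodes).shape[0]
        probs = []
        att_sum = None
        att_n = 0
        for lo in range(0, n, batch_size):
            hi = min(lo + batch_size, n)
            logits = self.forward(
                images[lo:hi] if images is not None else None,
                nodes[lo:hi] if nodes is not None else None,
                training=False,
            )
            probs.append(softmax(logits))
            if collect_attention and self.gat:
                a = self.gat[0].attention  # (B, K, n, n)
                s = a.sum(axis=(0, 1))
                att_sum = s if att_sum is None else att_sum + s
                att_n += a.shape[0] * a.shape[1]
        mean_att = att_sum / att_n if att_sum is not None else None
        return np.concatenate(probs), mean_att

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, (p, _) in enumerate(self.params())}
        header = json.dumps({"cfg": asdict(self.cfg), "mode": self.mode, "seed": self.seed})
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "FusionModel":
        with np.load(path) as z:
            header = json.loads(bytes(z["__header__"]).decode())
            cfg_d = header["cfg"]
            cfg_d["res_blocks"] = tuple(tuple(b) for b in cfg_d["res_blocks"])
            cfg_d["grid_shape"] = tuple(cfg_d["grid_shape"])
            model = cls(ModelConfig(**cfg_d), mode=header["mode"], seed=header["seed"])
            for i, (p, _) in enumerate(model.params()):
                p[...] = z[f"p{i}"]
        return model


def mean_attention(records: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean of attention matrices (heads/samples already stacked).

    Accepts matrices of shape (..., n, n); averages over all leading axes and
    over the sequence.  The mean of row-stochastic matrices is row-stochastic
    over the shared neighbourhood structure.
    """
    if len(records) == 0:
        raise ValueError("no attention records")
    acc = None
    count = 0
    for rec in records:
        rec = np.asarray(rec)
        mats = rec.reshape(-1, rec.shape[-2], rec.shape[-1])
        s = mats.sum(axis=0)
        acc = s if acc is None else acc + s
        count += mats.shape[0]
    return acc / count
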