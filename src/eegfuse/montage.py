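"""Electrode montages, 2-D grid mappings and channel-graph adjacency.

A montage fixes the ordered list of electrode labels (so that channel index
``i`` of a raw array always means the same scalp site) and places each
electrode into a cell of a small 2-D grid that mirrors the 10/20 layout seen
from above: row 0 is the front of the head, column 0 the left ear, and the
midline (``z``) electrodes run down the centre column.  Per-channel features
dropped into those cells form the sparse "feature image" consumed by the
convolutional branch; cells with no electrode stay exactly zero.

The channel graph used by the attention branch is fully connected with no
self-loops: every electrode is assumed a-priori related to every other one,
and the attention mechanism learns to re-weight those edges.

Montages are registered from small YAML files; only the 32-channel DEAP
montage ships, but additional montages can be registered at run time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterator, Mapping, Tuple

import numpy as np
import yaml

__all__ = [
    "Montage",
    "GridMapping",
    "get_montage",
    "register_montage",
    "available_montages",
    "build_grid_mapping",
    "build_adjacency",
    "ascii_grid",
]

Cell = Tuple[int, int]


class MontageError(ValueError):
    """Raised for unknown montages or malformed montage definitions."""


@dataclass(frozen=True)
class GridMapping:
    """Injective map from channel label to a cell of the feature-image grid."""

    entries: Mapping[str, Cell]
    grid_shape: Tuple[int, int] = (9, 9)

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        seen: Dict[Cell, str] = {}
        for label, (r, c) in self.entries.items():
            if not (0 <= r < rows and 0 <= c < cols):
                raise MontageError(f"cell {(r, c)} of {label!r} outside {self.grid_shape} grid")
            if (r, c) in seen:
                raise MontageError(f"{label!r} and {seen[(r, c)]!r} share cell {(r, c)}")
            seen[(r, c)] = label

    def __getitem__(self, label: str) -> Cell:
        return self.entries[label]

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def inverse(self) -> Dict[Cell, str]:
        return {cell: label for label, cell in self.entries.items()}


@dataclass(frozen=True)
class Montage:
    """An ordered electrode layout plus its grid placement."""

    name: str
    channels: Tuple[str, ...]
    grid_shape: Tuple[int, int] = (9, 9)
    grid: Mapping[str, Cell] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise MontageError(f"montage {self.name!r} has duplicate channel labels")
        missing = [c for c in self.channels if c not in self.grid]
        if missing:
            raise MontageError(f"montage {self.name!r} lacks grid cells for {missing}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, label: str) -> int:
        return self.channels.index(label)


_REGISTRY: Dict[str, Montage] = {}


def _load_builtin() -> None:
    data_dir = resources.files("eegfuse") / "data" / "montages"
    for entry in data_dir.iterdir():
        if entry.name.endswith(".yaml"):
            register_montage_file(entry)


def register_montage_file(path) -> Montage:
    """Register a montage from a YAML definition file."""
    raw = yaml.safe_load(Path(str(path)).read_text() if isinstance(path, (str, Path)) else path.read_text())
    channels = tuple(raw["channels"].keys())
    grid = {lab: tuple(cell) for lab, cell in raw["channels"].items()}
    montage = Montage(
        name=raw["name"],
        channels=channels,
        grid_shape=tuple(raw.get("grid_shape", (9, 9))),
        grid=grid,
    )
    return register_montage(montage)


def register_montage(montage: Montage) -> Montage:
    _REGISTRY[montage.name] = montage
    return montage


def available_montages() -> Tuple[str, ...]:
    if not _REGISTRY:
        _load_builtin()
    return tuple(sorted(_REGISTRY))


def get_montage(name: str = "deap32") -> Montage:
    if not _REGISTRY:
        _load_builtin()
    try:
        return _REGISTRY[name]
    except KeyError:
        raise MontageError(f"unsupported montage {name!r}; available: {sorted(_REGISTRY)}") from None


def build_grid_mapping(montage: Montage) -> GridMapping:
    """Return the validated channel -> grid-cell mapping of a montage."""
    if not montage.grid:
        raise MontageError(f"montage {montage.name!r} defines no grid")
    return GridMapping(entries=dict(montage.grid), grid_shape=montage.grid_shape)


def build_adjacency(n: int, dtype=np.float32) -> np.ndarray:
    """Fully connected channel adjacency: zero diagonal, ones elsewhere.

    Every channel is a-priori a neighbour of every other channel (no
    self-loops); the graph-attention layers learn data-dependent edge
    weights on top of this template.
    """
    if n < 2:
        raise MontageError(f"degenerate graph: need at least 2 channels, got {n}")
    adj = np.ones((n, n), dtype=dtype)
    np.fill_diagonal(adj, 0)
    return adj


def validate_adjacency(adj: np.ndarray) -> None:
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError(f"adjacency must be square, got {adj.shape}")
    if np.trace(np.abs(adj)) != 0:
        raise ValueError("adjacency must have a zero diagonal (no self-loops)")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")


def ascii_grid(montage: Montage, empty: str = ".") -> str:
    """Render the montage grid as fixed-width ASCII art (front of head on top)."""
    rows, cols = montage.grid_shape
    width = max(len(c) for c in montage.channels)
    inv = build_grid_mapping(montage).inverse()
    lines = []
    for r in range(rows):
        cells = [inv.get((r, c), empty).center(width) for c in range(cols)]
        lines.append(" ".join(cells))
    return "\n".join(lines)
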