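"""Synthetic cohorts with the DEAP recording geometry.

Real DEAP recordings are licensed, so every stage of the pipeline is
exercised on generated cohorts that copy the geometry exactly — per subject
40 trials x 32 EEG channels x 8064 samples (63 s at 128 Hz, the first 3 s a
pre-trial baseline) with 0-9 self-assessment ratings — and carry a
controllable class-dependent structure:

* every channel is an alpha-band sinusoid (8-13 Hz, random frequency and
  phase) plus broadband Gaussian noise;
* each trial draws a balanced latent class; for "high" trials a fixed
  frontal channel subset (Fp1, Fp2, F3, F4, AF3, AF4) has its whole signal
  scaled by (1 + effect_amplitude) — a variance/SD effect — and its
  noise-to-sinusoid ratio additionally scaled by (1 + effect_irregularity)
  — a fuzzy-entropy effect invisible to pure rescaling;
* channel pairs listed in ``coupled_pairs`` share an additive latent source,
  giving the graph branch a correlation structure to exploit;
* the rating is drawn from (5, 9] for high trials and [1, 5] for low ones,
  so threshold binarization recovers the latent class exactly, and the
  latent class is stored alongside the ratings so labeling errors can be
  distinguished from modeling errors.

This is a pipeline test-bed, not physiological EEG: there is no 1/f
spectrum, no artifacts, no volume conduction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Tuple

import numpy as np

from .dataset import Cohort, GraphSample, build_graph_sample
from .montage import get_montage

__all__ = ["SimConfig", "FRONTAL_CHANNELS", "generate_cohort", "generate_toy_graph"]

FRONTAL_CHANNELS: Tuple[str, ...] = ("Fp1", "Fp2", "F3", "F4", "AF3", "AF4")


@dataclass
class SimConfig:
    n_subjects: int = 4
    n_trials: int = 20
    fs: float = 128.0
    trial_seconds: float = 60.0
    baseline_seconds: float = 3.0
    n_channels: int = 32
    seed: int = 0
    effect_amplitude: float = 1.0
    effect_irregularity: float = 1.0
    coupled_pairs: Tuple[Tuple[str, str], ...] = (("Fp1", "F3"), ("Fp2", "F4"))
    noise_sd: float = 5.0  # uV, broadband noise level
    alpha_amplitude: float = 10.0  # uV, sinusoid amplitude
    coupling_sd: float = 3.0  # uV, shared latent source on coupled pairs
    montage_name: str = "deap32"

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_trials, self.n_channels) < 1:
            raise ValueError("counts must be positive")
        if self.effect_amplitude < 0 or self.effect_irregularity < 0:
            raise ValueError("effect sizes must be non-negative")

    @property
    def samples_per_trial(self) -> int:
        return int(round((self.trial_seconds + self.baseline_seconds) * self.fs))

    @property
    def baseline_samples(self) -> int:
        return int(round(self.baseline_seconds * self.fs))


def generate_cohort(cfg: SimConfig = SimConfig()) -> Cohort:
    """Generate a cohort of class-structured multi-channel recordings."""
    montage = get_montage(cfg.montage_name)
    if cfg.n_channels != montage.n_channels:
        raise ValueError(
            f"n_channels={cfg.n_channels} does not match montage "
            f"{montage.name!r} with {montage.n_channels} channels"
        )
    frontal_idx = np.array([montage.index(c) for c in FRONTAL_CHANNELS])
    pair_idx = []
    for a, b in cfg.coupled_pairs:
        try:
            pair_idx.append((montage.index(a), montage.index(b)))
        except ValueError:
            raise ValueError(f"coupled pair names unknown electrode: {(a, b)}") from None

    rng = np.random.default_rng(cfg.seed)
    S, T, C, N = cfg.n_subjects, cfg.n_trials, cfg.n_channels, cfg.samples_per_trial
    t = (np.arange(N, dtype=np.float32) / cfg.fs)[None, None, :]

    signals = np.empty((S, T, C, N), dtype=np.float32)
    ratings = np.empty((S, T, 4), dtype=np.float32)
    latent = np.empty((S, T), dtype=np.int8)

    for s in range(S):
        # balanced latent classes within each subject
        classes = np.zeros(T, dtype=np.int8)
        classes[: T // 2] = 1
        rng.shuffle(classes)
        latent[s] = classes

        freqs = rng.uniform(8.0, 13.0, size=(T, C, 1)).astype(np.float32)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(T, C, 1)).astype(np.float32)
        amp = np.full((T, C, 1), cfg.alpha_amplitude, dtype=np.float32)
        nsd = np.full((T, C, 1), cfg.noise_sd, dtype=np.float32)
        high = classes == 1
        # amplitude effect rescales the whole channel (variance/SD separation);
        # irregularity effect raises the noise-to-sinusoid ratio on top of it
        # (fuzzy-entropy separation, invisible to amplitude rescaling alone)
        gain = 1.0 + cfg.effect_amplitude
        amp[np.ix_(high, frontal_idx)] *= gain
        nsd[np.ix_(high, frontal_idx)] *= gain * (1.0 + cfg.effect_irregularity)

        sig = amp * np.sin(2.0 * np.pi * freqs * t + phases)
        sig += nsd * rng.standard_normal((T, C, N), dtype=np.float32)
        for ia, ib in pair_idx:
            shared = cfg.coupling_sd * rng.standard_normal((T, N), dtype=np.float32)
            sig[:, ia, :] += shared
            sig[:, ib, :] += shared
        signals[s] = sig

        # ratings: (5, 9] for high, [1, 5] for low, on valence and arousal alike
        r = np.where(
            classes == 1,
            rng.uniform(5.0, 9.0, size=T),
            rng.uniform(1.0, 5.0, size=T),
        ).astype(np.float32)
        r[classes == 1] = np.maximum(r[classes == 1], np.float32(np.nextafter(5.0, 9.0)))
        ratings[s, :, 0] = r  # valence
        ratings[s, :, 1] = r  # arousal
        ratings[s, :, 2:] = rng.uniform(1.0, 9.0, size=(T, 2)).astype(np.float32)

    return Cohort(
        signals=signals,
        ratings=ratings,
        fs=cfg.fs,
        baseline_samples=cfg.baseline_samples,
        montage_name=cfg.montage_name,
        latent_class=latent,
        metadata={"generator": "eegfuse.synthetic", "config": asdict(cfg)},
    )


def generate_toy_graph() -> GraphSample:
    """Fixed 5-node graph fixture for attention-oracle tests (no randomness).

    The adjacency is binary with a zero diagonal and every node has at least
    one neighbour; node features are a fixed deterministic 5 x 6 table.
    """
    adj = np.array(
        [
            [0, 1, 1, 0, 1],
            [1, 0, 1, 0, 0],
            [0, 1, 0, 1, 0],
            [1, 0, 1, 0, 1],
            [0, 1, 0, 1, 0],
        ],
        dtype=np.float64,
    )
    nodes = (np.arange(30, dtype=np.float64).reshape(5, 6) % 7 - 3.0) / 3.0
    return build_graph_sample(nodes, adj)
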