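"""Synthetic study data with known ground truth.

Emulates the object-naming / property-contemplation designs this toolkit
targets: 60 stimulus classes shown once per block over 6 blocks, each class
described by P = 218 ordinal semantic attributes, and a large pool of
neural features of which only a subset is truly driven by the attributes
through a planted linear map.  Also generates raw ECoG-like multichannel
recordings with a class-dependent high-gamma amplitude modulation so the
spectro-temporal extraction stage can be tested end to end.

All randomness flows through numpy's PCG64 ``default_rng`` seeded from the
config, so outputs are bit-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .ecog import EcogRecording
from .regression import AttributeMatrix, TrialTable, normalize_attribute_rows

__all__ = [
    "SyntheticConfig",
    "EcogSimConfig",
    "GroundTruth",
    "generate_attributes",
    "generate_trials",
    "generate_dataset",
    "generate_ecog_recording",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the tabular (trial-table) simulator.

    Defaults mirror the canonical design: 60 classes x 6 blocks (T = 360
    trials), 218 attributes, a 2,000-feature pool with 50 informative
    features at snr 1 (signal sd / trial-noise sd per informative feature),
    and a modest additive per-block drift.  ``attrs_per_feature`` controls
    the sparse planted map (each informative feature driven by a few
    attributes); ``dense_weights`` switches to the dense hard case.
    """

    n_classes: int = 60
    n_blocks: int = 6
    p_attributes: int = 218
    m_total: int = 2000
    n_informative: int = 50
    snr: float = 1.0
    block_drift_sd: float = 0.3
    attrs_per_feature: int = 3
    dense_weights: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.m_total:
            raise ValueError("n_informative cannot exceed m_total")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        for name in ("n_classes", "n_blocks", "p_attributes", "m_total"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Planted structure of one simulated dataset."""

    w_star: np.ndarray            # (P, n_informative) planted linear map
    informative_idx: np.ndarray   # positions of informative features in the table
    class_signal: np.ndarray      # (n_classes, n_informative) noiseless class means
    raw_scores: np.ndarray        # ordinal 1..5 attribute answers


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg_seed, stream]))


def generate_attributes(cfg: SyntheticConfig):
    """Simulate the class-by-attribute matrix.

    Ordinal answers in {1..5} per class/attribute are mapped linearly to
    [-1, 1] via (a - 3)/2 and rows are unit-normalized.  Returns the
    normalized :class:`AttributeMatrix` and the raw ordinal scores.
    """
    rng = _rng(cfg.seed, 0)
    raw = rng.integers(1, 6, size=(cfg.n_classes, cfg.p_attributes))
    scaled = (raw - 3) / 2.0
    # an all-3 row would be all-zero after rescaling; nudge deterministically
    zero_rows = np.flatnonzero(np.linalg.norm(scaled, axis=1) == 0)
    for i in zero_rows:
        raw[i, 0] = 4
        scaled[i, 0] = 0.5
    class_ids = [f"class{i:03d}" for i in range(cfg.n_classes)]
    attr_names = [f"attr{j:03d}" for j in range(cfg.p_attributes)]
    A = normalize_attribute_rows(AttributeMatrix(scaled, class_ids, attr_names))
    return A, raw


def generate_trials(cfg: SyntheticConfig, A: AttributeMatrix,
                    raw_scores: np.ndarray | None = None):
    """Simulate the blocked trial table from a (normalized) attribute matrix.

    Informative features carry a planted linear attribute->feature signal
    scaled to unit sd over classes, plus white trial noise of sd 1/snr and a
    per-(feature, block) additive drift offset; non-informative features are
    pure noise (plus the same drift process) with matched marginal variance.
    One trial per class per block, presentation order permuted within block.
    """
    rng = _rng(cfg.seed, 1)
    C, B, P, M = cfg.n_classes, cfg.n_blocks, A.P, cfg.m_total
    k = cfg.n_informative
    if cfg.dense_weights:
        w = rng.normal(size=(P, k))
    else:
        w = np.zeros((P, k))
        for j in range(k):
            support = rng.choice(P, size=min(cfg.attrs_per_feature, P), replace=False)
            w[support, j] = rng.normal(size=len(support))
    signal = A.values @ w  # (C, k)
    if cfg.snr > 0:
        sd = signal.std(axis=0)
        sd[sd == 0] = 1.0
        signal = (signal - signal.mean(axis=0)) / sd
        noise_sd = (1.0 / cfg.snr) if np.isfinite(cfg.snr) else 0.0
        signal_var = 1.0
    else:
        signal = np.zeros_like(signal)
        noise_sd = 1.0
        signal_var = 0.0

    informative_idx = np.sort(rng.choice(M, size=k, replace=False))
    noise_marginal_sd = np.sqrt(signal_var + noise_sd ** 2)

    class_order = np.concatenate([rng.permutation(C) for _ in range(B)])
    block_ids = np.repeat(np.arange(1, B + 1), C)
    T = C * B
    feats = rng.normal(0.0, noise_marginal_sd, size=(T, M))
    if noise_sd != noise_marginal_sd:
        feats[:, informative_idx] = rng.normal(0.0, noise_sd, size=(T, k)) if noise_sd > 0 \
            else 0.0
    feats[:, informative_idx] += signal[class_order]
    if cfg.block_drift_sd > 0:
        drift = rng.normal(0.0, cfg.block_drift_sd, size=(B, M))
        feats += drift[block_ids - 1]
    class_ids = np.array([A.class_ids[c] for c in class_order])
    meta = pd.DataFrame({"feature_id": [f"f{j:04d}" for j in range(M)]})
    table = TrialTable(feats, class_ids, block_ids, meta)
    truth = GroundTruth(w_star=w, informative_idx=informative_idx,
                        class_signal=signal, raw_scores=raw_scores)
    return table, truth


def generate_dataset(cfg: SyntheticConfig):
    """Attributes + trials + ground truth in one call."""
    A, raw = generate_attributes(cfg)
    table, truth = generate_trials(cfg, A, raw_scores=raw)
    return A, table, truth


@dataclass
class EcogSimConfig:
    """Conditions for the raw-recording simulator.

    Paper-style schedule: 1,000 Hz sampling, 1 s stimulus, inter-stimulus
    interval uniform in [3.5, 4.5] s, one presentation of every class per
    block.  Electrode count is configurable (real grids vary by patient);
    the default is a desk-scale 16-electrode layout in two grids.  Class
    information is planted as an amplitude modulation of 70-110 Hz
    band-limited noise on the responsive electrodes during the first 750 ms
    after onset.
    """

    n_classes: int = 60
    n_blocks: int = 6
    n_electrodes: int = 16
    n_grids: int = 2
    sample_rate: float = 1000.0
    t_stim: float = 1.0
    t_fix: tuple = (3.5, 4.5)
    mod_band: tuple = (70.0, 110.0)
    mod_depth: float = 1.0
    n_responsive: int = 8
    noise_scale: float = 1.0
    common_mode_scale: float = 0.5
    lead_in_s: float = 2.0
    seed: int = 0


def _one_over_f_noise(rng, n_channels, n_samples, f_floor=1.0, fs=1000.0):
    white = rng.normal(size=(n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(f, f_floor))
    x = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    return x / x.std(axis=1, keepdims=True)


def generate_ecog_recording(cfg: EcogSimConfig):
    """Simulate a raw multichannel recording with a planted high-gamma code.

    Per channel: 1/f background noise; per grid: a shared common-mode
    component (removed exactly by common-average referencing); on responsive
    electrodes: class-gain-modulated band-limited noise added for 750 ms
    after each onset.  Returns the :class:`EcogRecording` and a ground-truth
    dict with the class->gain map and responsive electrode list.
    """
    rng = _rng(cfg.seed, 2)
    fs = cfg.sample_rate
    C, B = cfg.n_classes, cfg.n_blocks
    n_events = C * B
    onsets, classes, blocks = [], [], []
    t = cfg.lead_in_s
    for b in range(1, B + 1):
        for c in rng.permutation(C):
            onsets.append(int(round(t * fs)))
            classes.append(f"class{c:03d}")
            blocks.append(b)
            t += cfg.t_stim + rng.uniform(*cfg.t_fix)
    n_samples = int(round((t + 1.0) * fs))
    signals = cfg.noise_scale * _one_over_f_noise(rng, cfg.n_electrodes, n_samples, fs=fs)

    per_grid = int(np.ceil(cfg.n_electrodes / cfg.n_grids))
    groups = [f"grid{(i // per_grid) + 1}" for i in range(cfg.n_electrodes)]
    for g in sorted(set(groups)):
        members = [i for i, gg in enumerate(groups) if gg == g]
        common = cfg.common_mode_scale * _one_over_f_noise(rng, 1, n_samples, fs=fs)[0]
        common += cfg.common_mode_scale * np.sin(
            2 * np.pi * 60.0 * np.arange(n_samples) / fs + rng.uniform(0, 2 * np.pi))
        signals[members] += common

    responsive = np.sort(rng.choice(cfg.n_electrodes, size=min(cfg.n_responsive,
                                                               cfg.n_electrodes),
                                    replace=False))
    gains = np.zeros((cfg.n_electrodes, C))
    sos = scipy.signal.butter(4, cfg.mod_band, btype="bandpass", fs=fs, output="sos")
    n_mod = int(round(0.750 * fs))
    taper = scipy.signal.windows.tukey(n_mod, alpha=0.2)
    for e in responsive:
        gains[e] = cfg.mod_depth * rng.uniform(0.0, 1.0, size=C)
        carrier = scipy.signal.sosfiltfilt(sos, rng.normal(size=n_samples))
        carrier /= carrier.std()
        for onset, cls in zip(onsets, classes):
            c = int(cls[5:])
            signals[e, onset:onset + n_mod] += gains[e, c] * taper * carrier[onset:onset + n_mod]

    events = pd.DataFrame({"onset_sample": onsets, "class_id": classes,
                           "block_id": blocks})
    rec = EcogRecording(signals=signals, sample_rate=fs,
                        channel_ids=[f"e{i:02d}" for i in range(cfg.n_electrodes)],
                        channel_groups=groups, events=events,
                        t_stim=cfg.t_stim, t_fix=cfg.t_fix)
    truth = {"responsive_electrodes": responsive, "class_gains": gains}
    return rec, truth
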