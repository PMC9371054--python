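"""Synthetic motor-imagery EEG with known ground truth.

The generator emulates the ingredients that matter for testing an artifact
removal pipeline end to end:

* band-limited sensorimotor sources whose mu-band (8-12 Hz) power is
  attenuated in one hemisphere depending on the trial class
  (event-related desynchronization, ERD);
* linear spatial mixing with gains that decay with great-circle distance
  from each source (a Gaussian volume-conduction kernel), which induces
  the broad spurious inter-channel correlations seen on real scalp data;
* additive broadband sensor noise at a requested SNR;
* optionally, a frontal-dominant ocular (blink) artifact source with its
  clean reference trace recorded for ground-truth error measurement.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Set, Tuple

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .dataset import TrialSet

__all__ = [
    "SourceGroundTruth",
    "synthetic_montage",
    "frontal_indices",
    "generate_mi_trials",
    "generate_cohort",
    "inject_eog",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass
class SourceGroundTruth:
    """Everything the generator knows that the pipeline must recover.

    ``source_signals`` has shape ``(n_trials, n_sources, n_samples)`` and
    ``mixing`` is ``(n_channels, n_sources)``; per trial the clean scalp
    signal is exactly ``mixing @ source_signals[trial]`` and the stored
    ``noise`` closes the energy budget: ``data = mixing @ sources + noise``.
    """

    source_signals: np.ndarray
    mixing: np.ndarray
    noise: np.ndarray
    artifact_indices: Set[int]
    class_label: np.ndarray
    seed: int
    source_positions: np.ndarray
    clean_data: Optional[np.ndarray] = None  # pre-artifact scalp data
    eog_reference: Optional[np.ndarray] = None  # (n_trials, n_samples) blink trace

    @property
    def n_sources(self) -> int:
        return self.mixing.shape[1]


def synthetic_montage(n_channels: int) -> np.ndarray:
    """Deterministic quasi-uniform electrode layout on the upper hemisphere.

    Uses a Fibonacci spiral so electrodes never coincide.  The convention
    is +y anterior, +x right, +z superior; the three most anterior rows
    serve as the designated "frontal" electrodes when no EOG channel is
    available.
    """
    if not (8 <= n_channels <= 128):
        raise ValueError(f"n_channels must be in [8, 128], got {n_channels}")
    i = np.arange(n_channels)
    z = (i + 0.5) / n_channels  # strictly inside (0, 1): upper hemisphere
    r = np.sqrt(1.0 - z**2)
    theta = _GOLDEN_ANGLE * i
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return pos


def frontal_indices(positions: np.ndarray, k: int = 3) -> np.ndarray:
    """Indices of the ``k`` most anterior electrodes (largest y)."""
    return np.argsort(-np.asarray(positions)[:, 1], kind="stable")[:k]


def _great_circle(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (radians) between unit vectors."""
    cosang = np.clip(np.asarray(a) @ np.asarray(b).T, -1.0, 1.0)
    return np.arccos(cosang)


def _band_noise(rng: np.random.Generator, band: Tuple[float, float], fs: float,
                n: int, order: int = 4) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band``."""
    sos = butter(order, band, btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


# Canonical source layout: lateral sensorimotor pairs plus background
# activity; x < 0 is the left hemisphere.
def _source_positions() -> np.ndarray:
    raw = np.array(
        [
            [-0.70, 0.10, 0.71],   # left sensorimotor, mu
            [+0.70, 0.10, 0.71],   # right sensorimotor, mu
            [-0.55, 0.05, 0.83],   # left sensorimotor, beta
            [+0.55, 0.05, 0.83],   # right sensorimotor, beta
            [0.00, -0.85, 0.53],   # occipital background
            [0.00, 0.60, 0.80],    # frontal-midline background
        ]
    )
    return raw / np.linalg.norm(raw, axis=1, keepdims=True)


def generate_mi_trials(
    n_trials: int = 40,
    n_channels: int = 16,
    fs: float = 250.0,
    duration_s: float = 3.0,
    snr_db: float = 10.0,
    seed: int = 0,
    erd_depth: float = 0.5,
    amplitude_jitter: float = 0.4,
    mixing_width_rad: float = 0.8,
    source_amplitude_uv: float = 10.0,
    frontal_background: bool = True,
) -> Tuple[TrialSet, SourceGroundTruth]:
    """Generate one subject's two-class motor-imagery session.

    Class 0 attenuates mu-band power in the left-hemisphere sources,
    class 1 in the right-hemisphere sources (amplitude scaled by
    ``erd_depth`` on the affected side).  Beta sources are lateralized
    the same way with a milder attenuation.  Every source amplitude is
    additionally jittered per trial by a lognormal factor
    (``exp(amplitude_jitter * N(0,1))``), reproducing the strong
    inter-trial variability of real sensorimotor rhythms that keeps
    single-trial classification well below ceiling.  SNR is the ratio of
    mixed source power to additive sensor-noise power averaged over
    channels.  ``frontal_background=False`` drops the non-discriminative
    frontal-midline background source, producing a subject with no
    frontal-dominant activity (a verified-clean condition).

    Returns the scalp :class:`~sdar.dataset.TrialSet` and the matching
    :class:`SourceGroundTruth`.
    """
    if n_channels < 8:
        raise ValueError("n_channels must be >= 8")
    if fs < 128:
        raise ValueError("fs must be >= 128 Hz")
    if n_trials % 2 != 0:
        raise ValueError("n_trials must be even (balanced classes)")
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")

    rng = np.random.default_rng(seed)
    n_samples = int(round(fs * duration_s))
    positions = synthetic_montage(n_channels)
    src_pos = _source_positions()
    if not frontal_background:
        src_pos = src_pos[:-1]  # drop the frontal-midline source
    n_sources = src_pos.shape[0]

    # Volume-conduction mixing: Gaussian kernel of great-circle distance.
    dist = _great_circle(positions, src_pos)          # (C, S)
    mixing = np.exp(-(dist**2) / (2.0 * mixing_width_rad**2))

    labels = rng.permutation(np.repeat([0, 1], n_trials // 2))

    mu_band = (8.0, 12.0)
    beta_band = (18.0, 26.0)
    bg_band = (1.0, 45.0)
    sources = np.empty((n_trials, n_sources, n_samples))
    for t in range(n_trials):
        lab = labels[t]
        # ERD: the class attenuates its same-side hemisphere sources.
        beta_depth = math.sqrt(erd_depth)                # milder beta ERD
        mu_gain = [erd_depth if lab == 0 else 1.0,       # left mu
                   erd_depth if lab == 1 else 1.0]       # right mu
        beta_gain = [beta_depth if lab == 0 else 1.0,
                     beta_depth if lab == 1 else 1.0]
        jit = np.exp(amplitude_jitter * rng.standard_normal(n_sources))
        sources[t, 0] = jit[0] * mu_gain[0] * _band_noise(rng, mu_band, fs, n_samples)
        sources[t, 1] = jit[1] * mu_gain[1] * _band_noise(rng, mu_band, fs, n_samples)
        sources[t, 2] = jit[2] * beta_gain[0] * _band_noise(rng, beta_band, fs, n_samples)
        sources[t, 3] = jit[3] * beta_gain[1] * _band_noise(rng, beta_band, fs, n_samples)
        sources[t, 4] = 0.8 * jit[4] * _band_noise(rng, bg_band, fs, n_samples)
        if frontal_background:
            sources[t, 5] = 0.8 * jit[5] * _band_noise(rng, bg_band, fs, n_samples)
    sources *= source_amplitude_uv

    clean = np.einsum("cs,nst->nct", mixing, sources)
    p_signal = np.mean(clean**2)
    p_noise = p_signal / (10.0 ** (snr_db / 10.0))
    noise = math.sqrt(p_noise) * rng.standard_normal(clean.shape)
    data = clean + noise

    names = [f"CH{i:02d}" for i in range(n_channels)]
    trials = TrialSet(data=data, fs=fs, channel_names=names,
                      positions=positions, labels=labels,
                      window=(0.0, duration_s))
    truth = SourceGroundTruth(
        source_signals=sources, mixing=mixing, noise=noise,
        artifact_indices=set(), class_label=labels.copy(), seed=seed,
        source_positions=src_pos,
    )
    return trials, truth


def generate_cohort(
    n_subjects: int,
    n_trials: int = 40,
    n_channels: int = 16,
    fs: float = 250.0,
    duration_s: float = 3.0,
    snr_db: float = 10.0,
    seed: int = 0,
    **kwargs,
) -> List[Tuple[TrialSet, SourceGroundTruth]]:
    """Generate ``n_subjects`` independent subjects with derived seeds."""
    ss = np.random.SeedSequence(seed)
    subject_seeds = [int(s) % (2**31 - 1) for s in ss.generate_state(n_subjects)]
    return [
        generate_mi_trials(n_trials=n_trials, n_channels=n_channels, fs=fs,
                           duration_s=duration_s, snr_db=snr_db, seed=s, **kwargs)
        for s in subject_seeds
    ]


def _blink_template(fs: float, rise_s: float = 0.05, decay_s: float = 0.15) -> np.ndarray:
    """Biexponential blink pulse, peak-normalized to 1."""
    t = np.arange(0.0, rise_s + 6.0 * decay_s, 1.0 / fs)
    pulse = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    peak = pulse.max()
    return pulse / peak if peak > 0 else pulse


def inject_eog(
    trials: TrialSet,
    truth: SourceGroundTruth,
    blink_rate_hz: float = 0.5,
    amplitude_uv: float = 100.0,
    seed: int = 0,
    topography_width_rad: float = 0.5,
) -> Tuple[TrialSet, SourceGroundTruth]:
    """Add a frontal-dominant blink artifact source.

    Blink onsets follow a Poisson process at ``blink_rate_hz`` per trial;
    the pulse is a biexponential (50 ms rise, 150 ms decay).  The
    topography is a Gaussian kernel of great-circle distance from a
    virtual eye location just anterior-inferior to the montage, so it
    peaks at the most anterior electrodes and decays posteriorly.  The
    pre-injection data and the clean blink trace are kept in the returned
    :class:`SourceGroundTruth` for cleanup-error measurement.
    """
    if blink_rate_hz <= 0:
        raise ValueError("blink_rate_hz must be positive")
    if amplitude_uv < 0:
        raise ValueError("amplitude_uv must be non-negative")
    if amplitude_uv == 0.0:
        out = trials.copy()
        return out, truth

    rng = np.random.default_rng(seed)
    n_trials, n_channels, n_samples = trials.data.shape
    fs = trials.fs
    template = _blink_template(fs)

    eye = np.array([0.0, 0.94, -0.34])
    eye /= np.linalg.norm(eye)
    dist = _great_circle(trials.positions, eye[None, :])[:, 0]
    topo = np.exp(-(dist**2) / (2.0 * topography_width_rad**2))
    topo /= topo.max()  # most anterior electrode receives full amplitude

    reference = np.zeros((n_trials, n_samples))
    duration_s = n_samples / fs
    for t in range(n_trials):
        n_blinks = rng.poisson(blink_rate_hz * duration_s)
        onsets = np.sort(rng.uniform(0.0, duration_s, size=n_blinks))
        for onset in onsets:
            i0 = int(round(onset * fs))
            seg = min(len(template), n_samples - i0)
            if seg > 0:
                reference[t, i0:i0 + seg] += template[:seg]
    reference *= amplitude_uv

    contaminated = trials.data + topo[None, :, None] * reference[:, None, :]
    out = trials.with_data(contaminated)

    new_mixing = np.column_stack([truth.mixing, topo])
    blink_src = reference[:, None, :]
    new_sources = np.concatenate([truth.source_signals, blink_src], axis=1)
    artifact_idx = set(truth.artifact_indices) | {truth.mixing.shape[1]}
    new_truth = SourceGroundTruth(
        source_signals=new_sources,
        mixing=new_mixing,
        noise=truth.noise,
        artifact_indices=artifact_idx,
        class_label=truth.class_label,
        seed=truth.seed,
        source_positions=np.vstack([truth.source_positions, eye]),
        clean_data=trials.data.copy(),
        eog_reference=reference,
    )
    return out, new_truth
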