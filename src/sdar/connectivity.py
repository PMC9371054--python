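"""Functional-connectivity feature extraction over the sensorimotor rhythms.

Trials are cropped to the post-cue analysis window, band-pass filtered
into four rhythms — mu (8-12 Hz) and low/mid/high beta (12-15, 15-20,
18-40 Hz) — and every channel pair is reduced to one scalar per band by
one of five estimators:

* ``pearson``   — sample Pearson correlation of the band signals;
* ``motifs``    — fraction of time points at which the two signals'
  ordinal patterns (rank order of `degree` consecutive lagged samples)
  coincide;
* ``gfc``       — Gaussian-kernel similarity ``mean_t exp(-(x_t - x'_t)^2
  / 2 sigma^2)`` with the bandwidth set per trial by the median pairwise
  distance heuristic;
* ``coherence`` — Welch cross-spectral coherence magnitude averaged over
  the in-band frequency bins;
* ``plv``       — phase-locking value from analytic-signal phases.

The upper-triangular values (i < j, row-major) of each band's matrix are
concatenated in the fixed band order, giving a per-trial feature vector
of length ``4 * C * (C - 1) / 2``.
"""

from __future__ import annotations

import warnings
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import butter, csd, hilbert, sosfiltfilt, welch

from .dataset import TrialSet

__all__ = [
    "RHYTHM_BANDS", "MEASURES",
    "bandpass", "crop_window",
    "fc_pearson", "fc_motifs", "fc_gaussian", "fc_coherence", "fc_plv",
    "build_features",
]

#: The four analysis rhythms, in fixed order.
RHYTHM_BANDS: Tuple[Tuple[str, float, float], ...] = (
    ("mu", 8.0, 12.0),
    ("beta_l", 12.0, 15.0),
    ("beta_m", 15.0, 20.0),
    ("beta_h", 18.0, 40.0),
)

MEASURES = ("pearson", "motifs", "gfc", "coherence", "plv")


# ---------------------------------------------------------------------------
# temporal preprocessing

def bandpass(trials: TrialSet, band: Tuple[float, float],
             order: int = 5) -> TrialSet:
    """Zero-phase Butterworth band-pass per channel per trial."""
    low, high = band
    if not 0 < low < high:
        raise ValueError(f"invalid band {band}")
    if high >= trials.fs / 2:
        raise ValueError(f"band edge {high} Hz at or above Nyquist "
                         f"({trials.fs / 2} Hz)")
    sos = butter(order, (low, high), btype="bandpass", fs=trials.fs,
                 output="sos")
    return trials.with_data(sosfiltfilt(sos, trials.data, axis=-1))


def crop_window(trials: TrialSet, start_s: float, end_s: float) -> TrialSet:
    """Keep samples in the half-open window ``[start_s, end_s)`` (cue-relative)."""
    w0, w1 = trials.window
    if start_s < w0 - 1e-9 or end_s > w1 + 1e-9:
        raise ValueError(f"window [{start_s}, {end_s}) outside trial extent "
                         f"[{w0}, {w1}]")
    i0 = int(round((start_s - w0) * trials.fs))
    i1 = int(round((end_s - w0) * trials.fs))
    if i1 <= i0:
        raise ValueError("empty crop window")
    return trials.with_data(trials.data[:, :, i0:i1], window=(start_s, end_s))


# ---------------------------------------------------------------------------
# pairwise estimators (vector form)

def fc_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; 0 (with warning) on zero variance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("series must share a length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        warnings.warn("zero-variance series in Pearson FC", RuntimeWarning)
        return 0.0
    return float((xc @ yc) / denom)


def _ordinal_patterns(x: np.ndarray, degree: int, lag: int) -> np.ndarray:
    """Ordinal pattern code per window, ties broken earlier-index-smaller.

    Works on the last axis of ``x``; output length is
    ``T - (degree - 1) * lag``.
    """
    x = np.asarray(x, float)
    span = (degree - 1) * lag + 1
    if x.shape[-1] < span:
        raise ValueError("series shorter than one pattern window")
    win = sliding_window_view(x, span, axis=-1)[..., ::lag]  # (..., T', degree)
    order = np.argsort(win, axis=-1, kind="stable")
    ranks = np.argsort(order, axis=-1, kind="stable")
    code = np.zeros(ranks.shape[:-1], dtype=np.int64)
    for k in range(degree):
        code = code * degree + ranks[..., k]
    return code


def fc_motifs(x: np.ndarray, y: np.ndarray, degree: int = 3,
              lag: int = 1) -> float:
    """Fraction of aligned positions with coinciding ordinal patterns."""
    px = _ordinal_patterns(x, degree, lag)
    py = _ordinal_patterns(y, degree, lag)
    return float(np.mean(px == py))


def fc_gaussian(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Gaussian-kernel similarity averaged over time samples."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = np.asarray(x, float) - np.asarray(y, float)
    return float(np.mean(np.exp(-(d**2) / (2.0 * sigma**2))))


def _welch_nperseg(n: int, fs: float) -> int:
    """Segment length: min(256, T/4), floored so band bins are resolvable."""
    return int(max(min(256, n // 4), min(64, n)))


def fc_coherence(x: np.ndarray, y: np.ndarray, fs: float,
                 band: Tuple[float, float] | None = None,
                 nperseg: int | None = None) -> float:
    """Welch coherence magnitude, averaged over in-band bins.

    ``|E[S_xy]| / sqrt(E[S_xx] E[S_yy])`` with the expectation over 50 %
    overlapping Hann segments; ``band=None`` averages all positive bins.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 64:
        raise ValueError("coherence needs >= 64 samples")
    if nperseg is None:
        nperseg = _welch_nperseg(x.size, fs)
    f, pxy = csd(x, y, fs=fs, window="hann", nperseg=nperseg,
                 noverlap=nperseg // 2)
    _, pxx = welch(x, fs=fs, window="hann", nperseg=nperseg,
                   noverlap=nperseg // 2)
    _, pyy = welch(y, fs=fs, window="hann", nperseg=nperseg,
                   noverlap=nperseg // 2)
    if band is not None:
        sel = (f >= band[0]) & (f <= band[1])
        if not sel.any():
            sel = slice(None)
    else:
        sel = slice(None)
    denom = np.sqrt(pxx[sel] * pyy[sel])
    num = np.abs(pxy[sel])
    if np.all(denom == 0):
        warnings.warn("zero in-band power; coherence set to 0", RuntimeWarning)
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, num / denom, 0.0)
    return float(np.mean(coh))


def fc_plv(x: np.ndarray, y: np.ndarray) -> float:
    """Phase-locking value of the analytic-signal phase difference."""
    ax = hilbert(np.asarray(x, float))
    ay = hilbert(np.asarray(y, float))
    amp = np.abs(ax) * np.abs(ay)
    valid = amp > 0
    if not valid.all():
        warnings.warn("zero-amplitude samples skipped in PLV", RuntimeWarning)
    if not valid.any():
        return 0.0
    phasor = (ax[valid] / np.abs(ax[valid])) * np.conj(ay[valid] / np.abs(ay[valid]))
    return float(np.abs(phasor.mean()))


# ---------------------------------------------------------------------------
# matrix forms used by the feature builder

def _pearson_matrix(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=-1, keepdims=True)
    sd = Xc.std(axis=-1)
    cov = (Xc @ Xc.T) / X.shape[-1]
    denom = np.outer(sd, sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


def _motif_matrix(X: np.ndarray, degree: int = 3, lag: int = 1) -> np.ndarray:
    codes = _ordinal_patterns(X, degree, lag)        # (C, T')
    return (codes[:, None, :] == codes[None, :, :]).mean(axis=-1)


def _pooled_sigma(X: np.ndarray) -> float:
    """Median |x_i(t) - x_j(t)| over all i<j pairs and samples."""
    iu, ju = np.triu_indices(X.shape[0], 1)
    d = np.abs(X[iu] - X[ju])
    sigma = float(np.median(d))
    if sigma == 0:
        sigma = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
    return sigma


def _gaussian_matrix(X: np.ndarray, sigma: float | None = None,
                     per_pair: bool = False) -> np.ndarray:
    D = X[:, None, :] - X[None, :, :]
    if per_pair:
        med = np.median(np.abs(D), axis=-1)
        med[med == 0] = np.median(np.abs(D)) or 1.0
        sig2 = med[..., None] ** 2
    else:
        if sigma is None:
            sigma = _pooled_sigma(X)
        sig2 = sigma**2
    return np.exp(-(D**2) / (2.0 * sig2)).mean(axis=-1)


def _coherence_matrix(X: np.ndarray, fs: float,
                      band: Tuple[float, float]) -> np.ndarray:
    nperseg = _welch_nperseg(X.shape[-1], fs)
    f, pxy = csd(X[:, None, :], X[None, :, :], fs=fs, window="hann",
                 nperseg=nperseg, noverlap=nperseg // 2, axis=-1)
    sel = (f >= band[0]) & (f <= band[1])
    if not sel.any():
        sel = np.ones_like(f, bool)
    pxy = pxy[..., sel]
    auto = np.real(np.einsum("iif->if", pxy))        # (C, F)
    denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, np.abs(pxy) / denom, 0.0)
    return np.clip(coh.mean(axis=-1), 0.0, 1.0)


def _plv_matrix(X: np.ndarray) -> np.ndarray:
    analytic = hilbert(X, axis=-1)
    amp = np.abs(analytic)
    safe = np.where(amp > 0, amp, 1.0)
    ph = analytic / safe
    plv = np.abs(ph @ np.conj(ph.T)) / X.shape[-1]
    return np.clip(plv, 0.0, 1.0)


def _fc_matrix(X: np.ndarray, measure: str, fs: float,
               band: Tuple[float, float], gfc_per_pair: bool) -> np.ndarray:
    if measure == "pearson":
        return _pearson_matrix(X)
    if measure == "motifs":
        return _motif_matrix(X)
    if measure == "gfc":
        return _gaussian_matrix(X, per_pair=gfc_per_pair)
    if measure == "coherence":
        return _coherence_matrix(X, fs, band)
    if measure == "plv":
        return _plv_matrix(X)
    raise ValueError(f"unknown FC measure {measure!r}; "
                     f"choose one of {MEASURES}")


# ---------------------------------------------------------------------------
# feature assembly

def build_features(
    trials: TrialSet,
    measure: str = "gfc",
    window: Tuple[float, float] | None = None,
    bands: Sequence[Tuple[str, float, float]] = RHYTHM_BANDS,
    gfc_per_pair: bool = False,
) -> Tuple[np.ndarray, List[Tuple[str, int, int]]]:
    """Per-trial FC feature vectors across the four rhythms.

    Returns ``(features, pair_index)`` where ``features`` is
    ``(n_trials, len(bands) * C * (C - 1) / 2)`` and ``pair_index`` lists
    ``(band_name, i, j)`` with ``i < j`` in row-major upper-triangular
    order, concatenated band by band.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown FC measure {measure!r}; "
                         f"choose one of {MEASURES}")
    cropped = trials if window is None else crop_window(trials, *window)
    C = cropped.n_channels
    iu, ju = np.triu_indices(C, 1)
    n_pairs = len(iu)
    features = np.empty((cropped.n_trials, len(bands) * n_pairs))
    pair_index: List[Tuple[str, int, int]] = []
    for b, (name, low, high) in enumerate(bands):
        bp = bandpass(cropped, (low, high))
        for t in range(bp.n_trials):
            M = _fc_matrix(bp.data[t], measure, bp.fs, (low, high),
                           gfc_per_pair)
            features[t, b * n_pairs:(b + 1) * n_pairs] = M[iu, ju]
        pair_index.extend((name, int(i), int(j)) for i, j in zip(iu, ju))
    return features, pair_index
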