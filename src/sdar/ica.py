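"""FastICA decomposition and correlation-thresholded ocular artifact removal.

Scalp EEG is modeled as a linear mixture ``X = W S`` of statistically
independent, non-Gaussian sources.  FastICA with the Gaussian contrast
``exp(-u^2/2)`` is fitted on whitened, trial-concatenated data (as many
components as channels).  Each recovered source is scored by its Pearson
correlation with the available artifact references — explicit EOG
channels when recorded, otherwise the three most anterior electrodes —
per trial, aggregated as the mean absolute correlation.  Components
whose score exceeds the 3-sigma level of the z-scored score distribution
are zeroed before reconstruction.  The full fit / score / threshold /
reconstruct cycle is run twice by default: the second pass catches
residual ocular activity that the first unmixing split across
components.

Data are 1 Hz high-passed (zero-phase 5th-order Butterworth) before any
decomposition; since the lowest analysis rhythm starts at 8 Hz, the
drift removal cannot affect downstream features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import butter, sosfiltfilt
from sklearn.decomposition import FastICA

from .dataset import TrialSet
from .synthetic import frontal_indices

__all__ = [
    "ICADecomposition", "RejectionMask",
    "highpass_for_ica", "fit_fastica", "score_components",
    "threshold_3sigma", "build_rejection_mask", "remove_and_reconstruct",
    "clean_eog",
]


@dataclass
class ICADecomposition:
    """Fitted FastICA model on trial-concatenated data.

    ``sources_S`` is ``(Q, n_trials * n_samples)`` with unit-variance
    rows; ``mixing_W`` is ``(C, Q)``.  ``X_hp = mixing_W @ sources_S +
    mean`` reconstructs the high-passed input exactly when Q = C.
    """

    mixing_W: np.ndarray
    unmixing: np.ndarray
    sources_S: np.ndarray
    whitening: np.ndarray
    mean: np.ndarray
    n_components_Q: int
    n_trials: int
    n_samples: int

    def sources_by_trial(self) -> np.ndarray:
        """Sources reshaped to ``(Q, n_trials, n_samples)``."""
        return self.sources_S.reshape(self.n_components_Q, self.n_trials,
                                      self.n_samples)


@dataclass
class RejectionMask:
    """Per-component keep/reject decision with its evidence."""

    keep: np.ndarray                 # (Q,) bool
    corr_scores: np.ndarray          # (Q, n_refs) mean |r| per reference
    gamma: float                     # threshold on the correlation scale
    pass_index: int = 1

    @property
    def n_rejected(self) -> int:
        return int(np.sum(~self.keep))


def highpass_for_ica(trials: TrialSet, cutoff_hz: float = 1.0,
                     order: int = 5) -> TrialSet:
    """Zero-phase Butterworth high-pass to strip slow drifts."""
    if trials.fs <= 2.0:
        raise ValueError("sampling rate too low for the 1 Hz high-pass")
    sos = butter(order, cutoff_hz, btype="highpass", fs=trials.fs, output="sos")
    pad = 3 * (2 * order + 1)
    if trials.n_samples <= pad:
        raise ValueError(
            f"trials of {trials.n_samples} samples are shorter than the "
            f"filter warm-up ({pad} samples)")
    filtered = sosfiltfilt(sos, trials.data, axis=-1)
    return trials.with_data(filtered)


def fit_fastica(trials: TrialSet, seed: int = 0,
                max_iter: int = 500, tol: float = 1e-4) -> ICADecomposition:
    """Fit FastICA with the Gaussian contrast on concatenated trials.

    The number of components equals the number of channels, capped at
    the numerical rank of the data: fitting full-rank ICA on
    rank-deficient input (e.g. after a previous rejection pass) would
    blow up the whitening and wreck the reconstruction.  Data are
    whitened so the unmixing rows are orthonormal in whitened space.
    Convergence failures emit a warning and return the best iterate.
    """
    n_trials, n_channels, n_samples = trials.data.shape
    total = n_trials * n_samples
    if total < 10 * n_channels**2:
        raise ValueError(
            f"need >= {10 * n_channels**2} concatenated samples to fit "
            f"{n_channels} components, got {total}")
    X = trials.data.transpose(1, 0, 2).reshape(n_channels, total).T  # (N, C)
    sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    rank = int(np.sum(sv > sv[0] * 1e-8))
    n_comp = min(n_channels, max(rank, 1))
    ica = FastICA(n_components=n_comp, algorithm="parallel", fun="exp",
                  whiten="unit-variance", random_state=int(seed),
                  max_iter=max_iter, tol=tol)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        S = ica.fit_transform(X)                                     # (N, Q)
    unmixing = ica.components_                                       # (Q, C)
    return ICADecomposition(
        mixing_W=ica.mixing_.copy(),
        unmixing=unmixing.copy(),
        sources_S=np.ascontiguousarray(S.T),
        whitening=ica.whitening_.copy(),
        mean=ica.mean_.copy(),
        n_components_Q=n_comp,
        n_trials=n_trials,
        n_samples=n_samples,
    )


def _per_trial_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|Pearson r| per trial between two (n_trials, T) arrays, mean over trials.

    Zero-variance trials contribute a correlation of 0.
    """
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    sa = a.std(axis=-1)
    sb = b.std(axis=-1)
    num = np.abs((a * b).mean(axis=-1))
    denom = sa * sb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, 0.0)
    return float(r.mean())


def score_components(ica: ICADecomposition,
                     references: np.ndarray) -> np.ndarray:
    """Mean absolute per-trial Pearson correlation, component x reference.

    ``references`` has shape ``(n_refs, n_trials, n_samples)`` aligned
    with the decomposition's trial structure.  A reference or component
    with zero variance in a trial scores 0 for that trial (with a
    warning if it is globally silent).
    """
    refs = np.asarray(references, dtype=np.float64)
    if refs.ndim == 2:  # single reference trace (n_trials, T)
        refs = refs[None, :, :]
    if refs.shape[1:] != (ica.n_trials, ica.n_samples):
        raise ValueError("references are not sample-aligned with the sources")
    S = ica.sources_by_trial()
    n_refs = refs.shape[0]
    scores = np.zeros((ica.n_components_Q, n_refs))
    for r in range(n_refs):
        if refs[r].std() == 0:
            warnings.warn(f"reference {r} has zero variance; scores set to 0",
                          RuntimeWarning)
            continue
        for q in range(ica.n_components_Q):
            scores[q, r] = _per_trial_corr(S[q], refs[r])
    return scores


def threshold_3sigma(scores: np.ndarray) -> float:
    """Rejection threshold at z = 3 of the pooled score distribution.

    Scores are pooled across components and references, z-scored, and
    the z = 3 level is mapped back to the correlation scale
    (``mean + 3 * std``).  Degenerate (zero-variance) score sets reject
    nothing: gamma = +inf.
    """
    vals = np.asarray(scores, dtype=np.float64).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 finite scores")
    sd = vals.std()
    if sd <= 1e-12 * max(1.0, abs(vals.mean())):
        warnings.warn("score distribution has zero variance; "
                      "no component rejected", RuntimeWarning)
        return np.inf
    return float(vals.mean() + 3.0 * sd)


def build_rejection_mask(scores: np.ndarray, gamma: Optional[float] = None,
                         pass_index: int = 1) -> RejectionMask:
    """Combine scores and the 3-sigma threshold into a keep mask."""
    scores = np.asarray(scores, dtype=np.float64)
    if gamma is None:
        gamma = threshold_3sigma(scores)
    keep = scores.max(axis=1) <= gamma
    return RejectionMask(keep=keep, corr_scores=scores, gamma=float(gamma),
                         pass_index=pass_index)


def remove_and_reconstruct(trials: TrialSet, ica: ICADecomposition,
                           mask: RejectionMask) -> TrialSet:
    """Zero the rejected sources and back-project to channel space.

    The operation is a linear projection: applying it twice with the
    same mask equals applying it once.
    """
    if mask.keep.shape[0] != ica.n_components_Q:
        raise ValueError("mask dimension does not match the decomposition")
    if not mask.keep.any():
        raise ValueError("all components rejected; refusing to return "
                         "all-zero data")
    n_trials, n_channels, n_samples = trials.data.shape
    X = trials.data.transpose(1, 0, 2).reshape(n_channels, -1)
    S = ica.unmixing @ (X - ica.mean[:, None])
    S[~mask.keep] = 0.0
    Xc = ica.mixing_W @ S + ica.mean[:, None]
    out = Xc.reshape(n_channels, n_trials, n_samples).transpose(1, 0, 2)
    return trials.with_data(out)


def _frontal_references(trials: TrialSet, k: int = 3) -> np.ndarray:
    idx = frontal_indices(trials.positions, k)
    return trials.data[:, idx, :].transpose(1, 0, 2)  # (k, n_trials, T)


def clean_eog(
    trials: TrialSet,
    references: Optional[np.ndarray] = None,
    ref_mode: str = "auto",
    seed: int = 0,
    passes: int = 2,
    highpass: bool = True,
    fit_index: Optional[np.ndarray] = None,
) -> Tuple[TrialSet, List[RejectionMask], List[ICADecomposition]]:
    """Full ocular cleanup: high-pass, then ``passes`` ICA reject cycles.

    Parameters
    ----------
    references
        Optional explicit EOG traces, ``(n_refs, n_trials, n_samples)``
        or ``(n_trials, n_samples)``; they are high-passed with the same
        filter as the data so correlations are computed on matching
        content.  References are used only for scoring — they are never
        mixed into the output.
    ref_mode
        ``"eog"`` requires explicit references, ``"frontal"`` uses the
        three most anterior electrodes of the current data, ``"auto"``
        picks ``"eog"`` when references are given.
    fit_index
        Optional trial indices to fit/score on; the cleanup is still
        applied to every trial.  Used to keep held-out test trials out
        of the unmixing estimation in leakage-controlled evaluation.

    Returns the cleaned trials plus the per-pass rejection masks and
    decompositions.
    """
    if ref_mode == "auto":
        ref_mode = "eog" if references is not None else "frontal"
    if ref_mode == "eog" and references is None:
        raise ValueError("ref_mode='eog' requires explicit references")

    out = highpass_for_ica(trials) if highpass else trials.copy()
    if references is not None:
        refs_arr = np.asarray(references, dtype=np.float64)
        if refs_arr.ndim == 2:
            refs_arr = refs_arr[None]
        sos = butter(5, 1.0, btype="highpass", fs=trials.fs, output="sos")
        refs_arr = sosfiltfilt(sos, refs_arr, axis=-1)
        if fit_index is not None:
            refs_arr = refs_arr[:, fit_index, :]
    masks: List[RejectionMask] = []
    icas: List[ICADecomposition] = []
    for p in range(1, passes + 1):
        fit_set = out if fit_index is None else out.select_trials(fit_index)
        ica = fit_fastica(fit_set, seed=seed + (p - 1))
        refs = refs_arr if ref_mode == "eog" else _frontal_references(fit_set)
        scores = score_components(ica, refs)
        mask = build_rejection_mask(scores, pass_index=p)
        out = remove_and_reconstruct(out, ica, mask)
        masks.append(mask)
        icas.append(ica)
    return out, masks, icas
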