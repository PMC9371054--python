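"""Readers and writers.

The package's interchange format is a single HDF5 file per subject
holding the epoched data tensor, labels, sampling rate, channel names
and unit-sphere electrode positions; round-trips are lossless.  Readers
for the two common acquisition layouts are provided: GDF continuous
recordings with cue events (epoched through MNE) and MATLAB containers
in the GigaDB motor-imagery layout (per-class imagery blocks at 512 Hz).
"""

from __future__ import annotations

import os
from typing import Optional, Sequence, Tuple

import h5py
import numpy as np

from .dataset import TrialSet
from .synthetic import frontal_indices

__all__ = ["save_trialset", "load_trialset", "read_gdf_like",
           "read_mat_like", "save_features"]


def save_trialset(path: str, trials: TrialSet,
                  references: Optional[np.ndarray] = None) -> None:
    """Write a TrialSet (and optional EOG references) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=trials.data)
        f.create_dataset("labels", data=np.asarray(trials.labels, np.int64))
        f.create_dataset("positions", data=trials.positions)
        f.create_dataset("channel_names",
                         data=np.array(trials.channel_names, dtype="S32"))
        f.attrs["fs"] = float(trials.fs)
        f.attrs["window"] = list(trials.window)
        if references is not None:
            f.create_dataset("references", data=np.asarray(references))


def load_trialset(path: str) -> Tuple[TrialSet, Optional[np.ndarray]]:
    """Read the interchange format back; inverse of :func:`save_trialset`."""
    with h5py.File(path, "r") as f:
        names = [n.decode() for n in f["channel_names"][()]]
        trials = TrialSet(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            channel_names=names,
            positions=f["positions"][()],
            labels=f["labels"][()],
            window=tuple(f.attrs["window"]),
        )
        refs = f["references"][()] if "references" in f else None
    return trials, refs


def read_gdf_like(
    path: str,
    window: Tuple[float, float] = (0.0, 4.0),
    eog_prefix: str = "EOG",
) -> Tuple[TrialSet, Optional[np.ndarray]]:
    """Epoch a GDF recording around its cue events.

    EEG channels keep their montage positions (looked up by name from
    the standard 10-05 layout and renormalized to the unit sphere); EOG
    channels are split off and returned as reference traces, excluded
    from the data block.  Channels whose position cannot be resolved
    raise an error naming them.
    """
    import mne

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    eog_names = [ch for ch in raw.ch_names if ch.upper().startswith(eog_prefix)]
    eeg_names = [ch for ch in raw.ch_names if ch not in eog_names]

    montage = mne.channels.make_standard_montage("standard_1005")
    pos_map = montage.get_positions()["ch_pos"]
    positions = []
    unknown = []
    for ch in eeg_names:
        key = ch.replace("EEG-", "").strip()
        if key in pos_map and np.isfinite(pos_map[key]).all():
            v = np.asarray(pos_map[key], float)
            positions.append(v / np.linalg.norm(v))
        else:
            unknown.append(ch)
    if unknown:
        raise ValueError("no montage position for channels: "
                         + ", ".join(unknown))
    positions = np.asarray(positions)

    events, event_id = mne.events_from_annotations(raw, verbose="error")
    cue_ids = {k: v for k, v in event_id.items() if k in
               {"769", "770", "771", "772"}} or event_id
    epochs = mne.Epochs(raw, events, event_id=cue_ids, tmin=window[0],
                        tmax=window[1], baseline=None, preload=True,
                        verbose="error")
    data_all = epochs.get_data(copy=True) * 1e6  # volts -> microvolts
    ch_index = {ch: i for i, ch in enumerate(epochs.ch_names)}
    eeg_idx = [ch_index[ch] for ch in eeg_names]
    data = data_all[:, eeg_idx, :]
    refs = (data_all[:, [ch_index[ch] for ch in eog_names], :]
            .transpose(1, 0, 2) if eog_names else None)
    label_of = {v: i for i, v in enumerate(sorted(cue_ids.values()))}
    labels = np.array([label_of[e] for e in epochs.events[:, 2]])
    trials = TrialSet(data=data, fs=float(raw.info["sfreq"]),
                      channel_names=eeg_names, positions=positions,
                      labels=labels, window=(window[0], window[1]))
    return trials, refs


def read_mat_like(
    path: str,
    window: Tuple[float, float] = (0.0, 3.0),
) -> Tuple[TrialSet, Optional[np.ndarray]]:
    """Read a GigaDB-layout MATLAB container (two-class MI, 64 channels).

    Expects an ``eeg`` struct with ``imagery_left`` / ``imagery_right``
    blocks (channels x samples), ``srate``, ``imagery_event`` (cue
    sample markers) and optionally ``psenloc`` electrode coordinates.
    Missing variables raise an error naming them.  Labels are 0 (left)
    and 1 (right); frontal electrodes serve as artifact references
    downstream.
    """
    from scipy.io import loadmat

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    mat = loadmat(path, squeeze_me=True, struct_as_record=False)
    if "eeg" not in mat:
        raise ValueError("missing expected variable 'eeg' in MAT file")
    eeg = mat["eeg"]
    missing = [k for k in ("imagery_left", "imagery_right", "srate",
                           "imagery_event") if not hasattr(eeg, k)]
    if missing:
        raise ValueError("MAT file lacks expected fields: "
                         + ", ".join(missing))
    fs = float(eeg.srate)
    onsets = np.flatnonzero(np.asarray(eeg.imagery_event).ravel() == 1)
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))

    def _epoch(cont: np.ndarray) -> np.ndarray:
        cont = np.asarray(cont, float)
        segs = []
        for on in onsets:
            if on + i1 <= cont.shape[1]:
                segs.append(cont[:, on + i0:on + i1])
        if not segs:
            raise ValueError("no complete epochs within the recording")
        return np.stack(segs)

    left = _epoch(eeg.imagery_left)
    right = _epoch(eeg.imagery_right)
    data = np.concatenate([left, right])
    labels = np.concatenate([np.zeros(len(left), int), np.ones(len(right), int)])
    n_channels = data.shape[1]
    if hasattr(eeg, "psenloc"):
        pos = np.asarray(eeg.psenloc, float)
        pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    else:
        from .synthetic import synthetic_montage
        pos = synthetic_montage(n_channels)
    names = [f"E{i+1:02d}" for i in range(n_channels)]
    trials = TrialSet(data=data, fs=fs, channel_names=names, positions=pos,
                      labels=labels, window=(window[0], window[1]))
    refs = trials.data[:, frontal_indices(pos), :].transpose(1, 0, 2)
    return trials, refs


def save_features(path: str, features: np.ndarray,
                  pair_index: Sequence[Tuple[str, int, int]],
                  labels: Optional[np.ndarray] = None) -> None:
    """Write a trials x features matrix as delimited text.

    The header records the (band, channel_i, channel_j) identity of each
    column; an optional final column carries the trial labels.
    """
    header_cols = [f"{b}:{i}-{j}" for b, i, j in pair_index]
    mat = np.asarray(features, float)
    if labels is not None:
        mat = np.column_stack([mat, np.asarray(labels, float)])
        header_cols.append("label")
    np.savetxt(path, mat, delimiter="\t", header="\t".join(header_cols))
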