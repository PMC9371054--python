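"""Epoched EEG container shared by every pipeline stage.

A :class:`TrialSet` holds a ``trials x channels x samples`` tensor of scalp
potentials (microvolts) together with the montage geometry and the class
labels of a motor-imagery session.  Every preprocessing stage (surface
Laplacian, ICA cleanup, band filtering, cropping) maps a ``TrialSet`` to a
new ``TrialSet`` with the same metadata conventions, so stages compose
freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, Tuple

import numpy as np

__all__ = ["TrialSet"]


@dataclass
class TrialSet:
    """Epoched multichannel EEG.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        One name per channel.
    positions
        ``(n_channels, 3)`` electrode coordinates on the unit sphere
        (+y anterior, +x right, +z superior).
    labels
        Integer class label per trial.
    window
        ``(start_s, end_s)`` of the epoch relative to cue onset; half-open
        ``[start, end)`` convention.
    """

    data: np.ndarray
    fs: float
    channel_names: Sequence[str]
    positions: np.ndarray
    labels: np.ndarray
    window: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.channel_names = list(self.channel_names)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples), got "
                             f"ndim={self.data.ndim}")
        n_trials, n_channels, _ = self.data.shape
        if len(self.channel_names) != n_channels:
            raise ValueError("channel_names length does not match data")
        if self.positions.shape != (n_channels, 3):
            raise ValueError("positions must be (n_channels, 3)")
        if self.labels.shape != (n_trials,):
            raise ValueError("labels length must equal number of trials")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        norms = np.linalg.norm(self.positions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("electrode positions must lie on the unit sphere")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    # -- convenience -----------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to cue onset."""
        start = self.window[0]
        return start + np.arange(self.n_samples) / self.fs

    def copy(self) -> "TrialSet":
        return replace(
            self,
            data=self.data.copy(),
            positions=self.positions.copy(),
            labels=self.labels.copy(),
            channel_names=list(self.channel_names),
        )

    def with_data(self, data: np.ndarray, window: Tuple[float, float] | None = None) -> "TrialSet":
        """Return a new TrialSet sharing this one's metadata.

        ``window`` may be overridden when the sample axis was cropped.
        """
        return replace(
            self,
            data=np.asarray(data, dtype=np.float64),
            window=self.window if window is None else tuple(window),
        )

    def select_trials(self, index: np.ndarray) -> "TrialSet":
        return replace(self, data=self.data[index], labels=self.labels[index])
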