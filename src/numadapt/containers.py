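"""In-memory containers for epoched EEG and averaged ERPs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class EpochSet:
    """Epoched EEG for one participant and condition.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_channels, n_times)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    time_ms : ndarray, shape (n_times,)
        Time axis in ms relative to stimulus onset; strictly increasing,
        uniform at 1000/fs.
    channel_names : tuple of str
    channel_positions : ndarray, shape (n_channels, 3) or None
        Unit-sphere electrode coordinates.
    condition : str
    participant : str or int
    """

    data: np.ndarray
    fs: float
    time_ms: np.ndarray
    channel_names: tuple
    channel_positions: np.ndarray | None = None
    condition: str = ""
    participant: str | int = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if self.data.shape[2] != self.time_ms.size:
            raise ValueError("time axis does not match time_ms")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        dt = np.diff(self.time_ms)
        if self.time_ms.size > 1 and not np.allclose(dt, 1000.0 / self.fs, atol=1e-6):
            raise ValueError("time axis must be uniform at 1/fs")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy_with(self, **kw) -> "EpochSet":
        return replace(self, **kw)

    def average(self) -> "ErpWaveform":
        """Trial-average ERP."""
        return ErpWaveform(
            data=self.data.mean(axis=0),
            fs=self.fs,
            time_ms=self.time_ms,
            channel_names=self.channel_names,
            n_trials=self.n_trials,
            condition=self.condition,
            participant=self.participant,
        )


@dataclass
class ErpWaveform:
    """Trial-averaged ERP (channels x time, microvolts)."""

    data: np.ndarray
    fs: float
    time_ms: np.ndarray
    channel_names: tuple
    n_trials: int = 1
    condition: str = ""
    participant: str | int = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.data.shape != (len(self.channel_names), self.time_ms.size):
            raise ValueError("data must be channels x time")
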