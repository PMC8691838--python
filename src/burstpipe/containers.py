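"""In-memory containers for continuous LFP and derived arrays."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Columns required in the per-channel metadata table.
CHANNEL_COLUMNS = ["name", "site", "hemisphere", "contact"]


@dataclass
class LfpRecording:
    """Continuous multi-channel LFP.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in volts or arbitrary units.
    fs : float
        Sampling rate in Hz.
    channels : pandas.DataFrame
        One row per channel with columns ``name``, ``site`` (e.g. ``STN``,
        ``THAL_VENTRAL``, ``THAL_DORSAL``, ``SMC``), ``hemisphere`` and
        ``contact`` (contact index on the lead/strip, or the pair label for
        bipolar channels).
    artifact_mask : ndarray of bool, shape (n_samples,)
        True where a sample belongs to a rejected 1-s artifact segment.
    """

    data: np.ndarray
    fs: float
    channels: pd.DataFrame
    artifact_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel table length != number of data rows")
        for col in CHANNEL_COLUMNS:
            if col not in self.channels.columns:
                raise ValueError(f"channel table missing column {col!r}")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.data.shape[1], dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != (self.data.shape[1],):
            raise ValueError("artifact_mask length != number of samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "LfpRecording":
        out = replace(self, **kwargs)
        return out

    def pick(self, rows) -> "LfpRecording":
        """Sub-recording with the given channel rows (boolean or index array)."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return LfpRecording(
            data=self.data[rows],
            fs=self.fs,
            channels=self.channels.iloc[rows].reset_index(drop=True),
            artifact_mask=self.artifact_mask.copy(),
        )
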