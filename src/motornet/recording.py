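"""Containers and CSV I/O for multichannel hemodynamic recordings.

A recording holds one subject's optical-topography time series: concentration
changes of oxygenated (or deoxygenated) hemoglobin, in mM·mm, for a fixed
channel montage sampled at a constant rate.  The on-disk dialect is a plain
CSV with one header row of channel labels (``Ch1`` … ``ChN``) and one row per
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["HemodynamicRecording", "read_recording_csv", "write_recording_csv"]


@dataclass
class HemodynamicRecording:
    """One subject's channels × samples hemodynamic matrix.

    Parameters
    ----------
    subject_id : str
        Identifier used to join against the cohort metadata table.
    data : ndarray, shape (n_channels, n_samples)
        Concentration-change time series in mM·mm.
    fs : float
        Sampling rate in Hz.
    chromophore : str
        ``"HbO2"`` (default) or ``"Hb"``.
    channel_labels : list of str, optional
        Defaults to ``Ch1`` … ``ChN``.
    """

    subject_id: str
    data: np.ndarray
    fs: float
    chromophore: str = "HbO2"
    channel_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels × samples array")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_labels is None:
            self.channel_labels = [f"Ch{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length does not match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "HemodynamicRecording":
        """Copy of this recording with ``data`` replaced (labels/rate kept)."""
        return replace(self, data=np.asarray(data, dtype=float))

    def copy(self) -> "HemodynamicRecording":
        return replace(self, data=self.data.copy())


def write_recording_csv(recording: HemodynamicRecording, path: str | Path) -> Path:
    """Write a recording as a samples × channels CSV with channel-label header."""
    path = Path(path)
    frame = pd.DataFrame(recording.data.T, columns=recording.channel_labels)
    frame.to_csv(path, index=False, float_format="%.6g")
    return path


def read_recording_csv(
    path: str | Path,
    fs: float,
    subject_id: str | None = None,
    chromophore: str = "HbO2",
) -> HemodynamicRecording:
    """Load a recording from the CSV dialect written by :func:`write_recording_csv`.

    The sampling rate is not stored in the file and must be supplied.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.isna().any().any():
        raise ValueError(f"{path}: missing values in signal file")
    return HemodynamicRecording(
        subject_id=subject_id if subject_id is not None else path.stem,
        data=frame.to_numpy().T,
        fs=fs,
        chromophore=chromophore,
        channel_labels=list(frame.columns),
    )
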