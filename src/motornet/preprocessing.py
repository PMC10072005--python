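"""Resting-state hemodynamic preprocessing.

Four stages, applied in this order by :func:`preprocess`:

1. motion-artifact detection (moving-window excursion against a robust,
   median-absolute-deviation-based SD) and correction by smoothing-spline
   subtraction with level re-matching (MARA-style);
2. zero-phase second-order Butterworth band-pass, 0.01–0.1 Hz, isolating the
   slow spontaneous oscillations carrying resting-state connectivity;
3. common average reference (CAR) spatial filtering to suppress the shared
   superficial (scalp) component;
4. trimming of the first and last 5 s to drop filter edge effects.

If too large a fraction of the corrected signal still looks artifactual, the
pipeline falls back to the cleanest contiguous 180-s window rather than
analysing a corrupted full record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.signal
from scipy.interpolate import make_smoothing_spline

from .recording import HemodynamicRecording

__all__ = [
    "ArtifactMask",
    "PreprocessParams",
    "detect_artifacts",
    "correct_artifacts_spline",
    "bandpass",
    "common_average_reference",
    "trim_edges",
    "preprocess",
]


@dataclass
class ArtifactMask:
    """Boolean per-sample artifact mask plus its run-length segment list."""

    mask: np.ndarray  # (n_channels, n_samples) bool
    segments: list[tuple[int, int, int]]  # (channel, start, end) half-open

    @property
    def flagged_fraction(self) -> float:
        return float(self.mask.mean())

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        n_ch, n_s = self.mask.shape
        for ch, start, end in self.segments:
            if not (0 <= ch < n_ch and 0 <= start < end <= n_s):
                raise ValueError(f"segment ({ch}, {start}, {end}) out of bounds")


def _segments_from_mask(mask_row: np.ndarray) -> list[tuple[int, int]]:
    padded = np.diff(np.concatenate(([0], mask_row.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def detect_artifacts(
    recording: HemodynamicRecording, window: float = 1.0, k: float = 6.0
) -> ArtifactMask:
    """Flag samples whose moving-window excursion exceeds ``k`` robust SDs.

    The excursion is max − min inside a sliding window of ``window`` seconds;
    the scale is the MAD-based robust SD per channel, so the spikes being
    hunted do not inflate their own detection threshold.  Flags are dilated
    by half a window on each side.  A zero-variance channel yields no flags.
    """
    fs = recording.fs
    w = int(round(window * fs))
    if w < 2:
        raise ValueError("window must cover at least 2 samples")
    if w > recording.n_samples:
        raise ValueError("window longer than recording")
    data = recording.data
    excursion = scipy.ndimage.maximum_filter1d(
        data, size=w, axis=1, mode="nearest"
    ) - scipy.ndimage.minimum_filter1d(data, size=w, axis=1, mode="nearest")
    mad = np.median(np.abs(data - np.median(data, axis=1, keepdims=True)), axis=1)
    robust_sd = 1.4826 * mad
    mask = np.zeros_like(data, dtype=bool)
    ok = robust_sd > 0
    mask[ok] = excursion[ok] > k * robust_sd[ok, None]
    half = w // 2
    if half:
        mask = scipy.ndimage.binary_dilation(
            mask, structure=np.ones((1, 2 * half + 1), dtype=bool)
        )
    segments = [
        (ch, s, e)
        for ch in range(recording.n_channels)
        for s, e in _segments_from_mask(mask[ch])
    ]
    return ArtifactMask(mask=mask, segments=segments)


def _anchor(data_row: np.ndarray, start: int, end: int, fs: float) -> tuple[float, float]:
    """Mean levels just before and just after a segment (≤1 s each side)."""
    w = max(int(round(fs)), 1)
    pre = data_row[max(start - w, 0) : start]
    post = data_row[end : end + w]
    if pre.size == 0 and post.size == 0:
        return float(data_row[start:end].mean()), float(data_row[start:end].mean())
    if pre.size == 0:
        return float(post.mean()), float(post.mean())
    if post.size == 0:
        return float(pre.mean()), float(pre.mean())
    return float(pre.mean()), float(post.mean())


def correct_artifacts_spline(
    recording: HemodynamicRecording,
    mask: ArtifactMask,
    spline_degree: int = 3,
    lam: float | None = None,
) -> HemodynamicRecording:
    """Replace flagged segments by their smoothing-spline residual.

    Within each flagged segment a cubic smoothing spline is fitted and
    subtracted — the spline tracks the large, slow artifact excursion, the
    residual keeps the fast physiological detail — then the residual is
    re-seated on a linear baseline interpolating the clean levels on either
    side of the segment (movement-artifact-reduction-algorithm style).
    Samples outside flagged segments are untouched.  A segment spanning an
    entire channel is left unchanged with a warning.

    ``lam`` is the spline smoothing parameter (``None`` → generalized
    cross-validation); ``spline_degree`` must be 3 (cubic).
    """
    if spline_degree != 3:
        raise ValueError("only cubic smoothing splines are supported")
    if mask.mask.shape != recording.data.shape:
        raise ValueError("mask shape does not match recording")
    out = recording.copy()
    for ch, start, end in mask.segments:
        row = recording.data[ch]
        if end - start >= recording.n_samples:
            warnings.warn(
                f"channel {ch}: artifact segment spans entire channel; left unchanged"
            )
            continue
        seg = row[start:end]
        pre, post = _anchor(row, start, end, recording.fs)
        baseline = np.linspace(pre, post, seg.size)
        if seg.size < 5:
            out.data[ch, start:end] = baseline
            continue
        t = np.arange(seg.size, dtype=float)
        spline = make_smoothing_spline(t, seg, lam=lam)
        resid = seg - spline(t)
        out.data[ch, start:end] = resid - resid.mean() + baseline
    return out


def bandpass(
    recording: HemodynamicRecording,
    low: float = 0.01,
    high: float = 0.1,
    order: int = 2,
) -> HemodynamicRecording:
    """Zero-phase Butterworth band-pass applied per channel.

    ``order`` is the design order of the underlying filter; the
    forward-backward application doubles the effective order and cancels
    phase distortion (important when the downstream statistic is a
    zero-lag correlation).  Initial conditions follow Gustafsson's method,
    which minimizes the start/end transients that would otherwise dominate
    a record only a few filter time constants long (the low corner sits at
    0.01 Hz, a 100-s time constant).  Output length equals input length.
    """
    if not 0 < low < high < recording.fs / 2:
        raise ValueError(
            f"invalid band ({low}, {high}) for fs={recording.fs}"
        )
    b, a = scipy.signal.butter(order, [low, high], btype="bandpass", fs=recording.fs)
    # the channel mean is removed first: it lies outside the passband anyway,
    # and keeping it out of the filter avoids exciting the slow transient
    centered = recording.data - recording.data.mean(axis=1, keepdims=True)
    return recording.with_data(
        scipy.signal.filtfilt(b, a, centered, axis=1, method="gust")
    )


def common_average_reference(recording: HemodynamicRecording) -> HemodynamicRecording:
    """Subtract the cross-channel mean at every sample."""
    if recording.n_channels < 2:
        raise ValueError("common average reference undefined for a single channel")
    return recording.with_data(recording.data - recording.data.mean(axis=0, keepdims=True))


def trim_edges(
    recording: HemodynamicRecording, head: float = 5.0, tail: float = 5.0
) -> HemodynamicRecording:
    """Drop the first ``head`` and last ``tail`` seconds."""
    if head < 0 or tail < 0:
        raise ValueError("trim durations must be non-negative")
    n_head = int(round(head * recording.fs))
    n_tail = int(round(tail * recording.fs))
    if n_head + n_tail >= recording.n_samples:
        raise ValueError("trim exceeds recording length")
    stop = recording.n_samples - n_tail if n_tail else recording.n_samples
    return recording.with_data(recording.data[:, n_head:stop])


@dataclass
class PreprocessParams:
    """Tunable parameters of the preprocessing chain."""

    window: float = 1.0  # s, artifact-detection window
    k: float = 6.0  # robust-SD multiples
    spline_lam: float | None = None  # None → GCV
    low: float = 0.01  # Hz
    high: float = 0.1  # Hz
    order: int = 2
    head: float = 5.0  # s
    tail: float = 5.0  # s
    residual_limit: float = 0.05  # flagged fraction triggering the fallback
    fallback_duration: float = 180.0  # s


def _cleanest_window(mask: np.ndarray, n_win: int) -> int:
    """Start index of the length-``n_win`` window with fewest flagged samples."""
    per_sample = mask.sum(axis=0).astype(float)
    csum = np.concatenate(([0.0], np.cumsum(per_sample)))
    window_flags = csum[n_win:] - csum[:-n_win]
    return int(np.argmin(window_flags))


def preprocess(
    recording: HemodynamicRecording, params: PreprocessParams | None = None
) -> tuple[HemodynamicRecording, dict]:
    """Run the full chain: detect → correct → band-pass → CAR → trim.

    After the chain, artifact detection is re-run on the processed signal;
    if the flagged fraction exceeds ``params.residual_limit`` the cleanest
    contiguous ``params.fallback_duration`` window is kept instead of the
    full record.  Returns the processed recording and a log dict with the
    detected segments, residual fraction and fallback decision.
    """
    p = params if params is not None else PreprocessParams()
    mask = detect_artifacts(recording, window=p.window, k=p.k)
    corrected = correct_artifacts_spline(recording, mask, lam=p.spline_lam)
    filtered = bandpass(corrected, low=p.low, high=p.high, order=p.order)
    referenced = common_average_reference(filtered)
    trimmed = trim_edges(referenced, head=p.head, tail=p.tail)

    residual = detect_artifacts(trimmed, window=p.window, k=p.k)
    log = {
        "subject_id": recording.subject_id,
        "n_artifact_segments": len(mask.segments),
        "artifact_fraction": mask.flagged_fraction,
        "residual_fraction": residual.flagged_fraction,
        "fallback": False,
        "duration": trimmed.duration,
    }
    if residual.flagged_fraction > p.residual_limit:
        n_win = int(round(p.fallback_duration * trimmed.fs))
        if n_win < trimmed.n_samples:
            start = _cleanest_window(residual.mask, n_win)
            trimmed = trimmed.with_data(trimmed.data[:, start : start + n_win])
            log["fallback"] = True
            log["fallback_start_s"] = start / trimmed.fs
            log["duration"] = trimmed.duration
    return trimmed, log
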