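"""EEG preprocessing: band-pass filtering, task-edge trimming, artifact rejection.

The filter is a zero-phase 4th-order Butterworth applied forward–backward
(phase preservation matters for the connectivity stage).  Artifact handling is
a deliberately simple windowed amplitude-rejection stage: windows whose peak
absolute amplitude exceeds a multiple of the channel's *robust* standard
deviation (median absolute deviation × 1.4826, so spikes cannot inflate their
own threshold) are dropped.  This replaces subspace-reconstruction/ICA
chains, which target human artifact classes (muscle, eye movement, cardiac
field) that band-limited synthetic data does not contain.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from .recording import Recording


@dataclasses.dataclass
class RejectionMask:
    """Which time windows survived amplitude rejection."""

    kept_windows: list[tuple[float, float]]
    rejected_fraction: float

    def __post_init__(self) -> None:
        starts = [w[0] for w in self.kept_windows]
        if starts != sorted(starts):
            raise ValueError("kept windows must be ordered")
        for (_, e0), (s1, _) in zip(self.kept_windows, self.kept_windows[1:]):
            if s1 < e0:
                raise ValueError("kept windows must not overlap")
        if not 0.0 <= self.rejected_fraction <= 1.0:
            raise ValueError("rejected_fraction must lie in [0, 1]")


def bandpass(rec: Recording, low: float = 1.5, high: float = 60.0) -> Recording:
    """Zero-phase band-pass filter each channel; removes DC, preserves length."""
    if not 0 < low < high < rec.fs / 2:
        raise ValueError(
            f"cutoffs ({low}, {high}) Hz outside (0, Nyquist={rec.fs / 2}) or unordered"
        )
    sos = signal.butter(4, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    return rec.copy_with(signal.sosfiltfilt(sos, rec.data, axis=1))


def trim_edges(rec: Recording, trim_s: float = 30.0) -> Recording:
    """Drop the first and last ``trim_s`` seconds (movement-artifact guard).

    Annotations are shifted to the new time origin; those falling entirely
    outside the kept segment are dropped.
    """
    if trim_s < 0:
        raise ValueError("trim_s must be non-negative")
    if trim_s == 0:
        return rec.copy_with(rec.data.copy())
    n_trim = int(round(trim_s * rec.fs))
    if rec.n_samples <= 2 * n_trim:
        raise ValueError(
            f"recording of {rec.duration_s:.1f} s too short for {trim_s} s edge trimming"
        )
    kept_end_s = (rec.n_samples - n_trim) / rec.fs
    annotations = [
        (max(s - trim_s, 0.0), min(e - trim_s, kept_end_s - trim_s), tag)
        for s, e, tag in rec.annotations
        if e > trim_s and s < kept_end_s
    ]
    return rec.copy_with(rec.data[:, n_trim : rec.n_samples - n_trim], annotations)


def reject_artifacts(
    rec: Recording, z_amp: float = 10.0, win_s: float = 1.0
) -> tuple[Recording, RejectionMask]:
    """Drop windows whose peak amplitude exceeds ``z_amp`` robust SDs.

    The channel-wise robust SD is MAD × 1.4826 computed on the whole
    recording.  A window is rejected if *any* channel's peak absolute
    (median-centred) amplitude within it exceeds ``z_amp`` times that
    channel's robust SD.  Surviving windows are concatenated; a trailing
    partial window is kept and treated like a full one.
    """
    if win_s < 1.0 / rec.fs:
        raise ValueError("window shorter than one sample")
    n_win = int(round(win_s * rec.fs))
    med = np.median(rec.data, axis=1, keepdims=True)
    centred = rec.data - med
    robust_sd = 1.4826 * np.median(np.abs(centred), axis=1, keepdims=True)
    robust_sd = np.where(robust_sd == 0, np.inf, robust_sd)
    thresh = z_amp * robust_sd

    starts = range(0, rec.n_samples, n_win)
    kept_slices: list[tuple[int, int]] = []
    n_rejected = 0
    for s in starts:
        e = min(s + n_win, rec.n_samples)
        peak = np.abs(centred[:, s:e]).max(axis=1, keepdims=True)
        if np.any(peak > thresh):
            n_rejected += 1
        else:
            kept_slices.append((s, e))
    if not kept_slices:
        raise ValueError("all windows rejected")
    data = np.concatenate([rec.data[:, s:e] for s, e in kept_slices], axis=1)
    n_windows = n_rejected + len(kept_slices)
    mask = RejectionMask(
        kept_windows=[(s / rec.fs, e / rec.fs) for s, e in kept_slices],
        rejected_fraction=n_rejected / n_windows,
    )
    return rec.copy_with(data, annotations=[]), mask
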