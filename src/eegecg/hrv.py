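"""Lorenz (Poincaré) plot heart-rate-variability indices and change scores.

The Lorenz plot scatters each RR interval against the next.  Its spread
perpendicular to the identity line (SD1) captures beat-to-beat, vagally
mediated variability; the spread along the identity line (SD2) captures
slower variability.  From the paired points (RRIₙ, RRIₙ₊₁):

    SD1 = sd((RRIₙ₊₁ − RRIₙ) / √2)      SD2 = sd((RRIₙ₊₁ + RRIₙ) / √2)

with sample (n−1) standard deviations.  The transverse and longitudinal
extents are T = 4·SD1 and L = 4·SD2; the cardiac sympathetic index is
CSI = L/T = SD2/SD1 and the cardiac vagal index CVI = log10(L·T).  Normal
RR series have more slow than fast variability, so CSI > 1; sympathetic
activation raises it, vagal activation raises CVI.  The log10 base (rather
than the natural log) is the convention under which typical CVI values fall
near 4–5 for resting adults; it is switchable via ``log_base``.

Within-task change scores subtract the first task minute's value from the
last minute's.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as _signal

from .recording import Recording, RRISeries


@dataclasses.dataclass
class LorenzIndices:
    """Poincaré-cloud geometry summary.

    ``defined`` is False when either spread is zero (degenerate geometry).
    CVI is then NaN; CSI is NaN only when SD1 (the denominator spread) is
    zero — an all-alternating series legitimately has CSI = 0.  Degeneracy
    is an explicit flag, never a silent infinity.
    """

    sd1: float
    sd2: float
    T: float
    L: float
    csi: float
    cvi: float
    defined: bool
    n_beats: int
    mean_rri: float
    log_base: float = 10.0


@dataclasses.dataclass
class SegmentedIndices:
    """Whole-task, first-minute and last-minute indices plus change scores."""

    total: LorenzIndices
    first_min: LorenzIndices
    last_min: LorenzIndices
    csi_change: float
    cvi_change: float
    rri_change: float


def lorenz_indices(
    rri: RRISeries, ddof: int = 1, log_base: float = 10.0
) -> LorenzIndices:
    """Lorenz-plot indices of an RR-interval series.

    Equivalent to building the 2-D point cloud of successive interval pairs,
    rotating it by 45°, and taking the coordinate standard deviations.
    """
    x = rri.intervals
    if x.size < 3:
        raise ValueError("need at least 3 RR intervals")
    # centre first: keeps degenerate geometries exactly zero instead of
    # leaving catastrophic-cancellation residue in the summed coordinate
    y = x - x.mean()
    diff = (y[1:] - y[:-1]) / np.sqrt(2.0)
    summ = (y[1:] + y[:-1]) / np.sqrt(2.0)
    sd1 = float(np.std(diff, ddof=ddof))
    sd2 = float(np.std(summ, ddof=ddof))
    T, L = 4.0 * sd1, 4.0 * sd2
    defined = sd1 > 0 and sd2 > 0
    # CSI needs only a non-zero denominator (T); CVI needs both spreads
    csi = L / T if sd1 > 0 else float("nan")
    cvi = float(np.log(L * T) / np.log(log_base)) if defined else float("nan")
    return LorenzIndices(
        sd1=sd1,
        sd2=sd2,
        T=T,
        L=L,
        csi=csi,
        cvi=cvi,
        defined=defined,
        n_beats=int(x.size),
        mean_rri=float(x.mean()),
        log_base=log_base,
    )


def segment_indices(
    rri: RRISeries, segment_s: float = 60.0, log_base: float = 10.0
) -> SegmentedIndices:
    """Whole-task vs first/last-minute indices and change scores.

    A beat belongs to a segment if the R-peak closing its interval lies
    inside it.  Requires at least two full segments of task time and at
    least 3 beats per segment.
    """
    duration = rri.duration_s
    if duration < 2 * segment_s:
        raise ValueError(
            f"series of {duration:.1f} s shorter than two {segment_s:.0f}-s segments"
        )
    first = rri.slice_time(0.0, segment_s)
    last = rri.slice_time(duration - segment_s, duration + 1e-9)
    for name, seg in (("first", first), ("last", last)):
        if seg.n_beats < 3:
            raise ValueError(f"{name} segment has fewer than 3 beats")
    total_ix = lorenz_indices(rri, log_base=log_base)
    first_ix = lorenz_indices(first, log_base=log_base)
    last_ix = lorenz_indices(last, log_base=log_base)
    return SegmentedIndices(
        total=total_ix,
        first_min=first_ix,
        last_min=last_ix,
        csi_change=last_ix.csi - first_ix.csi,
        cvi_change=last_ix.cvi - first_ix.cvi,
        rri_change=float(last.intervals.mean() - first.intervals.mean()),
    )


def detect_rpeaks(
    ecg: Recording,
    refractory_s: float = 0.25,
    threshold_frac: float = 0.5,
    min_crest: float = 5.0,
) -> RRISeries:
    """Detect R-peaks by adaptive amplitude thresholding; return RR intervals.

    The threshold is ``threshold_frac`` of the largest median-centred
    absolute amplitude, with a ``refractory_s`` minimum peak spacing.  Two
    plausibility guards reject signals without QRS-like structure: the peak
    amplitude must stand at least ``min_crest`` robust SDs above baseline,
    and the median detected interval must be physiologically long (≥ 300 ms).
    """
    if ecg.n_channels != 1:
        raise ValueError("detect_rpeaks expects a single-channel recording")
    if ecg.fs < 250:
        raise ValueError("sampling rate below 250 Hz is insufficient for R-peaks")
    x = ecg.data[0] - np.median(ecg.data[0])
    robust_sd = 1.4826 * np.median(np.abs(x))
    peak_amp = np.abs(x).max()
    if peak_amp == 0 or (robust_sd > 0 and peak_amp < min_crest * robust_sd):
        raise ValueError("no QRS-like peaks: amplitude crest factor too low")
    # detect on the polarity with the larger excursion
    if np.abs(x.min()) > np.abs(x.max()):
        x = -x
    peaks, _ = _signal.find_peaks(
        x, height=threshold_frac * x.max(), distance=int(round(refractory_s * ecg.fs))
    )
    if peaks.size < 3:
        raise ValueError("fewer than 3 R-peaks detected")
    intervals_ms = np.diff(peaks) / ecg.fs * 1000.0
    if np.median(intervals_ms) < 300.0:
        raise ValueError("detected peak spacing not physiological; no QRS structure")
    return RRISeries(intervals_ms, t0=float(peaks[0] / ecg.fs))
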