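"""Power spectra, relative band power, frontal alpha asymmetry, band-power tables.

Spectra are Welch averages of Hann-tapered, 50%-overlapping windows (2 s by
default, giving 0.5-Hz resolution) with density scaling, so the integral of
the spectrum over frequency matches the time-domain variance (Parseval)
within taper tolerance.  Relative band power is the integral over a band
divided by the integral over a reference range, 1–60 Hz by default.

The frontal alpha asymmetry (FAA) score is the relative alpha power (8–13 Hz
over 1–60 Hz) at F4 minus that at F3.  Alpha power is inversely related to
cortical activation, so higher scores index relatively greater *left*
frontal activity.  Relative rather than absolute power is used for its
better test–retest reliability, and it makes the score invariant under
global amplitude rescaling.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal

from .bands import ALPHA_BAND, SENSOR_SCHEME, TOTAL_RANGE, BandScheme
from .recording import Recording


@dataclasses.dataclass
class PowerSpectrum:
    """Per-channel Welch power spectral density."""

    freqs: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs), amplitude²/Hz
    window_s: float
    n_windows: int
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("spectral power must be non-negative")

    def channel(self, label: str) -> np.ndarray:
        return self.power[self.labels.index(label)]


@dataclasses.dataclass
class FAAScore:
    """Frontal alpha asymmetry: F4 minus F3 relative alpha power."""

    value: float
    f3_rel: float
    f4_rel: float

    def __post_init__(self) -> None:
        for frac in (self.f3_rel, self.f4_rel):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("relative powers must lie in [0, 1]")


def psd(rec: Recording, window_s: float = 2.0, overlap: float = 0.5) -> PowerSpectrum:
    """Welch power spectral density of every channel."""
    nperseg = int(round(window_s * rec.fs))
    if rec.n_samples < nperseg:
        raise ValueError(
            f"recording of {rec.duration_s:.2f} s shorter than one {window_s} s window"
        )
    noverlap = int(round(overlap * nperseg))
    freqs, power = signal.welch(
        rec.data,
        fs=rec.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        axis=1,
    )
    step = nperseg - noverlap
    n_windows = 1 + (rec.n_samples - nperseg) // step
    return PowerSpectrum(freqs, power, window_s, int(n_windows), rec.labels)


def band_integral(spec: PowerSpectrum, band: tuple[float, float]) -> np.ndarray:
    """Integral of the spectrum over ``band`` per channel (trapezoidal)."""
    lo, hi = band
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    if mask.sum() < 2:
        raise ValueError(f"band {band} contains fewer than two frequency bins")
    return np.trapezoid(spec.power[:, mask], spec.freqs[mask], axis=1)


def relative_band_power(
    spec: PowerSpectrum,
    band: tuple[float, float],
    total: tuple[float, float] = TOTAL_RANGE,
) -> np.ndarray:
    """Band power as a fraction of power in the reference range, per channel."""
    if not (total[0] <= band[0] and band[1] <= total[1]):
        raise ValueError(f"band {band} not contained in reference range {total}")
    num = band_integral(spec, band)
    den = band_integral(spec, total)
    if np.any(den <= 0):
        raise ValueError("zero total power in reference range")
    frac = num / den
    return np.clip(frac, 0.0, 1.0)


def faa(rec: Recording, window_s: float = 2.0) -> FAAScore:
    """Frontal alpha asymmetry score of a (preprocessed) recording."""
    for ch in ("F3", "F4"):
        if ch not in rec.labels:
            raise ValueError(f"recording lacks channel {ch}")
    spec = psd(rec, window_s=window_s)
    rel = relative_band_power(spec, ALPHA_BAND)
    f3 = float(rel[rec.labels.index("F3")])
    f4 = float(rel[rec.labels.index("F4")])
    return FAAScore(value=f4 - f3, f3_rel=f3, f4_rel=f4)


def band_power_table(
    records: Iterable[tuple[str, str, Recording]],
    scheme: BandScheme = SENSOR_SCHEME,
    window_s: float = 2.0,
) -> pd.DataFrame:
    """Relative band power for every (subject, condition, site, band).

    ``records`` yields ``(subject, condition, recording)`` triples; the
    recordings are expected to be preprocessed already.  Sites are the
    recording's channel (or ROI) labels.  All recordings must share one
    sampling rate.
    """
    rows = []
    fs_seen: set[float] = set()
    for subject, condition, rec in records:
        fs_seen.add(rec.fs)
        if len(fs_seen) > 1:
            raise ValueError(f"mixed sampling rates in cohort: {sorted(fs_seen)}")
        spec = psd(rec, window_s=window_s)
        for band_name in scheme.band_names:
            rel = relative_band_power(spec, scheme[band_name])
            for site, value in zip(rec.labels, rel):
                rows.append((subject, condition, site, band_name, float(value)))
    return pd.DataFrame(
        rows, columns=["subject", "condition", "site", "band", "rel_power"]
    )


def cohort_records(cohort, which: str = "eeg", transform=None):
    """Adapter: yield ``(subject, condition, Recording)`` from a PairedCohort.

    ``which`` selects the ``eeg`` or ``roi`` member of each bundle;
    ``transform`` optionally preprocesses each recording.
    """
    from .synth import CONDITIONS  # local import to avoid a cycle

    for sub in cohort:
        for cond in CONDITIONS:
            rec = getattr(sub.bundle(cond), which)
            if transform is not None:
                rec = transform(rec)
            yield sub.subject, cond, rec
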