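"""Lagged phase synchronization (LPS) between ROI time series per band.

Complex coherency is estimated from Hann-tapered, 50%-overlapping windows
(matching the spectral module): within each window and each in-band frequency
bin, every series' Fourier coefficient is normalised to unit modulus (the
phase-synchronization variant — amplitudes carry no weight), and the
coherency ρ of a pair is the average over windows and bins of one series'
normalised coefficient times the conjugate of the other's, so |ρ| ≤ 1.

The lagged component of phase synchronization is

    LPS = Im(ρ)² / (1 − Re(ρ)²)  ∈ [0, 1].

Instantaneous (zero-lag) mixing — e.g. volume conduction — contributes only
to Re(ρ) and is therefore suppressed; a pure delay drives LPS toward 1.
When 1 − Re(ρ)² is numerically zero the pair is perfectly synchronized at
zero lag, carries no lagged component, and the value is defined as 0 (the
pair is flagged degenerate).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .bands import SOURCE_SCHEME, BandScheme
from .recording import Recording

_EPS = 1e-12


@dataclasses.dataclass
class ConnectivityMatrix:
    """Symmetric ROI × ROI LPS values for one band (diagonal masked NaN)."""

    band: str
    labels: tuple[str, ...]
    values: np.ndarray
    n_windows: int

    def __post_init__(self) -> None:
        v = self.values
        off = ~np.eye(v.shape[0], dtype=bool)
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any((v[off] < 0) | (v[off] > 1)):
            raise ValueError("LPS values must lie in [0, 1]")

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def phase_coherency(
    x: Recording,
    band: tuple[float, float],
    window_s: float = 2.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, int]:
    """Complex coherency matrix of unit-modulus-normalised spectra.

    Returns ``(rho, n_windows)`` where ``rho[i, j]`` is the average over
    windows and in-band bins of channel i's normalised Fourier coefficient
    times the conjugate of channel j's.  ``rho[i, i] == 1`` exactly.
    """
    lo, hi = band
    if not 0 < lo < hi < x.fs / 2:
        raise ValueError(f"band {band} outside (0, Nyquist)")
    nperseg = int(round(window_s * x.fs))
    step = nperseg - int(round(overlap * nperseg))
    if x.n_samples < nperseg + step:
        raise ValueError("need at least two windows for coherency")
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / x.fs)
    bins = np.nonzero((freqs >= lo) & (freqs <= hi))[0]
    if bins.size == 0:
        raise ValueError(f"band {band} contains no frequency bins at {window_s}-s windows")
    taper = np.hanning(nperseg)
    starts = range(0, x.n_samples - nperseg + 1, step)
    zs = []
    for s in starts:
        seg = x.data[:, s : s + nperseg] * taper
        coeff = np.fft.rfft(seg, axis=1)[:, bins]
        mod = np.abs(coeff)
        mod[mod == 0] = 1.0
        zs.append(coeff / mod)
    z = np.concatenate(zs, axis=1)  # (channels, n_windows * n_bins)
    rho = (z @ z.conj().T) / z.shape[1]
    return rho, len(zs)


def lps(rho: complex | np.ndarray) -> float | np.ndarray:
    """Lagged phase synchronization of a complex coherency value (or array).

    ``Im(ρ)² / (1 − Re(ρ)²)``, with the degenerate perfectly-real-|ρ|=1 case
    (pure zero-lag synchronization) mapped to 0.
    """
    rho = np.asarray(rho)
    if np.any(np.abs(rho) > 1 + 1e-9):
        raise ValueError("|rho| must not exceed 1")
    re2 = np.real(rho) ** 2
    denom = 1.0 - re2
    out = np.where(denom < _EPS, 0.0, np.imag(rho) ** 2 / np.where(denom < _EPS, 1.0, denom))
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def connectivity_matrix(
    x: Recording,
    band_name: str,
    scheme: BandScheme = SOURCE_SCHEME,
    window_s: float = 2.0,
) -> ConnectivityMatrix:
    """LPS matrix of an ROI series set for one named band."""
    rho, n_windows = phase_coherency(x, scheme[band_name], window_s=window_s)
    values = lps(rho)
    np.fill_diagonal(values, np.nan)
    values = (values + values.T) / 2.0  # enforce exact symmetry against rounding
    return ConnectivityMatrix(band_name, x.labels, values, n_windows)


def fc_table(
    records: Iterable[tuple[str, str, Recording]],
    scheme: BandScheme = SOURCE_SCHEME,
    window_s: float = 2.0,
) -> pd.DataFrame:
    """Long-format LPS table: subject, condition, band, roi_a, roi_b, lps.

    One row per unordered ROI pair (roi_a < roi_b in label order as given).
    All records must share one ROI label set.
    """
    rows = []
    labels_seen: tuple[str, ...] | None = None
    for subject, condition, rec in records:
        if labels_seen is None:
            labels_seen = rec.labels
        elif rec.labels != labels_seen:
            raise ValueError("mismatched ROI labels across subjects")
        for band_name in scheme.band_names:
            mat = connectivity_matrix(rec, band_name, scheme=scheme, window_s=window_s)
            for i in range(len(rec.labels)):
                for j in range(i + 1, len(rec.labels)):
                    rows.append(
                        (
                            subject,
                            condition,
                            band_name,
                            rec.labels[i],
                            rec.labels[j],
                            float(mat.values[i, j]),
                        )
                    )
    return pd.DataFrame(
        rows, columns=["subject", "condition", "band", "roi_a", "roi_b", "lps"]
    )
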