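"""Core containers for multichannel biosignal segments and RR-interval series.

A :class:`Recording` is the unit of EEG preprocessing and spectral analysis:
a labelled channels × samples matrix with a sampling rate.  The same container
holds ROI source time series (see :class:`ROISeriesSet`, a thin alias with ROI
labels).  An :class:`RRISeries` is an ordered list of R–R intervals in
milliseconds with cumulative-time addressing, the unit of HRV analysis.

File formats are deliberately plain text so cohorts can be written, inspected
and re-read without binary dependencies:

* EEG/ROI matrix: one ``#``-prefixed header line carrying the sampling rate and
  channel labels, then one row per sample (tab-delimited, channels as columns).
* RRI: one interval in milliseconds per line; ``#`` lines are comments.

An optional EDF reader is provided through :mod:`mne` when it is installed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

#: The 19 electrodes of the international 10-20 system used for acquisition.
MONTAGE_10_20 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Default 19-ROI source parcellation.  The first 13 regions are the named
#: social-cognition/default-network nodes the analysis reports on; the
#: remaining six complete the 19-region scheme and are configurable.
ROI_19 = (
    "mPFC", "ACC", "DLPFC_L", "DLPFC_R", "LTC_L", "LTC_R",
    "MTL_L", "MTL_R", "PCC", "Precuneus", "MedFG",
    "Fusiform_L", "Fusiform_R",
    "IPL_L", "IPL_R", "TPJ_L", "TPJ_R", "V1", "SMA",
)


@dataclasses.dataclass
class Recording:
    """A labelled multichannel signal segment.

    Parameters
    ----------
    labels
        Channel (electrode or ROI) labels, one per data row.
    fs
        Sampling rate in Hz.
    data
        ``(n_channels, n_samples)`` float array.
    annotations
        Optional ``(start_s, end_s, tag)`` triples.
    """

    labels: tuple[str, ...]
    fs: float
    data: np.ndarray
    annotations: list[tuple[float, float, str]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels × samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} data rows"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the sample row for ``label`` (raises ``KeyError`` if absent)."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present (have {self.labels})")
        return self.data[idx]

    def copy_with(self, data: np.ndarray, annotations=None) -> "Recording":
        return Recording(
            self.labels,
            self.fs,
            data,
            list(self.annotations) if annotations is None else annotations,
        )


class ROISeriesSet(Recording):
    """Recording whose rows are source-space ROI time series.

    Structurally identical to :class:`Recording`; a separate type keeps call
    sites honest about whether they operate at sensor or source level.
    """


@dataclasses.dataclass
class RRISeries:
    """Ordered R–R intervals in milliseconds.

    ``cumulative_time`` assigns each beat the time (in seconds, relative to
    ``t0``) of the R-peak that *closes* its interval, so a beat belongs to a
    task segment if that peak time lies inside the segment.
    """

    intervals: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be a 1-D sequence")
        if self.intervals.size and not np.all(self.intervals > 0):
            raise ValueError("all RR intervals must be positive")

    @property
    def n_beats(self) -> int:
        return int(self.intervals.size)

    @property
    def cumulative_time(self) -> np.ndarray:
        """Seconds since ``t0`` of the R-peak closing each interval."""
        return self.t0 + np.cumsum(self.intervals) / 1000.0

    @property
    def duration_s(self) -> float:
        return float(self.intervals.sum() / 1000.0)

    def slice_time(self, start_s: float, end_s: float) -> "RRISeries":
        """Beats whose closing R-peak lies in ``[start_s, end_s)`` of task time."""
        t = self.cumulative_time - self.t0
        keep = (t >= start_s) & (t < end_s)
        return RRISeries(self.intervals[keep], t0=start_s)


# ---------------------------------------------------------------------------
# plain-text I/O


def write_matrix(path: str | Path, rec: Recording) -> None:
    """Write a Recording as a headered, tab-delimited samples × channels table."""
    path = Path(path)
    header = f"fs={rec.fs:g} labels={','.join(rec.labels)}"
    np.savetxt(path, rec.data.T, fmt="%.8e", delimiter="\t", header=header)


def read_matrix(path: str | Path, cls=Recording) -> Recording:
    """Read a Recording previously written by :func:`write_matrix`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("#"):
        raise ValueError(f"{path}: missing header line")
    fields = dict(
        item.split("=", 1) for item in first.lstrip("# ").split() if "=" in item
    )
    if "fs" not in fields or "labels" not in fields:
        raise ValueError(f"{path}: header must declare fs= and labels=")
    data = np.loadtxt(path, delimiter="\t")
    if data.ndim == 1:
        data = data[:, None]
    return cls(tuple(fields["labels"].split(",")), float(fields["fs"]), data.T)


def write_rri(path: str | Path, rri: RRISeries) -> None:
    """Write RR intervals, one millisecond value per line."""
    with open(path, "w") as fh:
        fh.write("# RR intervals [ms], one per line\n")
        for v in rri.intervals:
            fh.write(f"{v:.6f}\n")


def read_rri(
    path: str | Path,
    valid_range_ms: tuple[float, float] | None = (300.0, 2000.0),
) -> tuple[RRISeries, int]:
    """Read an RRI text file.

    Intervals outside ``valid_range_ms`` are dropped as non-physiological
    (ectopic beats / detection artifacts); the count of dropped beats is
    returned alongside the series so callers can log it.  Pass ``None`` to
    disable the filter.
    """
    vals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            vals.append(float(line))
    arr = np.asarray(vals, dtype=float)
    n_dropped = 0
    if valid_range_ms is not None and arr.size:
        keep = (arr >= valid_range_ms[0]) & (arr <= valid_range_ms[1])
        n_dropped = int((~keep).sum())
        arr = arr[keep]
    return RRISeries(arr), n_dropped


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a Recording (labels taken from the EDF header).

    Requires :mod:`mne`; raises ``ImportError`` with guidance otherwise.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "EDF support requires mne (pip install eegecg[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(tuple(raw.ch_names), float(raw.info["sfreq"]), raw.get_data())
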