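"""Synthetic paired-cohort generator for EEG, ROI source series and RRI data.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage of the pipeline can be exercised and calibrated
without human recordings:

* 19-channel scalp EEG (10–20 montage, 1000 Hz by default) built as a sum of
  band-limited stochastic processes — white noise zero-phase filtered into
  each canonical band, normalised to unit variance and scaled by a per-band
  amplitude — on top of 1/f-shaped background noise.  A frontal-asymmetry
  offset raises the F4 alpha amplitude and lowers F3's symmetrically.
* 19-ROI source time series with tunable band-specific lagged coupling: a
  coupled pair shares a band component delayed by an integer number of
  samples, so pure-delay coupling yields maximal lagged phase
  synchronization while zero-lag mixing yields none, by construction.
* RR-interval series with controllable Poincaré geometry: a slow first-order
  autoregressive component sets the spread along the identity line (SD2), a
  fast white component the perpendicular spread (SD1); linear trends on the
  mean and on the fast spread emulate within-task autonomic drift.

Condition effects are additive on generator parameters and subject effects
are Gaussian random intercepts, the simplest structure under which paired
tests are exactly the right analysis.  One root seed spawns per-subject,
per-condition, per-stream child generators, so identical configurations are
bit-reproducible while streams stay independent.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import signal

from .bands import SENSOR_SCHEME, SOURCE_SCHEME, TOTAL_RANGE, BandScheme
from .recording import (
    MONTAGE_10_20,
    ROI_19,
    Recording,
    ROISeriesSet,
    RRISeries,
    read_matrix,
    read_rri,
    write_matrix,
    write_rri,
)

# ---------------------------------------------------------------------------
# configuration

#: Default per-band generating amplitudes (arbitrary units ~ µV): a plausible
#: resting-task mixture dominated by alpha and low frequencies.
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "delta": 8.0,
    "theta": 6.0,
    "alpha": 10.0,
    "beta": 4.0,
    "gamma": 2.0,
}

#: Default band-specific lagged couplings among ROIs (roi_a, roi_b, band,
#: lag in samples, strength).  Present identically in both conditions: the
#: study design carries autonomic/asymmetry condition effects, not
#: connectivity ones.
DEFAULT_COUPLING: tuple[tuple[str, str, str, int, float], ...] = (
    ("LTC_L", "LTC_R", "gamma", 10, 0.4),
    ("MTL_L", "DLPFC_L", "theta", 15, 0.3),
    ("LTC_R", "DLPFC_R", "alpha", 12, 0.3),
)


@dataclasses.dataclass
class SimConfig:
    """Knobs of the paired-cohort simulation.

    The defaults encode the study conditions the analysis is designed for:
    31 subjects, 1000-Hz 19-channel EEG, tasks of ~4 minutes, a frontal
    alpha-asymmetry condition contrast sized near d ≈ 0.5 and a
    sympathetic-index (CSI-change) contrast near d ≈ 0.37, with RR-interval
    geometry matching a resting mean of ~790 ms, SD1 ≈ 20 ms, SD2 ≈ 45 ms.

    ``faa_shift`` is the *between-condition difference* in the dimensionless
    alpha-amplitude asymmetry applied to F4/F3 (altruistic gets +shift/2,
    selfish −shift/2 around a common negative baseline).  ``csi_trend`` is
    the between-condition difference in the per-minute drift of the fast
    (SD1-like) RRI spread, in ms/min; a positive value makes short-term
    variability grow faster in the altruistic condition, pushing its CSI
    change negative.
    """

    n_subjects: int = 31
    seed: int = 0
    fs: float = 1000.0
    duration_s: float = 240.0
    band_amplitudes: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    noise_sd: float = 5.0
    # frontal alpha asymmetry model (dimensionless amplitude asymmetry)
    faa_shift: float = 0.0105
    faa_baseline: float = -0.0105
    faa_subject_sd: float = 0.023
    faa_noise_sd: float = 0.0105
    # RRI / Poincaré model
    rri_mean_ms: float = 790.0
    sd1_ms: float = 20.0
    sd2_ms: float = 45.0
    rri_trend_ms_per_min: float = -4.5
    rri_trend_sd: float = 4.0
    csi_trend: float = 2.6
    csi_trend_base: float = 0.55
    csi_trend_sd: float = 3.5
    # task-time endpoint (seconds)
    time_mean_s: float = 212.9
    time_effect_s: float = 15.5
    time_subject_sd: float = 48.0
    time_noise_sd: float = 28.0
    coupling_spec: tuple = DEFAULT_COUPLING
    channels: tuple[str, ...] = MONTAGE_10_20
    roi_labels: tuple[str, ...] = ROI_19

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if not self.fs > 120.0:
            raise ValueError("fs must exceed 120 Hz (Nyquist above the gamma top)")
        if not self.duration_s > 60.0:
            raise ValueError("duration_s must exceed 60 s to survive edge trimming")
        for a, b, band, lag, strength in self.coupling_spec:
            if not 0.0 <= strength <= 1.0:
                raise ValueError(f"coupling strength {strength} outside [0, 1]")
            if lag < 0:
                raise ValueError("coupling lag must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["coupling_spec"] = [list(c) for c in self.coupling_spec]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["coupling_spec"] = tuple(tuple(c) for c in d.get("coupling_spec", ()))
        for key in ("channels", "roi_labels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclasses.dataclass
class ConditionBundle:
    """One subject's measurements under one condition."""

    eeg: Recording
    roi: ROISeriesSet
    rri: RRISeries
    task_time_s: float


@dataclasses.dataclass
class SubjectBundle:
    subject: str
    order: str  # "AS" = altruistic first, "SA" = selfish first
    altruistic: ConditionBundle
    selfish: ConditionBundle

    def bundle(self, condition: str) -> ConditionBundle:
        return getattr(self, condition)


@dataclasses.dataclass
class PairedCohort:
    """Paired two-condition cohort plus the true simulation parameters."""

    subjects: list[SubjectBundle]
    truth: SimConfig

    def __iter__(self) -> Iterator[SubjectBundle]:
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)


CONDITIONS = ("altruistic", "selfish")

# ---------------------------------------------------------------------------
# primitive processes


def _rng(seed_parts: Sequence[int]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(seed_parts)))


def band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance white noise zero-phase filtered into ``band``.

    Normalised to unit sample standard deviation so a caller scaling by an
    amplitude *a* gets a component of variance a² exactly.
    """
    lo, hi = band
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate band-limited process")
    return x / sd


def pink_background(
    rng: np.random.Generator, n: int, fs: float, f_lo: float = 1.0
) -> np.ndarray:
    """Unit-variance 1/f-shaped background noise with support [f_lo, fs/2]."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs >= f_lo
    shape[nz] = 1.0 / np.sqrt(freqs[nz])
    spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) * shape
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def pink_band_fraction(
    band: tuple[float, float], fs: float, f_lo: float = 1.0
) -> float:
    """Fraction of 1/f background variance falling inside ``band``.

    The background PSD is ∝ 1/f on [f_lo, fs/2], so the variance fraction in
    [a, b] is log(b/a) / log((fs/2)/f_lo).
    """
    a = max(band[0], f_lo)
    b = min(band[1], fs / 2.0)
    if b <= a:
        return 0.0
    return float(np.log(b / a) / np.log((fs / 2.0) / f_lo))


def expected_relative_band_power(
    band_amplitudes: dict[str, float],
    noise_sd: float,
    band: str,
    fs: float,
    scheme: BandScheme = SENSOR_SCHEME,
    total: tuple[float, float] = TOTAL_RANGE,
) -> float:
    """Parseval prediction of relative band power for a generated channel.

    Each band component contributes amplitude² of variance inside its own
    band; the 1/f background contributes ``noise_sd²`` split analytically
    across frequencies.  Used as the independent oracle for recovery tests.
    """
    amps = {b: band_amplitudes.get(b, 0.0) for b in scheme.band_names}
    bg = noise_sd**2
    num = amps[band] ** 2 + bg * pink_band_fraction(scheme[band], fs)
    den = sum(a**2 for a in amps.values()) + bg * pink_band_fraction(total, fs)
    return num / den


def expected_faa(
    band_amplitudes: dict[str, float],
    noise_sd: float,
    faa_shift: float,
    fs: float,
) -> float:
    """Parseval prediction of the FAA score for a given amplitude asymmetry.

    F4's alpha amplitude is scaled by (1 + shift), F3's by (1 − shift); the
    expected score is the difference of the two predicted relative alpha
    powers.
    """

    def rel_alpha(scale: float) -> float:
        amps = dict(band_amplitudes)
        amps["alpha"] = amps.get("alpha", 0.0) * scale
        return expected_relative_band_power(amps, noise_sd, "alpha", fs)

    return rel_alpha(1.0 + faa_shift) - rel_alpha(1.0 - faa_shift)


# ---------------------------------------------------------------------------
# generators


def gen_eeg(
    channels: Sequence[str],
    fs: float,
    duration_s: float,
    band_amplitudes: dict,
    faa_shift: float = 0.0,
    noise_sd: float = 5.0,
    seed: int | Sequence[int] = 0,
) -> Recording:
    """Generate a multichannel scalp-EEG-like recording.

    Each channel is a sum of independent band-limited processes (one per
    sensor-scheme band, variance = amplitude²) plus 1/f background of
    variance ``noise_sd²``.  ``faa_shift`` scales the F4 alpha amplitude by
    (1 + shift) and F3's by (1 − shift); positive values therefore produce a
    positive frontal alpha asymmetry score downstream (more alpha power on
    the right, i.e. relatively greater left-frontal activity).
    """
    channels = tuple(channels)
    unknown = set(channels) - set(MONTAGE_10_20)
    if unknown:
        raise ValueError(f"unknown electrode labels: {sorted(unknown)}")
    if faa_shift != 0.0 and not {"F3", "F4"} <= set(channels):
        raise ValueError("faa_shift requires both F3 and F4 channels")
    n = int(round(duration_s * fs))
    if n < 61 * fs:
        raise ValueError("recording too short to survive 30-s edge trimming")
    amp_by_channel = _resolve_amplitudes(channels, band_amplitudes)
    seed_parts = [seed] if isinstance(seed, (int, np.integer)) else list(seed)
    rng = _rng(seed_parts)
    data = np.empty((len(channels), n))
    for i, ch in enumerate(channels):
        amps = dict(amp_by_channel[ch])
        if ch == "F4":
            amps["alpha"] = amps.get("alpha", 0.0) * (1.0 + faa_shift)
        elif ch == "F3":
            amps["alpha"] = amps.get("alpha", 0.0) * (1.0 - faa_shift)
        x = noise_sd * pink_background(rng, n, fs)
        for band_name in SENSOR_SCHEME.band_names:
            a = amps.get(band_name, 0.0)
            component = band_limited_noise(rng, n, fs, SENSOR_SCHEME[band_name])
            if a:
                x = x + a * component
        data[i] = x
    return Recording(channels, fs, data)


def _resolve_amplitudes(
    channels: Sequence[str], band_amplitudes: dict
) -> dict[str, dict[str, float]]:
    """Accept either a global band→amp map or a channel→band→amp map."""
    if band_amplitudes and isinstance(next(iter(band_amplitudes.values())), dict):
        missing = set(channels) - set(band_amplitudes)
        if missing:
            raise ValueError(f"no band amplitudes for channels: {sorted(missing)}")
        return {ch: dict(band_amplitudes[ch]) for ch in channels}
    return {ch: dict(band_amplitudes) for ch in channels}


def gen_roi_series(
    roi_labels: Sequence[str],
    fs: float,
    duration_s: float,
    coupling_spec: Sequence[tuple[str, str, str, int, float]] = (),
    seed: int | Sequence[int] = 0,
    band_amplitudes: dict | None = None,
    noise_sd: float = 2.0,
) -> ROISeriesSet:
    """Generate ROI source time series with optional lagged band coupling.

    Uncoupled ROIs are sums of independent band-limited processes (source
    scheme) plus 1/f background.  For a coupling ``(a, b, band, lag,
    strength)``, ROI b's component in that band becomes::

        strength · delay(a's component, lag) + √(1 − strength²) · independent

    so variance is preserved.  ``lag = 0`` produces instantaneous mixing
    only, which lagged phase synchronization must suppress; a pure delay
    with ``strength = 1`` drives it toward its maximum.
    """
    roi_labels = tuple(roi_labels)
    if len(set(roi_labels)) != len(roi_labels):
        raise ValueError("ROI labels must be unique")
    n = int(round(duration_s * fs))
    for a, b, band, lag, strength in coupling_spec:
        for name in (a, b):
            if name not in roi_labels:
                raise ValueError(f"coupling references unknown ROI {name!r}")
        if band not in SOURCE_SCHEME.band_names:
            raise ValueError(f"unknown band {band!r}")
        if lag >= n:
            raise ValueError("coupling lag is not shorter than the recording")
        if not 0.0 <= strength <= 1.0:
            raise ValueError("coupling strength must lie in [0, 1]")
    if band_amplitudes is None:
        band_amplitudes = dict(DEFAULT_BAND_AMPLITUDES)
    seed_parts = [seed] if isinstance(seed, (int, np.integer)) else list(seed)
    rng = _rng(seed_parts)
    # independent components for every roi × band, then apply couplings
    comps: dict[tuple[str, str], np.ndarray] = {}
    background: dict[str, np.ndarray] = {}
    for roi in roi_labels:
        background[roi] = noise_sd * pink_background(rng, n, fs)
        for band_name in SOURCE_SCHEME.band_names:
            comps[(roi, band_name)] = band_limited_noise(
                rng, n, fs, SOURCE_SCHEME[band_name]
            )
    for a, b, band, lag, strength in coupling_spec:
        shared = np.roll(comps[(a, band)], lag)
        comps[(b, band)] = strength * shared + np.sqrt(
            max(0.0, 1.0 - strength**2)
        ) * comps[(b, band)]
    data = np.empty((len(roi_labels), n))
    for i, roi in enumerate(roi_labels):
        x = background[roi]
        for band_name in SOURCE_SCHEME.band_names:
            x = x + band_amplitudes.get(band_name, 0.0) * comps[(roi, band_name)]
        data[i] = x
    return ROISeriesSet(roi_labels, fs, data)


def gen_rri(
    n_beats: int,
    mean_ms: float,
    sd1_ms: float,
    sd2_ms: float,
    trend_ms_per_min: float = 0.0,
    seed: int | Sequence[int] = 0,
    sd1_trend_ms_per_min: float = 0.0,
    phi: float | None = None,
) -> RRISeries:
    """Generate an RR-interval series with controlled Poincaré geometry.

    The series is ``mean + slow + fast + trend`` where *slow* is a
    first-order autoregressive component with lag-1 coefficient φ and *fast*
    is white.  For the Poincaré cloud of (RRIₙ, RRIₙ₊₁) this yields

    ``SD1² = σ_s²(1 − φ) + σ_w²`` and ``SD2² = σ_s²(1 + φ) + σ_w²``

    so the two variances are solved from the SD1/SD2 targets.
    ``trend_ms_per_min`` drifts the mean linearly; ``sd1_trend_ms_per_min``
    drifts the *fast component's* standard deviation by that many ms per
    minute, pivoted at mid-series so the whole-task spread stays at its
    target while the first and last minutes differ — emulating within-task
    autonomic change that moves the cardiac sympathetic index (a growing
    fast spread pulls CSI down, a shrinking one pushes it up).
    """
    if mean_ms <= 0:
        raise ValueError("mean_ms must be positive")
    if sd1_ms < 0 or sd2_ms < 0:
        raise ValueError("sd1_ms and sd2_ms must be non-negative")
    seed_parts = [seed] if isinstance(seed, (int, np.integer)) else list(seed)
    rng = _rng(seed_parts)
    t_min = np.arange(n_beats) * (mean_ms / 60000.0)  # approx time in minutes

    if sd1_ms == 0 and sd2_ms == 0:
        x = np.full(n_beats, mean_ms) + trend_ms_per_min * t_min
    else:
        var1, var2 = sd1_ms**2, sd2_ms**2
        if var1 == var2:
            phi_eff = 0.0
            var_s, var_w = 0.0, var1
        else:
            sign = 1.0 if var2 > var1 else -1.0
            # smallest |φ| keeps the white variance non-negative; a modest
            # margin and a floor of 0.6 keep the slow component short-memory,
            # which tightens finite-series SD2 estimates
            p_min = abs(var2 - var1) / (var2 + var1)
            p = min(0.99, max(0.6, p_min * 1.1))
            if phi is not None:
                p = abs(phi)
            phi_eff = sign * p
            var_s = (var2 - var1) / (2.0 * phi_eff)
            var_w = var1 - var_s * (1.0 - phi_eff)
            if var_w < 0:
                if var_w > -1e-9 * max(var1, var2):
                    var_w = 0.0
                else:
                    raise ValueError(
                        "infeasible SD1/SD2 combination for the AR(1)+white model"
                    )
        slow = np.zeros(n_beats)
        if var_s > 0:
            e = rng.normal(0.0, np.sqrt(var_s * (1 - phi_eff**2)), n_beats)
            slow[0] = rng.normal(0.0, np.sqrt(var_s))
            for i in range(1, n_beats):
                slow[i] = phi_eff * slow[i - 1] + e[i]
        fast = rng.normal(0.0, 1.0, n_beats) * np.sqrt(var_w)
        if sd1_trend_ms_per_min != 0.0:
            sd_w = np.sqrt(var_w)
            t_mid = t_min[-1] / 2.0 if n_beats > 1 else 0.0
            sd_w_t = np.clip(sd_w + sd1_trend_ms_per_min * (t_min - t_mid), 0.0, None)
            fast = fast * (sd_w_t / sd_w if sd_w > 0 else 0.0)
        x = mean_ms + slow + fast + trend_ms_per_min * t_min

    if np.any(x <= 0):
        raise ValueError("parameter combination produced non-positive intervals")
    return RRISeries(x)


# ---------------------------------------------------------------------------
# paired cohort


def gen_subject(config: SimConfig, index: int) -> SubjectBundle:
    """Generate one subject's paired bundles deterministically from the root seed."""
    root = config.seed
    sub_rng = _rng([root, index, 0xFACE])
    # subject-level random effects (shared across conditions)
    faa_subj = sub_rng.normal(0.0, config.faa_subject_sd)
    time_subj = sub_rng.normal(0.0, config.time_subject_sd)
    rri_mean_subj = config.rri_mean_ms * np.exp(sub_rng.normal(0.0, 0.08))
    sd_scale_subj = np.exp(sub_rng.normal(0.0, 0.15))
    trend_subj = sub_rng.normal(0.0, config.rri_trend_sd)
    order = "AS" if sub_rng.random() < 0.5 else "SA"

    bundles = {}
    for ci, cond in enumerate(CONDITIONS):
        cond_sign = +1.0 if cond == "altruistic" else -1.0
        crng = _rng([root, index, ci, 0xC0DE])
        shift = (
            config.faa_baseline
            + faa_subj
            + cond_sign * config.faa_shift / 2.0
            + crng.normal(0.0, config.faa_noise_sd)
        )
        eeg = gen_eeg(
            config.channels,
            config.fs,
            config.duration_s,
            config.band_amplitudes,
            faa_shift=shift,
            noise_sd=config.noise_sd,
            seed=[root, index, ci, 1],
        )
        roi = gen_roi_series(
            config.roi_labels,
            config.fs,
            config.duration_s,
            config.coupling_spec,
            seed=[root, index, ci, 2],
            noise_sd=config.noise_sd / 2.0,
        )
        # 5% beat-count margin so the realised series always covers the task
        n_beats = int(np.ceil(1.05 * config.duration_s * 1000.0 / rri_mean_subj)) + 5
        sd1_trend = (
            config.csi_trend_base
            + cond_sign * config.csi_trend / 2.0
            + crng.normal(0.0, config.csi_trend_sd)
        )
        rri = gen_rri(
            n_beats,
            rri_mean_subj,
            config.sd1_ms * sd_scale_subj,
            config.sd2_ms * sd_scale_subj,
            trend_ms_per_min=config.rri_trend_ms_per_min
            + trend_subj
            + crng.normal(0.0, config.rri_trend_sd),
            sd1_trend_ms_per_min=sd1_trend,
            seed=[root, index, ci, 3],
        )
        task_time = (
            config.time_mean_s
            + time_subj
            + cond_sign * config.time_effect_s / 2.0
            + crng.normal(0.0, config.time_noise_sd)
        )
        bundles[cond] = ConditionBundle(eeg, roi, rri, float(task_time))
    return SubjectBundle(
        subject=f"sub-{index + 1:02d}",
        order=order,
        altruistic=bundles["altruistic"],
        selfish=bundles["selfish"],
    )


def iter_subjects(config: SimConfig) -> Iterator[SubjectBundle]:
    """Lazily generate the cohort one subject at a time (memory-friendly)."""
    for i in range(config.n_subjects):
        yield gen_subject(config, i)


def gen_paired_cohort(config: SimConfig) -> PairedCohort:
    """Generate and materialise the full paired cohort (see :func:`iter_subjects`)."""
    return PairedCohort(list(iter_subjects(config)), truth=config)


def gen_paired_endpoints(
    n: int, d: float, seed: int | Sequence[int], sd: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one paired endpoint sample with true standardized effect ``d``.

    The endpoint model implied by the cohort generator: per-subject values
    share a Gaussian random intercept and conditions differ by an additive
    shift, so the paired differences are N(d·sd, sd²).  Used for type-I and
    power calibration of the statistics layer at realistic sample sizes.
    """
    seed_parts = [seed] if isinstance(seed, (int, np.integer)) else list(seed)
    rng = _rng(seed_parts)
    subject = rng.normal(0.0, 1.0, n)
    x = subject + rng.normal(0.0, sd / np.sqrt(2.0), n) + d * sd / 2.0
    y = subject + rng.normal(0.0, sd / np.sqrt(2.0), n) - d * sd / 2.0
    return x, y


# ---------------------------------------------------------------------------
# on-disk cohort layout


def write_cohort(outdir: str | Path, cohort: PairedCohort | Iterator[SubjectBundle],
                 config: SimConfig | None = None) -> Path:
    """Write a cohort to the per-subject/per-condition directory layout.

    ``outdir/sub-XX/<condition>/{eeg.tsv, roi.tsv, rri.txt}`` plus a
    ``manifest.json`` recording the SimConfig, subject order flags and task
    times.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(cohort, PairedCohort):
        config = cohort.truth
        subjects = iter(cohort.subjects)
    else:
        if config is None:
            raise ValueError("config is required when writing from an iterator")
        subjects = cohort
    manifest: dict = {"config": config.to_dict(), "subjects": {}}
    for sub in subjects:
        manifest["subjects"][sub.subject] = {"order": sub.order, "task_time_s": {}}
        for cond in CONDITIONS:
            b = sub.bundle(cond)
            d = outdir / sub.subject / cond
            d.mkdir(parents=True, exist_ok=True)
            write_matrix(d / "eeg.tsv", b.eeg)
            write_matrix(d / "roi.tsv", b.roi)
            write_rri(d / "rri.txt", b.rri)
            manifest["subjects"][sub.subject]["task_time_s"][cond] = b.task_time_s
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


def read_cohort(indir: str | Path) -> PairedCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    config = SimConfig.from_dict(manifest["config"])
    subjects = []
    for sub_id in sorted(manifest["subjects"]):
        meta = manifest["subjects"][sub_id]
        bundles = {}
        for cond in CONDITIONS:
            d = indir / sub_id / cond
            eeg = read_matrix(d / "eeg.tsv")
            roi = read_matrix(d / "roi.tsv", cls=ROISeriesSet)
            rri, _ = read_rri(d / "rri.txt", valid_range_ms=None)
            bundles[cond] = ConditionBundle(
                eeg, roi, rri, float(meta["task_time_s"][cond])
            )
        subjects.append(
            SubjectBundle(sub_id, meta["order"], bundles["altruistic"], bundles["selfish"])
        )
    return PairedCohort(subjects, truth=config)
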