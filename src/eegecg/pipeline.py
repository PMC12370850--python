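"""End-to-end orchestration: simulate/load → preprocess → measures → statistics.

``run`` executes the whole paired-condition analysis and writes a
:class:`ReportBundle` of plain CSV/JSON tables:

* ``table1.csv`` — paired comparisons of the global endpoints (task time,
  frontal alpha asymmetry, total CSI/CVI/RRI and their first-vs-last-minute
  change scores), each routed through normality testing, with effect sizes
  and report tiers.
* ``topography.csv`` — per-band, per-electrode relative-power contrasts,
  BH-FDR corrected across electrodes within a band.
* ``roi_power.csv`` / ``fc.csv`` — ROI band-power and connectivity
  contrasts, corrected by the max-statistic sign-flip permutation procedure.
* ``correlations.csv`` — per-condition correlations of each global index
  with ROI band-power maps and connectivity maps, corrected by the
  max-statistic subject-shuffle procedure.
* ``endpoints.csv``, ``provenance.json`` — per-subject endpoint values and
  everything needed to re-run bit-identically (config, seeds).

Everything is deterministic given the configuration seed; output files carry
no timestamps, so identical configurations produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from . import __version__
from .bands import SENSOR_SCHEME, SOURCE_SCHEME
from .connectivity import fc_table
from .hrv import segment_indices
from .preprocess import bandpass, reject_artifacts, trim_edges
from .recording import Recording
from .spectral import band_power_table, faa
from .stats import (
    CorrectedMap,
    bh_fdr,
    paired_compare,
    perm_maxstat_corr,
    perm_maxstat_paired,
)
from .synth import (
    CONDITIONS,
    PairedCohort,
    SimConfig,
    SubjectBundle,
    iter_subjects,
    read_cohort,
    write_cohort,
)

#: Global endpoints reported in the paired-comparison table, in report order.
TABLE1_MEASURES = (
    "time_s",
    "faa",
    "total_csi",
    "total_cvi",
    "total_rri",
    "csi_change",
    "cvi_change",
    "rri_change",
)


@dataclasses.dataclass
class RunConfig:
    """Configuration of one end-to-end analysis run."""

    mode: Literal["simulate", "files"] = "simulate"
    sim: SimConfig | None = None
    in_dir: str | None = None
    out_dir: str | None = None
    seed: int | None = None  # statistics seed (permutations); falls back to sim.seed
    n_perm: int = 5000
    wilcoxon_mode: Literal["auto", "approx", "exact"] = "auto"
    cvi_log_base: float = 10.0
    bp_low: float = 1.5
    bp_high: float = 60.0
    trim_s: float = 30.0
    z_amp: float = 10.0
    window_s: float = 2.0
    hrv_segment_s: float = 60.0
    correlate_indices: tuple[str, ...] = (
        "faa",
        "total_csi",
        "total_cvi",
        "csi_change",
        "cvi_change",
        "rri_change",
    )

    def __post_init__(self) -> None:
        if self.mode == "simulate":
            if self.sim is None:
                raise ValueError("simulate mode requires a SimConfig")
        elif self.mode == "files":
            if self.in_dir is None:
                raise ValueError("files mode requires in_dir")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def stats_seed(self) -> int:
        if self.seed is not None:
            return self.seed
        if self.sim is not None:
            return self.sim.seed
        return 0


@dataclasses.dataclass
class ReportBundle:
    """All result tables of one run plus provenance."""

    table1: pd.DataFrame
    endpoints: pd.DataFrame
    topography: dict[str, CorrectedMap]
    roi_power: dict[str, CorrectedMap]
    fc: dict[str, CorrectedMap]
    correlations: dict[tuple[str, str, str, str], CorrectedMap]
    rejection_log: pd.DataFrame
    provenance: dict

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        self.table1.to_csv(outdir / "table1.csv", index=False, float_format=fmt)
        self.endpoints.to_csv(outdir / "endpoints.csv", index=False, float_format=fmt)
        _maps_frame(self.topography, "band").to_csv(
            outdir / "topography.csv", index=False, float_format=fmt
        )
        _maps_frame(self.roi_power, "band").to_csv(
            outdir / "roi_power.csv", index=False, float_format=fmt
        )
        _maps_frame(self.fc, "band").to_csv(
            outdir / "fc.csv", index=False, float_format=fmt
        )
        corr_frames = []
        for (condition, index, level, band), cmap in self.correlations.items():
            frame = _map_frame(cmap)
            frame.insert(0, "band", band)
            frame.insert(0, "level", level)
            frame.insert(0, "index", index)
            frame.insert(0, "condition", condition)
            corr_frames.append(frame)
        pd.concat(corr_frames, ignore_index=True).to_csv(
            outdir / "correlations.csv", index=False, float_format=fmt
        )
        self.rejection_log.to_csv(
            outdir / "rejection_log.csv", index=False, float_format=fmt
        )
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
        return outdir


def _map_frame(cmap: CorrectedMap) -> pd.DataFrame:
    from .stats import tier_of

    return pd.DataFrame(
        {
            "site": list(cmap.sites),
            "stat": cmap.raw_stat,
            "p_raw": cmap.p_raw,
            "p_corrected": cmap.p_corrected,
            "method": cmap.method,
            "tier": [tier_of(p) for p in cmap.p_corrected],
        }
    )


def _maps_frame(maps: dict[str, CorrectedMap], key: str) -> pd.DataFrame:
    frames = []
    for name, cmap in maps.items():
        frame = _map_frame(cmap)
        frame.insert(0, key, name)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _preprocess(rec: Recording, config: RunConfig) -> tuple[Recording, float]:
    rec = bandpass(rec, config.bp_low, config.bp_high)
    if config.trim_s > 0:
        rec = trim_edges(rec, config.trim_s)
    rec, mask = reject_artifacts(rec, z_amp=config.z_amp)
    return rec, mask.rejected_fraction


def subject_endpoints(
    sub: SubjectBundle, condition: str, config: RunConfig
) -> tuple[dict, Recording, Recording]:
    """Preprocess one bundle and compute its global endpoints.

    Returns the endpoint dict plus the preprocessed EEG and ROI recordings
    (for the map stages) so each bundle is processed exactly once.
    """
    bundle = sub.bundle(condition)
    eeg, rej_eeg = _preprocess(bundle.eeg, config)
    roi, rej_roi = _preprocess(bundle.roi, config)
    seg = segment_indices(
        bundle.rri, segment_s=config.hrv_segment_s, log_base=config.cvi_log_base
    )
    score = faa(eeg, window_s=config.window_s)
    endpoints = {
        "subject": sub.subject,
        "condition": condition,
        "order": sub.order,
        "time_s": bundle.task_time_s,
        "faa": score.value,
        "total_csi": seg.total.csi,
        "total_cvi": seg.total.cvi,
        "total_rri": seg.total.mean_rri,
        "csi_change": seg.csi_change,
        "cvi_change": seg.cvi_change,
        "rri_change": seg.rri_change,
        "rejected_fraction_eeg": rej_eeg,
        "rejected_fraction_roi": rej_roi,
    }
    return endpoints, eeg, roi


def _table1(endpoints: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Paired comparisons of the global endpoints (A = altruistic − selfish)."""
    rows = []
    wide = endpoints.pivot(index="subject", columns="condition")
    for measure in TABLE1_MEASURES:
        x = wide[(measure, "altruistic")].to_numpy(float)
        y = wide[(measure, "selfish")].to_numpy(float)
        res = paired_compare(x, y, wilcoxon_mode=config.wilcoxon_mode)
        if res.method == "paired_t":
            center_a, spread_a = float(np.mean(x)), float(np.std(x, ddof=1))
            center_b, spread_b = float(np.mean(y)), float(np.std(y, ddof=1))
            center_kind = "mean_sd"
        else:
            center_a, spread_a = float(np.median(x)), float(np.subtract(*np.percentile(x, [75, 25])))
            center_b, spread_b = float(np.median(y)), float(np.subtract(*np.percentile(y, [75, 25])))
            center_kind = "median_iqr"
        rows.append(
            {
                "measure": measure,
                "center_kind": center_kind,
                "altruistic_center": center_a,
                "altruistic_spread": spread_a,
                "selfish_center": center_b,
                "selfish_spread": spread_b,
                "method": res.method,
                "statistic": res.statistic,
                "df": res.df if res.df is not None else "",
                "p": res.p,
                "effect": res.effect,
                "effect_type": res.effect_type,
                "effect_label": res.effect_label,
                "tier": res.tier,
            }
        )
    return pd.DataFrame(rows)


def _paired_maps(
    table: pd.DataFrame, value: str, site_cols: list[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pivot a long table into (subjects × sites) matrices per condition."""
    site_key = table[site_cols[0]] if len(site_cols) == 1 else table[site_cols].agg(
        "-".join, axis=1
    )
    t = table.assign(_site=site_key)
    wide = t.pivot_table(
        index="subject", columns=["condition", "_site"], values=value, sort=True
    )
    sites = sorted(t["_site"].unique())
    A = wide["altruistic"][sites].to_numpy(float)
    B = wide["selfish"][sites].to_numpy(float)
    return A, B, sites


def _derive_seed(root: int, k: int) -> int:
    return int((root * 1000003 + k * 7919 + 17) % (2**31 - 1))


def run(config: RunConfig, write: bool = True) -> ReportBundle:
    """Execute the full analysis described in the module docstring."""
    if config.mode == "simulate":
        subjects: Iterable[SubjectBundle] = iter_subjects(config.sim)
        sim_dict = config.sim.to_dict()
    else:
        cohort = read_cohort(config.in_dir)
        subjects = cohort.subjects
        sim_dict = cohort.truth.to_dict()

    endpoint_rows = []
    sensor_records = []
    roi_records = []
    for sub in subjects:
        for condition in CONDITIONS:
            ep, eeg, roi = subject_endpoints(sub, condition, config)
            endpoint_rows.append(ep)
            sensor_records.append((sub.subject, condition, eeg))
            roi_records.append((sub.subject, condition, roi))
    endpoints = pd.DataFrame(endpoint_rows)

    table1 = _table1(endpoints, config)

    # sensor topography: per-band relative power, per-subject mean subtracted,
    # per-electrode paired t, BH-FDR across electrodes within each band
    sensor_power = band_power_table(
        sensor_records, SENSOR_SCHEME, window_s=config.window_s
    )
    centred = sensor_power.copy()
    centred["rel_power"] -= centred.groupby(["subject", "band"], sort=False)[
        "rel_power"
    ].transform("mean")
    topography: dict[str, CorrectedMap] = {}
    from scipy import stats as sps

    for band in SENSOR_SCHEME.band_names:
        sub_tab = centred[centred["band"] == band]
        A, B, sites = _paired_maps(sub_tab, "rel_power", ["site"])
        t_res = sps.ttest_rel(A, B, axis=0)
        cmap = bh_fdr(t_res.pvalue, sites=sites)
        cmap.raw_stat = np.asarray(t_res.statistic)
        topography[band] = cmap

    # source-level maps: ROI band power and connectivity with max-statistic
    # sign-flip permutation correction
    roi_power_tab = band_power_table(roi_records, SOURCE_SCHEME, window_s=config.window_s)
    fc_tab = fc_table(roi_records, SOURCE_SCHEME, window_s=config.window_s)
    roi_power: dict[str, CorrectedMap] = {}
    fc_maps: dict[str, CorrectedMap] = {}
    seed_k = 0
    for band in SOURCE_SCHEME.band_names:
        A, B, sites = _paired_maps(
            roi_power_tab[roi_power_tab["band"] == band], "rel_power", ["site"]
        )
        roi_power[band] = perm_maxstat_paired(
            A, B, n_perm=config.n_perm,
            seed=_derive_seed(config.stats_seed, seed_k), sites=sites,
        )
        seed_k += 1
        A, B, sites = _paired_maps(
            fc_tab[fc_tab["band"] == band], "lps", ["roi_a", "roi_b"]
        )
        fc_maps[band] = perm_maxstat_paired(
            A, B, n_perm=config.n_perm,
            seed=_derive_seed(config.stats_seed, seed_k), sites=sites,
        )
        seed_k += 1

    # index-vs-map correlations per condition
    correlations: dict[tuple[str, str, str, str], CorrectedMap] = {}
    ep_wide = endpoints.pivot(index="subject", columns="condition")
    for condition in CONDITIONS:
        for index_name in config.correlate_indices:
            index = ep_wide[(index_name, condition)].to_numpy(float)
            for level, tab, value, site_cols in (
                ("roi_power", roi_power_tab, "rel_power", ["site"]),
                ("fc", fc_tab, "lps", ["roi_a", "roi_b"]),
            ):
                cond_tab = tab[tab["condition"] == condition]
                for band in SOURCE_SCHEME.band_names:
                    band_tab = cond_tab[cond_tab["band"] == band]
                    site_key = (
                        band_tab[site_cols[0]]
                        if len(site_cols) == 1
                        else band_tab[site_cols].agg("-".join, axis=1)
                    )
                    wide = band_tab.assign(_site=site_key).pivot_table(
                        index="subject", columns="_site", values=value, sort=True
                    )
                    sites = list(wide.columns)
                    correlations[(condition, index_name, level, band)] = perm_maxstat_corr(
                        index,
                        wide.to_numpy(float),
                        n_perm=config.n_perm,
                        seed=_derive_seed(config.stats_seed, seed_k),
                        sites=sites,
                    )
                    seed_k += 1

    rejection_log = endpoints[
        ["subject", "condition", "rejected_fraction_eeg", "rejected_fraction_roi"]
    ].copy()
    provenance = {
        "package_version": __version__,
        "run_config": {
            "mode": config.mode,
            "in_dir": config.in_dir,
            "n_perm": config.n_perm,
            "stats_seed": config.stats_seed,
            "wilcoxon_mode": config.wilcoxon_mode,
            "cvi_log_base": config.cvi_log_base,
            "bandpass_hz": [config.bp_low, config.bp_high],
            "trim_s": config.trim_s,
            "z_amp": config.z_amp,
            "window_s": config.window_s,
        },
        "sim_config": sim_dict,
    }
    bundle = ReportBundle(
        table1=table1,
        endpoints=endpoints.drop(
            columns=["rejected_fraction_eeg", "rejected_fraction_roi"]
        ),
        topography=topography,
        roi_power=roi_power,
        fc=fc_maps,
        correlations=correlations,
        rejection_log=rejection_log,
        provenance=provenance,
    )
    if write and config.out_dir is not None:
        bundle.write(config.out_dir)
    return bundle


def make_fixtures(outdir: str | Path, seed: int) -> Path:
    """Write a miniature cohort for the test suite (n = 6, 250 Hz, ~61 s).

    Small enough to round-trip through files mode in seconds; analyses of it
    should disable edge trimming (``trim_s=0``) to keep usable signal.
    """
    config = SimConfig(
        n_subjects=6,
        seed=seed,
        fs=128.0,
        duration_s=61.0,
        channels=("F3", "F4", "Fz", "Cz"),
        roi_labels=("LTC_L", "LTC_R", "MTL_L", "DLPFC_L"),
        coupling_spec=(("LTC_L", "LTC_R", "alpha", 3, 1.0),),
    )
    return write_cohort(outdir, iter_subjects(config), config=config)


#: RunConfig settings suited to analysing the miniature fixture cohort.
FIXTURE_RUN_KWARGS = dict(trim_s=0.0, hrv_segment_s=20.0, n_perm=200)


def simulate_to_dir(config: SimConfig, outdir: str | Path) -> Path:
    """Generate a cohort and write it to ``outdir`` (lazy, subject by subject)."""
    return write_cohort(outdir, iter_subjects(config), config=config)
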