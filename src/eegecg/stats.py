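"""Paired-comparison statistics with effect sizes and multiplicity corrections.

The layer implements the analysis conventions of a within-subject
two-condition design:

* Endpoints are routed by a Shapiro–Wilk normality test on the paired
  differences (α = 0.05): normal → paired t-test with Cohen's d
  (mean difference over its SD, equivalently t/√n); otherwise Wilcoxon
  signed-rank with the matched-pairs rank-biserial correlation r.
* Effect sizes are labelled small/medium/large at d = 0.2/0.5/0.8 and
  r = 0.1/0.3/0.5.
* Two-tier reporting: p < 0.05 significant; 0.05 ≤ p < 0.10 a statistical
  trend (half-open intervals: p = 0.05 is a trend, p = 0.10 is ns).
* Sensor-level maps are corrected by Benjamini–Hochberg FDR; source-level
  maps and index-vs-map correlations by a nonparametric max-statistic
  randomization procedure (5000 permutations by default): per-subject sign
  flips of difference maps for condition contrasts, subject shuffles of the
  index for correlations, with each site's corrected p the proportion of
  permutations (plus the observed arrangement) whose maximum statistic over
  sites reaches that site's observed statistic.
* The a-priori sample size for a paired design uses the normal-approximation
  closed form n = ⌈((z₁₋α/₂ + z_power)/d)²⌉ by default; an exact
  noncentral-t mode is available.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05
TREND = 0.10

_D_THRESHOLDS = ((0.8, "large"), (0.5, "medium"), (0.2, "small"))
_R_THRESHOLDS = ((0.5, "large"), (0.3, "medium"), (0.1, "small"))


@dataclasses.dataclass
class TestResult:
    """One paired comparison: test statistic, p, effect size, report tier."""

    method: Literal["paired_t", "wilcoxon"]
    statistic: float
    df: int | None
    p: float
    effect: float
    effect_type: Literal["d", "r"]
    effect_label: str
    tier: Literal["significant", "trend", "ns"]
    n: int


def tier_of(p: float) -> str:
    if p < ALPHA:
        return "significant"
    if p < TREND:
        return "trend"
    return "ns"


def effect_label(effect: float, effect_type: str) -> str:
    thresholds = _D_THRESHOLDS if effect_type == "d" else _R_THRESHOLDS
    mag = abs(effect)
    for cut, label in thresholds:
        if mag >= cut:
            return label
    return "none"


def shapiro_normality(x: Sequence[float]) -> float:
    """Shapiro–Wilk p-value for normality of ``x`` (3 ≤ n ≤ 5000)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro–Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample")
    return float(sps.shapiro(x).pvalue)


def t_p_value(t: float, df: int) -> float:
    """Two-sided p of a central t statistic."""
    if df < 1:
        raise ValueError("df must be positive")
    return float(2.0 * sps.t.sf(abs(t), df))


def cohens_d_from_t(t: float, n: int) -> float:
    """Paired-design Cohen's d from a paired t statistic: d = t / √n."""
    if n < 2:
        raise ValueError("need at least 2 subjects")
    return float(t / math.sqrt(n))


def wilcoxon_p(
    W: float, n: int, mode: Literal["approx", "exact"] = "approx"
) -> float:
    """Two-sided p for a Wilcoxon signed-rank statistic W with n non-zero pairs.

    ``approx`` is the continuity-corrected normal approximation

        z = (|W − n(n+1)/4| − 0.5) / √(n(n+1)(2n+1)/24)

    valid with ties (W may then be half-integer).  ``exact`` enumerates the
    null distribution of the positive-rank sum for untied ranks (n ≤ 25).
    """
    S = n * (n + 1) / 2.0
    if not 0 <= W <= S:
        raise ValueError(f"W={W} outside [0, {S}]")
    if mode == "exact":
        if n > 25:
            raise ValueError("exact mode limited to n <= 25")
        counts = _signed_rank_null_counts(n)
        total = 2.0**n
        w_lo = int(math.floor(min(W, S - W)))
        p = 2.0 * counts[: w_lo + 1].sum() / total
        return float(min(p, 1.0))
    mu = n * (n + 1) / 4.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = max(abs(W - mu) - 0.5, 0.0) / sigma
    return float(min(2.0 * sps.norm.sf(z), 1.0))


def _signed_rank_null_counts(n: int) -> np.ndarray:
    """counts[w] = number of sign assignments with positive-rank sum w."""
    smax = n * (n + 1) // 2
    counts = np.zeros(smax + 1, dtype=float)
    counts[0] = 1.0
    for rank in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[rank:] = counts[:-rank] if rank else counts
        counts = counts + shifted
    return counts


def rank_biserial(W: float, n: int) -> float:
    """Matched-pairs rank-biserial correlation: r = 2W/S − 1, S = n(n+1)/2.

    Equals (W⁺ − W⁻)/(W⁺ + W⁻); signed for direction, |r| is used for
    effect-size labelling.
    """
    S = n * (n + 1) / 2.0
    if not 0 <= W <= S:
        raise ValueError(f"W={W} outside [0, {S}]")
    return float(2.0 * W / S - 1.0)


def paired_compare(
    x: Sequence[float],
    y: Sequence[float],
    wilcoxon_mode: Literal["approx", "exact", "auto"] = "auto",
) -> TestResult:
    """Compare two paired samples, routing by normality of the differences.

    Differences x − y are tested with Shapiro–Wilk at α = 0.05: normal →
    paired t-test with d = mean(diff)/sd(diff); otherwise Wilcoxon
    signed-rank (zero differences dropped, mid-ranks for ties, W = sum of
    positive-difference ranks) with rank-biserial r.  In ``auto`` mode the
    Wilcoxon p is exact when there are no ties or zeros and n ≤ 25, else
    the continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length samples with at least 3 pairs")
    diff = x - y
    if np.all(diff == 0):
        raise ValueError("all paired differences are zero")
    n = int(diff.size)
    normal_p = shapiro_normality(diff)
    if normal_p >= ALPHA:
        sd = diff.std(ddof=1)
        t = float(diff.mean() / (sd / math.sqrt(n)))
        p = t_p_value(t, n - 1)
        d = cohens_d_from_t(t, n)
        return TestResult(
            "paired_t", t, n - 1, p, d, "d", effect_label(d, "d"), tier_of(p), n
        )
    nz = diff[diff != 0]
    n_eff = int(nz.size)
    ranks = sps.rankdata(np.abs(nz))
    W = float(ranks[nz > 0].sum())
    has_ties = np.unique(np.abs(nz)).size < n_eff
    had_zeros = n_eff < n
    if wilcoxon_mode == "auto":
        mode = "exact" if (not has_ties and not had_zeros and n_eff <= 25) else "approx"
    else:
        mode = wilcoxon_mode
    p = wilcoxon_p(W, n_eff, mode=mode)
    r = rank_biserial(W, n_eff)
    return TestResult(
        "wilcoxon", W, None, p, r, "r", effect_label(r, "r"), tier_of(p), n
    )


# ---------------------------------------------------------------------------
# multiplicity corrections


@dataclasses.dataclass
class CorrectedMap:
    """Per-site statistics with multiplicity-corrected p-values."""

    sites: tuple[str, ...]
    raw_stat: np.ndarray
    p_raw: np.ndarray
    p_corrected: np.ndarray
    method: Literal["bh_fdr", "perm_maxstat"]
    n_perm: int | None = None
    seed: int | None = None
    degenerate: tuple[str, ...] = ()

    @property
    def significant(self) -> np.ndarray:
        return self.p_corrected < ALPHA

    def __post_init__(self) -> None:
        if np.any((self.p_corrected < 0) | (self.p_corrected > 1)):
            raise ValueError("corrected p outside [0, 1]")


def bh_fdr(
    p: Sequence[float], q: float = 0.05, sites: Sequence[str] | None = None
) -> CorrectedMap:
    """Benjamini–Hochberg step-up adjusted p-values and rejections at ``q``."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    if sites is None:
        sites = tuple(str(i) for i in range(p.size))
    return CorrectedMap(
        sites=tuple(sites),
        raw_stat=p.copy(),
        p_raw=p.copy(),
        p_corrected=p_adj,
        method="bh_fdr",
    )


def _paired_t_per_site(diff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site paired t on an (n_subjects, n_sites) difference matrix.

    Returns (t, degenerate_mask).  Zero-variance sites get t = 0 when the
    mean is also zero (exact null), ±inf otherwise, and are flagged.
    """
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
        # zero variance: exact null when the mean is zero too, else infinite effect
        t = np.where(degenerate, np.sign(mean) * np.inf, t)
        t = np.where(degenerate & (mean == 0), 0.0, t)
    return t, degenerate


def perm_maxstat_paired(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    n_perm: int = 5000,
    seed: int | None = None,
    sites: Sequence[str] | None = None,
    exhaustive: bool = False,
) -> CorrectedMap:
    """Max-statistic sign-flip permutation correction for paired map contrasts.

    Per site, a paired t on A − B; the familywise null is built by randomly
    flipping each subject's difference map sign and recording the maximum
    |t| over sites.  Corrected p per site = proportion of permutations
    (plus the observed arrangement) whose max |t| ≥ the site's observed |t|.
    ``exhaustive=True`` enumerates all 2ⁿ sign patterns instead (the
    corrected p is then the exact proportion over all patterns).
    """
    A = np.asarray(maps_a, dtype=float)
    B = np.asarray(maps_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("maps must be two equal-shape (subjects × sites) matrices")
    n, m = A.shape
    if n < 4:
        raise ValueError("need at least 4 subjects")
    diff = A - B
    t_obs, degen = _paired_t_per_site(diff)
    if sites is None:
        sites = tuple(str(i) for i in range(m))

    if exhaustive:
        if n > 20:
            raise ValueError("exhaustive enumeration limited to n <= 20 subjects")
        signs = np.array(
            [[1 if (k >> i) & 1 else -1 for i in range(n)] for k in range(2**n)],
            dtype=float,
        )
        n_eff = signs.shape[0]
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        n_eff = n_perm

    max_null = np.empty(n_eff)
    chunk = 1000
    for s0 in range(0, n_eff, chunk):
        sl = signs[s0 : s0 + chunk]
        flipped_mean = (sl @ diff) / n  # (chunk, m)
        # var of flipped diffs: E[x²] is sign-invariant
        sq_mean = (diff**2).mean(axis=0)  # (m,)
        var = (sq_mean - flipped_mean**2) * n / (n - 1)
        sd = np.sqrt(np.maximum(var, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = flipped_mean / (sd / math.sqrt(n))
        t_null = np.nan_to_num(t_null, nan=0.0, posinf=np.inf, neginf=-np.inf)
        max_null[s0 : s0 + chunk] = np.abs(t_null).max(axis=1)

    abs_obs = np.abs(t_obs)
    p_site = np.empty(m)
    if exhaustive:
        p_corr = np.array([(max_null >= a - 1e-12).mean() for a in abs_obs])
        for j in range(m):
            null_j = np.abs(_site_null_signs(diff[:, j], signs))
            p_site[j] = (null_j >= abs_obs[j] - 1e-12).mean()
        n_perm_out = n_eff
    else:
        p_corr = np.array(
            [(1.0 + (max_null >= a - 1e-12).sum()) / (n_perm + 1.0) for a in abs_obs]
        )
        for j in range(m):
            null_j = np.abs(_site_null_signs(diff[:, j], signs))
            p_site[j] = (1.0 + (null_j >= abs_obs[j] - 1e-12).sum()) / (n_perm + 1.0)
        n_perm_out = n_perm
    p_corr = np.maximum(p_corr, p_site)  # corrected p can never undercut raw p
    return CorrectedMap(
        sites=tuple(sites),
        raw_stat=t_obs,
        p_raw=p_site,
        p_corrected=np.clip(p_corr, 0.0, 1.0),
        method="perm_maxstat",
        n_perm=n_perm_out,
        seed=seed,
        degenerate=tuple(np.asarray(sites)[degen]),
    )


def _site_null_signs(diff_col: np.ndarray, signs: np.ndarray) -> np.ndarray:
    n = diff_col.size
    mean = (signs @ diff_col) / n
    var = ((diff_col**2).mean() - mean**2) * n / (n - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)


def perm_maxstat_corr(
    index: Sequence[float],
    maps: np.ndarray,
    n_perm: int = 5000,
    seed: int | None = None,
    sites: Sequence[str] | None = None,
) -> CorrectedMap:
    """Max-|r| permutation correction for index-vs-map correlations.

    Pearson correlation of a per-subject index with each site's map values;
    the familywise null shuffles the index across subjects and records the
    maximum |r| over sites.
    """
    index = np.asarray(index, dtype=float)
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] != index.size:
        raise ValueError("maps must be (subjects × sites) matching the index length")
    n, m = maps.shape
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if np.ptp(index) == 0:
        raise ValueError("constant index")
    if sites is None:
        sites = tuple(str(i) for i in range(m))

    mc = maps - maps.mean(axis=0)
    col_ss = (mc**2).sum(axis=0)
    degen_sites = col_ss == 0

    def corr_with(vec: np.ndarray) -> np.ndarray:
        vc = vec - vec.mean()
        denom = np.sqrt((vc**2).sum() * col_ss)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (vc @ mc) / denom
        return np.where(degen_sites, 0.0, r)

    r_obs = corr_with(index)
    rng = np.random.default_rng(seed)
    # all shuffles at once: (n_perm, n) index matrix against centred maps
    null_site = np.empty((n_perm, m))
    for k in range(n_perm):
        null_site[k] = np.abs(corr_with(index[rng.permutation(n)]))
    max_null = null_site.max(axis=1)
    abs_obs = np.abs(r_obs)
    p_corr = np.array(
        [(1.0 + (max_null >= a - 1e-12).sum()) / (n_perm + 1.0) for a in abs_obs]
    )
    p_site = (1.0 + (null_site >= abs_obs[None, :] - 1e-12).sum(axis=0)) / (n_perm + 1.0)
    p_corr = np.maximum(p_corr, p_site)
    return CorrectedMap(
        sites=tuple(sites),
        raw_stat=r_obs,
        p_raw=p_site,
        p_corrected=np.clip(p_corr, 0.0, 1.0),
        method="perm_maxstat",
        n_perm=n_perm,
        seed=seed,
        degenerate=tuple(np.asarray(sites)[degen_sites]),
    )


def power_sample_size(
    d: float,
    alpha: float = 0.05,
    power: float = 0.80,
    mode: Literal["normal", "exact"] = "normal",
) -> int:
    """Required paired-design sample size for effect size ``d`` (two-tailed).

    ``normal`` uses the closed form n = ⌈((z₁₋α/₂ + z_power)/d)²⌉;
    ``exact`` iterates the noncentral-t power function (slightly larger n).
    """
    if d <= 0:
        raise ValueError("effect size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if mode == "exact":
        from statsmodels.stats.power import TTestPower

        n = TTestPower().solve_power(effect_size=d, alpha=alpha, power=power)
        return int(math.ceil(n))
    z_a = sps.norm.ppf(1.0 - alpha / 2.0)
    z_b = sps.norm.ppf(power)
    return int(math.ceil(((z_a + z_b) / d) ** 2))


def sample_size_with_margin(n: int, margin: float = 0.05) -> int:
    """Inflate a required n by an attrition margin (e.g. 32 → 34 at 5%)."""
    return int(math.ceil(n * (1.0 + margin)))
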