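"""Reliability statistics: how well do short-window HRV features agree
with their 180-second counterparts?

Four complementary analyses, all non-parametric (a Kolmogorov-Smirnov
screen shows the feature measurements are not normally distributed):

* **Acceptance matrix** — per run, a two-sided Wilcoxon rank-sum test
  between the full short-window vector and the full reference vector;
  a cell is the percentage of runs with p > alpha (no significant
  difference).  Vectors are compared unaligned: the rank-sum test does
  not require equal lengths.
* **Correlation summary** — per run, Spearman's rho between the
  center-time-aligned vectors; per cell, the percentage of runs with a
  significant correlation and the Fisher-z weighted mean rho (weights
  n-3, so longer runs count more).
* **Trend regressions** — ordinary least squares of any per-window row
  (acceptance percentages or Fisher means) against the window-reduction
  index x = (180 - window)/10 in {0..17}.
* **Bland-Altman** — non-parametric: the bias is the median of aligned
  paired differences and the limits of agreement are the 2.5th/97.5th
  percentiles.

Undefined measurements (NaN) are dropped pairwise everywhere; runs that
drop out of a cell entirely are counted in the summaries' drop logs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError, ConfigurationError, ValidationError
from .feature_bank import RunFeatures
from .windowing import FeatureVector, WindowGrid, align_to_reference

log = logging.getLogger(__name__)

__all__ = [
    "AcceptanceMatrix",
    "CorrelationSummary",
    "RegressionSummary",
    "BlandAltmanSummary",
    "ks_normality",
    "rank_sum_test",
    "wilcoxon_acceptance_matrix",
    "spearman_per_run",
    "fisher_mean_correlation",
    "correlation_summary",
    "window_trend_regression",
    "bland_altman",
]

_NAN = float("nan")


# --------------------------------------------------------------------------
# normality screen
# --------------------------------------------------------------------------

def ks_normality(values: Sequence[float]) -> float:
    """One-sample KS p-value of standardized values against N(0, 1).

    Values are standardized (sample mean/std) first; note this makes
    the plain-KS p-value optimistic (the Lilliefors caveat), which is
    reported as-is rather than corrected.  Returns NaN for constant
    input (test inapplicable); requires >= 8 defined values.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 8:
        raise ValidationError(f"ks_normality needs >= 8 defined values, got {x.size}")
    sd = np.std(x, ddof=1)
    if sd == 0:
        return _NAN
    z = (x - np.mean(x)) / sd
    return float(stats.kstest(z, "norm").pvalue)


# --------------------------------------------------------------------------
# Wilcoxon rank-sum
# --------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _combination_indices(n: int, k: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating every allocation.

    Pools both samples, assigns mid-ranks (tie-aware), and enumerates
    all C(n1+n2, n1) ways the pooled ranks could split; the two-sided p
    is min(1, 2 * min(lower tail, upper tail)) at the observed rank sum.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n = x.size, pooled.size
    w_obs = float(np.sum(ranks[:n1]))
    combos = _combination_indices(n, n1)
    w_all = ranks[combos].sum(axis=1)
    lo = np.mean(w_all <= w_obs + 1e-9)
    hi = np.mean(w_all >= w_obs - 1e-9)
    return float(min(1.0, 2.0 * min(lo, hi)))


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``method='auto'`` uses the exact null distribution (full
    enumeration, tie-aware mid-ranks) when both samples have <= 10
    values, and the tie-corrected normal approximation otherwise.
    NaNs are dropped first.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    xa = xa[np.isfinite(xa)]
    ya = ya[np.isfinite(ya)]
    if xa.size == 0 or ya.size == 0:
        return _NAN
    if method == "auto":
        method = "exact" if (xa.size <= 10 and ya.size <= 10) else "asymptotic"
    if method == "exact":
        return _exact_rank_sum_p(xa, ya)
    if method != "asymptotic":
        raise ConfigurationError(f"unknown method {method!r}")
    return float(
        stats.mannwhitneyu(xa, ya, alternative="two-sided", method="asymptotic").pvalue
    )


@dataclass
class AcceptanceMatrix:
    """Percentage of runs with no significant short-vs-reference
    difference, per (feature, window)."""

    features: tuple[str, ...]
    windows: tuple[float, ...]
    values: np.ndarray  # (n_features, n_windows), percent
    n_runs: np.ndarray  # runs actually tested per cell
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.features), columns=list(self.windows)
        )

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self.features.index(feature_id)]


def wilcoxon_acceptance_matrix(
    study_features: Sequence[RunFeatures],
    alpha: float = 0.05,
    method: str = "auto",
) -> AcceptanceMatrix:
    """Build the features x windows acceptance matrix across runs.

    Per run and cell, the full short-window vector is tested against
    the full reference vector (no alignment — lengths may differ); the
    cell is 100 * (#runs with p > alpha) / (#runs tested).  Runs whose
    feature is entirely undefined at a window are excluded from that
    cell and logged.
    """
    if not study_features:
        raise ValidationError("empty study")
    grid = study_features[0].grid
    ref_w = grid.reference_s
    first = study_features[0]
    features = tuple(dict.fromkeys(f for (f, _) in first.vectors))
    windows = tuple(grid.sizes_s)

    values = np.full((len(features), len(windows)), _NAN)
    n_runs = np.zeros((len(features), len(windows)), dtype=int)
    n_dropped = 0
    for fi, fid in enumerate(features):
        for wi, w in enumerate(windows):
            accepted = 0
            tested = 0
            for run in study_features:
                ref = run.vector(fid, ref_w)
                short = run.vector(fid, w)
                if ref.n_defined == 0 or short.n_defined == 0:
                    n_dropped += 1
                    continue
                p = rank_sum_test(short.values, ref.values, method=method)
                if math.isnan(p):
                    n_dropped += 1
                    continue
                tested += 1
                if p > alpha:
                    accepted += 1
            n_runs[fi, wi] = tested
            if tested:
                values[fi, wi] = 100.0 * accepted / tested
    if n_dropped:
        log.info("acceptance matrix: %d run-cells dropped (undefined)", n_dropped)
    return AcceptanceMatrix(
        features=features, windows=windows, values=values, n_runs=n_runs, alpha=alpha
    )


# --------------------------------------------------------------------------
# Spearman correlation
# --------------------------------------------------------------------------

@lru_cache(maxsize=16)
def _permutation_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt(np.sum(a**2) * np.sum(b**2))
    return float(np.sum(a * b) / den) if den > 0 else _NAN


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman's rho (n <= 9)."""
    perms = _permutation_matrix(rx.size)
    ry_perm = ry[perms]  # (n!, n)
    a = rx - rx.mean()
    b = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    den = np.sqrt(np.sum(a**2) * np.sum(b**2, axis=1))
    with np.errstate(invalid="ignore"):
        rhos = (b @ a) / den
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-9))


def spearman_per_run(
    short: FeatureVector, ref: FeatureVector
) -> tuple[float, float, int]:
    """Spearman's rho between one short-window vector and the reference.

    The short vector is first aligned to the reference's center times;
    pairs with any NaN are dropped.  Rho is the Pearson correlation of
    mid-ranks; the two-sided p uses the exact permutation distribution
    when n <= 9 and the t-approximation otherwise.  Returns
    ``(rho, p, n_pairs)``; rho is NaN when either aligned vector is
    constant (the correlation is undefined).
    """
    s_vals, r_vals = align_to_reference(short, ref)
    mask = np.isfinite(s_vals) & np.isfinite(r_vals)
    s_vals, r_vals = s_vals[mask], r_vals[mask]
    n = int(s_vals.size)
    if n < 3:
        return _NAN, _NAN, n
    if np.all(s_vals == s_vals[0]) or np.all(r_vals == r_vals[0]):
        return _NAN, _NAN, n
    rx = stats.rankdata(s_vals)
    ry = stats.rankdata(r_vals)
    rho = _pearson(rx, ry)
    if n <= 9:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        res = stats.spearmanr(s_vals, r_vals)
        rho = float(res.statistic)
        p = float(res.pvalue)
    return rho, p, n


def fisher_mean_correlation(
    rhos: Sequence[float], ns: Sequence[float]
) -> float:
    """Back-transformed run-size-weighted mean correlation.

    Each rho is Fisher z-transformed (atanh, after clipping |rho| at
    1 - 1e-12), averaged with weights n_i - 3 (longer runs weigh more),
    and transformed back with tanh.  NaN rhos are dropped; all-NaN
    input returns NaN.
    """
    r = np.asarray(rhos, dtype=float)
    n = np.asarray(ns, dtype=float)
    if r.shape != n.shape:
        raise ConfigurationError("rhos and ns must have equal length")
    mask = np.isfinite(r)
    r, n = r[mask], n[mask]
    if r.size == 0:
        return _NAN
    if np.any(n < 4):
        raise ConfigurationError("every run needs n >= 4 pairs for Fisher weights")
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    w = n - 3.0
    return float(np.tanh(np.sum(w * z) / np.sum(w)))


@dataclass
class CorrelationSummary:
    """Fisher-mean rho and % significantly-correlated runs per cell."""

    features: tuple[str, ...]
    windows: tuple[float, ...]
    fisher_mean: np.ndarray  # (n_features, n_windows)
    sig_pct: np.ndarray
    n_dropped: np.ndarray  # runs excluded per cell
    alpha: float = 0.05

    def fisher_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fisher_mean, index=list(self.features), columns=list(self.windows)
        )

    def sig_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.sig_pct, index=list(self.features), columns=list(self.windows)
        )

    def fisher_row(self, feature_id: str) -> np.ndarray:
        return self.fisher_mean[self.features.index(feature_id)]

    def fisher_cell(self, feature_id: str, window_s: float) -> float:
        fi = self.features.index(feature_id)
        wi = self.windows.index(float(window_s))
        return float(self.fisher_mean[fi, wi])


def correlation_summary(
    study_features: Sequence[RunFeatures], alpha: float = 0.05
) -> CorrelationSummary:
    """Fill the full features x windows correlation matrices.

    The reference column is (1, 100%) by construction — a vector is
    perfectly correlated with itself.  Runs with undefined correlations
    (constant vectors, too few pairs) are dropped per cell and counted.
    """
    if not study_features:
        raise ValidationError("empty study")
    grid = study_features[0].grid
    ref_w = grid.reference_s
    first = study_features[0]
    features = tuple(dict.fromkeys(f for (f, _) in first.vectors))
    windows = tuple(grid.sizes_s)

    fisher = np.full((len(features), len(windows)), _NAN)
    sig = np.full((len(features), len(windows)), _NAN)
    dropped = np.zeros((len(features), len(windows)), dtype=int)
    for fi, fid in enumerate(features):
        for wi, w in enumerate(windows):
            if w == ref_w:
                fisher[fi, wi] = 1.0
                sig[fi, wi] = 100.0
                continue
            rhos, ns, n_sig = [], [], 0
            for run in study_features:
                ref = run.vector(fid, ref_w)
                short = run.vector(fid, w)
                try:
                    rho, p, n = spearman_per_run(short, ref)
                except AlignmentError:
                    dropped[fi, wi] += 1
                    continue
                if not math.isfinite(rho) or n < 4:
                    dropped[fi, wi] += 1
                    continue
                rhos.append(rho)
                ns.append(n)
                if p < alpha:
                    n_sig += 1
            if rhos:
                fisher[fi, wi] = fisher_mean_correlation(rhos, ns)
                sig[fi, wi] = 100.0 * n_sig / len(rhos)
    return CorrelationSummary(
        features=features, windows=windows, fisher_mean=fisher, sig_pct=sig,
        n_dropped=dropped, alpha=alpha,
    )


# --------------------------------------------------------------------------
# window-trend regression
# --------------------------------------------------------------------------

@dataclass
class RegressionSummary:
    """OLS of a per-window row against the window-reduction index.

    One x unit = 10 s of window reduction; the reference window sits at
    x = 0, so the intercept is the (extrapolated) value at 180 s.
    """

    slope: float
    intercept: float
    r2: float
    n: int


def window_trend_regression(
    y: Sequence[float], grid: WindowGrid | None = None
) -> RegressionSummary:
    """Fit value-vs-window-reduction by ordinary least squares.

    ``y`` holds one value per grid window (ordered like the grid);
    x_k = (reference - window_k)/10.  Constant y gives slope 0 with an
    undefined (NaN) R².  Requires >= 3 defined values.
    """
    grid = grid or WindowGrid()
    ya = np.asarray(y, dtype=float)
    if ya.size != len(grid.sizes_s):
        raise ConfigurationError(
            f"y has {ya.size} values but the grid has {len(grid.sizes_s)} windows"
        )
    x = (grid.reference_s - np.asarray(grid.sizes_s)) / 10.0
    mask = np.isfinite(ya)
    if mask.sum() < 3:
        raise ValidationError("window_trend_regression needs >= 3 defined values")
    xm, ym = x[mask], ya[mask]
    if np.all(ym == ym[0]):
        return RegressionSummary(slope=0.0, intercept=float(ym[0]), r2=_NAN, n=int(mask.sum()))
    slope, intercept = np.polyfit(xm, ym, 1)
    pred = slope * xm + intercept
    ss_res = float(np.sum((ym - pred) ** 2))
    ss_tot = float(np.sum((ym - ym.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return RegressionSummary(
        slope=float(slope), intercept=float(intercept), r2=r2, n=int(mask.sum())
    )


# --------------------------------------------------------------------------
# Bland-Altman
# --------------------------------------------------------------------------

@dataclass
class BlandAltmanSummary:
    """Non-parametric agreement summary for one feature/window/run."""

    bias: float  # median of paired differences
    loa_low: float  # 2.5th percentile
    loa_high: float  # 97.5th percentile
    frac_within: float
    n: int


def bland_altman(short: FeatureVector, ref: FeatureVector) -> BlandAltmanSummary:
    """Non-parametric Bland-Altman of aligned paired differences.

    Differences are short - reference on center-aligned pairs; the bias
    is their median and the 95% limits of agreement are the 2.5th and
    97.5th percentiles (linear-interpolation definition).  Requires at
    least 10 defined pairs.
    """
    s_vals, r_vals = align_to_reference(short, ref)
    d = s_vals - r_vals
    d = d[np.isfinite(d)]
    if d.size < 10:
        raise ValidationError(
            f"bland_altman needs >= 10 defined pairs, got {d.size}"
        )
    lo, hi = np.percentile(d, [2.5, 97.5])
    return BlandAltmanSummary(
        bias=float(np.median(d)),
        loa_low=float(lo),
        loa_high=float(hi),
        frac_within=float(np.mean((d >= lo) & (d <= hi))),
        n=int(d.size),
    )
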