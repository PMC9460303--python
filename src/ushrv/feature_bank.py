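"""The 31-feature HRV bank: time, geometric, non-linear and frequency domains.

The registry holds 31 features partitioned 6/3/6/16:

* time (6): mNN, SDNN, SDSD, RMSSD, NN50, pNN50
* geometric (3): TI, TINN, SI
* non-linear (6): ApEn, SD1, SD2, PTM, KFD, HFD
* frequency (16): VLF, LF, HF, VLFnu, LFnu, HFnu, VLFpeak, LFpeak,
  HFpeak, VLFpeak_nu, LFpeak_nu, HFpeak_nu, totPow, Peak, LF_HF,
  LFpeak_HFpeak

Units follow HRV convention: RR statistics in ms, band powers in ms²,
spectral peaks in Hz, pNN50 and normalized band powers in percent.
Undefined values (degenerate segments, empty spectral bands) are NaN
markers, never silent zeros; downstream statistics drop them pairwise.

Spectral estimation resamples the tachogram (RR vs beat time, cubic
interpolation) onto a uniform 4-Hz grid, removes the mean, and takes a
Hann-tapered single-segment periodogram with density scaling.  A single
segment is used (no Welch averaging) because a 10-s window has too few
samples to split.  The standard bands partition (left-open):
VLF (0, 0.04], LF (0.04, 0.15], HF (0.15, 0.4] Hz.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from numpy.lib.stride_tricks import sliding_window_view
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import interpolate, signal

from .exceptions import ConfigurationError, ValidationError
from .rr_model import RRSeries
from .windowing import FeatureVector, WindowGrid, segment_indices

log = logging.getLogger(__name__)

__all__ = [
    "TIME_FEATURES",
    "GEOMETRIC_FEATURES",
    "NONLINEAR_FEATURES",
    "FREQUENCY_FEATURES",
    "VLF_BAND",
    "LF_BAND",
    "HF_BAND",
    "band_period_s",
    "FeatureRegistry",
    "FeatureConfig",
    "SpectralEstimate",
    "RunFeatures",
    "time_domain_features",
    "geometric_features",
    "poincare_sd",
    "approximate_entropy",
    "point_transition_measure",
    "katz_fd",
    "higuchi_fd",
    "estimate_psd",
    "frequency_features",
    "compute_segment_features",
    "extract_all",
]

TIME_FEATURES = ("mNN", "SDNN", "SDSD", "RMSSD", "NN50", "pNN50")
GEOMETRIC_FEATURES = ("TI", "TINN", "SI")
NONLINEAR_FEATURES = ("ApEn", "SD1", "SD2", "PTM", "KFD", "HFD")
FREQUENCY_FEATURES = (
    "VLF",
    "LF",
    "HF",
    "VLFnu",
    "LFnu",
    "HFnu",
    "VLFpeak",
    "LFpeak",
    "HFpeak",
    "VLFpeak_nu",
    "LFpeak_nu",
    "HFpeak_nu",
    "totPow",
    "Peak",
    "LF_HF",
    "LFpeak_HFpeak",
)

#: Band edges in Hz; each band is left-open, right-closed so the three
#: bands partition (0, 0.4].
VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


def band_period_s(frequency_hz: float) -> float:
    """Oscillation period (s) of a band-edge frequency: 1/f.

    The slowest LF oscillation (0.04 Hz) has a 25-s period and the
    fastest (0.15 Hz) a ~6.7-s period, which is why very short analysis
    windows cannot capture a full VLF — and barely an LF — cycle.
    """
    if frequency_hz <= 0:
        raise ConfigurationError("frequency must be > 0")
    return 1.0 / frequency_hz


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered feature ids with their domain tags."""

    feature_ids: tuple[str, ...] = (
        TIME_FEATURES + GEOMETRIC_FEATURES + NONLINEAR_FEATURES + FREQUENCY_FEATURES
    )

    def __post_init__(self) -> None:
        known = set(TIME_FEATURES + GEOMETRIC_FEATURES + NONLINEAR_FEATURES + FREQUENCY_FEATURES)
        unknown = [f for f in self.feature_ids if f not in known]
        if unknown:
            raise ConfigurationError(f"unknown feature ids: {unknown}")
        if len(self.feature_ids) == 0:
            raise ConfigurationError("registry must not be empty")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ConfigurationError("registry contains duplicate feature ids")
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))

    def __len__(self) -> int:
        return len(self.feature_ids)

    def __iter__(self):
        return iter(self.feature_ids)

    def domain(self, feature_id: str) -> str:
        if feature_id in TIME_FEATURES:
            return "time"
        if feature_id in GEOMETRIC_FEATURES:
            return "geometric"
        if feature_id in NONLINEAR_FEATURES:
            return "nonlinear"
        return "frequency"

    @property
    def domains(self) -> dict[str, int]:
        counts = {"time": 0, "geometric": 0, "nonlinear": 0, "frequency": 0}
        for f in self.feature_ids:
            counts[self.domain(f)] += 1
        return counts

    def subset(self, ids: Sequence[str]) -> "FeatureRegistry":
        return FeatureRegistry(feature_ids=tuple(ids))


@dataclass(frozen=True)
class FeatureConfig:
    """Tunables for the feature bank.

    min_beats
        Segments with fewer RR intervals yield NaN for every feature
        (ApEn with m=2 needs at least 4 points).
    ti_bin_ms
        TI/TINN histogram bin width, 1000/128 ≈ 7.8125 ms, anchored at 0
        (the standard 1/128-s convention).
    si_bin_ms
        Stress-index histogram bin width (Baevsky convention, 50 ms),
        bins centered on multiples of the width.
    apen_m, apen_r_factor
        Approximate-entropy embedding dimension and tolerance factor
        (r = factor * SDNN of the segment), self-matches included.
    kmax
        Higuchi maximum scale; None means min(8, floor((N-1)/2)),
        adapting to the window size.
    resample_hz
        Uniform tachogram resampling rate for spectral estimation.
    min_psd_window_s
        Windows shorter than this get NaN for all frequency features.
    kfd_cap
        Guard value reported when the Katz denominator degenerates.
    """

    min_beats: int = 4
    ti_bin_ms: float = 1000.0 / 128.0
    si_bin_ms: float = 50.0
    apen_m: int = 2
    apen_r_factor: float = 0.2
    kmax: int | None = None
    resample_hz: float = 4.0
    min_psd_window_s: float = 10.0
    kfd_cap: float = 10.0


_NAN = float("nan")


# --------------------------------------------------------------------------
# time domain
# --------------------------------------------------------------------------

def time_domain_features(rr: Sequence[float], min_beats: int = 4) -> dict[str, float]:
    """mNN, SDNN, SDSD, RMSSD, NN50, pNN50 of one RR segment (ms).

    Standard deviations use the sample (N-1) denominator; NN50 counts
    successive differences exceeding 50 ms in magnitude and pNN50 is
    that count as a percentage of the N-1 differences.
    """
    x = np.asarray(rr, dtype=float)
    if x.size < min_beats:
        return {f: _NAN for f in TIME_FEATURES}
    d = np.diff(x)
    nn50 = int(np.sum(np.abs(d) > 50.0))
    return {
        "mNN": float(np.mean(x)),
        "SDNN": float(np.std(x, ddof=1)),
        "SDSD": float(np.std(d, ddof=1)),
        "RMSSD": float(np.sqrt(np.mean(d**2))),
        "NN50": float(nn50),
        "pNN50": 100.0 * nn50 / (x.size - 1),
    }


# --------------------------------------------------------------------------
# geometric domain
# --------------------------------------------------------------------------

def _triangular_sse(
    centers: np.ndarray, counts: np.ndarray, apex_x: float, apex_y: float,
    m_edges: np.ndarray, n_edges: np.ndarray,
) -> tuple[float, float]:
    """Best (M, N) triangle-base edges by exhaustive squared-error search.

    The candidate triangle is zero outside [M, N] and rises linearly to
    the histogram's modal height at the modal bin center.  Fully
    vectorized over the (M, N) candidate grid; ties resolve to the
    first (narrowest-from-the-left) pair.
    """
    rise = np.clip(
        (centers[None, :] - m_edges[:, None]) / (apex_x - m_edges[:, None]),
        0.0, 1.0,
    )
    fall = np.clip(
        (n_edges[:, None] - centers[None, :]) / (n_edges[:, None] - apex_x),
        0.0, 1.0,
    )
    tri = apex_y * np.minimum(rise[:, None, :], fall[None, :, :])
    sse = np.sum((counts[None, None, :] - tri) ** 2, axis=2)
    i, j = np.unravel_index(int(np.argmin(sse)), sse.shape)
    return float(m_edges[i]), float(n_edges[j])


def geometric_features(
    rr: Sequence[float],
    ti_bin_ms: float = 1000.0 / 128.0,
    si_bin_ms: float = 50.0,
    min_beats: int = 4,
) -> dict[str, float]:
    """TI, TINN and Baevsky's stress index of one RR segment.

    TI is the sample count divided by the modal bin count of the
    NN-interval histogram (bin width ``ti_bin_ms`` anchored at 0); TINN
    is the base width of the best-fitting triangular interpolation of
    that histogram.  SI = AMo / (2 * Mo * MxDMn) with a separate 50-ms
    histogram whose bins are centered on multiples of 50 ms: Mo is the
    modal bin center in seconds, AMo the percentage of intervals in the
    modal bin, MxDMn the RR range in seconds.
    """
    x = np.asarray(rr, dtype=float)
    if x.size < min_beats:
        return {f: _NAN for f in GEOMETRIC_FEATURES}

    # --- TI / TINN on the 1/128-s histogram anchored at 0
    j = np.floor(x / ti_bin_ms).astype(int)
    j_lo, j_hi = int(j.min()), int(j.max())
    counts = np.bincount(j - j_lo, minlength=j_hi - j_lo + 1).astype(float)
    max_count = counts.max()
    ti = x.size / max_count

    occupied = np.flatnonzero(counts > 0)
    if occupied.size == 1:
        tinn = 0.0
    else:
        j_mode = int(np.argmax(counts))  # first modal bin on ties
        centers = (np.arange(j_lo - 1, j_hi + 2) + 0.5) * ti_bin_ms
        full_counts = np.concatenate(([0.0], counts, [0.0]))
        apex_x = (j_mode + j_lo + 0.5) * ti_bin_ms
        apex_y = max_count
        m_edges = np.arange(j_lo - 1, j_mode + j_lo + 1) * ti_bin_ms
        n_edges = np.arange(j_mode + j_lo + 1, j_hi + 3) * ti_bin_ms
        m_best, n_best = _triangular_sse(
            centers, full_counts, apex_x, apex_y, m_edges, n_edges
        )
        tinn = float(n_best - m_best)

    # --- SI on 50-ms bins centered at multiples of 50 ms
    k = np.round(x / si_bin_ms).astype(int)
    k_counts = np.bincount(k - k.min())
    k_mode = int(np.argmax(k_counts)) + k.min()
    mo_s = k_mode * si_bin_ms / 1000.0
    amo_pct = 100.0 * k_counts.max() / x.size
    mxdmn_s = float(x.max() - x.min()) / 1000.0
    si = amo_pct / (2.0 * mo_s * mxdmn_s) if mxdmn_s > 0 else _NAN

    return {"TI": float(ti), "TINN": tinn, "SI": float(si)}


# --------------------------------------------------------------------------
# non-linear domain
# --------------------------------------------------------------------------

def poincare_sd(rr: Sequence[float], min_beats: int = 4) -> tuple[float, float]:
    """SD1/SD2 by direct 45° rotation of the Poincaré cloud.

    Points (rr_i, rr_{i+1}) are rotated onto axes perpendicular to and
    along the identity line; SD1/SD2 are the sample standard deviations
    of the rotated coordinates.  The direct computation (rather than the
    SDNN/SDSD approximation) cannot go negative on ultra-short
    alternating segments, and SD1 == SDSD/sqrt(2) holds exactly under
    the shared sample-denominator convention.
    """
    x = np.asarray(rr, dtype=float)
    if x.size < min_beats:
        return _NAN, _NAN
    u = (x[1:] - x[:-1]) / np.sqrt(2.0)
    v = (x[1:] + x[:-1]) / np.sqrt(2.0)
    return float(np.std(u, ddof=1)), float(np.std(v, ddof=1))


def approximate_entropy(
    rr: Sequence[float], m: int = 2, r: float | None = None,
    r_factor: float = 0.2,
) -> float:
    """Approximate entropy ApEn(m, r) with self-matches.

    ``r`` defaults to ``r_factor * SDNN`` of the segment.  C_i^m(r) is
    the fraction of m-templates within Chebyshev distance r of template
    i; ApEn = Phi^m - Phi^{m+1} with Phi the mean log of the C_i.
    Regular signals score near 0; irregular ones higher.
    """
    x = np.asarray(rr, dtype=float)
    if r is None:
        r = r_factor * float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if r < 0:
        raise ConfigurationError("ApEn tolerance r must be >= 0")
    if x.size < m + 2:
        return _NAN

    def phi(mm: int) -> float:
        templates = sliding_window_view(x, mm)
        dist = np.max(
            np.abs(templates[:, None, :] - templates[None, :, :]), axis=2
        )
        c = np.mean(dist <= r + 1e-12, axis=1)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def point_transition_measure(rr: Sequence[float], min_beats: int = 4) -> float:
    """Mean Euclidean distance between consecutive Poincaré points (ms).

    Quantifies beat-to-beat temporal variation of the Poincaré cloud:
    consecutive points differ by (d_i, d_{i+1}) where d is the
    successive-difference series, so each step length is
    sqrt(d_i^2 + d_{i+1}^2).
    """
    x = np.asarray(rr, dtype=float)
    if x.size < min_beats:
        return _NAN
    d = np.diff(x)
    steps = np.sqrt(d[:-1] ** 2 + d[1:] ** 2)
    return float(np.mean(steps))


def katz_fd(rr: Sequence[float], cap: float = 10.0, min_beats: int = 4) -> float:
    """Katz fractal dimension of the RR waveform.

    Uses the waveform convention of unit abscissa spacing: curve length
    L is the summed absolute ordinate steps, planar extent d the maximum
    deviation from the first sample, n = N-1.  Returns 1 on a monotone
    ramp (d == L); a constant segment is undefined (NaN); when the
    denominator log10(n) + log10(d/L) degenerates toward 0 the value is
    capped at ``cap`` (flagged in the log) rather than diverging.
    """
    x = np.asarray(rr, dtype=float)
    if x.size < min_beats:
        return _NAN
    L = float(np.sum(np.abs(np.diff(x))))
    if L == 0.0:
        return _NAN
    d = float(np.max(np.abs(x - x[0])))
    n = x.size - 1
    if d == L:
        return 1.0
    den = math.log10(n) + math.log10(d / L)
    if den <= 1e-12:
        log.debug("KFD denominator degenerate (n=%d, d/L=%.4g); capped", n, d / L)
        return cap
    return min(math.log10(n) / den, cap)


def higuchi_fd(rr: Sequence[float], kmax: int | None = None) -> float:
    """Higuchi fractal dimension of the RR series.

    Average normalized curve length L(k) over k offsets, with the
    standard (N-1)/(floor((N-m)/k)*k) normalization; HFD is the slope of
    the least-squares fit of ln L(k) against ln(1/k) for k = 1..kmax.
    A straight line scores 1, white noise approaches 2.  ``kmax``
    defaults to min(8, floor((N-1)/2)), shrinking with the window size.
    """
    x = np.asarray(rr, dtype=float)
    N = x.size
    if kmax is None:
        kmax = min(8, (N - 1) // 2)
    if kmax < 2:
        raise ConfigurationError(f"higuchi_fd needs kmax >= 2 (N={N})")
    if N < 2 * kmax:
        return _NAN
    log_l = []
    log_inv_k = []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, N, k)
            nseg = idx.size - 1
            if nseg < 1:
                continue
            lm = np.sum(np.abs(np.diff(x[idx]))) * (N - 1) / (nseg * k) / k
            lengths.append(lm)
        if not lengths:
            continue
        mean_l = float(np.mean(lengths))
        if mean_l <= 0:
            return _NAN
        log_l.append(math.log(mean_l))
        log_inv_k.append(math.log(1.0 / k))
    slope, _ = np.polyfit(log_inv_k, log_l, 1)
    return float(slope)


# --------------------------------------------------------------------------
# frequency domain
# --------------------------------------------------------------------------

@dataclass
class SpectralEstimate:
    """One segment's power spectral density (ms²/Hz) on (0, 2] Hz."""

    freqs_hz: np.ndarray
    psd: np.ndarray
    resample_hz: float
    window_s: float


def estimate_psd(
    rr: Sequence[float],
    t_end_s: Sequence[float],
    window_s: float,
    resample_hz: float = 4.0,
    min_beats: int = 4,
) -> SpectralEstimate | None:
    """PSD of one windowed tachogram segment.

    ``t_end_s`` are the beat times at which each interval ends.  The
    tachogram is cubic-interpolated onto a uniform ``resample_hz`` grid
    spanning the segment, the mean removed, and a Hann-tapered
    single-segment periodogram taken with density normalization (the
    integral of the psd over frequency recovers the detrended signal's
    variance up to taper leakage).  Frequencies below 1/window_s carry
    no full oscillation inside the window and are discarded.

    Returns None when the segment is degenerate (too few beats).
    """
    x = np.asarray(rr, dtype=float)
    t = np.asarray(t_end_s, dtype=float)
    if x.size < max(min_beats, 4) or t.size != x.size:
        return None
    span = t[-1] - t[0]
    n_grid = int(np.floor(span * resample_hz)) + 1
    if n_grid < 8:
        return None
    grid = t[0] + np.arange(n_grid) / resample_hz
    spline = interpolate.CubicSpline(t, x)
    series = spline(grid)
    freqs, psd = signal.periodogram(
        series, fs=resample_hz, window="hann", detrend="constant",
        scaling="density",
    )
    keep = freqs >= (1.0 / window_s) - 1e-12
    keep &= freqs > 0
    return SpectralEstimate(
        freqs_hz=freqs[keep], psd=psd[keep], resample_hz=resample_hz,
        window_s=window_s,
    )


def _band_integral(
    freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float
) -> float:
    """Integral of the piecewise-linear PSD over (lo, hi].

    Values at the exact band edges are linearly interpolated so that
    adjacent bands partition the total power exactly.
    """
    f0, f1 = freqs[0], freqs[-1]
    a = max(lo, f0)
    b = min(hi, f1)
    if b <= a:
        return 0.0
    # sample the piecewise-linear psd at the clipped edges plus interior points
    inner = freqs[(freqs > a) & (freqs < b)]
    fs = np.concatenate(([a], inner, [b]))
    ps = np.interp(fs, freqs, psd)
    return float(np.trapezoid(ps, fs))


def _band_mask(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (freqs > lo + 1e-12) & (freqs <= hi + 1e-12)


def frequency_features(spec: SpectralEstimate | None) -> dict[str, float]:
    """The 16 frequency-domain features from one spectral estimate.

    Band powers integrate the PSD over VLF (0, 0.04], LF (0.04, 0.15]
    and HF (0.15, 0.4]; totPow is the power over (0, 0.4], so the three
    normalized band powers sum to 100.  Band peaks are the frequency of
    the PSD maximum inside each band (Hz); the "peak normalized" value
    is the PSD at the peak divided by the summed PSD over (0, 0.4].
    A band whose grid is empty (1/window_s above its upper edge) yields
    NaN for that band's features.
    """
    out = {f: _NAN for f in FREQUENCY_FEATURES}
    if spec is None or spec.freqs_hz.size < 2:
        return out
    freqs, psd = spec.freqs_hz, spec.psd

    full_mask = _band_mask(freqs, 0.0, HF_BAND[1])
    psd_sum = float(np.sum(psd[full_mask])) if np.any(full_mask) else 0.0

    powers: dict[str, float] = {}
    for name, (lo, hi) in (("VLF", VLF_BAND), ("LF", LF_BAND), ("HF", HF_BAND)):
        mask = _band_mask(freqs, lo, hi)
        if not np.any(mask):
            log.debug("window %.0f s: empty %s band grid", spec.window_s, name)
            continue
        powers[name] = _band_integral(freqs, psd, lo, hi)
        f_band = freqs[mask]
        p_band = psd[mask]
        peak_idx = int(np.argmax(p_band))
        out[f"{name}peak"] = float(f_band[peak_idx])
        if psd_sum > 0:
            out[f"{name}peak_nu"] = float(p_band[peak_idx] / psd_sum)
        out[name] = powers[name]

    tot = sum(powers.values())
    out["totPow"] = tot if powers else _NAN
    if tot > 0:
        for name in powers:
            out[f"{name}nu"] = 100.0 * powers[name] / tot
    if np.any(full_mask):
        f_all = freqs[full_mask]
        out["Peak"] = float(f_all[int(np.argmax(psd[full_mask]))])
    hf = powers.get("HF", _NAN)
    lf = powers.get("LF", _NAN)
    out["LF_HF"] = lf / hf if hf and hf > 0 and not math.isnan(lf) else _NAN
    if not math.isnan(out["LFpeak"]) and not math.isnan(out["HFpeak"]) and out["HFpeak"] > 0:
        out["LFpeak_HFpeak"] = out["LFpeak"] / out["HFpeak"]
    return out


# --------------------------------------------------------------------------
# per-segment dispatch + whole-run extraction
# --------------------------------------------------------------------------

def compute_segment_features(
    rr: np.ndarray,
    t_end_s: np.ndarray,
    window_s: float,
    registry: FeatureRegistry,
    config: FeatureConfig,
) -> dict[str, float]:
    """All requested features of one windowed RR segment.

    Shared intermediates (histograms, spectra) are computed once per
    domain; undefined features are NaN.
    """
    wanted = set(registry.feature_ids)
    out: dict[str, float] = {}
    n = rr.size

    if n < config.min_beats:
        return {f: _NAN for f in registry.feature_ids}

    if wanted & set(TIME_FEATURES):
        td = time_domain_features(rr, config.min_beats)
        out.update({k: v for k, v in td.items() if k in wanted})
    if wanted & set(GEOMETRIC_FEATURES):
        gd = geometric_features(rr, config.ti_bin_ms, config.si_bin_ms, config.min_beats)
        out.update({k: v for k, v in gd.items() if k in wanted})
    if wanted & set(NONLINEAR_FEATURES):
        if "ApEn" in wanted:
            out["ApEn"] = approximate_entropy(
                rr, m=config.apen_m, r_factor=config.apen_r_factor
            )
        if "SD1" in wanted or "SD2" in wanted:
            sd1, sd2 = poincare_sd(rr, config.min_beats)
            if "SD1" in wanted:
                out["SD1"] = sd1
            if "SD2" in wanted:
                out["SD2"] = sd2
        if "PTM" in wanted:
            out["PTM"] = point_transition_measure(rr, config.min_beats)
        if "KFD" in wanted:
            out["KFD"] = katz_fd(rr, cap=config.kfd_cap, min_beats=config.min_beats)
        if "HFD" in wanted:
            kmax = config.kmax or min(8, (n - 1) // 2)
            out["HFD"] = higuchi_fd(rr, kmax=kmax) if kmax >= 2 else _NAN
    if wanted & set(FREQUENCY_FEATURES):
        if window_s < config.min_psd_window_s:
            spec = None
        else:
            spec = estimate_psd(
                rr, t_end_s, window_s, config.resample_hz, config.min_beats
            )
        ff = frequency_features(spec)
        out.update({k: v for k, v in ff.items() if k in wanted})
    return {f: out.get(f, _NAN) for f in registry.feature_ids}


@dataclass
class RunFeatures:
    """All feature vectors of one run: one per (feature, window) pair."""

    subject_id: str
    run_id: str
    vectors: dict[tuple[str, float], FeatureVector]
    grid: WindowGrid

    def vector(self, feature_id: str, window_s: float) -> FeatureVector:
        return self.vectors[(feature_id, float(window_s))]

    def __len__(self) -> int:
        return len(self.vectors)

    def to_frame(self):
        """Long-format table: subject, run, feature, window, center, value."""
        import pandas as pd

        rows = []
        for (feature_id, window_s), vec in self.vectors.items():
            for c, v in zip(vec.centers_s, vec.values):
                rows.append(
                    (self.subject_id, self.run_id, feature_id, window_s, c, v)
                )
        return pd.DataFrame(
            rows,
            columns=[
                "subject_id", "run_id", "feature_id", "window_s",
                "center_s", "value",
            ],
        )


def extract_all(
    series: RRSeries,
    grid: WindowGrid | None = None,
    registry: FeatureRegistry | None = None,
    config: FeatureConfig | None = None,
) -> RunFeatures:
    """Extract every (feature, window) vector of one run.

    On the default registry and grid this yields 31 x 18 = 558 feature
    vectors; windows longer than the run produce empty vectors (with a
    logged warning) so the count is invariant.  Undefined measurements
    are preserved positionally as NaN.
    """
    grid = grid or WindowGrid()
    registry = registry or FeatureRegistry()
    config = config or FeatureConfig()
    if len(registry) == 0:  # pragma: no cover - registry forbids empty
        raise ConfigurationError("empty feature registry")

    t = series.t_beats_s
    vectors: dict[tuple[str, float], FeatureVector] = {}
    n_undefined = 0
    for window_s in grid.sizes_s:
        centers, i0, i1 = segment_indices(t, window_s, grid.step_s)
        if centers.size == 0:
            log.warning(
                "run %s/%s: duration %.1f s < window %.0f s; empty vectors",
                series.subject_id, series.run_id, series.duration_s, window_s,
            )
        values = np.empty((len(registry), centers.size))
        for k in range(centers.size):
            seg_rr = series.rr_ms[i0[k]:i1[k]]
            seg_t = t[i0[k] + 1 : i1[k] + 1]
            feats = compute_segment_features(seg_rr, seg_t, window_s, registry, config)
            for fi, fid in enumerate(registry.feature_ids):
                values[fi, k] = feats[fid]
        n_undefined += int(np.sum(~np.isfinite(values)))
        for fi, fid in enumerate(registry.feature_ids):
            vectors[(fid, float(window_s))] = FeatureVector(
                feature_id=fid,
                window_s=float(window_s),
                centers_s=centers,
                values=values[fi],
                subject_id=series.subject_id,
                run_id=series.run_id,
            )
    if n_undefined:
        log.info(
            "run %s/%s: %d undefined feature values across all windows",
            series.subject_id, series.run_id, n_undefined,
        )
    return RunFeatures(
        subject_id=series.subject_id,
        run_id=series.run_id,
        vectors=vectors,
        grid=grid,
    )
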