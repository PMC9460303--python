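"""Sliding-window segmentation and feature-vector alignment.

Every feature is extracted with a sliding window of fixed duration that
advances by a 1-second hop; each measurement is stamped with the center
time of the RR stretch it was computed from.  The default grid spans
180 s down to 10 s in 10-s decrements (18 sizes); the 180-s vectors
serve as the reference ("gold standard") in the reliability analysis.

Window semantics
----------------
Placement ``k`` covers the half-open span ``[k*step, k*step + window)``
in run time.  An RR interval belongs to a placement iff its attributed
span ``(t_{i-1}, t_i]`` lies wholly inside — each interval is counted at
most once per placement and never split.  The number of placements on a
run of duration ``D`` is ``floor((D - window)/step) + 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .exceptions import AlignmentError, ConfigurationError
from .rr_model import RRSeries

__all__ = [
    "WindowGrid",
    "FeatureVector",
    "DEFAULT_SIZES_S",
    "window_sizes",
    "segment",
    "segment_indices",
    "align_to_reference",
]

log = logging.getLogger(__name__)

#: Default window durations: 180, 170, ..., 10 s (18 sizes).
DEFAULT_SIZES_S: tuple[float, ...] = tuple(float(s) for s in range(180, 0, -10))

_EPS = 1e-9


@dataclass(frozen=True)
class WindowGrid:
    """Ordered window durations plus the hop between placements."""

    sizes_s: tuple[float, ...] = DEFAULT_SIZES_S
    step_s: float = 1.0

    def __post_init__(self) -> None:
        sizes = tuple(float(s) for s in self.sizes_s)
        if len(sizes) == 0:
            raise ConfigurationError("WindowGrid needs at least one size")
        if any(s <= 0 for s in sizes):
            raise ConfigurationError(f"window sizes must be > 0, got {sizes}")
        if self.step_s <= 0:
            raise ConfigurationError("step_s must be > 0")
        object.__setattr__(self, "sizes_s", sizes)

    @property
    def reference_s(self) -> float:
        """The largest window (the reliability reference)."""
        return max(self.sizes_s)


def window_sizes(grid: WindowGrid | None = None) -> tuple[float, ...]:
    """Return the grid's window durations (default: 18 sizes, 180→10 s)."""
    return (grid or WindowGrid()).sizes_s


@dataclass
class FeatureVector:
    """One feature at one window size for one run: center times + values.

    Undefined measurements are NaN; they are excluded pairwise from all
    downstream statistics.
    """

    feature_id: str
    window_s: float
    centers_s: np.ndarray
    values: np.ndarray
    subject_id: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        self.centers_s = np.asarray(self.centers_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.centers_s.shape != self.values.shape:
            raise ConfigurationError(
                f"{self.feature_id}@{self.window_s}s: centers and values "
                f"lengths differ ({self.centers_s.size} vs {self.values.size})"
            )
        if self.centers_s.size > 1 and not np.all(np.diff(self.centers_s) > 0):
            raise ConfigurationError(
                f"{self.feature_id}@{self.window_s}s: centers must be "
                "strictly increasing"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def n_defined(self) -> int:
        return int(np.sum(np.isfinite(self.values)))


def _n_placements(duration_s: float, window_s: float, step_s: float) -> int:
    if duration_s < window_s - _EPS:
        return 0
    return int(np.floor((duration_s - window_s + _EPS) / step_s)) + 1


def segment_indices(
    t_beats_s: np.ndarray, window_s: float, step_s: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized placement bookkeeping.

    Returns ``(centers_s, i0, i1)`` where placement ``k`` holds RR
    intervals ``rr[i0[k]:i1[k]]`` — exactly those whose span
    ``(t_{i-1}, t_i]`` lies inside ``[k*step, k*step + window)``.
    """
    t = np.asarray(t_beats_s, dtype=float)
    duration = float(t[-1])
    n = _n_placements(duration, window_s, step_s)
    if n == 0:
        return np.empty(0), np.empty(0, dtype=int), np.empty(0, dtype=int)
    starts = np.arange(n) * step_s
    centers = starts + window_s / 2.0
    # interval i starts at t[i], ends at t[i+1]
    i0 = np.searchsorted(t[:-1], starts - _EPS, side="left")
    i1 = np.searchsorted(t[1:], starts + window_s - _EPS, side="left")
    return centers, i0, i1


def segment(
    series: RRSeries, window_s: float, step_s: float = 1.0
) -> list[tuple[float, np.ndarray]]:
    """Slice a run into sliding-window RR sub-sequences.

    Returns ``[(center_s, rr_subsequence), ...]``; empty (with a logged
    warning) when the run is shorter than the window, in which case the
    run simply contributes nothing at this window size.
    """
    if window_s <= 0 or step_s <= 0:
        raise ConfigurationError("window_s and step_s must be > 0")
    centers, i0, i1 = segment_indices(series.t_beats_s, window_s, step_s)
    if centers.size == 0:
        log.warning(
            "run %s/%s: duration %.1f s < window %.0f s; no placements",
            series.subject_id,
            series.run_id,
            series.duration_s,
            window_s,
        )
        return []
    return [
        (float(c), series.rr_ms[a:b]) for c, a, b in zip(centers, i0, i1)
    ]


def align_to_reference(
    short: FeatureVector, ref: FeatureVector
) -> tuple[np.ndarray, np.ndarray]:
    """Pair a shorter-window vector with the reference vector index-wise.

    Takes the portion of ``short`` whose centers fall within the
    reference's center range, pairing each reference center with the
    short-vector measurement at the same center time.  On the default
    grid all centers share the 1-s lattice exactly; for custom grids
    whose centers are offset by a half-step parity, the nearest short
    center is snapped (ties broken toward earlier time).

    Returns ``(short_values, ref_values)``, both of the reference's
    length.
    """
    if short.window_s > ref.window_s + _EPS:
        raise AlignmentError(
            f"short window {short.window_s}s exceeds reference {ref.window_s}s"
        )
    cs, cr = short.centers_s, ref.centers_s
    if cs.size == 0 or cr.size == 0:
        raise AlignmentError("cannot align empty feature vectors")
    if cs[-1] < cr[0] - _EPS or cs[0] > cr[-1] + _EPS:
        raise AlignmentError(
            f"no overlapping centers: short spans [{cs[0]}, {cs[-1]}] s, "
            f"reference spans [{cr[0]}, {cr[-1]}] s"
        )
    # nearest short center for each reference center, ties toward earlier
    right = np.searchsorted(cs, cr, side="left")
    left = np.clip(right - 1, 0, cs.size - 1)
    right = np.clip(right, 0, cs.size - 1)
    d_left = np.abs(cr - cs[left])
    d_right = np.abs(cs[right] - cr)
    idx = np.where(d_left <= d_right + _EPS, left, right)
    dist = np.abs(cs[idx] - cr)
    max_snap = short_step = _infer_step(cs) / 2.0
    if np.any(dist > max_snap + _EPS):
        raise AlignmentError(
            "reference centers fall outside the short vector's grid "
            f"(max offset {dist.max():.3f} s > half-step {max_snap:.3f} s)"
        )
    return short.values[idx].copy(), ref.values.copy()


def _infer_step(centers: np.ndarray) -> float:
    if centers.size < 2:
        return 1.0
    return float(np.min(np.diff(centers)))
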