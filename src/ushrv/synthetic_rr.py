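"""Synthetic RR-series generator.

Emulates the kind of study the reliability analysis targets: ~21
subjects with up to 4 runs each, run durations of roughly 200-900 s,
mean RR around 600-1100 ms, with low-frequency (0.04-0.15 Hz) and
high-frequency (0.15-0.4 Hz) oscillatory modulation, additive beat-wise
noise, and optional piecewise parameter shifts emulating changes in
cognitive load.

The generator uses beat-domain sinusoidal modulation: each interval is

    rr_i = mean_rr + amp_lf * sin(2*pi*f_lf*t_{i-1})
                   + amp_hf * sin(2*pi*f_hf*t_{i-1}) + eps_i,

with ``eps_i ~ Normal(0, noise_sd^2)`` and ``t_i = t_{i-1} + rr_i/1000``.
This is an auditable approximation of integral-pulse-frequency
modulation: it places spectral peaks at the configured frequencies,
which is what the downstream frequency-domain features need, without
modelling full cardiac pacemaker physiology.  Intervals at or below a
250 ms physiological floor are resampled (and counted in the debug log).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError
from .rr_model import RRSeries, StudySet

__all__ = [
    "GenSegment",
    "GenConfig",
    "generate_rr",
    "generate_study",
    "default_segment",
    "default_config",
    "config_to_dict",
    "config_from_dict",
]

log = logging.getLogger(__name__)

RR_FLOOR_MS = 250.0
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass(frozen=True)
class GenSegment:
    """One stationary stretch of simulated autonomic state.

    ``check_bands=False`` permits modulation frequencies outside the
    conventional LF/HF bands (useful for fixtures); feasibility checks
    always apply.
    """

    duration_s: float
    mean_rr_ms: float = 800.0
    amp_lf_ms: float = 30.0
    f_lf_hz: float = 0.10
    amp_hf_ms: float = 25.0
    f_hf_hz: float = 0.25
    noise_sd_ms: float = 15.0
    check_bands: bool = True

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("segment duration_s must be > 0")
        if self.mean_rr_ms <= 0:
            raise ConfigurationError("mean_rr_ms must be > 0")
        if min(self.amp_lf_ms, self.amp_hf_ms, self.noise_sd_ms) < 0:
            raise ConfigurationError("amplitudes and noise_sd must be >= 0")
        if self.mean_rr_ms <= (
            self.amp_lf_ms + self.amp_hf_ms + 5.0 * self.noise_sd_ms
        ):
            raise ConfigurationError(
                "mean_rr_ms must exceed amp_lf + amp_hf + 5*noise_sd; the "
                "configuration admits no reliably positive RR interval"
            )
        if self.check_bands:
            if self.amp_lf_ms > 0 and not (LF_BAND[0] <= self.f_lf_hz <= LF_BAND[1]):
                raise ConfigurationError(
                    f"f_lf_hz={self.f_lf_hz} outside the LF band {LF_BAND}; "
                    "pass check_bands=False to override"
                )
            if self.amp_hf_ms > 0 and not (HF_BAND[0] <= self.f_hf_hz <= HF_BAND[1]):
                raise ConfigurationError(
                    f"f_hf_hz={self.f_hf_hz} outside the HF band {HF_BAND}; "
                    "pass check_bands=False to override"
                )


@dataclass(frozen=True)
class GenConfig:
    """Ordered segments (>= 1) plus the run's seed.

    Multiple segments emulate cognitive-state shifts within a run; the
    total run duration is the sum of segment durations.
    """

    segments: tuple[GenSegment, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ConfigurationError("GenConfig needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def total_duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))


def default_segment(duration_s: float = 600.0, **overrides) -> GenSegment:
    """The study-condition segment: mean RR 800 ms, LF 30 ms @ 0.10 Hz,
    HF 25 ms @ 0.25 Hz, beat noise 15 ms."""
    return GenSegment(duration_s=duration_s, **overrides)


def default_config(duration_s: float = 600.0, seed: int = 0, **overrides) -> GenConfig:
    return GenConfig(segments=(default_segment(duration_s, **overrides),), seed=seed)


def generate_rr(
    config: GenConfig, subject_id: str = "S01", run_id: str = "R1"
) -> RRSeries:
    """Generate one run by the beat-by-beat recursion.

    Generation of a segment stops once the cumulative run time exceeds
    that segment's budget; an identical seed always yields an identical
    series.
    """
    rng = np.random.default_rng(config.seed)
    rr: list[float] = []
    t = 0.0
    resampled = 0
    for seg in config.segments:
        budget = t + seg.duration_s
        while t < budget - 1e-12:
            base = (
                seg.mean_rr_ms
                + seg.amp_lf_ms * np.sin(2.0 * np.pi * seg.f_lf_hz * t)
                + seg.amp_hf_ms * np.sin(2.0 * np.pi * seg.f_hf_hz * t)
            )
            value = base + rng.normal(0.0, seg.noise_sd_ms) if seg.noise_sd_ms else base
            attempts = 0
            while value <= RR_FLOOR_MS:
                resampled += 1
                attempts += 1
                if attempts > 1000:
                    raise ConfigurationError(
                        "could not draw an RR interval above the 250 ms floor"
                    )
                value = base + rng.normal(0.0, seg.noise_sd_ms)
            rr.append(float(value))
            t += value / 1000.0
    if resampled:
        log.debug(
            "run %s/%s: resampled %d sub-floor RR draws", subject_id, run_id, resampled
        )
    return RRSeries(subject_id=subject_id, run_id=run_id, rr_ms=np.asarray(rr))


def _derived_seed(master_seed: int, *labels: str) -> np.random.SeedSequence:
    """Stable per-entity seed: hash the labels, mix with the master seed."""
    digest = zlib.crc32("|".join(labels).encode())
    return np.random.SeedSequence([int(master_seed), digest])


def generate_study(
    n_subjects: int = 21,
    runs_per_subject: int = 4,
    duration_range_s: tuple[float, float] = (200.0, 900.0),
    seed: int = 0,
    base: GenConfig | GenSegment | None = None,
    subject_mean_jitter_ms: float = 60.0,
    amp_jitter_frac: float = 0.2,
) -> StudySet:
    """Generate a whole study with per-subject physiology jitter.

    One master seed deterministically derives per-subject and per-run
    seeds (by hashing the labels), so studies are reproducible while
    runs stay statistically independent.  Durations are uniform in
    ``duration_range_s``; each subject gets a jittered mean RR
    (Normal sd ``subject_mean_jitter_ms``, clipped to 600-1100 ms) and
    jittered LF/HF amplitudes (uniform ±``amp_jitter_frac``).
    """
    if n_subjects < 1 or runs_per_subject < 1:
        raise ConfigurationError("counts must be >= 1")
    lo, hi = duration_range_s
    if hi < lo or lo <= 0:
        raise ConfigurationError(f"invalid duration range {duration_range_s}")
    if base is None:
        base = default_segment(duration_s=1.0)
    if isinstance(base, GenSegment):
        base = GenConfig(segments=(base,), seed=0)

    runs: list[RRSeries] = []
    for si in range(1, n_subjects + 1):
        subject_id = f"S{si:02d}"
        subj_rng = np.random.default_rng(_derived_seed(seed, subject_id))
        mean_delta = float(subj_rng.normal(0.0, subject_mean_jitter_ms))
        amp_scale = float(subj_rng.uniform(1 - amp_jitter_frac, 1 + amp_jitter_frac))
        for ri in range(1, runs_per_subject + 1):
            run_id = f"R{ri}"
            run_ss = _derived_seed(seed, subject_id, run_id)
            run_rng = np.random.default_rng(run_ss)
            duration = float(run_rng.uniform(lo, hi))
            total = sum(s.duration_s for s in base.segments)
            segments = tuple(
                replace(
                    s,
                    duration_s=duration * s.duration_s / total,
                    mean_rr_ms=float(np.clip(s.mean_rr_ms + mean_delta, 600.0, 1100.0)),
                    amp_lf_ms=s.amp_lf_ms * amp_scale,
                    amp_hf_ms=s.amp_hf_ms * amp_scale,
                )
                for s in base.segments
            )
            run_seed = int(run_ss.generate_state(1)[0] % (2**31))
            config = GenConfig(segments=segments, seed=run_seed)
            runs.append(generate_rr(config, subject_id, run_id))
    return StudySet(
        runs=runs,
        provenance=(
            f"synthetic: n_subjects={n_subjects} runs_per_subject={runs_per_subject} "
            f"duration_range={duration_range_s} seed={seed}"
        ),
    )


def config_to_dict(config: GenConfig) -> dict:
    """Serialize a GenConfig to plain types (YAML/JSON friendly)."""
    return {
        "seed": config.seed,
        "segments": [asdict(s) for s in config.segments],
    }


def config_from_dict(payload: dict) -> GenConfig:
    segments = tuple(GenSegment(**s) for s in payload.get("segments", []))
    return GenConfig(segments=segments, seed=int(payload.get("seed", 0)))
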