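import numpy as np
import pytest

from ushrv import (
    FeatureConfig,
    FeatureRegistry,
    GenConfig,
    GenSegment,
    RRSeries,
    WindowGrid,
    default_config,
    extract_all,
    generate_rr,
)


@pytest.fixture(scope="session")
def constant_series() -> RRSeries:
    """250 identical 800-ms intervals (200 s)."""
    return RRSeries("S01", "R1", np.full(250, 800.0))


@pytest.fixture(scope="session")
def noisy_run() -> RRSeries:
    """A 200-s run with the default LF/HF modulation and noise."""
    return generate_rr(default_config(200.0, seed=11), "S01", "R1")


@pytest.fixture(scope="session")
def lf_run() -> RRSeries:
    """A 300-s run dominated by a 0.10-Hz LF oscillation."""
    cfg = GenConfig(
        segments=(
            GenSegment(
                duration_s=300.0, mean_rr_ms=800.0, amp_lf_ms=50.0,
                f_lf_hz=0.10, amp_hf_ms=0.0, noise_sd_ms=5.0,
            ),
        ),
        seed=21,
    )
    return generate_rr(cfg, "S01", "R1")


@pytest.fixture(scope="session")
def noisy_features(noisy_run):
    """Full 31x18 extraction of the 200-s noisy run (shared: expensive)."""
    return extract_all(noisy_run)
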