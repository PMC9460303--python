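import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ushrv import (
    FeatureRegistry,
    WindowGrid,
    band_period_s,
    extract_all,
)
from ushrv.feature_bank import (
    FREQUENCY_FEATURES,
    GEOMETRIC_FEATURES,
    NONLINEAR_FEATURES,
    TIME_FEATURES,
    approximate_entropy,
    estimate_psd,
    frequency_features,
    geometric_features,
    higuchi_fd,
    katz_fd,
    poincare_sd,
    point_transition_measure,
    time_domain_features,
)

ALTERNATING = [800.0, 860.0, 800.0, 860.0]


def _naive_time_domain(rr):
    """Loop-based oracle for the six time-domain features."""
    n = len(rr)
    mean = sum(rr) / n
    sdnn = math.sqrt(sum((x - mean) ** 2 for x in rr) / (n - 1))
    d = [rr[i + 1] - rr[i] for i in range(n - 1)]
    dm = sum(d) / len(d)
    sdsd = math.sqrt(sum((x - dm) ** 2 for x in d) / (len(d) - 1))
    rmssd = math.sqrt(sum(x**2 for x in d) / len(d))
    nn50 = sum(1 for x in d if abs(x) > 50)
    return mean, sdnn, sdsd, rmssd, nn50, 100.0 * nn50 / (n - 1)


class TestRegistry:
    def test_partition_is_6_3_6_16(self):
        reg = FeatureRegistry()
        assert len(reg) == 31
        assert reg.domains == {"time": 6, "geometric": 3, "nonlinear": 6,
                               "frequency": 16}

    def test_band_edge_periods(self):
        # slowest LF oscillation: 25-s period; fastest: ~6.7 s — why
        # very short windows cannot hold a full low-frequency cycle
        assert band_period_s(0.04) == pytest.approx(25.0)
        assert band_period_s(0.15) == pytest.approx(6.7, abs=0.05)


class TestTimeDomain:
    def test_constant_segment(self):
        f = time_domain_features([800.0] * 4)
        assert f["mNN"] == 800 and f["SDNN"] == 0 and f["SDSD"] == 0
        assert f["RMSSD"] == 0 and f["NN50"] == 0 and f["pNN50"] == 0

    def test_alternating_hand_values(self):
        f = time_domain_features(ALTERNATING)
        assert f["mNN"] == pytest.approx(830.0)
        assert f["NN50"] == 3
        assert f["pNN50"] == pytest.approx(100.0)
        assert f["RMSSD"] == pytest.approx(60.0)
        assert f["SDSD"] == pytest.approx(69.282, abs=1e-3)

    def test_matches_naive_oracle_on_random_segment(self):
        rng = np.random.default_rng(2)
        rr = rng.uniform(600, 1100, size=100)
        f = time_domain_features(rr)
        oracle = _naive_time_domain(list(rr))
        for key, expect in zip(TIME_FEATURES, oracle):
            assert f[key] == pytest.approx(expect, rel=1e-9)

    def test_rmssd_sdsd_identity(self):
        # RMSSD^2 = ((N-2)/(N-1)) SDSD^2 + mean(d)^2
        rng = np.random.default_rng(3)
        rr = rng.uniform(600, 1100, size=57)
        f = time_domain_features(rr)
        d = np.diff(rr)
        m = d.size
        assert f["RMSSD"] ** 2 == pytest.approx(
            (m - 1) / m * f["SDSD"] ** 2 + d.mean() ** 2, rel=1e-9
        )

    def test_short_segment_undefined(self):
        assert all(math.isnan(v) for v in time_domain_features([800.0] * 3).values())


class TestGeometric:
    def test_identical_intervals(self):
        f = geometric_features([800.0] * 10)
        assert f["TI"] == pytest.approx(1.0)
        assert f["TINN"] == 0.0
        assert math.isnan(f["SI"])

    def test_stress_index_hand_value(self):
        # Mo = 0.8 s, AMo = 60 %, MxDMn = 0.2 s -> SI = 60/(2*0.8*0.2)
        f = geometric_features([700.0, 800.0, 800.0, 800.0, 900.0])
        assert f["SI"] == pytest.approx(187.5)

    def test_triangular_base_width_on_symmetric_histogram(self):
        # triangular RR distribution spanning 700-900 ms
        rng = np.random.default_rng(5)
        rr = rng.triangular(700, 800, 900, size=4000)
        f = geometric_features(rr)
        assert abs(f["TINN"] - 200.0) <= 2 * (1000.0 / 128.0)

    def test_ti_equals_n_over_modal_count(self):
        rr = [700.0, 800.0, 800.0, 800.0, 900.0]
        assert geometric_features(rr)["TI"] == pytest.approx(5 / 3)


class TestPoincare:
    def test_constant_segment(self):
        assert poincare_sd([800.0] * 10) == (0.0, 0.0)

    def test_sd1_is_sdsd_over_sqrt2(self):
        f = time_domain_features(ALTERNATING)
        sd1, sd2 = poincare_sd(ALTERNATING)
        assert sd1 == pytest.approx(f["SDSD"] / math.sqrt(2), rel=1e-12)
        assert sd1 == pytest.approx(48.99, abs=0.01)
        # SD2 from the rotated coordinates directly
        v = (np.array(ALTERNATING[1:]) + np.array(ALTERNATING[:-1])) / math.sqrt(2)
        assert sd2 == pytest.approx(float(np.std(v, ddof=1)), rel=1e-12)

    @given(st.lists(st.floats(300, 2000), min_size=4, max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_sd1_identity_holds_generally(self, rr):
        sd1, _ = poincare_sd(rr)
        sdsd = time_domain_features(rr)["SDSD"]
        assert sd1 == pytest.approx(sdsd / math.sqrt(2), rel=1e-9, abs=1e-9)


class TestApproximateEntropy:
    def test_constant_segment_is_zero(self):
        assert approximate_entropy([800.0] * 20) == pytest.approx(0.0, abs=1e-12)

    def test_periodic_alternation_is_regular(self):
        rr = [800.0, 860.0] * 50
        assert approximate_entropy(rr) < 0.2

    def test_noise_more_irregular_than_periodic(self):
        rng = np.random.default_rng(6)
        noise = 800 + rng.normal(0, 30, size=200)
        periodic = [800.0, 860.0] * 100
        assert approximate_entropy(noise) > approximate_entropy(periodic)

    def test_negative_tolerance_rejected(self):
        from ushrv.exceptions import ConfigurationError

        with pytest.raises(ConfigurationError):
            approximate_entropy([800.0] * 10, r=-1.0)


class TestPointTransitionMeasure:
    def test_constant_segment(self):
        assert point_transition_measure([800.0] * 10) == 0.0

    def test_alternating_hand_value(self):
        # every Poincare step is (±60, ∓60): length 60*sqrt(2)
        assert point_transition_measure(ALTERNATING) == pytest.approx(
            60 * math.sqrt(2), abs=1e-9
        )

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        rr = rng.uniform(600, 1100, 50)
        assert point_transition_measure(rr) == pytest.approx(
            point_transition_measure(rr + 123.4), rel=1e-12
        )


class TestFractalDimensions:
    def test_kfd_ramp_is_one(self):
        assert katz_fd([800.0, 810.0, 820.0, 830.0, 840.0]) == 1.0

    def test_kfd_degenerate_denominator_capped(self):
        # L=240, d=60, n=4: log10(n)+log10(d/L) = 0 -> guard kicks in
        assert katz_fd([800.0, 860.0, 800.0, 860.0, 800.0], cap=10.0) == 10.0

    def test_kfd_constant_undefined(self):
        assert math.isnan(katz_fd([800.0] * 10))

    def test_kfd_noise_exceeds_ramp(self):
        rng = np.random.default_rng(9)
        noise = 800 + rng.normal(0, 30, 200)
        ramp = 800 + np.arange(200.0)
        assert katz_fd(noise) > katz_fd(ramp)

    def test_hfd_line_is_one(self):
        assert higuchi_fd(800 + np.arange(100.0)) == pytest.approx(1.0, abs=0.05)

    def test_hfd_white_noise_near_two(self):
        rng = np.random.default_rng(10)
        assert 1.7 <= higuchi_fd(rng.normal(0, 30, 400)) <= 2.05

    def test_hfd_affine_invariance(self):
        rng = np.random.default_rng(11)
        x = rng.normal(800, 30, 300)
        assert higuchi_fd(3.0 * x + 100.0) == pytest.approx(higuchi_fd(x), abs=1e-6)

    def test_hfd_kmax_guard(self):
        from ushrv.exceptions import ConfigurationError

        with pytest.raises(ConfigurationError):
            higuchi_fd([800.0, 810.0, 820.0], kmax=1)


def _sinusoid_segment(f_hz, amp_ms=40.0, duration_s=185.0, mean_ms=800.0):
    """Beat-recursion tachogram with one pure oscillation."""
    rr, t = [], 0.0
    while t < duration_s:
        v = mean_ms + amp_ms * math.sin(2 * math.pi * f_hz * t)
        rr.append(v)
        t += v / 1000.0
    rr = np.array(rr)
    t_end = np.cumsum(rr) / 1000.0
    return rr, t_end


class TestSpectral:
    def test_constant_segment_has_no_power(self):
        rr = np.full(230, 800.0)
        spec = estimate_psd(rr, np.cumsum(rr) / 1000.0, 180.0)
        assert np.all(spec.psd <= 1e-6)

    def test_pure_hf_sinusoid_peaks_at_its_frequency(self):
        rr, t_end = _sinusoid_segment(0.25)
        spec = estimate_psd(rr, t_end, 180.0)
        df = spec.freqs_hz[1] - spec.freqs_hz[0]
        peak = spec.freqs_hz[np.argmax(spec.psd)]
        assert abs(peak - 0.25) <= df + 1e-12

    def test_parseval_total_power(self):
        # integrated psd ~ variance of the sinusoid (= amp^2/2) within
        # taper leakage
        rr, t_end = _sinusoid_segment(0.25, amp_ms=40.0)
        spec = estimate_psd(rr, t_end, 180.0)
        total = np.trapezoid(spec.psd, spec.freqs_hz)
        assert total == pytest.approx(40.0**2 / 2, rel=0.10)

    def test_hf_fixture_features(self):
        rr, t_end = _sinusoid_segment(0.25)
        f = frequency_features(estimate_psd(rr, t_end, 180.0))
        assert f["HFpeak"] == pytest.approx(0.25, abs=0.01)
        assert f["HFnu"] > 80.0
        assert f["LF_HF"] < 0.25
        assert f["Peak"] == f["HFpeak"]

    def test_lf_fixture_features(self):
        rr, t_end = _sinusoid_segment(0.10)
        f = frequency_features(estimate_psd(rr, t_end, 180.0))
        assert f["LFpeak"] == pytest.approx(0.10, abs=0.01)
        assert f["Peak"] == f["LFpeak"]
        assert f["LFpeak_HFpeak"] == pytest.approx(f["LFpeak"] / f["HFpeak"])

    def test_normalized_band_powers_sum_to_100(self):
        rr, t_end = _sinusoid_segment(0.10, amp_ms=30.0)
        rng = np.random.default_rng(12)
        rr = rr + rng.normal(0, 10, rr.size)
        f = frequency_features(estimate_psd(rr, np.cumsum(rr) / 1000.0, 180.0))
        assert f["VLFnu"] + f["LFnu"] + f["HFnu"] == pytest.approx(100.0, abs=1e-6)

    def test_band_peaks_inside_their_bands(self):
        rr, t_end = _sinusoid_segment(0.10, amp_ms=30.0)
        f = frequency_features(estimate_psd(rr, t_end, 180.0))
        assert 0 < f["VLFpeak"] <= 0.04
        assert 0.04 < f["LFpeak"] <= 0.15
        assert 0.15 < f["HFpeak"] <= 0.40

    def test_very_short_window_drops_vlf(self):
        rr, t_end = _sinusoid_segment(0.25, duration_s=12.0)
        f = frequency_features(estimate_psd(rr[:14], t_end[:14], 10.0))
        assert math.isnan(f["VLF"])  # 1/10 Hz floor is above the VLF edge


class TestExtractAll:
    def test_grid_restricted_to_reference_gives_31_vectors(self, noisy_run):
        feats = extract_all(noisy_run, grid=WindowGrid(sizes_s=(180.0,)))
        assert len(feats) == 31

    def test_constant_run_propagates_constants_and_markers(self, constant_series):
        feats = extract_all(
            constant_series,
            grid=WindowGrid(sizes_s=(180.0,)),
            registry=FeatureRegistry().subset(["mNN", "SI"]),
        )
        assert np.all(feats.vector("mNN", 180.0).values == 800.0)
        assert np.all(np.isnan(feats.vector("SI", 180.0).values))

    def test_translation_covariance_of_mnn(self):
        rng = np.random.default_rng(13)
        rr = rng.uniform(700, 900, 100)
        a = time_domain_features(rr)
        b = time_domain_features(rr + 50.0)
        assert b["mNN"] == pytest.approx(a["mNN"] + 50.0)
        for inv in ("SDNN", "SDSD", "RMSSD"):
            assert b[inv] == pytest.approx(a[inv], rel=1e-9)
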