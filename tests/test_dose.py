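"""Reduced-dose simulation: noise scaling law, noise texture, frame dropping."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctperf import (
    DegenerateSeriesError,
    DynamicSeries,
    GROUP_PROTOCOLS,
    InvalidInputError,
    NoisePlan,
    ReductionSpec,
    added_noise_sd,
    autocorrelated_noise_field,
    build_phantom,
    downsample_temporal,
    measure_roi_noise,
    study_protocol_grid,
    simulate_reduced_dose,
)


class TestAddedNoiseSd:
    @pytest.mark.parametrize(
        "sd_e1, e1, e2, expected",
        [
            (7.81, 100.0, 100.0, 0.0),          # no reduction, nothing to add
            (7.81, 100.0, 60.0, 6.3771),        # group A, 40% reduction
            (6.09, 180.0, 108.0, 4.9723),       # group B, 40% reduction
        ],
    )
    def test_quadrature_law(self, sd_e1, e1, e2, expected):
        # oracle: SD(E2) = SD(E1)*sqrt(E1/E2); SD(E3) = sqrt(SD(E2)^2 - SD(E1)^2)
        assert added_noise_sd(sd_e1, e1, e2) == pytest.approx(expected, abs=1e-3)
        sd_e2 = sd_e1 * np.sqrt(e1 / e2)
        assert added_noise_sd(sd_e1, e1, e2) == pytest.approx(
            np.sqrt(sd_e2**2 - sd_e1**2), rel=1e-12
        )

    def test_cannot_remove_noise(self):
        with pytest.raises(InvalidInputError):
            added_noise_sd(5.0, 100.0, 120.0)
        with pytest.raises(InvalidInputError):
            added_noise_sd(5.0, 100.0, 0.0)

    @given(st.floats(0.01, 0.9), st.floats(0.01, 0.9))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_reduction_fraction(self, r1, r2):
        lo, hi = sorted((r1, r2))
        sd_lo = added_noise_sd(7.81, 100.0, 100.0 * (1 - lo))
        sd_hi = added_noise_sd(7.81, 100.0, 100.0 * (1 - hi))
        assert sd_hi >= sd_lo
        assert added_noise_sd(7.81, 100.0, 100.0) == 0.0


class TestNoisePlan:
    def test_inconsistent_sd_e3_rejected(self):
        with pytest.raises(InvalidInputError):
            NoisePlan(e1=100.0, e2=60.0, sd_e1=7.81, sd_e3=1.0)

    def test_from_reduction(self):
        plan = NoisePlan.from_reduction(7.81, 100.0, 0.40, seed=3)
        assert plan.e2 == pytest.approx(60.0)
        assert plan.sd_e3 == pytest.approx(6.377, abs=1e-3)


class TestMeasureRoiNoise:
    def test_constant_roi_is_zero(self, clean_phantom):
        series, truth = clean_phantom
        roi = truth.region_mask("normal_wm")
        assert measure_roi_noise(series, roi, 0) == 0.0

    def test_sample_sd_uses_n_minus_1(self, group_a):
        series, truth = build_phantom(group_a, baseline_noise_sd=0.0, shape=(16, 16, 1))
        data = series.data.copy()
        roi = np.zeros((16, 16, 1), dtype=bool)
        roi[0, :5, 0] = True
        data[0, :5, 0, 0] = [1, 2, 3, 4, 5]
        series2 = DynamicSeries(data, series.time, series.voxel_dims, series.protocol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny ROI warning is expected
            sd = measure_roi_noise(series2, roi, 0)
        assert sd == pytest.approx(np.sqrt(2.5))

    def test_recovers_group_a_noise_level(self, group_a):
        series, truth = build_phantom(
            group_a, baseline_noise_sd=7.81, shape=(96, 96, 1), seed=9
        )
        roi = truth.region_mask("background")
        assert roi.sum() >= 1000
        assert measure_roi_noise(series, roi, 0) == pytest.approx(7.81, rel=0.10)

    def test_empty_roi_rejected(self, clean_phantom):
        series, _ = clean_phantom
        with pytest.raises(InvalidInputError):
            measure_roi_noise(series, np.zeros(series.spatial_shape, bool), 0)


class TestAutocorrelatedNoiseField:
    def test_zero_target_gives_zero_field(self):
        assert np.all(autocorrelated_noise_field((64, 64), 1.5, 0.0, seed=1) == 0)

    def test_exact_rescaling(self):
        f = autocorrelated_noise_field((256, 256), 1.5, 6.377, seed=7)
        assert f.std() == pytest.approx(6.377, rel=1e-9)
        assert abs(f.mean()) < 3 * 6.377 / np.sqrt(f.size)

    def test_lag1_spatial_autocorrelation(self):
        f = autocorrelated_noise_field((256, 256), 1.5, 5.0, seed=2)
        r = np.corrcoef(f[:-1].ravel(), f[1:].ravel())[0, 1]
        assert r > 0.3
        white = autocorrelated_noise_field((256, 256), 0.0, 5.0, seed=2)
        rw = np.corrcoef(white[:-1].ravel(), white[1:].ravel())[0, 1]
        assert abs(rw) < 0.05

    def test_deterministic(self):
        a = autocorrelated_noise_field((32, 32), 1.5, 3.0, seed=4)
        b = autocorrelated_noise_field((32, 32), 1.5, 3.0, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_negative_sd_rejected(self):
        with pytest.raises(InvalidInputError):
            autocorrelated_noise_field((8, 8), 1.0, -1.0)


class TestSimulateReducedDose:
    def test_no_reduction_is_bit_exact(self, noisy_phantom):
        series, _ = noisy_phantom
        plan = NoisePlan.from_reduction(7.81, 100.0, 0.0, seed=1)
        out = simulate_reduced_dose(series, plan)
        np.testing.assert_array_equal(out.data, series.data)
        assert out.protocol.tube_load == 100.0

    def test_difference_image_sd_matches_plan(self, group_a):
        series, _ = build_phantom(group_a, baseline_noise_sd=7.81, shape=(64, 64, 2), seed=0)
        plan = NoisePlan.from_reduction(7.81, 100.0, 0.40, seed=5)
        out = simulate_reduced_dose(series, plan)
        diff_sd = np.std(out.data - series.data)
        assert out.protocol.tube_load == pytest.approx(60.0)
        assert diff_sd == pytest.approx(plan.sd_e3, rel=0.02)
        assert diff_sd == pytest.approx(6.377, rel=0.02)

    def test_noise_scaling_law_in_composite_image(self, group_a):
        # homogeneous background of the composite image carries SD(E2) = SD(E1)*sqrt(E1/E2)
        series, truth = build_phantom(group_a, baseline_noise_sd=7.81, shape=(128, 128, 2), seed=1)
        plan = NoisePlan.from_reduction(7.81, 100.0, 0.40, seed=6)
        out = simulate_reduced_dose(series, plan)
        bg = truth.region_mask("background")
        assert bg.sum() * series.n_frames >= 1e5
        sd = np.std(out.data[bg], ddof=1)
        assert sd == pytest.approx(7.81 * np.sqrt(100 / 60), rel=0.02)

    def test_mismatched_tube_load_rejected(self, noisy_phantom):
        series, _ = noisy_phantom
        plan = NoisePlan.from_reduction(7.81, 180.0, 0.40, seed=1)
        with pytest.raises(InvalidInputError):
            simulate_reduced_dose(series, plan)

    def test_deterministic(self, noisy_phantom):
        series, _ = noisy_phantom
        plan = NoisePlan.from_reduction(7.81, 100.0, 0.30, seed=8)
        a = simulate_reduced_dose(series, plan)
        b = simulate_reduced_dose(series, plan)
        np.testing.assert_array_equal(a.data, b.data)


class TestDownsampleTemporal:
    def test_half_sampling_of_group_a(self, clean_phantom):
        series, _ = clean_phantom  # 50 frames at 1 s
        out = downsample_temporal(series, 2, 0)
        assert out.n_frames == 25
        assert out.protocol.sampling_interval == 2.0
        np.testing.assert_array_equal(out.data, series.data[..., ::2])

    def test_identity(self, clean_phantom):
        series, _ = clean_phantom
        out = downsample_temporal(series, 1)
        np.testing.assert_array_equal(out.data, series.data)
        assert out.protocol == series.protocol

    def test_third_sampling_of_35_frames(self):
        proto = GROUP_PROTOCOLS["C"]  # 35 frames at 1.25 s
        series, _ = build_phantom(proto, baseline_noise_sd=0.0, shape=(12, 12, 1))
        out = downsample_temporal(series, 3, 0)
        assert out.n_frames == 12  # ceil(35/3)
        assert out.protocol.sampling_interval == pytest.approx(3.75)

    def test_phase_offsets_select_distinct_frames(self, clean_phantom):
        series, _ = clean_phantom
        a = downsample_temporal(series, 2, 0)
        b = downsample_temporal(series, 2, 1)
        assert a.time[0] == 0.0 and b.time[0] == 1.0

    def test_composition_k2_twice_equals_k4(self, clean_phantom):
        series, _ = clean_phantom
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # K=4 is beyond the studied range
            twice = downsample_temporal(downsample_temporal(series, 2, 0), 2, 0)
            once = downsample_temporal(series, 4, 0)
        np.testing.assert_array_equal(twice.data, once.data)
        np.testing.assert_array_equal(twice.time, once.time)

    def test_too_few_frames_rejected(self, clean_phantom):
        series, _ = clean_phantom
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(DegenerateSeriesError):
                downsample_temporal(series, 9, 0)  # 50 frames -> 6 remain


def test_study_grid_enumerates_8_distinct_protocols(clean_phantom):
    series, _ = clean_phantom
    grid = study_protocol_grid()
    assert len(grid) == len(set(grid)) == 8
    assert {s.mas_reduction for s in grid} == {0.10, 0.20, 0.30, 0.40}
    assert {s.sampling_keep for s in grid} == {2, 3}
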