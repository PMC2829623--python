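import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.ndimage import distance_transform_edt, gaussian_filter

import myotrace as mt
from myotrace.tv_smoothing import (
    SmoothingParams,
    SmoothingState,
    _central_gradient,
    estimate_noise_variance,
    tv_step,
)


def _state(u, u0=None, fidelity=True):
    u0 = u if u0 is None else u0
    st_ = SmoothingState(
        u=u.copy(), u0=u0, grad_u0=_central_gradient(u0), fidelity=fidelity
    )
    st_.sigma2 = estimate_noise_variance(st_.u)
    return st_


class TestNoiseVariance:
    def test_constant_image_gives_zero(self):
        assert estimate_noise_variance(np.full((32, 32), 0.5)) == 0.0

    def test_bias_corrected_estimate_recovers_injected_variance(self):
        # var(u) - var(G*u) removes edge variance too; the noise part is
        # isolated by subtracting the clean-image baseline.
        video = mt.render_video(
            mt.CellModel(),
            mt.TwitchProtocol(duration=1 / 30, amplitude=0.0, noise_sigma=0.0, seed=0),
            shape=(256, 256),
        )
        clean = video.sequence.frames[0]
        rng = np.random.default_rng(5)
        noise = rng.normal(0.0, np.sqrt(0.001), clean.shape)
        est = estimate_noise_variance(clean + noise) - estimate_noise_variance(clean)
        assert est == pytest.approx(noise.var(), rel=0.30)

    def test_blurring_reduces_the_estimate_for_pure_noise(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            u = rng.uniform(0, 1, (48, 48))
            blurred = gaussian_filter(u, 1.0, mode="nearest", truncate=3.0)
            assert estimate_noise_variance(blurred) <= estimate_noise_variance(u)


class TestTvStep:
    def test_constant_image_is_a_fixed_point(self):
        u = np.full((16, 16), 0.3)
        out = tv_step(_state(u), SmoothingParams())
        np.testing.assert_array_equal(out.u, u)

    def test_lambda_zero_on_first_iteration(self):
        # u = u0 means the gradient residual of the fidelity weight vanishes
        rng = np.random.default_rng(0)
        u = rng.uniform(0, 1, (24, 24))
        st_ = _state(u)
        st_.sigma2 = 0.01
        out = tv_step(st_, SmoothingParams())
        np.testing.assert_array_equal(out.lambda_map, 0.0)

    def test_time_step_hits_bounds_at_gradient_extremes(self):
        params = SmoothingParams()
        u = np.full((20, 20), 0.8)
        u[8:12, 8:12] = 0.2  # sharp block: max gradient at its border
        out = tv_step(_state(u), params)
        dt = out.dt_map
        assert dt.min() >= params.dt_min - 1e-15
        assert dt.max() <= params.dt_max + 1e-15
        ux, uy = _central_gradient(u)
        gmag = np.hypot(ux, uy)
        assert dt[gmag == gmag.max()] == pytest.approx(params.dt_min)
        assert dt[gmag == 0.0] == pytest.approx(1.0 / 4.0)  # 1/(2d), d = 2

    def test_sigma2_zero_takes_a_pure_smoothing_step(self):
        rng = np.random.default_rng(1)
        u = rng.uniform(0, 1, (16, 16))
        st_ = _state(u, u0=np.zeros_like(u))  # nonzero residual
        st_.sigma2 = 0.0
        out = tv_step(st_, SmoothingParams())
        np.testing.assert_array_equal(out.lambda_map, 0.0)
        assert np.all(np.isfinite(out.u))


class TestTvSmooth:
    def test_noise_free_rod_preserves_far_field_and_edge_location(
        self, static_clean_video
    ):
        mask = static_clean_video.masks[0]
        u = np.where(mask, 0.25, 0.8)  # piecewise-constant rod
        sm, _ = mt.tv_smooth(u)
        bdist = np.where(
            mask, distance_transform_edt(mask), distance_transform_edt(~mask)
        )
        # the evolution only reworks a band around the edge; pixels away
        # from the boundary are untouched
        assert np.abs(sm - u)[bdist > 7].max() < 0.01
        row = mask.shape[0] // 2
        shift = abs(
            int(np.abs(np.diff(u[row])).argmax())
            - int(np.abs(np.diff(sm[row])).argmax())
        )
        assert shift <= 1
        assert mt.dice(mt.segment_frame(sm).mask, mask) >= 0.99

    def test_background_variance_reduction_on_noisy_rod(self, static_noisy_video):
        noisy = static_noisy_video.sequence.frames[0]
        mask = static_noisy_video.masks[0]
        sm, _ = mt.tv_smooth(noisy)
        bg = distance_transform_edt(~mask) > 5
        assert sm[bg].var() <= 0.2 * noisy[bg].var()

    def test_total_variation_drops_on_pure_noise_first_step(self):
        rng = np.random.default_rng(2)
        u = rng.uniform(0, 1, (64, 64))
        out = tv_step(_state(u), SmoothingParams())

        def total_variation(im):
            return np.abs(np.diff(im, axis=0)).sum() + np.abs(np.diff(im, axis=1)).sum()

        assert total_variation(out.u) < total_variation(u)

    def test_pure_curvature_flow_flattens_small_image(self):
        rng = np.random.default_rng(2)
        u = rng.uniform(0, 1, (8, 8))
        out, _ = mt.tv_smooth(u, SmoothingParams(max_iters=2000), fidelity=False)
        assert np.ptp(out) < 0.1 * np.ptp(u)

    def test_reference_correlation_is_recorded(self, static_clean_video):
        clean = static_clean_video.sequence.frames[0]
        rng = np.random.default_rng(6)
        noisy = np.clip(clean + rng.normal(0.0, 0.05, clean.shape), 0.0, 1.0)
        _, hist = mt.tv_smooth(noisy, SmoothingParams(max_iters=30), reference=clean)
        assert len(hist["corr_ref"]) == 30
        # denoising raises the correlation with the clean scene
        assert hist["corr_ref"][-1] > hist["corr_ref"][0]

    def test_rejects_non_finite_input(self):
        u = np.zeros((8, 8))
        u[3, 3] = np.nan
        with pytest.raises(ValueError):
            mt.tv_smooth(u)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(4, 12), st.integers(4, 12)),
            elements=st.floats(0, 1),
        )
    )
    def test_no_iteration_produces_non_finite_values(self, u):
        out, _ = mt.tv_smooth(u, SmoothingParams(max_iters=20))
        assert np.all(np.isfinite(out))

    def test_dt_within_bounds_every_iteration(self, static_noisy_video):
        params = SmoothingParams()
        st_ = _state(static_noisy_video.sequence.frames[0])
        for _ in range(30):
            st_.sigma2 = estimate_noise_variance(st_.u)
            tv_step(st_, params)
            assert st_.dt_map.min() >= params.dt_min - 1e-15
            assert st_.dt_map.max() <= params.dt_max + 1e-15
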