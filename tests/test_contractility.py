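import numpy as np
import pytest
from conftest import rigid

import myotrace as mt
from myotrace.errors import NoEdgeError, NoTwitchError, ZeroNormError


def _vec(mags, method="centroid-distance"):
    return mt.DescriptorVector(magnitudes=np.asarray(mags, float), method=method)


class TestDescriptorDistance:
    def test_identity_is_zero(self, rod_contour):
        v = mt.describe_contour(rod_contour)
        assert mt.descriptor_distance(v, v) == 0.0

    def test_uniform_scale_gives_analytic_percent(self, rod_contour):
        b = mt.describe_contour(rod_contour)
        a = mt.describe_contour(rigid(rod_contour, scale=0.9))
        assert mt.descriptor_distance(a, b) == pytest.approx(10.0, abs=1e-4)

    def test_matches_independent_reimplementation(self, rod_contour):
        # nested rod: lengthwise scale 0.92, area-preserving-style bulge
        inner = mt.ClosedContour(
            points=(rod_contour.points - rod_contour.points.mean(0))
            * np.array([0.92, 1.0])
            + rod_contour.points.mean(0)
        )

        def brute_descriptors(c, K=30):
            x, y = c.points[:, 0], c.points[:, 1]
            r = np.sqrt((x - x.mean()) ** 2 + (y - y.mean()) ** 2)
            n = len(r)
            Q = np.array(
                [
                    np.sum(r * np.exp(-2j * np.pi * k * np.arange(n) / n)) / n
                    for k in range(n)
                ]
            )
            phi1 = np.arctan2(Q[1].imag, Q[1].real)
            return np.abs(Q * np.exp(-1j * phi1 * np.arange(n)))[:K]

        a_b = brute_descriptors(inner)
        b_b = brute_descriptors(rod_contour)
        expected = 100 * np.linalg.norm(a_b - b_b) / np.linalg.norm(b_b)
        got = mt.descriptor_distance(
            mt.describe_contour(inner), mt.describe_contour(rod_contour)
        )
        assert got == pytest.approx(expected, rel=1e-9)

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroNormError):
            mt.descriptor_distance(_vec([1, 2]), _vec([0, 0]))

    def test_method_and_k_must_match(self):
        with pytest.raises(ValueError):
            mt.descriptor_distance(_vec([1, 2]), _vec([1, 2], "complex-coords"))
        with pytest.raises(ValueError):
            mt.descriptor_distance(_vec([1, 2]), _vec([1, 2, 3]))

    def test_symmetric_when_norms_equal(self):
        a = _vec([3.0, 4.0])
        b = _vec([4.0, 3.0])
        assert mt.descriptor_distance(a, b) == mt.descriptor_distance(b, a)


class TestContractionTrace:
    def test_identical_frames_give_zero_trace(self, rod_contour):
        v = mt.describe_contour(rod_contour)
        rec = mt.contraction_trace([v] * 5, frame_rate=30.0)
        np.testing.assert_array_equal(rec.values, 0.0)
        assert rec.times[-1] == pytest.approx(4 / 30)

    def test_max_norm_reference_picks_most_relaxed(self, rod_contour):
        relaxed = mt.describe_contour(rod_contour)
        contracted = mt.describe_contour(rigid(rod_contour, scale=0.9))
        rec = mt.contraction_trace([contracted, relaxed, contracted], 30.0)
        assert rec.reference_frame == 1
        assert rec.values[1] == 0.0
        assert rec.values[0] == pytest.approx(10.0, abs=1e-4)

    def test_explicit_reference_policy(self, rod_contour):
        vs = [
            mt.describe_contour(rigid(rod_contour, scale=s))
            for s in (1.0, 0.95, 0.9)
        ]
        rec = mt.contraction_trace(vs, 30.0, reference=2)
        assert rec.reference_frame == 2
        assert rec.values[2] == 0.0

    def test_trace_invariant_under_global_rigid_motion(self, rod_contour):
        scales = [1.0, 0.95, 0.9, 0.95, 1.0]
        plain = [mt.describe_contour(rigid(rod_contour, scale=s)) for s in scales]
        moved = [
            mt.describe_contour(
                rigid(rod_contour, theta=0.7, tx=20.0, ty=-10.0, shift=31, scale=s)
            )
            for s in scales
        ]
        a = mt.contraction_trace(plain, 30.0).values
        b = mt.contraction_trace(moved, 30.0).values
        np.testing.assert_allclose(b, a, atol=1e-5)

    def test_too_few_frames_rejected(self, rod_contour):
        with pytest.raises(ValueError):
            mt.contraction_trace([mt.describe_contour(rod_contour)], 30.0)


def _periodic_trace(n_twitches=4, fps=24.0, pacing=0.25, noise=0.0, seed=0):
    p = mt.TwitchProtocol(
        pacing_rate=pacing, frame_rate=fps, duration=n_twitches / pacing
    )
    t = np.arange(p.n_frames) / fps
    values = 100.0 * np.asarray(mt.twitch_waveform(t, p))
    if noise:
        values = values + np.random.default_rng(seed).normal(
            0, noise * values.max(), len(values)
        )
    return mt.ContractionRecord(times=t, values=values, reference_frame=0)


class TestTwitchAnalysis:
    def test_identical_twitches_average_to_single_window(self):
        rec = mt.analyze_twitches(_periodic_trace())
        assert len(rec.twitch_peaks) == 4
        # the trace has an exact integer period (96 frames), so every twitch
        # window is identical and the average must reproduce one of them
        win = len(rec.mean_transient)
        residual = min(
            np.abs(rec.values[s : s + win] - rec.mean_transient).max()
            for s in range(len(rec.values) - win)
        )
        assert residual < 1e-9

    def test_normalized_spans_unit_range(self):
        rec = mt.analyze_twitches(_periodic_trace())
        assert rec.normalized.min() == 0.0
        assert rec.normalized.max() == 1.0

    def test_averaging_suppresses_trace_noise(self):
        clean = mt.analyze_twitches(_periodic_trace())
        noisy = mt.analyze_twitches(_periodic_trace(noise=0.02, seed=8))
        assert noisy.mean_transient.max() == pytest.approx(
            clean.mean_transient.max(), rel=0.02
        )

    def test_flat_trace_raises(self):
        rec = mt.ContractionRecord(
            times=np.arange(10) / 30, values=np.zeros(10), reference_frame=0
        )
        with pytest.raises(NoTwitchError):
            mt.analyze_twitches(rec)

    @pytest.mark.parametrize("seed,count", [(s, 2 + s % 9) for s in range(10)])
    def test_twitch_count_recovery(self, seed, count):
        """Counts from 2 to 10 twitches recovered across seeded cell shapes."""
        cell = mt.CellModel(pixel_size=1.0, end_jaggedness=1.0)
        p = mt.TwitchProtocol(
            pacing_rate=count / 12.0, duration=12.0, seed=seed
        )
        contours, _ = mt.silhouette_sequence(cell, p)
        vecs = [
            mt.describe_contour(mt.resample_contour(c, 7)) for c in contours
        ]
        rec = mt.analyze_twitches(mt.contraction_trace(vecs, p.frame_rate))
        assert len(rec.twitch_peaks) == count


class TestRasterLine:
    def test_known_extent_recovered(self):
        row = np.full(200, 0.8)
        row[40:141] = 0.25  # cell spans columns 40..140
        frame = np.tile(row, (5, 1))
        length = mt.raster_line_length(frame, row=2, threshold=0.5)
        assert length == pytest.approx(100, abs=1.0)

    def test_uniform_row_raises_no_edge(self):
        with pytest.raises(NoEdgeError):
            mt.raster_line_length(np.full((5, 50), 0.8), row=2, threshold=0.5)

    def test_trace_defaults_to_center_row(self):
        frame = np.full((21, 60), 0.8)
        frame[8:13, 20:40] = 0.2
        rec = mt.raster_line_trace([frame, frame], frame_rate=30.0)
        assert rec.row == 10
        assert np.all(rec.lengths > 18)
        sp = rec.shortening_percent()
        np.testing.assert_allclose(sp, 0.0)
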