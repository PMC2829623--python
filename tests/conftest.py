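import numpy as np
import pytest

import myotrace as mt

PX = mt.CellModel(pixel_size=1.0)  # 100 µm x 25 µm cell at 1 µm/px


def rigid(c, theta=0.0, tx=0.0, ty=0.0, shift=0, scale=1.0):
    """Rigid motion (+ optional uniform scale about the centroid) of a contour."""
    pts = c.points.copy()
    ctr = pts.mean(axis=0)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    pts = (pts - ctr) * scale @ rot.T + ctr + np.array([tx, ty])
    pts = np.roll(pts, shift, axis=0)
    return mt.ClosedContour(points=pts, frame_index=c.frame_index)


@pytest.fixture(scope="session")
def rod_contour():
    """Analytic resting-cell boundary, resampled to 128 vertices."""
    contours, _ = mt.silhouette_sequence(
        PX, mt.TwitchProtocol(duration=1 / 30, amplitude=0.0)
    )
    return mt.resample_contour(contours[0], 7)


@pytest.fixture(scope="session")
def static_noisy_video():
    """One noisy static frame of the default-geometry cell + ground truth."""
    return mt.render_video(
        PX,
        mt.TwitchProtocol(duration=1 / 30, amplitude=0.0, noise_sigma=0.02, seed=11),
    )


@pytest.fixture(scope="session")
def static_clean_video():
    """Noise-free counterpart of the static frame."""
    return mt.render_video(
        PX,
        mt.TwitchProtocol(duration=1 / 30, amplitude=0.0, noise_sigma=0.0, seed=11),
    )
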