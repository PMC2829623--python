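"""End-to-end orchestration: smooth → segment → contour → descriptors → trace.

The pipeline is deterministic: identical configuration and input produce
byte-identical outputs. Every stage's intermediate result is persisted so a
run can be inspected or resumed stage by stage: smoothed frames and masks as
TIFF stacks, contours and descriptors as CSV tables, the trace as the CSV
written by :func:`myotrace.videoio.write_trace`.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .contour import extract_contour, resample_contour, smooth_contour
from .contractility import (
    ContractionRecord,
    analyze_twitches,
    contraction_trace,
    raster_line_trace,
)
from .descriptors import describe_contour
from .errors import ConfigError
from .segmentation import segment_frame
from .tv_smoothing import SmoothingParams, tv_smooth
from .videoio import FrameSequence, load_frames, write_trace

log = logging.getLogger("myotrace")


@dataclass
class PipelineConfig:
    """All stage parameters plus I/O paths; YAML round-trippable."""

    input: str = ""
    outdir: str = "myotrace_out"
    frame_rate: float | None = None
    # smoothing
    smooth_iters: int = 100
    epsilon: float = 1.0 / 255.0
    gauss_sigma: float = 1.0
    # segmentation
    polarity: str = "dark-cell"
    # contour
    contour_sigma: float = 2.0
    M: int = 7
    # descriptors
    method: str = "centroid-distance"
    K: int = 30
    # contraction
    reference: str | int = "max-norm"
    min_prominence: float = 0.3
    # raster baseline
    raster_row: int | None = None
    raster_threshold: float = 0.5
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.M < 3:
            raise ConfigError(f"M must be >= 3, got {self.M}")
        if self.K < 1 or self.K > 2 ** self.M // 2:
            raise ConfigError(f"K={self.K} incompatible with 2^M={2 ** self.M} points")
        if self.polarity not in ("dark-cell", "bright-cell"):
            raise ConfigError(f"unknown polarity {self.polarity!r}")
        if self.method not in ("centroid-distance", "complex-coords"):
            raise ConfigError(f"unknown method {self.method!r}")
        if self.smooth_iters < 1:
            raise ConfigError("smooth_iters must be >= 1")
        return self

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data).validate()


def process_sequence(seq: FrameSequence, cfg: PipelineConfig) -> dict:
    """Run all stages on an in-memory sequence; return per-stage artifacts.

    Returns a dict with ``smoothed`` (list of frames), ``masks``,
    ``contours`` (resampled), ``vectors``, ``record`` (twitch-analyzed
    ContractionRecord) and ``raster`` (RasterLineRecord or None).
    """
    cfg.validate()
    params = SmoothingParams(
        max_iters=cfg.smooth_iters, epsilon=cfg.epsilon, gauss_sigma=cfg.gauss_sigma
    )
    t0 = time.perf_counter()
    # Clamp back to the canonical intensity domain: the explicit evolution
    # can overshoot [0, 1] by a little at corners.
    smoothed = [np.clip(tv_smooth(f, params)[0], 0.0, 1.0) for f in seq.frames]
    log.info("smoothing: %d frames in %.1fs", len(smoothed), time.perf_counter() - t0)

    t0 = time.perf_counter()
    masks = [
        segment_frame(u, polarity=cfg.polarity, frame_index=i)
        for i, u in enumerate(smoothed)
    ]
    contours = [
        resample_contour(
            smooth_contour(extract_contour(m, intensity=u), cfg.contour_sigma), cfg.M
        )
        for m, u in zip(masks, smoothed)
    ]
    vectors = [describe_contour(c, cfg.method, cfg.K) for c in contours]
    log.info("segmentation+descriptors in %.1fs", time.perf_counter() - t0)

    record = contraction_trace(vectors, seq.frame_rate, cfg.reference)
    try:
        record = analyze_twitches(record, cfg.min_prominence)
    except Exception as exc:  # a flat trace is still a valid record
        log.warning("twitch analysis skipped: %s", exc)

    raster = None
    try:
        raster = raster_line_trace(
            smoothed, cfg.raster_row, cfg.raster_threshold, seq.frame_rate
        )
    except Exception as exc:
        log.warning("raster baseline skipped: %s", exc)

    return {
        "smoothed": smoothed,
        "masks": masks,
        "contours": contours,
        "vectors": vectors,
        "record": record,
        "raster": raster,
    }


def run_pipeline(
    cfg: PipelineConfig, seq: FrameSequence | None = None
) -> ContractionRecord:
    """Execute the full pipeline and persist every intermediate to disk."""
    cfg.validate()
    if seq is None:
        seq = load_frames(cfg.input, frame_rate_override=cfg.frame_rate)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("myotrace %s: %d frames from %s", __version__, len(seq), seq.source)
    cfg.to_yaml(outdir / "config.yaml")

    art = process_sequence(seq, cfg)

    # float64 so a stage-by-stage rerun from the persisted stack is exact
    tifffile.imwrite(outdir / "smoothed.tif", np.stack(art["smoothed"]))
    tifffile.imwrite(
        outdir / "masks.tif",
        np.stack([m.mask for m in art["masks"]]).astype(np.uint8) * 255,
    )
    pd.concat(
        [
            pd.DataFrame(
                {"frame": c.frame_index, "n": np.arange(len(c)), "x": c.x, "y": c.y}
            )
            for c in art["contours"]
        ]
    ).to_csv(outdir / "contours.csv", index=False, float_format="%.17g")
    pd.concat(
        [
            pd.DataFrame(
                {
                    "frame": v.frame_index,
                    "k": np.arange(v.K)
                    + (1 if cfg.method == "complex-coords" else 0),
                    "magnitude": v.magnitudes,
                }
            )
            for v in art["vectors"]
        ]
    ).to_csv(outdir / "descriptors.csv", index=False, float_format="%.17g")
    write_trace(art["record"], outdir / "trace.csv")
    if art["raster"] is not None:
        pd.DataFrame(
            {
                "frame": np.arange(len(art["raster"].lengths)),
                "time_s": art["raster"].times,
                "length_px": art["raster"].lengths,
            }
        ).to_csv(outdir / "raster_trace.csv", index=False, float_format="%.17g")
    return art["record"]
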