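"""Spatiotemporal diameter matrices (kymographs) and the TTX comparison.

A kymograph here is numerically a time x position matrix of bowel widths:
row t holds the per-column width profile of frame t.  The temporal median
per position serves as the resting-diameter baseline, and the pre/post
tetrodotoxin (TTX) comparison is the per-position ratio of those baselines
— equivalence of resting diameter before and after neural blockade rules
out tonic neural tone as a confounder.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .segmentation import BowelSegmenter, SegmentationError

logger = logging.getLogger(__name__)

#: Recordings where more than this fraction of frames fail segmentation are
#: rejected as unusable.
MAX_FAILED_FRAME_FRACTION = 0.10


@dataclass
class DiameterMatrix:
    """Time x position bowel-width matrix.

    ``values[t, p]`` is the width in pixels at frame t, column p.  Frames
    whose segmentation failed are retained (to preserve time alignment) but
    flagged false in ``valid_rows``; ``valid_columns`` marks positions
    outside the cannula margin that held foreground in every valid frame.
    """

    values: np.ndarray
    frame_rate_fps: float
    valid_rows: np.ndarray
    valid_columns: np.ndarray
    pixel_size_mm_per_px: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_rows = np.asarray(self.valid_rows, dtype=bool)
        self.valid_columns = np.asarray(self.valid_columns, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (time x position)")
        if len(self.valid_rows) != self.values.shape[0]:
            raise ValueError("valid_rows length must equal the frame count")
        if len(self.valid_columns) != self.values.shape[1]:
            raise ValueError("valid_columns length must equal the position count")
        if np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError("widths cannot be negative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_fps

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_fps

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write the matrix as TSV plus a ``<path>.json`` metadata sidecar."""
        path = Path(path)
        header = "\t".join(str(p) for p in range(self.values.shape[1]))
        np.savetxt(path, self.values, fmt="%.3f", delimiter="\t", header=header, comments="")
        meta = {
            "frame_rate_fps": self.frame_rate_fps,
            "pixel_size_mm_per_px": self.pixel_size_mm_per_px,
            "valid_rows": self.valid_rows.astype(int).tolist(),
            "valid_columns": self.valid_columns.astype(int).tolist(),
        }
        Path(str(path) + ".json").write_text(json.dumps(meta))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DiameterMatrix":
        path = Path(path)
        values = np.loadtxt(path, delimiter="\t", skiprows=1)
        values = np.atleast_2d(values)
        meta = json.loads(Path(str(path) + ".json").read_text())
        return cls(
            values=values,
            frame_rate_fps=meta["frame_rate_fps"],
            valid_rows=np.asarray(meta["valid_rows"], dtype=bool),
            valid_columns=np.asarray(meta["valid_columns"], dtype=bool),
            pixel_size_mm_per_px=meta.get("pixel_size_mm_per_px"),
        )


@dataclass
class BaselineProfile:
    """Per-position temporal median width; NaN at invalid positions."""

    values: np.ndarray
    valid: np.ndarray


@dataclass
class ConditionComparison:
    """Per-position post/pre baseline ratio with a summary."""

    ratios: np.ndarray
    valid: np.ndarray
    mean_ratio: float
    sd_ratio: float
    n_positions: int


def build_kymograph(
    frames: np.ndarray,
    segmenter: BowelSegmenter | None = None,
    frame_rate_fps: float = 15.0,
) -> DiameterMatrix:
    """Segment every frame of a (T, H, W) stack into a DiameterMatrix.

    Frames that fail segmentation become all-invalid rows (logged, never
    silently dropped); more than 10% failed frames raises, since such a
    recording cannot be scored.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (T, H, W) stack with at least 2 frames")
    segmenter = segmenter or BowelSegmenter()

    T, _, W = frames.shape
    values = np.zeros((T, W))
    valid_rows = np.ones(T, dtype=bool)
    col_valid = np.ones(W, dtype=bool)
    for t in range(T):
        try:
            prof = segmenter.segment_frame(frames[t])
        except SegmentationError as exc:
            logger.warning("frame %d failed segmentation: %s", t, exc)
            valid_rows[t] = False
            continue
        values[t] = prof.widths_px
        col_valid &= prof.valid

    failed = 1.0 - valid_rows.mean()
    if failed > MAX_FAILED_FRAME_FRACTION:
        raise ValueError(
            f"{failed:.0%} of frames failed segmentation; recording is unusable"
        )
    return DiameterMatrix(
        values=values,
        frame_rate_fps=frame_rate_fps,
        valid_rows=valid_rows,
        valid_columns=col_valid,
        pixel_size_mm_per_px=segmenter.pixel_size_mm_per_px,
    )


def baseline_profile(dm: DiameterMatrix) -> BaselineProfile:
    """Per-position median width over time (valid rows and columns only)."""
    if not dm.valid_columns.any():
        raise ValueError("no valid positions in diameter matrix")
    med = np.full(dm.values.shape[1], np.nan)
    med[dm.valid_columns] = np.median(
        dm.values[dm.valid_rows][:, dm.valid_columns], axis=0
    )
    return BaselineProfile(values=med, valid=dm.valid_columns.copy())


def compare_conditions(pre: DiameterMatrix, post: DiameterMatrix) -> ConditionComparison:
    """Per-position post/pre resting-diameter ratio (the TTX comparison)."""
    if pre.values.shape[1] != post.values.shape[1]:
        raise ValueError("pre and post matrices must share the position count")
    if (pre.pixel_size_mm_per_px is None) != (post.pixel_size_mm_per_px is None):
        raise ValueError("pre and post matrices must share units")
    b_pre = baseline_profile(pre)
    b_post = baseline_profile(post)
    valid = b_pre.valid & b_post.valid
    zero_pre = valid & (b_pre.values == 0)
    if zero_pre.any():
        logger.warning(
            "%d positions with zero pre-TTX baseline excluded from the ratio",
            int(zero_pre.sum()),
        )
        valid &= ~zero_pre
    ratios = np.full(pre.values.shape[1], np.nan)
    ratios[valid] = b_post.values[valid] / b_pre.values[valid]
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no positions usable for the pre/post comparison")
    return ConditionComparison(
        ratios=ratios,
        valid=valid,
        mean_ratio=float(np.mean(ratios[valid])),
        sd_ratio=float(np.std(ratios[valid], ddof=1)) if n > 1 else 0.0,
        n_positions=n,
    )


def plot_kymograph(dm: DiameterMatrix, path: str | Path, events=None) -> None:
    """Render the kymograph (time vertical, position horizontal) to PNG.

    ``events`` may be a sequence of detected contraction events whose peak
    trajectories are overlaid.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 8))
    shown = np.where(dm.valid_columns[None, :], dm.values, np.nan)
    im = ax.imshow(
        shown,
        aspect="auto",
        origin="upper",
        cmap="viridis",
        extent=(0, dm.values.shape[1], dm.duration_s, 0),
    )
    if events:
        for ev in events:
            ax.plot(ev.positions_px, ev.peak_times_s, "r.", markersize=1)
    ax.set_xlabel("position along bowel (px, proximal at 0)")
    ax.set_ylabel("time (s)")
    fig.colorbar(im, ax=ax, label="bowel width (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
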