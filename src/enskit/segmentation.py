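"""Frame-level bowel segmentation: threshold, isolate, measure width.

Mirrors the stages of kymograph preprocessing for organ-bath video: each
grayscale frame is thresholded (Otsu by default), the bowel is isolated as
the largest 8-connected foreground component, and bowel width is measured
as the foreground pixel count in each column along the proximal-distal
axis (proximal = column 0).  Columns near the frame edges are flagged
invalid to exclude cannulas/pins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label
from sklearn.base import BaseEstimator

DEFAULT_MARGIN_PX = 10


class SegmentationError(ValueError):
    """A frame could not be segmented."""


class UnthresholdableFrameError(SegmentationError):
    """Constant-intensity frame: Otsu has no histogram valley to split."""


class EmptySegmentationError(SegmentationError):
    """Thresholding produced no foreground pixels."""


@dataclass
class WidthProfile:
    """Per-column bowel width for one frame.

    ``widths_px[c]`` is the number of foreground pixels in column ``c``;
    columns inside the edge margin, or without any foreground, carry width
    0 and ``valid[c] == False``.
    """

    widths_px: np.ndarray
    valid: np.ndarray
    pixel_size_mm_per_px: float | None = None

    @property
    def widths_mm(self) -> np.ndarray | None:
        if self.pixel_size_mm_per_px is None:
            return None
        return self.widths_px * self.pixel_size_mm_per_px


def threshold_frame(
    frame: np.ndarray, method: str = "otsu", fixed_value: float | None = None
) -> np.ndarray:
    """Binarize a grayscale frame; foreground where intensity > threshold."""
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.shape[0] < 2 or frame.shape[1] < 2:
        raise ValueError("frame must be a 2-D array of at least 2x2 pixels")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite intensities")
    if method == "otsu":
        if np.ptp(frame) == 0:
            raise UnthresholdableFrameError(
                "constant-intensity frame cannot be Otsu-thresholded"
            )
        thr = threshold_otsu(frame, nbins=256)
    elif method == "fixed":
        if fixed_value is None or not 0 <= fixed_value <= 255:
            raise ValueError("fixed thresholding requires fixed_value in [0, 255]")
        thr = fixed_value
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return frame > thr


def isolate_bowel(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Ties are broken toward the component containing the lexicographically
    smallest (row, column) foreground pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("mask is empty")
    if not mask.any():
        raise EmptySegmentationError("no foreground pixels to isolate")
    labels = label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = counts.max()
    candidates = np.flatnonzero(counts == best)
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        flat = labels.ravel()
        keep = min(candidates, key=lambda lb: int(np.argmax(flat == lb)))
    return labels == keep


def width_profile(
    mask: np.ndarray,
    margin_px: int = DEFAULT_MARGIN_PX,
    pixel_size_mm_per_px: float | None = None,
) -> WidthProfile:
    """Per-column foreground count, with edge columns marked invalid."""
    mask = np.asarray(mask, dtype=bool)
    n_cols = mask.shape[1]
    if not 0 <= margin_px < n_cols / 2:
        raise ValueError("margin_px must satisfy 0 <= margin < half the frame width")
    widths = mask.sum(axis=0).astype(float)
    interior = np.zeros(n_cols, dtype=bool)
    interior[margin_px : n_cols - margin_px] = True
    valid = interior & (widths > 0)
    widths[~valid] = 0.0
    return WidthProfile(widths, valid, pixel_size_mm_per_px)


class BowelSegmenter(BaseEstimator):
    """Stateless frame segmenter packaging the three stages.

    Parameters
    ----------
    method : {"otsu", "fixed"}
        Threshold rule.  Otsu is the default; fixed-value mode gives exact
        reproducibility when the illumination is known.
    fixed_value : float, optional
        Threshold for ``method="fixed"``.
    margin_px : int
        Columns within this distance of either frame edge are excluded
        (cannula/pin exclusion).
    pixel_size_mm_per_px : float, optional
        Spatial calibration; widths in mm are reported when present.
    """

    def __init__(
        self,
        method: str = "otsu",
        fixed_value: float | None = None,
        margin_px: int = DEFAULT_MARGIN_PX,
        pixel_size_mm_per_px: float | None = None,
    ):
        self.method = method
        self.fixed_value = fixed_value
        self.margin_px = margin_px
        self.pixel_size_mm_per_px = pixel_size_mm_per_px

    def fit(self, X=None, y=None):  # noqa: D102 - no state to learn
        return self

    def segment_frame(self, frame: np.ndarray) -> WidthProfile:
        mask = threshold_frame(frame, self.method, self.fixed_value)
        mask = isolate_bowel(mask)
        return width_profile(mask, self.margin_px, self.pixel_size_mm_per_px)

    def transform(self, frames: np.ndarray) -> np.ndarray:
        """Width profiles for a (T, H, W) stack as a (T, W) array."""
        frames = np.asarray(frames)
        return np.stack([self.segment_frame(f).widths_px for f in frames])


# ---------------------------------------------------------------------------
# Frame stack I/O


def read_frames(path: str | Path) -> np.ndarray:
    """Load a frame stack from a directory of PNGs or a multi-page TIFF."""
    import imageio.v3 as iio
    import tifffile

    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"})
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames found in {path}")
        return np.stack([iio.imread(f) for f in files])
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    raise ValueError(f"unsupported frame source: {path}")


def write_frames(frames: np.ndarray, out_dir: str | Path, prefix: str = "frame") -> list[Path]:
    """Write a (T, H, W) uint8 stack as numbered PNGs."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(np.asarray(frames)):
        p = out_dir / f"{prefix}_{i:05d}.png"
        iio.imwrite(p, frame.astype(np.uint8))
        paths.append(p)
    return paths
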