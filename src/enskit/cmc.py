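"""Contraction-event detection and colonic motor complex (CMC) scoring.

A CMC is a repetitive neurogenic contraction that propagates along the
colon with a defined peak point of contraction.  Manual scoring of such
events from kymographs is here operationalised as:

1. smooth the diameter matrix (moving average, 0.2 s x 5 px by default —
   long temporal windows wash out fast-propagating waves, which dwell only
   ~sigma_p/|v| seconds at any one position);
2. binarize: a (time, position) cell is *contracted* when its width falls
   below ``(1 - a)`` times that position's temporal-median baseline
   (default a = 0.10, i.e. a 10% width reduction);
3. label 8-connected spatiotemporal components of the contracted mask;
4. discard components shorter than a minimum duration;
5. per component, the peak trajectory is the time of minimum width at each
   spanned position (the centre of the minimum plateau, since pixel-count
   widths are quantised); propagation velocity is the inverse of the
   least-squares slope of peak time on position, and the sign of the
   velocity (against a dead-band) gives the direction.

An event is scored as a CMC when it is antegrade, spans at least half of
the valid bowel length, has a well-defined peak, and was recorded under
neurogenic-capable conditions (pre-TTX).  All thresholds are parameters:
the manual criteria they stand in for are not numerically enumerable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.measure import label, regionprops
from sklearn.base import BaseEstimator

from .kymograph import DiameterMatrix

#: Duration CMC frequencies are normalised to, in seconds (20 minutes, the
#: standard organ-bath recording length).
REFERENCE_DURATION_S = 1200.0


class DegenerateBaselineError(ValueError):
    """Every cell is below threshold: the baseline cannot be trusted."""


@dataclass
class ContractionEvent:
    """One detected spatiotemporal contraction."""

    start_s: float
    end_s: float
    extent_fraction: float
    positions_px: np.ndarray = field(repr=False)
    peak_times_s: np.ndarray = field(repr=False)
    velocity_px_per_s: float
    direction: str
    max_amplitude_fraction: float
    peak_defined: bool

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("event must end after it starts")
        if not 0.0 < self.extent_fraction <= 1.0:
            raise ValueError("extent_fraction must lie in (0, 1]")


@dataclass
class CmcSummary:
    """CMC count and normalised frequency for one recording."""

    cmc_count: int
    duration_s: float
    frequency_per_20min: float
    events: list[ContractionEvent]
    cmc_events: list[ContractionEvent]


def classify_direction(velocity_px_per_s: float, deadband_px_per_s: float) -> str:
    """Antegrade (+), retrograde (-), or localized (within the dead-band)."""
    if velocity_px_per_s > deadband_px_per_s:
        return "antegrade"
    if velocity_px_per_s < -deadband_px_per_s:
        return "retrograde"
    return "localized"


class CmcDetector(BaseEstimator):
    """Detect contraction events in a diameter matrix and score CMCs.

    Parameters
    ----------
    amplitude_threshold_fraction : float
        Fractional width reduction that counts as contracted (default 0.10).
    min_duration_s : float
        Components lasting less than this are discarded.
    min_extent_fraction : float
        Minimum fraction of the valid bowel length a CMC must span
        (default 0.5).
    direction_deadband_px_per_s : float
        |velocity| below this is classified as localized.
    smoothing_window_s, smoothing_window_px : float, int
        Moving-average window applied before binarization.
    peak_uniqueness_fraction : float
        Fraction of spanned positions whose width minima must form a single
        contiguous plateau in time for the event's peak to count as
        "defined" (disconnected minima mean no single peak point).

    Attributes
    ----------
    events_ : list of ContractionEvent
        Detected events ordered by start time.
    n_events_ : int
    duration_s_ : float
        Recording duration of the fitted matrix.
    """

    def __init__(
        self,
        amplitude_threshold_fraction: float = 0.10,
        min_duration_s: float = 0.5,
        min_extent_fraction: float = 0.5,
        direction_deadband_px_per_s: float = 5.0,
        smoothing_window_s: float = 0.2,
        smoothing_window_px: int = 5,
        peak_uniqueness_fraction: float = 0.9,
    ):
        self.amplitude_threshold_fraction = amplitude_threshold_fraction
        self.min_duration_s = min_duration_s
        self.min_extent_fraction = min_extent_fraction
        self.direction_deadband_px_per_s = direction_deadband_px_per_s
        self.smoothing_window_s = smoothing_window_s
        self.smoothing_window_px = smoothing_window_px
        self.peak_uniqueness_fraction = peak_uniqueness_fraction

    def _validate(self) -> None:
        if not 0.0 < self.amplitude_threshold_fraction < 1.0:
            raise ValueError("amplitude_threshold_fraction must lie in (0, 1)")
        if not 0.0 < self.min_extent_fraction <= 1.0:
            raise ValueError("min_extent_fraction must lie in (0, 1]")
        if min(self.min_duration_s, self.smoothing_window_s) <= 0:
            raise ValueError("durations must be positive")

    def fit(self, dm: DiameterMatrix, y=None) -> "CmcDetector":
        """Detect contraction events in ``dm``."""
        self._validate()
        min_rows = max(2, int(math.ceil(self.min_duration_s * dm.frame_rate_fps)))
        if dm.n_frames < min_rows:
            raise ValueError("recording shorter than the minimum event duration")

        col_idx = np.flatnonzero(dm.valid_columns)
        if col_idx.size == 0:
            raise ValueError("no valid positions to analyse")
        sub = dm.values[:, col_idx].copy()
        # Failed frames are filled with the per-column median so smoothing
        # does not bleed zeros into neighbours; they are un-flagged below.
        if not dm.valid_rows.all():
            med = np.median(sub[dm.valid_rows], axis=0)
            sub[~dm.valid_rows] = med

        wt = max(1, int(round(self.smoothing_window_s * dm.frame_rate_fps)))
        wp = max(1, int(self.smoothing_window_px))
        smoothed = uniform_filter(sub, size=(wt, wp), mode="nearest")
        baseline = np.median(smoothed[dm.valid_rows], axis=0)
        if np.any(baseline <= 0):
            raise DegenerateBaselineError("non-positive baseline at a valid position")

        contracted = smoothed < (1.0 - self.amplitude_threshold_fraction) * baseline
        contracted[~dm.valid_rows] = False
        if contracted[dm.valid_rows].all():
            raise DegenerateBaselineError(
                "every frame and position is below threshold; baseline is "
                "degenerate (miscalibrated or saturated recording)"
            )

        fps = dm.frame_rate_fps
        events: list[ContractionEvent] = []
        for region in regionprops(label(contracted, connectivity=2)):
            rows = region.coords[:, 0]
            cols = region.coords[:, 1]
            t0, t1 = rows.min(), rows.max()
            if (t1 - t0 + 1) / fps < self.min_duration_s:
                continue
            uniq_cols = np.unique(cols)
            peak_rows = np.empty(uniq_cols.size, dtype=float)
            single_peak = np.empty(uniq_cols.size, dtype=bool)
            for j, c in enumerate(uniq_cols):
                r = np.sort(rows[cols == c])
                vals = smoothed[r, c]
                at_min = r[vals == vals.min()]
                # quantised widths produce flat minima; a contiguous plateau
                # is one peak (take its centre), disconnected minima are not
                single_peak[j] = at_min.max() - at_min.min() + 1 == at_min.size
                peak_rows[j] = at_min.mean()
            positions = col_idx[uniq_cols].astype(float)
            peak_times = peak_rows / fps
            if positions.size >= 2:
                slope = np.polyfit(positions, peak_times, 1)[0]
                velocity = math.inf if slope == 0 else 1.0 / slope
            else:
                velocity = 0.0
            depth = 1.0 - smoothed[rows, cols] / baseline[cols]
            events.append(
                ContractionEvent(
                    start_s=t0 / fps,
                    end_s=(t1 + 1) / fps,
                    extent_fraction=uniq_cols.size / col_idx.size,
                    positions_px=positions,
                    peak_times_s=peak_times,
                    velocity_px_per_s=float(velocity),
                    direction=classify_direction(
                        velocity, self.direction_deadband_px_per_s
                    ),
                    max_amplitude_fraction=float(depth.max()),
                    peak_defined=bool(
                        single_peak.mean() >= self.peak_uniqueness_fraction
                    ),
                )
            )
        events.sort(key=lambda e: e.start_s)
        self.events_ = events
        self.n_events_ = len(events)
        self.duration_s_ = dm.duration_s
        return self

    def summarize(self, neurogenic: bool = True) -> CmcSummary:
        """Score fitted events as CMCs for one recording."""
        if not hasattr(self, "events_"):
            raise RuntimeError("call fit() before summarize()")
        return score_cmcs(
            self.events_,
            duration_s=self.duration_s_,
            neurogenic=neurogenic,
            min_extent_fraction=self.min_extent_fraction,
        )


def detect_events(dm: DiameterMatrix, params: CmcDetector | None = None) -> list[ContractionEvent]:
    """Functional wrapper over :class:`CmcDetector`."""
    det = params if params is not None else CmcDetector()
    return det.fit(dm).events_


def score_cmcs(
    events: list[ContractionEvent],
    duration_s: float,
    neurogenic: bool,
    min_extent_fraction: float = 0.5,
) -> CmcSummary:
    """Count CMCs among detected events and normalise per 20 minutes.

    Neurogenicity is a recording-level condition (pre- vs post-TTX), not a
    per-event inference: in a TTX recording no event can be a CMC.
    """
    if duration_s <= 0:
        raise ValueError("recording duration must be positive")
    cmcs = [
        e
        for e in events
        if neurogenic
        and e.direction == "antegrade"
        and e.extent_fraction >= min_extent_fraction
        and e.peak_defined
    ]
    return CmcSummary(
        cmc_count=len(cmcs),
        duration_s=duration_s,
        frequency_per_20min=len(cmcs) * REFERENCE_DURATION_S / duration_s,
        events=list(events),
        cmc_events=cmcs,
    )


def events_to_records(events: list[ContractionEvent]) -> list[dict]:
    """Flatten events for CSV/JSON export (trajectories omitted)."""
    return [
        {
            "start_s": e.start_s,
            "end_s": e.end_s,
            "extent_fraction": e.extent_fraction,
            "velocity_px_per_s": e.velocity_px_per_s,
            "direction": e.direction,
            "max_amplitude_fraction": e.max_amplitude_fraction,
            "peak_defined": e.peak_defined,
        }
        for e in events
    ]
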