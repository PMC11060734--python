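"""FITC-dextran transit: percent fluorescence and the geometric center.

After gavage, the bowel is cut into 19 ordered segments — stomach
(segment 1), 12 equal small-intestine segments, cecum, and 5 equal colon
segments (segment 19, distal colon) — and FITC fluorescence is read per
segment.  The distribution is expressed as percent of total, and transit
is summarised by the geometric center

    GC = sum_{i=1..19} i * x_i / 100,

the segment-index-weighted mean of the percent distribution x.  GC lies in
[1, 19]; larger values mean the marker travelled further.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Cutting protocol: stomach + 12 small-intestine + cecum + 5 colon segments.
SEGMENT_LAYOUT: dict[str, int] = {
    "stomach": 1,
    "small_intestine": 12,
    "cecum": 1,
    "colon": 5,
}
N_SEGMENTS: int = sum(SEGMENT_LAYOUT.values())

SEGMENT_COLUMNS = [f"segment_{i:02d}" for i in range(1, N_SEGMENTS + 1)]


@dataclass
class TransitProfile:
    """One animal's 19-segment fluorescence readings."""

    raw_intensity: np.ndarray

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw_intensity, dtype=float)
        if raw.shape != (N_SEGMENTS,):
            raise ValueError(
                f"expected exactly {N_SEGMENTS} segment readings, got shape {raw.shape}"
            )
        if not np.all(np.isfinite(raw)):
            raise ValueError("fluorescence readings must be finite")
        if np.any(raw < 0):
            raise ValueError("fluorescence readings must be nonnegative")
        if raw.sum() <= 0:
            raise ValueError("all-zero fluorescence profile")
        self.raw_intensity = raw

    @property
    def percent(self) -> np.ndarray:
        return 100.0 * self.raw_intensity / self.raw_intensity.sum()


def percent_fluorescence(raw) -> TransitProfile:
    """Validate raw readings and wrap them as a TransitProfile."""
    return TransitProfile(np.asarray(raw, dtype=float))


def geometric_center(profile) -> float:
    """GC = sum_i i * x_i / 100 over the 19 ordered segments."""
    if not isinstance(profile, TransitProfile):
        profile = percent_fluorescence(profile)
    idx = np.arange(1, N_SEGMENTS + 1)
    return float(np.sum(idx * profile.percent) / 100.0)


def transit_table(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal geometric centers and per-group segment means with SEM.

    ``profiles`` must hold one row per animal with columns
    ``segment_01..segment_19`` and ``group``.  Returns ``(per_animal,
    per_group)``; SEM uses the n-1 sample SD and is reported as NaN for
    single-animal groups.
    """
    missing = [c for c in SEGMENT_COLUMNS + ["group"] if c not in profiles.columns]
    if missing:
        raise ValueError(f"profiles table is missing columns: {missing}")
    if profiles.empty:
        raise ValueError("profiles table is empty")
    counts = profiles.groupby("group").size()
    if (counts == 0).any():  # pragma: no cover - groupby drops empty groups
        raise ValueError("empty group in profiles table")

    per_animal = profiles[["group"]].copy()
    per_animal["geometric_center"] = [
        geometric_center(row) for row in profiles[SEGMENT_COLUMNS].to_numpy()
    ]

    pct = profiles[SEGMENT_COLUMNS].div(profiles[SEGMENT_COLUMNS].sum(axis=1), axis=0) * 100.0
    pct["group"] = profiles["group"].to_numpy()
    long = pct.melt(id_vars="group", var_name="segment", value_name="pct")
    per_group = (
        long.groupby(["group", "segment"])["pct"]
        .agg(mean_pct="mean", sem_pct=lambda s: s.std(ddof=1) / np.sqrt(len(s)))
        .reset_index()
    )
    return per_animal, per_group
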