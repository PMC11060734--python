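"""Enteric neuron density, categorical proportions, and the exact binomial test.

Neuron counts come from confocal fields of known area: the full field of
view used at P5/P15 (180,625 um^2) or the two-quadrant area used at P0
(90,312.5 um^2).  Densities are reported per mm^2.  Categorical phenotypes
(e.g. the fraction of animals with a deformed colon) are summarised as
one-decimal percentages and tested with an exact two-sided binomial test.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import binom

#: Full-field-of-view area used for P5/P15 whole-mount counts, in um^2.
FIELD_AREA_FULL_UM2 = 180_625.0
#: Two-quadrant area used for P0 whole-mount counts, in um^2.
FIELD_AREA_QUADRANTS_UM2 = 90_312.5

UM2_PER_MM2 = 1e6


def density(count: float, field_area_um2: float) -> float:
    """Neurons per mm^2 from a raw count over a field of known area."""
    if count < 0:
        raise ValueError("count must be nonnegative")
    if field_area_um2 <= 0:
        raise ValueError("field area must be positive")
    return count / (field_area_um2 / UM2_PER_MM2)


def proportion(k: int, n: int) -> float:
    """Percent affected, rounded half-away-from-zero to one decimal."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    pct = Decimal(100 * k) / Decimal(n)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def per_day_bound(cumulative_percent: float, n_days: int, decimals: int = 2) -> float:
    """Per-day upper bound from a cumulative labeling percentage.

    E.g. a 3-day EdU pulse labelling at most 1% of neurons bounds the
    daily birth rate at 0.33%/day.
    """
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    if cumulative_percent < 0:
        raise ValueError("cumulative_percent must be nonnegative")
    rate = Decimal(str(cumulative_percent)) / Decimal(n_days)
    return float(rate.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


# Relative guard when comparing point probabilities in the minlike tail sum,
# absorbing floating-point jitter between equal-probability outcomes.
_MINLIKE_RELATIVE_GUARD = 1e-7


def binomial_two_sided(k: int, n: int, p0: float, method: str = "minlike") -> float:
    """Exact two-sided binomial test of X ~ Binomial(n, p0) at X = k.

    ``method="minlike"`` (default) sums P(X = j) over every outcome j no
    more likely than the observed one — the small-probability definition of
    the two-sided p-value.  ``method="central"`` doubles the smaller tail.
    Both are capped at 1.
    """
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly in (0, 1)")
    j = np.arange(n + 1)
    pmf = binom.pmf(j, n, p0)
    if method == "minlike":
        p = pmf[pmf <= pmf[k] * (1.0 + _MINLIKE_RELATIVE_GUARD)].sum()
    elif method == "central":
        p = 2.0 * min(pmf[: k + 1].sum(), pmf[k:].sum())
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(min(1.0, p))


def summarize_fields(fields: pd.DataFrame) -> pd.DataFrame:
    """Per-animal densities and marker proportions from a field-count table.

    ``fields`` holds one row per imaged field with columns ``animal``,
    ``region`` (PSI/DSI/PCO/DCO), ``plexus`` (myenteric/submucosal),
    ``total_count``, ``field_area_um2`` and any number of additional
    ``<marker>_count`` columns.  Technical replicates (fields) are averaged
    within animal x region x plexus; marker proportions are percentages of
    the summed total count.
    """
    required = {"animal", "region", "plexus", "total_count", "field_area_um2"}
    missing = required - set(fields.columns)
    if missing:
        raise ValueError(f"field table is missing columns: {sorted(missing)}")
    if (fields["field_area_um2"] <= 0).any():
        raise ValueError("field areas must be positive")
    marker_cols = [c for c in fields.columns if c.endswith("_count") and c != "total_count"]
    bad = fields[marker_cols].gt(fields["total_count"], axis=0)
    if bad.to_numpy().any():
        raise ValueError("marker counts cannot exceed the total count")

    df = fields.copy()
    df["density_per_mm2"] = df["total_count"] / (df["field_area_um2"] / UM2_PER_MM2)
    grouped = df.groupby(["animal", "region", "plexus"])
    out = grouped.agg(
        n_fields=("total_count", "size"),
        mean_density_per_mm2=("density_per_mm2", "mean"),
        total_count=("total_count", "sum"),
    )
    for c in marker_cols:
        marker = c.removesuffix("_count")
        out[f"pct_{marker}"] = 100.0 * grouped[c].sum() / out["total_count"]
    return out.reset_index()
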