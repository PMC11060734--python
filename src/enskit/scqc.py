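"""Single-cell QC filtering, PC-count selection, and marker-gene rules.

Stand-alone implementations of three numeric rules common to droplet
scRNA-seq pipelines:

* **cell filter** — keep a cell iff it has more than 1,500 detected genes
  (removes low expressors), fewer than 50,000 UMIs (removes likely
  doublets), and at most 10% mitochondrial reads (removes damaged cells).
  The gene and UMI bounds are strict as printed; "remove >10% mito" is
  read as keep <= 10%.  All cutoffs are parameters.
* **PC selection** — given the descending standard deviations of a PCA,
  stop at the earlier of (a) the first component after which the next
  component contributes less than 5% of the total SD while the cumulative
  contribution has reached 90%, or (b) the first component whose
  contribution differs from the next by less than 0.1 percentage points
  (the spectrum has flattened).
* **marker rule** — a gene is a candidate marker of a cluster only when
  expressed (count > 0) in more than 10% of that cluster's cells, and is
  called enriched when ln((mean_in + eps)/(mean_out + eps)) exceeds 0.25,
  with a pseudocount eps (default 1).

Normalisation, integration, clustering and embedding are the province of
established toolkits and are deliberately not re-implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

QC_COLUMNS = ("n_genes", "n_umis", "pct_mito")


@dataclass(frozen=True)
class QCThresholds:
    """Cell-filter cutoffs; defaults are the standard printed values."""

    min_genes_exclusive: int = 1_500
    max_umis_exclusive: int = 50_000
    max_pct_mito_inclusive: float = 10.0

    def __post_init__(self) -> None:
        if min(self.min_genes_exclusive, self.max_umis_exclusive) <= 0:
            raise ValueError("count thresholds must be positive")
        if self.max_pct_mito_inclusive <= 0:
            raise ValueError("mito threshold must be positive")


def _validate_qc_table(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in QC_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"QC table is missing columns: {missing}")
    ids = (
        records["cell_id"].astype(str)
        if "cell_id" in records.columns
        else records.index.astype(str)
    )
    for i, (cid, g, u, m) in enumerate(
        zip(ids, records["n_genes"], records["n_umis"], records["pct_mito"])
    ):
        if not np.isfinite([g, u, m]).all():
            raise ValueError(f"malformed QC record for cell {cid!r}: non-finite value")
        if g < 0 or u < 0 or g > u:
            raise ValueError(
                f"malformed QC record for cell {cid!r}: need 0 <= n_genes <= n_umis"
            )
        if not 0 <= m <= 100:
            raise ValueError(
                f"malformed QC record for cell {cid!r}: pct_mito outside [0, 100]"
            )
    return records.set_axis(ids, axis=0) if "cell_id" in records.columns else records


class CellQCFilter(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer applying the three-rule cell filter.

    Attributes (after ``fit``)
    --------------------------
    keep_mask_ : ndarray of bool, per input row
    kept_ids_ : list of cell ids that pass
    reasons_ : DataFrame indexed by cell id with boolean columns
        ``low_n_genes``, ``high_n_umis``, ``high_pct_mito`` and a
        semicolon-joined ``reasons`` string (empty for kept cells).
    """

    def __init__(
        self,
        min_genes: int = 1_500,
        max_umis: int = 50_000,
        max_pct_mito: float = 10.0,
    ):
        self.min_genes = min_genes
        self.max_umis = max_umis
        self.max_pct_mito = max_pct_mito

    def fit(self, X: pd.DataFrame, y=None) -> "CellQCFilter":
        thr = QCThresholds(self.min_genes, self.max_umis, self.max_pct_mito)
        records = _validate_qc_table(X)
        low_genes = records["n_genes"].to_numpy() <= thr.min_genes_exclusive
        high_umis = records["n_umis"].to_numpy() >= thr.max_umis_exclusive
        high_mito = records["pct_mito"].to_numpy() > thr.max_pct_mito_inclusive
        reasons = pd.DataFrame(
            {
                "low_n_genes": low_genes,
                "high_n_umis": high_umis,
                "high_pct_mito": high_mito,
            },
            index=records.index,
        )
        reasons["reasons"] = [
            ";".join(col for col, flag in zip(reasons.columns[:3], flags) if flag)
            for flags in reasons.to_numpy()
        ]
        self.keep_mask_ = ~(low_genes | high_umis | high_mito)
        self.kept_ids_ = list(records.index[self.keep_mask_])
        self.reasons_ = reasons
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "keep_mask_"):
            raise RuntimeError("call fit() before transform()")
        return X.loc[np.asarray(self.keep_mask_)]


def filter_cells(
    records: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[list, pd.DataFrame]:
    """Apply the cell filter; returns (kept cell ids, rejection reasons)."""
    thr = thresholds or QCThresholds()
    f = CellQCFilter(
        thr.min_genes_exclusive, thr.max_umis_exclusive, thr.max_pct_mito_inclusive
    ).fit(records)
    return f.kept_ids_, f.reasons_


class PCSelector(BaseEstimator):
    """Select the number of principal components to retain.

    With ``contrib_i = 100 * sd_i / sum(sd)`` and cumulative ``cum_i``:
    clause A fires at the first i with ``contrib_{i+1} < pct_contrib_cut``
    and ``cum_i >= cum_pct_cut``; clause B fires at the first i with
    ``|contrib_i - contrib_{i+1}| < delta_pct_cut``.  The selected count is
    the earlier of the two, or the full spectrum if neither fires.
    """

    def __init__(
        self,
        pct_contrib_cut: float = 5.0,
        cum_pct_cut: float = 90.0,
        delta_pct_cut: float = 0.1,
    ):
        self.pct_contrib_cut = pct_contrib_cut
        self.cum_pct_cut = cum_pct_cut
        self.delta_pct_cut = delta_pct_cut

    def fit(self, spectrum, y=None) -> "PCSelector":
        sd = np.asarray(spectrum, dtype=float)
        if sd.ndim != 1 or sd.size < 2:
            raise ValueError("need at least 2 component standard deviations")
        if np.any(sd <= 0):
            raise ValueError("standard deviations must be positive")
        if np.any(np.diff(sd) > 0):
            raise ValueError("spectrum must be nonincreasing")
        contrib = 100.0 * sd / sd.sum()
        cum = np.cumsum(contrib)
        n = sd.size
        k_a = k_b = n
        for i in range(n - 1):  # i is 0-based; rules are stated 1-based
            if contrib[i + 1] < self.pct_contrib_cut and cum[i] >= self.cum_pct_cut:
                k_a = i + 1
                break
        for i in range(n - 1):
            if abs(contrib[i] - contrib[i + 1]) < self.delta_pct_cut:
                k_b = i + 1
                break
        self.n_components_ = int(min(k_a, k_b))
        self.contributions_ = contrib
        return self


def select_pcs(
    spectrum,
    pct_contrib_cut: float = 5.0,
    cum_pct_cut: float = 90.0,
    delta_pct_cut: float = 0.1,
) -> int:
    """Functional wrapper over :class:`PCSelector`."""
    return PCSelector(pct_contrib_cut, cum_pct_cut, delta_pct_cut).fit(spectrum).n_components_


@dataclass(frozen=True)
class MarkerCriteria:
    """Marker-gene inclusion thresholds."""

    min_pct_expressing: float = 0.10
    min_ln_fc: float = 0.25
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_pct_expressing <= 1.0:
            raise ValueError("min_pct_expressing must lie in [0, 1]")
        if self.min_ln_fc < 0:
            raise ValueError("min_ln_fc must be nonnegative")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


class MarkerFinder(BaseEstimator):
    """Per-cluster marker table under the percent-gate and ln-FC rules.

    ``fit(X, y)`` takes a gene x cell expression matrix (DataFrame with
    genes as rows, or ndarray) and per-cell cluster labels; the fitted
    ``markers_`` DataFrame has one row per (cluster, gene) with
    ``pct_in``, ``pct_out``, ``ln_fc``, the percent-gate ``candidate``
    flag, and ``enriched`` (candidate and ln_fc above threshold).
    """

    def __init__(
        self,
        min_pct_expressing: float = 0.10,
        min_ln_fc: float = 0.25,
        pseudocount: float = 1.0,
    ):
        self.min_pct_expressing = min_pct_expressing
        self.min_ln_fc = min_ln_fc
        self.pseudocount = pseudocount

    def fit(self, X, y) -> "MarkerFinder":
        crit = MarkerCriteria(self.min_pct_expressing, self.min_ln_fc, self.pseudocount)
        if isinstance(X, pd.DataFrame):
            genes = list(X.index)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            genes = [f"gene_{g}" for g in range(values.shape[0])]
        if values.ndim != 2:
            raise ValueError("expression matrix must be 2-D (genes x cells)")
        if np.any(values < 0):
            raise ValueError("expression values must be nonnegative")
        labels = np.asarray(y)
        if labels.shape[0] != values.shape[1]:
            raise ValueError("one cluster label per cell is required")
        clusters = pd.unique(labels)
        if len(clusters) < 2:
            raise ValueError("need at least 2 clusters to compare")

        rows = []
        eps = crit.pseudocount
        for cl in clusters:
            mask = labels == cl
            if mask.sum() == 0 or (~mask).sum() == 0:
                raise ValueError(f"cluster {cl!r} has no cells on one side")
            pct_in = (values[:, mask] > 0).mean(axis=1)
            pct_out = (values[:, ~mask] > 0).mean(axis=1)
            ln_fc = np.log(
                (values[:, mask].mean(axis=1) + eps)
                / (values[:, ~mask].mean(axis=1) + eps)
            )
            candidate = pct_in > crit.min_pct_expressing
            rows.append(
                pd.DataFrame(
                    {
                        "cluster": cl,
                        "gene": genes,
                        "pct_in": pct_in,
                        "pct_out": pct_out,
                        "ln_fc": ln_fc,
                        "candidate": candidate,
                        "enriched": candidate & (ln_fc > crit.min_ln_fc),
                    }
                )
            )
        self.markers_ = pd.concat(rows, ignore_index=True)
        return self


def find_markers(X, labels, criteria: MarkerCriteria | None = None) -> pd.DataFrame:
    """Functional wrapper over :class:`MarkerFinder`."""
    crit = criteria or MarkerCriteria()
    return (
        MarkerFinder(crit.min_pct_expressing, crit.min_ln_fc, crit.pseudocount)
        .fit(X, labels)
        .markers_
    )
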