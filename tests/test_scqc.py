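"""Cell filtering, PC-count selection, and marker-gene rules."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enskit.scqc import (
    CellQCFilter,
    MarkerCriteria,
    MarkerFinder,
    PCSelector,
    QCThresholds,
    filter_cells,
    find_markers,
    select_pcs,
)
from enskit.synthetic import generate_labeled_expression, generate_qc_table


def brute_force_filter(df, min_genes=1500, max_umis=50000, max_mito=10.0):
    kept = []
    for _, row in df.iterrows():
        if row.n_genes > min_genes and row.n_umis < max_umis and row.pct_mito <= max_mito:
            kept.append(row.cell_id if "cell_id" in df.columns else row.name)
    return kept


TOY_QC = pd.DataFrame(
    {
        "cell_id": [f"c{i}" for i in range(6)],
        "n_genes": [2000, 1500, 2500, 3000, 1800, 2200],
        "n_umis": [10_000, 9_000, 50_000, 12_000, 11_000, 9_500],
        "pct_mito": [5.0, 4.0, 6.0, 12.0, 9.9, 10.0],
    }
)


class TestFilterCells:
    def test_clean_cell_kept(self):
        kept, reasons = filter_cells(
            pd.DataFrame({"cell_id": ["a"], "n_genes": [2000],
                          "n_umis": [10_000], "pct_mito": [5.0]})
        )
        assert kept == ["a"] and reasons.loc["a", "reasons"] == ""

    def test_gene_boundary_is_strict(self):
        kept, reasons = filter_cells(
            pd.DataFrame({"cell_id": ["edge"], "n_genes": [1500],
                          "n_umis": [10_000], "pct_mito": [5.0]})
        )
        assert kept == [] and reasons.loc["edge", "reasons"] == "low_n_genes"

    def test_toy_table_one_violation_per_rule(self):
        kept, reasons = filter_cells(TOY_QC)
        assert kept == ["c0", "c4", "c5"]  # mito boundary 10.0 is kept
        assert reasons.loc["c1", "low_n_genes"]
        assert reasons.loc["c2", "high_n_umis"]
        assert reasons.loc["c3", "high_pct_mito"]

    def test_matches_brute_force_on_random_tables(self):
        for seed in range(4):
            table = generate_qc_table(300, umi_mean=30_000, umi_sd=20_000,
                                      mito_mean_pct=8.0, mito_sd_pct=4.0, seed=seed)
            kept, _ = filter_cells(table)
            assert kept == brute_force_filter(table)

    @given(st.integers(1000, 4000), st.integers(5_000, 60_000), st.floats(1.0, 20.0))
    @settings(deadline=None, max_examples=40)
    def test_survivors_nonincreasing_as_thresholds_tighten(self, g, u, m):
        table = generate_qc_table(200, umi_mean=20_000, umi_sd=15_000,
                                  mito_mean_pct=8.0, mito_sd_pct=5.0, seed=9)
        loose, _ = filter_cells(table, QCThresholds(1, 10**9, 100.0))
        mid, _ = filter_cells(table, QCThresholds(g, u, m))
        tight, _ = filter_cells(table, QCThresholds(g + 500, max(u - 4000, 1), max(m - 1, 0.5)))
        assert set(tight) <= set(mid) <= set(loose)

    def test_malformed_record_names_cell(self):
        bad = pd.DataFrame({"cell_id": ["weird"], "n_genes": [500],
                            "n_umis": [100], "pct_mito": [5.0]})
        with pytest.raises(ValueError, match="weird"):
            filter_cells(bad)

    def test_transformer_interface(self):
        f = CellQCFilter().fit(TOY_QC)
        out = f.transform(TOY_QC)
        assert list(out["cell_id"]) == ["c0", "c4", "c5"]
        assert f.keep_mask_.sum() == 3


class TestSelectPcs:
    def test_dominant_first_component(self):
        # clause A fires at i=1 (cum 91.7%, next contributes 0.9%),
        # clause B fires at i=2 (consecutive change 0): min is 1
        assert select_pcs([10.0] + [0.1] * 9) == 1

    def test_flat_spectrum_stops_immediately(self):
        assert select_pcs([1.0] * 10) == 1

    def test_geometric_spectrum_frozen_value(self):
        # ratio-1/2 spectrum, 20 components: cumulative hits 90% with the
        # next contribution below 5% at k=4; the flatness clause fires at 9
        sds = [0.5**i for i in range(20)]
        assert select_pcs(sds) == 4

    def test_neither_clause_firing_keeps_all(self):
        # contributions 40/30/20/10: never below 5% and gaps are >= 0.1
        assert select_pcs([4.0, 3.0, 2.0, 1.0]) == 4

    def test_non_descending_rejected(self):
        with pytest.raises(ValueError, match="nonincreasing"):
            select_pcs([1.0, 2.0, 0.5])

    @given(st.floats(0.01, 100.0))
    @settings(deadline=None, max_examples=40)
    def test_invariant_under_uniform_scaling(self, c):
        sds = np.array([8.0, 4.0, 2.0, 1.0, 0.5, 0.25])
        assert select_pcs(sds) == select_pcs(c * sds)

    def test_never_exceeds_component_count(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sds = np.sort(rng.uniform(0.1, 10.0, rng.integers(2, 15)))[::-1]
            assert select_pcs(sds) <= len(sds)

    def test_estimator_exposes_contributions(self):
        sel = PCSelector().fit([10.0, 5.0, 1.0])
        assert sel.contributions_.sum() == pytest.approx(100.0)


TOY_EXPR = pd.DataFrame(
    # 3 genes x 12 cells; first 6 cells cluster "a", rest "b"
    [
        [5, 4, 6, 5, 7, 4, 0, 1, 0, 0, 0, 0],  # marker of a
        [0, 0, 0, 0, 0, 1, 4, 6, 5, 5, 4, 7],  # marker of b
        [2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2],  # flat
    ],
    index=["g_a", "g_b", "g_flat"],
    columns=[f"cell{i}" for i in range(12)],
)
TOY_LABELS = np.array(["a"] * 6 + ["b"] * 6)


def brute_force_markers(expr, labels, crit=MarkerCriteria()):
    rows = []
    for cl in pd.unique(labels):
        inside = [c for c, l in zip(expr.columns, labels) if l == cl]
        outside = [c for c in expr.columns if c not in inside]
        for gene in expr.index:
            x_in = expr.loc[gene, inside]
            x_out = expr.loc[gene, outside]
            pct_in = sum(v > 0 for v in x_in) / len(inside)
            ln_fc = math.log(
                (sum(x_in) / len(inside) + crit.pseudocount)
                / (sum(x_out) / len(outside) + crit.pseudocount)
            )
            rows.append(
                {
                    "cluster": cl,
                    "gene": gene,
                    "pct_in": pct_in,
                    "ln_fc": ln_fc,
                    "enriched": pct_in > crit.min_pct_expressing
                    and ln_fc > crit.min_ln_fc,
                }
            )
    return pd.DataFrame(rows)


class TestFindMarkers:
    def test_percent_gate_excludes_rare_gene(self):
        # expressed in 1 of 20 in-cluster cells (5%) but hugely enriched
        expr = np.zeros((1, 40))
        expr[0, 0] = 100.0
        labels = np.array(["in"] * 20 + ["out"] * 20)
        table = find_markers(expr, labels)
        row = table[(table.cluster == "in")].iloc[0]
        assert not row.candidate and not row.enriched and row.ln_fc > 0.25

    def test_identical_means_not_enriched(self):
        expr = np.tile([[1.0]], (1, 10))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        table = find_markers(expr, labels)
        assert np.allclose(table.ln_fc, 0.0)
        assert not table.enriched.any()

    def test_toy_matrix_matches_brute_force(self):
        got = find_markers(TOY_EXPR, TOY_LABELS).set_index(["cluster", "gene"])
        want = brute_force_markers(TOY_EXPR, TOY_LABELS).set_index(["cluster", "gene"])
        for key in want.index:
            assert got.loc[key, "pct_in"] == pytest.approx(want.loc[key, "pct_in"])
            assert got.loc[key, "ln_fc"] == pytest.approx(want.loc[key, "ln_fc"])
            assert got.loc[key, "enriched"] == want.loc[key, "enriched"]

    def test_swapping_clusters_negates_ln_fc(self):
        table = find_markers(TOY_EXPR, TOY_LABELS).set_index(["cluster", "gene"])
        for gene in TOY_EXPR.index:
            assert table.loc[("a", gene), "ln_fc"] == pytest.approx(
                -table.loc[("b", gene), "ln_fc"], abs=1e-12
            )

    def test_planted_markers_recovered(self):
        expr, labels = generate_labeled_expression(seed=4)
        table = find_markers(expr, labels.to_numpy())
        planted_a = {"gene_000", "gene_001", "gene_002"}
        found = set(table[(table.cluster == "c0") & table.enriched].gene)
        assert planted_a <= found

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            find_markers(np.ones((2, 4)), np.array(["a"] * 4))

    def test_negative_expression_rejected(self):
        with pytest.raises(ValueError):
            find_markers(-np.ones((2, 4)), np.array(["a", "a", "b", "b"]))

    def test_estimator_clone(self):
        from sklearn.base import clone

        mf = MarkerFinder(min_pct_expressing=0.2)
        assert clone(mf).get_params()["min_pct_expressing"] == 0.2
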