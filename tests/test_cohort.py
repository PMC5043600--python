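"""Editing level, editing matrix, clustering, correlation, RPKM,
stage summaries and stage-specificity tests."""

import numpy as np
import pandas as pd
import pytest

from editome.cohort import (build_editing_matrix, cell_editing_levels,
                            cluster_cells, correlate, cut_clusters,
                            editing_level, expression_vs_frequency,
                            rank_sum_test, rpkm, stage_specific_editing,
                            stage_summaries, to_newick)


class TestEditingLevel:
    def test_no_sites_zero(self):
        assert editing_level(0, 10**7) == 0.0

    def test_arithmetic(self):
        assert editing_level(50, 10**7) == pytest.approx(5.0)

    def test_scale_invariance(self):
        assert editing_level(100, 2 * 10**7) == editing_level(50, 10**7)

    def test_zero_mapped_errors(self):
        with pytest.raises(ValueError):
            editing_level(5, 0)


def make_annotated(rows):
    df = pd.DataFrame(rows, columns=["cell_id", "chrom", "pos", "freq",
                                     "k", "retained"])
    return df


class TestEditingMatrix:
    def setup_method(self):
        self.annotated = make_annotated([
            ("c1", "c", 100, 0.3, 6, True),
            ("c2", "c", 200, 0.5, 5, True),
        ])
        self.depths = pd.DataFrame({
            "cell_id": ["c1", "c1", "c2", "c2"],
            "chrom": ["c"] * 4, "pos": [100, 200, 100, 200],
            "depth": [20, 10, 3, 10]})

    def test_codes(self):
        m = build_editing_matrix(self.annotated, self.depths)
        assert m.loc["c1", "c:100"] == pytest.approx(0.3)   # k=6, n=20
        assert m.loc["c1", "c:200"] == 0.0                  # covered, no edit
        assert m.loc["c2", "c:100"] == -1.0                 # depth 3
        assert m.loc["c2", "c:200"] == pytest.approx(0.5)

    def test_column_order_deterministic(self):
        m = build_editing_matrix(self.annotated, self.depths)
        assert list(m.columns) == ["c:100", "c:200"]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            build_editing_matrix(make_annotated([]), self.depths)


class TestClustering:
    def test_identical_rows_merge_first(self):
        m = pd.DataFrame([[0.1, 0.2], [0.1, 0.2], [0.9, 0.9]],
                         index=["a", "b", "c"])
        Z, tree = cluster_cells(m)
        assert Z[0, 2] == 0.0  # first merge at distance zero
        assert {"a", "b", "c"} == {t.name for t in tree.tips()}

    def test_euclidean_distance(self):
        m = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"])
        Z, _ = cluster_cells(m)
        assert Z[0, 2] == pytest.approx(np.sqrt(2))

    def test_two_group_recovery(self):
        rng = np.random.default_rng(31)
        hi = rng.uniform(0.4, 0.8, (6, 40))
        lo = rng.uniform(0.0, 0.05, (6, 40))
        m = pd.DataFrame(np.vstack([hi, lo]))
        Z, _ = cluster_cells(m)
        labels = cut_clusters(Z, 2)
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[-1]

    def test_single_cell_errors(self):
        with pytest.raises(ValueError):
            cluster_cells(pd.DataFrame([[1.0]]))

    def test_newick_roundtrip(self):
        m = pd.DataFrame(np.eye(3), index=["x", "y", "z"])
        _, tree = cluster_cells(m)
        nwk = to_newick(tree)
        assert nwk.endswith(";") and all(n in nwk for n in "xyz")


class TestCorrelate:
    def test_perfect_linear(self):
        r, _ = correlate([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_monotone_decreasing_spearman(self):
        r, _ = correlate([1, 2, 3, 4], [10, 7, 3, 1], method="spearman")
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(37)
        x = rng.normal(size=10)
        y = 0.4 * x + rng.normal(size=10)
        r, _ = correlate(x, y)
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean())**2) * np.sum((y - y.mean())**2))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1], [1, 2, 3])


class TestRpkm:
    def test_formula(self):
        assert rpkm(10, 1000, 10**6) == pytest.approx(10.0)

    def test_zero_count(self):
        assert rpkm(0, 1000, 10**6) == 0.0

    def test_total_scaling(self):
        assert rpkm(10, 1000, 2 * 10**6) == pytest.approx(
            rpkm(10, 1000, 10**6) / 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rpkm(10, 0, 10**6)


class TestRankSum:
    def test_shifted_distributions_significant(self):
        rng = np.random.default_rng(41)
        a = rng.normal(0, 1, 15)
        b = rng.normal(2.5, 1, 15)
        assert rank_sum_test(a, b) < 0.05

    def test_identical_samples_not_significant(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [1.5, 2.5, 3.5, 4.5]
        assert rank_sum_test(a, b) > 0.5


class TestStageSummaries:
    def levels_frame(self, spec):
        rows = []
        for stage, values in spec.items():
            for i, v in enumerate(values):
                rows.append({"cell_id": f"{stage}{i}", "stage": stage,
                             "n_sites": int(v * 10), "editing_level": v})
        return pd.DataFrame(rows)

    def test_single_cell_stage_flagged(self):
        lv = self.levels_frame({"oocyte": [5.0], "zygote": [4.0, 6.0]})
        summaries, _ = stage_summaries(lv)
        s = {x.stage: x for x in summaries}
        assert s["oocyte"].single_cell and s["oocyte"].sd_level == 0.0
        assert not s["zygote"].single_cell

    def test_shifted_stages_significant(self):
        rng = np.random.default_rng(43)
        lv = self.levels_frame({"4cell": list(rng.normal(10, 1, 12)),
                                "8cell": list(rng.normal(3, 1, 12))})
        _, ranksum = stage_summaries(lv)
        assert ranksum.iloc[0]["rank_sum_p"] < 0.05

    def test_stage_order_follows_development(self):
        lv = self.levels_frame({"morula": [1.0, 2.0], "oocyte": [5.0, 6.0]})
        summaries, _ = stage_summaries(lv)
        assert [s.stage for s in summaries] == ["oocyte", "morula"]


class TestExpressionVsFrequency:
    def fixture_tables(self, freqs, exprs):
        cells = [f"c{i}" for i in range(len(freqs))]
        annotated = pd.DataFrame({
            "cell_id": cells, "chrom": "c", "pos": 100,
            "freq": freqs, "k": 5, "retained": True, "feature": "3UTR",
            "gene_id": "g1"})
        matrix = pd.DataFrame({"c:100": freqs}, index=cells)
        expression = pd.DataFrame([exprs], index=["g1"], columns=cells)
        return annotated, matrix, expression

    def test_perfect_anticorrelation(self):
        ann, m, e = self.fixture_tables(
            [0.9, 0.7, 0.5, 0.3, 0.1], [1, 2, 3, 4, 5])
        out = expression_vs_frequency(ann, m, e)
        assert out.iloc[0]["spearman_r"] == pytest.approx(-1.0)

    def test_insufficient_cells_skipped(self):
        ann, m, e = self.fixture_tables([0.5, 0.4], [1, 2])
        assert len(expression_vs_frequency(ann, m, e)) == 0

    def test_null_flag_rate_controlled(self):
        """Independent frequency and expression across many genes yields
        BH flags at no more than the nominal rate."""
        rng = np.random.default_rng(47)
        cells = [f"c{i}" for i in range(20)]
        rows, mats, exprs = [], {}, {}
        for g in range(60):
            freqs = rng.uniform(0.1, 0.9, 20)
            rows += [{"cell_id": c, "chrom": "c", "pos": 100 + g,
                      "freq": f, "k": 5, "retained": True,
                      "feature": "3UTR", "gene_id": f"g{g}"}
                     for c, f in zip(cells, freqs)]
            mats[f"c:{100 + g}"] = freqs
            exprs[f"g{g}"] = rng.lognormal(2, 1, 20)
        out = expression_vs_frequency(
            pd.DataFrame(rows), pd.DataFrame(mats, index=cells),
            pd.DataFrame(exprs, index=cells).T)
        assert out["flagged"].mean() <= 0.1


class TestStageSpecificEditing:
    def cohort_meta(self, per_stage=6):
        rows = []
        for stage in ["oocyte", "zygote", "2cell", "4cell", "8cell"]:
            for i in range(per_stage):
                rows.append({"cell_id": f"{stage}{i}", "stage": stage,
                             "embryo_id": f"E{stage}{i % 2}"})
        return pd.DataFrame(rows)

    def test_single_stage_gene_flagged(self):
        meta = self.cohort_meta()
        edited = pd.DataFrame({"gene_id": "gA",
                               "cell_id": [f"oocyte{i}" for i in range(6)]})
        out = stage_specific_editing(edited, meta, mode="single_stage")
        flagged = out.loc[out["flagged"]]
        assert list(flagged["window"]) == ["oocyte"]
        # hypergeometric oracle for 6/6 edited in-stage vs 0/24 out:
        # the observed table is the most extreme; its probability is
        # 1 / C(30, 6) and no other table is as improbable
        import math
        assert flagged.iloc[0]["p"] == pytest.approx(
            1 / math.comb(30, 6), abs=1e-12)

    def test_uniform_editing_not_flagged(self):
        meta = self.cohort_meta()
        edited = pd.DataFrame({
            "gene_id": "gB",
            "cell_id": [f"{s}{i}" for s in
                        ["oocyte", "zygote", "2cell", "4cell", "8cell"]
                        for i in range(3)]})
        out = stage_specific_editing(edited, meta, mode="single_stage")
        assert not out["flagged"].any()

    def test_two_sequential_window(self):
        meta = self.cohort_meta()
        edited = pd.DataFrame({
            "gene_id": "gC",
            "cell_id": [f"zygote{i}" for i in range(6)]
            + [f"2cell{i}" for i in range(6)]})
        out = stage_specific_editing(edited, meta, mode="two_sequential")
        flagged = out.loc[out["flagged"], "window"].tolist()
        assert "zygote+2cell" in flagged

    def test_small_stages_excluded(self):
        meta = self.cohort_meta(per_stage=6)
        meta = pd.concat([meta, pd.DataFrame([
            {"cell_id": "pronucleus0", "stage": "pronucleus",
             "embryo_id": "EP0"}])], ignore_index=True)
        edited = pd.DataFrame({"gene_id": "gD", "cell_id": ["pronucleus0"]})
        out = stage_specific_editing(edited, meta, mode="single_stage")
        assert not (out["window"] == "pronucleus").any() if len(out) else True


def test_cell_editing_levels_from_pipeline(small_result, small_cohort):
    lv = small_result.levels
    retained = small_result.annotated.loc[small_result.annotated["retained"]]
    cell = retained["cell_id"].iloc[0]
    expected = 1e6 * retained.loc[retained["cell_id"] == cell, "k"].sum() / \
        int(small_cohort.meta.set_index("cell_id")
            .loc[cell, "uniquely_mapped_bases"])
    got = lv.set_index("cell_id").loc[cell, "editing_level"]
    assert got == pytest.approx(expected)
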