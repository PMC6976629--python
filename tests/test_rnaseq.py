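"""Transcriptomics stage: filter, log-CPM, DE calls, Jaccard, clustering, MDS."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from arginet import rnaseq, syndata
from arginet.errors import DegenerateSampleError, InvalidThresholdError

from conftest import SEED, make_expr


def counts_from_cpm(cpm_rows, lib_size=1_000_000):
    """Counts whose CPM equals the given rows (library size fixed by a
    padding gene)."""
    arr = np.asarray(cpm_rows, dtype=float)
    counts = arr * lib_size / 1e6
    pad = lib_size - counts.sum(axis=0)
    data = np.vstack([counts, pad]).round().astype(int)
    genes = [f"g{i}" for i in range(arr.shape[0])] + ["pad"]
    return pd.DataFrame(data, index=genes, columns=[f"s{j}" for j in range(arr.shape[1])])


class TestFilterExpressed:
    def test_threshold_arithmetic(self):
        c = counts_from_cpm([[0.8, 0.8, 0.8, 0.1]])
        assert rnaseq.filter_expressed(c, min_samples=3)["g0"]

    def test_boundary_is_strict(self):
        # library size 4e6 makes CPM exactly 0.75 with integer count 3
        c = counts_from_cpm([[0.75, 0.75, 0.75, 0.75]], lib_size=4_000_000)
        assert (rnaseq.cpm(c).loc["g0"] == 0.75).all()
        assert not rnaseq.filter_expressed(c, min_samples=3)["g0"]

    def test_all_zero_gene_dropped(self):
        c = counts_from_cpm([[0.0, 0.0, 0.0, 0.0]])
        assert not rnaseq.filter_expressed(c, min_samples=3)["g0"]

    def test_log_base_free(self):
        """The filter inequality log(CPM+0.25)>0 is equivalent to
        CPM>0.75 in any base; spot-check against natural log."""
        rng = np.random.default_rng(SEED)
        cpm_vals = rng.uniform(0, 3, size=(50, 4))
        c = counts_from_cpm(cpm_vals)
        mask = rnaseq.filter_expressed(c, min_samples=3)
        x = rnaseq.cpm(c)
        oracle = (np.log(x + 0.25) > 0).sum(axis=1) >= 3
        pd.testing.assert_series_equal(mask, oracle)

    def test_min_samples_exceeding_samples_rejected(self):
        c = counts_from_cpm([[1, 1, 1, 1]])
        with pytest.raises(InvalidThresholdError):
            rnaseq.filter_expressed(c, min_samples=5)


class TestNormalizeLogcpm:
    def test_all_zero_sample_errors(self):
        c = pd.DataFrame({"s1": [0, 0], "s2": [5, 5]}, index=["a", "b"])
        with pytest.raises(DegenerateSampleError):
            rnaseq.normalize_logcpm(c)

    def test_zero_counts_finite_and_equal(self):
        c = pd.DataFrame({"s1": [0, 0, 10], "s2": [3, 4, 5]}, index=list("abc"))
        e = rnaseq.normalize_logcpm(c)
        assert np.isfinite(e.to_numpy()).all()
        assert e.loc["a", "s1"] == e.loc["b", "s1"]

    def test_monotone_in_count(self):
        c = pd.DataFrame({"s1": [10, 20, 70]}, index=list("abc"))
        e = rnaseq.normalize_logcpm(c)
        assert e.loc["b", "s1"] > e.loc["a", "s1"]

    def test_composition_bias_corrected(self, design_ab):
        """A dominant gene massively induced in one condition must not
        drag apparent fold changes of unchanged genes (median-of-ratios
        library scaling)."""
        rng = np.random.default_rng(SEED)
        base = np.tile(rng.integers(100, 1000, size=(200, 1)), (1, 8))
        counts = pd.DataFrame(base, index=[f"g{i}" for i in range(200)],
                              columns=design_ab.sample_ids)
        # one gene holds ~half the library and goes up 8x in B
        counts.loc["g0"] = 100_000
        counts.loc["g0", design_ab.samples_for("B")] *= 8
        e = rnaseq.normalize_logcpm(counts)
        a = e[design_ab.samples_for("A")].mean(axis=1)
        b = e[design_ab.samples_for("B")].mean(axis=1)
        null_lfc = (a - b).drop("g0")
        assert null_lfc.abs().median() < 0.2
        # without scaling the distortion is large (sanity contrast)
        e_raw = rnaseq.normalize_logcpm(counts, scale_libraries=False)
        raw_lfc = (e_raw[design_ab.samples_for("A")].mean(axis=1)
                   - e_raw[design_ab.samples_for("B")].mean(axis=1)).drop("g0")
        assert raw_lfc.abs().median() > 1.0

    def test_scale_invariance(self, design_ab):
        """Multiplying a column by a constant leaves log-CPM unchanged;
        exactly proportional columns are identical."""
        c, _ = syndata.gen_counts(50, design_ab, seed=SEED)
        doubled = c.copy()
        doubled.iloc[:, 0] = 2 * doubled.iloc[:, 0]
        e1 = rnaseq.normalize_logcpm(c)
        e2 = rnaseq.normalize_logcpm(doubled)
        np.testing.assert_allclose(
            e1.iloc[:, 0].to_numpy(), e2.iloc[:, 0].to_numpy(), atol=1e-12
        )


class TestTestDE:
    def test_identical_groups_not_called(self, design_ab):
        vals = np.tile(np.arange(1.0, 6.0)[:, None], (1, 8))
        e = make_expr(vals, design_ab.sample_ids)
        de = rnaseq.test_de(e, design_ab, ("A", "B"))
        assert (de.table["log2fc"] == 0).all()
        assert not de.table["called"].any()

    def test_null_fdr_control(self, design_ab):
        """With no planted effects, essentially nothing is called."""
        c, _ = syndata.gen_counts(2000, design_ab, de_fraction=0.0,
                                  dispersion=0.05, seed=SEED)
        e = rnaseq.normalize_logcpm(c.loc[rnaseq.filter_expressed(c)])
        de = rnaseq.test_de(e, design_ab, ("A", "B"))
        assert (de.table["fdr"] < 0.05).mean() <= 0.01

    def test_null_pvalues_uniform(self, design_ab):
        c, _ = syndata.gen_counts(2000, design_ab, de_fraction=0.0,
                                  dispersion=0.05, seed=SEED + 3)
        e = rnaseq.normalize_logcpm(c.loc[rnaseq.filter_expressed(c)])
        de = rnaseq.test_de(e, design_ab, ("A", "B"))
        assert kstest(de.table["p"], "uniform").statistic < 0.05

    def test_called_respects_both_thresholds(self, design_ab):
        c, _ = syndata.gen_counts(500, design_ab, de_fraction=0.2,
                                  lfc_magnitude=3.0, seed=SEED)
        e = rnaseq.normalize_logcpm(c.loc[rnaseq.filter_expressed(c)])
        de = rnaseq.test_de(e, design_ab, ("A", "B"))
        t = de.table
        assert (t.loc[t["called"], "log2fc"].abs() > 1.0).all()
        assert (t.loc[t["called"], "fdr"] < 0.05).all()

    def test_unknown_condition_rejected(self, design_ab):
        e = make_expr(np.zeros((3, 8)), design_ab.sample_ids)
        with pytest.raises(Exception):
            rnaseq.test_de(e, design_ab, ("A", "Z"))


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"a", "b"}, {"b", "c"}, 1 / 3),
            ({"a", "b"}, {"a", "b"}, 1.0),
            (set(), set(), 1.0),
            ({"a"}, set(), 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert rnaseq.jaccard(a, b) == pytest.approx(expected)

    @given(
        a=st.sets(st.integers(0, 30), max_size=20),
        b=st.sets(st.integers(0, 30), max_size=20),
    )
    @settings(derandomize=True, max_examples=100)
    def test_symmetric_and_bounded(self, a, b):
        j = rnaseq.jaccard(a, b)
        assert j == rnaseq.jaccard(b, a)
        assert 0.0 <= j <= 1.0
        if a and a == b:
            assert j == 1.0
        if j == 1.0:
            assert a == b


def naive_complete_linkage(points: np.ndarray):
    """O(n^3) agglomerative complete linkage; returns sorted merge heights."""
    clusters = [[i] for i in range(len(points))]
    heights = []
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if h < best[0]:
                    best = (h, (i, j))
        h, (i, j) = best
        heights.append(h)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


class TestClusterTopGenes:
    def _de_for(self, expr, design):
        return rnaseq.test_de(expr, design, ("A", "B"))

    def test_duplicated_blocks_split_at_two(self, design_ab):
        rng = np.random.default_rng(SEED)
        block = rng.normal(size=(10, 1))
        vals = np.hstack([np.tile(block, (1, 4)), np.tile(block + 5, (1, 4))])
        e = make_expr(vals, design_ab.sample_ids)
        de = self._de_for(e, design_ab)
        res = rnaseq.cluster_top_genes(e, de, k=10)
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(res.linkage, 2, criterion="maxclust")
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert set(labels[:4]) != set(labels[4:])

    def test_constant_gene_rows_are_zscored_to_zero(self):
        e = make_expr([[5.0] * 4], ["s1", "s2", "s3", "s4"])
        z = rnaseq.zscore_rows(e)
        assert (z.to_numpy() == 0).all()

    def test_merge_heights_match_naive_oracle(self, design_ab):
        rng = np.random.default_rng(SEED)
        vals = rng.normal(size=(5, 8))
        e = make_expr(vals, design_ab.sample_ids)
        de = self._de_for(e, design_ab)
        res = rnaseq.cluster_top_genes(e, de, k=5)
        z = rnaseq.zscore_rows(e.loc[res.genes]).to_numpy().T
        np.testing.assert_allclose(
            sorted(res.linkage[:, 2]), naive_complete_linkage(z), rtol=1e-10
        )

    def test_newick_contains_all_samples(self, design_ab):
        rng = np.random.default_rng(SEED)
        e = make_expr(rng.normal(size=(6, 8)), design_ab.sample_ids)
        de = self._de_for(e, design_ab)
        nwk = rnaseq.cluster_top_genes(e, de, k=4).to_newick()
        assert nwk.endswith(";")
        for s in design_ab.sample_ids:
            assert s in nwk

    def test_invalid_k_rejected(self, design_ab):
        e = make_expr(np.zeros((3, 8)), design_ab.sample_ids)
        de = self._de_for(e, design_ab)
        with pytest.raises(InvalidThresholdError):
            rnaseq.cluster_top_genes(e, de, k=0)


class TestMDS:
    def test_identical_samples_coincide(self):
        vals = np.array([[1.0, 1.0, 2.0], [3.0, 3.0, 1.0]])
        e = make_expr(vals, ["s1", "s2", "s3"])
        coords = rnaseq.mds_coordinates(e, dims=2)
        np.testing.assert_allclose(
            coords.loc["s1"].to_numpy(), coords.loc["s2"].to_numpy(), atol=1e-9
        )

    def test_centered_at_origin(self, design_ab):
        rng = np.random.default_rng(SEED)
        e = make_expr(rng.normal(size=(30, 8)), design_ab.sample_ids)
        coords = rnaseq.mds_coordinates(e, dims=3)
        np.testing.assert_allclose(coords.mean(axis=0), 0.0, atol=1e-9)

    def test_recovers_3_4_5_triangle(self):
        """Three samples at pairwise distances (3,4,5) embed exactly."""
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        e = pd.DataFrame(pts.T, index=["g1", "g2"], columns=["s1", "s2", "s3"])
        coords = rnaseq.mds_coordinates(e, dims=2).to_numpy()
        d = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        assert d[0, 1] == pytest.approx(3.0, abs=1e-6)
        assert d[0, 2] == pytest.approx(4.0, abs=1e-6)
        assert d[1, 2] == pytest.approx(5.0, abs=1e-6)

    def test_too_few_samples_rejected(self):
        e = make_expr(np.zeros((3, 2)), ["s1", "s2"])
        with pytest.raises(InvalidThresholdError):
            rnaseq.mds_coordinates(e, dims=2)
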