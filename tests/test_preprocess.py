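"""Preprocessing: present calls, probe collapse, quantile normalization,
bridge batch correction, variable genes, size factors, sample correlation."""

import numpy as np
import pandas as pd
import pytest

from monomap import preprocess as pp
from monomap.containers import ExpressionDataset, SampleDesign

from conftest import make_dataset, make_design


class TestPresentCallFilter:
    def test_boundary_semantics(self):
        # max group mean 6.9 < 7 -> excluded; exactly 7.0 -> retained
        ds = make_dataset([[6.2, 6.2, 6.9, 6.9], [6.2, 6.2, 7.0, 7.0]], genes=["lo", "hi"])
        design = make_design(["A", "A", "B", "B"])
        out = pp.present_call_filter(ds, design, threshold=7.0)
        assert list(out.genes) == ["hi"]

    def test_matches_brute_force_on_planted_matrix(self, rng):
        vals = rng.normal(6.0, 0.1, size=(100, 6))
        above = rng.choice(100, size=40, replace=False)
        vals[above, :2] += 2.0  # group A mean ~8 for planted genes
        ds = make_dataset(vals)
        design = make_design(["A", "A", "B", "B", "C", "C"])
        out = pp.present_call_filter(ds, design, threshold=7.0)
        # brute force over group means
        expected = []
        for g in ds.genes:
            gm = [ds.values.loc[g, ds.samples[design.table["condition"] == c]].mean() for c in "ABC"]
            if max(gm) >= 7.0:
                expected.append(g)
        assert list(out.genes) == expected
        assert len(out.genes) == 40

    def test_rejects_nonfinite_threshold(self, two_group_ds):
        ds, design = two_group_ds
        with pytest.raises(ValueError):
            pp.present_call_filter(ds, design, threshold=np.nan)


class TestCollapseProbes:
    def test_highest_mean_probe_survives(self):
        ds = make_dataset([[8.1, 8.1], [7.3, 7.3], [5.0, 5.0]], genes=["p1", "p2", "p3"])
        out = pp.collapse_probes(ds, {"p1": "G", "p2": "G", "p3": "H"})
        assert list(out.genes) == ["G", "H"]
        assert out.values.loc["G"].tolist() == [8.1, 8.1]

    def test_single_probe_gene_unchanged(self):
        ds = make_dataset([[1.0, 2.0]], genes=["p1"])
        out = pp.collapse_probes(ds, {"p1": "G"})
        assert out.values.loc["G"].tolist() == [1.0, 2.0]

    def test_unannotated_probes_dropped(self):
        ds = make_dataset([[1, 1], [2, 2]], genes=["p1", "p2"])
        out = pp.collapse_probes(ds, {"p1": "G"})
        assert list(out.genes) == ["G"]

    def test_random_map_matches_argmax_oracle(self, rng):
        n = 60
        probes = [f"p{i:02d}" for i in range(n)]
        genes = [f"G{i}" for i in rng.integers(0, 15, size=n)]
        ds = make_dataset(rng.normal(8, 2, size=(n, 5)), genes=probes)
        mapping = dict(zip(probes, genes))
        out = pp.collapse_probes(ds, mapping)
        means = ds.values.mean(axis=1)
        for gene in set(genes):
            cands = [p for p in probes if mapping[p] == gene]
            best = max(cands, key=lambda p: (means[p], p))
            # exhaustive arg-max (ties impossible with continuous draws)
            assert np.allclose(out.values.loc[gene], ds.values.loc[best])

    def test_duplicate_probe_rows_rejected(self):
        ds = make_dataset([[1, 1]], genes=["p1"])
        dup = pd.Series(["G", "G"], index=["p1", "p1"])
        with pytest.raises(ValueError, match="duplicate"):
            pp.collapse_probes(ds, dup)


class TestQuantileNormalize:
    def test_analytic_rank_means(self):
        ds = make_dataset([[1, 4], [2, 5], [3, 6]])
        out = pp.quantile_normalize(ds)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        assert np.allclose(out.values.to_numpy(), expected)

    def test_identical_columns_unchanged(self):
        ds = make_dataset([[1, 1], [5, 5], [3, 3]])
        out = pp.quantile_normalize(ds)
        assert np.allclose(out.values.to_numpy(), ds.values.to_numpy())

    def test_columns_share_one_multiset(self, rng):
        ds = make_dataset(rng.normal(8, 2, size=(50, 6)))
        out = pp.quantile_normalize(ds)
        X = np.sort(out.values.to_numpy(), axis=0)
        for j in range(1, 6):
            assert np.allclose(X[:, 0], X[:, j])

    def test_preserves_within_column_ranking(self, rng):
        ds = make_dataset(rng.normal(0, 1, size=(30, 4)))
        out = pp.quantile_normalize(ds)
        for col in ds.samples:
            assert (
                ds.values[col].rank().tolist() == out.values[col].rank().tolist()
            )

    def test_idempotent(self, rng):
        ds = make_dataset(rng.normal(8, 2, size=(40, 5)))
        once = pp.quantile_normalize(ds)
        twice = pp.quantile_normalize(once)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12)

    def test_needs_two_samples(self):
        ds = make_dataset([[1.0], [2.0]])
        with pytest.raises(ValueError):
            pp.quantile_normalize(ds)


class TestBridgeBatchCorrect:
    def _two_batch(self, shift):
        base = np.array([[8.0, 8.0, 9.0, 9.0]] * 3)
        vals = base.copy()
        vals[:, 2:] += shift  # batch 2 shifted
        ds = make_dataset(vals)
        design = make_design(["MO", "X", "MO", "X"], batch=["b1", "b1", "b2", "b2"])
        return ds, design

    def test_constant_shift_removed(self):
        ds, design = self._two_batch(1.5)
        out = pp.bridge_batch_correct(ds, design, "MO")
        bridge = out.values[["s0", "s2"]]
        assert np.allclose(bridge["s0"], bridge["s2"], atol=1e-12)

    def test_single_batch_is_identity(self):
        ds = make_dataset([[1.0, 2.0], [3.0, 4.0]])
        design = make_design(["MO", "X"], batch=["b1", "b1"])
        out = pp.bridge_batch_correct(ds, design, "MO")
        assert np.allclose(out.values.to_numpy(), ds.values.to_numpy())

    def test_planted_pergene_shift_recovered_exactly(self, rng):
        # zero noise: per-gene random shift on batch 2, estimated offsets exact
        n = 50
        base = rng.normal(8, 1, size=(n, 1))
        vals = np.hstack([base, base + 0.3, base, base + 0.3])
        shift = rng.normal(0, 2, size=n)
        vals[:, 2:] += shift[:, None]
        ds = make_dataset(vals)
        design = make_design(["MO", "X", "MO", "X"], batch=["b1", "b1", "b2", "b2"])
        out = pp.bridge_batch_correct(ds, design, "MO")
        # both batches should coincide with the half-shift-removed average
        resid = out.values.to_numpy()[:, 2:] - (vals[:, :2] + shift[:, None] / 2)
        assert np.abs(resid).max() < 1e-12

    def test_within_batch_contrasts_invariant(self, rng):
        vals = rng.normal(8, 1, size=(20, 6))
        ds = make_dataset(vals)
        design = make_design(
            ["MO", "X", "Y", "MO", "X", "Y"], batch=["b1"] * 3 + ["b2"] * 3
        )
        out = pp.bridge_batch_correct(ds, design, "MO")
        before = ds.values["s1"] - ds.values["s2"]
        after = out.values["s1"] - out.values["s2"]
        assert np.allclose(before, after, atol=1e-12)

    def test_batch_without_bridge_named(self):
        ds = make_dataset(np.zeros((2, 4)))
        design = make_design(["MO", "X", "Y", "Z"], batch=["b1", "b1", "b2", "b2"])
        with pytest.raises(ValueError, match="b2"):
            pp.bridge_batch_correct(ds, design, "MO")


class TestTopVariable:
    def test_n_equals_gene_count_returns_all(self, rng):
        ds = make_dataset(rng.normal(size=(10, 4)))
        assert sorted(pp.top_variable(ds, 10)) == sorted(ds.genes)

    def test_planted_high_variance_gene_first(self, rng):
        vals = rng.normal(8, 0.1, size=(20, 5))
        vals[7] = [0, 5, 10, 15, 20]
        ds = make_dataset(vals)
        assert pp.top_variable(ds, 1) == ["g007"]

    def test_matches_exhaustive_variance_ranking(self, rng):
        ds = make_dataset(rng.normal(size=(50, 6)))
        got = pp.top_variable(ds, 10)
        var = ds.values.var(axis=1, ddof=1)
        expected = list(var.sort_values(ascending=False).index[:10])
        assert got == expected

    @pytest.mark.parametrize("bad_n", [0, -3])
    def test_rejects_nonpositive_n(self, bad_n, rng):
        ds = make_dataset(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            pp.top_variable(ds, bad_n)


class TestSizeFactors:
    def test_doubling_sample_closed_form(self):
        c1 = np.array([10, 20, 30, 40], dtype=float)
        counts = pd.DataFrame({"a": c1, "b": 2 * c1}, index=[f"g{i}" for i in range(4)])
        design = make_design(["A", "A"])
        design.table.index = ["a", "b"]
        _, factors = pp.size_factors_and_filter(counts, design, min_mean=0)
        assert np.allclose(factors.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_samples_unit_factors(self):
        c = np.array([5, 15, 25], dtype=float)
        counts = pd.DataFrame({"a": c, "b": c, "c": c})
        design = make_design(["A", "A", "B"])
        design.table.index = ["a", "b", "c"]
        _, factors = pp.size_factors_and_filter(counts, design, min_mean=0)
        assert np.allclose(factors.to_numpy(), 1.0)

    def test_min_mean_filter_and_clamp(self):
        counts = pd.DataFrame(
            {"a": [100.0, 4.0, 0.0], "b": [100.0, 4.0, 1.0]},
            index=["hi", "lo", "zero"],
        )
        design = make_design(["A", "A"])
        design.table.index = ["a", "b"]
        norm, _ = pp.size_factors_and_filter(counts, design, min_mean=10)
        assert list(norm.index) == ["hi"]
        assert (norm.to_numpy() >= 1.0).all()

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 0.0]})
        design = make_design(["A", "A"])
        design.table.index = ["a", "b"]
        with pytest.raises(ValueError, match="all-zero"):
            pp.size_factors_and_filter(counts, design)

    def test_matches_pydeseq2_on_random_counts(self, rng):
        # independent median-of-ratios implementation as oracle
        from pydeseq2.preprocessing import deseq2_norm

        counts = pd.DataFrame(
            rng.poisson(50, size=(80, 6)) + 1,
            index=[f"g{i}" for i in range(80)],
            columns=[f"s{i}" for i in range(6)],
        )
        design = make_design(["A"] * 3 + ["B"] * 3)
        _, factors = pp.size_factors_and_filter(counts.astype(float), design, min_mean=0)
        _, sf = deseq2_norm(counts.T)
        assert np.allclose(factors.to_numpy(), np.asarray(sf).ravel(), rtol=1e-10)


class TestSampleCorrelation:
    def test_duplicated_sample_gives_one(self, rng):
        x = rng.normal(size=10)
        ds = make_dataset(np.column_stack([x, x, rng.normal(size=10)]))
        corr = pp.sample_correlation_matrix(ds)
        assert corr.loc["s0", "s1"] == pytest.approx(1.0)

    def test_negated_sample_gives_minus_one(self, rng):
        x = rng.normal(size=10)
        ds = make_dataset(np.column_stack([x, -x]))
        corr = pp.sample_correlation_matrix(ds)
        assert corr.loc["s0", "s1"] == pytest.approx(-1.0)

    def test_matches_brute_force(self, rng):
        ds = make_dataset(rng.normal(size=(30, 5)))
        corr = pp.sample_correlation_matrix(ds)
        for i, a in enumerate(ds.samples):
            for b in ds.samples[i:]:
                expected = np.corrcoef(ds.values[a], ds.values[b])[0, 1]
                assert corr.loc[a, b] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)

    def test_constant_sample_warns_nan(self, rng):
        vals = rng.normal(size=(10, 3))
        vals[:, 2] = 4.2
        ds = make_dataset(vals)
        with pytest.warns(UserWarning, match="constant"):
            corr = pp.sample_correlation_matrix(ds)
        assert np.isnan(corr.loc["s0", "s2"])


def test_filter_collapse_commutes_one_probe_per_gene(rng):
    """With one probe per gene, present-filter then collapse equals
    collapse then filter."""
    ds = make_dataset(rng.normal(7, 1, size=(30, 4)), genes=[f"p{i}" for i in range(30)])
    design = make_design(["A", "A", "B", "B"])
    mapping = {f"p{i}": f"G{i}" for i in range(30)}
    a = pp.collapse_probes(pp.present_call_filter(ds, design, 7.0), mapping)
    b = pp.present_call_filter(pp.collapse_probes(ds, mapping), design, 7.0)
    assert list(a.genes) == list(b.genes)
    assert np.allclose(a.values.to_numpy(), b.values.to_numpy())


def test_donorwise_average_merges_paired_conditions(rng):
    vals = rng.normal(8, 1, size=(10, 5))
    ds = make_dataset(vals)
    design = make_design(
        ["cMO", "iMO", "cMO", "iMO", "DC"],
        donor=["d1", "d1", "d2", "d2", "d1"],
    )
    out, out_design = pp.donorwise_average(ds, design, ["cMO", "iMO"], "MO")
    assert sorted(out_design.conditions) == ["DC", "MO"]
    merged = out.values["MO_d1"]
    assert np.allclose(merged, (vals[:, 0] + vals[:, 1]) / 2)
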