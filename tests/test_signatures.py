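"""Signature constructions: the common derived-cell signature with
consistency filter, subset-specific markers, receptor profiles, the
IL-4 meta-signature and the time-resolved regulator filter."""

import numpy as np
import pandas as pd
import pytest

from monomap import signatures as sg
from monomap.containers import ExpressionDataset

from conftest import make_dataset, make_design


def _derived_design():
    # monocyte reference + four derived-cell groups, 2 samples each
    conds = ["MO"] * 2 + ["M1"] * 2 + ["M2"] * 2 + ["M3"] * 2 + ["M4"] * 2
    return make_design(conds)


class TestCommonSignature:
    def _ds(self, derived_means):
        """One gene whose derived-group means are given; MO mean is 4."""
        row = [4.0, 4.0]
        for m in derived_means:
            row += [m, m]
        return make_dataset([row], genes=["g"])

    def test_consistent_gene_kept(self):
        # max pairwise log2 gap 0.7 -> ratio 2^0.7 ~ 1.62 <= 1.7
        ds = self._ds([5.0, 5.5, 5.2, 5.7])
        pairs = [(["g"], []), (["g"], []), (["g"], [])]
        sig = sg.common_monocyte_derived_signature(
            pairs, ds, _derived_design(), ["M1", "M2", "M3", "M4"], consistency_fc=1.7
        )
        assert sig.induced == ["g"]
        assert 2 ** 0.7 == pytest.approx(1.6245, abs=1e-4)

    def test_inconsistent_gene_dropped(self):
        # 1.0 log2 gap -> ratio 2.0 > 1.7
        ds = self._ds([5.0, 6.0, 5.2, 5.5])
        pairs = [(["g"], []), (["g"], []), (["g"], [])]
        sig = sg.common_monocyte_derived_signature(
            pairs, ds, _derived_design(), ["M1", "M2", "M3", "M4"]
        )
        assert sig.induced == []

    def test_gene_in_two_of_three_contrasts_excluded(self):
        ds = self._ds([5.0, 5.0, 5.0, 5.0])
        pairs = [(["g"], []), (["g"], []), ([], [])]
        sig = sg.common_monocyte_derived_signature(
            pairs, ds, _derived_design(), ["M1", "M2", "M3", "M4"]
        )
        assert sig.induced == []

    def test_fewer_than_two_contrasts_rejected(self):
        ds = self._ds([5.0, 5.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            sg.common_monocyte_derived_signature(
                [(["g"], [])], ds, _derived_design(), ["M1"]
            )

    def test_provenance_replays_lists(self, rng):
        """The provenance pre-filter lists plus the consistency rule
        reconstruct the final signature."""
        vals = rng.normal(6, 1, size=(40, 10))
        ds = make_dataset(vals)
        design = _derived_design()
        genes = list(ds.genes)
        pairs = [
            (genes[:20], genes[20:30]),
            (genes[5:25], genes[20:28]),
            (genes[:25], genes[18:30]),
        ]
        sig = sg.common_monocyte_derived_signature(
            pairs, ds, design, ["M1", "M2", "M3", "M4"]
        )
        replay = sg.common_monocyte_derived_signature(
            pairs, ds, design, ["M1", "M2", "M3", "M4"]
        )
        assert sig.induced == replay.induced and sig.repressed == replay.repressed
        assert set(sig.induced) <= set(sig.provenance["pre_filter"]["up"])


class TestSubsetSpecificMarkers:
    def test_all_fcs_above_cut_is_specific(self, rng):
        # target mean 10; others at 10 - log2(2.5), -log2(3), -log2(2.1)
        others = [10 - np.log2(2.5), 10 - np.log2(3.0), 10 - np.log2(2.1)]
        row = [10.0] * 2 + sum(([m] * 2 for m in others), [])
        ds = make_dataset([row], genes=["g"])
        design = make_design(["T"] * 2 + ["A"] * 2 + ["B"] * 2 + ["C"] * 2)
        out = sg.subset_specific_markers(ds, design, "T", ["A", "B", "C"], fc_cut=2.0)
        assert out == ["g"]

    def test_one_fc_below_cut_not_specific(self):
        others = [10 - np.log2(2.5), 10 - np.log2(3.0), 10 - np.log2(1.9)]
        row = [10.0] * 2 + sum(([m] * 2 for m in others), [])
        ds = make_dataset([row], genes=["g"])
        design = make_design(["T"] * 2 + ["A"] * 2 + ["B"] * 2 + ["C"] * 2)
        out = sg.subset_specific_markers(ds, design, "T", ["A", "B", "C"], fc_cut=2.0)
        assert out == []

    def test_planted_markers_recovered_exactly(self, rng):
        n = 100
        vals = np.tile(rng.normal(8, 0.5, size=(n, 1)), (1, 8))
        planted = sorted(rng.choice(n, size=15, replace=False))
        vals[planted, :2] += 1.5  # target-specific elevation > 2-fold
        ds = make_dataset(vals)
        design = make_design(["T"] * 2 + ["A"] * 2 + ["B"] * 2 + ["C"] * 2)
        out = sg.subset_specific_markers(ds, design, "T", ["A", "B", "C"], fc_cut=2.0)
        assert out == [f"g{i:03d}" for i in planted]

    def test_universe_restriction_and_exclusions(self, rng):
        vals = np.tile(rng.normal(8, 0.5, size=(20, 1)), (1, 4))
        vals[:5, :2] += 2.0
        genes = ["HLA-A", "g1", "g2", "g3", "g4"] + [f"bg{i}" for i in range(15)]
        ds = make_dataset(vals, genes=genes)
        design = make_design(["T", "T", "A", "A"])
        out = sg.subset_specific_markers(
            ds, design, "T", ["A"],
            universe=["HLA-A", "g1", "g2", "g3"],
            exclude=["g3"], exclude_prefixes=["HLA-"],
        )
        assert out == ["g1", "g2"]

    def test_target_among_others_rejected(self, rng):
        ds = make_dataset(rng.normal(size=(3, 4)))
        design = make_design(["T", "T", "A", "A"])
        with pytest.raises(ValueError):
            sg.subset_specific_markers(ds, design, "T", ["T", "A"])


class TestPrrRegulated:
    def _ds_with_fcs(self, fcs):
        """One receptor gene with the given signed FCs vs the reference."""
        offs = [np.log2(f) if f > 0 else -np.log2(-f) for f in fcs]
        row = [8.0] * 2 + sum(([8.0 + o] * 2 for o in offs), [])
        return make_dataset([row], genes=["TLR9"])

    def test_boundary_negative_two_retained(self):
        ds = self._ds_with_fcs([1.5, -2.0, 1.1])
        design = make_design(["MO"] * 2 + ["A"] * 2 + ["B"] * 2 + ["C"] * 2)
        out = sg.prr_regulated(ds, design, ["A", "B", "C"], "MO", ["TLR9"])
        assert "TLR9" in out.index

    def test_below_boundary_dropped(self):
        ds = self._ds_with_fcs([1.5, -1.9, 1.1])
        design = make_design(["MO"] * 2 + ["A"] * 2 + ["B"] * 2 + ["C"] * 2)
        out = sg.prr_regulated(ds, design, ["A", "B", "C"], "MO", ["TLR9"])
        assert out.empty

    def test_matches_brute_force_filter(self, rng):
        vals = rng.normal(8, 1, size=(40, 8))
        ds = make_dataset(vals)
        design = make_design(["MO"] * 2 + ["A"] * 2 + ["B"] * 2 + ["C"] * 2)
        prr = [f"g{i:03d}" for i in range(40)]
        out = sg.prr_regulated(ds, design, ["A", "B", "C"], "MO", prr, fc_cut=2.0)
        mo = vals[:, :2].mean(axis=1)
        for i, g in enumerate(prr):
            diffs = [vals[i, 2 + 2 * j : 4 + 2 * j].mean() - mo[i] for j in range(3)]
            keep = any(abs(d) >= 1.0 for d in diffs)  # |log2 FC| >= 1 <=> |FC| >= 2
            assert (g in out.index) == keep

    def test_empty_receptor_list_rejected(self, rng):
        ds = make_dataset(rng.normal(size=(3, 4)))
        design = make_design(["MO", "MO", "A", "A"])
        with pytest.raises(ValueError):
            sg.prr_regulated(ds, design, ["A"], "MO", [])


class TestIl4MetaSignature:
    def test_two_dataset_support_required(self):
        degs = {
            "d1": (["a", "b"], ["x"]),
            "d2": (["a"], ["x", "y"]),
            "d3": (["c"], ["z"]),
        }
        sig = sg.il4_meta_signature(degs)
        assert sig.induced == ["a"]
        assert sig.repressed == ["x"]

    def test_single_dataset_gene_excluded(self):
        degs = {"d1": (["a"], []), "d2": (["b"], []), "d3": ([], [])}
        sig = sg.il4_meta_signature(degs)
        assert sig.induced == []

    def test_conflicting_gene_reported_not_listed(self):
        degs = {
            "d1": (["a"], []),
            "d2": (["a"], ["a"]),
            "d3": ([], ["a"]),
        }
        sig = sg.il4_meta_signature(degs)
        assert sig.induced == [] and sig.repressed == []
        assert sig.provenance["conflicts"] == ["a"]

    def test_counts_match_set_arithmetic(self, rng):
        universe = [f"g{i}" for i in range(200)]
        lists = {}
        for d in range(3):
            up = list(rng.choice(universe, size=60, replace=False))
            down = list(rng.choice([g for g in universe if g not in up], size=60, replace=False))
            lists[f"d{d}"] = (up, down)
        sig = sg.il4_meta_signature(lists)
        ups = [set(u) for u, _ in lists.values()]
        downs = [set(d) for _, d in lists.values()]
        up2 = (ups[0] & ups[1]) | (ups[0] & ups[2]) | (ups[1] & ups[2])
        down2 = (downs[0] & downs[1]) | (downs[0] & downs[2]) | (downs[1] & downs[2])
        conflict = up2 & down2
        assert set(sig.induced) == up2 - conflict
        assert set(sig.repressed) == down2 - conflict

    def test_fewer_than_two_datasets_rejected(self):
        with pytest.raises(ValueError):
            sg.il4_meta_signature({"d1": (["a"], [])})


class TestTrSpecificCandidates:
    def _design(self):
        return make_design(
            ["MO"] * 2 + ["GM"] * 2 + ["IL4e"] * 2 + ["IL4l"] * 2
        )

    def test_planted_regulators_recovered_and_ranked(self, rng):
        n = 100
        vals = np.tile(rng.normal(8, 0.3, size=(n, 1)), (1, 8))
        qualify = sorted(rng.choice(n, size=7, replace=False))
        # IL-4 induction at both time points over both references
        vals[qualify, 4:] += 1.2          # IL4 early+late vs everything
        vals[qualify, 2:4] += 0.3         # GM mildly above MO (FC > 1)
        ds = make_dataset(vals)
        out = sg.tr_specific_candidates(
            ds, self._design(), list(ds.genes), "IL4e", "IL4l", "GM", "MO", fc=1.5
        )
        assert sorted(out.index) == [f"g{i:03d}" for i in qualify]
        # ranked by early-condition expression, descending
        expr = out["early_expression"].to_numpy()
        assert (np.diff(expr) <= 1e-12).all()

    def test_gmcsf_below_reference_dropped(self):
        row = [8.0] * 2 + [8.0 - 0.14] * 2 + [9.5] * 2 + [9.5] * 2  # GM vs MO ~ -1.1
        ds = make_dataset([row], genes=["tr1"])
        out = sg.tr_specific_candidates(
            ds, self._design(), ["tr1"], "IL4e", "IL4l", "GM", "MO"
        )
        assert out.empty

    def test_missing_condition_rejected(self, rng):
        ds = make_dataset(rng.normal(size=(3, 8)))
        with pytest.raises(ValueError, match="missing"):
            sg.tr_specific_candidates(
                ds, self._design(), list(ds.genes), "IL4e", "IL4l", "GM", "nope"
            )


def test_thresholds_are_anti_monotone(rng):
    """Tightening any cutoff never grows a signature."""
    n = 80
    vals = np.tile(rng.normal(8, 0.5, size=(n, 1)), (1, 8)) + rng.normal(0, 0.4, size=(n, 8))
    ds = make_dataset(vals)
    design = make_design(["T"] * 2 + ["A"] * 2 + ["B"] * 2 + ["C"] * 2)
    sizes = [
        len(sg.subset_specific_markers(ds, design, "T", ["A", "B", "C"], fc_cut=fc))
        for fc in [1.1, 1.5, 2.0, 3.0]
    ]
    assert sizes == sorted(sizes, reverse=True)
    prr_sizes = [
        len(sg.prr_regulated(ds, design, ["A", "B", "C"], "T", list(ds.genes), fc_cut=fc))
        for fc in [1.2, 1.5, 2.0, 3.0]
    ]
    assert prr_sizes == sorted(prr_sizes, reverse=True)


def test_signature_rejects_overlapping_directions():
    with pytest.raises(ValueError):
        sg.GeneSignature(induced=["a", "b"], repressed=["b"])
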