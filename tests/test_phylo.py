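"""Tree metrics: grafting, cophenetic distances, SES-MPD, signal, imputation."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from conftest import ultrametric_error
from griddiv import phylo, synthetic
from griddiv.assembly import PresenceMatrix
from griddiv.grid import GridSpec
from griddiv.traits import TraitTable


def _naive_path_distance(tree, a, b):
    """Oracle: walk both tips up to the root and subtract the shared part."""
    def path(label):
        node = tree.find_node_with_taxon_label(label)
        out = []
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out

    pa, pb = path(a), path(b)
    shared = {id(n) for n in pa} & {id(n) for n in pb}
    d = 0.0
    for node in pa + pb:
        if id(node) not in shared:
            d += node.edge.length or 0.0
    return d


class TestCophenetic:
    def test_cherry(self):
        t = dendropy.Tree.get(data="(A:1.0,B:1.0);", schema="newick")
        labels, D = phylo.cophenetic_matrix(t)
        assert D[labels.index("A"), labels.index("B")] == pytest.approx(2.0)

    def test_ultrametric_distances_bounded_by_tree_height(self, tree50):
        _, D = phylo.cophenetic_matrix(tree50)
        np.testing.assert_allclose(np.diag(D), 0.0)
        assert D.max() == pytest.approx(2.0)  # unit-height tree: through-root pairs

    def test_matches_naive_path_walking(self):
        t = synthetic.generate_phylogeny(10, seed=77)
        labels, D = phylo.cophenetic_matrix(t)
        for i, j in itertools.combinations(range(10), 2):
            assert D[i, j] == pytest.approx(
                _naive_path_distance(t, labels[i], labels[j]), abs=1e-10
            )


class TestGraftTaxa:
    def test_single_graft_preserves_ultrametricity(self, tree50):
        labels = [lf.taxon.label for lf in tree50.leaf_node_iter()]
        out = phylo.graft_taxa(tree50, {"newsp": labels[:4]})
        assert len(out.leaf_nodes()) == 51
        assert ultrametric_error(out) < 1e-9

    def test_graft_into_two_tip_clade_makes_polytomy(self):
        t = dendropy.Tree.get(data="((A:1.0,B:1.0):1.0,C:2.0);", schema="newick")
        out = phylo.graft_taxa(t, {"X": ["A", "B"]})
        mrca = out.mrca(taxon_labels=["A", "B"])
        assert len(mrca.child_nodes()) == 3
        assert ultrametric_error(out) < 1e-9

    def test_fifteen_grafts_add_fifteen_tips(self, tree50):
        labels = [lf.taxon.label for lf in tree50.leaf_node_iter()]
        placements = {f"extra{i}": labels[2 * i:2 * i + 3] for i in range(15)}
        out = phylo.graft_taxa(tree50, placements)
        assert len(out.leaf_nodes()) == 65

    def test_grafting_preserves_existing_distances(self, tree50):
        labels, D0 = phylo.cophenetic_matrix(tree50)
        out = phylo.graft_taxa(tree50, {"newsp": labels[:3]})
        _, D1 = phylo.cophenetic_matrix(out, labels)
        np.testing.assert_allclose(D1, D0, atol=1e-12)

    def test_single_tip_anchor(self):
        t = dendropy.Tree.get(data="((A:1.0,B:1.0):1.0,C:2.0);", schema="newick")
        out = phylo.graft_taxa(t, {"X": ["C"]})
        assert len(out.leaf_nodes()) == 4
        assert ultrametric_error(out) < 1e-9

    def test_unknown_anchor_names_species(self, tree50):
        with pytest.raises(ValueError, match="newsp"):
            phylo.graft_taxa(tree50, {"newsp": ["not_a_tip"]})


class TestSesMpd:
    def _matrix(self, grid, labels, cells_species):
        vals = np.zeros((grid.n_cells, len(labels)), np.uint8)
        for cell, idxs in cells_species.items():
            vals[cell, idxs] = 1
        return PresenceMatrix(grid, labels, vals)

    def test_whole_pool_community_has_zero_ses(self):
        t = synthetic.generate_phylogeny(6, seed=1)
        labels, D = phylo.cophenetic_matrix(t)
        grid = GridSpec(2, 2)
        m = self._matrix(grid, labels, {0: list(range(6))})
        res = phylo.ses_mpd(m, (labels, D), n_null=99, seed=0)
        assert res.ses[0] == 0.0
        assert res.nri[0] == 0.0

    def test_two_species_cell_equals_pairwise_distance(self):
        t = synthetic.generate_phylogeny(8, seed=2)
        labels, D = phylo.cophenetic_matrix(t)
        grid = GridSpec(2, 2)
        m = self._matrix(grid, labels, {1: [0, 3]})
        res = phylo.ses_mpd(m, (labels, D), n_null=99, seed=0)
        assert res.obs_mpd[1] == pytest.approx(D[0, 3])

    def test_single_species_cell_undefined(self):
        t = synthetic.generate_phylogeny(5, seed=3)
        labels, D = phylo.cophenetic_matrix(t)
        grid = GridSpec(2, 2)
        m = self._matrix(grid, labels, {0: [0]})
        res = phylo.ses_mpd(m, (labels, D), n_null=99, seed=0)
        assert np.isnan(res.ses[0])

    def test_null_matches_exhaustive_enumeration(self):
        # pool of 5, richness 2: exhaustive null = all 10 unordered pairs
        t = synthetic.generate_phylogeny(5, seed=4)
        labels, D = phylo.cophenetic_matrix(t)
        grid = GridSpec(2, 2)
        m = self._matrix(grid, labels, {0: [1, 4]})
        res = phylo.ses_mpd(m, (labels, D), n_null=9999, seed=5)
        exact = [phylo.mpd(D, np.array(c))
                 for c in itertools.combinations(range(5), 2)]
        se = np.std(exact, ddof=1) / np.sqrt(9999)
        assert abs(res.null_mean[0] - np.mean(exact)) < 3 * se

    def test_nri_is_exactly_minus_ses(self, tree50):
        labels, D = phylo.cophenetic_matrix(tree50)
        grid = GridSpec(3, 3)
        rng = np.random.default_rng(0)
        vals = (rng.random((9, 50)) < 0.3).astype(np.uint8)
        m = PresenceMatrix(grid, labels, vals)
        res = phylo.ses_mpd(m, (labels, D), n_null=99, seed=1)
        ok = ~np.isnan(res.ses)
        np.testing.assert_array_equal(res.nri[ok], -res.ses[ok])

    def test_ses_mean_near_zero_across_richness(self, tree50):
        # SES under the equal-richness null is centred regardless of richness
        labels, D = phylo.cophenetic_matrix(tree50)
        rng = np.random.default_rng(9)
        grid = GridSpec(25, 40)
        for k in (2, 5, 10):
            vals = np.zeros((1000, 50), np.uint8)
            for c in range(1000):
                vals[c, rng.choice(50, k, replace=False)] = 1
            m = PresenceMatrix(grid, labels, vals)
            res = phylo.ses_mpd(m, (labels, D), n_null=999, seed=k)
            assert abs(np.nanmean(res.ses)) < 0.1

    def test_deterministic(self, tree50):
        labels, D = phylo.cophenetic_matrix(tree50)
        grid = GridSpec(2, 2)
        m = self._matrix(GridSpec(2, 2), labels, {0: [0, 1, 2]})
        a = phylo.ses_mpd(m, (labels, D), n_null=199, seed=7)
        b = phylo.ses_mpd(m, (labels, D), n_null=199, seed=7)
        np.testing.assert_array_equal(a.ses, b.ses)


class TestBlombergK:
    def test_shuffling_destroys_signal(self, tree100, cov100):
        tt = synthetic.simulate_traits(tree100, 1, sigma2=1.0, seed=11)
        k_obs = phylo.blomberg_k(tree100, tt.data["q1"], n_reps=0, _cov=cov100).statistic
        rng = np.random.default_rng(0)
        k_shuf = np.median([
            phylo.blomberg_k(
                tree100,
                pd.Series(rng.permutation(tt.data["q1"].values),
                          index=tt.data.index),
                n_reps=0, _cov=cov100,
            ).statistic
            for _ in range(20)
        ])
        assert k_shuf < k_obs

    def test_p_value_in_unit_interval_and_significant_for_bm(self, tree100):
        tt = synthetic.simulate_traits(tree100, 1, sigma2=1.0, seed=13)
        res = phylo.blomberg_k(tree100, tt.data["q1"], n_reps=199, seed=1)
        assert 0 < res.p_value <= 1
        assert res.p_value < 0.05  # strong BM signal on 100 tips

    def test_constant_trait_rejected(self, tree50):
        trait = {lf.taxon.label: 1.0 for lf in tree50.leaf_node_iter()}
        with pytest.raises(ValueError):
            phylo.blomberg_k(tree50, trait, n_reps=0)


class TestCategoricalSignal:
    def test_single_state(self, tree50):
        trait = {lf.taxon.label: "a" for lf in tree50.leaf_node_iter()}
        res = phylo.categorical_signal(tree50, trait, n_reps=99, seed=0)
        assert res.statistic == 0 and res.p_value == 1.0

    def test_balanced_split_needs_one_step(self):
        t = dendropy.Tree.get(
            data="(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);",
            schema="newick",
        )
        trait = dict(zip("ABCDEFGH", "AAAABBBB"))
        res = phylo.categorical_signal(t, trait, n_reps=199, seed=1)
        assert res.statistic == 1
        assert res.p_value < 0.05

    def test_clade_sorted_trait_in_lower_null_tail(self, tree50):
        labels = [lf.taxon.label for lf in tree50.leaf_node_iter()]
        trait = {sp: ("A" if i < 25 else "B") for i, sp in enumerate(labels)}
        res = phylo.categorical_signal(tree50, trait, n_reps=199, seed=2)
        assert res.statistic <= res.null_mean


class TestImputeTraits:
    def _masked_world(self, tree, seed, frac=0.165):
        full = synthetic.simulate_traits(tree, 3, sigma2=[1.0, 2.0, 0.5], seed=seed)
        masked = synthetic.mask_trait_values(full, frac, seed=seed + 1)
        return full, masked

    def test_complete_table_unchanged(self, tree50):
        full = synthetic.simulate_traits(tree50, 2, seed=1)
        out = phylo.impute_traits(tree50, full)
        pd.testing.assert_frame_equal(out.data, full.data)

    def test_observed_entries_preserved(self, tree50):
        _, masked = self._masked_world(tree50, 21)
        out = phylo.impute_traits(tree50, masked)
        obs = ~masked.data[masked.quantitative].isna()
        for c in masked.quantitative:
            sel = obs[c]
            pd.testing.assert_series_equal(
                out.data.loc[sel, c], masked.data.loc[sel, c]
            )
        assert out.is_complete()

    def test_zero_length_cherry_copies_sister(self):
        t = dendropy.Tree.get(data="((A:0.0,B:0.0):1.0,C:1.0);", schema="newick")
        df = pd.DataFrame({"x": [3.0, np.nan, 9.0]}, index=["A", "B", "C"])
        out = phylo.impute_traits(t, TraitTable(df, ["x"], []))
        assert out.data.loc["B", "x"] == pytest.approx(3.0, abs=1e-4)

    def test_order_invariance(self, tree50):
        _, masked = self._masked_world(tree50, 31)
        out1 = phylo.impute_traits(tree50, masked)
        shuffled = TraitTable(
            masked.data.iloc[::-1].copy(), masked.quantitative, masked.categorical
        )
        out2 = phylo.impute_traits(tree50, shuffled)
        pd.testing.assert_frame_equal(
            out1.data.sort_index(), out2.data.sort_index(), atol=1e-6
        )

    def test_affine_invariance(self, tree50):
        _, masked = self._masked_world(tree50, 41)
        out1 = phylo.impute_traits(tree50, masked)
        scaled = masked.copy()
        scaled.data["svl" if "svl" in scaled.data else "q1"] = (
            scaled.data["q1"] * 3.0 + 10.0
        )
        out2 = phylo.impute_traits(tree50, scaled)
        np.testing.assert_allclose(
            out2.data["q1"].to_numpy(),
            out1.data["q1"].to_numpy() * 3.0 + 10.0,
            rtol=1e-5, atol=1e-5,
        )

    def test_beats_mean_imputation(self, tree50):
        wins = 0
        for rep in range(25):
            full, masked = self._masked_world(tree50, 100 + rep)
            out = phylo.impute_traits(tree50, masked)
            X0 = full.quantitative_matrix()
            Xm = masked.quantitative_matrix()
            miss = np.isnan(Xm)
            rmse = np.sqrt(np.mean((out.quantitative_matrix()[miss] - X0[miss]) ** 2))
            fill = np.where(miss, np.nanmean(Xm, axis=0), Xm)
            rmse_mean = np.sqrt(np.mean((fill[miss] - X0[miss]) ** 2))
            wins += rmse < rmse_mean
        assert wins >= 23

    def test_trait_with_no_observations_rejected(self, tree50):
        labels = [lf.taxon.label for lf in tree50.leaf_node_iter()]
        df = pd.DataFrame({"x": np.full(50, np.nan)}, index=labels)
        with pytest.raises(ValueError, match="no observed"):
            phylo.impute_traits(tree50, TraitTable(df, ["x"], []))
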