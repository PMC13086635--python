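"""Gower distances, PCoA, phylogenetic decoupling, FDis."""

import numpy as np
import pandas as pd
import pytest

from griddiv import functional, phylo, synthetic
from griddiv.assembly import PresenceMatrix
from griddiv.functional import Ordination, ResidualTraitSpace
from griddiv.grid import GridSpec
from griddiv.traits import TraitTable


def _table(rows, quantitative, categorical):
    df = pd.DataFrame(rows).set_index("species")
    return TraitTable(df, quantitative, categorical)


class TestGower:
    def test_hand_computed_mixed_example(self):
        # SVL range 10-30 over the pool; |10-20|/20 = 0.5; nominal mismatch = 1
        tt = _table(
            [
                {"species": "A", "svl": 10.0, "tadpole": "exotrophic"},
                {"species": "B", "svl": 20.0, "tadpole": "endotrophic-free"},
                {"species": "C", "svl": 30.0, "tadpole": "exotrophic"},
            ],
            ["svl"], ["tadpole"],
        )
        sp, D = functional.gower(tt)
        assert D[sp.index("A"), sp.index("B")] == pytest.approx((0.5 + 1.0) / 2)

    def test_identical_rows_and_maximal_difference(self):
        tt = _table(
            [
                {"species": "A", "svl": 1.0, "dev": "direct"},
                {"species": "B", "svl": 1.0, "dev": "direct"},
                {"species": "C", "svl": 5.0, "dev": "indirect"},
            ],
            ["svl"], ["dev"],
        )
        sp, D = functional.gower(tt)
        assert D[sp.index("A"), sp.index("B")] == 0.0
        assert D[sp.index("A"), sp.index("C")] == 1.0
        assert D.min() >= 0 and D.max() <= 1

    def test_zero_range_trait_dropped_matches_remean_oracle(self):
        tt = _table(
            [
                {"species": "A", "svl": 3.0, "hw": 1.0, "dev": "direct"},
                {"species": "B", "svl": 3.0, "hw": 2.0, "dev": "indirect"},
            ],
            ["svl", "hw"], ["dev"],
        )
        with pytest.warns(UserWarning, match="zero range"):
            sp, D = functional.gower(tt)
        # oracle: mean over the two informative traits only
        assert D[0, 1] == pytest.approx((1.0 + 1.0) / 2)

    def test_incomplete_table_rejected(self):
        tt = _table(
            [{"species": "A", "svl": np.nan}, {"species": "B", "svl": 2.0}],
            ["svl"], [],
        )
        with pytest.raises(ValueError, match="complete"):
            functional.gower(tt)


class TestPcoa:
    def test_planar_points_round_trip(self):
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((5, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ord_ = functional.pcoa(D)
        assert (ord_.eigenvalues > 1e-8).sum() == 2
        rec = np.linalg.norm(
            ord_.coordinates[:, None] - ord_.coordinates[None, :], axis=-1
        )
        np.testing.assert_allclose(rec, D, atol=1e-8)

    def test_sqrt_correction_bounds_negative_eigenvalues(self):
        rng = np.random.default_rng(5)
        t = synthetic.generate_phylogeny(20, seed=5)
        tt = synthetic.simulate_traits(
            t, 2, categorical_spec={"dev": (["a", "b"], 0.5)}, seed=5
        )
        _, G = functional.gower(tt)
        ord_ = functional.pcoa(G, correction="sqrt")
        assert ord_.eigenvalues.min() >= -1e-8

    def test_duplicated_species_coincide(self):
        D = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        ord_ = functional.pcoa(D)
        np.testing.assert_allclose(ord_.coordinates[0], ord_.coordinates[1], atol=1e-10)

    def test_asymmetric_input_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            functional.pcoa(D)

    def test_agrees_with_skbio(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((8, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ours = functional.pcoa(D)
        ref = skbio_ord.pcoa(D)
        ref_eig = np.asarray(ref.eigvals)[:3]
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues[:3]), np.sort(ref_eig), rtol=1e-8
        )


def _phylo_ordination(tree):
    labels, D = phylo.cophenetic_matrix(tree)
    return labels, functional.pcoa(D, species=labels)


class TestDecouple:
    def test_residuals_orthogonal_to_predictors(self):
        t = synthetic.generate_phylogeny(25, seed=8)
        labels, pord = _phylo_ordination(t)
        tt = synthetic.simulate_traits(t, 3, seed=8)
        _, G = functional.gower(tt)
        res = functional.decouple(G, pord, species=labels, max_predictors=10)
        E = pord.coordinates[:, :10]
        inner = np.abs(E.T @ res.coordinates)
        assert inner.max() < 1e-8

    def test_collinear_traits_leave_no_residual(self):
        # traits built as exact linear maps of phylogenetic eigenvectors
        t = synthetic.generate_phylogeny(20, seed=9)
        labels, pord = _phylo_ordination(t)
        Y = pord.coordinates[:, :2] @ np.array([[1.0, 0.4], [-0.3, 2.0]])
        D = np.linalg.norm(Y[:, None] - Y[None, :], axis=-1)
        res = functional.decouple(D ** 2, pord, species=labels)  # sqrt undoes square
        assert np.linalg.norm(res.coordinates) < 1e-6
        assert res.variance_explained_by_phylogeny > 0.999

    def test_orthogonal_phylogeny_changes_nothing(self):
        rng = np.random.default_rng(10)
        n = 15
        labels = [f"s{i}" for i in range(n)]
        pts = rng.standard_normal((n, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        # predictors orthogonal to everything: zero eigenvector block
        pord = Ordination(labels, np.zeros((n, 1)), np.array([0.0]))
        res = functional.decouple(D ** 2, pord, species=labels)
        assert res.variance_explained_by_phylogeny == pytest.approx(0.0, abs=1e-10)

    def test_too_many_predictors_rejected(self):
        t = synthetic.generate_phylogeny(10, seed=11)
        labels, pord = _phylo_ordination(t)
        fat = Ordination(labels, np.random.default_rng(0).standard_normal((10, 12)),
                         np.ones(12))
        tt = synthetic.simulate_traits(t, 2, seed=11)
        _, G = functional.gower(tt)
        with pytest.raises(ValueError, match="truncate"):
            functional.decouple(G, fat, species=labels)


class TestFunctionalDispersion:
    def _space(self, coords):
        labels = [f"s{i}" for i in range(len(coords))]
        return labels, ResidualTraitSpace(labels, np.asarray(coords, float), 0.0)

    def _matrix(self, labels, present_by_cell, grid=None):
        grid = grid or GridSpec(2, 2)
        vals = np.zeros((grid.n_cells, len(labels)), np.uint8)
        for cell, idxs in present_by_cell.items():
            vals[cell, idxs] = 1
        return PresenceMatrix(grid, labels, vals)

    def test_single_species_zero_empty_nan(self):
        labels, space = self._space([[0.0, 0.0], [1.0, 1.0]])
        m = self._matrix(labels, {0: [0]})
        fd = functional.functional_dispersion(m, space)
        assert fd.values[0] == 0.0
        assert np.isnan(fd.values[1])

    def test_two_species_half_distance(self):
        labels, space = self._space([[0.0, 0.0], [3.0, 4.0]])
        m = self._matrix(labels, {0: [0, 1]})
        fd = functional.functional_dispersion(m, space)
        assert fd.values[0] == pytest.approx(2.5)  # d = 5, FDis = d/2

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        coords = rng.standard_normal((6, 4))
        labels, space = self._space(coords)
        m = self._matrix(labels, {0: list(range(6))})
        fd = functional.functional_dispersion(m, space)
        cent = coords.mean(axis=0)
        oracle = np.mean([np.sqrt(((c - cent) ** 2).sum()) for c in coords])
        assert fd.values[0] == pytest.approx(oracle, abs=1e-10)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(13)
        coords = rng.standard_normal((5, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        labels, space1 = self._space(coords)
        _, space2 = self._space(coords @ R.T + np.array([5.0, -2.0]))
        m = self._matrix(labels, {0: [0, 1, 2, 3, 4]})
        fd1 = functional.functional_dispersion(m, space1)
        fd2 = functional.functional_dispersion(m, space2)
        assert fd1.values[0] == pytest.approx(fd2.values[0], abs=1e-10)

    def test_unknown_species_rejected(self):
        labels, space = self._space([[0.0], [1.0]])
        m = self._matrix(labels + ["ghost"], {0: [0, 2]})
        with pytest.raises(ValueError, match="ghost"):
            functional.functional_dispersion(m, space)


class TestEndToEndDecoupling:
    def test_star_phylogeny_barely_changes_fdis(self):
        # equal-branch star: phylo eigenvectors carry no trait structure
        import dendropy

        n = 100
        newick = "(" + ",".join(f"s{i}:1.0" for i in range(n)) + ");"
        star = dendropy.Tree.get(data=newick, schema="newick")
        tt = synthetic.simulate_traits(star, 3, seed=14)
        labels, G = functional.gower(tt)
        raw = functional.pcoa(G, correction="sqrt", species=labels)
        _, D = phylo.cophenetic_matrix(star, labels)
        pord = functional.pcoa(D, species=labels)
        res = functional.decouple(G, pord, species=labels, max_predictors=5)
        grid = GridSpec(2, 2)
        rng = np.random.default_rng(15)
        vals = (rng.random((4, n)) < 0.5).astype(np.uint8)
        m = PresenceMatrix(grid, labels, vals)
        fd_raw = functional.functional_dispersion(m, raw)
        fd_res = functional.functional_dispersion(m, res)
        ratio = fd_res.values / fd_raw.values
        assert np.all(np.abs(ratio - 1.0) < 0.05)
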