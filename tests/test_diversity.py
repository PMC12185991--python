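import numpy as np
import pandas as pd
import pytest

from dysbiome import AbundanceTable
from dysbiome.diversity import (
    DistanceMatrix,
    bray_curtis_matrix,
    inverse_simpson,
    pcoa,
    permanova,
    shannon,
)


def _dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"S{i}" for i in range(len(values))]
    return DistanceMatrix(data=pd.DataFrame(values, index=ids, columns=ids))


class TestAlpha:
    def test_shannon_uniform_is_log_richness(self):
        assert shannon([1, 1, 1, 1]) == pytest.approx(np.log(4))

    def test_shannon_single_taxon_zero(self):
        assert shannon([0, 5, 0]) == 0.0

    def test_shannon_direct_formula(self):
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=1e-4)

    def test_inverse_simpson_uniform_is_richness(self):
        for k in (2, 5, 17):
            assert inverse_simpson([1.0] * k) == pytest.approx(k)

    def test_inverse_simpson_single_taxon(self):
        assert inverse_simpson([3.0]) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        v = rng.uniform(0.1, 5, 20)
        for f in (shannon, inverse_simpson):
            assert f(v) == pytest.approx(f(v * 37.5), rel=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = AbundanceTable(
            data=pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["A", "B"],
                              columns=["k__B|s__x", "k__B|s__y"]),
            rank="species",
        )
        assert bray_curtis_matrix(t).values[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        t = AbundanceTable(
            data=pd.DataFrame([[3.0, 0.0], [0.0, 5.0]], index=["A", "B"],
                              columns=["k__B|s__x", "k__B|s__y"]),
            rank="species",
        )
        assert bray_curtis_matrix(t).values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        t = AbundanceTable(
            data=pd.DataFrame([[2.0, 0.0], [1.0, 1.0]], index=["A", "B"],
                              columns=["k__B|s__x", "k__B|s__y"]),
            rank="species",
        )
        assert bray_curtis_matrix(t).values[0, 1] == pytest.approx(0.5)

    def test_range_symmetry_diagonal(self, default_cohort):
        table, _, _ = default_cohort
        sub = AbundanceTable(data=table.data.iloc[:40], rank="species")
        dm = bray_curtis_matrix(sub).values
        assert dm.min() >= 0 and dm.max() <= 1
        np.testing.assert_allclose(dm, dm.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(dm), 0, atol=1e-12)

    def test_zero_total_sample_named(self):
        t = AbundanceTable(
            data=pd.DataFrame([[1.0, 0.0], [0.0, 0.0]], index=["A", "Bad"],
                              columns=["k__B|s__x", "k__B|s__y"]),
            rank="species",
        )
        with pytest.raises(ValueError, match="Bad"):
            bray_curtis_matrix(t)


class TestPCoA:
    def test_three_collinear_points(self):
        res = pcoa(_dm([[0, 1, 2], [1, 0, 1], [2, 1, 0]]))
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 1
        ax1 = np.sort(res.coordinates["PC1"].to_numpy())
        np.testing.assert_allclose(ax1, [-1, 0, 1], atol=1e-10)

    def test_two_samples_midpoint_symmetry(self):
        res = pcoa(_dm([[0, 3.0], [3.0, 0]]))
        np.testing.assert_allclose(
            np.sort(res.coordinates["PC1"].to_numpy()), [-1.5, 1.5], atol=1e-12
        )

    def test_recovers_euclidean_configuration(self, rng):
        pts = rng.normal(size=(15, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(_dm(d), n_axes=2)
        x = res.coordinates.to_numpy()
        # Procrustes: optimal rotation of recovered onto original centred points
        y = pts - pts.mean(0)
        u, _, vt = np.linalg.svd(x.T @ y)
        err = np.linalg.norm(x @ u @ vt - y)
        assert err < 1e-8

    def test_eigenvalues_sorted_proportions_positive_only(self, default_cohort):
        table, _, _ = default_cohort
        sub = AbundanceTable(data=table.data.iloc[:30], rank="species")
        res = pcoa(bray_curtis_matrix(sub))
        assert (np.diff(res.eigenvalues) <= 1e-9).all()
        assert res.proportion_explained.sum() == pytest.approx(1.0)
        assert (res.proportion_explained > 0).all()

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        pts = rng.uniform(size=(12, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ours = pcoa(_dm(d))
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        np.testing.assert_allclose(
            ours.eigenvalues[:4], theirs.eigvals.to_numpy()[:4], atol=1e-8
        )


class TestPermanova:
    def _separated(self, gap=10.0, n=10, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal(0, 1, (n, 2)), rng.normal(gap, 1, (n, 2))])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        labels = np.repeat(["a", "b"], n)
        return _dm(d), labels

    def test_strong_separation_min_p(self):
        """With huge between-group separation p reaches the attainable
        minimum 1/(n_perm+1) — up to the rare random permutation that exactly
        preserves (or swaps) the group partition and so reproduces F."""
        dm, labels = self._separated()
        res = permanova(dm, labels, n_perm=999, seed=0)
        grp = next(r for r in res if r.term == "group")
        assert 1 / 1000 <= grp.p_value <= 2 / 1000

    def test_ss_partition_sums_to_total(self, default_cohort):
        table, meta, _ = default_cohort
        sub = AbundanceTable(data=table.data.iloc[:50], rank="species")
        dm = bray_curtis_matrix(sub)
        labels = (np.arange(50) % 2).astype(str)
        res = permanova(dm, labels, covariates=meta.iloc[:50][["age", "smoking"]],
                        n_perm=99, seed=1)
        from dysbiome.diversity import _gower_center

        total = np.trace(_gower_center(dm.values))
        assert sum(r.sum_of_squares for r in res) == pytest.approx(total, abs=1e-8)
        assert sum(r.R2 for r in res) == pytest.approx(1.0, abs=1e-10)

    def test_identical_blocks_no_separation(self):
        base = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        d = np.block([[base, base], [base, base]])
        np.fill_diagonal(d, 0.0)
        res = permanova(_dm(d), np.repeat(["x", "y"], 3), n_perm=99, seed=0)
        grp = next(r for r in res if r.term == "group")
        assert np.isfinite(grp.pseudo_F)
        assert grp.R2 == pytest.approx(0.0, abs=1e-10)

    def test_constant_group_rejected(self):
        dm, _ = self._separated()
        with pytest.raises(ValueError, match="constant"):
            permanova(dm, ["a"] * 20, n_perm=99)

    def test_pseudo_f_matches_skbio_one_way(self):
        skbio = pytest.importorskip("skbio")
        dm, labels = self._separated(gap=2.0, seed=3)
        ours = permanova(dm, labels, n_perm=99, seed=0)
        grp = next(r for r in ours if r.term == "group")
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.values, ids=dm.sample_ids), labels,
            permutations=99,
        )
        assert grp.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_f_equivariant_under_sample_reordering(self):
        dm, labels = self._separated(gap=2.0, seed=4)
        rng = np.random.default_rng(9)
        perm = rng.permutation(20)
        d2 = _dm(dm.values[np.ix_(perm, perm)])
        r1 = permanova(dm, labels, n_perm=99, seed=0)
        r2 = permanova(d2, np.asarray(labels)[perm], n_perm=99, seed=0)
        f1 = next(r for r in r1 if r.term == "group").pseudo_F
        f2 = next(r for r in r2 if r.term == "group").pseudo_F
        assert f1 == pytest.approx(f2, rel=1e-10)
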