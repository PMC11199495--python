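"""Rarefaction, alpha metrics, Bray-Curtis, PCoA, PERMANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import hypergeom

from digestax import (InvalidInputError, alpha_diversity, bray_curtis, pcoa,
                      permanova, permanova_by_factor, rarefy)

from ._oracles import permanova_exact_p, permanova_f


def _counts(rows, samples, taxa):
    return pd.DataFrame(rows, index=samples, columns=taxa, dtype=np.int64)


class TestRarefy:
    def test_exact_depth_sample_unchanged(self):
        t = _counts([[4000, 6000]], ["s1"], ["a", "b"])
        out, excluded = rarefy(t, 10_000, 0)
        assert out.loc["s1"].tolist() == [4000, 6000]
        assert excluded == []

    def test_single_feature_sample(self):
        t = _counts([[20_000]], ["s1"], ["a"])
        out, _ = rarefy(t, 10_000, 1)
        assert out.loc["s1", "a"] == 10_000

    def test_totals_exactly_at_depth(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame(rng.integers(0, 5000, size=(8, 30)))
        t = t.loc[t.sum(axis=1) >= 10_000]
        out, _ = rarefy(t, 10_000, 3)
        assert (out.sum(axis=1) == 10_000).all()

    def test_shallow_samples_excluded(self):
        t = _counts([[5000, 4000], [6000, 6000]], ["shallow", "deep"],
                    ["a", "b"])
        out, excluded = rarefy(t, 10_000, 4)
        assert excluded == ["shallow"]
        assert list(out.index) == ["deep"]

    def test_hypergeometric_mean(self):
        """Two-feature sample 15k/5k at depth 10k: feature-1 mean 7500."""
        t = _counts([[15_000, 5_000]] * 100,
                    [f"s{i}" for i in range(100)], ["a", "b"])
        out, _ = rarefy(t, 10_000, 5)
        mean = out["a"].mean()
        sd = hypergeom(20_000, 15_000, 10_000).std()
        assert abs(mean - 7500) < 3 * sd / np.sqrt(100)

    def test_deterministic_under_seed(self):
        t = _counts([[7000, 8000]], ["s1"], ["a", "b"])
        a, _ = rarefy(t, 10_000, 6)
        b, _ = rarefy(t, 10_000, 6)
        pd.testing.assert_frame_equal(a, b)


class TestAlphaDiversity:
    def test_uniform_inverse_simpson_equals_richness(self):
        t = _counts([[100] * 10], ["s1"], [f"t{i}" for i in range(10)])
        out = alpha_diversity(t)
        assert out.loc["s1", "observed_richness"] == 10
        assert out.loc["s1", "inverse_simpson"] == pytest.approx(10.0)

    def test_single_feature(self):
        t = _counts([[500]], ["s1"], ["a"])
        out = alpha_diversity(t)
        assert out.loc["s1", "observed_richness"] == 1
        assert out.loc["s1", "inverse_simpson"] == pytest.approx(1.0)

    def test_closed_form_half_quarter_quarter(self):
        t = _counts([[2, 1, 1]], ["s1"], ["a", "b", "c"])
        out = alpha_diversity(t)
        assert out.loc["s1", "inverse_simpson"] == pytest.approx(1 / 0.375)

    def test_all_zero_sample_raises(self):
        with pytest.raises(InvalidInputError):
            alpha_diversity(_counts([[0, 0]], ["s1"], ["a", "b"]))


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        rel = pd.DataFrame([[0.5, 0.5, 0, 0], [0.5, 0.5, 0, 0],
                            [0, 0, 0.3, 0.7]],
                           index=["a", "b", "c"])
        dm = bray_curtis(rel)
        assert dm.loc["a", "b"] == pytest.approx(0.0)
        assert dm.loc["a", "c"] == pytest.approx(1.0)
        assert np.allclose(dm, dm.T) and np.allclose(np.diag(dm), 0)

    def test_closed_form_3_1_vs_1_3(self):
        rel = pd.DataFrame([[3, 1], [1, 3]], index=["a", "b"],
                           dtype=float)
        assert bray_curtis(rel).loc["a", "b"] == pytest.approx(0.5)

    def test_bounds(self):
        rng = np.random.default_rng(7)
        rel = pd.DataFrame(rng.dirichlet(np.ones(20), size=10))
        dm = bray_curtis(rel).to_numpy()
        assert (dm >= -1e-12).all() and (dm <= 1 + 1e-12).all()


class TestPcoa:
    def test_collinear_points_single_axis(self):
        dm = pd.DataFrame([[0, 1, 2], [1, 0, 1], [2, 1, 0]],
                          index=list("abc"), columns=list("abc"),
                          dtype=float)
        res = pcoa(dm)
        assert res.explained[0] == pytest.approx(1.0)

    def test_euclidean_embedding_reconstructed(self):
        """Distances from planted 2-D points reproduce to 1e-9."""
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 2))
        dm = pd.DataFrame(squareform(pdist(pts)))
        res = pcoa(dm)
        coords = res.coordinates.to_numpy()
        recon = squareform(pdist(coords))
        assert np.abs(recon - dm.to_numpy()).max() < 1e-9

    def test_two_samples_single_axis_full_variance(self):
        dm = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["a", "b"],
                          columns=["a", "b"])
        res = pcoa(dm)
        assert res.coordinates.shape[1] == 1
        assert res.explained[0] == pytest.approx(1.0)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 3))
        dm = pd.DataFrame(squareform(pdist(pts)))
        a = pcoa(dm).coordinates
        b = pcoa(dm).coordinates
        pd.testing.assert_frame_equal(a, b)
        for col in a.columns:
            assert a[col].abs().idxmax() == a[col].idxmax()

    def test_asymmetric_input_rejected(self):
        dm = pd.DataFrame([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(InvalidInputError):
            pcoa(dm)

    def test_non_euclidean_negative_eigenvalues_reported(self):
        rng = np.random.default_rng(10)
        rel = pd.DataFrame(rng.dirichlet(np.ones(8), size=10))
        res = pcoa(bray_curtis(rel))
        assert res.eigenvalues.min() < 0  # reported, not corrected


class TestPermanova:
    def _dm(self, rng, n):
        rel = pd.DataFrame(rng.dirichlet(np.ones(25), size=n))
        return bray_curtis(rel)

    def test_exact_matches_bruteforce_at_n6(self):
        """All 20 label splits of 3+3 enumerate to the oracle's p."""
        rng = np.random.default_rng(11)
        dm = self._dm(rng, 6)
        labels = ["x", "x", "x", "y", "y", "y"]
        res = permanova(dm, labels, method="exact")
        oracle_p = permanova_exact_p(dm.to_numpy().tolist(), labels)
        assert res.n_permutations == 20
        assert res.p_value == pytest.approx(oracle_p, abs=1e-12)
        assert res.pseudo_f == pytest.approx(
            permanova_f(dm.to_numpy().tolist(), labels), abs=1e-9)

    def test_separated_clusters_maximally_significant(self):
        rng = np.random.default_rng(12)
        a = rng.dirichlet([50, 1, 1, 1, 1], size=8)
        b = rng.dirichlet([1, 1, 1, 1, 50], size=8)
        rel = pd.DataFrame(np.vstack([a, b]))
        labels = ["a"] * 8 + ["b"] * 8
        res = permanova(bray_curtis(rel), labels, n_permutations=999,
                        seed=13)
        assert res.r2 > 0.5
        assert res.p_value == pytest.approx(1 / 1000)

    def test_r2_invariant_to_sample_order(self):
        rng = np.random.default_rng(14)
        dm = self._dm(rng, 10)
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=dm.index)
        perm = rng.permutation(10)
        dm2 = dm.iloc[perm, perm]
        r1 = permanova(dm, labels, seed=0).r2
        r2 = permanova(dm2, labels.iloc[perm], seed=0).r2
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_null_rejection_rate_calibrated(self):
        """Labels independent of distances: ~5% rejections at alpha=.05
        over 500 simulated datasets."""
        rng = np.random.default_rng(15)
        labels = ["a"] * 6 + ["b"] * 6
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            dm = self._dm(rng, 12)
            res = permanova(dm, labels, n_permutations=999, seed=rng)
            rejections += res.p_value <= 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_small_group_and_constant_factor_rejected(self):
        rng = np.random.default_rng(16)
        dm = self._dm(rng, 5)
        with pytest.raises(InvalidInputError):
            permanova(dm, ["a", "a", "a", "a", "b"])
        with pytest.raises(InvalidInputError):
            permanova(dm, ["a"] * 5)

    def test_by_factor_marginal(self):
        rng = np.random.default_rng(17)
        dm = self._dm(rng, 8)
        meta = pd.DataFrame({
            "substrate": ["M", "M", "M", "M", "F", "F", "F", "F"],
            "temperature": ["T", "T", "M", "M", "T", "T", "M", "M"],
        }, index=dm.index)
        out = permanova_by_factor(dm, meta, ["substrate", "temperature"])
        assert list(out["factor"]) == ["substrate", "temperature"]
        assert ((out["r2"] >= 0) & (out["r2"] <= 1)).all()


class TestAgainstScikitBio:
    """Independent cross-checks against an established implementation."""

    def test_permanova_f_matches_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(18)
        rel = pd.DataFrame(rng.dirichlet(np.ones(15), size=12))
        dm = bray_curtis(rel)
        labels = ["a"] * 6 + ["b"] * 6
        mine = permanova(dm, labels, n_permutations=99, seed=0)
        theirs = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(dm.to_numpy(),
                                       ids=[str(i) for i in dm.index]),
            grouping=labels, permutations=99)
        assert mine.pseudo_f == pytest.approx(theirs["test statistic"],
                                              rel=1e-9)

    def test_pcoa_explained_matches_skbio(self):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(19)
        rel = pd.DataFrame(rng.dirichlet(np.ones(10), size=8))
        dm = bray_curtis(rel)
        mine = pcoa(dm)
        theirs = skbio_ord.pcoa(skbio_dist.DistanceMatrix(
            dm.to_numpy(), ids=[str(i) for i in dm.index]))
        n = len(mine.explained)
        assert np.allclose(mine.explained,
                           theirs.proportion_explained.to_numpy()[:n]
                           / theirs.proportion_explained.to_numpy()[
                               theirs.eigvals.to_numpy() > 0].sum(),
                           atol=1e-6)
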