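import numpy as np
import pandas as pd
import pytest
import skbio.stats.distance as skdist
import skbio.stats.ordination as skord

from viropop.ecology import (
    bootstrap_prevalence_median,
    bray_curtis,
    pairwise_centroid_distance,
    pcoa,
    permanova,
    simper,
)
from viropop.synthetic_data import SimulationConfig, simulate_abundance_matrix


def taxa_by_samples(data, samples, taxa=None):
    """Build a taxa x samples DataFrame (the abundance-matrix orientation)."""
    df = pd.DataFrame(data, columns=samples)
    if taxa is not None:
        df.index = taxa
    return df


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        m = taxa_by_samples({"s1": [1, 2, 3], "s2": [1, 2, 3]}, ["s1", "s2"])
        d = bray_curtis(m, transform="none")
        assert d["s1", "s2"] == 0.0

    def test_disjoint_supports_distance_one(self):
        m = taxa_by_samples({"s1": [5, 0], "s2": [0, 7]}, ["s1", "s2"])
        assert bray_curtis(m, transform="none")["s1", "s2"] == pytest.approx(1.0)

    def test_cube_root_hand_example(self):
        # u=(8,0), v=(1,1); cube-rooted u'=(2,0), v'=(1,1): d=(1+1)/(3+1)=0.5
        m = taxa_by_samples({"u": [8, 0], "v": [1, 1]}, ["u", "v"])
        assert bray_curtis(m, transform="cube_root")["u", "v"] == pytest.approx(0.5)

    def test_negative_abundance_error(self):
        m = taxa_by_samples({"s1": [1, -1], "s2": [1, 1]}, ["s1", "s2"])
        with pytest.raises(ValueError):
            bray_curtis(m)

    def test_all_zero_pair_warns_and_zeroes(self):
        m = taxa_by_samples({"s1": [0, 0], "s2": [0, 0], "s3": [1, 1]}, ["s1", "s2", "s3"])
        with pytest.warns(UserWarning):
            d = bray_curtis(m, transform="none")
        assert d["s1", "s2"] == 0.0


class TestPcoa:
    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(0)
        points = rng.normal(size=(6, 2))
        D = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
        d = skdist.DistanceMatrix(D, ids=[f"s{i}" for i in range(6)])
        res = pcoa(d)
        got = np.linalg.norm(
            res.coords[:, None, :] - res.coords[None, :, :], axis=-1
        )
        assert np.allclose(got, D, atol=1e-8)

    def test_two_samples_closed_form(self):
        d = skdist.DistanceMatrix([[0, 0.4], [0.4, 0]], ids=["a", "b"])
        res = pcoa(d)
        assert res.coords.shape[1] == 1
        assert abs(res.coords[0, 0] - res.coords[1, 0]) == pytest.approx(0.4)

    def test_three_equidistant_points(self):
        d = skdist.DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        res = pcoa(d)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_matches_skbio_on_braycurtis(self):
        rng = np.random.default_rng(1)
        m = taxa_by_samples(rng.lognormal(size=(20, 8)), [f"s{i}" for i in range(8)])
        d = bray_curtis(m, transform="cube_root")
        mine = pcoa(d)
        ref = skord.pcoa(d, number_of_dimensions=mine.coords.shape[1])
        n_pos = mine.coords.shape[1]
        assert np.allclose(
            np.sort(mine.eigenvalues[:n_pos]),
            np.sort(ref.eigvals.to_numpy()[:n_pos]),
            atol=1e-8,
        )
        for k in range(n_pos):  # axes agree up to sign
            a, b = mine.coords[:, k], ref.samples.to_numpy()[:, k]
            assert np.allclose(a, b, atol=1e-6) or np.allclose(a, -b, atol=1e-6)

    def test_eigenvalues_descending_and_pct_bounded(self):
        rng = np.random.default_rng(2)
        m = taxa_by_samples(rng.lognormal(size=(10, 6)), [f"s{i}" for i in range(6)])
        res = pcoa(bray_curtis(m))
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert res.pct_explained.sum() <= 100 + 1e-9


class TestPermanova:
    def _clustered(self, n_per=6, sep=5.0, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(n_per, 3))
        b = rng.normal(sep, 1, size=(n_per, 3))
        X = np.vstack([a, b])
        ids = [f"s{i}" for i in range(2 * n_per)]
        D = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        return skdist.DistanceMatrix(D, ids=ids), ["A"] * n_per + ["B"] * n_per

    def test_pseudo_f_matches_skbio(self):
        d, groups = self._clustered(sep=1.0)
        mine = permanova(d, groups, n_perm=99, seed=0)
        ref = skdist.permanova(d, grouping=groups, permutations=99)
        assert mine.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_separated_clusters_significant(self):
        d, groups = self._clustered(n_per=12, sep=8.0)
        res = permanova(d, groups, n_perm=999, seed=3)
        assert res.p == pytest.approx(1 / 1000)
        assert res.r2 > 0.8

    def test_scale_invariance_of_p(self):
        d, groups = self._clustered(sep=2.0)
        r1 = permanova(d, groups, n_perm=199, seed=5)
        d2 = skdist.DistanceMatrix(3.7 * np.asarray(d.data), ids=list(d.ids))
        r2 = permanova(d2, groups, n_perm=199, seed=5)
        assert r1.p == r2.p
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F)

    def test_degenerate_groupings_rejected(self):
        d, groups = self._clustered()
        with pytest.raises(ValueError):
            permanova(d, ["A"] * len(groups))
        with pytest.raises(ValueError):
            permanova(d, [str(i) for i in range(len(groups))])

    def test_identical_points_error(self):
        D = np.zeros((4, 4))
        d = skdist.DistanceMatrix(D, ids=list("abcd"))
        with pytest.raises(ValueError):
            permanova(d, ["A", "A", "B", "B"], n_perm=9, seed=0)


class TestCentroidDistance:
    def test_singleton_groups_equal_point_distance(self):
        d = skdist.DistanceMatrix([[0, 2.0], [2.0, 0]], ids=["a", "b"])
        res = pcoa(d)
        table = pairwise_centroid_distance(res, ["g1", "g2"])
        assert table["distance"].iloc[0] == pytest.approx(2.0)

    def test_mirrored_clusters(self):
        from viropop.ecology import OrdinationResult

        coords = np.array([[1.0, 1.0], [1.0, 1.0], [-1.0, -1.0], [-1.0, -1.0]])
        res = OrdinationResult(["a", "b", "c", "d"], coords,
                               np.array([1.0, 1.0]), np.array([50.0, 50.0]))
        table = pairwise_centroid_distance(res, ["g1", "g1", "g2", "g2"])
        assert table["distance"].iloc[0] == pytest.approx(2 * np.sqrt(2))

    def test_identical_groups_zero(self):
        from viropop.ecology import OrdinationResult

        coords = np.tile([[2.0, 3.0]], (4, 1))
        res = OrdinationResult(list("abcd"), coords, np.array([1.0]), np.array([100.0]))
        table = pairwise_centroid_distance(res, ["g1", "g2", "g1", "g2"])
        assert table["distance"].iloc[0] == 0.0

    def test_empty_group_error(self):
        from viropop.ecology import OrdinationResult

        res = OrdinationResult(["a"], np.zeros((1, 1)), np.array([1.0]), np.array([100.0]))
        with pytest.raises(ValueError):
            pairwise_centroid_distance(res, ["g1"])


class TestSimper:
    def test_single_discriminating_taxon(self):
        m = taxa_by_samples(
            {"a1": [10, 5, 5], "a2": [10, 5, 5], "b1": [0, 5, 5], "b2": [0, 5, 5]},
            ["a1", "a2", "b1", "b2"],
            taxa=["t1", "t2", "t3"],
        )
        res = simper(m, ["A", "A", "B", "B"], transform="none")
        assert res.iloc[0]["taxon_id"] == "t1"
        assert res.iloc[0]["mean_contribution"] == pytest.approx(1.0)

    def test_contributions_sum_to_one(self):
        rng = np.random.default_rng(8)
        m = taxa_by_samples(rng.lognormal(size=(30, 8)), [f"s{i}" for i in range(8)])
        res = simper(m, ["A"] * 4 + ["B"] * 4)
        assert res["mean_contribution"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (res["mean_contribution"] >= 0).all()
        assert res["cumulative"].is_monotonic_increasing

    def test_recovers_simulated_effect_taxa(self):
        config = SimulationConfig(seed=13, n_populations=40, n_effect_taxa=10,
                                  effect_size=3.0, abundance_sigma=0.5)
        matrix, truth = simulate_abundance_matrix(config)
        res = simper(matrix, matrix.sample_meta["group"].tolist())
        assert set(res.head(10)["taxon_id"]) == set(truth["taxon_id"])

    def test_requires_two_groups(self):
        m = taxa_by_samples({"a": [1], "b": [2], "c": [3]}, ["a", "b", "c"])
        with pytest.raises(ValueError):
            simper(m, ["A", "B", "C"])


class TestBootstrapPrevalenceMedian:
    def test_constant_list_degenerate(self):
        med, lo, hi = bootstrap_prevalence_median([4] * 30, n_boot=100, seed=0)
        assert med == lo == hi == 4.0

    def test_deterministic_under_seed(self):
        counts = list(np.random.default_rng(1).integers(0, 145, 100))
        assert bootstrap_prevalence_median(counts, 500, seed=3) == (
            bootstrap_prevalence_median(counts, 500, seed=3)
        )

    def test_ci_brackets_observed_median(self):
        counts = list(np.random.default_rng(2).poisson(20, 200))
        med, lo, hi = bootstrap_prevalence_median(counts, 1000, seed=4)
        assert lo <= med <= hi

    def test_empty_error(self):
        with pytest.raises(ValueError):
            bootstrap_prevalence_median([])
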