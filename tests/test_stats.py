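"""Statistics core: hand-computed oracles, brute-force enumeration and
cross-checks against independent implementations (scipy / statsmodels /
scikit-bio)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from guildnet.containers import RelAbundanceTable, SymmetricMatrix
from guildnet.errors import PreconditionError
from guildnet.stats import (anosim, bh_adjust, bray_curtis, diversity_table,
                            observed_richness, pcoa, permanova, shannon,
                            spearman_matrix)


def _distance_from_points(points: np.ndarray, ids=None) -> SymmetricMatrix:
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    ids = ids or [f"p{i}" for i in range(len(points))]
    return SymmetricMatrix(ids, d, "distance")


class TestAlphaDiversity:
    def test_shannon_uniform_and_point_mass(self):
        assert shannon([0.25] * 4) == pytest.approx(np.log(4), abs=1e-12)
        assert shannon([1.0, 0.0, 0.0]) == 0.0

    def test_shannon_matches_direct_summation(self):
        p = [0.5, 0.25, 0.25]
        direct = -sum(v * np.log(v) for v in p)
        assert shannon(p) == pytest.approx(direct, abs=1e-12)

    def test_shannon_rejects_bad_input(self):
        with pytest.raises(PreconditionError):
            shannon([0.5, -0.1, 0.6])
        with pytest.raises(PreconditionError):
            shannon([0.5, 0.2])

    def test_richness(self):
        assert observed_richness([5, 0, 2, 0]) == 2
        assert observed_richness([0, 0]) == 0
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 3, 50)
        assert observed_richness(counts) == sum(1 for c in counts if c > 0)

    def test_diversity_table_shape(self):
        counts = pd.DataFrame([[1, 2], [3, 0]], index=["a", "b"],
                              columns=["s1", "s2"])
        table = diversity_table(counts)
        assert list(table.columns) == ["shannon", "observed_richness"]
        assert table.loc["s2", "observed_richness"] == 1


class TestBrayCurtis:
    def test_identical_disjoint_and_hand_value(self):
        rel = RelAbundanceTable(pd.DataFrame(
            {"u": [0.6, 0.4, 0.0], "v": [0.2, 0.8, 0.0],
             "w": [0.6, 0.4, 0.0], "z": [0.0, 0.0, 1.0]},
            index=["t1", "t2", "t3"]))
        d = bray_curtis(rel)
        frame = d.to_dataframe()
        assert frame.loc["u", "w"] == pytest.approx(0.0, abs=1e-12)
        assert frame.loc["u", "z"] == pytest.approx(1.0)
        assert frame.loc["u", "v"] == pytest.approx(0.4)

    def test_matches_scikit_bio(self):
        from skbio.diversity import beta_diversity
        rng = np.random.default_rng(1)
        comp = rng.dirichlet(np.ones(8), size=6)
        rel = RelAbundanceTable(pd.DataFrame(
            comp.T, index=[f"t{i}" for i in range(8)],
            columns=[f"s{i}" for i in range(6)]))
        ours = bray_curtis(rel).values
        theirs = beta_diversity("braycurtis", comp,
                                ids=[f"s{i}" for i in range(6)]).data
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestPCoA:
    def test_equidistant_points_give_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(SymmetricMatrix(list("abc"), d, "distance"), k=2)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_line_embedding_reproduces_distances(self):
        points = np.array([[0.0], [1.0], [2.5], [7.0]])
        res = pcoa(_distance_from_points(points), k=1)
        axis = res.coordinates["PCo1"].to_numpy()
        rebuilt = np.abs(axis[:, None] - axis[None, :])
        expected = np.abs(points[:, 0][:, None] - points[:, 0][None, :])
        np.testing.assert_allclose(rebuilt, expected, atol=1e-9)

    def test_euclidean_distances_fully_reconstructed(self):
        rng = np.random.default_rng(2)
        points = rng.normal(size=(7, 3))
        dist = _distance_from_points(points)
        res = pcoa(dist, k=7)
        coords = res.coordinates.to_numpy()
        rebuilt = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        np.testing.assert_allclose(rebuilt, dist.values, atol=1e-6)
        assert res.truncated  # only n-1 positive axes exist

    def test_id_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        points = rng.normal(size=(5, 2))
        ids = list("abcde")
        res = pcoa(_distance_from_points(points, ids), k=2)
        order = [3, 0, 4, 1, 2]
        permuted = _distance_from_points(points[order], [ids[i] for i in order])
        res2 = pcoa(permuted, k=2)
        for axis in ("PCo1", "PCo2"):
            a = res.coordinates[axis].reindex(ids).to_numpy()
            b = res2.coordinates[axis].reindex(ids).to_numpy()
            np.testing.assert_allclose(np.abs(a), np.abs(b), atol=1e-9)

    def test_matches_scikit_bio(self):
        import skbio
        rng = np.random.default_rng(4)
        points = rng.normal(size=(8, 4))
        dist = _distance_from_points(points)
        ours = pcoa(dist, k=3)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dist.values, ids=dist.ids))
        np.testing.assert_allclose(ours.eigenvalues[:3],
                                   theirs.eigvals.to_numpy()[:3], atol=1e-8)
        for i in range(3):
            a = ours.coordinates.iloc[:, i].to_numpy()
            b = theirs.samples.iloc[:, i].to_numpy()
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8


def _anosim_r_brute(dist: np.ndarray, labels) -> float:
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ranks = sps.rankdata([dist[i, j] for i, j in pairs])
    between = [r for r, (i, j) in zip(ranks, pairs) if labels[i] != labels[j]]
    within = [r for r, (i, j) in zip(ranks, pairs) if labels[i] == labels[j]]
    return (np.mean(between) - np.mean(within)) / (len(pairs) / 2.0)


class TestAnosim:
    def test_fully_separated_gives_r_one(self):
        points = np.array([[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]])
        res = anosim(_distance_from_points(points), [0, 0, 0, 1, 1, 1],
                     n_perm=999, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_statistic_matches_brute_force_and_skbio(self):
        import skbio
        rng = np.random.default_rng(5)
        points = rng.normal(size=(10, 2))
        labels = [0, 0, 0, 1, 1, 1, 2, 2, 2, 2]
        dist = _distance_from_points(points)
        res = anosim(dist, labels, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(
            _anosim_r_brute(dist.values, labels), abs=1e-12)
        theirs = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(dist.values, ids=dist.ids),
            grouping=[str(g) for g in labels], permutations=0)
        assert res.statistic == pytest.approx(theirs["test statistic"],
                                              abs=1e-12)

    def test_exact_p_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(3):
            points = rng.normal(size=(6, 2))
            dist = _distance_from_points(points)
            labels = [0, 0, 0, 1, 1, 1]
            res = anosim(dist, labels, n_perm=999, seed=0)
            splits = [lab for lab in
                      set(itertools.permutations(labels))]
            stats = [_anosim_r_brute(dist.values, lab) for lab in splits]
            expected = np.mean([s >= res.statistic - 1e-12 for s in stats])
            assert res.p_value == pytest.approx(expected)
            assert res.extras["exact"]

    def test_null_mean_r_near_zero(self):
        rng = np.random.default_rng(7)
        r_values = []
        for _ in range(200):
            points = rng.normal(size=(12, 2))
            labels = rng.permutation([0] * 6 + [1] * 6)
            res = anosim(_distance_from_points(points), labels, n_perm=0 + 99,
                         seed=0)
            r_values.append(res.statistic)
        assert abs(np.mean(r_values)) < 0.05

    def test_rejects_singleton_group(self):
        points = np.arange(5.0)[:, None]
        with pytest.raises(PreconditionError):
            anosim(_distance_from_points(points), [0, 0, 0, 0, 1])


def _permanova_f_brute(dist: np.ndarray, labels) -> float:
    labels = np.asarray(labels)
    n = len(labels)
    d2 = dist ** 2
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss_within += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    a = len(np.unique(labels))
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_exact_p_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            points = rng.normal(size=(6, 3))
            dist = _distance_from_points(points)
            labels = [0, 0, 0, 1, 1, 1]
            res = permanova(dist, labels, n_perm=999, seed=0)
            splits = set(itertools.permutations(labels))
            assert len(splits) == 20
            stats = [_permanova_f_brute(dist.values, lab) for lab in splits]
            expected = np.mean([s >= res.statistic - 1e-12 for s in stats])
            assert res.p_value == pytest.approx(expected)

    def test_statistic_matches_brute_force_and_skbio(self):
        import skbio
        rng = np.random.default_rng(9)
        points = rng.normal(size=(9, 2))
        labels = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        dist = _distance_from_points(points)
        res = permanova(dist, labels, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(
            _permanova_f_brute(dist.values, labels), abs=1e-10)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dist.values, ids=dist.ids),
            grouping=[str(g) for g in labels], permutations=0)
        assert res.statistic == pytest.approx(theirs["test statistic"],
                                              abs=1e-10)

    def test_duplicated_group_has_no_between_structure(self):
        rng = np.random.default_rng(10)
        points = rng.normal(size=(4, 2))
        doubled = np.vstack([points, points])
        dist = _distance_from_points(doubled)
        res = permanova(dist, [0, 0, 0, 0, 1, 1, 1, 1], n_perm=199, seed=0)
        assert res.statistic < 0.5
        assert res.p_value > 0.5

    def test_degenerate_all_equal_distances(self):
        d = np.zeros((6, 6))
        res = permanova(SymmetricMatrix(list("abcdef"), d, "distance"),
                        [0, 0, 0, 1, 1, 1], n_perm=99, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_sim = 400
        for s in range(n_sim):
            points = rng.normal(size=(16, 2))
            dist = _distance_from_points(points)
            p = permanova(dist, [0] * 8 + [1] * 8, n_perm=199, seed=s).p_value
            rejections += p <= 0.05
        assert 0.02 <= rejections / n_sim <= 0.08

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(12)
        points = rng.normal(size=(14, 2))
        dist = _distance_from_points(points)
        labels = [0] * 7 + [1] * 7
        a = permanova(dist, labels, n_perm=199, seed=5)
        b = permanova(dist, labels, n_perm=199, seed=5)
        assert a.p_value == b.p_value


class TestSpearman:
    def test_perfect_monotone(self):
        x = pd.DataFrame([[1, 2, 3, 4, 5, 6], [2, 4, 9, 16, 25, 36],
                          [6, 5, 4, 3, 2, 1]],
                         index=["inc", "inc2", "dec"],
                         columns=list("abcdef"))
        table = spearman_matrix(x).set_index(["id_a", "id_b"])
        assert table.loc[("inc", "inc2"), "rho"] == pytest.approx(1.0)
        assert table.loc[("inc", "dec"), "rho"] == pytest.approx(-1.0)

    def test_tied_fixture_matches_midrank_formula(self):
        # 8 points with one tie in x: compute rho by explicit mid-ranks
        xv = np.array([1.0, 2.0, 2.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        yv = np.array([3.0, 1.0, 4.0, 2.0, 6.0, 5.0, 8.0, 7.0])
        rx, ry = sps.rankdata(xv), sps.rankdata(yv)
        expected = (np.corrcoef(rx, ry))[0, 1]
        table = spearman_matrix(pd.DataFrame([xv, yv], index=["x", "y"]))
        assert table["rho"].iloc[0] == pytest.approx(expected, abs=1e-12)
        # and against scipy's implementation
        assert table["rho"].iloc[0] == pytest.approx(
            sps.spearmanr(xv, yv).statistic, abs=1e-12)

    def test_large_n_p_matches_scipy_t_approximation(self):
        rng = np.random.default_rng(13)
        xv = rng.normal(size=30)
        yv = xv + rng.normal(size=30)
        table = spearman_matrix(pd.DataFrame([xv, yv], index=["x", "y"]))
        ref = sps.spearmanr(xv, yv)
        assert table["rho"].iloc[0] == pytest.approx(ref.statistic, abs=1e-12)
        assert table["p"].iloc[0] == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_flagged_invalid(self):
        x = pd.DataFrame([[1, 1, 1, 1, 1, 1], [1, 2, 3, 4, 5, 6]],
                         index=["const", "inc"])
        table = spearman_matrix(x)
        assert not table["valid"].iloc[0]
        assert np.isnan(table["q"].iloc[0])

    def test_missing_values_dropped_pairwise(self):
        x = pd.DataFrame([[1, 2, 3, 4, 5, np.nan, 7],
                          [1, 2, 3, 4, 5, 6, 7]], index=["a", "b"])
        table = spearman_matrix(x)
        assert table["n"].iloc[0] == 6
        assert table["rho"].iloc[0] == pytest.approx(1.0)


class TestBHAdjust:
    def test_hand_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_all_ones(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(14)
        p = rng.uniform(size=40)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(PreconditionError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_properties_q_ge_p_and_order_invariance(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0 + 1e-15)
        order = np.argsort(p)[::-1]
        q_shuffled = bh_adjust(p[order])
        np.testing.assert_allclose(q_shuffled, q[order], atol=1e-12)


@given(st.integers(min_value=0, max_value=10_000))
def test_anosim_r_always_in_range(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 12))
    points = rng.normal(size=(n, 2))
    half = n // 2
    labels = [0] * half + [1] * (n - half)
    res = anosim(_distance_from_points(points), labels, n_perm=0 + 99, seed=0)
    assert -1.0 - 1e-9 <= res.statistic <= 1.0 + 1e-9
    res_f = permanova(_distance_from_points(points), labels, n_perm=99, seed=0)
    assert res_f.statistic >= 0.0
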