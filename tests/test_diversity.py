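import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy import stats

from viromeflow.diversity import (
    DistanceMatrix,
    alpha_condition_correlation,
    centroids_and_extremes,
    distance_matrix,
    expected_rarefied_richness,
    pcoa,
    permanova,
    pielou,
    rarefied_richness,
    relative_abundance,
    shannon,
    _ss_partition,
)
from viromeflow.io_formats import AbundanceMatrix, ValidationError


class TestAlphaDiversity:
    def test_relative_abundance_simple(self):
        counts = pd.DataFrame({"s": [2.0, 2.0, 4.0]}, index=list("abc"))
        rel = relative_abundance(counts)
        assert rel["s"].tolist() == [0.25, 0.25, 0.5]

    def test_shannon_closed_forms(self):
        assert shannon(np.full(8, 1 / 8)) == pytest.approx(np.log(8))
        assert pielou(np.full(8, 1 / 8)) == pytest.approx(1.0)
        assert shannon([1.0]) == 0.0
        assert np.isnan(pielou([1.0]))
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.5 * np.log(2))

    def test_shannon_maximal_at_uniform(self, rng):
        for _ in range(50):
            s = int(rng.integers(2, 30))
            p = rng.dirichlet(np.ones(s))
            assert shannon(p) <= np.log(s) + 1e-12

    def test_rarefied_richness_exact_cases(self, rng):
        counts = [5, 3, 2]
        assert rarefied_richness(counts, 10, reps=10, rng=rng) == 3.0
        singletons = np.ones(20, dtype=int)
        assert rarefied_richness(singletons, 7, reps=5, rng=rng) == 7.0

    def test_rarefied_richness_matches_hypergeometric_expectation(self, rng):
        counts = rng.integers(0, 40, size=30)
        counts[0] += 1
        depth = int(counts.sum() // 3)
        reps = 400
        est = rarefied_richness(counts, depth, reps=reps, rng=rng)
        exp = expected_rarefied_richness(counts, depth)
        # MC standard error of the mean richness across reps
        draws = [
            rarefied_richness(counts, depth, reps=1, rng=rng) for _ in range(100)
        ]
        se = np.std(draws, ddof=1) / np.sqrt(reps)
        assert abs(est - exp) <= 3 * max(se, 1e-6)

    def test_depth_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            rarefied_richness([1, 2], 100, reps=2)


class TestDistances:
    def test_identical_samples_distance_zero(self):
        t = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]}, index=["x", "y"])
        for metric in ("canberra", "bray_curtis"):
            assert distance_matrix(t, metric).values[0, 1] == pytest.approx(0.0)

    def test_disjoint_support(self):
        t = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]}, index=["x", "y"])
        assert distance_matrix(t, "canberra").values[0, 1] == pytest.approx(2.0)
        assert distance_matrix(t, "bray_curtis").values[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_formula(self):
        t = pd.DataFrame({"a": [2.0, 2.0], "b": [1.0, 3.0]}, index=["x", "y"])
        assert distance_matrix(t, "bray_curtis").values[0, 1] == pytest.approx(0.25)

    def test_unknown_metric_lists_supported(self):
        t = pd.DataFrame({"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError, match="canberra"):
            distance_matrix(t, "euclidean")

    def test_metric_axioms_on_random_data(self, rng):
        t = pd.DataFrame(rng.random((10, 6)), columns=[f"s{i}" for i in range(6)])
        for metric in ("canberra", "bray_curtis"):
            d = distance_matrix(t, metric)
            assert np.allclose(d.values, d.values.T)
            assert np.allclose(np.diag(d.values), 0)
            assert (d.values >= 0).all()


class TestPcoa:
    def test_equilateral_triangle_gives_equal_positive_eigenvalues(self):
        vals = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(["a", "b", "c"], vals, "test"))
        pos = res.eigenvalues[res.eigenvalues > 0]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_reconstructs_euclidean_distances_of_planar_points(self, rng):
        pts = rng.normal(size=(20, 2))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(20)], d, "euclidean"))
        coords = res.coordinates.iloc[:, :2].to_numpy()
        assert np.allclose(squareform(pdist(coords)), d, atol=1e-8)

    def test_duplicated_point_coincident(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(list("abcd"), d, "euclidean"))
        c = res.coordinates.to_numpy()
        assert np.allclose(c[1], c[2], atol=1e-8)

    def test_non_symmetric_rejected(self):
        vals = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValidationError):
            DistanceMatrix(["a", "b"], vals, "x")

    def test_agrees_with_skbio(self, rng):
        """Independent cross-check against scikit-bio's PCoA."""
        import skbio

        t = pd.DataFrame(rng.random((15, 8)), columns=[f"s{i}" for i in range(8)])
        d = distance_matrix(t, "bray_curtis")
        ours = pcoa(d)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.values, ids=d.ids)
        )
        n_pos = int((ours.eigenvalues > 1e-10).sum())
        ours_e = np.sort(ours.eigenvalues[:n_pos])[::-1]
        theirs_e = np.sort(theirs.eigvals.to_numpy())[::-1][:n_pos]
        assert np.allclose(ours_e, theirs_e, atol=1e-8)
        # coordinates agree up to per-axis sign
        for ax in range(2):
            a = ours.coordinates.iloc[:, ax].to_numpy()
            b = theirs.samples.iloc[:, ax].to_numpy()
            assert np.allclose(a, b, atol=1e-6) or np.allclose(a, -b, atol=1e-6)


def _brute_force_f(d2: np.ndarray, labels: list) -> float:
    """Direct textbook pseudo-F from squared distances (oracle)."""
    n = len(labels)
    groups = sorted(set(labels))
    a = len(groups)
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i, lab in enumerate(labels) if lab == g]
        ss_within += sum(
            d2[i, j] for i in idx for j in idx if i < j
        ) / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def _clustered_dm(self, rng, sep=10.0, k=8):
        # group size 8: the chance a permutation reproduces the original
        # partition (tying the observed F) is 2/C(16,8), negligible
        pts = np.vstack(
            [rng.normal(0, 0.1, (k, 2)), rng.normal(sep, 0.1, (k, 2))]
        )
        d = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(2 * k)]
        return DistanceMatrix(ids, d, "euclidean"), ["A"] * k + ["B"] * k

    def test_separated_clusters_maximal_effect(self, rng):
        dm, labels = self._clustered_dm(rng)
        res = permanova(dm, labels, n_perm=199, seed=1)
        assert res.r_squared > 0.9
        assert res.p_value == pytest.approx(1 / 200)

    def test_label_symmetry(self, rng):
        dm, labels = self._clustered_dm(rng, sep=1.0)
        res1 = permanova(dm, labels, n_perm=99, seed=2)
        swapped = ["B" if l == "A" else "A" for l in labels]
        res2 = permanova(dm, swapped, n_perm=99, seed=2)
        assert res1.pseudo_F == pytest.approx(res2.pseudo_F)
        assert res1.r_squared == pytest.approx(res2.r_squared)

    def test_exact_p_matches_exhaustive_enumeration(self, rng):
        """n=6, two groups of 3: exact mode reproduces the brute-force
        enumeration over all C(6,3) label assignments."""
        for _ in range(5):
            pts = rng.normal(size=(6, 2))
            d = squareform(pdist(pts))
            dm = DistanceMatrix([f"s{i}" for i in range(6)], d, "euclidean")
            labels = ["A", "A", "A", "B", "B", "B"]
            res = permanova(dm, labels, exact=True)
            d2 = d**2
            f_obs = _brute_force_f(d2, labels)
            fs = []
            for combo in itertools.combinations(range(6), 3):
                lab = ["A" if i in combo else "B" for i in range(6)]
                fs.append(_brute_force_f(d2, lab))
            p_oracle = np.mean([f >= f_obs - 1e-12 for f in fs])
            assert res.p_value == pytest.approx(p_oracle)
            assert res.pseudo_F == pytest.approx(f_obs)

    def test_sum_of_squares_partition(self, rng):
        pts = rng.normal(size=(12, 3))
        d2 = squareform(pdist(pts)) ** 2
        codes = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2])
        ss_total, ss_within = _ss_partition(d2, codes, 3)
        ss_between = ss_total - ss_within
        assert 0 <= ss_between <= ss_total + 1e-9
        res = permanova(
            DistanceMatrix([f"s{i}" for i in range(12)], np.sqrt(d2), "e"),
            [str(c) for c in codes],
            n_perm=9,
            seed=0,
        )
        assert res.r_squared == pytest.approx(ss_between / ss_total)
        assert 0.0 <= res.r_squared <= 1.0

    def test_agrees_with_skbio_statistic(self, rng):
        """Cross-check the pseudo-F against scikit-bio's PERMANOVA."""
        import skbio

        pts = rng.normal(size=(12, 4))
        d = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(12)]
        labels = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        ours = permanova(DistanceMatrix(ids, d, "e"), labels, n_perm=9, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d, ids=ids), grouping=labels, permutations=9
        )
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"])


class TestCentroidsAndCorrelation:
    def _ordination(self, coords):
        df = pd.DataFrame(coords, columns=["PCo1", "PCo2"])
        df.index = [f"s{i}" for i in range(len(df))]
        from viromeflow.diversity import OrdinationResult

        return OrdinationResult(df, np.array([2.0, 1.0]))

    def test_single_sample_group_is_its_own_centroid(self, rng):
        coords = rng.normal(size=(4, 2))
        ordn = self._ordination(coords)
        groups = {"s0": "solo", "s1": "rest", "s2": "rest", "s3": "rest"}
        cents = centroids_and_extremes(
            ordn, pd.Series(1.0, index=ordn.coordinates.index), groups, n_extreme=2
        )
        assert np.allclose(cents.loc["group:solo"].to_numpy(), coords[0])

    def test_symmetric_points_centre_at_origin(self):
        coords = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
        ordn = self._ordination(coords)
        groups = {s: "g" for s in ordn.coordinates.index}
        cents = centroids_and_extremes(
            ordn, pd.Series([1, 2, 3, 4.0], index=ordn.coordinates.index), groups, 2
        )
        assert np.allclose(cents.loc["group:g"].to_numpy(), [0, 0])

    def test_centroid_equals_coordinate_mean_oracle(self, rng):
        coords = rng.normal(size=(12, 2))
        ordn = self._ordination(coords)
        alpha = pd.Series(rng.random(12), index=ordn.coordinates.index)
        groups = {s: ("a" if i < 7 else "b") for i, s in enumerate(ordn.coordinates.index)}
        cents = centroids_and_extremes(ordn, alpha, groups, n_extreme=3)
        assert np.allclose(cents.loc["group:a"].to_numpy(), coords[:7].mean(axis=0))
        top3 = alpha.sort_values(ascending=False).index[:3]
        oracle = ordn.coordinates.loc[top3].mean(axis=0).to_numpy()
        assert np.allclose(cents.loc["high_alpha"].to_numpy(), oracle)

    def test_perfect_monotone_association(self):
        alpha = [3.0, 2.0, 1.0]
        rho, _ = alpha_condition_correlation(alpha, ["Control", "UC", "CD"])
        assert rho == pytest.approx(-1.0)

    def test_null_association_small_rho(self, rng):
        hits = 0
        for _ in range(20):
            alpha = rng.random(60)
            conds = list(rng.choice(["Control", "UC", "CD"], size=60))
            rho, p = alpha_condition_correlation(alpha, conds)
            if p < 0.05:
                hits += 1
        assert hits <= 4  # null: ~5% false positives expected

    def test_tied_data_matches_rank_then_pearson_oracle(self):
        alpha = [1.0, 1.0, 2.0, 3.0, 3.0, 4.0]
        conds = ["Control", "UC", "UC", "CD", "Control", "CD"]
        enc = {"Control": 0, "UC": 1, "CD": 2}
        rho, _ = alpha_condition_correlation(alpha, conds, enc)
        ra = stats.rankdata(alpha)
        rc = stats.rankdata([enc[c] for c in conds])
        oracle = np.corrcoef(ra, rc)[0, 1]
        assert rho == pytest.approx(oracle)

    def test_constant_input_reported_missing(self):
        rho, p = alpha_condition_correlation([1.0, 1.0], ["Control", "CD"])
        assert np.isnan(rho) and np.isnan(p)
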