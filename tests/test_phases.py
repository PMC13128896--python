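import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from strataclock.phases import (
    DEFAULT_SCALES,
    Dendrogram,
    SupportedDendrogram,
    bin_average_beta,
    cluster_raw_beta,
    compare_sex_phases,
    cut_phases,
    fit_au,
    multiscale_bootstrap,
    ward_cluster,
)


def ward_oracle(X):
    """Independent Ward.D2 reference: Lance-Williams recursion on squared
    Euclidean distances. Returns [(frozenset members, height)] in merge order."""
    n = X.shape[0]
    d2 = squareform(pdist(X)) ** 2
    active = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dd = {(i, j): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    for _ in range(n - 1):
        (i, j), best = min(dd.items(), key=lambda kv: (kv[1], kv[0]))
        merged = active[i] | active[j]
        merges.append((merged, np.sqrt(best)))
        ni, nj = sizes[i], sizes[j]
        new = {k: v for k, v in dd.items() if i not in k and j not in k}
        for k in active:
            if k in (i, j):
                continue
            dik = dd[(min(i, k), max(i, k))]
            djk = dd[(min(j, k), max(j, k))]
            nk = sizes[k]
            new[(min(k, next_id), max(k, next_id))] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * best
            ) / (ni + nj + nk)
        dd = new
        del active[i], active[j], sizes[i], sizes[j]
        active[next_id] = merged
        sizes[next_id] = ni + nj
        next_id += 1
    return merges


def _merges_of(d: Dendrogram):
    return list(zip(d.merge_members(), d.heights))


class TestWardCluster:
    def test_identical_profiles_merge_at_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        d = ward_cluster(X, labels=["a", "b", "c"])
        members, heights = d.merge_members(), d.heights
        assert members[0] == frozenset({0, 1})
        assert heights[0] == pytest.approx(0.0)

    def test_close_pair_merges_first(self):
        X = np.array([[0.0], [1.0], [100.0]])
        d = ward_cluster(X)
        assert d.merge_members()[0] == frozenset({0, 1})

    def test_oracle_equivalence_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            X = rng.normal(size=(6, 20))
            d = ward_cluster(X)
            for (m1, h1), (m2, h2) in zip(_merges_of(d), ward_oracle(X)):
                assert m1 == m2
                assert h1 == pytest.approx(h2, abs=1e-8)

    def test_feature_permutation_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(7, 15))
        perm = rng.permutation(15)
        d1, d2 = ward_cluster(X), ward_cluster(X[:, perm])
        assert d1.merge_members() == d2.merge_members()
        np.testing.assert_allclose(d1.heights, d2.heights, atol=1e-10)

    def test_single_bin_error(self):
        with pytest.raises(ValueError, match="2 bins"):
            ward_cluster(np.ones((1, 5)))

    def test_missing_values_error(self):
        X = np.ones((3, 4))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            ward_cluster(X)


class TestFitAu:
    def test_flat_half_bp_gives_half_au(self):
        au, v, c, flag = fit_au([0.5, 0.8, 1.0, 1.2], [0.5] * 4, 100)
        assert flag == ""
        assert v == pytest.approx(0.0, abs=1e-12)
        assert c == pytest.approx(0.0, abs=1e-12)
        assert au == pytest.approx(0.5)

    def test_single_scale_falls_back_to_bp(self):
        au, v, c, flag = fit_au([1.0], [0.85], 100)
        assert flag == "degenerate_fit"
        assert au == pytest.approx(0.85)

    def test_all_degenerate_bp_falls_back(self):
        au, _, _, flag = fit_au([0.5, 1.0, 1.4], [1.0, 1.0, 1.0], 100)
        assert flag == "degenerate_fit"
        assert au == 1.0

    def test_au_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            bp = rng.uniform(0.05, 0.95, size=10)
            au, *_ = fit_au(DEFAULT_SCALES, bp, 1000)
            assert 0.0 <= au <= 1.0


@pytest.fixture(scope="module")
def planted_split():
    rng = np.random.default_rng(1)
    X = rng.normal(0, 0.1, size=(6, 40))
    X[:3] += 5.0  # group {A,B,C} vs {D,E,F}, separation >> spread
    return multiscale_bootstrap(X, labels=list("ABCDEF"), n_bootstrap=200, seed=0)


class TestMultiscaleBootstrap:

    def test_true_split_strongly_supported(self, planted_split):
        edge = planted_split.edge_for(["A", "B", "C"])
        assert edge is not None
        assert edge.au >= 0.95
        assert edge.bp >= 0.95

    def test_bp_binomial_variation_across_seeds(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 30))
        B = 100
        first = multiscale_bootstrap(X, n_bootstrap=B, seed=0, scales=(1.0,))
        second = multiscale_bootstrap(X, n_bootstrap=B, seed=99, scales=(1.0,))
        for e1 in first.edges:
            e2 = second.edge_for(e1.members)
            assert e2 is not None  # same observed tree
            bp = max(min(e1.bp, 0.99), 0.01)
            tol = 4 * np.sqrt(bp * (1 - bp) / B) + 1e-9
            assert abs(e1.bp - e2.bp) <= tol

    def test_au_matches_bp_when_curvature_is_zero(self):
        # calibration: when psi_r is proportional to sqrt(r) (zero curvature
        # term), AU equals BP at r = 1
        from scipy.stats import norm

        scales = np.array(DEFAULT_SCALES)
        for v in (-1.0, -0.3, 0.3, 1.0):
            bp = 1.0 - norm.cdf(v * np.sqrt(scales))
            au, v_hat, c_hat, flag = fit_au(scales, bp, 1000)
            assert flag == ""
            assert c_hat == pytest.approx(0.0, abs=1e-8)
            bp_at_1 = bp[np.argmin(np.abs(scales - 1.0))]
            assert au == pytest.approx(bp_at_1, abs=0.05)

    def test_serialization_round_trip(self, planted_split, tmp_path):
        planted_split.to_json(tmp_path / "tree.json")
        back = SupportedDendrogram.from_json(tmp_path / "tree.json")
        np.testing.assert_allclose(back.dendrogram.linkage, planted_split.dendrogram.linkage)
        for e1, e2 in zip(back.edges, planted_split.edges):
            assert e1.members == e2.members
            assert e1.au == pytest.approx(e2.au)

    def test_newick_contains_labels_and_support(self, planted_split):
        nwk = planted_split.to_newick()
        assert nwk.endswith(";")
        for label in "ABCDEF":
            assert label in nwk
        assert "au" in nwk and "bp" in nwk

    def test_min_bootstrap_enforced(self):
        with pytest.raises(ValueError, match="n_bootstrap"):
            multiscale_bootstrap(np.random.default_rng(0).normal(size=(4, 10)), n_bootstrap=5)


class TestCutPhases:
    def _tree(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 10)) * 0.1
        X[3:] += 10
        return ward_cluster(X, labels=["b1", "b2", "b3", "b4", "b5"])

    def test_above_root_single_phase(self):
        d = self._tree()
        out = cut_phases(d, height=d.heights.max() + 1)
        assert out.n_phases == 1

    def test_height_zero_all_singletons(self):
        d = self._tree()
        out = cut_phases(d, height=0.0)
        assert out.n_phases == 5

    def test_k_mode_minimal_height(self):
        d = self._tree()
        out = cut_phases(d, k=2)
        assert out.n_phases == 2
        # reusing the recorded height reproduces the same partition
        again = cut_phases(d, height=out.cut_height)
        assert again.phases == out.phases

    def test_k_exceeds_leaves(self):
        with pytest.raises(ValueError, match="k"):
            cut_phases(self._tree(), k=6)

    def test_exactly_one_of_height_or_k(self):
        d = self._tree()
        with pytest.raises(ValueError):
            cut_phases(d)
        with pytest.raises(ValueError):
            cut_phases(d, height=1.0, k=2)

    def test_phases_numbered_by_first_leaf(self):
        d = self._tree()
        out = cut_phases(d, k=2)
        assert out.phases[0] == 1
        assert max(out.phases) == 2


class TestCompareSexPhases:
    def _grouped_profile(self, boundaries, seed, n_bins=10, n_feat=40, sep=8.0):
        """Bins 0..n_bins-1 with level jumps at the given bin indices."""
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 0.1, size=(n_bins, n_feat))
        offsets = np.zeros(n_bins)
        for b in boundaries:
            offsets[b:] += sep
        # jump direction varies by feature to keep groups separated in all dims
        signs = rng.choice([-1.0, 1.0], size=n_feat)
        X += offsets[:, None] * signs[None, :]
        labels = [f"bin{i}" for i in range(n_bins)]
        return multiscale_bootstrap(X, labels=labels, n_bootstrap=100, seed=seed)

    def test_identical_profiles_identical_phases(self):
        tree = self._grouped_profile([5], seed=0)
        out = compare_sex_phases({"male": tree, "female": tree}, cut_height=tree.dendrogram.heights.max() / 2)
        male, female = out["male"][0], out["female"][0]
        assert male.phases == female.phases

    def test_planted_boundary_counts(self):
        male = self._grouped_profile([5], seed=1)
        female = self._grouped_profile([3, 7], seed=2)
        # shared cut between subgroup merges and boundary merges of both trees
        height = min(male.dendrogram.heights.max(), female.dendrogram.heights.max()) * 0.8
        out = compare_sex_phases({"male": male, "female": female}, cut_height=height)
        assert out["male"][0].n_phases == 2
        assert out["female"][0].n_phases == 3
        assert out["male"][1] == 2
        assert out["female"][1] == 3

    def test_impossible_threshold_zero_supported(self):
        tree = self._grouped_profile([5], seed=3)
        out = compare_sex_phases({"m": tree, "f": tree},
                                 cut_height=tree.dendrogram.heights.max() / 2,
                                 threshold=1.01)
        assert out["m"][1] == 0 and out["f"][1] == 0

    def test_mismatched_bins_error(self):
        t1 = self._grouped_profile([5], seed=4)
        t2 = self._grouped_profile([5], seed=5, n_bins=8)
        with pytest.raises(ValueError, match="mismatch"):
            compare_sex_phases({"m": t1, "f": t2}, cut_height=1.0)


class TestRawBetaRoute:
    def test_same_matrix_same_dendrogram_either_path(self):
        rng = np.random.default_rng(6)
        frame = pd.DataFrame(rng.uniform(size=(6, 30)),
                             index=[f"bin{i}" for i in range(6)])
        via_raw = cluster_raw_beta(frame, n_bootstrap=50, seed=1, scales=(1.0,))
        via_shap = multiscale_bootstrap(frame, n_bootstrap=50, seed=1, scales=(1.0,))
        np.testing.assert_allclose(via_raw.dendrogram.linkage, via_shap.dendrogram.linkage)
        for e1, e2 in zip(via_raw.edges, via_shap.edges):
            assert e1.bp == e2.bp

    def test_constant_beta_all_merges_at_zero(self):
        X = np.full((4, 10), 0.5)
        d = ward_cluster(X)
        np.testing.assert_allclose(d.heights, 0.0, atol=1e-12)

    def test_bin_average_beta(self, small_cohort):
        beta, meta, _ = small_cohort
        frame = bin_average_beta(beta, meta)
        assert frame.shape[1] == beta.n_probes
        assert (frame.to_numpy() >= 0).all() and (frame.to_numpy() <= 1).all()

    def test_planted_boundaries_agree_between_routes(self, small_cohort):
        beta, meta, truth = small_cohort
        frame = bin_average_beta(beta, meta)
        d = ward_cluster(frame)
        out = cut_phases(d, k=4)
        # step-structured CpGs dominate: phases are contiguous in age
        from strataclock.attribution import AgeBinScheme
        from strataclock.simulate import truth_phase_partition
        from sklearn.metrics import adjusted_rand_score

        scheme = AgeBinScheme()
        kept = [scheme.labels().index(b) for b in frame.index]
        intervals = [scheme.intervals()[i] for i in kept]
        planted = truth_phase_partition(truth, intervals)
        assert adjusted_rand_score(planted, out.phases) >= 0.5
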