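import numpy as np
import pytest

from icsearch.relevance import (
    admission_test,
    build_affinity,
    build_affinity_unsupervised,
    build_spectral_cache,
    cluster_score,
    cluster_score_dense,
    encode_labels,
    feature_score,
    standardize_voxels,
)


def brute_quadratic_form(x, S):
    """x L x' computed as the pairwise form (1/2) sum S_jk (x_j - x_k)^2."""
    n = len(x)
    total = 0.0
    for j in range(n):
        for k in range(n):
            total += S[j, k] * (x[j] - x[k]) ** 2
    return total / 2.0


class TestAffinity:
    def test_two_class_balanced_entries(self):
        m = build_affinity(np.array(["A", "A", "B", "B"]))
        assert m.S_b[0, 1] == pytest.approx(1 / 4 - 1 / 2)  # same class
        assert m.S_b[0, 2] == pytest.approx(1 / 4)          # cross class
        assert m.S_w[0, 1] == pytest.approx(0.5)
        assert m.S_w[0, 2] == 0.0

    def test_row_sums_identity(self, rng):
        for _ in range(50):
            n = rng.integers(4, 15)
            labels = rng.integers(0, rng.integers(2, 4), size=n)
            if len(np.unique(labels)) < 2:
                continue
            m = build_affinity(labels)
            assert np.allclose(m.S_b.sum(axis=1), 0.0)
            assert np.allclose(m.S_w.sum(axis=1), 1.0)
            for L in (m.L_b, m.L_w):
                assert np.allclose(L, L.T)
                assert np.allclose(L.sum(axis=1), 0.0)
                assert np.linalg.eigvalsh(L).min() >= -1e-10

    def test_two_singleton_classes(self):
        m = build_affinity(np.array([0, 1]))
        assert np.allclose(m.S_w, np.eye(2))
        assert np.allclose(m.L_w, 0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="labels required"):
            build_affinity(np.array([1, 1, 1]))

    def test_encode_counts(self):
        enc = encode_labels(np.array([2, 0, 2, 0, 2]))
        assert enc.n == 5
        assert enc.counts.sum() == enc.n
        assert set(enc.counts.tolist()) == {2, 3}


class TestSpectralCache:
    def test_quadratic_form_oracle(self, rng):
        """Cached b_i, w_i equal the explicit pairwise double-loop forms
        (1/2) sum_jk S[j,k] (x_j - x_k)^2, valid because degrees are row sums."""
        X = rng.standard_normal((20, 10))
        y = np.repeat([0, 1], 5)
        m = build_affinity(y)
        cache = build_spectral_cache(X, m, standardize=False)
        for i in range(20):
            assert cache.b[i] == pytest.approx(
                brute_quadratic_form(X[i], m.S_b), abs=1e-9)
            assert cache.w[i] == pytest.approx(
                brute_quadratic_form(X[i], m.S_w), abs=1e-9)

    def test_constant_voxel_scores_zero(self):
        X = np.vstack([np.full(8, 3.0), np.arange(8, dtype=float)])
        y = np.repeat([0, 1], 4)
        cache = build_spectral_cache(X, build_affinity(y), standardize=False)
        assert cache.b[0] == pytest.approx(0.0, abs=1e-12)
        assert cache.w[0] == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_even_with_duplicated_subject(self, rng):
        X = rng.standard_normal((10, 9))
        X = np.column_stack([X, X[:, 0]])
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 0])
        cache = build_spectral_cache(X, build_affinity(y))
        assert (cache.b >= 0).all() and (cache.w >= 0).all()

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.standard_normal((5, 7))
        m = build_affinity(np.repeat([0, 1], 4))
        with pytest.raises(ValueError, match="subjects"):
            build_spectral_cache(X, m)


class TestClusterScore:
    def test_singleton_equals_feature_score(self, spectral_setup):
        _, _, _, cache = spectral_setup
        for i in (0, 5, 11):
            assert cluster_score(cache, np.array([i])) == feature_score(cache, i)

    def test_matches_dense_trace_oracle(self, rng):
        X = rng.standard_normal((30, 16))
        y = np.repeat([0, 1], 8)
        m = build_affinity(y)
        cache = build_spectral_cache(X, m, standardize=True)
        for _ in range(30):
            size = rng.integers(1, 8)
            members = rng.choice(30, size=size, replace=False)
            assert cluster_score(cache, members) == pytest.approx(
                cluster_score_dense(X, m, members, standardize=True), abs=1e-10)

    def test_order_invariance_and_mediant(self, spectral_setup, rng):
        _, _, _, cache = spectral_setup
        members = rng.choice(27, size=6, replace=False)
        s = cluster_score(cache, members)
        assert s == cluster_score(cache, members[::-1])
        ratios = cache.b[members] / cache.w[members]
        assert ratios.min() - 1e-12 <= s <= ratios.max() + 1e-12

    def test_two_voxel_mediant_example(self):
        from icsearch.relevance import SpectralCache
        cache = SpectralCache(b=np.array([2.0, 0.0]), w=np.array([1.0, 1.0]))
        assert cluster_score(cache, np.array([0, 1])) == pytest.approx(1.0)

    def test_degenerate_denominator_warns_inf(self):
        from icsearch.relevance import SpectralCache
        cache = SpectralCache(b=np.array([1.0]), w=np.array([0.0]))
        with pytest.warns(RuntimeWarning, match="degenerate within-class"):
            assert cluster_score(cache, np.array([0])) == np.inf


class TestAdmission:
    def test_zero_between_candidate_rejected(self):
        from icsearch.relevance import SpectralCache
        cache = SpectralCache(b=np.array([4.0, 0.0]), w=np.array([1.0, 1.0]))
        admit, dif = admission_test(cache, np.array([0]), 1)
        assert not admit and dif < 0

    def test_score_neutral_candidate_rejected(self):
        from icsearch.relevance import SpectralCache
        cache = SpectralCache(b=np.array([4.0, 4.0]), w=np.array([1.0, 1.0]))
        admit, dif = admission_test(cache, np.array([0]), 1)
        assert not admit and dif == pytest.approx(0.0)

    def test_agrees_with_dense_recomputation(self, rng):
        X = rng.standard_normal((15, 12))
        y = np.repeat([0, 1], 6)
        m = build_affinity(y)
        cache = build_spectral_cache(X, m)
        for _ in range(20):
            members = rng.choice(15, size=4, replace=False)
            cand = int(rng.choice(np.setdiff1d(np.arange(15), members)))
            admit, _ = admission_test(cache, members, cand)
            dense_old = cluster_score_dense(X, m, members)
            dense_new = cluster_score_dense(X, m, np.append(members, cand))
            assert admit == (dense_new - dense_old > 1e-14) or \
                abs(dense_new - dense_old) < 1e-10

    def test_existing_member_rejected(self, spectral_setup):
        _, _, _, cache = spectral_setup
        with pytest.raises(ValueError, match="already a member"):
            admission_test(cache, np.array([1, 2]), 2)


class TestUnsupervised:
    def test_symmetry_and_identical_subjects(self, rng):
        X = rng.standard_normal((10, 8))
        X[:, 1] = X[:, 0]  # two identical subjects
        m = build_affinity_unsupervised(X, k_neighbors=3)
        assert np.allclose(m.S_w, m.S_w.T)
        assert m.S_w[0, 1] == pytest.approx(1.0)  # zero distance, heat kernel
        assert np.allclose(m.S_b, 1.0 / 8)

    def test_separating_voxel_outranks_noise(self, rng):
        n = 40
        X = rng.standard_normal((10, n)) * 0.2
        X[0, n // 2:] += 4.0  # voxel 0 separates two subject blobs
        m = build_affinity_unsupervised(X, k_neighbors=5)
        cache = build_spectral_cache(X, m)
        scores = cache.b / np.maximum(cache.w, 1e-300)
        assert scores[0] > scores[1:].max()

    def test_invalid_kernel_width(self, rng):
        X = rng.standard_normal((5, 8))
        with pytest.raises(ValueError, match="kernel_width"):
            build_affinity_unsupervised(X, kernel_width=np.inf)
        with pytest.raises(ValueError, match="subjects"):
            build_affinity_unsupervised(X[:, :4], k_neighbors=5)


def test_standardize_voxels_properties(rng):
    X = rng.standard_normal((6, 30)) * 5 + 2
    Z = standardize_voxels(X)
    assert np.allclose(Z.mean(axis=1), 0.0, atol=1e-12)
    assert np.allclose(Z.std(axis=1), 1.0)
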