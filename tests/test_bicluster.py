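import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from biclustsurv import (
    CohortSpec,
    laplacian_cocluster_oracle,
    normalize_bipartite,
    reorder_checkerboard,
    simulate_cohort,
    spectral_cocluster,
)
from biclustsurv.errors import ValidationError


def _blockdiag():
    rows = np.repeat([0, 1, 2], [4, 5, 6])
    cols = np.repeat([0, 1, 2], [3, 4, 5])
    X = np.zeros((15, 12))
    for r, v in zip(range(3), (2.0, 5.0, 9.0)):
        X[np.ix_(rows == r, cols == r)] = v
    return X, rows, cols


def _planted(m=40, n=30, seed=2, noise=0.3):
    spec = CohortSpec(n_samples=m, n_genes=n, noise_sd=noise, seed=seed)
    expr, _, truth = simulate_cohort(spec)
    return expr.T.to_numpy(), truth


class TestNormalize:
    def test_uniform_matrix(self):
        Xn, _ = normalize_bipartite([[1.0, 1], [1, 1]])
        assert Xn == pytest.approx(np.full((2, 2), 0.5))

    def test_hand_computed_diagonal(self):
        Xn, f = normalize_bipartite([[2.0, 0], [0, 8]])
        assert Xn == pytest.approx(np.eye(2))
        assert f.row_sums == pytest.approx([2, 8])
        assert f.col_sums == pytest.approx([2, 8])

    @pytest.mark.parametrize("seed", range(5))
    def test_top_singular_value_is_one(self, seed):
        # oracle: full SVD of the normalized matrix
        rng = np.random.default_rng(seed)
        X = rng.random((12, 9)) + 0.01
        Xn, _ = normalize_bipartite(X)
        s = np.linalg.svd(Xn, compute_uv=False)
        assert abs(s[0] - 1.0) < 1e-8

    def test_zero_row_names_offender(self):
        import pandas as pd

        X = pd.DataFrame([[1.0, 2], [0, 0]], index=["s_ok", "s_bad"],
                         columns=["g1", "g2"])
        with pytest.raises(ValidationError, match="s_bad"):
            normalize_bipartite(X)

    def test_negative_entry_instructs_shift(self):
        with pytest.raises(ValidationError, match="shift"):
            normalize_bipartite([[1.0, -2], [3, 4]])


class TestSpectralCocluster:
    def test_noiseless_blockdiag_exact(self):
        X, rows, cols = _blockdiag()
        m = spectral_cocluster(X, k=3, seed=0)
        assert adjusted_rand_score(rows, m.sample_labels) == 1.0
        assert adjusted_rand_score(cols, m.gene_labels) == 1.0

    def test_planted_recovery(self):
        X, truth = _planted()
        m = spectral_cocluster(X, k=3, seed=0)
        assert adjusted_rand_score(truth.sample_labels, m.sample_labels) >= 0.95

    def test_p_is_ceil_log2_k(self):
        X, _ = _planted()
        for k, p in ((2, 1), (3, 2), (4, 2), (5, 3)):
            assert spectral_cocluster(X, k=k, seed=0).p == p

    def test_trivial_pair_constant_and_excluded(self):
        X, _ = _planted()
        shifted = X - X.min()
        Xn, f = normalize_bipartite(shifted)
        U, s, _ = np.linalg.svd(Xn, full_matrices=False)
        assert abs(s[0] - 1.0) < 1e-8
        z1 = U[:, 0] / np.sqrt(f.row_sums)
        assert np.ptp(z1) < 1e-8  # the trivial embedding coordinate is constant

    def test_determinism(self):
        X, _ = _planted()
        m1 = spectral_cocluster(X, k=3, seed=5)
        m2 = spectral_cocluster(X, k=3, seed=5)
        assert (m1.sample_labels == m2.sample_labels).all()
        assert (m1.gene_labels == m2.gene_labels).all()
        assert m1.inertia == m2.inertia

    def test_permutation_equivariance(self):
        X, _ = _planted()
        rng = np.random.default_rng(0)
        rp, cp = rng.permutation(X.shape[0]), rng.permutation(X.shape[1])
        ma = spectral_cocluster(X, k=3, seed=7)
        mb = spectral_cocluster(X[np.ix_(rp, cp)], k=3, seed=7)
        back_s = np.empty_like(mb.sample_labels)
        back_s[rp] = mb.sample_labels
        back_g = np.empty_like(mb.gene_labels)
        back_g[cp] = mb.gene_labels
        assert adjusted_rand_score(ma.sample_labels, back_s) == 1.0
        assert adjusted_rand_score(ma.gene_labels, back_g) == 1.0

    def test_singular_value_sum_permutation_invariant(self):
        X, _ = _planted()
        rng = np.random.default_rng(1)
        Xp = X[np.ix_(rng.permutation(X.shape[0]), rng.permutation(X.shape[1]))]
        s1 = spectral_cocluster(X, k=3, seed=0).singular_values
        s2 = spectral_cocluster(Xp, k=3, seed=0).singular_values
        assert s1.sum() == pytest.approx(s2.sum(), rel=1e-9)

    def test_shift_recorded(self):
        X, _ = _planted()
        m = spectral_cocluster(X, k=3, seed=0)
        assert m.shift == pytest.approx(X.min())

    def test_k_too_large(self):
        X, _ = _planted(m=10, n=8)
        with pytest.raises(ValidationError, match="exceeds"):
            spectral_cocluster(X, k=9, seed=0)

    def test_k_below_two(self):
        X, _ = _planted(m=10, n=8)
        with pytest.raises(ValidationError, match="k must be"):
            spectral_cocluster(X, k=1, seed=0)


class TestLaplacianOracle:
    def test_blockdiag_matches_svd_path(self):
        X, _, _ = _blockdiag()
        m1 = spectral_cocluster(X, k=3, seed=0)
        m2 = laplacian_cocluster_oracle(X, k=3, seed=0)
        assert adjusted_rand_score(m1.sample_labels, m2.sample_labels) == 1.0
        assert adjusted_rand_score(m1.gene_labels, m2.gene_labels) == 1.0

    def test_random_wellseparated_agreement(self):
        rng = np.random.default_rng(7)
        agree = 0
        trials = 25
        for _ in range(trials):
            rows = rng.integers(0, 2, 20)
            cols = rng.integers(0, 2, 15)
            means = np.array([[2.0, 0.3], [0.3, 2.0]])
            X = means[np.ix_(rows, cols)] + rng.normal(0, 0.15, (20, 15))
            X -= X.min()
            m1 = spectral_cocluster(X, k=2, seed=0)
            m2 = laplacian_cocluster_oracle(X, k=2, seed=0)
            both = np.concatenate([m1.sample_labels, m1.gene_labels])
            other = np.concatenate([m2.sample_labels, m2.gene_labels])
            agree += adjusted_rand_score(both, other) == 1.0
        assert agree >= 0.95 * trials

    def test_k2_sign_split_equals_kmeans(self):
        rng = np.random.default_rng(3)
        rows = np.repeat([0, 1], [10, 10])
        cols = np.repeat([0, 1], [8, 7])
        means = np.array([[3.0, 0.3], [0.3, 3.0]])
        X = means[np.ix_(rows, cols)] + rng.normal(0, 0.1, (20, 15))
        X -= X.min()
        m = spectral_cocluster(X, k=2, seed=0)
        sign_split = (m.Z[:, 0] > 0).astype(int)
        labels = np.concatenate([m.sample_labels, m.gene_labels])
        assert adjusted_rand_score(sign_split, labels) == 1.0

    def test_size_bound_refusal(self):
        X = np.random.default_rng(0).random((250, 200)) + 0.1
        with pytest.raises(ValidationError, match="oracle limited"):
            laplacian_cocluster_oracle(X, k=2)


class TestReorderCheckerboard:
    def test_identity_when_contiguous(self):
        X, rows, cols = _blockdiag()
        m = spectral_cocluster(X, k=3, seed=0)
        # relabel model clusters so labels are already contiguous ascending
        m.sample_labels = rows
        m.gene_labels = cols
        permuted, (ri, ci) = reorder_checkerboard(X, m)
        assert (ri == np.arange(X.shape[0])).all()
        assert (ci == np.arange(X.shape[1])).all()
        assert (permuted == X).all()

    def test_round_trip_inverse(self):
        X, truth = _planted()
        m = spectral_cocluster(X, k=3, seed=0)
        permuted, (ri, ci) = reorder_checkerboard(X, m)
        restored = np.empty_like(X)
        restored[np.ix_(ri, ci)] = permuted
        assert (restored == X).all()

    def test_planted_within_block_variance_smaller(self):
        X, truth = _planted(noise=0.25)
        m = spectral_cocluster(X, k=3, seed=0)
        total_var = X.var()
        within = []
        for r in np.unique(m.sample_labels):
            for c in np.unique(m.gene_labels):
                blk = X[np.ix_(m.sample_labels == r, m.gene_labels == c)]
                if blk.size > 1:
                    within.append(blk.var())
        assert np.mean(within) < total_var  # between-block structure dominates

    def test_dimension_mismatch(self):
        X, _ = _planted()
        m = spectral_cocluster(X, k=3, seed=0)
        with pytest.raises(ValidationError, match="shape"):
            reorder_checkerboard(X[:-1], m)
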