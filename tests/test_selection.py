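import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from biclustsurv import SpecificityCriteria, select_specific_genes, welch_t
from biclustsurv.errors import DegenerateInputError, ValidationError
from biclustsurv.selection import _welch_t_rows, benjamini_hochberg

# frozen from the closed-form Welch computation:
# means 3, 4; variances 2.5; se = 1; t = -1; df = 8; p = 2*sf(1, 8)
WELCH_ORACLE_P = 0.34659350708733416


class TestWelchT:
    def test_textbook_oracle(self):
        t, p = welch_t([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert t == pytest.approx(-1.0, abs=1e-12)
        assert p == pytest.approx(WELCH_ORACLE_P, abs=1e-10)

    def test_identical_constant_groups(self):
        t, p = welch_t([5, 5, 5], [5, 5, 5])
        assert t == 0.0 and p == 1.0

    def test_constant_unequal_groups(self):
        t, p = welch_t([5, 5, 5], [7, 7, 7])
        assert t == -np.inf and p == 0.0

    def test_swap_symmetry(self):
        a, b = [1.0, 2.5, 3.1, 4.0], [2.2, 3.3, 4.1, 5.7, 6.0]
        t1, p1 = welch_t(a, b)
        t2, p2 = welch_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_sign_matches_mean_difference(self):
        t, _ = welch_t([10, 11, 12], [1, 2, 3])
        assert t > 0

    def test_small_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            welch_t([1], [1, 2, 3])

    def test_pooled_matches_scipy(self):
        a = np.array([1.0, 2, 3, 4, 5.5])
        b = np.array([2.0, 3, 4, 6])
        t, p = welch_t(a, b, pooled=True)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_vectorized_matches_scalar(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(6, 5))
        B = rng.normal(size=(6, 7))
        A[0] = 1.0  # constant row in one group
        ts, ps = _welch_t_rows(A, B)
        for i in range(6):
            t, p = welch_t(A[i], B[i])
            assert ts[i] == pytest.approx(t, rel=1e-12)
            assert ps[i] == pytest.approx(p, rel=1e-12)


def _naive_select(expr, labels, target, crit):
    """Independent double-loop re-evaluation of the printed criteria."""
    chosen = []
    others = [t for t in pd.unique(labels) if t != target]
    for gene in expr.index:
        row = expr.loc[gene]
        tvals = row[(labels == target).to_numpy()].to_numpy()
        ok = True
        for o in others:
            ovals = row[(labels == o).to_numpy()].to_numpy()
            fold = 2.0 ** (tvals.mean() - ovals.mean())
            _, p = welch_t(tvals, ovals)
            if not (fold > crit.min_fold and p < crit.max_p):
                ok = False
                break
        if ok:
            chosen.append(gene)
    return set(chosen)


def _random_matrix(rng, n_genes=60, n_per=8, types=("A", "B", "C")):
    cols = [f"s{i}" for i in range(n_per * len(types))]
    labels = pd.Series(np.repeat(types, n_per), index=cols)
    base = rng.normal(6, 1, size=(n_genes, 1))
    vals = base + rng.normal(0, 1.2, size=(n_genes, len(cols)))
    expr = pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)], columns=cols)
    return expr, labels


class TestSelectSpecificGenes:
    def _single_gene(self, means, sd=0.2, n=30, seed=0):
        rng = np.random.default_rng(seed)
        types = [f"t{i}" for i in range(len(means))]
        cols = [f"s{i}" for i in range(n * len(means))]
        labels = pd.Series(np.repeat(types, n), index=cols)
        vals = np.concatenate([rng.normal(m, sd, n) for m in means])[None, :]
        return pd.DataFrame(vals, index=["g"], columns=cols), labels

    def test_clearly_specific_gene_selected(self):
        expr, labels = self._single_gene([8, 6, 6, 6])
        panel = select_specific_genes(expr, labels, "t0")
        assert panel.genes == ["g"]

    def test_equal_gene_not_selected(self):
        expr, labels = self._single_gene([6, 6, 6, 6])
        panel = select_specific_genes(expr, labels, "t0")
        assert panel.genes == []

    def test_all_quantifier_one_equal_type_blocks(self):
        # 4-fold above two types but equal to the third -> excluded
        expr, labels = self._single_gene([8, 6, 6, 8])
        panel = select_specific_genes(expr, labels, "t0")
        assert panel.genes == []

    def test_missing_values_excluded_with_count(self):
        expr, labels = self._single_gene([8, 6, 6, 6])
        expr.loc["g2"] = expr.loc["g"]
        expr.iloc[1, 3] = np.nan
        panel = select_specific_genes(expr, labels, "t0")
        assert panel.n_excluded_missing == 1
        assert panel.genes == ["g"]

    def test_absent_target_errors(self):
        expr, labels = self._single_gene([8, 6])
        with pytest.raises(ValidationError, match="absent"):
            select_specific_genes(expr, labels, "nope")

    def test_matches_naive_reevaluation(self, rng):
        crit = SpecificityCriteria(min_fold=1.3, max_p=0.05)
        for _ in range(5):
            expr, labels = _random_matrix(rng)
            panel = select_specific_genes(expr, labels, "A", criteria=crit)
            assert panel.as_set() == _naive_select(expr, labels, "A", crit)

    def test_monotone_in_criteria(self, rng):
        expr, labels = _random_matrix(rng)
        loose = select_specific_genes(
            expr, labels, "A", SpecificityCriteria(min_fold=1.2, max_p=0.2)).as_set()
        tighter_fold = select_specific_genes(
            expr, labels, "A", SpecificityCriteria(min_fold=1.6, max_p=0.2)).as_set()
        tighter_p = select_specific_genes(
            expr, labels, "A", SpecificityCriteria(min_fold=1.2, max_p=0.01)).as_set()
        assert tighter_fold <= loose
        assert tighter_p <= loose

    def test_order_descending_min_fold(self, pan_cancer):
        _, expr, labels, _ = pan_cancer
        panel = select_specific_genes(expr, labels, "type_0")
        folds = panel.stats.loc[panel.genes, "min_fold"].to_numpy()
        assert (np.diff(folds) <= 1e-12).all()

    def test_gene_list_restricts(self, pan_cancer):
        _, expr, labels, truth = pan_cancer
        keep = truth.specific_genes[:10]
        panel = select_specific_genes(expr, labels, "type_0", gene_list=keep)
        assert panel.as_set() <= set(keep)

    def test_sensitivity_and_fpr_over_seeds(self):
        from biclustsurv import PanCancerSpec, simulate_pan_cancer

        sens, fp, n_neg = [], 0, 0
        for seed in range(20):
            spec = PanCancerSpec(seed=seed)
            expr, labels, truth = simulate_pan_cancer(spec)
            got = select_specific_genes(expr, labels, "type_0").as_set()
            planted = set(truth.specific_genes)
            sens.append(len(got & planted) / len(planted))
            fp += len(got - planted)
            n_neg += spec.n_genes - spec.n_specific
        assert np.mean(sens) >= 0.95
        assert fp / n_neg <= 0.001

    def test_anova_reported_not_gating(self, rng):
        expr, labels = _random_matrix(rng, n_genes=20)
        panel = select_specific_genes(expr, labels, "A",
                                      SpecificityCriteria(min_fold=1.1, max_p=0.5))
        assert "anova_p" in panel.stats.columns
        assert panel.stats["anova_p"].between(0, 1).all()


class TestBenjaminiHochberg:
    def test_matches_statsmodels_convention(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205])
        q = benjamini_hochberg(p)
        # classic worked example: q_i = min over j>=i of p_j * n / j
        n = len(p)
        expected = [min((p[j] * n / (j + 1)) for j in range(i, n)) for i in range(n)]
        assert q == pytest.approx(expected)

    def test_bounded_and_monotone_in_rank(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        q = benjamini_hochberg(p)
        assert ((0 <= q) & (q <= 1)).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
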