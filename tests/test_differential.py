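import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from concordia import ValidationError, bh_adjust, call_degs, welch_contrast
from concordia.io import ExpressionMatrix


def _matrix(case: np.ndarray, control: np.ndarray, genes=None) -> ExpressionMatrix:
    n_case, n_ctrl = case.shape[1], control.shape[1]
    samples = [f"c{i}" for i in range(n_case)] + [f"u{i}" for i in range(n_ctrl)]
    genes = genes or [f"g{i}" for i in range(case.shape[0])]
    df = pd.DataFrame(np.hstack([case, control]), index=genes, columns=samples)
    groups = pd.Series(["case"] * n_case + ["control"] * n_ctrl, index=samples)
    return ExpressionMatrix(values=df, groups=groups)


def welch_oracle(x, y):
    """From-scratch Welch t and two-sided p for one gene."""
    n1, n2 = len(x), len(y)
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (np.mean(x) - np.mean(y)) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, 2 * stats.t.sf(abs(t), df)


def bh_oracle(p):
    """Quadratic-time direct evaluation of q_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i in range(m):
        q[order[rank_i]] = min(
            min(p[order[j]] * m / (j + 1) for j in range(rank_i, m)), 1.0
        )
    return q


class TestWelchContrast:
    def test_matches_hand_welch_on_3v3(self):
        case = np.array([[2.3, 1.9, 2.8], [5.0, 5.5, 4.5]])
        ctrl = np.array([[1.1, 0.9, 1.6], [5.2, 5.1, 4.7]])
        out = welch_contrast(_matrix(case, ctrl))
        for i in range(2):
            t, p = welch_oracle(case[i], ctrl[i])
            assert out["t"].iloc[i] == pytest.approx(t, rel=1e-12)
            assert out["p"].iloc[i] == pytest.approx(p, rel=1e-12)
            assert out["log2fc"].iloc[i] == pytest.approx(
                case[i].mean() - ctrl[i].mean(), rel=1e-12
            )

    def test_equal_means_give_zero_lfc_and_p_one(self):
        case = np.array([[1.0, 2.0, 3.0]])
        ctrl = np.array([[3.0, 2.0, 1.0]])
        out = welch_contrast(_matrix(case, ctrl))
        assert out["log2fc"].iloc[0] == 0.0
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_null_p_values_are_uniform(self, rng):
        case = rng.normal(0, 1, size=(1000, 5))
        ctrl = rng.normal(0, 1, size=(1000, 5))
        out = welch_contrast(_matrix(case, ctrl))
        assert stats.kstest(out["p"], "uniform").pvalue > 0.01

    def test_label_swap_flips_lfc_and_preserves_p(self, rng):
        case = rng.normal(0, 1, size=(50, 4))
        ctrl = rng.normal(0.5, 1.5, size=(50, 6))
        fwd = welch_contrast(_matrix(case, ctrl))
        rev = welch_contrast(_matrix(ctrl, case))
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], rtol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], rtol=1e-12)

    def test_zero_variance_degenerate_genes(self):
        case = np.array([[1.0, 1.0], [2.0, 2.0]])
        ctrl = np.array([[1.0, 1.0], [1.0, 1.0]])
        out = welch_contrast(_matrix(case, ctrl))
        assert out["p"].iloc[0] == 1.0 and out["t"].iloc[0] == 0.0
        assert out["p"].iloc[1] < 1e-300 and out["t"].iloc[1] == np.inf

    def test_single_sample_group_is_error(self):
        with pytest.raises(ValidationError, match="2 samples"):
            welch_contrast(_matrix(np.ones((3, 1)), np.ones((3, 4))))

    def test_pooled_variance_switch(self):
        case = np.array([[2.3, 1.9, 2.8]])
        ctrl = np.array([[1.1, 0.9, 1.6, 1.3]])
        out = welch_contrast(_matrix(case, ctrl), equal_var=True)
        t, p = stats.ttest_ind(case[0], ctrl[0], equal_var=True)
        assert out["t"].iloc[0] == pytest.approx(t, rel=1e-12)
        assert out["p"].iloc[0] == pytest.approx(p, rel=1e-12)


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.05, 1.0]), [0.015, 0.075, 1.0], rtol=1e-12
        )

    def test_constant_vector_is_fixed_point(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 7), [0.2] * 7, rtol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.2], [-0.1], [np.nan]])
    def test_out_of_range_p_rejected(self, bad):
        with pytest.raises(ValidationError):
            bh_adjust(bad)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0, exclude_min=False),
                 min_size=1, max_size=60)
    )
    def test_matches_quadratic_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), rtol=1e-10)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(1e-6, 1.0, size=100)
        q = bh_adjust(p)
        perm = rng.permutation(100)
        np.testing.assert_allclose(bh_adjust(p[perm]), q[perm], rtol=1e-12)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(1e-8, 1.0, size=500)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], rtol=1e-10
        )


class TestCallDegs:
    @staticmethod
    def _contrast(log2fc, q):
        genes = [f"g{i}" for i in range(len(log2fc))]
        return pd.DataFrame(
            {"log2fc": log2fc, "t": 0.0, "p": q, "q": q},
            index=pd.Index(genes, name="gene"),
        )

    def test_boundary_genes_excluded_by_strict_inequalities(self):
        # exactly FC=2 (log2fc=1) at tiny q; exactly FDR=0.05 at big fold
        contrast = self._contrast([1.0, 3.0, -3.0], [0.01, 0.05, 0.05])
        degs = call_degs(contrast, fc_threshold=2, fdr_threshold=0.05)
        assert degs.up == set() and degs.down == set()

    def test_calls_both_directions(self):
        contrast = self._contrast([1.5, -1.5, 0.5], [0.01, 0.01, 0.01])
        degs = call_degs(contrast)
        assert degs.up == {"g0"} and degs.down == {"g1"}
        assert degs.universe == {"g0", "g1", "g2"}

    def test_no_gene_passes_gives_empty_sets(self):
        degs = call_degs(self._contrast([3.0, -3.0], [0.9, 0.9]))
        assert degs.up == set() == degs.down

    def test_tightening_thresholds_is_monotone(self, rng):
        contrast = self._contrast(rng.normal(0, 2, 300),
                                  rng.uniform(1e-4, 1, 300))
        loose = call_degs(contrast, 1.5, 0.1)
        for fc, fdr in [(2.0, 0.1), (1.5, 0.05), (4.0, 0.01)]:
            tight = call_degs(contrast, fc, fdr)
            assert tight.up <= loose.up and tight.down <= loose.down

    def test_invalid_threshold(self):
        with pytest.raises(ValidationError):
            call_degs(self._contrast([1.0], [0.5]), fc_threshold=0)
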