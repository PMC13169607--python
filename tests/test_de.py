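"""Differential-expression machinery: CPM, filtering, TMM, moderated t, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirax.containers import MiraxError
from mirax.de import (bh_adjust, cpm, direction_sets, filter_low_expression,
                      moderated_t, tmm_factors)

from conftest import make_expr


class TestCPM:
    def test_linear_cpm_arithmetic(self):
        em = make_expr([[5, 2], [5, 2], [0, 6]])
        out = cpm(em)
        np.testing.assert_allclose(out.values.iloc[:, 0], [5e5, 5e5, 0.0])

    def test_all_zero_feature_stays_zero(self):
        em = make_expr([[1, 1], [0, 0], [3, 7]])
        assert (cpm(em).values.iloc[1] == 0).all()

    def test_log2_cpm_closed_form(self):
        # one count of zero at library size 1e6 with prior 0.5
        vals = np.zeros((2, 1))
        vals[1, 0] = 1e6
        em = make_expr(vals)
        out = cpm(em, prior_count=0.5, log=True)
        expected = np.log2(0.5 / (1e6 + 1.0) * 1e6)
        assert out.values.iloc[0, 0] == pytest.approx(expected, abs=1e-12)
        assert out.values.iloc[0, 0] == pytest.approx(-1.0, abs=1e-5)

    def test_zero_library_size_names_sample(self):
        em = make_expr([[1, 0], [1, 0]])
        with pytest.raises(MiraxError, match="s1"):
            cpm(em)


class TestFilter:
    def test_retained_and_removed(self):
        # s libsizes 100 -> CPM = count * 1e4
        em = make_expr([[10, 10, 10], [0, 0, 0], [90, 90, 90]],
                       groups=["tumor", "tumor", "normal"])
        out = filter_low_expression(em, cpm_threshold=1.0, min_samples=1)
        assert list(out.feature_ids) == ["g0", "g2"]

    def test_min_samples_enumerated_toy(self):
        # 3 features; exactly one has CPM >= threshold in >= 2 samples
        em = make_expr(
            [[100, 100, 0], [100, 0, 0], [0, 0, 100]],
            groups=["tumor", "tumor", "normal"],
        )
        out = filter_low_expression(em, cpm_threshold=1e5, min_samples=2)
        assert list(out.feature_ids) == ["g0"]

    def test_min_samples_exceeds_n(self):
        em = make_expr([[1, 1]])
        with pytest.raises(MiraxError):
            filter_low_expression(em, min_samples=5)


class TestTMM:
    def test_identical_columns_unit_factors(self, rng):
        col = rng.integers(1, 500, 200)
        em = make_expr(np.tile(col[:, None], (1, 4)))
        np.testing.assert_allclose(tmm_factors(em).to_numpy(), 1.0, atol=1e-12)

    def test_pure_depth_change_is_ignored(self, rng):
        col = rng.integers(1, 500, 300)
        mat = np.tile(col[:, None], (1, 3)).astype(float)
        mat[:, 2] *= 2.0  # doubled depth, same composition
        em = make_expr(mat)
        np.testing.assert_allclose(tmm_factors(em).to_numpy(), 1.0, atol=1e-9)

    def test_two_sample_toy_matches_brute_force(self, rng):
        # independent re-implementation of the trimmed weighted mean on a toy
        n = 400
        base = rng.integers(20, 2000, n).astype(float)
        other = base.copy()
        other[:40] *= 6.0  # asymmetric DE block
        em = make_expr(np.column_stack([base, other]))
        f = tmm_factors(em).to_numpy()

        lib1, lib2 = base.sum(), other.sum()
        p1, p2 = other / lib2, base / lib1  # obs = sample 2 against ref = sample 1? both orders checked
        # determine which sample was the reference via upper quartiles
        uq = [np.quantile(base / lib1, 0.75), np.quantile(other / lib2, 0.75)]
        ref_idx = int(np.argmin(np.abs(np.array(uq) - np.mean(uq))))
        obs_idx = 1 - ref_idx
        cols = [base, other]
        libs = [lib1, lib2]
        obs, ref = cols[obs_idx], cols[ref_idx]
        lo, lr = libs[obs_idx], libs[ref_idx]
        m = np.log2((obs / lo) / (ref / lr))
        a = 0.5 * np.log2((obs / lo) * (ref / lr))
        w = (lo - obs) / (lo * obs) + (lr - ref) / (lr * ref)
        rm, ra = stats.rankdata(m), stats.rankdata(a)
        nn = len(m)
        keep = ((rm >= np.floor(nn * 0.3) + 1) & (rm <= nn - np.floor(nn * 0.3))
                & (ra >= np.floor(nn * 0.05) + 1) & (ra <= nn - np.floor(nn * 0.05)))
        expected_obs = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
        expected = np.array([1.0, 1.0])
        expected[obs_idx] = expected_obs
        expected /= np.exp(np.mean(np.log(expected)))
        np.testing.assert_allclose(f, expected, rtol=1e-10)

    def test_all_zero_sample_errors(self):
        em = make_expr([[1, 0], [2, 0]])
        with pytest.raises(MiraxError):
            tmm_factors(em)


class TestModeratedT:
    @staticmethod
    def _toy(rng, n_genes=300, n1=8, n2=8, shift=0.0):
        x = rng.normal(0, 1, size=(n_genes, n1 + n2))
        x[: n_genes // 10, :n1] += shift
        return make_expr(x, groups=["tumor"] * n1 + ["normal"] * n2, scale="log2")

    def test_no_shrinkage_equals_ordinary_t(self, rng):
        em = self._toy(rng, shift=1.0)
        res = moderated_t(em, d0=0.0)
        mat = em.values.to_numpy()
        t_ref = stats.ttest_ind(mat[:, :8], mat[:, 8:], axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["t"].to_numpy(), t_ref.statistic, atol=1e-10)
        np.testing.assert_allclose(res.table["p"].to_numpy(), t_ref.pvalue, atol=1e-10)

    def test_full_shrinkage_uses_prior_variance(self, rng):
        em = self._toy(rng)
        s0 = 2.0
        res = moderated_t(em, d0=np.inf, s0_sq=s0)
        mat = em.values.to_numpy()
        diff = mat[:, :8].mean(axis=1) - mat[:, 8:].mean(axis=1)
        t_expected = diff / (np.sqrt(s0) * np.sqrt(1 / 8 + 1 / 8))
        np.testing.assert_allclose(res.table["t"].to_numpy(), t_expected, atol=1e-10)

    def test_shift_invariance_per_gene(self, rng):
        em = self._toy(rng)
        shifted = make_expr(em.values.to_numpy() + 7.5,
                            groups=list(em.sample_meta["group"]), scale="log2")
        a = moderated_t(em).table
        b = moderated_t(shifted).table
        np.testing.assert_allclose(a["t"], b["t"], atol=1e-8)

    def test_paired_equals_one_sample_t_on_differences(self, rng):
        n_pairs, n_genes = 10, 200
        diffs = rng.normal(0.3, 1.0, size=(n_genes, n_pairs))
        base = rng.normal(5, 1, size=(n_genes, n_pairs))
        vals = np.concatenate([base + diffs, base], axis=1)
        em = make_expr(vals, groups=["tumor"] * n_pairs + ["normal"] * n_pairs,
                       patients=[f"p{i}" for i in range(n_pairs)] * 2, scale="log2")
        res = moderated_t(em, paired=True, d0=0.0)
        t_ref = stats.ttest_1samp(diffs, 0.0, axis=1)
        np.testing.assert_allclose(res.table["t"].to_numpy(), t_ref.statistic, atol=1e-10)

    def test_constant_gene_excluded_with_warning(self, rng):
        em = self._toy(rng, n_genes=50)
        vals = em.values.to_numpy().copy()
        vals[0] = 3.14
        em2 = make_expr(vals, groups=list(em.sample_meta["group"]), scale="log2")
        with pytest.warns(UserWarning, match="constant"):
            res = moderated_t(em2)
        assert "g0" not in res.table.index

    def test_too_few_samples_errors(self, rng):
        em = make_expr(rng.normal(size=(10, 3)), groups=["tumor", "tumor", "normal"],
                       scale="log2")
        with pytest.raises(MiraxError):
            moderated_t(em)


class TestBH:
    def test_hand_worked_example(self):
        q = bh_adjust(np.array([0.01, 0.03, 0.04, 0.05]))
        np.testing.assert_allclose(q, [0.04, 0.05, 0.05, 0.05], atol=1e-12)

    def test_all_equal_and_singleton(self):
        np.testing.assert_allclose(bh_adjust(np.full(5, 0.2)), 0.2)
        np.testing.assert_allclose(bh_adjust(np.array([0.037])), [0.037])

    def test_out_of_range_errors(self):
        with pytest.raises(MiraxError):
            bh_adjust(np.array([0.5, 1.2]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_bh_dominates_p_and_is_monotone(self, ps):
        p = np.array(ps)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0 + 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestDirectionSets:
    def test_threshold_and_fdr_gates(self):
        table = pd.DataFrame(
            {"log2fc": [1.2, 0.9, -0.6, -1.5], "q": [0.04, 0.04, 0.01, 0.2]},
            index=["a", "b", "c", "d"],
        )
        up, down = direction_sets(table, lfc_threshold=1.0, fdr=0.05)
        assert up == {"a"} and down == set()

    def test_mirna_threshold_log2_1p5(self):
        table = pd.DataFrame({"log2fc": [-0.6], "q": [0.01]}, index=["m"])
        up, down = direction_sets(table, lfc_threshold=np.log2(1.5), fdr=0.05)
        assert down == {"m"} and up == set()

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_up_down_disjoint(self, seed):
        r = np.random.default_rng(seed)
        n = 50
        table = pd.DataFrame({"log2fc": r.normal(0, 2, n), "q": r.uniform(0, 1, n)},
                             index=[f"g{i}" for i in range(n)])
        up, down = direction_sets(table, lfc_threshold=r.uniform(0, 2), fdr=0.1)
        assert not (up & down)
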