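"""Elastic-net Cox, concordance, KM/log-rank, screen and locked validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from mirax.containers import MiraxError
from mirax.survival import (AxisFeatureMatrix, PenalizedCoxModel,
                            assemble_axis_matrix, cluster_axes, cox_loglik,
                            cox_univariable, coxnet_fit, coxnet_path,
                            default_lambda_path, harrell_cindex, km_estimator,
                            lambda_max, locked_external_validate, logrank_test,
                            median_split, nested_cv, final_fit, survival_screen)

from conftest import toy_survival


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def brute_force_cindex(risk, time, event):
    """Literal pair-enumeration oracle (kept deliberately naive)."""
    conc = ties = comp = 0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i] == 1:
                comp += 1
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] == risk[j]:
                    ties += 1
    return (conc + 0.5 * ties) / comp if comp else float("nan")


class TestCIndex:
    def test_perfect_order_and_inversion(self):
        t = np.array([1.0, 2.0, 3.0]); e = np.ones(3, int)
        assert harrell_cindex(np.array([3, 2, 1]), t, e) == 1.0
        assert harrell_cindex(np.array([1, 2, 3]), t, e) == 0.0

    def test_tied_risk_hand_enumeration(self):
        # pairs: (0,1) tied risks, (0,2) concordant, (1,2) concordant -> 2.5/3
        t = np.array([1.0, 2.0, 3.0]); e = np.ones(3, int)
        c = harrell_cindex(np.array([2.0, 2.0, 1.0]), t, e)
        assert c == pytest.approx(2.5 / 3)

    def test_matches_brute_force_on_random_data(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 60))
            t = rng.choice(np.arange(1, 15, dtype=float), n)  # ties in time
            e = rng.integers(0, 2, n)
            r = rng.choice(np.arange(5, dtype=float), n)  # ties in risk
            if e.sum() == 0:
                e[0] = 1
            assert harrell_cindex(r, t, e) == pytest.approx(
                brute_force_cindex(r, t, e), abs=1e-12)

    def test_no_comparable_pairs_is_nan(self):
        c = harrell_cindex(np.array([1.0, 2.0]), np.array([5.0, 5.0]),
                           np.array([1, 1]))
        assert np.isnan(c)


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

class TestKM:
    def test_product_limit_by_hand(self):
        surv = toy_survival([1.0, 2.0, 3.0], [1, 0, 1])
        km = km_estimator(surv)["all"]
        s = km["survival"]
        assert s.loc[1.0] == pytest.approx(2 / 3)
        assert s.loc[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        surv = toy_survival([3.0, 6.0, 9.0], [0, 0, 0])
        km = km_estimator(surv)["all"]
        assert (km["survival"] == 1.0).all()

    def test_nonincreasing_and_truncated(self, rng):
        surv = toy_survival(rng.exponential(60, 50).round(1) + 0.1,
                            rng.integers(0, 2, 50))
        km = km_estimator(surv, t_max=120.0)["all"]
        assert (np.diff(km["survival"]) <= 1e-12).all()
        assert km.index.max() <= 120.0
        assert km.attrs["at_risk"][0] == 50


class TestLogrank:
    def test_identical_groups_null(self):
        surv = toy_survival([1, 2, 3, 1, 2, 3], [1, 0, 1, 1, 0, 1])
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=surv.index)
        chi2, p = logrank_test(surv, labels)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_label_swap_symmetric(self, rng):
        surv = toy_survival(rng.exponential(10, 20).round(2) + 0.1,
                            rng.integers(0, 2, 20))
        lab = pd.Series(rng.choice(["A", "B"], 20), index=surv.index)
        swapped = lab.map({"A": "B", "B": "A"})
        assert logrank_test(surv, lab)[0] == pytest.approx(logrank_test(surv, swapped)[0])

    def test_no_events_stat_zero(self):
        surv = toy_survival([1, 2, 3, 4], [0, 0, 0, 0])
        labels = pd.Series(["A", "A", "B", "B"], index=surv.index)
        assert logrank_test(surv, labels) == (0.0, 1.0)


# ---------------------------------------------------------------------------
# Univariable Cox
# ---------------------------------------------------------------------------

class TestUnivariableCox:
    def test_reparameterization_scaling(self, rng):
        n = 80
        x = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        t = rng.exponential(1 / np.exp(0.5 * x.to_numpy()))
        surv = toy_survival(t, np.ones(n, int), index=list(x.index))
        a = cox_univariable(x, surv, dichotomize="none")
        b = cox_univariable(10 * x, surv, dichotomize="none")
        assert b.beta == pytest.approx(a.beta / 10, rel=1e-4)
        assert b.wald_p == pytest.approx(a.wald_p, rel=1e-4)

    def test_direction_of_adverse_covariate(self, rng):
        n = 200
        x = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        t = np.maximum(rng.exponential(1 / np.exp(1.0 * x.to_numpy())), 1e-3)
        surv = toy_survival(t, np.ones(n, int), index=list(x.index))
        res = cox_univariable(x, surv, dichotomize="median")
        assert res.hr > 1 and res.ci_low > 1

    def test_median_tie_rule_low(self):
        vals = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"))
        labels = median_split(vals)
        assert list(labels) == ["Low", "Low", "Low", "High"]

    def test_constant_covariate_rejected(self):
        surv = toy_survival([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(MiraxError):
            cox_univariable(pd.Series([1.0] * 4, index=surv.index), surv)


# ---------------------------------------------------------------------------
# Elastic-net Cox
# ---------------------------------------------------------------------------

def _sim_cox(rng, n=120, p=5, beta=None, censor=0.3):
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    beta = np.zeros(p) if beta is None else beta
    t = rng.exponential(1 / np.exp(X @ beta))
    c = rng.exponential(t.mean() / max(censor, 1e-9)) if censor else np.full(n, np.inf)
    return X, np.minimum(t, c) + 1e-6, (t <= c).astype(int)


class TestCoxnet:
    def test_lambda_max_gives_null_solution(self, rng):
        X, t, e = _sim_cox(rng, beta=np.array([0.8, -0.5, 0.0, 0.0, 0.3]))
        lmax = lambda_max(X, t, e, alpha=1.0)
        beta = coxnet_fit(X, t, e, alpha=1.0, lam=lmax * 1.0001)
        assert np.all(beta == 0.0)
        # slightly below lambda_max something enters
        beta2 = coxnet_fit(X, t, e, alpha=1.0, lam=lmax * 0.8)
        assert np.any(beta2 != 0.0)

    def test_unpenalized_matches_independent_optimizer(self, rng):
        # independent oracle: BFGS on a literal Breslow partial likelihood
        X, t, e = _sim_cox(rng, n=60, p=3, beta=np.array([0.7, -0.4, 0.2]),
                           censor=0.0)

        def neg_pl(b):
            eta = X @ b
            ll = 0.0
            for i in np.flatnonzero(e == 1):
                ll += eta[i] - np.log(np.exp(eta[t >= t[i]]).sum())
            return -ll

        res = optimize.minimize(neg_pl, np.zeros(3), method="BFGS",
                                options={"gtol": 1e-10})
        beta = coxnet_fit(X, t, e, alpha=0.5, lam=0.0, tol=1e-12)
        np.testing.assert_allclose(beta, res.x, atol=1e-6)

    def test_ridge_spreads_lasso_concentrates_on_duplicates(self, rng):
        X, t, e = _sim_cox(rng, n=150, p=2, beta=np.array([0.8, 0.0]), censor=0.0)
        X[:, 1] = X[:, 0]  # exact duplicate feature
        lam = 0.1
        b_ridge = coxnet_fit(X, t, e, alpha=0.0, lam=lam)
        b_lasso = coxnet_fit(X, t, e, alpha=1.0, lam=lam)
        assert abs(b_ridge[0] - b_ridge[1]) < 1e-6  # ridge splits evenly
        assert abs(b_lasso[0] - b_lasso[1]) > abs(b_ridge[0] - b_ridge[1])

    def test_l1_norm_nonincreasing_along_path(self, rng):
        X, t, e = _sim_cox(rng, beta=np.array([0.8, -0.5, 0.3, 0.0, 0.0]))
        lams = default_lambda_path(X, t, e, alpha=1.0, n_lambda=30)
        betas = coxnet_path(X, t, e, alpha=1.0, lambdas=lams)
        l1 = np.abs(betas).sum(axis=1)
        assert (np.diff(l1) >= -1e-7).all()  # decreasing lambda -> growing norm

    def test_kkt_conditions_at_solution(self, rng):
        X, t, e = _sim_cox(rng, beta=np.array([0.8, -0.5, 0.0, 0.0, 0.3]))
        n = len(t)
        alpha, lam = 0.7, 0.05
        beta = coxnet_fit(X, t, e, alpha=alpha, lam=lam, tol=1e-12)
        # numerical gradient of the unpenalized part of the objective
        def f(b):
            return -cox_loglik(b, X, t, e) / n
        g = optimize.approx_fprime(beta, f, 1e-7)
        for j in range(len(beta)):
            gj = g[j] + lam * (1 - alpha) * beta[j]
            if beta[j] != 0:
                assert gj + lam * alpha * np.sign(beta[j]) == pytest.approx(0.0, abs=1e-4)
            else:
                assert abs(gj) <= lam * alpha + 1e-4

    def test_no_events_errors(self, rng):
        X, t, _ = _sim_cox(rng, n=20, p=2)
        with pytest.raises(MiraxError):
            coxnet_fit(X, t, np.zeros(20, int), alpha=0.5, lam=0.1)


# ---------------------------------------------------------------------------
# Feature assembly / clustering
# ---------------------------------------------------------------------------

class TestAssembly:
    @staticmethod
    def _inputs(rng, n=30, missing_stage=0):
        samples = [f"s{i}" for i in range(n)]
        mirna = pd.DataFrame(rng.normal(size=(4, n)),
                             index=[f"m{i}" for i in range(4)], columns=samples)
        acts = pd.DataFrame(rng.normal(size=(n, 4)), index=samples,
                            columns=[f"m{i}" for i in range(4)])
        stage = rng.choice([1.0, 2.0, 3.0], n)
        if missing_stage:
            stage[:missing_stage] = np.nan
        surv = toy_survival(rng.exponential(20, n) + 0.1, rng.integers(0, 2, n),
                            index=samples, age=rng.normal(60, 10, n),
                            sex=rng.integers(0, 2, n), stage=stage)
        return mirna, acts, surv

    def test_incomplete_cases_dropped(self, rng):
        mirna, acts, surv = self._inputs(rng, n=30, missing_stage=3)
        feats, surv_cc = assemble_axis_matrix(mirna, acts, surv)
        assert len(feats.sample_ids) == 27 and len(surv_cc) == 27

    def test_no_missingness_keeps_all(self, rng):
        mirna, acts, surv = self._inputs(rng, n=25)
        feats, _ = assemble_axis_matrix(mirna, acts, surv)
        assert len(feats.sample_ids) == 25
        assert feats.values.shape[1] == 8

    def test_standardized_columns(self, rng):
        mirna, acts, surv = self._inputs(rng)
        feats, _ = assemble_axis_matrix(mirna, acts, surv)
        z = feats.standardized()
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_empty_intersection_errors(self, rng):
        mirna, acts, surv = self._inputs(rng)
        surv2 = surv.copy(); surv2.index = [f"x{i}" for i in range(len(surv2))]
        with pytest.raises(MiraxError):
            assemble_axis_matrix(mirna, acts, surv2)


class TestCluster:
    def test_separated_blobs_high_silhouette(self, rng):
        a = rng.normal(0, 0.3, size=(40, 4)) + 4
        b = rng.normal(0, 0.3, size=(40, 4)) - 4
        feats = AxisFeatureMatrix.from_values(
            pd.DataFrame(np.vstack([a, b]), columns=list("wxyz")))
        rep = cluster_axes(feats, seed=0)
        assert rep.silhouette[2] >= 0.7

    def test_single_blob_low_silhouette(self, rng):
        feats = AxisFeatureMatrix.from_values(
            pd.DataFrame(rng.normal(size=(80, 4)), columns=list("wxyz")))
        rep = cluster_axes(feats, seed=0)
        assert rep.silhouette[2] < 0.3

    def test_duplicate_rows_share_labels(self, rng):
        base = rng.normal(size=(20, 4))
        dup = np.vstack([base, base])
        feats = AxisFeatureMatrix.from_values(pd.DataFrame(dup, columns=list("wxyz")))
        rep = cluster_axes(feats, seed=0)
        for k, lab in rep.labels.items():
            np.testing.assert_array_equal(lab[:20], lab[20:])


# ---------------------------------------------------------------------------
# Nested CV
# ---------------------------------------------------------------------------

def _cv_inputs(rng, n=60, signal=0.0):
    samples = [f"s{i}" for i in range(n)]
    mol = pd.DataFrame(rng.normal(size=(n, 4)), index=samples,
                       columns=[f"f{i}" for i in range(4)])
    risk = signal * mol.iloc[:, 0].to_numpy()
    t = np.maximum(rng.exponential(20 / np.exp(risk)), 0.01)
    surv = toy_survival(t, (rng.random(n) < 0.75).astype(int), index=samples,
                        age=rng.normal(60, 10, n), sex=rng.integers(0, 2, n),
                        stage=rng.choice([1.0, 2.0, 3.0], n))
    return mol, surv


class TestNestedCV:
    def test_identical_seed_reproduces_folds_and_cindex(self, rng):
        mol, surv = _cv_inputs(rng, signal=0.8)
        kw = dict(specs=("axes",), alpha_grid=(0.5,), n_lambda=10, seed=3)
        a = nested_cv(mol, surv, **kw)
        b = nested_cv(mol, surv, **kw)
        pd.testing.assert_series_equal(a.fold_assignments, b.fold_assignments)
        assert a.fold_cindex == b.fold_cindex

    def test_folds_partition_samples(self, rng):
        mol, surv = _cv_inputs(rng)
        cv = nested_cv(mol, surv, specs=("axes",), alpha_grid=(0.5,), n_lambda=8, seed=1)
        assert sorted(cv.fold_assignments.index) == sorted(mol.index)
        assert set(cv.fold_assignments) == set(range(5))

    def test_training_fold_stats_differ_from_heldout(self, rng):
        # leakage guard: means computed on a training fold are not the
        # held-out fold means when the data carry fold-scale structure
        mol, surv = _cv_inputs(rng, n=50)
        cv = nested_cv(mol, surv, specs=("axes",), alpha_grid=(0.5,), n_lambda=8, seed=1)
        f = cv.fold_assignments
        tr_mean = mol.loc[f != 0].mean()
        te_mean = mol.loc[f == 0].mean()
        assert not np.allclose(tr_mean, te_mean)


# ---------------------------------------------------------------------------
# Locked validation
# ---------------------------------------------------------------------------

def _toy_model(rng, p=4):
    feats = [f"abund_m{i}" for i in range(p)]
    return PenalizedCoxModel(
        beta=pd.Series(rng.normal(size=p), index=feats),
        alpha=0.5, lam=0.1,
        means=pd.Series(rng.normal(size=p), index=feats),
        sds=pd.Series(rng.uniform(0.5, 2.0, p), index=feats),
    )


class TestLockedValidation:
    def test_self_application_reproduces_linear_predictor(self, rng):
        model = _toy_model(rng)
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=model.features,
                         index=[f"s{i}" for i in range(40)])
        lp1 = model.linear_predictor(X)
        lp2 = model.linear_predictor(X.copy())
        np.testing.assert_allclose(lp1, lp2, atol=1e-15)
        manual = ((X - model.means) / model.sds) @ model.beta
        np.testing.assert_allclose(lp1, manual, atol=1e-12)

    def test_constant_feature_shift_preserves_ranking_and_split(self, rng):
        model = _toy_model(rng)
        n = 60
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=model.features,
                         index=[f"s{i}" for i in range(n)])
        t = np.maximum(rng.exponential(20, n), 0.1)
        surv = toy_survival(t, (rng.random(n) < 0.7).astype(int), index=list(X.index))
        rep1 = locked_external_validate(model, X, surv, seed=5, n_boot=50)
        shifts = pd.Series([3.0, -2.0, 10.0, 0.5], index=model.features)
        rep2 = locked_external_validate(model, X + shifts, surv, seed=5, n_boot=50)
        assert rep1.cindex == pytest.approx(rep2.cindex, abs=1e-12)
        np.testing.assert_array_equal(np.argsort(rep1.risk.to_numpy()),
                                      np.argsort(rep2.risk.to_numpy()))
        pd.testing.assert_series_equal(rep1.labels, rep2.labels)

    def test_feature_subset_mode_and_missing_feature_error(self, rng):
        model = _toy_model(rng)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=model.features[:2],
                         index=[f"s{i}" for i in range(30)])
        with pytest.raises(MiraxError):
            model.linear_predictor(X, allow_subset=False)
        lp = model.linear_predictor(X, allow_subset=True)
        manual = ((X - model.means[model.features[:2]]) / model.sds[model.features[:2]]
                  ) @ model.beta[model.features[:2]]
        np.testing.assert_allclose(lp, manual, atol=1e-12)

    def test_zero_training_sd_errors(self, rng):
        model = _toy_model(rng)
        model.sds.iloc[0] = 0.0
        X = pd.DataFrame(rng.normal(size=(10, 4)), columns=model.features)
        with pytest.raises(MiraxError):
            model.linear_predictor(X)

    def test_model_json_round_trip(self, rng, tmp_path):
        import json
        model = _toy_model(rng)
        path = tmp_path / "model.json"
        path.write_text(json.dumps(model.to_dict()))
        back = PenalizedCoxModel.from_dict(json.loads(path.read_text()))
        pd.testing.assert_series_equal(model.beta, back.beta)
        assert back.alpha == model.alpha and back.lam == model.lam


# ---------------------------------------------------------------------------
# Survival screen
# ---------------------------------------------------------------------------

class TestScreen:
    def test_single_gene_q_equals_p(self, rng):
        n = 40
        genes = pd.DataFrame(rng.normal(size=(1, n)), index=["g"],
                             columns=[f"s{i}" for i in range(n)])
        surv = toy_survival(rng.exponential(20, n) + 0.1, rng.integers(0, 2, n),
                            index=list(genes.columns))
        out = survival_screen(genes, surv)
        assert out[0].q == pytest.approx(out[0].logrank_p)

    def test_adverse_gene_flagged_risk(self, rng):
        n = 150
        x = rng.normal(size=n)
        t = np.maximum(rng.exponential(1 / np.exp(0.9 * x)), 1e-3)
        genes = pd.DataFrame(x[None, :], index=["g"],
                             columns=[f"s{i}" for i in range(n)])
        surv = toy_survival(t, np.ones(n, int), index=list(genes.columns))
        out = survival_screen(genes, surv, fdr=0.05)
        assert out[0].direction == "risk" and out[0].shortlist

    def test_constant_gene_skipped(self, rng):
        n = 20
        genes = pd.DataFrame(np.vstack([np.ones(n), rng.normal(size=n)]),
                             index=["flat", "g"], columns=[f"s{i}" for i in range(n)])
        surv = toy_survival(rng.exponential(20, n) + 0.1, rng.integers(0, 2, n),
                            index=list(genes.columns))
        out = survival_screen(genes, surv)
        assert out[0].status.startswith("skipped")
        assert out[1].status == "ok" if hasattr(out[1], "status") else True
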