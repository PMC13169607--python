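"""Axis-feature survival modeling: elastic-net Cox, CV, validation, screen.

The risk model is an elastic-net penalized Cox proportional-hazards
regression on the eight standardized axis features (four miRNA log-CPM
abundances and four target-set activities).  The fitted risk score of
sample *i* is the linear predictor

    RiskScore_i = sum_j beta_j * X_ij

on standardized features X_ij.  The penalized fit minimizes

    -(1/n) log PL(beta)  +  lambda * ( alpha*||beta||_1 + (1-alpha)/2*||beta||_2^2 )

with Breslow handling of tied event times, solved by iteratively
reweighted least squares with cyclic coordinate descent (soft
thresholding), warm-started along a decreasing lambda path.  Univariable
Cox fits (survival screen, High/Low validation contrasts) use lifelines
with Efron ties.

External transfer uses a *locked linear predictor*: frozen training
coefficients and frozen training standardization statistics are applied
to the validation cohort with no refitting; when only a subset of model
features is available (e.g. miRNA abundances alone), scoring restricts to
that subset explicitly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .containers import MiraxError, validate_survival_table

logger = logging.getLogger(__name__)

__all__ = [
    "AxisFeatureMatrix",
    "PenalizedCoxModel",
    "CVReport",
    "ScreenResult",
    "ClusterReport",
    "ValidationReport",
    "assemble_axis_matrix",
    "cluster_axes",
    "coxnet_fit",
    "lambda_max",
    "coxnet_path",
    "nested_cv",
    "final_fit",
    "harrell_cindex",
    "bootstrap_cindex_ci",
    "km_estimator",
    "logrank_test",
    "cox_univariable",
    "survival_screen",
    "locked_external_validate",
    "median_split",
]

CLINICAL_FEATURES = ["age", "sex", "stage"]
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 2))


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

@dataclass
class AxisFeatureMatrix:
    """Samples-by-features table of raw axis features with frozen
    standardization statistics (training means and SDs)."""

    values: pd.DataFrame  # samples x features, raw scale
    means: pd.Series
    sds: pd.Series

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    def standardized(self) -> pd.DataFrame:
        if (self.sds <= 0).any():
            bad = list(self.sds.index[self.sds <= 0])
            raise MiraxError(f"zero/negative training SD for feature(s): {bad}")
        return (self.values - self.means) / self.sds

    @classmethod
    def from_values(cls, values: pd.DataFrame) -> "AxisFeatureMatrix":
        return cls(values=values, means=values.mean(axis=0), sds=values.std(axis=0, ddof=1))


def assemble_axis_matrix(
    mirna_logcpm: pd.DataFrame,
    activities: pd.DataFrame,
    survival: pd.DataFrame,
) -> tuple[AxisFeatureMatrix, pd.DataFrame]:
    """Join miRNA abundances, target-set activities and survival on sample ID.

    ``mirna_logcpm`` is miRNA-by-sample (log-CPM), ``activities`` is
    sample-by-axis.  Only complete cases (no missing feature, time, event or
    clinical covariate) are retained; the drop tally is logged.  Returns the
    feature matrix (with standardization statistics computed on the retained
    samples) and the aligned survival table.
    """
    validate_survival_table(survival)
    abund = mirna_logcpm.T.add_prefix("abund_")
    act = activities.add_prefix("activity_")
    common = abund.index.intersection(act.index).intersection(survival.index)
    if len(common) == 0:
        raise MiraxError("no samples shared between features and survival table")
    feats = pd.concat([abund.loc[common], act.loc[common]], axis=1)
    surv = survival.loc[common]
    clin = [c for c in CLINICAL_FEATURES if c in surv.columns]
    complete = feats.notna().all(axis=1) & surv[["time_months", "event"] + clin].notna().all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        logger.info("assemble_axis_matrix: dropped %d incomplete case(s) of %d", n_drop, len(common))
    feats, surv = feats.loc[complete], surv.loc[complete]
    return AxisFeatureMatrix.from_values(feats), surv


# ---------------------------------------------------------------------------
# Unsupervised structure
# ---------------------------------------------------------------------------

@dataclass
class ClusterReport:
    pca_coords: pd.DataFrame  # samples x PC1/PC2
    variance_explained: np.ndarray
    labels: dict[int, np.ndarray]  # K -> labels
    silhouette: dict[int, float]  # K -> average silhouette width


def cluster_axes(
    features: AxisFeatureMatrix, k_range: range = range(2, 7), seed: int = 0, n_init: int = 10
) -> ClusterReport:
    """PCA plus k-means over a K range with average silhouette widths."""
    X = features.standardized().to_numpy()
    if X.shape[0] <= max(k_range):
        raise MiraxError("need more samples than the largest K")
    pca = PCA(n_components=2, random_state=seed)
    coords = pca.fit_transform(X)
    labels, sil = {}, {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(X)
        labels[k] = lab
        sil[k] = float(silhouette_score(X, lab)) if len(np.unique(lab)) > 1 else np.nan
    return ClusterReport(
        pca_coords=pd.DataFrame(coords, index=features.sample_ids, columns=["PC1", "PC2"]),
        variance_explained=pca.explained_variance_ratio_,
        labels=labels,
        silhouette=sil,
    )


# ---------------------------------------------------------------------------
# Elastic-net Cox (Breslow ties) by IRLS + coordinate descent
# ---------------------------------------------------------------------------

def _breslow_quantities(eta: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Log partial likelihood (Breslow), per-sample gradient u and diagonal
    Hessian w of the log-likelihood with respect to eta."""
    n = len(time)
    order = np.argsort(time, kind="stable")
    t_s, e_s, eta_s = time[order], event[order], eta[order]
    exp_eta = np.exp(eta_s)
    # risk-set sums: S(t_k) = sum of exp(eta) over subjects with time >= t_k
    rev_cum = np.cumsum(exp_eta[::-1])[::-1]
    uniq, first_idx, inverse = np.unique(t_s, return_index=True, return_inverse=True)
    S = rev_cum[first_idx]  # risk-set sum at each unique time
    d = np.bincount(inverse, weights=e_s.astype(float))
    ev_mask = d > 0
    uniq_ev, S_ev, d_ev = uniq[ev_mask], S[ev_mask], d[ev_mask]
    loglik = float(np.sum(eta_s[e_s == 1]) - np.sum(d_ev * np.log(S_ev)))
    # cumulative hazard-style sums over event times with t_k <= t_i
    cum_dS = np.concatenate([[0.0], np.cumsum(d_ev / S_ev)])
    cum_dS2 = np.concatenate([[0.0], np.cumsum(d_ev / S_ev**2)])
    pos = np.searchsorted(uniq_ev, t_s, side="right")
    A = cum_dS[pos]
    B = cum_dS2[pos]
    u_s = e_s - exp_eta * A
    w_s = exp_eta * A - exp_eta**2 * B
    u = np.empty(n)
    w = np.empty(n)
    u[order] = u_s
    w[order] = w_s
    return loglik, u, np.maximum(w, 1e-9)


def cox_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    ll, _, _ = _breslow_quantities(X @ beta, time, event)
    return ll


def lambda_max(X: np.ndarray, time: np.ndarray, event: np.ndarray, alpha: float) -> float:
    """Smallest lambda with an all-zero elastic-net solution (for alpha > 0);
    for near-ridge alpha the glmnet convention alpha=0.001 is used."""
    n = X.shape[0]
    _, u, _ = _breslow_quantities(np.zeros(n), time, event)
    grad = np.abs(X.T @ u) / n
    return float(grad.max() / max(alpha, 1e-3))


def _soft(x: float, thr: float) -> float:
    return np.sign(x) * max(abs(x) - thr, 0.0)


def coxnet_fit(
    X: np.ndarray | pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    alpha: float = 0.5,
    lam: float = 0.0,
    beta_init: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> np.ndarray:
    """Elastic-net Cox coefficients at one (alpha, lambda).

    ``X`` must already be standardized (columns mean 0, SD 1) for the
    penalty to act symmetrically.  Raises on zero events or non-convergence.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    n, p = X.shape
    if event.sum() < 1:
        raise MiraxError("coxnet_fit needs at least one event")
    if not (0.0 <= alpha <= 1.0) or lam < 0:
        raise MiraxError("need alpha in [0,1] and lambda >= 0")
    beta = np.zeros(p) if beta_init is None else np.array(beta_init, dtype=float)
    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)

    def objective(b: np.ndarray) -> float:
        ll, _, _ = _breslow_quantities(X @ b, time, event)
        return -ll / n + l1 * np.abs(b).sum() + 0.5 * l2 * (b**2).sum()

    obj = objective(beta)
    for it in range(max_iter):
        eta = X @ beta
        _, u, w = _breslow_quantities(eta, time, event)
        z = eta + u / w
        beta_old_outer = beta.copy()
        # coordinate descent on the penalized weighted least squares problem,
        # covariance form: all sufficient statistics are p x p
        Xw = X * w[:, None]
        XtWX = (Xw.T @ X) / n
        XtWz = (Xw.T @ z) / n
        diag = np.diag(XtWX)
        for _inner in range(1000):
            max_delta = 0.0
            for j in range(p):
                rho = XtWz[j] - XtWX[j] @ beta + diag[j] * beta[j]
                new_b = _soft(rho, l1) / (diag[j] + l2)
                delta = new_b - beta[j]
                if delta != 0.0:
                    beta[j] = new_b
                    if abs(delta) > max_delta:
                        max_delta = abs(delta)
            if max_delta < tol:
                break
        # step-halving keeps the penalized objective monotone
        new_obj = objective(beta)
        halvings = 0
        while new_obj > obj + 1e-12 and halvings < 25:
            beta = 0.5 * (beta + beta_old_outer)
            new_obj = objective(beta)
            halvings += 1
        obj = new_obj
        if np.max(np.abs(beta)) > 30.0:
            raise MiraxError(
                f"coxnet_fit diverged at iteration {it} (monotone likelihood / separation)"
            )
        if np.max(np.abs(beta - beta_old_outer)) < tol:
            return beta
    if np.max(np.abs(beta - beta_old_outer)) > 1e-4:
        raise MiraxError(f"coxnet_fit did not converge in {max_iter} IRLS iterations")
    warnings.warn("coxnet_fit reached max_iter with loose residual; returning last iterate")
    return beta


def coxnet_path(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
    tol: float = 1e-6,
) -> np.ndarray:
    """Warm-started coefficient path over a decreasing lambda sequence.

    If the fit destabilizes at the small-lambda end (quasi-separation on
    small data), the path is truncated: remaining entries repeat the last
    stable solution.  Returns an array of shape (len(lambdas), p).
    """
    p = X.shape[1]
    betas = np.zeros((len(lambdas), p))
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        try:
            beta = coxnet_fit(X, time, event, alpha=alpha, lam=lam, beta_init=beta, tol=tol)
        except MiraxError:
            logger.warning("lambda path truncated at %g (%d of %d steps)",
                           lam, i, len(lambdas))
            betas[i:] = beta
            return betas
        betas[i] = beta
    return betas


def default_lambda_path(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, alpha: float,
    n_lambda: int = 100, decades: float = 4.0,
) -> np.ndarray:
    lmax = lambda_max(X, time, event, alpha)
    return lmax * np.logspace(0.0, -decades, n_lambda)


# ---------------------------------------------------------------------------
# Penalized Cox model container
# ---------------------------------------------------------------------------

@dataclass
class PenalizedCoxModel:
    """Frozen elastic-net Cox model: coefficients plus the training
    standardization needed to emit a locked linear predictor."""

    beta: pd.Series  # indexed by feature name
    alpha: float
    lam: float
    means: pd.Series
    sds: pd.Series
    spec: str = "axes"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lam < 0 or not (0.0 <= self.alpha <= 1.0):
            raise MiraxError("need lambda >= 0 and alpha in [0,1]")

    @property
    def features(self) -> list[str]:
        return list(self.beta.index)

    def linear_predictor(self, features: pd.DataFrame, allow_subset: bool = False) -> pd.Series:
        """Locked linear predictor sum_j beta_j (x_ij - mu_j)/sigma_j.

        With ``allow_subset=True``, scoring restricts to the model features
        present in ``features`` (feature-subset transfer); otherwise every
        model feature must be present.
        """
        present = [f for f in self.features if f in features.columns]
        missing = [f for f in self.features if f not in features.columns]
        if missing and not allow_subset:
            raise MiraxError(f"validation matrix missing model feature(s): {missing}")
        if not present:
            raise MiraxError("no model features present in the supplied matrix")
        if missing:
            logger.warning(
                "feature-subset scoring: %d of %d model features used (%s dropped)",
                len(present), len(self.features), missing,
            )
        sds = self.sds[present]
        if (sds <= 0).any():
            raise MiraxError(f"zero training SD for: {list(sds.index[sds <= 0])}")
        z = (features[present] - self.means[present]) / sds
        return (z * self.beta[present]).sum(axis=1)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.to_dict(),
            "alpha": self.alpha,
            "lambda": self.lam,
            "means": self.means.to_dict(),
            "sds": self.sds.to_dict(),
            "spec": self.spec,
            "seed": self.seed,
            "ties": "breslow",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PenalizedCoxModel":
        return cls(
            beta=pd.Series(d["beta"]),
            alpha=float(d["alpha"]),
            lam=float(d["lambda"]),
            means=pd.Series(d["means"]),
            sds=pd.Series(d["sds"]),
            spec=d.get("spec", "axes"),
            seed=d.get("seed"),
        )


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def harrell_cindex(risk: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's concordance index.

    A pair (i, j) is comparable iff the earlier of the two times belongs to
    a subject with an event (tied times are not comparable).  Concordant
    pairs have the higher risk on the shorter time; tied risks credit 0.5.
    Returns NaN if no pair is comparable.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    # comparable[i, j]: t_i < t_j and event_i
    ti = time[:, None]
    tj = time[None, :]
    comp = (ti < tj) & (event[:, None] == 1)
    if not comp.any():
        return float("nan")
    ri = risk[:, None]
    rj = risk[None, :]
    concordant = (ri > rj) & comp
    tied = (ri == rj) & comp
    n_comp = comp.sum()
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


def bootstrap_cindex_ci(
    risk: np.ndarray, time: np.ndarray, event: np.ndarray,
    n_boot: int = 1000, seed: int = 0, level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the c-index (resampling samples)."""
    rng = np.random.default_rng(seed)
    n = len(time)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        c = harrell_cindex(risk[idx], time[idx], event[idx])
        if np.isfinite(c):
            vals.append(c)
    lo = (1.0 - level) / 2.0
    return float(np.quantile(vals, lo)), float(np.quantile(vals, 1.0 - lo))


# ---------------------------------------------------------------------------
# Kaplan-Meier, log-rank, univariable Cox
# ---------------------------------------------------------------------------

def km_estimator(
    surv: pd.DataFrame,
    labels: pd.Series | None = None,
    t_max: float = 120.0,
    at_risk_ticks: tuple[float, ...] = (0, 24, 48, 72, 96, 120),
) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves per group, truncated for display at
    ``t_max`` months, with numbers at risk at the requested ticks."""
    validate_survival_table(surv)
    if labels is None:
        labels = pd.Series("all", index=surv.index)
    out: dict[str, pd.DataFrame] = {}
    for grp in sorted(pd.unique(labels)):
        ids = labels.index[labels == grp]
        if len(ids) == 0:
            raise MiraxError(f"empty group {grp!r}")
        kmf = KaplanMeierFitter()
        sub = surv.loc[ids]
        kmf.fit(sub["time_months"], sub["event"], label=str(grp))
        sf = kmf.survival_function_
        sf = sf[sf.index <= t_max]
        at_risk = {
            t: int((sub["time_months"] >= t).sum()) for t in at_risk_ticks
        }
        df = sf.rename(columns={str(grp): "survival"})
        df.index.name = "time_months"
        df.attrs["median"] = float(kmf.median_survival_time_)
        df.attrs["at_risk"] = at_risk
        out[str(grp)] = df
    return out


def logrank_test(surv: pd.DataFrame, labels: pd.Series) -> tuple[float, float]:
    """1-df log-rank test between two groups; (chi2, p).

    With no events at all the statistic is 0 and p = 1.
    """
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise MiraxError(f"logrank_test needs exactly 2 groups, got {len(groups)}")
    a = labels.index[labels == groups[0]]
    b = labels.index[labels == groups[1]]
    if len(a) == 0 or len(b) == 0:
        raise MiraxError("both groups must be nonempty")
    if surv.loc[labels.index, "event"].sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(
        surv.loc[a, "time_months"], surv.loc[b, "time_months"],
        event_observed_A=surv.loc[a, "event"], event_observed_B=surv.loc[b, "event"],
    )
    return float(res.test_statistic), float(res.p_value)


def median_split(values: pd.Series) -> pd.Series:
    """High/Low labels by the median; samples equal to the median go to Low."""
    med = values.median()
    return pd.Series(np.where(values > med, "High", "Low"), index=values.index)


@dataclass
class UnivariableCox:
    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    beta: float
    separation: bool = False


def cox_univariable(
    values: pd.Series, surv: pd.DataFrame, dichotomize: str = "median"
) -> UnivariableCox:
    """Univariable Cox PH fit (Efron ties) of one covariate.

    ``dichotomize="median"`` converts the covariate to a High(1)/Low(0)
    indicator (median ties to Low); ``"none"`` uses it continuously.
    Monotone-likelihood separation is flagged with an unbounded CI.
    """
    validate_survival_table(surv)
    common = values.index.intersection(surv.index)
    x = values.loc[common].astype(float)
    if dichotomize == "median":
        x = (median_split(x) == "High").astype(float)
    elif dichotomize != "none":
        raise MiraxError("dichotomize must be 'median' or 'none'")
    if x.nunique() < 2:
        raise MiraxError("covariate is constant after dichotomization")
    df = pd.DataFrame({
        "time": surv.loc[common, "time_months"],
        "event": surv.loc[common, "event"],
        "x": x,
    })
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        beta = float(cph.params_["x"])
        se = float(cph.standard_errors_["x"])
        if se > 100:  # effectively infinite SE -> separation
            raise MiraxError("separation")
        return UnivariableCox(
            hr=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.96 * se)),
            ci_high=float(np.exp(beta + 1.96 * se)),
            wald_p=float(cph.summary.loc["x", "p"]),
            beta=beta,
        )
    except Exception:
        # monotone-likelihood separation or non-convergence
        direction = np.sign(np.corrcoef(x, df["time"])[0, 1]) if df["event"].sum() else 0.0
        hr = np.inf if direction < 0 else 0.0
        return UnivariableCox(hr=hr, ci_low=0.0, ci_high=np.inf, wald_p=np.nan,
                              beta=np.log(hr) if hr > 0 else -np.inf, separation=True)


# ---------------------------------------------------------------------------
# Survival screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    gene: str
    hr: float
    ci_low: float
    ci_high: float
    logrank_p: float
    q: float
    shortlist: bool
    direction: str  # "risk" | "protective"
    status: str = "ok"


def survival_screen(
    genes: pd.DataFrame, surv: pd.DataFrame, fdr: float = 0.01
) -> list[ScreenResult]:
    """Median-split KM + log-rank + univariable Cox per gene, BH across genes.

    ``genes`` is a gene-by-sample expression matrix (log scale).  The
    shortlist flags genes with BH-adjusted log-rank q <= ``fdr``; direction
    is "risk" when the High group has HR > 1.
    """
    validate_survival_table(surv)
    common = genes.columns.intersection(surv.index)
    if len(common) < 4:
        raise MiraxError("survival_screen needs >= 4 shared samples")
    results: list[ScreenResult] = []
    tested_idx: list[int] = []
    pvals: list[float] = []
    for gene, row in genes[common].iterrows():
        if row.nunique() < 2:
            results.append(ScreenResult(gene, np.nan, np.nan, np.nan, np.nan,
                                        np.nan, False, "ns", status="skipped: constant"))
            continue
        labels = median_split(row)
        if labels.nunique() < 2:
            results.append(ScreenResult(gene, np.nan, np.nan, np.nan, np.nan,
                                        np.nan, False, "ns", status="skipped: degenerate split"))
            continue
        _, p_lr = logrank_test(surv.loc[common], labels)
        cox = cox_univariable(row, surv.loc[common], dichotomize="median")
        results.append(ScreenResult(
            gene=str(gene), hr=cox.hr, ci_low=cox.ci_low, ci_high=cox.ci_high,
            logrank_p=p_lr, q=np.nan, shortlist=False,
            direction="risk" if cox.hr > 1 else "protective",
        ))
        tested_idx.append(len(results) - 1)
        pvals.append(p_lr)
    if pvals:
        from .de import bh_adjust

        qs = bh_adjust(np.array(pvals))
        for i, q in zip(tested_idx, qs):
            results[i].q = float(q)
            results[i].shortlist = bool(q <= fdr)
    return results


def screen_table(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.gene, r.hr, r.ci_low, r.ci_high, r.logrank_p, r.q, r.shortlist, r.direction, r.status)
            for r in results
        ],
        columns=["gene", "hr", "ci_low", "ci_high", "logrank_p", "q", "shortlist", "direction", "status"],
    ).set_index("gene")


# ---------------------------------------------------------------------------
# Nested cross-validation over three model specifications
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    fold_assignments: pd.Series  # sample -> outer fold id
    fold_cindex: dict[str, list[float]]  # spec -> per-fold c-index
    selected_alpha: dict[str, list[float]]
    seed: int = 0

    def mean_cindex(self, spec: str) -> float:
        return float(np.nanmean(self.fold_cindex[spec]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for spec, cs in self.fold_cindex.items():
            for fold, (c, a) in enumerate(zip(cs, self.selected_alpha[spec])):
                rows.append((spec, fold, c, a))
        return pd.DataFrame(rows, columns=["spec", "fold", "cindex", "alpha"])


def _event_stratified_folds(event: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels (0..k-1) with events and censorings dealt separately."""
    n = len(event)
    folds = np.empty(n, dtype=int)
    for val in (1, 0):
        idx = np.flatnonzero(event == val)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def _design_matrix(
    spec: str, molecular: pd.DataFrame, surv: pd.DataFrame
) -> pd.DataFrame:
    clin = surv[CLINICAL_FEATURES].astype(float)
    if spec == "clinical":
        return clin
    if spec == "axes":
        return molecular
    if spec == "combined":
        return pd.concat([clin, molecular], axis=1)
    raise MiraxError(f"unknown model spec {spec!r}")


def _cv_deviance(
    X: np.ndarray, time: np.ndarray, event: np.ndarray,
    alpha: float, lambdas: np.ndarray, k: int, rng: np.random.Generator,
) -> np.ndarray:
    """Inner-CV partial-likelihood deviance per lambda (V&VH estimator:
    deviance contribution of fold v is -2*(ll(all) - ll(train))."""
    folds = _event_stratified_folds(event, k, rng)
    dev = np.zeros(len(lambdas))
    for v in range(k):
        tr = folds != v
        if event[tr].sum() < 2:
            continue
        betas = coxnet_path(X[tr], time[tr], event[tr], alpha, lambdas)
        for i, beta in enumerate(betas):
            ll_all = cox_loglik(beta, X, time, event)
            ll_tr = cox_loglik(beta, X[tr], time[tr], event[tr])
            dev[i] += -2.0 * (ll_all - ll_tr)
    return dev


def _tune_and_fit(
    X: pd.DataFrame, time: np.ndarray, event: np.ndarray,
    alpha_grid, n_lambda: int, k_inner: int, rng: np.random.Generator,
) -> tuple[np.ndarray, float, float]:
    """Inner-CV choice of (alpha, lambda) followed by a fit on all rows of X."""
    Xn = X.to_numpy(dtype=float)
    best = (np.inf, None, None)
    for alpha in alpha_grid:
        lambdas = default_lambda_path(Xn, time, event, alpha, n_lambda=n_lambda)
        dev = _cv_deviance(Xn, time, event, alpha, lambdas, k_inner, rng)
        i = int(np.argmin(dev))
        if dev[i] < best[0]:
            best = (dev[i], alpha, lambdas[i])
    _, alpha_star, lam_star = best
    beta = coxnet_fit(Xn, time, event, alpha=alpha_star, lam=lam_star)
    return beta, float(alpha_star), float(lam_star)


def nested_cv(
    molecular: pd.DataFrame,
    surv: pd.DataFrame,
    specs: tuple[str, ...] = ("clinical", "axes", "combined"),
    k_outer: int = 5,
    k_inner: int = 5,
    alpha_grid=DEFAULT_ALPHA_GRID,
    n_lambda: int = 100,
    seed: int = 0,
) -> CVReport:
    """Common outer 5-fold CV shared across model specifications.

    Standardization statistics are recomputed inside each training fold only
    (no leakage into held-out folds); (alpha, lambda) are tuned per training
    fold by inner CV on partial-likelihood deviance; held-out performance is
    Harrell's c-index.
    """
    validate_survival_table(surv, require_clinical=True)
    if (surv["event"].sum()) < k_outer:
        raise MiraxError("need at least k_outer events")
    surv = surv.loc[molecular.index]
    time = surv["time_months"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    rng = np.random.default_rng(seed)
    folds = _event_stratified_folds(event, k_outer, rng)
    fold_assign = pd.Series(folds, index=molecular.index, name="fold")
    fold_c: dict[str, list[float]] = {s: [] for s in specs}
    sel_a: dict[str, list[float]] = {s: [] for s in specs}
    for spec in specs:
        Xall = _design_matrix(spec, molecular, surv)
        for v in range(k_outer):
            tr, te = folds != v, folds == v
            mu = Xall.loc[tr].mean(axis=0)
            sd = Xall.loc[tr].std(axis=0, ddof=1).replace(0.0, 1.0)
            Xtr = (Xall.loc[tr] - mu) / sd
            Xte = (Xall.loc[te] - mu) / sd
            inner_rng = np.random.default_rng(seed * 1000 + v + 1)
            beta, alpha_star, _ = _tune_and_fit(
                Xtr, time[tr], event[tr], alpha_grid, n_lambda, k_inner, inner_rng
            )
            risk = Xte.to_numpy() @ beta
            fold_c[spec].append(harrell_cindex(risk, time[te], event[te]))
            sel_a[spec].append(alpha_star)
    return CVReport(fold_assignments=fold_assign, fold_cindex=fold_c,
                    selected_alpha=sel_a, seed=seed)


def final_fit(
    molecular: pd.DataFrame,
    surv: pd.DataFrame,
    spec: str = "axes",
    alpha: float | None = None,
    cv_report: CVReport | None = None,
    k_inner: int = 5,
    n_lambda: int = 100,
    seed: int = 0,
) -> PenalizedCoxModel:
    """Fit the final penalized Cox model on all complete cases.

    ``alpha`` defaults to the modal CV-selected alpha of ``cv_report`` for
    this spec (smallest on ties); lambda is chosen by inner CV at that alpha.
    Standardization statistics of the full training data are frozen into the
    returned model.
    """
    surv = surv.loc[molecular.index]
    X = _design_matrix(spec, molecular, surv)
    time = surv["time_months"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    if alpha is None:
        if cv_report is not None:
            picks = cv_report.selected_alpha[spec]
            vals, counts = np.unique(np.round(picks, 6), return_counts=True)
            alpha = float(vals[counts == counts.max()].min())
        else:
            alpha = 0.5
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd <= 0).any():
        raise MiraxError(f"constant feature(s): {list(sd.index[sd <= 0])}")
    Xs = (X - mu) / sd
    rng = np.random.default_rng(seed + 99)
    Xn = Xs.to_numpy(dtype=float)
    lambdas = default_lambda_path(Xn, time, event, alpha, n_lambda=n_lambda)
    dev = _cv_deviance(Xn, time, event, alpha, lambdas, k_inner, rng)
    lam = float(lambdas[int(np.argmin(dev))])
    beta = coxnet_fit(Xn, time, event, alpha=alpha, lam=lam)
    return PenalizedCoxModel(
        beta=pd.Series(beta, index=X.columns), alpha=float(alpha), lam=lam,
        means=mu, sds=sd, spec=spec, seed=seed,
    )


# ---------------------------------------------------------------------------
# Locked external validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    risk: pd.Series
    cindex: float
    cindex_ci: tuple[float, float]
    cutpoint: float
    fold_cutpoints: list[float]
    labels: pd.Series  # High/Low
    logrank_chi2: float
    logrank_p: float
    cox: UnivariableCox
    km: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_high: int = 0
    n_low: int = 0


def _best_cut(risk: pd.Series, surv: pd.DataFrame,
              quantiles: np.ndarray) -> float:
    """Cut value (from risk quantiles) maximizing the log-rank statistic."""
    best_stat, best_cut = -np.inf, float(risk.median())
    for q in quantiles:
        cut = float(risk.quantile(q))
        labels = pd.Series(np.where(risk > cut, "High", "Low"), index=risk.index)
        if labels.nunique() < 2:
            continue
        sub = surv.loc[risk.index]
        if sub.loc[labels == "High", "event"].sum() + sub.loc[labels == "Low", "event"].sum() == 0:
            continue
        try:
            stat, _ = logrank_test(sub, labels)
        except MiraxError:
            continue
        if stat > best_stat:
            best_stat, best_cut = stat, cut
    return best_cut


def locked_external_validate(
    model: PenalizedCoxModel,
    features_val: pd.DataFrame,
    surv_val: pd.DataFrame,
    k_cut: int = 5,
    seed: int = 0,
    n_boot: int = 1000,
    allow_subset: bool = True,
) -> ValidationReport:
    """Apply a locked linear predictor to an external cohort, no refitting.

    Risk scores use the frozen training coefficients and standardization.
    Discrimination is the c-index of the continuous risk (bootstrap
    percentile CI).  The High/Low cutpoint is derived by k-fold CV inside
    the validation cohort: per fold, the training portion's risk quantiles
    0.2-0.8 (step 0.05) are scanned for the maximal log-rank statistic and
    the final cutpoint is the mean of the fold optima.
    """
    validate_survival_table(surv_val)
    common = features_val.index.intersection(surv_val.index)
    risk = model.linear_predictor(features_val.loc[common], allow_subset=allow_subset)
    surv = surv_val.loc[common]
    time = surv["time_months"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    c = harrell_cindex(risk.to_numpy(), time, event)
    ci = bootstrap_cindex_ci(risk.to_numpy(), time, event, n_boot=n_boot, seed=seed)
    rng = np.random.default_rng(seed)
    folds = _event_stratified_folds(event, k_cut, rng)
    quantiles = np.arange(0.2, 0.8001, 0.05)
    cuts = []
    for v in range(k_cut):
        tr = folds != v
        cuts.append(_best_cut(risk[tr], surv.loc[risk.index[tr]], quantiles))
    cutpoint = float(np.mean(cuts))
    labels = pd.Series(np.where(risk > cutpoint, "High", "Low"), index=risk.index)
    if labels.nunique() < 2:
        raise MiraxError("degenerate High/Low split at the CV cutpoint")
    chi2, p = logrank_test(surv, labels)
    cox = cox_univariable((labels == "High").astype(float), surv, dichotomize="none")
    km = km_estimator(surv, labels)
    return ValidationReport(
        risk=risk, cindex=c, cindex_ci=ci, cutpoint=cutpoint, fold_cutpoints=cuts,
        labels=labels, logrank_chi2=chi2, logrank_p=p, cox=cox, km=km,
        n_high=int((labels == "High").sum()), n_low=int((labels == "Low").sum()),
    )
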