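"""Filtering, normalization and moderated differential expression.

Implements the standard RNA-seq contrast workflow for tumor-vs-normal
comparisons: CPM computation and low-expression filtering, TMM (trimmed
mean of M-values) scaling factors, empirical-Bayes moderated t-statistics
(unpaired two-group and paired one-sample designs), Benjamini-Hochberg
adjustment, and direction/effect-size set construction.

The moderated test shrinks per-gene sample variances ``s_g^2`` (residual
df ``d``) toward a prior ``s0^2`` with prior df ``d0``::

    s_tilde_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

with ``(d0, s0^2)`` estimated by matching the first two moments of
``log s_g^2`` through the digamma/trigamma identities for log-chi-square
variables.  The moderated t is referred to a t distribution on ``d0 + d``
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, MiraxError

__all__ = [
    "ModerationParams",
    "DEResult",
    "cpm",
    "filter_low_expression",
    "tmm_factors",
    "moderated_t",
    "bh_adjust",
    "direction_sets",
]


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes hyperparameters of the moderated t-test.

    ``d0`` is the prior degrees of freedom (``inf`` = full shrinkage),
    ``s0_sq`` the prior variance, ``d`` the per-gene residual df.
    """

    d0: float
    s0_sq: float
    d: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise MiraxError("prior df d0 must be >= 0")
        if self.s0_sq <= 0:
            raise MiraxError("prior variance s0_sq must be > 0")


@dataclass
class DEResult:
    """Per-feature differential expression table.

    ``table`` has columns ``log2fc`` (tumor - normal), ``t`` (moderated t),
    ``p`` (two-sided), ``q`` (BH-adjusted) and ``direction`` in
    {``up``, ``down``, ``ns``}; the index holds feature symbols.
    """

    table: pd.DataFrame
    params: ModerationParams
    lfc_threshold: float | None = None
    fdr: float | None = None

    def up(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["direction"] == "up"])

    def down(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["direction"] == "down"])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "feature"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# CPM and filtering
# ---------------------------------------------------------------------------

def cpm(
    counts: ExpressionMatrix,
    prior_count: float = 0.0,
    log: bool = False,
    norm_factors: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Counts per million, linear or log2.

    Library sizes are column sums, optionally multiplied by TMM
    normalization factors.  The log variant uses
    ``log2((counts + prior_count) / (libsize + 2*prior_count) * 1e6)``.
    """
    if counts.scale != "counts":
        raise MiraxError("cpm expects raw counts")
    mat = counts.values.to_numpy(dtype=float)
    libsize = mat.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise MiraxError(f"zero library size for sample(s): {list(counts.sample_ids[zero])}")
    if norm_factors is not None:
        libsize = libsize * np.asarray(norm_factors, dtype=float)
    if log:
        vals = np.log2((mat + prior_count) / (libsize + 2.0 * prior_count) * 1e6)
        scale = "log2"
    else:
        vals = mat / libsize * 1e6
        scale = "counts"  # linear CPM stays on the counts-like non-negative scale
    out = pd.DataFrame(vals, index=counts.values.index, columns=counts.values.columns)
    return ExpressionMatrix(out, counts.sample_meta.copy(), assay=counts.assay, scale=scale)


def filter_low_expression(
    counts: ExpressionMatrix, cpm_threshold: float = 1.0, min_samples: int | None = None
) -> ExpressionMatrix:
    """Keep features with linear CPM >= threshold in at least ``min_samples`` samples.

    ``min_samples`` defaults to the size of the smaller group, the standard
    edgeR-style guidance that keeps group-specific features.
    """
    if counts.scale != "counts":
        raise MiraxError("filter_low_expression expects raw counts")
    if min_samples is None:
        sizes = counts.sample_meta["group"].value_counts()
        min_samples = int(sizes.min())
    if min_samples > counts.n_samples:
        raise MiraxError(
            f"min_samples={min_samples} exceeds number of samples ({counts.n_samples})"
        )
    lin = cpm(counts, log=False).values.to_numpy()
    keep = (lin >= cpm_threshold).sum(axis=1) >= min_samples
    return counts.subset_features(counts.feature_ids[keep])


# ---------------------------------------------------------------------------
# TMM normalization factors
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              trim_m: float = 0.3, trim_a: float = 0.05) -> float:
    """Two-sample TMM factor: weighted trimmed mean of M-values (log2)."""
    mask = (obs > 0) & (ref > 0)
    obs, ref = obs[mask], ref[mask]
    if obs.size == 0:
        return 1.0
    p_obs = obs / lib_obs
    p_ref = ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) variance of M for count data
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    if np.max(np.abs(m)) < 1e-6:  # identical relative profiles
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f)


def tmm_factors(counts: ExpressionMatrix, trim_m: float = 0.3, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean rescaled to 1.

    The reference sample is the one whose 75th-percentile CPM is closest to
    the mean 75th percentile across samples.
    """
    if counts.scale != "counts":
        raise MiraxError("tmm_factors expects raw counts")
    mat = counts.values.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        bad = list(counts.sample_ids[lib == 0])
        raise MiraxError(f"sample(s) with all-zero counts: {bad}")
    uq = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = mat[:, ref_idx]
    factors = np.array([
        _tmm_pair(mat[:, j], ref, lib[j], lib[ref_idx], trim_m, trim_a)
        for j in range(mat.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    # starting value from the asymptotic expansion trigamma(y) ~ 1/y + 1/(2y^2)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Estimate (d0, s0_sq) by moment matching on log s^2.

    Under the scaled chi-square model, ``e = log s^2 - digamma(d/2) + log(d/2)``
    has mean ``log s0^2 + digamma(d0/2) - log(d0/2)`` and excess variance
    ``trigamma(d0/2)`` beyond ``trigamma(d/2)``.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    evar = np.var(e, ddof=1) - special.polygamma(1, d / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(np.mean(e)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _moderate(diff: np.ndarray, s2: np.ndarray, d: float, se_factor: float,
              d0: float | None, s0_sq: float | None) -> tuple[np.ndarray, np.ndarray, ModerationParams]:
    if d0 is None or s0_sq is None:
        est_d0, est_s0 = estimate_prior(s2, d)
        d0 = est_d0 if d0 is None else d0
        s0_sq = est_s0 if s0_sq is None else s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    t = diff / (np.sqrt(s2_post) * se_factor)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p, ModerationParams(d0=float(d0), s0_sq=float(s0_sq), d=float(d))


def moderated_t(
    expr: ExpressionMatrix,
    paired: bool = False,
    lfc_threshold: float = 1.0,
    fdr: float = 0.05,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> DEResult:
    """Moderated t-test of tumor vs normal on a log2-scale matrix.

    Unpaired mode fits a per-gene two-sample comparison with pooled variance;
    paired mode takes within-patient (tumor - normal) differences over
    complete pairs and applies a one-sample moderated t.  Constant genes are
    excluded before estimating the variance prior.

    Set ``d0=0`` to disable shrinkage (ordinary t) or ``d0=np.inf`` for full
    shrinkage to the prior variance.
    """
    if expr.scale != "log2":
        raise MiraxError("moderated_t expects a log2-scale matrix")
    groups = expr.sample_meta["group"]
    mat = expr.values.to_numpy(dtype=float)
    features = expr.values.index

    if paired:
        meta = expr.sample_meta
        tumors = meta[meta["group"] == "tumor"]
        normals = meta[meta["group"] == "normal"]
        common = sorted(set(tumors["patient_id"]) & set(normals["patient_id"]))
        if len(common) < 2:
            raise MiraxError("paired analysis requires >= 2 complete patient pairs")
        t_ids = [tumors.index[tumors["patient_id"] == p][0] for p in common]
        n_ids = [normals.index[normals["patient_id"] == p][0] for p in common]
        diffs = expr.values[t_ids].to_numpy() - expr.values[n_ids].to_numpy()
        n_pairs = len(common)
        diff = diffs.mean(axis=1)
        s2 = diffs.var(axis=1, ddof=1)
        d = float(n_pairs - 1)
        se_factor = np.sqrt(1.0 / n_pairs)
    else:
        is_t = (groups == "tumor").to_numpy()
        is_n = (groups == "normal").to_numpy()
        n1, n2 = int(is_t.sum()), int(is_n.sum())
        if n1 < 2 or n2 < 2:
            raise MiraxError("each group needs >= 2 samples")
        xt, xn = mat[:, is_t], mat[:, is_n]
        diff = xt.mean(axis=1) - xn.mean(axis=1)
        s2 = ((n1 - 1) * xt.var(axis=1, ddof=1) + (n2 - 1) * xn.var(axis=1, ddof=1)) / (
            n1 + n2 - 2
        )
        d = float(n1 + n2 - 2)
        se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)

    nonconstant = s2 > 0
    if not nonconstant.all():
        import warnings

        warnings.warn(
            f"{int((~nonconstant).sum())} all-constant feature(s) excluded from testing"
        )
    diff_nc, s2_nc = diff[nonconstant], s2[nonconstant]
    t, p, params = _moderate(diff_nc, s2_nc, d, se_factor, d0, s0_sq)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {"log2fc": diff_nc, "t": t, "p": p, "q": q},
        index=features[nonconstant],
    )
    up, down = direction_sets(table, lfc_threshold, fdr)
    direction = np.where(
        table.index.isin(up), "up", np.where(table.index.isin(down), "down", "ns")
    )
    table["direction"] = direction
    return DEResult(table=table, params=params, lfc_threshold=lfc_threshold, fdr=fdr)


# ---------------------------------------------------------------------------
# Multiple testing and direction sets
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise MiraxError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def direction_sets(
    de: pd.DataFrame | DEResult, lfc_threshold: float, fdr: float
) -> tuple[frozenset[str], frozenset[str]]:
    """Split features into up/down sets by FDR and signed log2FC threshold."""
    table = de.table if isinstance(de, DEResult) else de
    sig = table["q"] <= fdr
    up = frozenset(table.index[sig & (table["log2fc"] >= lfc_threshold)])
    down = frozenset(table.index[sig & (table["log2fc"] <= -lfc_threshold)])
    return up, down
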