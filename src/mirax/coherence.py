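"""Per-sample target-set activity and abundance-activity coherence.

For each axis, a *target-set activity* is the per-tumor-sample mean of the
row-z-scored log expression of the axis's supported targets.  *Coherence*
is the Spearman rank correlation between the regulator miRNA's abundance
(log-CPM) and that activity across tumors carrying both assays; negative
coherence supports repression.

Conventions: row z-scores use the sample standard deviation (n-1
denominator); quartile blocks order samples by decreasing activity with a
stable sample-ID tie-break.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AxisDefinition, ExpressionMatrix, MiraxError
from .de import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityProfile",
    "CoherenceStat",
    "collapse_duplicates",
    "row_zscore",
    "target_set_activity",
    "spearman_coherence",
    "coherence_panel",
]


@dataclass
class ActivityProfile:
    """Per-sample activity of one axis (mean z over supported targets)."""

    mirna_id: str
    activity: pd.Series  # indexed by sample ID
    n_targets_used: int

    @property
    def samples(self) -> pd.Index:
        return self.activity.index


@dataclass
class CoherenceStat:
    """Spearman coherence of one axis with BH-adjusted significance."""

    mirna_id: str
    rho: float
    p: float
    n: int
    q: float = np.nan
    n_targets_used: int = 0
    quartile_means: pd.DataFrame | None = None  # rows Q1..Q4, cols activity/abundance
    status: str = "ok"


def collapse_duplicates(
    expr: ExpressionMatrix, symbol_map: dict[str, str] | None = None
) -> ExpressionMatrix:
    """Collapse rows sharing a symbol by the per-sample median.

    ``symbol_map`` optionally renames feature IDs (e.g. probe -> symbol)
    before collapsing.
    """
    values = expr.values
    if symbol_map:
        values = values.rename(index=lambda s: symbol_map.get(s, s))
    if values.index.duplicated().any():
        values = values.groupby(level=0, sort=False).median()
    return ExpressionMatrix(values, expr.sample_meta.copy(), assay=expr.assay, scale=expr.scale)


def row_zscore(expr: ExpressionMatrix, tumor_only: bool = True) -> pd.DataFrame:
    """Row-wise z-scores over the selected samples (sample SD, ddof=1).

    Zero-variance rows are dropped with a warning; returns a features-by-
    samples DataFrame restricted to the selected samples.
    """
    samples = expr.tumor_samples() if tumor_only else list(expr.sample_ids)
    if len(samples) < 2:
        raise MiraxError("row_zscore needs >= 2 samples")
    mat = expr.values[samples]
    mu = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("%d zero-variance row(s) dropped before z-scoring", int((~keep).sum()))
    z = mat.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return z


def target_set_activity(
    z: pd.DataFrame, axis: AxisDefinition, min_targets: int = 2
) -> ActivityProfile | None:
    """Unweighted per-sample mean of the z rows of the axis's present targets.

    Returns ``None`` (axis skipped) when fewer than ``min_targets`` supported
    targets are present in the z matrix.
    """
    present = sorted(set(axis.supported_targets) & set(z.index))
    if len(present) < min_targets:
        logger.warning(
            "axis %s skipped: %d of %d targets present (< min_targets=%d)",
            axis.mirna_id, len(present), axis.n_targets, min_targets,
        )
        return None
    activity = z.loc[present].mean(axis=0)
    return ActivityProfile(mirna_id=axis.mirna_id, activity=activity, n_targets_used=len(present))


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = float(np.mean(rx[list(perm)] * ry))
        total += 1
        if abs(r) >= target:
            count += 1
    return count / total


def spearman_coherence(
    abundance: pd.Series,
    activity: ActivityProfile | pd.Series,
    mirna_id: str | None = None,
) -> CoherenceStat:
    """Spearman rank correlation between miRNA abundance and target-set activity.

    Sample IDs are intersected first.  For n >= 10 the p-value uses the
    t-approximation ``t = rho * sqrt((n-2)/(1-rho^2))`` on n-2 df; for
    3 <= n < 10 the exact permutation distribution is enumerated.
    """
    if isinstance(activity, ActivityProfile):
        act = activity.activity
        mid = mirna_id or activity.mirna_id
        n_targets = activity.n_targets_used
    else:
        act = activity
        mid = mirna_id or "axis"
        n_targets = 0
    common = abundance.index.intersection(act.index)
    if len(common) < 3:
        raise MiraxError("spearman_coherence needs >= 3 paired samples")
    x = abundance.loc[common].to_numpy(dtype=float)
    y = act.loc[common].to_numpy(dtype=float)
    n = len(common)
    if np.std(x) == 0 or np.std(y) == 0:
        return CoherenceStat(
            mirna_id=mid, rho=np.nan, p=np.nan, n=n, n_targets_used=n_targets,
            status="zero-variance input",
        )
    rho = float(stats.spearmanr(x, y).statistic)
    if n >= 10:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    else:
        p = _exact_spearman_p(x, y, rho)
    qm = _quartile_means(pd.Series(y, index=common), pd.Series(x, index=common))
    return CoherenceStat(
        mirna_id=mid, rho=rho, p=p, n=n, n_targets_used=n_targets, quartile_means=qm
    )


def _quartile_means(activity: pd.Series, abundance: pd.Series) -> pd.DataFrame:
    """Mean activity and abundance in quartile blocks Q1..Q4 of the activity
    ordering (decreasing activity, ties broken by sample ID)."""
    order = activity.to_frame("activity")
    order["sample"] = order.index
    order = order.sort_values(["activity", "sample"], ascending=[False, True], kind="stable")
    blocks = np.array_split(np.arange(len(order)), 4)
    rows = []
    for qi, idx in enumerate(blocks, start=1):
        ids = order.index[idx]
        rows.append((f"Q{qi}", float(activity.loc[ids].mean()), float(abundance.loc[ids].mean())))
    return pd.DataFrame(rows, columns=["quartile", "activity", "abundance"]).set_index("quartile")


def coherence_panel(
    axes: list[AxisDefinition],
    z: pd.DataFrame,
    mirna_logcpm: pd.DataFrame,
    min_targets: int = 2,
) -> list[CoherenceStat]:
    """Coherence per axis with BH adjustment across the tested axes only.

    ``mirna_logcpm`` is a miRNA-by-sample log-CPM matrix restricted to (or
    at least covering) the tumor samples of ``z``.
    """
    results: list[CoherenceStat] = []
    for axis in axes:
        profile = target_set_activity(z, axis, min_targets=min_targets)
        if profile is None:
            results.append(
                CoherenceStat(
                    mirna_id=axis.mirna_id, rho=np.nan, p=np.nan, n=0,
                    status="skipped: too few targets",
                )
            )
            continue
        if axis.mirna_id not in mirna_logcpm.index:
            results.append(
                CoherenceStat(
                    mirna_id=axis.mirna_id, rho=np.nan, p=np.nan, n=0,
                    status="skipped: miRNA not in abundance matrix",
                )
            )
            continue
        abundance = mirna_logcpm.loc[axis.mirna_id]
        results.append(spearman_coherence(abundance, profile))
    tested = [r for r in results if r.status == "ok" and np.isfinite(r.p)]
    if tested:
        qs = bh_adjust(np.array([r.p for r in tested]))
        for r, q in zip(tested, qs):
            r.q = float(q)
    return results


def coherence_table(results: list[CoherenceStat]) -> pd.DataFrame:
    rows = [
        (r.mirna_id, r.rho, r.p, r.q, r.n, r.n_targets_used, r.status) for r in results
    ]
    return pd.DataFrame(
        rows, columns=["mirna_id", "rho", "p", "q", "n", "n_targets_used", "status"]
    ).set_index("mirna_id")
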