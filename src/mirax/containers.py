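"""Shared data containers for expression cohorts, axes and survival tables.

The central object is :class:`ExpressionMatrix`, a feature-by-sample numeric
matrix carrying per-sample metadata (tumor/normal group, patient and cohort
identifiers), the assay kind (mRNA or miRNA) and the scale of its values
(raw counts or log2 expression).  Survival tables are plain pandas
DataFrames indexed by sample ID with columns ``time_months``, ``event`` and
the clinical covariates ``age``, ``sex``, ``stage``; :func:`validate_survival_table`
enforces the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

ASSAYS = ("mrna", "mirna")
SCALES = ("counts", "log2")

SURVIVAL_COLUMNS = ("time_months", "event")
CLINICAL_COLUMNS = ("age", "sex", "stage")


class MiraxError(ValueError):
    """Base error for invalid inputs or configurations."""


@dataclass
class ExpressionMatrix:
    """Feature-by-sample expression matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame of shape (n_features, n_samples); the index holds feature
        symbols (duplicates allowed until collapsed), columns are sample IDs.
    sample_meta
        DataFrame indexed by sample ID with columns ``group`` (``tumor`` or
        ``normal``), ``patient_id`` and ``cohort``.
    assay
        ``"mrna"`` or ``"mirna"``.
    scale
        ``"counts"`` for raw counts, ``"log2"`` for log-scale expression
        (log-CPM or pre-normalized microarray intensities).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    assay: str = "mrna"
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise MiraxError(f"assay must be one of {ASSAYS}, got {self.assay!r}")
        if self.scale not in SCALES:
            raise MiraxError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise MiraxError(f"duplicate sample IDs: {dupes}")
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise MiraxError(f"samples missing from metadata: {missing[:5]}")
        # align metadata to the column order of the matrix
        self.sample_meta = self.sample_meta.loc[self.values.columns]
        if self.scale == "counts" and (self.values.to_numpy() < 0).any():
            raise MiraxError("counts must be non-negative")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def groups(self) -> pd.Series:
        return self.sample_meta["group"]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [s for s in sample_ids]
        return ExpressionMatrix(
            values=self.values[ids],
            sample_meta=self.sample_meta.loc[ids],
            assay=self.assay,
            scale=self.scale,
        )

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[list(feature_ids)],
            sample_meta=self.sample_meta,
            assay=self.assay,
            scale=self.scale,
        )

    def tumor_samples(self) -> list[str]:
        g = self.sample_meta["group"]
        return list(g.index[g == "tumor"])

    # -- I/O -------------------------------------------------------------------

    def to_tsv(self, counts_path: str | Path, meta_path: str | Path | None = None) -> None:
        """Write the matrix (first column = feature symbol) and optionally the metadata."""
        out = self.values.copy()
        out.index.name = "feature"
        out.to_csv(counts_path, sep="\t")
        if meta_path is not None:
            meta = self.sample_meta.copy()
            meta.index.name = "sample_id"
            meta.to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        meta_path: str | Path,
        assay: str = "mrna",
        scale: str = "counts",
    ) -> "ExpressionMatrix":
        values = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={"patient_id": str})
        return cls(values=values, sample_meta=meta, assay=assay, scale=scale)


def validate_survival_table(surv: pd.DataFrame, require_clinical: bool = False) -> pd.DataFrame:
    """Check a survival table: positive times, 0/1 events, no missing time/event.

    Returns the table unchanged; raises :class:`MiraxError` on violations.
    """
    for col in SURVIVAL_COLUMNS:
        if col not in surv.columns:
            raise MiraxError(f"survival table missing column {col!r}")
    if surv["time_months"].isna().any() or surv["event"].isna().any():
        raise MiraxError("survival table has missing time or event values")
    if (surv["time_months"] <= 0).any():
        raise MiraxError("survival times must be positive")
    if not surv["event"].isin([0, 1]).all():
        raise MiraxError("event indicator must be 0/1")
    if require_clinical:
        for col in CLINICAL_COLUMNS:
            if col not in surv.columns:
                raise MiraxError(f"survival table missing clinical column {col!r}")
    return surv


@dataclass(frozen=True)
class AxisDefinition:
    """One miRNA-mRNA regulatory axis: a miRNA, its direction, and the
    predicted targets whose differential-expression direction is opposite."""

    mirna_id: str
    direction: str  # "up" | "down"
    supported_targets: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise MiraxError(f"axis direction must be 'up' or 'down', got {self.direction!r}")

    @property
    def n_targets(self) -> int:
        return len(self.supported_targets)


@dataclass
class TargetPredictionPair:
    """Predicted target sets per miRNA from two prediction resources.

    ``intersection`` holds, per miRNA, only genes predicted by both sources.
    """

    sourceA: dict[str, frozenset[str]]
    sourceB: dict[str, frozenset[str]]

    @property
    def intersection(self) -> dict[str, frozenset[str]]:
        mirnas = set(self.sourceA) & set(self.sourceB)
        return {m: frozenset(self.sourceA[m]) & frozenset(self.sourceB[m]) for m in mirnas}

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for source, mapping in (("A", self.sourceA), ("B", self.sourceB)):
            for mirna, targets in sorted(mapping.items()):
                for t in sorted(targets):
                    rows.append((mirna, t, source))
        pd.DataFrame(rows, columns=["mirna_id", "target_symbol", "source"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TargetPredictionPair":
        df = pd.read_csv(path, sep="\t")
        out: dict[str, dict[str, set[str]]] = {"A": {}, "B": {}}
        for mirna, target, source in df[["mirna_id", "target_symbol", "source"]].itertuples(index=False):
            out[str(source)].setdefault(str(mirna), set()).add(str(target))
        return cls(
            sourceA={m: frozenset(s) for m, s in out["A"].items()},
            sourceB={m: frozenset(s) for m, s in out["B"].items()},
        )


def harmonize_symbols(symbols: Iterable[str], alias_map: dict[str, str] | None = None) -> list[str]:
    """Uppercase gene symbols and apply an optional alias -> canonical map.

    Deterministic stand-in for full HGNC harmonization; real alias tables can
    be supplied through ``alias_map``.
    """
    alias_map = {k.upper(): v.upper() for k, v in (alias_map or {}).items()}
    out = []
    for s in symbols:
        u = str(s).upper()
        out.append(alias_map.get(u, u))
    return out
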