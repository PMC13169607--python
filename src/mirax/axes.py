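"""Cross-cohort consensus sets, inverse-direction target filtering and ORA.

A regulatory *axis* is a differentially expressed miRNA paired with the
predicted targets whose own differential-expression direction is opposite
to the miRNA's: an upregulated miRNA with consensus-downregulated targets
(candidate repression) and vice versa.  Predicted targets must appear in
both prediction resources before the direction filter is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy import stats

from .containers import AxisDefinition, MiraxError, TargetPredictionPair
from .de import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusSets",
    "EnrichmentResult",
    "consensus_degs",
    "consensus_mirnas",
    "inverse_filter",
    "build_axes",
    "build_bipartite",
    "ora_enrich",
]


@dataclass(frozen=True)
class ConsensusSets:
    """Genes differentially expressed in the same direction in every cohort."""

    up: frozenset[str]
    down: frozenset[str]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise MiraxError("consensus up and down sets must be disjoint")


@dataclass
class EnrichmentResult:
    """Hypergeometric over-representation result, one row per term.

    Columns: ``term_id``, ``k`` (query-term overlap), ``K`` (term size in
    universe), ``n`` (query size in universe), ``N`` (universe size), ``p``
    (upper-tail hypergeometric), ``q`` (BH across tested terms).
    """

    table: pd.DataFrame
    universe_size: int = 0


def consensus_degs(
    sets_by_cohort: list[tuple[frozenset[str] | set[str], frozenset[str] | set[str]]],
    cohort_ids: list[str] | None = None,
) -> ConsensusSets:
    """Intersect per-cohort (up, down) DEG sets into direction-concordant consensus sets."""
    if not sets_by_cohort:
        raise MiraxError("consensus_degs needs at least one cohort")
    up = frozenset(sets_by_cohort[0][0])
    down = frozenset(sets_by_cohort[0][1])
    for u, d in sets_by_cohort[1:]:
        up &= frozenset(u)
        down &= frozenset(d)
    # a gene significant in opposite directions across cohorts is discordant
    discordant = up & down
    if discordant:
        up -= discordant
        down -= discordant
    if not up and not down:
        logger.warning("consensus DEG sets are empty (disjoint cohorts?)")
    prov = tuple(cohort_ids) if cohort_ids else tuple(f"cohort{i}" for i in range(len(sets_by_cohort)))
    return ConsensusSets(up=up, down=down, provenance=prov)


def consensus_mirnas(
    results: list[tuple[frozenset[str] | set[str], frozenset[str] | set[str]]],
) -> list[tuple[str, str]]:
    """miRNAs significant with the same direction in every input design/cohort.

    Each input is an (up, down) pair of disjoint miRNA sets.  A miRNA
    appearing with conflicting directions is excluded (counted in the log,
    not an error).
    """
    if not results:
        raise MiraxError("consensus_mirnas needs at least one result")
    for u, d in results:
        if set(u) & set(d):
            raise MiraxError("each input's up/down sets must be disjoint")
    up = frozenset(results[0][0])
    down = frozenset(results[0][1])
    any_up = set().union(*(set(u) for u, _ in results))
    any_down = set().union(*(set(d) for _, d in results))
    for u, d in results[1:]:
        up &= frozenset(u)
        down &= frozenset(d)
    conflicted = any_up & any_down
    if conflicted:
        logger.info("%d miRNA(s) excluded for conflicting directions", len(conflicted))
        up -= conflicted
        down -= conflicted
    out = [(m, "up") for m in sorted(up)] + [(m, "down") for m in sorted(down)]
    return out


def inverse_filter(
    mirna: tuple[str, str],
    predicted: frozenset[str] | set[str],
    consensus: ConsensusSets,
) -> AxisDefinition:
    """Keep predicted targets whose consensus DE direction opposes the miRNA's."""
    mirna_id, direction = mirna
    if direction == "up":
        supported = frozenset(predicted) & consensus.down
    elif direction == "down":
        supported = frozenset(predicted) & consensus.up
    else:
        raise MiraxError(f"unknown miRNA direction {direction!r}")
    if not supported:
        logger.warning("axis %s (%s): no DEG-supported targets", mirna_id, direction)
    return AxisDefinition(mirna_id=mirna_id, direction=direction, supported_targets=supported)


def build_axes(
    mirnas: list[tuple[str, str]],
    targets: TargetPredictionPair,
    consensus: ConsensusSets,
) -> list[AxisDefinition]:
    """Apply the two-source intersection and inverse-direction filter per miRNA."""
    inter = targets.intersection
    axes = []
    for mirna_id, direction in mirnas:
        predicted = inter.get(mirna_id, frozenset())
        axes.append(inverse_filter((mirna_id, direction), predicted, consensus))
    return axes


def build_bipartite(axes: list[AxisDefinition]) -> nx.Graph:
    """Bipartite miRNA-target graph with node type/direction attributes."""
    if not axes:
        raise MiraxError("build_bipartite needs at least one axis")
    g = nx.Graph()
    for axis in axes:
        g.add_node(axis.mirna_id, kind="mirna", direction=axis.direction, bipartite=0)
        for t in sorted(axis.supported_targets):
            if t not in g:
                g.add_node(t, kind="gene", bipartite=1)
            g.add_edge(axis.mirna_id, t)
    return g


def write_network(g: nx.Graph, edge_tsv: str | Path, graphml: str | Path | None = None) -> None:
    rows = [
        (u, v) if g.nodes[u].get("kind") == "mirna" else (v, u)
        for u, v in sorted(g.edges())
    ]
    pd.DataFrame(rows, columns=["mirna_id", "target_symbol"]).to_csv(
        edge_tsv, sep="\t", index=False
    )
    if graphml is not None:
        nx.write_graphml(g, graphml)


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT gene-set file: term <tab> description <tab> genes..."""
    terms: dict[str, frozenset[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise MiraxError(f"malformed GMT line: {line[:60]!r}")
        terms[parts[0]] = frozenset(g for g in parts[2:] if g)
    return terms


def ora_enrich(
    query: frozenset[str] | set[str],
    terms: dict[str, frozenset[str] | set[str]],
    universe: frozenset[str] | set[str],
    min_term_size: int = 3,
    max_term_size: int = 500,
) -> EnrichmentResult:
    """Hypergeometric over-representation of ``query`` in each term.

    Terms are clipped to the universe and kept only if their within-universe
    size is in [min_term_size, max_term_size].  Query symbols outside the
    universe are dropped with a warning.  ``p = P[X >= k]`` for
    ``X ~ Hypergeometric(N, K, n)``; BH across tested terms.
    """
    universe = frozenset(universe)
    if not universe:
        raise MiraxError("empty gene universe")
    query = frozenset(query)
    outside = query - universe
    if outside:
        logger.warning("%d query symbol(s) outside the universe dropped", len(outside))
    query &= universe
    N, n = len(universe), len(query)
    rows = []
    for term_id, members in terms.items():
        members = frozenset(members) & universe
        K = len(members)
        if K < min_term_size or K > max_term_size:
            continue
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, k, K, n, N, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p"])
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        table["q"] = pd.Series(dtype=float)
    return EnrichmentResult(table=table, universe_size=N)
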