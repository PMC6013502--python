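"""Clustering of association patterns into cis-regulatory modules (cRM).

Patterns whose anchors lie within a pairing radius are compared with
theta; edges with |theta| above threshold (default 0.6) define a graph
whose connected components are the modules (single-link clustering).
Modules are classified as single-gene/single-tissue, single-gene/
multi-tissue, or multi-gene, and cell-type sharing of modules is tested
against a random-assortment null by simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .theta import AssociationPattern, ThetaParams, compare_patterns

logger = logging.getLogger(__name__)

SINGLE_GENE_SINGLE_TISSUE = "single-gene/single-tissue"
SINGLE_GENE_MULTI_TISSUE = "single-gene/multi-tissue"
MULTI_GENE = "multi-gene"


@dataclass
class PatternMeta:
    """Gene/tissue annotation of one association pattern node."""

    pattern_id: str
    gene: str
    tissue: str


@dataclass
class RegulatoryModule:
    module_id: str
    members: list[PatternMeta]
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def genes(self) -> set[str]:
        return {m.gene for m in self.members}

    @property
    def tissues(self) -> set[str]:
        return {m.tissue for m in self.members}

    @property
    def label(self) -> str:
        return classify_module(self)


def classify_module(module: RegulatoryModule) -> str:
    """Three-way class label from the member gene and tissue sets."""
    if len(module.genes) > 1:
        return MULTI_GENE
    if len(module.tissues) > 1:
        return SINGLE_GENE_MULTI_TISSUE
    return SINGLE_GENE_SINGLE_TISSUE


# ---------------------------------------------------------------------------
# graph construction and clustering


def pairwise_theta(
    patterns: dict[str, AssociationPattern],
    params: ThetaParams | None = None,
    pairing_radius: float = 2_000_000.0,
) -> pd.DataFrame:
    """theta for every pattern pair whose anchors are within the radius."""
    params = params or ThetaParams()
    rows = []
    ids = sorted(patterns)
    for ia, ib in combinations(ids, 2):
        a, b = patterns[ia], patterns[ib]
        if a.anchor[0] != b.anchor[0]:
            continue
        if abs(a.anchor[1] - b.anchor[1]) > pairing_radius:
            continue
        cmp = compare_patterns(a, b, params)
        rows.append(
            (ia, ib, cmp.r_w, cmp.r_ws, cmp.theta, cmp.n_informative, cmp.defined)
        )
    return pd.DataFrame(
        rows, columns=["a", "b", "r_w", "r_ws", "theta", "n_informative", "defined"]
    )


def build_theta_graph(
    theta_table: pd.DataFrame,
    node_ids,
    threshold: float = 0.6,
) -> nx.Graph:
    """Nodes for all patterns; edges where |theta| > threshold (sign kept)."""
    g = nx.Graph()
    g.add_nodes_from(node_ids)
    for row in theta_table.itertuples(index=False):
        if getattr(row, "defined", True) and abs(row.theta) > threshold:
            g.add_edge(row.a, row.b, theta=float(row.theta))
    return g


def prune_edges(graph: nx.Graph, removal_list) -> nx.Graph:
    """Delete listed edges (pairs of node ids) before clustering."""
    g = graph.copy()
    for a, b in removal_list:
        if g.has_edge(a, b):
            g.remove_edge(a, b)
            logger.info("pruned edge %s -- %s", a, b)
        else:
            logger.warning("edge %s -- %s not in graph; skipped", a, b)
    return g


def single_link_cluster(
    graph: nx.Graph, meta: dict[str, PatternMeta]
) -> list[RegulatoryModule]:
    """Connected components as modules; singletons form their own modules.

    Module ids are assigned deterministically in order of the smallest
    member pattern id.
    """
    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    modules = []
    for k, comp in enumerate(comps):
        members = [meta[pid] for pid in sorted(comp)]
        edges = [
            (a, b, d["theta"]) for a, b, d in graph.subgraph(comp).edges(data=True)
        ]
        modules.append(RegulatoryModule(f"cRM{k:04d}", members, edges))
    return modules


def cluster_patterns(
    patterns: dict[str, AssociationPattern],
    meta: dict[str, PatternMeta],
    threshold: float = 0.6,
    params: ThetaParams | None = None,
    pairing_radius: float = 2_000_000.0,
    removal_list=(),
) -> tuple[list[RegulatoryModule], pd.DataFrame]:
    """Full clustering pipeline; returns (modules, theta edge table)."""
    table = pairwise_theta(patterns, params, pairing_radius)
    graph = build_theta_graph(table, patterns.keys(), threshold)
    if removal_list:
        graph = prune_edges(graph, removal_list)
    return single_link_cluster(graph, meta), table


def filter_modules_by_max_cells(modules, max_cells: int):
    """Modules involving no more than ``max_cells`` tissues."""
    return [m for m in modules if len(m.tissues) <= max_cells]


# ---------------------------------------------------------------------------
# composition reports


def class_composition(modules_or_counts) -> dict[str, float]:
    """Percentage of modules per class, rounded to whole percent.

    Accepts either a list of modules or a mapping class label -> count.
    """
    if isinstance(modules_or_counts, dict):
        counts = dict(modules_or_counts)
    else:
        counts = {}
        for m in modules_or_counts:
            counts[m.label] = counts.get(m.label, 0) + 1
    total = sum(counts.values())
    return {k: round(100.0 * v / total) for k, v in counts.items()}


def multigenic_fold_enrichment(
    n_multigenic_matching: int,
    n_matching: int,
    n_multigenic_total: int,
    n_total: int,
) -> tuple[float, float]:
    """(matching multigenic fraction, fold enrichment over the baseline)."""
    frac = n_multigenic_matching / n_matching
    baseline = n_multigenic_total / n_total
    return frac, frac / baseline


# ---------------------------------------------------------------------------
# excess sharing of modules between cell types


@dataclass
class SharingCounts:
    """Per-cell-type module counts and pairwise sharing counts.

    ``n_tT[t]`` is the number of modules containing tissue t; ``n_tu[(t,u)]``
    the number containing both t and u (symmetric).
    """

    n_tT: dict[str, int]
    n_tu: dict[tuple[str, str], int]

    def pair(self, t: str, u: str) -> int:
        return self.n_tu.get((t, u), self.n_tu.get((u, t), 0))

    def n_tS(self, t: str) -> int:
        return sum(self.pair(t, u) for u in self.n_tT if u != t)


def sharing_counts(modules, tissues=None) -> SharingCounts:
    tissues = sorted(tissues or {t for m in modules for t in m.tissues})
    n_tT = {t: sum(t in m.tissues for m in modules) for t in tissues}
    n_tu = {
        (t, u): sum(t in m.tissues and u in m.tissues for m in modules)
        for t, u in combinations(tissues, 2)
    }
    return SharingCounts(n_tT, n_tu)


def sharing_enrichment(
    counts: SharingCounts,
    reference: str,
    target: str,
    n_sims: int = 5000,
    rng: np.random.Generator | None = None,
) -> float:
    """p value for excess sharing between two cell types.

    The reference tissue's total sharing events are reassigned to the
    other tissues with probabilities proportional to their module counts
    (multinomial); p is the add-one fraction of simulations reaching the
    observed pairwise count for the target tissue.
    """
    rng = rng or np.random.default_rng()
    others = [t for t in counts.n_tT if t != reference]
    n_ts = counts.n_tS(reference)
    if n_ts == 0:
        return 1.0
    weights = np.array([counts.n_tT[t] for t in others], dtype=float)
    probs = weights / weights.sum()
    observed = counts.pair(reference, target)
    sims = rng.multinomial(n_ts, probs, size=n_sims)
    col = others.index(target)
    exceed = int(np.sum(sims[:, col] >= observed))
    return (1 + exceed) / (n_sims + 1)


def expected_sharing(counts: SharingCounts, reference: str, target: str) -> float:
    """Random-assortment expectation n_tS * n_uT / sum_{j != t} n_jT."""
    others = [t for t in counts.n_tT if t != reference]
    denom = sum(counts.n_tT[t] for t in others)
    return counts.n_tS(reference) * counts.n_tT[target] / denom
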