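"""Specific-enrichment (SE) and clustering-quality (CQ) metrics.

Given enrichment results for a set of clusters (term, p <= 0.05) and minimal
depths of the enriched terms in an ontology DAG, a term is *specific* when its
minimal depth from the root exceeds a threshold (the mean minimal depth over
the whole ontology snapshot, or an explicit value).  Then

    SE_i = |specific enriched terms_i| / |enriched terms_i|
    CQ   = sum_i SE_i * N_i          (N_i = number of genes in cluster i)

and the loss-information ratio of a clustering against a reference is
1 - CQ / CQ_ref.  Enrichment tables are inputs; no enrichment testing is
performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd

__all__ = [
    "EnrichedCluster",
    "read_term_dag",
    "min_depth",
    "mean_min_depth",
    "se_index",
    "clustering_quality",
    "loss_information_ratio",
]

ENRICHMENT_P_CUTOFF = 0.05


@dataclass(frozen=True)
class EnrichedCluster:
    """One cluster's enriched terms (p <= 0.05) and their minimal depths."""

    cluster_id: str
    n_genes: int
    enriched_terms: frozenset[str]
    term_depths: Mapping[str, int] = field(default_factory=dict)

    @classmethod
    def from_table(cls, cluster_id: str, n_genes: int,
                   terms: Iterable[tuple[str, float]],
                   term_depths: Mapping[str, int]) -> "EnrichedCluster":
        keep = frozenset(t for t, p in terms if p <= ENRICHMENT_P_CUTOFF)
        return cls(cluster_id, n_genes, keep, dict(term_depths))


def read_term_dag(path) -> nx.DiGraph:
    """Read a two-column TSV (child, parent) into a parent->child DiGraph."""
    df = pd.read_csv(path, sep="\t", header=None, names=["child", "parent"],
                     comment="#", dtype=str)
    g = nx.DiGraph()
    for child, parent in zip(df["child"], df["parent"]):
        g.add_edge(parent, child)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("term relation table contains a cycle")
    return g


def min_depth(dag: nx.DiGraph, root: str, term: str) -> int:
    """Length of the shortest root->term path in the ontology DAG."""
    try:
        return nx.shortest_path_length(dag, root, term)
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        raise ValueError(f"term {term!r} is not reachable from root {root!r}")


def mean_min_depth(dag: nx.DiGraph, root: str) -> float:
    """Mean minimal depth over all terms reachable from the root."""
    depths = nx.single_source_shortest_path_length(dag, root)
    return sum(depths.values()) / len(depths)


def se_index(cluster: EnrichedCluster, depth_threshold: float = 7.07) -> float:
    """Fraction of the cluster's enriched terms strictly deeper than threshold."""
    if not cluster.enriched_terms:
        raise ValueError(
            f"SE undefined for cluster {cluster.cluster_id!r}: no enriched terms"
        )
    specific = sum(
        1 for t in cluster.enriched_terms
        if cluster.term_depths[t] > depth_threshold
    )
    return specific / len(cluster.enriched_terms)


def clustering_quality(clusters: Iterable[EnrichedCluster],
                       depth_threshold: float = 7.07) -> float:
    """CQ = sum of SE_i * N_i; clusters with no enriched terms contribute 0."""
    total = 0.0
    for c in clusters:
        if not c.enriched_terms:
            continue
        total += se_index(c, depth_threshold) * c.n_genes
    return total


def loss_information_ratio(cq: float, cq_reference: float) -> float:
    """1 - CQ / CQ_ref: quality lost relative to an unclustered reference."""
    if cq_reference <= 0:
        raise ValueError("reference CQ must be positive")
    return 1.0 - cq / cq_reference
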