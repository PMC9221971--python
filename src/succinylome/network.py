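"""Confidence-filtered interaction subnetworks and node degrees.

Edges come from a STRING-style export (protein_a, protein_b, combined_score).
Scores above 1 anywhere in the table are taken to be the 0–1000 integer
convention and rescaled to [0, 1] (logged).  The high-confidence cut keeps
edges with confidence strictly greater than the threshold (default 0.7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class NetworkConfig:
    min_confidence: float = 0.7  # strict: keep confidence > min_confidence

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValueError("min_confidence must be in [0, 1]")


def build_network(edges: pd.DataFrame) -> nx.Graph:
    """Undirected graph from an edge table; duplicate undirected edges are
    collapsed (keeping the highest confidence) and self-loops dropped."""
    scores = edges["combined_score"].astype(float)
    if (scores > 1.0).any():
        logger.info("detected STRING 0-1000 scores; rescaling to [0, 1]")
        scores = scores / 1000.0
    if ((scores < 0) | (scores > 1)).any():
        raise ValueError("confidence scores must lie in [0, 1] (or 0-1000)")
    graph = nx.Graph()
    for a, b, conf in zip(edges["protein_a"], edges["protein_b"], scores):
        if a == b:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["confidence"] = max(graph[a][b]["confidence"], float(conf))
        else:
            graph.add_edge(a, b, confidence=float(conf))
    return graph


def filter_edges(graph: nx.Graph, config: NetworkConfig | None = None) -> nx.Graph:
    """Keep only edges with confidence strictly above the threshold.

    Nodes are preserved even when all their edges fall away, so isolated
    proteins still appear (with degree 0) downstream.
    """
    config = config or NetworkConfig()
    out = nx.Graph()
    out.add_nodes_from(graph.nodes)
    out.add_edges_from(
        (a, b, d)
        for a, b, d in graph.edges(data=True)
        if d["confidence"] > config.min_confidence
    )
    return out


def subnetwork(graph: nx.Graph, keep: Iterable[str]) -> nx.Graph:
    """Induced subgraph on ``keep`` ∩ nodes (a standalone copy)."""
    keep = set(keep) & set(graph.nodes)
    return nx.Graph(graph.subgraph(keep))


def node_degrees(graph: nx.Graph) -> dict[str, int]:
    """Undirected degree per node; isolated nodes report 0."""
    return dict(graph.degree())


def degree_table(graph: nx.Graph) -> pd.DataFrame:
    degrees = node_degrees(graph)
    return (
        pd.DataFrame({"protein": list(degrees), "degree": list(degrees.values())})
        .sort_values(["degree", "protein"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
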