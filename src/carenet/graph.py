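"""Build the weighted patient-sharing provider graph from visits.

Nodes are providers; an edge's weight is the number of distinct patients who
visited both endpoints during the study period (a patient counts at most
once per provider pair, however many times they co-visited). Edges carried
by a single shared patient are pruned so only the stable patient-sharing
relationships remain.
"""

from __future__ import annotations

import logging
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from carenet.config import ConfigurationError

logger = logging.getLogger(__name__)


def build_shared_patient_graph(visits: pd.DataFrame) -> nx.Graph:
    """Construct the shared-patient graph from a visit table.

    The node set is every provider present in the visits; for each patient,
    each unordered pair of distinct providers they visited contributes one
    shared patient to that pair's edge weight.
    """
    graph = nx.Graph()
    if visits.empty:
        logger.warning("empty visit table: returning empty graph")
        return graph
    graph.add_nodes_from(visits["npi"].unique())
    pairs: dict[tuple[str, str], int] = {}
    per_patient = (
        visits[["patient_id", "npi"]]
        .drop_duplicates()
        .sort_values(["patient_id", "npi"])
        .groupby("patient_id")["npi"]
    )
    for _, npis in per_patient:
        for u, v in combinations(npis.tolist(), 2):
            pairs[(u, v)] = pairs.get((u, v), 0) + 1
    graph.add_weighted_edges_from((u, v, w) for (u, v), w in pairs.items())
    return graph


def prune_edges(graph: nx.Graph, min_shared: int = 2) -> tuple[nx.Graph, list[str]]:
    """Drop edges below ``min_shared`` shared patients; remove new isolates.

    Nodes isolated by the pruning cannot join any detected community, so
    they are removed from the graph and returned for reporting.
    """
    if min_shared < 1:
        raise ConfigurationError("min_shared must be >= 1")
    pruned = graph.copy()
    weak = [
        (u, v) for u, v, w in pruned.edges(data="weight") if w < min_shared
    ]
    pruned.remove_edges_from(weak)
    isolates = sorted(nx.isolates(pruned))
    pruned.remove_nodes_from(isolates)
    if isolates:
        logger.info("pruning isolated %d providers", len(isolates))
    return pruned, isolates


def node_strengths(graph: nx.Graph) -> dict[str, float]:
    """Weighted degree (sum of incident edge weights) per node."""
    return dict(graph.degree(weight="weight"))


def total_weight(graph: nx.Graph) -> float:
    """Sum of edge weights, m."""
    return graph.size(weight="weight")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write a 3-column weighted edge list (npi_u, npi_v, weight) CSV."""
    rows = [
        {"npi_u": min(u, v), "npi_v": max(u, v), "weight": w}
        for u, v, w in graph.edges(data="weight")
    ]
    df = pd.DataFrame(rows, columns=["npi_u", "npi_v", "weight"]).sort_values(
        ["npi_u", "npi_v"]
    )
    df.to_csv(path, index=False)


def read_edge_list(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, dtype={"npi_u": str, "npi_v": str})
    graph = nx.Graph()
    graph.add_weighted_edges_from(df.itertuples(index=False, name=None))
    return graph
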