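"""Weighted modularity community detection on the patient-sharing graph.

Modularity of a partition is

    Q = (1/2m) * sum_ij [A_ij - k_i * k_j / (2m)] * delta(c_i, c_j)

with A_ij the shared-patient edge weights, k_i the node strengths, and
m the total edge weight: the within-community weight minus its expectation
under a strength-preserving random graph.

Detection is the fast-greedy agglomerative maximizer (Clauset-Newman-Moore):
start from singleton communities and repeatedly merge the connected pair of
communities with the largest modularity gain, stopping when no merge
improves Q. Merge ties are broken lexicographically on the communities'
smallest member labels, so detection is deterministic without a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from carenet.config import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExclusionSummary:
    n_communities: int
    n_providers: int
    mean_size: float


@dataclass(frozen=True)
class Partition:
    """A non-overlapping node -> community labeling.

    Labels are contiguous integers 1..K ordered by descending community
    size (ties on size broken by smallest member label).
    """

    assignment: dict[str, int]
    modularity: float
    sizes: dict[int, int]
    excluded: list[tuple[int, int]] = field(default_factory=list)

    @property
    def labels(self) -> list[int]:
        return sorted(self.sizes)

    def members(self, label: int) -> list[str]:
        return sorted(n for n, c in self.assignment.items() if c == label)

    def exclusion_summary(self) -> ExclusionSummary:
        n = len(self.excluded)
        total = sum(size for _, size in self.excluded)
        return ExclusionSummary(n, total, total / n if n else 0.0)


def modularity(graph: nx.Graph, assignment: dict[str, int]) -> float:
    """Weighted Newman-Girvan modularity of an assignment."""
    missing = [n for n in graph.nodes if n not in assignment]
    if missing:
        raise ValueError(f"assignment is missing node(s): {missing[:5]}")
    m = graph.size(weight="weight")
    if m <= 0:
        raise ValueError("modularity requires a graph with positive total weight")
    strengths = dict(graph.degree(weight="weight"))
    internal: dict[int, float] = {}
    strength_sum: dict[int, float] = {}
    for node in graph.nodes:
        c = assignment[node]
        strength_sum[c] = strength_sum.get(c, 0.0) + strengths[node]
    for u, v, w in graph.edges(data="weight", default=1):
        if assignment[u] == assignment[v]:
            internal[assignment[u]] = internal.get(assignment[u], 0.0) + w
    q = 0.0
    for c, s in strength_sum.items():
        q += internal.get(c, 0.0) / m - (s / (2.0 * m)) ** 2
    return q


def _relabel_by_size(groups: list[set[str]]) -> tuple[dict[str, int], dict[int, int]]:
    """Label groups 1..K by descending size, ties by smallest member."""
    ordered = sorted(groups, key=lambda g: (-len(g), min(g)))
    assignment: dict[str, int] = {}
    sizes: dict[int, int] = {}
    for label, group in enumerate(ordered, start=1):
        sizes[label] = len(group)
        for node in group:
            assignment[node] = label
    return assignment, sizes


def detect_communities(graph: nx.Graph) -> Partition:
    """Greedy agglomerative weighted modularity maximization.

    Communities start as singletons; at each step the connected community
    pair with the largest positive modularity gain

        dQ = 2 * (e_ij - a_i * a_j)

    is merged, where e_ij is the between-pair weight over 2m and a_i the
    community strength over 2m. Disconnected components never merge
    (their gain is always negative). Ties on dQ are broken by the
    lexicographically smallest pair of community representatives (each
    community represented by its minimum node label).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot detect communities on an empty graph")
    m = graph.size(weight="weight")
    if m <= 0:
        # Edgeless graph: every node is its own community, Q undefined -> 0.
        groups = [{n} for n in graph.nodes]
        assignment, sizes = _relabel_by_size(groups)
        return Partition(assignment=assignment, modularity=0.0, sizes=sizes)

    two_m = 2.0 * m
    # Community state: id -> members, strength fraction a_i, and the
    # between-community weight fractions e_ij (symmetric dict-of-dicts).
    comm_members: dict[int, set[str]] = {}
    rep: dict[int, str] = {}
    a: dict[int, float] = {}
    e: dict[int, dict[int, float]] = {}
    node_comm: dict[str, int] = {}
    for idx, node in enumerate(sorted(graph.nodes)):
        comm_members[idx] = {node}
        rep[idx] = node
        a[idx] = graph.degree(node, weight="weight") / two_m
        e[idx] = {}
        node_comm[node] = idx
    for u, v, w in graph.edges(data="weight", default=1):
        cu, cv = node_comm[u], node_comm[v]
        if cu == cv:
            continue
        e[cu][cv] = e[cu].get(cv, 0.0) + w / two_m
        e[cv][cu] = e[cv].get(cu, 0.0) + w / two_m

    while True:
        best_gain = 0.0
        best_pair: tuple[str, str] | None = None
        best_ids: tuple[int, int] | None = None
        for ci in comm_members:
            for cj, eij in e[ci].items():
                if cj <= ci:
                    continue
                gain = 2.0 * (eij - a[ci] * a[cj])
                if gain <= 1e-15:
                    continue
                lo, hi = sorted((rep[ci], rep[cj]))
                if (
                    best_pair is None
                    or gain > best_gain + 1e-15
                    or (abs(gain - best_gain) <= 1e-15 and (lo, hi) < best_pair)
                ):
                    best_gain = gain
                    best_pair = (lo, hi)
                    best_ids = (ci, cj)
        if best_ids is None:
            break
        ci, cj = best_ids
        comm_members[ci] |= comm_members.pop(cj)
        rep[ci] = min(rep[ci], rep[cj])
        a[ci] += a.pop(cj)
        for ck, ejk in e.pop(cj).items():
            if ck == ci:
                continue
            e[ck].pop(cj, None)
            e[ci][ck] = e[ci].get(ck, 0.0) + ejk
            e[ck][ci] = e[ci][ck]
        e[ci].pop(cj, None)

    assignment, sizes = _relabel_by_size(list(comm_members.values()))
    q = modularity(graph, assignment)
    return Partition(assignment=assignment, modularity=q, sizes=sizes)


def _set_partitions(items: list[str]):
    """Yield all set partitions of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in _set_partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [partial[i] | {first}] + partial[i + 1 :]
        yield partial + [{first}]


def brute_force_max_modularity(graph: nx.Graph) -> tuple[dict[str, int], float]:
    """Exhaustive maximum-modularity partition for graphs of <= 10 nodes.

    Test oracle only: enumerates every set partition of the node set and
    returns the global optimum.
    """
    n = graph.number_of_nodes()
    if n > 10:
        raise ValueError(f"brute force limited to 10 nodes, got {n}")
    if n == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes)
    best_q = float("-inf")
    best: dict[str, int] = {}
    for groups in _set_partitions(nodes):
        assignment = {node: i for i, group in enumerate(groups) for node in group}
        q = modularity(graph, assignment)
        if q > best_q:
            best_q = q
            best = assignment
    return best, best_q


def filter_small_communities(partition: Partition, min_size: int = 50) -> Partition:
    """Exclude communities below ``min_size`` providers, relabel the rest.

    Retained communities are relabeled 1..K by descending size; excluded
    communities are recorded as (original label, size) pairs for the run
    report. Raises if nothing survives.
    """
    if min_size < 1:
        raise ConfigurationError("min_size must be >= 1")
    retained_labels = {c for c, s in partition.sizes.items() if s >= min_size}
    excluded = sorted(
        (c, s) for c, s in partition.sizes.items() if s < min_size
    )
    if not retained_labels:
        raise ValueError(
            "every community falls below min_size "
            f"({min_size}); lower --min-community-size"
        )
    groups: dict[int, set[str]] = {c: set() for c in retained_labels}
    for node, c in partition.assignment.items():
        if c in retained_labels:
            groups[c].add(node)
    assignment, sizes = _relabel_by_size(list(groups.values()))
    summary = ExclusionSummary(
        len(excluded),
        sum(s for _, s in excluded),
        (sum(s for _, s in excluded) / len(excluded)) if excluded else 0.0,
    )
    logger.info(
        "excluded %d communities (%d providers, mean size %.1f)",
        summary.n_communities,
        summary.n_providers,
        summary.mean_size,
    )
    return Partition(
        assignment=assignment,
        modularity=partition.modularity,
        sizes=sizes,
        excluded=excluded,
    )
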