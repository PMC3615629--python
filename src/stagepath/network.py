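"""Confidence-weighted interaction graph and weighted shortest paths.

Each interaction carries a confidence score ``s`` in [0.150, 1].  The graph
distance ("intimacy weight") of an edge is ``1000 * (1 - s)``, so highly
confident interactions are short: a score of 0.700 (the conventional
"high confidence" cutoff) maps to a distance of 300, which is also the
path-length threshold used downstream by the transition screen.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import networkx as nx

from .cohort import SCORE_MAX, SCORE_MIN, ConfidenceEdgeList

#: edge distance of a score-0.700 interaction; the screening length cutoff
HIGH_CONFIDENCE_LENGTH = 300.0


def _check_score(score: float) -> None:
    if not (SCORE_MIN <= score <= SCORE_MAX):
        raise ValueError(
            f"confidence score {score!r} outside admissible range "
            f"[{SCORE_MIN}, {SCORE_MAX}]"
        )


def classify_confidence(score: float) -> str:
    """Rank a confidence score as low / medium / high / highest.

    Thresholds are strict: ``highest`` iff score > 0.900, ``high`` iff
    > 0.700, ``medium`` iff > 0.400, otherwise ``low``.  The admissible
    range is [0.150, 1] inclusive; 0.150 itself classifies as low.
    """
    _check_score(score)
    if score > 0.900:
        return "highest"
    if score > 0.700:
        return "high"
    if score > 0.400:
        return "medium"
    return "low"


def intimacy_weight(score: float) -> float:
    """Edge distance ``1000 * (1 - score)`` of a confidence score."""
    _check_score(score)
    return 1000.0 * (1.0 - score)


def build_graph(edges: ConfidenceEdgeList) -> nx.Graph:
    """Undirected simple graph with ``score`` and ``intimacy`` per edge."""
    g = nx.Graph()
    for a, b, s in edges:
        g.add_edge(a, b, score=float(s), intimacy=intimacy_weight(float(s)))
    return g


@dataclass
class PathResult:
    """A weighted shortest path between two proteins.

    ``length`` is the exact sum of intimacy weights along the edges;
    ``math.inf`` when the endpoints are disconnected.
    """

    node_sequence: list[str]
    length: float
    reachable: bool

    @property
    def interior(self) -> list[str]:
        return self.node_sequence[1:-1]


def shortest_path(graph: nx.Graph, source: str, target: str) -> PathResult:
    """Minimum-intimacy path with deterministic tie-breaking.

    Among equal-length paths the one with fewer hops wins; remaining ties
    are broken by lexicographic node sequence.  This makes "the" shortest
    path reproducible, which matters because interior nodes feed the
    transition-hub counts.
    """
    for node in (source, target):
        if node not in graph:
            raise KeyError(f"unknown node symbol {node!r}")
    if source == target:
        raise ValueError("source and target must differ")

    # label-setting search on the key (length, hops, node sequence); the key
    # is monotone under edge extension, so the first pop of a node is optimal
    done: set[str] = set()
    heap: list[tuple[float, int, tuple[str, ...]]] = [(0.0, 0, (source,))]
    while heap:
        dist, hops, path = heapq.heappop(heap)
        node = path[-1]
        if node in done:
            continue
        done.add(node)
        if node == target:
            return PathResult(list(path), dist, True)
        for nbr, attrs in graph.adj[node].items():
            if nbr not in done:
                heapq.heappush(heap, (dist + attrs["intimacy"], hops + 1, path + (nbr,)))
    return PathResult([], math.inf, False)


def single_source_lengths(graph: nx.Graph, source: str) -> dict[str, float]:
    """Dijkstra distances from *source* under the intimacy weight."""
    if source not in graph:
        raise KeyError(f"unknown node symbol {source!r}")
    return nx.single_source_dijkstra_path_length(graph, source, weight="intimacy")
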