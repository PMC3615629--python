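"""Permutation-based significance for signal propagation paths.

The null model permutes gene symbols: a random bijection over the union
of network-node and cohort-gene symbols is applied simultaneously to graph
node labels and expression row labels (topology and expression values are
untouched).  For each permutation the shortest-path length and BH-adjusted
correlation FDR of every screened pair are recomputed under the relabeled
symbols; a path's FDR is

    FDR = N1 / N2,

where N1 counts permutations in which the permuted length is strictly
shorter than the actual length AND the permuted correlation FDR is
strictly smaller than the actual FDR, and N2 is the number of
permutations (20,000 by default).

Because a relabeling only moves symbols, the permuted statistic of pair
(e, l) equals the actual statistic of the inverse-permuted pair; the
implementation therefore precomputes all-pairs graph distances and the
gene-gene correlation p-value matrix once and indexes into them per
permutation, which is exactly equivalent to relabel-and-recompute (the
literal construction is available as :func:`permute_instance`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import csgraph_from_dense
from scipy.sparse.csgraph import dijkstra as csgraph_dijkstra

from .cohort import ExpressionCohort
from .screen import SignalPropagationPath, bh_fdr, pearson_p_from_r

logger = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 20_000


def permute_instance(
    graph: nx.Graph,
    cohort: ExpressionCohort,
    seed: int | np.random.Generator,
    joint: bool = True,
) -> tuple[nx.Graph, ExpressionCohort]:
    """Relabel graph nodes and cohort gene rows by random bijection(s).

    With ``joint=True`` (default) a single bijection over the symbol union
    is applied to both structures, keeping them mutually consistent; with
    ``joint=False`` two independent bijections are drawn.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    universe = sorted(set(graph.nodes) | set(cohort.gene_ids))

    def _mapping() -> dict[str, str]:
        perm = rng.permutation(len(universe))
        return {universe[i]: universe[perm[i]] for i in range(len(universe))}

    m_graph = _mapping()
    m_cohort = m_graph if joint else _mapping()
    new_graph = nx.relabel_nodes(graph, m_graph, copy=True)
    new_values = cohort.values.rename(index=m_cohort)
    return new_graph, ExpressionCohort(values=new_values, stages=cohort.stages)


@dataclass
class _NullTables:
    """Precomputed lookup tables for the vectorized permutation loop."""

    universe: list[str]
    u_gene: np.ndarray   # universe index -> cohort gene row, or -1
    u_node: np.ndarray   # universe index -> graph node index, or -1
    dist: np.ndarray     # all-pairs intimacy distances among graph nodes
    pmat: np.ndarray     # gene x gene two-sided Pearson p-values (nan = constant)


def _build_tables(graph: nx.Graph, cohort: ExpressionCohort) -> _NullTables:
    universe = sorted(set(graph.nodes) | set(cohort.gene_ids))
    uidx = {s: i for i, s in enumerate(universe)}

    nodes = sorted(graph.nodes)
    node_idx = {s: i for i, s in enumerate(nodes)}
    # dense + null_value=inf keeps zero-weight edges (score 1.0) as real edges
    dense = np.full((len(nodes), len(nodes)), np.inf)
    for a, b, d in graph.edges(data=True):
        i, j = node_idx[a], node_idx[b]
        dense[i, j] = dense[j, i] = d["intimacy"]
    if len(nodes):
        dist = csgraph_dijkstra(
            csgraph_from_dense(dense, null_value=np.inf), directed=False
        )
    else:
        dist = dense

    bc = cohort.samples_in(("B", "C"))
    X = cohort.values.loc[:, bc].to_numpy(dtype=float)
    c = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((c * c).sum(axis=1))
    const = norm == 0
    norm[const] = 1.0
    z = c / norm[:, None]
    r = np.clip(z @ z.T, -1.0, 1.0)
    pmat = pearson_p_from_r(r, len(bc))
    pmat = np.maximum(pmat, np.finfo(float).tiny)
    pmat[const, :] = np.nan
    pmat[:, const] = np.nan

    u_gene = np.full(len(universe), -1, dtype=np.int64)
    for i, g in enumerate(cohort.gene_ids):
        u_gene[uidx[g]] = i
    u_node = np.full(len(universe), -1, dtype=np.int64)
    for s, i in node_idx.items():
        u_node[uidx[s]] = i
    return _NullTables(universe, u_gene, u_node, dist, pmat)


def path_fdr(
    paths: list[SignalPropagationPath],
    graph: nx.Graph,
    cohort: ExpressionCohort,
    early_mapped: list[str],
    late_mapped: list[str],
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator | None = None,
    joint: bool = True,
) -> list[SignalPropagationPath]:
    """Fill each path's ``permutation_fdr`` in place and return the list.

    Per permutation the correlation FDR is recomputed over the same pair
    family as the actual screen (all ordered early x late pairs with
    distinct symbols whose permuted symbols both carry expression), so
    actual and permuted FDRs are comparable.  A pair unreachable in a
    permuted graph contributes an infinite length, which is never
    "shorter than" the actual one.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if not paths:
        return paths
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    tables = _build_tables(graph, cohort)
    uidx = {s: i for i, s in enumerate(tables.universe)}
    n_u = len(tables.universe)

    pairs = [
        (e, l) for e in early_mapped for l in late_mapped if e != l
    ]
    ei = np.array([uidx[e] for e, _ in pairs], dtype=np.int64)
    li = np.array([uidx[l] for _, l in pairs], dtype=np.int64)
    pair_pos = {pair: k for k, pair in enumerate(pairs)}
    path_pos = np.array([pair_pos[(p.early_gene, p.late_gene)] for p in paths])
    actual_len = np.array([p.length for p in paths])
    actual_fdr = np.array([p.correlation_fdr for p in paths])

    n1 = np.zeros(len(paths), dtype=np.int64)
    for _ in range(n_permutations):
        perm = rng.permutation(n_u)
        inv = np.argsort(perm)
        if joint:
            inv_net = inv_coh = inv
        else:
            perm2 = rng.permutation(n_u)
            inv_net, inv_coh = inv, np.argsort(perm2)

        ge = tables.u_gene[inv_coh[ei]]
        gl = tables.u_gene[inv_coh[li]]
        has_expr = (ge >= 0) & (gl >= 0)
        pvals = np.full(len(pairs), np.nan)
        pvals[has_expr] = tables.pmat[ge[has_expr], gl[has_expr]]
        valid = np.isfinite(pvals)
        perm_fdr = np.full(len(pairs), np.nan)
        if valid.any():
            perm_fdr[valid] = bh_fdr(pvals[valid])

        ne_ = tables.u_node[inv_net[ei]]
        nl_ = tables.u_node[inv_net[li]]
        lens = np.full(len(pairs), math.inf)
        in_graph = (ne_ >= 0) & (nl_ >= 0)
        lens[in_graph] = tables.dist[ne_[in_graph], nl_[in_graph]]

        with np.errstate(invalid="ignore"):
            beat = (lens[path_pos] < actual_len) & (perm_fdr[path_pos] < actual_fdr)
        n1 += np.where(np.isnan(perm_fdr[path_pos]), False, beat)

    for k, p in enumerate(paths):
        p.permutation_fdr = float(n1[k] / n_permutations)
    logger.info(
        "permutation FDR over %d permutations: %d/%d paths below 0.05",
        n_permutations,
        int(sum(p.permutation_fdr < 0.05 for p in paths)),
        len(paths),
    )
    return paths
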