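"""Dual-criterion screening of early x late biomarker pairs.

A pair qualifies as a signal propagation path when (i) its weighted
shortest-path length in the interaction network is strictly below the
length cutoff (default 300, the distance of a single confidence-0.700
edge) and (ii) the Benjamini-Hochberg adjusted p-value of the Pearson
correlation of the two genes' expression over the pooled Dukes B and C
samples is strictly below the FDR cutoff (default 0.001).  BH is applied
once across all tested pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ExpressionCohort
from .markers import BiomarkerSet
from .network import HIGH_CONFIDENCE_LENGTH, shortest_path, single_source_lengths

logger = logging.getLogger(__name__)


def map_biomarkers(biomarkers: BiomarkerSet | list[str], graph: nx.Graph) -> list[str]:
    """Subset of biomarker genes present as network nodes, order preserved."""
    genes = biomarkers.optimal_genes if isinstance(biomarkers, BiomarkerSet) else list(biomarkers)
    mapped = [g for g in genes if g in graph]
    n_unmapped = len(genes) - len(mapped)
    if n_unmapped:
        logger.info("%d of %d biomarker(s) not present in the network", n_unmapped, len(genes))
    if not mapped:
        logger.warning("no biomarkers could be mapped onto the network")
    return mapped


def pearson_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-distribution p-value (n-2 df)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson_p_from_r(r: float | np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a sample correlation at sample size *n*."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return stats.false_discovery_control(p, method="bh")


@dataclass
class SignalPropagationPath:
    """A qualifying early -> late biomarker pair with its shortest path."""

    early_gene: str
    late_gene: str
    node_sequence: list[str]
    length: float
    pearson_r: float
    pearson_p: float
    correlation_fdr: float
    permutation_fdr: float | None = None

    @property
    def transition_genes(self) -> list[str]:
        """Interior nodes of the path (endpoints excluded)."""
        return self.node_sequence[1:-1]


@dataclass
class ScreenResult:
    """Outcome of the pairwise screen.

    ``tests`` holds one row per tested ordered (early, late) pair with its
    path length, Pearson statistics and adjusted FDR; ``paths`` the pairs
    passing both criteria, in (early index, late index) order.
    """

    paths: list[SignalPropagationPath]
    tests: pd.DataFrame
    n_pairs_tested: int
    n_bc_samples: int

    @property
    def n_paths(self) -> int:
        return len(self.paths)

    @property
    def early_linked(self) -> list[str]:
        return sorted({p.early_gene for p in self.paths})

    @property
    def late_linked(self) -> list[str]:
        return sorted({p.late_gene for p in self.paths})

    @property
    def transition_genes(self) -> list[str]:
        return sorted({g for p in self.paths for g in p.transition_genes})


def screen_transitions(
    graph: nx.Graph,
    early_mapped: list[str],
    late_mapped: list[str],
    cohort: ExpressionCohort,
    length_cutoff: float = HIGH_CONFIDENCE_LENGTH,
    fdr_cutoff: float = 0.001,
) -> ScreenResult:
    """Screen all ordered early x late pairs by the dual criterion.

    Pairs whose endpoints coincide (a gene in both biomarker sets) are
    excluded; constant-expression genes are excluded from correlation
    testing with a log entry.  Both criteria are strict inequalities.
    """
    if length_cutoff < 0 or fdr_cutoff < 0:
        raise ValueError("cutoffs must be non-negative")
    counts = cohort.stage_counts()
    if counts["B"] == 0 or counts["C"] == 0:
        raise ValueError("cohort must contain both Dukes B and Dukes C samples")
    bc = cohort.samples_in(("B", "C"))
    if len(bc) < 3:
        raise ValueError("need at least 3 pooled B/C samples for correlation testing")
    missing = [g for g in list(early_mapped) + list(late_mapped) if g not in cohort.values.index]
    if missing:
        raise KeyError(f"biomarker(s) without expression rows: {missing[:5]}")

    n_bc = len(bc)
    Xe = cohort.values.loc[early_mapped, bc].to_numpy(dtype=float)
    Xl = cohort.values.loc[late_mapped, bc].to_numpy(dtype=float)

    def _center_norm(X):
        c = X - X.mean(axis=1, keepdims=True)
        norm = np.sqrt((c * c).sum(axis=1))
        return c, norm

    ce, ne = _center_norm(Xe)
    cl, nl = _center_norm(Xl)
    const_e = ne == 0
    const_l = nl == 0
    if const_e.any() or const_l.any():
        logger.info(
            "excluding %d early and %d late constant gene(s) from correlation testing",
            int(const_e.sum()), int(const_l.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ce @ cl.T) / np.outer(ne, nl)
    r = np.clip(r, -1.0, 1.0)
    p = pearson_p_from_r(r, n_bc)

    early_arr = np.asarray(early_mapped, dtype=object)
    late_arr = np.asarray(late_mapped, dtype=object)
    self_pair = early_arr[:, None] == late_arr[None, :]
    testable = ~self_pair & ~const_e[:, None] & ~const_l[None, :]
    n_tested = int(testable.sum())

    fdr = np.full_like(p, np.nan)
    if n_tested:
        # p=0 from |r|=1 is nudged to the smallest positive float for BH
        pt = np.maximum(p[testable], np.finfo(float).tiny)
        fdr[testable] = bh_fdr(pt)

    lengths = np.full(p.shape, math.inf)
    for i, e in enumerate(early_mapped):
        if e not in graph:
            continue
        dist = single_source_lengths(graph, e)
        for j, l in enumerate(late_mapped):
            if l in dist:
                lengths[i, j] = dist[l]

    with np.errstate(invalid="ignore"):
        passed = testable & (lengths < length_cutoff) & (fdr < fdr_cutoff)

    paths: list[SignalPropagationPath] = []
    for i, j in np.argwhere(passed):
        pr = shortest_path(graph, early_mapped[i], late_mapped[j])
        paths.append(
            SignalPropagationPath(
                early_gene=early_mapped[i],
                late_gene=late_mapped[j],
                node_sequence=pr.node_sequence,
                length=pr.length,
                pearson_r=float(r[i, j]),
                pearson_p=float(p[i, j]),
                correlation_fdr=float(fdr[i, j]),
            )
        )

    ii, jj = np.nonzero(testable)
    tests = pd.DataFrame(
        {
            "early_gene": early_arr[ii],
            "late_gene": late_arr[jj],
            "path_length": lengths[ii, jj],
            "pearson_r": r[ii, jj],
            "pearson_p": p[ii, jj],
            "correlation_fdr": fdr[ii, jj],
            "passed": passed[ii, jj],
        }
    )
    logger.info(
        "screened %d pairs: %d passed length < %g, %d passed FDR < %g, %d paths retained "
        "(linking %d early and %d late genes)",
        n_tested,
        int((testable & (lengths < length_cutoff)).sum()),
        int((testable & (fdr < fdr_cutoff)).sum()),
        len(paths),
        len({p_.early_gene for p_ in paths}),
        len({p_.late_gene for p_ in paths}),
    )
    return ScreenResult(paths=paths, tests=tests, n_pairs_tested=n_tested, n_bc_samples=n_bc)
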