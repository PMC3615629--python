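"""Synthetic four-stage cohorts and interaction networks with known truth.

The generator emulates the shape of a staged expression study: a Dukes
A/B/C/D cohort in which planted early markers shift between stages A and
B and planted late markers between C and D, plus a confidence-scored
background interaction network in which selected early/late marker pairs
are joined by short high-confidence paths and co-expressed in the pooled
B and C samples.  Every downstream stage of the pipeline is testable
against the planted ground truth without any download.

Defaults mirror the study conditions of the emulated design at desk
scale: stage sizes 44/94/91/61, 500 genes (of 19,621), a 400-node
network (of 15,240), 10+10 planted markers with a 3-SD mean shift, and
5 planted pairs correlated at rho = 0.9 through 3-edge confidence-0.95
paths (weighted length 150 < 300).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ConfidenceEdgeList, ExpressionCohort, SCORE_MAX, SCORE_MIN, STAGES
from .network import build_graph

#: most edges a planted path may have so that 0.95-confidence edges keep
#: its weighted length strictly below 300 (6 x 50 = 300 would not qualify)
MAX_PLANTED_PATH_EDGES = 5

DEFAULT_N_PER_STAGE = {"A": 44, "B": 94, "C": 91, "D": 61}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort + network instance.

    ``effect_size`` is the planted mean shift in within-group SD units;
    ``path_rho`` the target Pearson correlation of planted pairs over the
    pooled B and C samples; ``confidence_range`` bounds background edge
    scores; ``marker_unmapped_fraction`` removes that share of non-planted
    markers from the network to exercise the biomarker-mapping step.
    """

    n_genes: int = 500
    n_per_stage: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_STAGE))
    n_early_markers: int = 10
    n_late_markers: int = 10
    effect_size: float = 3.0
    stage_shift_fraction: float = 0.3
    n_planted_paths: int = 5
    path_rho: float = 0.9
    planted_path_edges: int = 3
    planted_confidence: float = 0.95
    network_n_nodes: int = 400
    network_mean_degree: float = 6.0
    confidence_range: tuple[float, float] = (SCORE_MIN, SCORE_MAX)
    score_mixture_weights: tuple[float, float, float] = (0.85, 0.12, 0.03)
    marker_unmapped_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        missing = [s for s in STAGES if s not in self.n_per_stage]
        if missing:
            raise ValueError(f"stage map missing stage(s) {missing}")
        if any(self.n_per_stage[s] <= 0 for s in STAGES):
            raise ValueError("every stage needs a positive sample count")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_early_markers + self.n_late_markers > self.n_genes:
            raise ValueError("marker counts exceed n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0.0 <= self.stage_shift_fraction <= 1.0):
            raise ValueError("stage_shift_fraction must lie in [0, 1]")
        if not (0.0 <= self.path_rho <= 1.0):
            raise ValueError("path_rho must lie in [0, 1]")
        if self.n_planted_paths > min(self.n_early_markers, self.n_late_markers):
            raise ValueError("n_planted_paths exceeds the planted marker counts")
        if not (1 <= self.planted_path_edges <= MAX_PLANTED_PATH_EDGES):
            raise ValueError(
                f"planted_path_edges must be in [1, {MAX_PLANTED_PATH_EDGES}] so the "
                "planted path length stays strictly below 300"
            )
        lo, hi = self.confidence_range
        if not (SCORE_MIN <= lo < hi <= SCORE_MAX):
            raise ValueError(f"confidence_range must lie within [{SCORE_MIN}, {SCORE_MAX}]")
        if not (lo <= self.planted_confidence <= hi) or self.planted_confidence < 0.95:
            raise ValueError("planted_confidence must be >= 0.95 and inside confidence_range")
        if any(w < 0 for w in self.score_mixture_weights) or sum(self.score_mixture_weights) == 0:
            raise ValueError("score_mixture_weights must be non-negative, not all zero")
        if not (0.0 <= self.marker_unmapped_fraction < 1.0):
            raise ValueError("marker_unmapped_fraction must lie in [0, 1)")
        if self.network_n_nodes > self.n_genes:
            raise ValueError("network_n_nodes cannot exceed n_genes (shared symbol space)")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def sample_ids_and_stages(self) -> tuple[list[str], list[str]]:
        samples, stages = [], []
        for s in STAGES:
            for j in range(1, self.n_per_stage[s] + 1):
                samples.append(f"{s}{j:03d}")
                stages.append(s)
        return samples, stages


@dataclass
class GroundTruth:
    """Planted structure of a simulated instance."""

    early_marker_ids: set[str]
    late_marker_ids: set[str]
    planted_pairs: list[tuple[str, str, list[str]]]  # (early, late, path nodes)


def _rng_children(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    cohort_ss, network_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(cohort_ss), np.random.default_rng(network_ss)


def simulate_cohort(config: SimulationConfig) -> tuple[ExpressionCohort, GroundTruth]:
    """Draw the expression cohort and decide the planted ground truth.

    Background genes are i.i.d. Gaussian with gene-specific mean and SD
    drawn from hyperpriors; early markers shift by ``effect_size`` SDs in
    stage B relative to A, late markers in stage D relative to C; for each
    planted pair the late gene's pooled-B/C values are a rho-mixture of
    the early gene's standardized values and fresh noise.
    """
    rng, _ = _rng_children(config.seed)
    genes = config.gene_ids()
    samples, stage_list = config.sample_ids_and_stages()
    stages = pd.Series(stage_list, index=samples)

    means = rng.normal(8.0, 2.0, size=config.n_genes)
    sds = rng.uniform(0.5, 1.5, size=config.n_genes)
    X = means[:, None] + sds[:, None] * rng.standard_normal((config.n_genes, len(samples)))

    marker_idx = rng.choice(
        config.n_genes, size=config.n_early_markers + config.n_late_markers, replace=False
    )
    early_idx = marker_idx[: config.n_early_markers]
    late_idx = marker_idx[config.n_early_markers:]

    stage_mask = {s: (stages.to_numpy() == s) for s in STAGES}

    def _shift(gene_set: np.ndarray, stage: str) -> None:
        # two-component marker model: every marker shifts stage-wide by a
        # `stage_shift_fraction` share of the effect (grade-wide
        # dysregulation, what a per-gene t-test sees) and is additionally
        # elevated by the full effect in its own disjoint patient block
        # (mutually exclusive subtypes).  Markers are therefore individually
        # modest but jointly discriminative, so the optimal biomarker set
        # genuinely needs the whole planted panel.
        if gene_set.size == 0:
            return
        members = rng.permutation(np.flatnonzero(stage_mask[stage]))
        blocks = np.array_split(members, gene_set.size)
        for g, block in zip(gene_set, blocks):
            X[g, stage_mask[stage]] += config.stage_shift_fraction * config.effect_size * sds[g]
            X[g, block] += config.effect_size * sds[g]

    _shift(early_idx, "B")
    _shift(late_idx, "D")

    bc = stage_mask["B"] | stage_mask["C"]
    rho = config.path_rho
    planted: list[tuple[str, str, list[str]]] = []
    non_marker = np.setdiff1d(np.arange(config.n_genes), marker_idx)
    n_interior = config.planted_path_edges - 1
    interior_pool = rng.choice(
        non_marker, size=config.n_planted_paths * n_interior, replace=False
    ) if n_interior else np.array([], dtype=int)
    for k in range(config.n_planted_paths):
        e, l = early_idx[k], late_idx[k]
        ze = X[e, bc]
        ze = (ze - ze.mean()) / ze.std()
        noise = rng.standard_normal(bc.sum())
        X[l, bc] = means[l] + sds[l] * (rho * ze + np.sqrt(1.0 - rho * rho) * noise)
        interior = interior_pool[k * n_interior: (k + 1) * n_interior]
        planted.append(
            (genes[e], genes[l], [genes[e]] + [genes[i] for i in interior] + [genes[l]])
        )

    cohort = ExpressionCohort(
        values=pd.DataFrame(X, index=genes, columns=samples), stages=stages
    )
    truth = GroundTruth(
        early_marker_ids={genes[i] for i in early_idx},
        late_marker_ids={genes[i] for i in late_idx},
        planted_pairs=planted,
    )
    return cohort, truth


def _sample_scores(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    """Empirical-looking confidence mixture: mass near 0.15-0.4, thin high tail."""
    lo, hi = config.confidence_range
    w = np.asarray(config.score_mixture_weights, dtype=float)
    w = w / w.sum()
    comp = rng.choice(3, size=n, p=w)
    scores = np.empty(n)
    bounds = [(0.150, 0.400), (0.400, 0.900), (0.900, 1.000)]
    for c, (a, b) in enumerate(bounds):
        m = comp == c
        scores[m] = rng.uniform(a, b, size=int(m.sum()))
    return np.clip(np.round(scores, 3), lo, hi)


def simulate_network(config: SimulationConfig, truth: GroundTruth):
    """Build the edge list and graph consistent with the planted truth.

    A background Erdos-Renyi graph at ``network_mean_degree`` is scored
    from the confidence mixture; each planted pair's intended path edges
    get confidence ``planted_confidence`` (>= 0.95), so a 3-edge planted
    path has weighted length 150 < 300.  Returns (edge list, graph).
    """
    _, rng = _rng_children(config.seed)
    genes = config.gene_ids()

    required = {n for _, _, path in truth.planted_pairs for n in path}
    markers = sorted((truth.early_marker_ids | truth.late_marker_ids) - required)
    n_drop = int(np.floor(config.marker_unmapped_fraction * len(markers)))
    dropped = set(
        np.array(markers, dtype=object)[
            rng.choice(len(markers), size=n_drop, replace=False)
        ]
    ) if n_drop else set()
    nodes = list(required) + [m for m in markers if m not in dropped]
    if len(nodes) > config.network_n_nodes:
        raise ValueError(
            f"network_n_nodes={config.network_n_nodes} too small for the "
            f"{len(nodes)} planted/marker nodes"
        )
    background_pool = [g for g in genes if g not in set(nodes) and g not in dropped]
    fill = rng.choice(
        len(background_pool), size=config.network_n_nodes - len(nodes), replace=False
    )
    nodes = sorted(nodes + [background_pool[i] for i in sorted(fill)])

    n = len(nodes)
    p_edge = min(config.network_mean_degree / max(n - 1, 1), 1.0)
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < p_edge
    a_idx, b_idx = iu[0][present], iu[1][present]
    scores = _sample_scores(rng, len(a_idx), config)
    node_arr = np.asarray(nodes, dtype=object)
    records = list(zip(node_arr[a_idx], node_arr[b_idx], scores))

    for _, _, path in truth.planted_pairs:
        for u, v in zip(path[:-1], path[1:]):
            records.append((u, v, config.planted_confidence))

    edges = ConfidenceEdgeList.from_records(records)
    graph = build_graph(edges)
    graph.add_nodes_from(nodes)  # keep isolated nodes in the symbol space
    return edges, graph


def simulate(config: SimulationConfig):
    """Convenience: cohort, ground truth, edge list and graph in one call."""
    cohort, truth = simulate_cohort(config)
    edges, graph = simulate_network(config, truth)
    return cohort, truth, edges, graph
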