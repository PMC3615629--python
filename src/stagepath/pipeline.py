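"""End-to-end orchestration: simulate/ingest -> biomarkers -> screen -> FDR -> hubs.

``run_pipeline`` executes the stages in order, writes every result table
plus a run manifest (parameters, seed, versions, per-stage counts) to the
output directory, and is a pure function of its configuration: rerunning
with the same config reproduces all outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from . import __version__, io
from .cohort import ExpressionCohort
from .markers import BiomarkerSet, select_biomarkers
from .network import HIGH_CONFIDENCE_LENGTH, build_graph
from .permutation import DEFAULT_N_PERMUTATIONS, path_fdr
from .screen import ScreenResult, map_biomarkers, screen_transitions
from .simulate import GroundTruth, SimulationConfig, simulate
from .stats import OverlapStats, count_crossings, overlap_statistics

logger = logging.getLogger(__name__)

EARLY_CONTRAST = ("A", "B")
LATE_CONTRAST = ("C", "D")


@dataclass
class PipelineConfig:
    """Inputs and parameters of one pipeline run.

    Exactly one of ``simulation`` or the three input paths
    (``expression_path``, ``stage_path``, ``network_path``) must be set.
    """

    simulation: SimulationConfig | None = None
    expression_path: str | None = None
    stage_path: str | None = None
    network_path: str | None = None
    score_scale: str = "auto"

    scheme: str = "MIQ"
    k_sd: float = 1.0
    max_k: int | None = None
    length_cutoff: float = HIGH_CONFIDENCE_LENGTH
    fdr_cutoff: float = 0.001
    n_permutations: int = DEFAULT_N_PERMUTATIONS
    joint_relabeling: bool = True
    seed: int = 0
    out_dir: str = "stagepath_out"

    def __post_init__(self) -> None:
        has_paths = any([self.expression_path, self.stage_path, self.network_path])
        if (self.simulation is None) == (not has_paths):
            raise ValueError(
                "exactly one of a simulation block or input paths must be provided"
            )
        if has_paths and not all([self.expression_path, self.stage_path, self.network_path]):
            raise ValueError("expression, stage and network paths must all be given")
        if self.length_cutoff < 0 or self.fdr_cutoff <= 0 or self.n_permutations < 1:
            raise ValueError("cutoffs must be positive")


@dataclass
class PipelineResult:
    cohort: ExpressionCohort
    graph: nx.Graph
    truth: GroundTruth | None
    early: BiomarkerSet
    late: BiomarkerSet
    screen: ScreenResult
    hubs: "object"
    overlap: OverlapStats
    manifest: dict


def _stage_fail(stage: str, exc: Exception):
    raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "parameters": {
            "scheme": config.scheme,
            "k_sd": config.k_sd,
            "max_k": config.max_k,
            "length_cutoff": config.length_cutoff,
            "fdr_cutoff": config.fdr_cutoff,
            "n_permutations": config.n_permutations,
            "joint_relabeling": config.joint_relabeling,
        },
        "counts": {},
    }
    counts = manifest["counts"]

    # ---- stage 1: simulate or ingest
    truth = None
    try:
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.simulation.seed)
            manifest["simulation"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(sim).items()
            }
            cohort, truth, edges, graph = simulate(sim)
            io.write_expression(cohort, out / "expression.tsv", out / "stages.tsv")
            io.write_network(edges, out / "network.txt")
            io.write_ground_truth(truth, out / "ground_truth.json")
        else:
            cohort = io.read_expression(config.expression_path, config.stage_path)
            edges = io.read_network(config.network_path, score_scale=config.score_scale)
            graph = build_graph(edges)
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        _stage_fail("input", exc)
    counts["n_genes"] = cohort.n_genes
    counts["n_samples"] = cohort.n_samples
    counts["stage_sizes"] = cohort.stage_counts()
    counts["network_nodes"] = graph.number_of_nodes()
    counts["network_edges"] = graph.number_of_edges()

    # ---- stage 2: biomarker selection
    try:
        early = select_biomarkers(
            cohort, EARLY_CONTRAST, scheme=config.scheme, k_sd=config.k_sd, max_k=config.max_k
        )
        late = select_biomarkers(
            cohort, LATE_CONTRAST, scheme=config.scheme, k_sd=config.k_sd, max_k=config.max_k
        )
    except Exception as exc:
        _stage_fail("biomarker_selection", exc)
    io.write_biomarkers(early, out / "early_biomarkers.tsv", out / "early_ifs_curve.tsv")
    io.write_biomarkers(late, out / "late_biomarkers.tsv", out / "late_ifs_curve.tsv")
    counts["n_early_biomarkers"] = len(early.optimal_genes)
    counts["n_late_biomarkers"] = len(late.optimal_genes)
    counts["early_ifs_accuracy"] = early.curve.best_accuracy
    counts["late_ifs_accuracy"] = late.curve.best_accuracy

    # ---- stage 3: map + screen
    try:
        early_mapped = map_biomarkers(early, graph)
        late_mapped = map_biomarkers(late, graph)
        screen = screen_transitions(
            graph, early_mapped, late_mapped, cohort,
            length_cutoff=config.length_cutoff, fdr_cutoff=config.fdr_cutoff,
        )
    except Exception as exc:
        _stage_fail("transition_screen", exc)
    counts["n_early_mapped"] = len(early_mapped)
    counts["n_late_mapped"] = len(late_mapped)
    counts["n_pairs_tested"] = screen.n_pairs_tested
    counts["n_paths"] = screen.n_paths
    counts["n_early_linked"] = len(screen.early_linked)
    counts["n_late_linked"] = len(screen.late_linked)

    # ---- stage 4: permutation FDR
    try:
        path_fdr(
            screen.paths, graph, cohort, early_mapped, late_mapped,
            n_permutations=config.n_permutations, seed=config.seed,
            joint=config.joint_relabeling,
        )
    except Exception as exc:
        _stage_fail("permutation_fdr", exc)
    io.write_path_table(screen.paths, out / "paths.tsv")
    if screen.paths:
        fdrs = [p.permutation_fdr for p in screen.paths]
        counts["perm_fdr_below_0.05"] = int(sum(f < 0.05 for f in fdrs))
        counts["perm_fdr_below_0.01"] = int(sum(f < 0.01 for f in fdrs))

    # ---- stage 5: hubs + overlap + export
    try:
        hubs = count_crossings(screen.paths)
        overlap = overlap_statistics(
            early.optimal_genes, late.optimal_genes, cohort.n_genes
        )
    except Exception as exc:
        _stage_fail("summary_stats", exc)
    io.write_hub_table(hubs, out / "transition_hubs.tsv")
    (out / "overlap.json").write_text(json.dumps(overlap.round3(), indent=2) + "\n")
    counts["n_transition_genes"] = int(len(hubs))

    roles = {}
    for p in screen.paths:
        roles[p.early_gene] = "both" if roles.get(p.early_gene) == "late" else "early"
        roles[p.late_gene] = "both" if roles.get(p.late_gene) == "early" else "late"
    for g in screen.transition_genes:
        roles.setdefault(g, "transition")
    result_nodes = set(roles)
    if result_nodes:
        io.export_network(
            graph.subgraph(result_nodes).copy(), roles, "GraphML", out / "transition_network.graphml"
        )

    if truth is not None:
        planted = {(e, l) for e, l, _ in truth.planted_pairs}
        found = {(p.early_gene, p.late_gene) for p in screen.paths}
        counts["planted_pairs"] = len(planted)
        counts["planted_pairs_recovered"] = len(planted & found)
        counts["early_marker_recall"] = (
            len(truth.early_marker_ids & set(early.optimal_genes))
            / max(len(truth.early_marker_ids), 1)
        )
        counts["late_marker_recall"] = (
            len(truth.late_marker_ids & set(late.optimal_genes))
            / max(len(truth.late_marker_ids), 1)
        )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        cohort=cohort, graph=graph, truth=truth, early=early, late=late,
        screen=screen, hubs=hubs, overlap=overlap, manifest=manifest,
    )
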