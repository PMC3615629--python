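"""Readers and writers for every external format the pipeline touches.

Formats: TSV expression matrix (genes as rows, first column the gene id),
two-column sample -> stage TSV, STRING-style whitespace-delimited edge
list (unit- or milli-scale scores), TSV result tables (paths, hubs,
biomarkers, IFS curves) and SIF/GraphML network export.  Readers reject
malformed input with messages naming the offending row/column rather than
silently coercing.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import ConfidenceEdgeList, ExpressionCohort, STAGES
from .markers import BiomarkerSet, IFSCurve
from .screen import SignalPropagationPath

logger = logging.getLogger(__name__)

PATH_ARROW = "→"  # arrow joining node sequences in path tables

ROLE_TOKENS = ("early", "late", "both", "transition")


# ---------------------------------------------------------------- expression

def read_expression(matrix_path, stage_path) -> ExpressionCohort:
    """Read a genes x samples TSV plus a sample -> stage TSV."""
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers in {matrix_path}: {dups[:5]}")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() | raw[col].isna()
        if bad.any():
            gene = raw.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric or blank expression cell at gene {gene!r}, sample {col!r}"
            )
        values[col] = converted

    stages_df = pd.read_csv(stage_path, sep="\t", header=None, names=["sample", "stage"], dtype=str)
    if stages_df["sample"].duplicated().any():
        raise ValueError(f"duplicate sample id in stage file {stage_path}")
    stages = pd.Series(stages_df["stage"].to_numpy(), index=stages_df["sample"])
    bad_tokens = stages[~stages.isin(STAGES)]
    if len(bad_tokens):
        raise ValueError(
            f"unknown stage token {bad_tokens.iloc[0]!r} for sample {bad_tokens.index[0]!r}"
        )
    missing = [s for s in values.columns if s not in stages.index]
    if missing:
        raise ValueError(f"samples missing from stage file: {missing[:5]}")
    return ExpressionCohort(values=values, stages=stages)


def write_expression(cohort: ExpressionCohort, matrix_path, stage_path) -> None:
    df = cohort.values.copy()
    df.index.name = "gene"
    df.to_csv(matrix_path, sep="\t", lineterminator="\n")
    cohort.stages.to_csv(stage_path, sep="\t", header=False, lineterminator="\n")


# ------------------------------------------------------------------- network

def read_network(edge_path, score_scale: str = "auto") -> ConfidenceEdgeList:
    """Read a three-column (protein1, protein2, score) edge list.

    ``score_scale``: ``unit`` takes scores as-is, ``milli`` divides by 1000
    (STRING's native 150-999 integers), ``auto`` infers milli when any
    score exceeds 1.  Edges outside [0.150, 1] after normalization are
    dropped and counted, never clamped.
    """
    if score_scale not in ("auto", "unit", "milli"):
        raise ValueError(f"unknown score_scale {score_scale!r}")
    df = pd.read_csv(edge_path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] != 3:
        raise ValueError(
            f"expected 3 columns (protein1 protein2 score) in {edge_path}, got {df.shape[1]}"
        )
    df.columns = ["protein_a", "protein_b", "score"]
    try:
        df["score"] = df["score"].astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric score in {edge_path}: {exc}") from exc
    if score_scale == "milli" or (score_scale == "auto" and (df["score"] > 1).any()):
        df["score"] = df["score"] / 1000.0
    return ConfidenceEdgeList.from_records(df)


def write_network(edges: ConfidenceEdgeList, edge_path) -> None:
    """STRING-flavoured whitespace-delimited edge list on the unit scale."""
    edges.edges.to_csv(
        edge_path, sep=" ", header=False, index=False, float_format="%.3f",
        lineterminator="\n",
    )


# --------------------------------------------------------------- path tables

_PATH_COLUMNS = [
    "early_gene", "late_gene", "node_sequence", "path_length",
    "pearson_r", "pearson_p", "correlation_fdr", "permutation_fdr",
]


def write_path_table(paths: list[SignalPropagationPath], out_path) -> None:
    """One row per signal propagation path; node sequence arrow-joined."""
    rows = [
        {
            "early_gene": p.early_gene,
            "late_gene": p.late_gene,
            "node_sequence": PATH_ARROW.join(p.node_sequence),
            "path_length": p.length,
            "pearson_r": p.pearson_r,
            "pearson_p": p.pearson_p,
            "correlation_fdr": p.correlation_fdr,
            "permutation_fdr": "" if p.permutation_fdr is None else p.permutation_fdr,
        }
        for p in paths
    ]
    pd.DataFrame(rows, columns=_PATH_COLUMNS).to_csv(
        out_path, sep="\t", index=False, lineterminator="\n"
    )


def read_path_table(path) -> list[SignalPropagationPath]:
    df = pd.read_csv(path, sep="\t", dtype={"early_gene": str, "late_gene": str})
    out = []
    for row in df.itertuples(index=False):
        perm = getattr(row, "permutation_fdr")
        out.append(
            SignalPropagationPath(
                early_gene=row.early_gene,
                late_gene=row.late_gene,
                node_sequence=str(row.node_sequence).split(PATH_ARROW),
                length=float(row.path_length),
                pearson_r=float(row.pearson_r),
                pearson_p=float(row.pearson_p),
                correlation_fdr=float(row.correlation_fdr),
                permutation_fdr=None if pd.isna(perm) else float(perm),
            )
        )
    return out


# ----------------------------------------------------------- biomarker files

def write_biomarkers(bm: BiomarkerSet, ranked_path, curve_path) -> None:
    """Write the full mRMR ranking (optimal prefix flagged) and IFS curve."""
    opt = bm.curve.optimal_k
    pd.DataFrame(
        {
            "rank": np.arange(1, len(bm.ranked_genes) + 1),
            "gene": bm.ranked_genes,
            "in_optimal_set": [i < opt for i in range(len(bm.ranked_genes))],
        }
    ).to_csv(ranked_path, sep="\t", index=False, lineterminator="\n")
    pd.DataFrame(
        {"k": np.arange(1, len(bm.curve.accuracies) + 1), "accuracy": bm.curve.accuracies}
    ).to_csv(curve_path, sep="\t", index=False, lineterminator="\n")


def read_biomarkers(ranked_path, curve_path, contrast=("A", "B")) -> BiomarkerSet:
    ranked = pd.read_csv(ranked_path, sep="\t", dtype={"gene": str})
    curve = pd.read_csv(curve_path, sep="\t")
    return BiomarkerSet(
        contrast=tuple(contrast),
        ranked_genes=ranked["gene"].tolist(),
        curve=IFSCurve(curve["accuracy"].tolist()),
    )


def write_hub_table(hubs: pd.DataFrame, out_path) -> None:
    hubs.to_csv(out_path, sep="\t", index=False, lineterminator="\n")


# ------------------------------------------------------------ network export

def export_network(
    graph: nx.Graph,
    node_annotations: dict[str, str],
    fmt: str,
    out_path,
) -> None:
    """Export a result network as SIF or GraphML with node role annotations.

    Roles are restricted to {early, late, both, transition}.
    """
    bad = {r for r in node_annotations.values() if r not in ROLE_TOKENS}
    if bad:
        raise ValueError(f"unknown role token(s): {sorted(bad)}; allowed: {ROLE_TOKENS}")
    fmt = fmt.upper()
    if fmt == "SIF":
        lines = [f"{a}\tinteracts\t{b}" for a, b in sorted(graph.edges())]
        lines += [f"{n}" for n in sorted(graph.nodes()) if graph.degree[n] == 0]
        Path(out_path).write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "GRAPHML":
        g = graph.copy()
        for node, role in node_annotations.items():
            if node in g:
                g.nodes[node]["role"] = role
        nx.write_graphml(g, out_path)
    else:
        raise ValueError(f"unknown export format {fmt!r}; use SIF or GraphML")


# -------------------------------------------------------------- ground truth

def write_ground_truth(truth, out_path) -> None:
    payload = {
        "early_marker_ids": sorted(truth.early_marker_ids),
        "late_marker_ids": sorted(truth.late_marker_ids),
        "planted_pairs": [
            {"early": e, "late": l, "path": list(p)} for e, l, p in truth.planted_pairs
        ],
    }
    Path(out_path).write_text(json.dumps(payload, indent=2) + "\n")


def read_ground_truth(path):
    from .simulate import GroundTruth

    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        early_marker_ids=set(payload["early_marker_ids"]),
        late_marker_ids=set(payload["late_marker_ids"]),
        planted_pairs=[
            (d["early"], d["late"], list(d["path"])) for d in payload["planted_pairs"]
        ],
    )
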