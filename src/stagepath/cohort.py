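"""Core in-memory containers shared across the pipeline.

The pipeline operates on a genes x samples expression matrix with a
four-level Dukes stage label per sample (A = earliest, D = most advanced),
and on a confidence-scored undirected protein-interaction edge list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES: tuple[str, ...] = ("A", "B", "C", "D")

#: admissible confidence-score range for interaction edges
SCORE_MIN = 0.150
SCORE_MAX = 1.0


@dataclass
class ExpressionCohort:
    """Genes x samples expression matrix with per-sample Dukes stage labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier, columns are sample
        identifiers, entries are (finite) expression values.
    stages
        Series mapping each sample identifier to a stage in ``{A,B,C,D}``.
    """

    values: pd.DataFrame
    stages: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.all(np.isfinite(arr)):
            gi, si = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.values.index[gi]!r}, "
                f"sample {self.values.columns[si]!r}"
            )
        missing = [s for s in self.values.columns if s not in self.stages.index]
        if missing:
            raise ValueError(f"samples without a stage label: {missing[:5]}")
        self.stages = self.stages.loc[self.values.columns]
        bad = sorted(set(self.stages) - set(STAGES))
        if bad:
            offender = self.stages[~self.stages.isin(STAGES)].index[0]
            raise ValueError(
                f"unknown stage token(s) {bad} (first offending sample: {offender!r})"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def stage_counts(self) -> dict[str, int]:
        vc = self.stages.value_counts()
        return {s: int(vc.get(s, 0)) for s in STAGES}

    def samples_in(self, stages: Iterable[str]) -> list[str]:
        """Sample ids whose stage is in *stages*, in matrix column order."""
        wanted = set(stages)
        return [s for s in self.values.columns if self.stages[s] in wanted]

    def submatrix(self, stages: Iterable[str]) -> pd.DataFrame:
        """Genes x samples slice restricted to the given stages."""
        return self.values.loc[:, self.samples_in(stages)]


@dataclass
class ConfidenceEdgeList:
    """Validated undirected edge list with unit-scale confidence scores.

    Self-loops are removed; undirected duplicates are collapsed keeping the
    maximum score; edges whose score falls outside [0.150, 1] are dropped
    (never clamped) and counted in :attr:`n_dropped`.
    """

    edges: pd.DataFrame  # columns: protein_a, protein_b, score
    n_dropped: int = 0

    COLUMNS = ("protein_a", "protein_b", "score")

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, str, float]] | pd.DataFrame
    ) -> "ConfidenceEdgeList":
        df = pd.DataFrame(records, columns=list(cls.COLUMNS))
        df["score"] = df["score"].astype(float)

        n_loops = int((df["protein_a"] == df["protein_b"]).sum())
        if n_loops:
            logger.info("dropping %d self-loop edge(s)", n_loops)
            df = df[df["protein_a"] != df["protein_b"]]

        out_of_range = (df["score"] < SCORE_MIN) | (df["score"] > SCORE_MAX)
        n_bad = int(out_of_range.sum())
        if n_bad:
            logger.warning(
                "dropping %d edge(s) with confidence outside [%.3f, %.3f]",
                n_bad, SCORE_MIN, SCORE_MAX,
            )
            df = df[~out_of_range]

        # canonical undirected key, keep max score among duplicates
        a = df["protein_a"].to_numpy(dtype=object)
        b = df["protein_b"].to_numpy(dtype=object)
        lo = np.where(a <= b, a, b)
        hi = np.where(a <= b, b, a)
        df = pd.DataFrame({"protein_a": lo, "protein_b": hi, "score": df["score"].to_numpy()})
        df = (
            df.groupby(["protein_a", "protein_b"], as_index=False, sort=True)["score"]
            .max()
        )
        return cls(edges=df.reset_index(drop=True), n_dropped=n_bad + n_loops)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def proteins(self) -> set[str]:
        return set(self.edges["protein_a"]) | set(self.edges["protein_b"])

    def __iter__(self):
        return iter(self.edges.itertuples(index=False, name=None))
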