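"""Transition-hub ranking and biomarker-overlap statistics.

A transition gene is an interior node of a signal propagation path; a
transition hub is a gene crossed by many such paths.  The overlap
statistics quantify whether the early and late biomarker sets share more
or fewer genes than expected for independent draws from the gene universe.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .screen import SignalPropagationPath


def count_crossings(
    paths: list[SignalPropagationPath], include_endpoints: bool = False
) -> pd.DataFrame:
    """Rank genes by the number of paths crossing them.

    "Crossing" counts interior nodes only by default, so biomarker
    endpoints are not transition genes; ``include_endpoints=True`` is
    offered for sensitivity analysis.  Rows are sorted by count descending,
    ties by gene symbol ascending.
    """
    counter: Counter[str] = Counter()
    for p in paths:
        nodes = p.node_sequence if include_endpoints else p.transition_genes
        counter.update(set(nodes))  # simple paths: set() is a no-op safeguard
    table = pd.DataFrame(
        sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "crossing_count"],
    )
    return table


@dataclass
class OverlapStats:
    """Observed vs expected overlap of two gene sets within a universe.

    ``expected_overlap`` is |set1|*|set2|/N (the hypergeometric mean);
    ``odds_ratio`` is the classical 2x2 cross-product ratio
    (a*d)/(b*c), ``None`` when b*c = 0 (undefined).
    """

    n_universe: int
    n_set1: int
    n_set2: int
    n_overlap: int
    expected_overlap: float
    odds_ratio: float | None

    def round3(self) -> dict[str, float | int | None]:
        """Summary dict with reals to 3 significant figures."""
        sig3 = lambda x: None if x is None else float(f"{x:.3g}")
        return {
            "n_universe": self.n_universe,
            "n_set1": self.n_set1,
            "n_set2": self.n_set2,
            "n_overlap": self.n_overlap,
            "expected_overlap": sig3(self.expected_overlap),
            "odds_ratio": sig3(self.odds_ratio),
        }


def overlap_statistics(set1, set2, n_universe: int) -> OverlapStats:
    """Expected overlap and odds ratio for two subsets of a gene universe."""
    s1, s2 = set(set1), set(set2)
    if len(s1) > n_universe or len(s2) > n_universe:
        raise ValueError("set larger than universe")
    a = len(s1 & s2)
    b = len(s1) - a
    c = len(s2) - a
    d = n_universe - len(s1) - len(s2) + a
    if d < 0:
        raise ValueError("universe smaller than the union of the sets")
    expected = len(s1) * len(s2) / n_universe if n_universe else 0.0
    odds = (a * d) / (b * c) if b * c != 0 else None
    return OverlapStats(
        n_universe=n_universe,
        n_set1=len(s1),
        n_set2=len(s2),
        n_overlap=a,
        expected_overlap=expected,
        odds_ratio=odds,
    )
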