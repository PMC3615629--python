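import numpy as np
import pandas as pd
import pytest

import stagepath as sp


@pytest.fixture(scope="session")
def small_instance():
    """One modest simulated cohort + network shared by read-only tests."""
    cfg = sp.SimulationConfig(
        seed=11,
        n_genes=60,
        network_n_nodes=45,
        n_per_stage={"A": 8, "B": 15, "C": 15, "D": 8},
        n_early_markers=4,
        n_late_markers=4,
        n_planted_paths=2,
    )
    cohort, truth, edges, graph = sp.simulate(cfg)
    return cfg, cohort, truth, edges, graph


@pytest.fixture()
def tiny_cohort():
    """3 genes x 8 samples, two samples per stage, handmade values."""
    rng = np.random.default_rng(0)
    samples = [f"{s}{i}" for s in "ABCD" for i in (1, 2)]
    values = pd.DataFrame(
        rng.normal(size=(3, 8)), index=["g1", "g2", "g3"], columns=samples
    )
    stages = pd.Series([s[0] for s in samples], index=samples)
    return sp.ExpressionCohort(values=values, stages=stages)


@pytest.fixture()
def triangle_graph():
    edges = sp.ConfidenceEdgeList.from_records(
        [("A", "B", 0.9), ("B", "C", 0.9), ("A", "C", 0.75)]
    )
    return sp.build_graph(edges)
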