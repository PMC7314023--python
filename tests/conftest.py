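import numpy as np
import pandas as pd
import pytest

from bioidcall import (
    CallPolicy,
    ExperimentDesign,
    IntensityTable,
    Line,
    SimParams,
    TestPolicy,
    paper_design,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def design() -> ExperimentDesign:
    """The motivating 4-bait + leader design, 3 replicates per line."""
    return paper_design()


@pytest.fixture(scope="session")
def sim():
    """One default simulated experiment (table, design, truth), seed 7."""
    return simulate_experiment(SimParams(seed=7))


@pytest.fixture()
def fast_policy() -> CallPolicy:
    """Default thresholds with a fixed test seed."""
    return CallPolicy(test=TestPolicy(seed=11))


def two_line_table(bait_rows, ctrl_rows, ids=None) -> tuple[IntensityTable, ExperimentDesign]:
    """Small hand-built table with one bait line and one control bait line."""
    bait_rows = np.asarray(bait_rows, dtype=float)
    ctrl_rows = np.asarray(ctrl_rows, dtype=float)
    n = bait_rows.shape[0]
    ids = ids or [f"P{i}" for i in range(n)]
    data = pd.DataFrame(
        np.hstack([bait_rows, ctrl_rows]),
        index=pd.Index(ids, name="protein_id"),
        columns=["A_a", "A_b", "A_c", "B_a", "B_b", "B_c"],
    )
    design = ExperimentDesign(
        lines=[
            Line("A", "bait", ("A_a", "A_b", "A_c")),
            Line("B", "bait", ("B_a", "B_b", "B_c")),
            Line("NC", "negative_control", ("NC_a", "NC_b")),
        ]
    )
    # the NC line exists to satisfy the design invariant; give it no data columns
    data["NC_a"] = np.nan
    data["NC_b"] = np.nan
    return IntensityTable(data=data), design
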