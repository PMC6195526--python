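import numpy as np
import pandas as pd
import pytest

from sigscreen.types import ExpressionCohort, GeneSet, PlateSet


@pytest.fixture
def tiny_cohort():
    """4 genes x 6 samples with survival and subtype annotation."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(7, 1, size=(4, 6)),
        index=["g1", "g2", "g3", "g4"],
        columns=[f"s{i}" for i in range(6)],
    )
    ann = pd.DataFrame(
        {
            "time": [5.0, 3.0, 8.0, 2.0, 7.0, 4.0],
            "event": [1, 1, 0, 1, 0, 1],
            "sample_type": ["primary"] * 3 + ["metastasis"] * 3,
            "subtype": ["aggressive"] * 3 + ["normal-like"] * 3,
        },
        index=values.columns,
    )
    return ExpressionCohort(values=values, annotations=ann, name="tiny")


@pytest.fixture
def small_gene_set():
    return GeneSet(name="S", description="d", genes=["g1", "g2"])


def make_plate(
    plate_id="P1",
    condition="DMSO",
    cell_line="LNCaP",
    replicate=1,
    ntc_counts=(995, 1000, 1000, 1000, 1005, 990, 1010, 1000),
    pos_counts=(100,) * 8,
    sample_counts=(),
    genes=None,
):
    """Build a one-plate PlateSet from explicit control and sample counts."""
    rows = []
    for i, c in enumerate(ntc_counts):
        rows.append((plate_id, f"A{i + 1:02d}", cell_line, condition, "NTC", "", "", replicate, c))
    for i, c in enumerate(pos_counts):
        rows.append((plate_id, f"B{i + 1:02d}", cell_line, condition, "POS", "", "", replicate, c))
    genes = genes or [f"gene{i}" for i in range(len(sample_counts))]
    for i, c in enumerate(sample_counts):
        rows.append(
            (plate_id, f"C{i + 1:02d}", cell_line, condition, "sample",
             genes[i], f"{genes[i]}_si1", replicate, c)
        )
    cols = ["plate_id", "well", "cell_line", "condition", "role", "gene",
            "sirna_id", "replicate", "nuclei_count"]
    return PlateSet(wells=pd.DataFrame(rows, columns=cols))
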