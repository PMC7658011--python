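import numpy as np
import pandas as pd
import pytest

from symbiotrend import CountMatrix, DesignTable, GroupDesign, SampleDesign


@pytest.fixture
def design_3x3() -> DesignTable:
    designs = [
        SampleDesign(f"{g}_r{r}", g, r)
        for g in ("G2", "G6", "G9")
        for r in (1, 2, 3)
    ]
    return DesignTable(designs, ["G2", "G6", "G9"])


@pytest.fixture
def group_design_3x3(design_3x3) -> GroupDesign:
    return GroupDesign.from_design(design_3x3)


@pytest.fixture
def small_counts(design_3x3) -> CountMatrix:
    """Four-gene toy matrix: one declining, one rising, one flat, one symbiont."""
    rng = np.random.default_rng(7)
    samples = design_3x3.sample_ids
    counts = pd.DataFrame(
        {
            s: [0, 0, 0, 0] for s in samples
        },
        index=["g_down", "g_up", "g_flat", "sym_1"],
        dtype=np.int64,
    )
    counts.loc["g_down"] = [100, 110, 105, 60, 55, 58, 20, 25, 22]
    counts.loc["g_up"] = [10, 12, 11, 40, 42, 45, 90, 95, 99]
    counts.loc["g_flat"] = rng.integers(50, 60, 9)
    counts.loc["sym_1"] = [5, 6, 4, 5, 7, 6, 5, 4, 6]
    organism = pd.Series(
        ["host", "host", "host", "symbiont"], index=counts.index, name="organism"
    )
    return CountMatrix(counts=counts, organism=organism, design=design_3x3)
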