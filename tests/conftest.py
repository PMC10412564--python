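import numpy as np
import pandas as pd
import pytest

from refstab.io import CqMatrix


def make_matrix(values, genes=None, samples=None, conditions=None, setting_id="S1", sample_type="cell_line"):
    """Build a CqMatrix from a 2-D array (genes × samples)."""
    values = np.asarray(values, float)
    g, s = values.shape
    genes = genes or [f"G{i+1}" for i in range(g)]
    samples = samples or [f"smp{j+1}" for j in range(s)]
    conditions = conditions or ["control"] * (s // 2) + ["treated"] * (s - s // 2)
    return CqMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        condition_of=pd.Series(conditions, index=samples),
        setting_id=setting_id,
        sample_type=sample_type,
    )


@pytest.fixture
def toy_matrix():
    """3 genes × 3 samples: X and Y identical ramps, Z the reverse ramp."""
    return make_matrix([[1, 2, 3], [1, 2, 3], [3, 2, 1]], genes=["X", "Y", "Z"])


@pytest.fixture
def random_matrices():
    """100 random 5-gene × 6-sample Cq matrices on a realistic cycle scale."""
    rng = np.random.default_rng(42)
    out = []
    for _ in range(100):
        base = rng.uniform(15, 30, size=(5, 1))
        x = base + rng.normal(0, 1.0, size=(5, 6))
        out.append(make_matrix(x, conditions=["control"] * 3 + ["treated"] * 3))
    return out


def tidy_records(cells, sample_type="cell_line", setting="S1"):
    """Long-form Cq DataFrame from {(gene, sample, condition): [cq, ...]}."""
    rows = []
    for (gene, sample, condition), cqs in cells.items():
        for r, cq in enumerate(cqs, start=1):
            rows.append({
                "gene": gene, "sample": sample, "sample_type": sample_type,
                "setting": setting, "condition": condition, "replicate": r, "cq": cq,
            })
    return pd.DataFrame(rows)
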