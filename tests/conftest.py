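import numpy as np
import pandas as pd
import pytest

from panelex import QuantTable, SyntheticSpec, generate


@pytest.fixture
def tiny_table() -> QuantTable:
    """3 molecules x 4 samples, two conditions, one missing cell."""
    df = pd.DataFrame(
        [[2.0, 1.0, 10.0, 12.0],
         [3.0, np.nan, 5.0, 4.0],
         [5.0, 4.0, 6.0, 7.0]],
        index=["ALB", "CRP", "TF"],
        columns=["control_s1", "control_s2", "disease_s1", "disease_s2"])
    conds = {"control_s1": "control", "control_s2": "control",
             "disease_s1": "disease", "disease_s2": "disease"}
    return QuantTable(df, conds)


@pytest.fixture
def planted_dataset():
    """Default synthetic dataset with known relevant molecules."""
    return generate(SyntheticSpec(), seed=11)


def make_two_group_table(n_molecules: int, n_per_group: int, seed: int,
                         shifts: dict[int, float] | None = None,
                         sd: float = 1.0, mean: float = 10.0) -> QuantTable:
    """Plain Gaussian two-group table with optional per-row group-2 shifts."""
    rng = np.random.default_rng(seed)
    values = rng.normal(mean, sd, size=(n_molecules, 2 * n_per_group))
    for row, shift in (shifts or {}).items():
        values[row, n_per_group:] += shift
    values = np.clip(values, 0.0, None)
    mol = [f"m{i:03d}" for i in range(n_molecules)]
    cols = ([f"a_s{i}" for i in range(n_per_group)]
            + [f"b_s{i}" for i in range(n_per_group)])
    conds = {c: c.split("_")[0] for c in cols}
    return QuantTable(pd.DataFrame(values, index=mol, columns=cols), conds)
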