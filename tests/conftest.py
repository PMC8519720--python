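"""Shared helpers: compact construction of small masked datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from psoimpute.data import Dataset, VariableSchema

MISSING = object()  # sentinel for an unobserved cell in make_dataset


def make_dataset(columns: dict[str, list], vtypes: dict[str, str],
                 dependent: str) -> Dataset:
    """Build a Dataset from per-column lists; MISSING marks unobserved cells."""
    names = list(columns)
    mask = {}
    values = {}
    for name in names:
        cells = columns[name]
        mask[name] = [c is not MISSING for c in cells]
        values[name] = [np.nan if c is MISSING else c for c in cells]
    schema = tuple(
        VariableSchema(n, vtypes[n], "dependent" if n == dependent else "independent")
        for n in names
    )
    vdf = pd.DataFrame({n: pd.Series(values[n], dtype=object) for n in names})
    return Dataset(vdf, pd.DataFrame(mask), schema)


@pytest.fixture
def toy_binary_dataset() -> Dataset:
    """10 fully observed records, 2 continuous features, binary outcome."""
    rng = np.random.default_rng(7)
    x1 = rng.standard_normal(10)
    x2 = rng.standard_normal(10)
    y = (x1 + x2 > 0).astype(int)
    return make_dataset(
        {"x1": x1.tolist(), "x2": x2.tolist(), "y": y.tolist()},
        {"x1": "continuous", "x2": "continuous", "y": "discrete"},
        dependent="y",
    )
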