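import numpy as np
import pandas as pd
import pytest

from ordent import ResponseTable, likert4
from ordent.synthetic import TABLE1_COUNTS, table1_fixture

# Frozen oracle values for the worked 4x4 table (natural log), computed with
# the term-by-term summation oracle in _oracles.py.
TABLE1_ROW_H = (0.766022, 0.881558, 1.102211, 1.283096)
TABLE1_H_Y = 1.235724
TABLE1_H_YX = 1.023921
TABLE1_RATIO = 0.828600
TABLE1_MCE = 0.837276


@pytest.fixture
def table1():
    return table1_fixture()


def expand_pairs(counts, x_name="Qi", y_name="Qj"):
    """Reconstruct raw per-subject label pairs from a 4x4 count table."""
    rows = []
    for i, row in enumerate(counts):
        for j, c in enumerate(row):
            rows.extend({x_name: str(i + 1), y_name: str(j + 1)} for _ in range(c))
    return pd.DataFrame(rows)


@pytest.fixture
def table1_subjects():
    """The worked table re-expanded to one row per subject, as a ResponseTable."""
    df = expand_pairs(TABLE1_COUNTS)
    return ResponseTable(
        df,
        items={"Qi": likert4("negative"), "Qj": likert4("positive")},
    )


@pytest.fixture
def small_table():
    """Tiny hand-written response table with covariates and one missing cell."""
    df = pd.DataFrame(
        {
            "Q1": ["1", "4", "3", "2", "4"],
            "Q2": ["2", "0", "3", "1", "4"],
            "gender": ["m", "f", "f", "m", "f"],
            "age": ["16", "17", "25", "15", "18"],
            "country": ["US", "US", "GB", "US", "US"],
        }
    )
    return ResponseTable(
        df,
        items={"Q1": likert4(), "Q2": likert4()},
        covariates=("gender", "age", "country"),
    )


def random_tables(n_tables, rng, max_levels=5, max_count=20):
    """Random small count matrices with non-degenerate margins."""
    out = []
    while len(out) < n_tables:
        kx = rng.integers(2, max_levels + 1)
        ky = rng.integers(2, max_levels + 1)
        counts = rng.integers(0, max_count + 1, size=(kx, ky))
        if counts.sum() == 0:
            continue
        # need both margins non-constant for ratio/MCE statistics
        if (counts.sum(axis=1) > 0).sum() < 2 or (counts.sum(axis=0) > 0).sum() < 2:
            continue
        out.append(counts)
    return out
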