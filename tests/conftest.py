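"""Shared fixtures and helpers for the test suite."""

import numpy as np
import pandas as pd
import pytest

from sbaenet.grn import Grn
from sbaenet.io import ExpressionData


def make_cases(rows):
    """Build a case table from (case_id, date, sex, country, qual, drugs,
    events) tuples."""
    return pd.DataFrame({
        "case_id": [r[0] for r in rows],
        "report_date": pd.to_datetime([r[1] for r in rows]),
        "sex": [r[2] for r in rows],
        "country": [r[3] for r in rows],
        "qualification": [r[4] for r in rows],
        "drugs": [frozenset(r[5]) for r in rows],
        "events": [frozenset(r[6]) for r in rows],
    })


def make_grn(weights, tfs=None, genes=None, sex=""):
    w = np.asarray(weights, dtype=float)
    tfs = tfs or [f"TF{i}" for i in range(w.shape[0])]
    genes = genes or [f"G{j}" for j in range(w.shape[1])]
    return Grn(weights=pd.DataFrame(w, index=tfs, columns=genes), sex=sex)


def make_expression(counts, sexes, rin=None, tissue="liver"):
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[1]
    sample_ids = [f"S{i:03d}" for i in range(n)]
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "subject_id": [f"SUBJ{i:03d}" for i in range(n)],
        "sex": list(sexes),
        "tissue": [tissue] * n,
        "rin": list(rin) if rin is not None else [8.0] * n,
        "ischemic_time": [300.0] * n,
        "age": [50] * n,
    }).set_index("sample_id")
    genes = [f"G{i:03d}" for i in range(counts.shape[0])]
    return ExpressionData(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
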