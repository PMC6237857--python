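import numpy as np
import pandas as pd
import pytest

import hccpipe as h


@pytest.fixture
def tiny_counts() -> h.CountMatrix:
    return h.CountMatrix(
        pd.DataFrame(
            [[0, 9], [10, 1000]],
            index=["G1", "G2"],
            columns=["s1", "s2"],
        )
    )


@pytest.fixture
def stage_annotation() -> h.SampleAnnotation:
    """3 samples per stage plus 3 cirrhosis samples."""
    rows = []
    for g, tissue, stage in [
        ("cirrhosis", "cirrhosis", "NA"),
        ("T1", "tumor", "T1"),
        ("T2", "tumor", "T2"),
        ("T3", "tumor", "T3"),
    ]:
        for i in range(3):
            rows.append((f"{g}_{i}", tissue, stage, "unknown", "test"))
    df = pd.DataFrame(
        rows, columns=["sample_id", "tissue_class", "stage", "phenotype", "cohort"]
    ).set_index("sample_id")
    return h.SampleAnnotation(df)


@pytest.fixture
def expr_from_groups():
    """Build a one-gene ExpressionMatrix + annotation from per-stage value lists."""

    def _build(**groups):
        values, sample_ids, rows = [], [], []
        for stage, vals in groups.items():
            for i, v in enumerate(vals):
                sid = f"{stage}_{i}"
                sample_ids.append(sid)
                values.append(v)
                tissue = "cirrhosis" if stage == "cirrhosis" else "tumor"
                rows.append((sid, tissue, "NA" if stage == "cirrhosis" else stage,
                             "unknown", "test"))
        e = h.ExpressionMatrix(
            pd.DataFrame([values], index=["G1"], columns=sample_ids)
        )
        ann = h.SampleAnnotation(
            pd.DataFrame(
                rows,
                columns=["sample_id", "tissue_class", "stage", "phenotype", "cohort"],
            ).set_index("sample_id")
        )
        return e, ann

    return _build


def brute_force_bh(p):
    """Step-up definition: q_i = min_{j>=i} p_(j) * n / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(n)
    for rank_i in range(n):
        q_sorted[rank_i] = min(
            min(p[order[j]] * n / (j + 1) for j in range(rank_i, n)), 1.0
        )
    out = np.empty(n)
    out[order] = q_sorted
    return out
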