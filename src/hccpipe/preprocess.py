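"""Count preprocessing: low-count filtering, pseudo-count log2, median centering.

The three steps run in the fixed order filter -> log -> normalize.  Genes with
fewer than 10 reads summed across the whole dataset are discarded, counts get
a pseudo-count of 1 before the log2 transform, and each sample column is then
shifted so its median is 0, which makes samples with different library sizes
comparable and drives the pooled median of the matrix to 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, ExpressionMatrix


def filter_low_count(m: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Drop genes whose total count across all samples is below ``min_total``.

    "Less than 10 reads" means the boundary row-sum of exactly 10 is kept.
    Gene order and the sample set are preserved; an all-filtered matrix keeps
    its samples with an empty gene list.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = m.data.sum(axis=1) >= min_total
    return CountMatrix(m.data.loc[keep])


def log_transform(m: CountMatrix) -> ExpressionMatrix:
    """log2(count + 1), elementwise."""
    return ExpressionMatrix(np.log2(m.data.astype(float) + 1.0))


def normalize_median(e: ExpressionMatrix) -> ExpressionMatrix:
    """Center every sample column at median 0.

    The median of an even-length column is the midpoint of the two central
    values.  The operation is idempotent.
    """
    if e.data.shape[0] == 0:
        raise ValueError("cannot median-center a matrix with no genes")
    medians = e.data.median(axis=0)
    return ExpressionMatrix(e.data.sub(medians, axis=1))


def preprocess_counts(m: CountMatrix, min_total: int = 10) -> ExpressionMatrix:
    """Full preprocessing pipeline: filter -> log2(x+1) -> per-sample centering."""
    return normalize_median(log_transform(filter_low_count(m, min_total)))
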