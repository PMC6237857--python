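"""Peri- vs intra-tumoral differential expression and the exclusion gene set.

A per-gene two-sample t-test (pooled-variance Student by default, Welch via a
flag) compares peri-tumoral against intra-tumoral samples; p-values are
BH-adjusted and the exclusion gene set keeps genes at FDR < 0.125 with more
than 2-fold change, optionally restricted to those up-regulated in the
peri-tumoral (T-cell-excluded) phenotype.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st

from .io_formats import ExpressionMatrix, SampleAnnotation
from .stage_association import GeneStatTable, bh_adjust


def ttest_per_gene(
    e: ExpressionMatrix, ann: SampleAnnotation, welch: bool = False
) -> GeneStatTable:
    """Two-sided two-sample t-test of peri vs intra phenotype, per gene.

    Samples with unknown phenotype are excluded.  ``effect`` is
    mean(peri) - mean(intra) in log2 expression units, so a positive effect
    means higher expression in the peri-tumoral samples.
    """
    peri = [s for s in ann.samples_with(phenotype="peri") if s in e.data.columns]
    intra = [s for s in ann.samples_with(phenotype="intra") if s in e.data.columns]
    for name, ids in (("peri", peri), ("intra", intra)):
        if len(ids) < 2:
            raise ValueError(f"phenotype group {name!r} has fewer than 2 samples")
    a = e.data[peri].to_numpy()
    b = e.data[intra].to_numpy()
    res = st.ttest_ind(a, b, axis=1, equal_var=not welch)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # constant identical rows give 0/0; define t = 0, p = 1
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    table = pd.DataFrame(
        {
            "statistic": t,
            "p_value": p,
            "fdr": bh_adjust(p),
            "effect": a.mean(axis=1) - b.mean(axis=1),
        },
        index=e.data.index,
    )
    return GeneStatTable(table)


def select_ctl_ex(
    t: GeneStatTable,
    fdr_max: float = 0.125,
    min_abs_log2fc: float = 1.0,
    direction: str | None = "up_in_peri",
) -> list[str]:
    """Exclusion-signature selection: FDR < 0.125 and |log2FC| > 1, up in peri.

    Both cut-offs are strict.  ``direction=None`` keeps the two-sided
    selection; the default ``"up_in_peri"`` additionally requires a positive
    effect, matching the published definition of the exclusion gene set.
    """
    if direction not in (None, "up_in_peri"):
        raise ValueError(f"unknown direction {direction!r}")
    keep = (t.data["fdr"] < fdr_max) & (t.data["effect"].abs() > min_abs_log2fc)
    if direction == "up_in_peri":
        keep &= t.data["effect"] > 0
    return list(t.data.index[keep])
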