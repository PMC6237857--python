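"""Stage-associated gene discovery, trend clustering and signature scoring.

Genes associated with tumor stage are found by a per-gene one-way ANOVA over
the T1/T2/T3 groups (cirrhosis and unassessable TX/NA samples are excluded
from the test), with Benjamini-Hochberg FDR control and a log2
between-mean-variance effect filter.  Selected genes are clustered into trend
clusters (Ward linkage on 1 - Pearson correlation) and each cluster is scored
per sample as the average z-score of its genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, SampleAnnotation, TUMOR_STAGES

logger = logging.getLogger("hccpipe")

#: Transcriptional proxy for cytotoxic T-effector presence.
TEFF_GENES = ("GZMA", "GZMB", "PRF1", "EOMES", "CD8A")


@dataclass(frozen=True)
class GeneStatTable:
    """Per-gene test results.

    ``effect`` is the log2 between-mean variance for the stage ANOVA and the
    log2 fold-change (peri minus intra) for differential expression.
    """

    data: pd.DataFrame  # index gene_id; columns statistic, p_value, fdr, effect

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass(frozen=True)
class GeneClusterSet:
    """Disjoint gene clusters plus a description of the linkage used.

    Labels are integers 1..k assigned by decreasing cluster size, ties broken
    by the smallest member gene id.
    """

    clusters: dict[int, list[str]]
    linkage: str = "ward on 1 - Pearson correlation"

    def labels(self) -> pd.Series:
        out = {}
        for lab, genes in self.clusters.items():
            for g in genes:
                out[g] = lab
        return pd.Series(out, name="cluster")


@dataclass(frozen=True)
class SignatureScore:
    """Per-sample signature score (average of per-gene z-scores)."""

    scores: pd.Series  # index sample_id
    genes: tuple[str, ...] = field(default=())


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def anova_per_gene(
    e: ExpressionMatrix,
    ann: SampleAnnotation,
    groups: tuple[str, ...] = TUMOR_STAGES,
    between_mean_square: bool = False,
) -> GeneStatTable:
    """One-way fixed-effects ANOVA of expression against stage, per gene.

    Samples are grouped by annotated stage, keeping only tumor samples whose
    stage is in ``groups``.  For each gene the F statistic
    ``(SSB/(k-1)) / (SSW/(n-k))`` is referred to the upper tail of
    F(k-1, n-k).  The effect column is log2 of the sample variance (ddof 1)
    of the k group means (-inf when the means are identical), or, with
    ``between_mean_square=True``, log2 of the between-group mean square.
    """
    group_samples: list[np.ndarray] = []
    for g in groups:
        if g == "cirrhosis":
            ids = ann.samples_with(tissue_class="cirrhosis")
        else:
            ids = ann.samples_with(tissue_class="tumor", stage=g)
        ids = [s for s in ids if s in e.data.columns]
        if len(ids) < 2:
            raise ValueError(f"stage group {g!r} has fewer than 2 samples")
        group_samples.append(e.data[ids].to_numpy())
    if len(group_samples) < 2:
        raise ValueError("ANOVA needs at least 2 groups")

    k = len(group_samples)
    ns = np.array([g.shape[1] for g in group_samples])
    n = int(ns.sum())
    means = np.column_stack([g.mean(axis=1) for g in group_samples])  # genes x k
    grand = np.concatenate(group_samples, axis=1).mean(axis=1)
    ssb = (ns[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.zeros_like(ssb)
    for g, mu in zip(group_samples, means.T):
        ssw += ((g - mu[:, None]) ** 2).sum(axis=1)
    df1, df2 = k - 1, n - k
    msb = ssb / df1
    msw = ssw / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(msw > 0, msb / np.where(msw > 0, msw, 1.0), np.inf)
        f = np.where((msb == 0) & (msw == 0), np.nan, f)
        p = st.f.sf(f, df1, df2)
        bmv = msb if between_mean_square else means.var(axis=1, ddof=1)
        effect = np.where(bmv > 0, np.log2(np.where(bmv > 0, bmv, 1.0)), -np.inf)
    table = pd.DataFrame(
        {
            "statistic": f,
            "p_value": p,
            "fdr": bh_adjust(np.nan_to_num(p, nan=1.0)),
            "effect": effect,
        },
        index=e.data.index,
    )
    return GeneStatTable(table)


def select_stage_genes(
    t: GeneStatTable, fdr_max: float = 0.25, log2_bmv_min: float = -3.0
) -> list[str]:
    """Genes with FDR < ``fdr_max`` and log2 between-mean variance > ``log2_bmv_min``.

    Both inequalities are strict, so a gene sitting exactly at a cut-off is
    excluded.  Input order is preserved.
    """
    keep = (t.data["fdr"] < fdr_max) & (t.data["effect"] > log2_bmv_min)
    return list(t.data.index[keep])


def _relabel_by_size(genes: list[str], raw_labels: np.ndarray) -> dict[int, list[str]]:
    """Map raw cluster labels to 1..k by decreasing size, ties by smallest member."""
    members: dict[int, list[str]] = {}
    for g, lab in zip(genes, raw_labels):
        members.setdefault(int(lab), []).append(g)
    order = sorted(members, key=lambda lab: (-len(members[lab]), min(members[lab])))
    return {i + 1: members[lab] for i, lab in enumerate(order)}


def cluster_genes(e: ExpressionMatrix, genes: list[str], k: int) -> GeneClusterSet:
    """Ward agglomerative clustering of genes with distance 1 - Pearson r, cut at k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(genes) < k:
        raise ValueError(f"need at least k={k} genes, got {len(genes)}")
    x = e.data.loc[genes].to_numpy()
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = genes[int(np.argmax(sd == 0))]
        raise ValueError(f"gene {bad!r} has zero variance; correlation undefined")
    corr = np.corrcoef(x)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = sch.linkage(squareform(dist, checks=False), method="ward")
    raw = sch.fcluster(z, t=k, criterion="maxclust")
    return GeneClusterSet(_relabel_by_size(genes, raw))


def cluster_samples(e: ExpressionMatrix, k: int) -> pd.Series:
    """Ward clustering of samples on Euclidean distance; labels 1..k by size."""
    if k < 1:
        raise ValueError("k must be >= 1")
    samples = list(e.data.columns)
    if len(samples) < k:
        raise ValueError(f"need at least k={k} samples, got {len(samples)}")
    z = sch.linkage(e.data.to_numpy().T, method="ward")
    raw = sch.fcluster(z, t=k, criterion="maxclust")
    clusters = _relabel_by_size(samples, raw)
    out = pd.Series(index=samples, dtype=int, name="cluster")
    for lab, ids in clusters.items():
        out[ids] = lab
    return out


def signature_score(e: ExpressionMatrix, genes) -> SignatureScore:
    """Average z-score of the given genes, per sample.

    Each gene row is standardized across all samples of the matrix (mean 0,
    sd 1 with ddof 1); the score of a sample is the mean of these z-scores
    over the signature genes, so scores average to 0 across the scored
    samples.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in e.data.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    x = e.data.loc[genes]
    sd = x.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"zero-variance gene(s): {bad}")
    z = x.sub(x.mean(axis=1), axis=0).div(sd, axis=0)
    return SignatureScore(z.mean(axis=0).rename("score"), tuple(genes))


def teff_signature(e: ExpressionMatrix, genes=TEFF_GENES) -> SignatureScore:
    """T-effector signature: average z-score of GZMA, GZMB, PRF1, EOMES, CD8A."""
    missing = [g for g in genes if g not in e.data.index]
    if missing:
        raise KeyError(f"T-effector gene(s) absent from matrix: {missing}")
    return signature_score(e, genes)


def trend_summary(
    score: SignatureScore, ann: SampleAnnotation, order: tuple[str, ...]
) -> tuple[pd.Series, str]:
    """Group-mean scores along ``order`` plus a monotonicity verdict.

    The verdict is derived from strict comparisons of consecutive group
    means: ``decreasing``, ``increasing``, ``up_then_down`` (strictly rising
    then strictly falling), otherwise ``none``.
    """
    means = {}
    for g in order:
        if g in ("cirrhosis", "tumor"):
            ids = ann.samples_with(tissue_class=g)
        else:
            ids = ann.samples_with(stage=g)
        ids = [s for s in ids if s in score.scores.index]
        if not ids:
            raise ValueError(f"group {g!r} has no scored samples")
        means[g] = float(score.scores[ids].mean())
    m = pd.Series(means, name="mean_score")
    diffs = np.diff(m.to_numpy())
    if np.all(diffs < 0):
        verdict = "decreasing"
    elif np.all(diffs > 0):
        verdict = "increasing"
    else:
        peak = int(np.argmax(m.to_numpy()))
        rising, falling = diffs[:peak], diffs[peak:]
        if 0 < peak < len(m) - 1 and np.all(rising > 0) and np.all(falling < 0):
            verdict = "up_then_down"
        else:
            verdict = "none"
    return m, verdict
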