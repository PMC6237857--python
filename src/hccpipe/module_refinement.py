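"""Cross-indication refinement of a candidate gene set to a conserved module.

For each expression dataset ("indication") a Pearson correlation matrix is
computed over the candidate genes; the element-wise minimum of these matrices
is the reference correlation matrix, whose high cells mark gene pairs that
stay correlated in every dataset.  Clustering the reference matrix splits the
candidates into a conserved module (module1, the cluster with the highest
internal median reference correlation) and the remainder (module2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
from scipy.spatial.distance import squareform

from .io_formats import ExpressionMatrix
from .stage_association import SignatureScore, signature_score

logger = logging.getLogger("hccpipe")


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric gene-gene Pearson correlation matrix with unit diagonal."""

    data: pd.DataFrame  # square, index == columns == gene ids

    def __post_init__(self) -> None:
        v = self.data.to_numpy()
        if list(self.data.index) != list(self.data.columns):
            raise ValueError("correlation matrix index/columns mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix not symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.any(v < -1 - 1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass(frozen=True)
class ReferenceCorrelationMatrix(CorrelationMatrix):
    """Element-wise minimum of per-dataset correlation matrices."""

    sources: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class ModuleAssignment:
    """Partition of candidate genes into module1 (conserved) and module2."""

    labels: pd.Series  # gene_id -> "module1" | "module2"
    internal_medians: dict[str, float]

    def genes(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def correlation_matrix(e: ExpressionMatrix, genes) -> CorrelationMatrix:
    """Pairwise Pearson correlations of the given genes over this dataset's samples."""
    genes = list(genes)
    missing = [g for g in genes if g not in e.data.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    if e.data.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlations")
    x = e.data.loc[genes].to_numpy()
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = genes[int(np.argmax(sd == 0))]
        raise ValueError(f"gene {bad!r} has zero variance; correlation undefined")
    corr = np.clip(np.corrcoef(x), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(pd.DataFrame(corr, index=genes, columns=genes))


def min_reference_matrix(mats: list[CorrelationMatrix]) -> ReferenceCorrelationMatrix:
    """Cell-wise minimum across per-dataset correlation matrices.

    Matrices are aligned by gene id (order taken from the first matrix);
    genes absent from any dataset are dropped with a warning.  Negative
    correlations are allowed to dominate the minimum.
    """
    if not mats:
        raise ValueError("need at least one correlation matrix")
    shared = [g for g in mats[0].gene_ids if all(g in m.data.index for m in mats)]
    dropped = set(mats[0].gene_ids) - set(shared)
    for m in mats[1:]:
        dropped |= set(m.gene_ids) - set(shared)
    if dropped:
        logger.warning("%d gene(s) absent from some dataset dropped", len(dropped))
    if not shared:
        raise ValueError("no genes shared across all datasets")
    stack = np.stack([m.data.loc[shared, shared].to_numpy() for m in mats])
    ref = stack.min(axis=0)
    ref = (ref + ref.T) / 2.0  # guard float asymmetry from reindexing
    np.fill_diagonal(ref, 1.0)
    return ReferenceCorrelationMatrix(
        pd.DataFrame(ref, index=shared, columns=shared),
        sources=tuple(f"dataset{i}" for i in range(len(mats))),
    )


def _internal_median(ref: np.ndarray, idx: np.ndarray) -> float:
    """Median off-diagonal reference correlation within a gene subset.

    Singletons have no off-diagonal entries; their median is defined as
    -inf so a singleton is never preferred unless every cluster is one.
    """
    if idx.size < 2:
        return -np.inf
    sub = ref[np.ix_(idx, idx)]
    return float(np.median(sub[np.triu_indices(idx.size, k=1)]))


def extract_modules(r: ReferenceCorrelationMatrix, k: int = 2) -> ModuleAssignment:
    """Cluster the reference matrix and name the tightest cluster module1.

    Ward linkage on distance 1 - reference correlation, cut at ``k``;
    module1 is the cluster with the largest internal median off-diagonal
    reference correlation (ties broken deterministically by smallest member
    id, with a warning); all other genes are module2.
    """
    genes = r.gene_ids
    if len(genes) < k:
        raise ValueError(f"need at least k={k} genes, got {len(genes)}")
    ref = r.data.to_numpy()
    dist = np.clip(1.0 - ref, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = sch.linkage(squareform(dist, checks=False), method="ward")
    raw = sch.fcluster(z, t=k, criterion="maxclust")
    clusters = {lab: np.flatnonzero(raw == lab) for lab in np.unique(raw)}
    medians = {lab: _internal_median(ref, idx) for lab, idx in clusters.items()}
    best_m = max(medians.values())
    winners = [lab for lab, m in medians.items() if m == best_m]
    if len(winners) > 1:
        logger.warning("tie in internal median correlations; smallest member id wins")
        winners.sort(key=lambda lab: min(genes[i] for i in clusters[lab]))
    best = winners[0]
    labels = pd.Series(
        ["module1" if lab == best else "module2" for lab in raw],
        index=genes, name="module",
    )
    mod2_idx = np.flatnonzero(raw != best)
    return ModuleAssignment(
        labels=labels,
        internal_medians={
            "module1": medians[best],
            "module2": _internal_median(ref, mod2_idx),
        },
    )


def median_pairwise_correlation(e: ExpressionMatrix, genes) -> float:
    """Median off-diagonal pairwise Pearson correlation of ``genes`` in this dataset."""
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    corr = correlation_matrix(e, genes).data.to_numpy()
    return float(np.median(corr[np.triu_indices(len(genes), k=1)]))


def subtype_discrimination(
    e: ExpressionMatrix,
    module_genes,
    subtype_labels: pd.Series,
    flagged_subtype: str,
) -> tuple[pd.DataFrame, float]:
    """Module signature scores per subtype and a rank-sum test for the flagged one.

    Returns a per-sample table (score, subtype) and the two-sided
    Wilcoxon rank-sum p-value comparing the flagged subtype against all
    other samples; the exact null distribution is used when both groups have
    at most 10 samples.
    """
    labels = subtype_labels.reindex(e.data.columns)
    if labels.isna().any():
        raise ValueError("every sample needs a subtype label")
    if (labels == flagged_subtype).sum() == 0:
        raise ValueError(f"subtype {flagged_subtype!r} has no samples")
    if (labels != flagged_subtype).sum() == 0:
        raise ValueError("no samples outside the flagged subtype")
    score: SignatureScore = signature_score(e, module_genes)
    a = score.scores[labels == flagged_subtype].to_numpy()
    b = score.scores[labels != flagged_subtype].to_numpy()
    method = "exact" if max(len(a), len(b)) <= 10 else "asymptotic"
    p = float(st.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
    table = pd.DataFrame({"score": score.scores, "subtype": labels})
    return table, p
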