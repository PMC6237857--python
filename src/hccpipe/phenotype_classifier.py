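"""Immune-phenotype classification from a module signature score.

Samples are called peri-tumoral (CD8+ T-cell excluded; the positive class,
since the conserved module is up-regulated in excluded tumors) when their
signature score exceeds a threshold.  The threshold is fit on one cohort by
maximizing Youden's J over midpoints of consecutive sorted scores and can
then be frozen and applied to an independent cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stage_association import SignatureScore


@dataclass(frozen=True)
class ClassificationMetrics:
    threshold: float
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")


def _check_labels(labels: pd.Series) -> None:
    bad = set(labels.unique()) - {"peri", "intra"}
    if bad:
        raise ValueError(f"labels must be 'peri' or 'intra', got {sorted(bad)}")


def fit_threshold(scores: SignatureScore, labels: pd.Series, mode: str = "youden") -> float:
    """Fit a score threshold separating peri (positive, high) from intra.

    ``youden`` (default) maximizes sensitivity + specificity - 1 over the
    midpoints of consecutive sorted scores, taking the lowest maximizing
    threshold.  ``cluster`` instead splits the scores into two 1-D k-means
    clusters and returns the midpoint between the cluster means.
    """
    labels = labels.reindex(scores.scores.index).dropna()
    _check_labels(labels)
    s = scores.scores[labels.index].to_numpy()
    y = (labels == "peri").to_numpy()
    if y.all() or (~y).all():
        raise ValueError("both phenotype classes must be present to fit a threshold")

    if mode == "cluster":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(s.reshape(-1, 1))
        lo, hi = sorted(km.cluster_centers_.ravel())
        return float((lo + hi) / 2)
    if mode != "youden":
        raise ValueError(f"unknown threshold mode {mode!r}")

    order = np.sort(np.unique(s))
    if order.size == 1:
        candidates = np.array([order[0]])
    else:
        candidates = (order[:-1] + order[1:]) / 2.0
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    best_t, best_j = float(candidates[0]), -np.inf
    for t in candidates:
        calls = s > t
        sens = (calls & y).sum() / n_pos
        spec = (~calls & ~y).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j:  # strict: ties keep the lowest threshold
            best_j, best_t = j, float(t)
    return best_t


def classify(scores: SignatureScore, threshold: float) -> pd.Series:
    """Call each sample: score > threshold -> peri, else intra (strict boundary)."""
    calls = np.where(scores.scores.to_numpy() > threshold, "peri", "intra")
    return pd.Series(calls, index=scores.scores.index, name="call")


def evaluate(calls: pd.Series, labels: pd.Series, threshold: float = float("nan")) -> ClassificationMetrics:
    """Confusion counts and sensitivity/specificity with peri as positive class."""
    _check_labels(calls)
    missing = [s for s in calls.index if s not in labels.index]
    if missing:
        raise ValueError(f"called sample(s) without labels: {missing}")
    labels = labels.reindex(calls.index)
    _check_labels(labels)
    c = calls == "peri"
    y = labels == "peri"
    return ClassificationMetrics(
        threshold=threshold,
        tp=int((c & y).sum()),
        fn=int((~c & y).sum()),
        tn=int((~c & ~y).sum()),
        fp=int((c & ~y).sum()),
    )
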