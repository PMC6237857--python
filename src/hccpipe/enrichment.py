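"""Over-representation analysis of a gene list against a gene-set collection.

Each set is tested with a one-sided Fisher's exact (hypergeometric upper
tail) test for over-representation of the query list within the expression
universe; p-values are BH-adjusted across the tested sets and sets at
adjusted p < 0.10 are flagged significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.stats as st

from .io_formats import GeneSetCollection
from .stage_association import bh_adjust

logger = logging.getLogger("hccpipe")


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size_in_universe: int
    list_size: int
    universe_size: int
    p_value: float
    fdr: float
    significant: bool

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size_in_universe, self.list_size):
            raise ValueError("overlap exceeds its margins")


def fisher_enrichment(
    query,
    universe,
    sets: GeneSetCollection,
    fdr_max: float = 0.10,
    two_sided: bool = False,
    min_set_size: int = 2,
) -> list[EnrichmentResult]:
    """Fisher over-representation of ``query`` genes in each set, within ``universe``.

    Query genes outside the universe are dropped with a warning.  For a set
    with K genes in the universe of size M and a query of size N, the
    one-sided p is the hypergeometric upper tail P(X >= overlap); with
    ``two_sided=True`` the classical two-sided Fisher exact p is reported
    instead.  Sets with fewer than ``min_set_size`` genes in the universe are
    skipped with a warning.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty universe")
    useen = set()
    for g in universe:
        if g in useen:
            raise ValueError(f"duplicate gene {g!r} in universe")
        useen.add(g)
    query_set = set(query)
    stray = query_set - useen
    if stray:
        logger.warning("%d query gene(s) outside the universe dropped", len(stray))
        query_set -= stray
    M, N = len(universe), len(query_set)

    rows: list[tuple[str, int, int, float]] = []
    for name in sets:
        members = set(sets[name]) & useen
        K = len(members)
        if K < min_set_size:
            logger.warning("set %r has %d gene(s) in universe; skipped", name, K)
            continue
        x = len(members & query_set)
        if two_sided:
            table = [[x, K - x], [N - x, M - K - (N - x)]]
            p = float(st.fisher_exact(table, alternative="two-sided")[1])
        else:
            p = float(st.hypergeom.sf(x - 1, M, K, N))
        rows.append((name, x, K, p))

    fdrs = bh_adjust([r[3] for r in rows]) if rows else np.array([])
    return [
        EnrichmentResult(
            set_name=name,
            overlap=x,
            set_size_in_universe=K,
            list_size=N,
            universe_size=M,
            p_value=p,
            fdr=float(q),
            significant=bool(q < fdr_max),
        )
        for (name, x, K, p), q in zip(rows, fdrs)
    ]
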