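"""Classical overrepresentation analysis (ORA).

Each pathway is scored by the one-sided upper-tail hypergeometric
probability that a pathway of its size, drawn from a background of *n* DE
and *m* non-DE genes, contains at least as many DE genes as observed --
the enrichment-only Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .gene_sets import GenePathwayMatrix

__all__ = ["PathwayResult", "ora_pathway", "ora_pvalues", "run_ora"]


@dataclass(frozen=True)
class PathwayResult:
    """ORA result for one pathway: contingency counts, p-value and rank."""

    pathway_id: str
    a: int  # DE genes in the pathway
    b: int  # non-DE genes in the pathway
    p_value: float
    rank: int


def ora_pathway(a: int, b: int, n: int, m: int) -> float:
    """Upper-tail hypergeometric p-value for one pathway.

    P(X >= a) where X ~ Hypergeom(N = n+m, K = n, draw = a+b): the chance
    that a random gene set of the pathway's size contains at least ``a`` of
    the ``n`` DE genes.  An empty pathway (a + b = 0) scores 1.
    """
    if min(a, b, n, m) < 0:
        raise ValueError("counts must be non-negative")
    if a > n or b > m:
        raise ValueError("cell counts exceed margins (a <= n, b <= m required)")
    size = a + b
    if size == 0:
        return 1.0
    return float(hypergeom.sf(a - 1, n + m, n, size))


def ora_pvalues(a: np.ndarray, sizes: np.ndarray, n: int, m: int) -> np.ndarray:
    """Vectorised ``ora_pathway`` over per-pathway DE counts and sizes."""
    a = np.asarray(a, dtype=int)
    sizes = np.asarray(sizes, dtype=int)
    if (a < 0).any() or (sizes < a).any():
        raise ValueError("invalid counts")
    p = np.ones(a.shape, dtype=float)
    nonempty = sizes > 0
    p[nonempty] = hypergeom.sf(a[nonempty] - 1, n + m, n, sizes[nonempty])
    return p


def run_ora(X: GenePathwayMatrix, alpha: float = 0.05) -> list[PathwayResult]:
    """ORA over every column of a membership (or impact) matrix.

    ``a_i`` counts the 1s of column *i* among the top ``n_de`` rows, ``b_i``
    among the remaining rows; the background margins are the matrix's own
    (n_de, n_nde) split.  Results carry a 1-based rank by ascending p-value
    (ties keep column order).  All-zero columns score p = 1.
    """
    a = X.de_counts()
    sizes = X.column_sizes()
    p = ora_pvalues(a, sizes, X.n_de, X.n_nde)
    order = np.argsort(p, kind="stable")
    rank = np.empty(len(p), dtype=int)
    rank[order] = np.arange(1, len(p) + 1)
    return [
        PathwayResult(pid, int(ai), int(si - ai), float(pi), int(ri))
        for pid, ai, si, pi, ri in zip(X.pathway_ids, a, sizes, p, rank)
    ]


def results_frame(results: list[PathwayResult]) -> pd.DataFrame:
    """Ranked results table (rank, pathway, DE count, size, p-value)."""
    df = pd.DataFrame(
        {
            "rank": [r.rank for r in results],
            "pathway": [r.pathway_id for r in results],
            "de_in_pathway": [r.a for r in results],
            "pathway_size": [r.a + r.b for r in results],
            "p_value": [r.p_value for r in results],
        }
    )
    return df.sort_values("rank").reset_index(drop=True)
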