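"""Expression-driven crosstalk correction via leave-one-out PC1 correlation.

Each pathway's expression submatrix is summarised by its first principal
component (the "eigengene").  A gene is scored against each of its member
pathways by the Pearson correlation between its own expression profile and
the PC1 of the pathway *with the gene itself removed* (leave-one-out, so a
gene cannot vote for itself), and is reassigned to the member pathway with
the strongest correlation.  Because the sign of a principal component is
arbitrary, correlations are taken in absolute value by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix
from .gene_sets import GenePathwayMatrix, ImpactMatrix

__all__ = ["PC1Vector", "CorrelationMatrix", "pc1", "build_correlation_matrix", "pca_correct"]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class PC1Vector:
    """Per-subject scores of the first principal component of a gene block.

    ``degenerate`` marks an all-constant input (zero variance), for which the
    scores are a zero vector.
    """

    scores: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


def pc1(E: np.ndarray) -> PC1Vector:
    """First principal component scores of a genes x subjects block.

    Rows (genes) are mean-centered; no variance scaling.  The scores are the
    leading right-singular vector of the centered block, scaled by its
    singular value, with the sign fixed so that the largest-magnitude gene
    loading is positive.  A single-row block returns that row, centered.
    """
    E = np.atleast_2d(np.asarray(E, dtype=float))
    if E.shape[1] < 2:
        raise ValueError("at least two subjects required")
    M = E - E.mean(axis=1, keepdims=True)
    if not np.any(np.abs(M) > _EPS):
        return PC1Vector(np.zeros(E.shape[1]), degenerate=True)
    if M.shape[0] == 1:
        return PC1Vector(M[0].copy())
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    loadings = U[:, 0]
    scores = s[0] * Vt[0]
    if loadings[np.argmax(np.abs(loadings))] < 0:
        scores = -scores
    return PC1Vector(scores)


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r, defined as 0 when either vector is constant."""
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx < _EPS or ny < _EPS:
        return 0.0
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


@dataclass
class CorrelationMatrix:
    """Gene x pathway correlation scores C; zero wherever X is zero.

    ``degenerate`` flags member cells whose score is 0 only because the
    leave-one-out block or the gene row was constant (or the pathway is a
    singleton), not because the correlation itself vanished.
    """

    gene_ids: list[str]
    pathway_ids: list[str]
    values: np.ndarray
    degenerate: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        if self.values.shape != (len(self.gene_ids), len(self.pathway_ids)):
            raise ValueError("shape mismatch")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.pathway_ids)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")


def build_correlation_matrix(
    X: GenePathwayMatrix,
    expr: ExpressionMatrix,
    absolute: bool = True,
) -> CorrelationMatrix:
    """Score every (gene, member pathway) pair by leave-one-out PC1 correlation.

    For each member gene *i* of pathway *j*: remove gene *i*'s row from the
    pathway's expression block, take the PC1 of the remainder, and record the
    Pearson correlation with gene *i*'s own profile (absolute value by
    default; ``absolute=False`` keeps the signed value under the PC1 sign
    convention).  Non-member cells are exactly 0.  Singleton pathways and
    constant blocks produce a flagged 0.
    """
    if expr.n_samples < 2:
        raise ValueError("at least two subjects required")
    gene_to_row = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [g for g in X.gene_ids if g not in gene_to_row]
    if missing:
        raise ValueError(
            f"{len(missing)} matrix genes missing from expression data, "
            f"e.g. {missing[:5]}"
        )
    rows = np.array([gene_to_row[g] for g in X.gene_ids])
    E = expr.values[rows]  # aligned to X's gene order
    C = np.zeros((X.n_genes, X.n_pathways))
    degen = np.zeros(C.shape, dtype=bool)
    for j in range(X.n_pathways):
        members = np.flatnonzero(X.values[:, j])
        block = E[members]
        for pos, i in enumerate(members):
            if len(members) == 1:
                degen[i, j] = True
                continue
            loo = np.delete(block, pos, axis=0)
            comp = pc1(loo)
            if comp.degenerate:
                degen[i, j] = True
                continue
            r = _safe_pearson(comp.scores, E[i])
            if r == 0.0 and np.ptp(E[i]) < _EPS:
                degen[i, j] = True
            C[i, j] = abs(r) if absolute else r
    return CorrelationMatrix(
        gene_ids=list(X.gene_ids),
        pathway_ids=list(X.pathway_ids),
        values=C,
        degenerate=degen,
    )


def pca_correct(
    X: GenePathwayMatrix,
    expr: ExpressionMatrix,
    absolute: bool = True,
    return_correlations: bool = False,
) -> ImpactMatrix | tuple[ImpactMatrix, CorrelationMatrix]:
    """Reassign each gene to its best-correlated member pathway.

    The argmax runs over member columns only (a gene never leaves its
    original pathways); ties break to the lowest column index.  A gene whose
    every member score is degenerate falls back to its largest member
    pathway (logged).
    """
    C = build_correlation_matrix(X, expr, absolute=absolute)
    sizes = X.column_sizes()
    member_mask = X.values.astype(bool)
    Z = np.zeros_like(X.values, dtype=np.int8)
    n_fallback = 0
    for i in range(X.n_genes):
        cols = np.flatnonzero(member_mask[i])
        informative = cols[~C.degenerate[i, cols]]
        if informative.size == 0:
            # no informative score at all: largest member pathway wins
            j = cols[np.argmax(sizes[cols])]
            n_fallback += 1
        else:
            scores = C.values[i, informative]
            j = informative[np.argmax(scores)]
        Z[i, j] = 1
    if n_fallback:
        logger.warning(
            "%d gene(s) had only degenerate correlation scores; "
            "assigned to their largest member pathway",
            n_fallback,
        )
    impact = ImpactMatrix(
        gene_ids=list(X.gene_ids),
        pathway_ids=list(X.pathway_ids),
        values=Z,
        n_de=X.n_de,
        de_pvalues=X.de_pvalues.copy(),
    )
    impact.check_within(X)
    return (impact, C) if return_correlations else impact
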