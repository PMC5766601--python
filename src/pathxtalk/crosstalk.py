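"""Pairwise crosstalk quantification.

For every ordered pathway pair (i, j) the enrichment of P_i is recomputed
after deleting the genes P_i shares with P_j.  A pathway whose significance
collapses once an intersection is removed owes that significance to the
shared genes -- the crosstalk effect.  The background margins (n DE, m
non-DE) are left untouched: only the pathway's own membership shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_sets import GenePathwayMatrix
from .ora import ora_pvalues

__all__ = ["CrosstalkMatrix", "crosstalk_matrix", "export_heatmap"]


@dataclass
class CrosstalkMatrix:
    """k x k matrix of leave-intersection-out ORA p-values.

    Cell [i, j] is the p-value of pathway P_i after removing its
    intersection with P_j; the diagonal holds the original p-values.  Rows
    and columns are ordered by ascending original p-value.
    """

    pathway_ids: list[str]
    values: np.ndarray
    original_p: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.pathway_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.original_p = np.asarray(self.original_p, dtype=float)
        if self.values.shape != (k, k):
            raise ValueError("crosstalk matrix must be k x k")
        if not np.allclose(np.diag(self.values), self.original_p):
            raise ValueError("diagonal must equal the original p-values")
        if (self.values <= 0).any() or (self.values > 1).any():
            raise ValueError("p-values must lie in (0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pathway_ids, columns=self.pathway_ids)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "pathway"
        df.to_csv(path, sep="\t")

    def top(self, n: int) -> "CrosstalkMatrix":
        """Leading n x n submatrix (the most significant pathways)."""
        return CrosstalkMatrix(
            pathway_ids=self.pathway_ids[:n],
            values=self.values[:n, :n].copy(),
            original_p=self.original_p[:n].copy(),
        )


def crosstalk_matrix(X: GenePathwayMatrix, alpha: float = 0.05) -> CrosstalkMatrix:
    """Compute the full k x k crosstalk matrix of a membership matrix.

    For i != j, the remainder set P_i \\ P_j keeps
    ``a = a_i - |DE(P_i) ∩ DE(P_j)|`` DE genes and the analogous non-DE
    count; an empty remainder scores p = 1.  Rows/columns are sorted by the
    original ORA p-values (stable in original column order).
    """
    V = X.values.astype(np.int64)
    de = V[: X.n_de]
    nde = V[X.n_de :]
    a = de.sum(axis=0)
    b = nde.sum(axis=0)
    # pairwise overlap counts, split by DE status
    de_ov = de.T @ de
    nde_ov = nde.T @ nde
    a_rem = a[:, None] - de_ov  # a of P_i \ P_j in cell [i, j]
    b_rem = b[:, None] - nde_ov
    sizes = a_rem + b_rem
    p = ora_pvalues(a_rem.ravel(), sizes.ravel(), X.n_de, X.n_nde).reshape(a_rem.shape)
    p_orig = ora_pvalues(a, a + b, X.n_de, X.n_nde)
    np.fill_diagonal(p, p_orig)
    order = np.argsort(p_orig, kind="stable")
    return CrosstalkMatrix(
        pathway_ids=[X.pathway_ids[i] for i in order],
        values=p[np.ix_(order, order)],
        original_p=p_orig[order],
    )


def export_heatmap(
    M: CrosstalkMatrix,
    path: str | Path,
    top: int | None = None,
    annotate: bool = False,
) -> None:
    """Render the crosstalk matrix as a heat map of -log10 p-values.

    Small p-values show bright red, p near 1 bright green.  ``top`` limits
    the display to the leading sub-block; the full matrix is unaffected.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    view = M.top(top) if top is not None else M
    neglog = -np.log10(view.values)
    k = len(view.pathway_ids)
    fig, ax = plt.subplots(figsize=(max(4.0, 0.45 * k + 2), max(3.5, 0.45 * k + 1.5)))
    im = ax.imshow(neglog, cmap="RdYlGn_r", aspect="equal")
    ax.set_xticks(range(k), view.pathway_ids, rotation=90, fontsize=7)
    ax.set_yticks(range(k), view.pathway_ids, fontsize=7)
    if annotate:
        for i in range(k):
            for j in range(k):
                ax.text(
                    j, i, f"{view.values[i, j]:.2g}",
                    ha="center", va="center", fontsize=5,
                )
    fig.colorbar(im, ax=ax, label="-log10 p")
    ax.set_title("Crosstalk: p of $P_i$ after removing $P_i \\cap P_j$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
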