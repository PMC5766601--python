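"""Two-group differential expression testing and probe-to-gene collapsing.

A plain two-sample t-test (pooled-variance by default, Welch optional) on a
log-scale expression matrix, flagging genes with raw p < alpha as
differentially expressed.  No multiple-testing correction is applied: the
downstream enrichment machinery is defined on the nominal DE / non-DE split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ExpressionMatrix", "DEResult", "t_test_per_gene", "collapse_probes"]


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued expression matrix with a binary phenotype.

    ``groups`` holds one label per sample; exactly two distinct labels are
    required for testing, each with at least two samples.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape inconsistent with gene/sample ids")
        if len(self.groups) != len(self.sample_ids):
            raise ValueError("one group label per sample required")
        if np.isnan(self.values).any():
            raise ValueError("missing values are not supported")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def group_masks(self) -> tuple[np.ndarray, np.ndarray]:
        labels = sorted(set(self.groups))
        if len(labels) != 2:
            raise ValueError(f"exactly two groups required, got {labels}")
        g = np.asarray(self.groups)
        return g == labels[0], g == labels[1]

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset_rows(self, rows: Sequence[int]) -> np.ndarray:
        return self.values[np.asarray(rows, dtype=int)]

    def to_tsv(self, expr_path: str | Path, pheno_path: str | Path | None = None) -> None:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
        df.index.name = "gene"
        df.to_csv(expr_path, sep="\t")
        if pheno_path is not None:
            pd.DataFrame({"sample_id": self.sample_ids, "group": self.groups}).to_csv(
                pheno_path, sep="\t", index=False
            )

    @classmethod
    def from_tsv(cls, expr_path: str | Path, pheno_path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(expr_path, sep="\t", index_col=0)
        pheno = pd.read_csv(pheno_path, sep="\t")
        mapping = dict(zip(pheno["sample_id"].astype(str), pheno["group"].astype(str)))
        missing = [s for s in df.columns if s not in mapping]
        if missing:
            raise ValueError(f"samples without phenotype: {missing[:5]}")
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
            groups=[mapping[str(s)] for s in df.columns],
        )


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    p_value: float
    is_de: bool


def t_test_per_gene(
    expr: ExpressionMatrix, alpha: float = 0.05, equal_var: bool = True
) -> list[DEResult]:
    """Two-sided two-sample t-test per gene row.

    ``equal_var=True`` gives the pooled-variance Student test (default);
    ``False`` gives Welch.  Degenerate rows where both groups have zero
    variance get p = 1 when the group means agree and the smallest positive
    float (with a warning) when they differ, so that an exactly separated
    constant row is still called DE.
    """
    m1, m2 = expr.group_masks()
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs at least two samples")
    a, b = expr.values[:, m1], expr.values[:, m2]
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if degenerate.any():
        same = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & same] = 1.0
        sep = degenerate & ~same
        if sep.any():
            warnings.warn(
                f"{int(sep.sum())} zero-variance gene(s) with unequal group "
                "means: reporting the smallest positive p-value",
                stacklevel=2,
            )
            p[sep] = np.finfo(float).tiny
    return [
        DEResult(g, float(pv), bool(pv < alpha))
        for g, pv in zip(expr.gene_ids, p)
    ]


def collapse_probes(
    results: Iterable[tuple[str, str, float]], alpha: float = 0.05
) -> list[DEResult]:
    """Collapse probe-level p-values to gene level by the minimum p-value.

    ``results`` yields ``(probe_id, gene_id, p_value)``; per gene the probe
    with the lowest p-value is kept, ties resolved by lexicographically
    smallest probe id.  Output order follows first appearance of each gene.
    """
    best: dict[str, tuple[float, str]] = {}
    order: list[str] = []
    for probe, gene, p in results:
        key = (float(p), probe)
        if gene not in best:
            best[gene] = key
            order.append(gene)
        elif key < best[gene]:
            best[gene] = key
    return [
        DEResult(g, best[g][0], bool(best[g][0] < alpha)) for g in order
    ]
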