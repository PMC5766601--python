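"""Gene-set collections and the binary gene x pathway membership matrix.

The membership matrix ``X`` is the central data structure of the workflow:
rows are genes (differentially expressed genes first, ranked by ascending
p-value), columns are pathways, and ``X[i, j] = 1`` iff gene *i* is annotated
to pathway *j*.  Genes annotated to no pathway are excluded, so the row set is
the "pathway universe" used as the enrichment background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .modules_detect import Module

__all__ = [
    "GeneSetCollection",
    "GenePathwayMatrix",
    "MembershipMatrix",
    "ImpactMatrix",
    "read_gmt",
    "build_membership",
    "expand_with_modules",
]


class GmtParseError(ValueError):
    """Raised when a GMT file violates the three-field-minimum line format."""


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of named gene sets.

    ``sets`` is a tuple of ``(pathway_id, genes)`` pairs; pathway ids are
    unique and every set is non-empty.  Gene identifiers are matched by exact,
    case-sensitive string equality throughout.
    """

    sets: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.sets]
        if len(ids) != len(set(ids)):
            dupes = sorted({p for p in ids if ids.count(p) > 1})
            raise ValueError(f"duplicate pathway ids: {dupes}")
        for pid, genes in self.sets:
            if not genes:
                raise ValueError(f"gene set {pid!r} is empty")
            if any(not g for g in genes):
                raise ValueError(f"gene set {pid!r} contains an empty gene symbol")

    @property
    def pathway_ids(self) -> list[str]:
        return [pid for pid, _ in self.sets]

    @property
    def genes(self) -> frozenset[str]:
        """Union of all member genes."""
        out: set[str] = set()
        for _, g in self.sets:
            out |= g
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with a measured-gene universe.

        Sets left empty after the intersection are dropped, mirroring the
        construction of a pathway collection restricted to the genes actually
        measured on a platform.
        """
        uni = frozenset(universe)
        kept = tuple(
            (pid, genes & uni) for pid, genes in self.sets if genes & uni
        )
        return GeneSetCollection(kept)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a gene-set collection in Broad GMT format.

    Each line is ``name TAB description TAB gene [TAB gene ...]``.  The
    description field is discarded and duplicate genes within a line are
    de-duplicated.  Blank lines are ignored.

    Raises
    ------
    GmtParseError
        If a line has fewer than three tab-separated fields (reported with
        its 1-based line number).
    ValueError
        If two lines share the same set name.
    """
    sets: list[tuple[str, frozenset[str]]] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in seen:
                raise ValueError(f"{path}: duplicate pathway name {name!r}")
            seen.add(name)
            genes = frozenset(g for g in fields[2:] if g)
            sets.append((name, genes))
    return GeneSetCollection(tuple(sets))


@dataclass
class GenePathwayMatrix:
    """Common base for binary gene x pathway matrices.

    ``values`` is an ``(m+n, k)`` 0/1 array; the first ``n_de`` rows are the
    differentially expressed genes and rows are ordered by ascending
    differential-expression p-value (``de_pvalues``).
    """

    gene_ids: list[str]
    pathway_ids: list[str]
    values: np.ndarray
    n_de: int
    de_pvalues: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.de_pvalues = np.asarray(self.de_pvalues, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.pathway_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.pathway_ids)} pathways"
            )
        if len(self.de_pvalues) != len(self.gene_ids):
            raise ValueError("de_pvalues length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.pathway_ids)) != len(self.pathway_ids):
            raise ValueError("duplicate pathway ids")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_ids)

    @property
    def n_nde(self) -> int:
        """Number of non-DE genes (the ``m`` of the m+n background)."""
        return self.n_genes - self.n_de

    def column_sizes(self) -> np.ndarray:
        """Pathway sizes restricted to the matrix universe."""
        return self.values.sum(axis=0)

    def de_counts(self) -> np.ndarray:
        """Per-pathway count of DE genes (1s in the top ``n_de`` rows)."""
        return self.values[: self.n_de].sum(axis=0)

    def zero_columns(self) -> list[str]:
        """Pathway ids whose column is all zero (flagged, kept for indexing)."""
        sizes = self.column_sizes()
        return [p for p, s in zip(self.pathway_ids, sizes) if s == 0]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def pathway_index(self) -> dict[str, int]:
        return {p: j for j, p in enumerate(self.pathway_ids)}

    def members(self, pathway_id: str) -> frozenset[str]:
        j = self.pathway_index()[pathway_id]
        rows = np.flatnonzero(self.values[:, j])
        return frozenset(self.gene_ids[i] for i in rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.pathway_ids
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: first column gene id, header row of pathway ids."""
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")


@dataclass
class MembershipMatrix(GenePathwayMatrix):
    """Binary membership matrix with DE genes in the top rows."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if (self.values.sum(axis=1) == 0).any():
            bad = [g for g, r in zip(self.gene_ids, self.values.sum(axis=1)) if r == 0]
            raise ValueError(f"genes with no pathway membership: {bad[:5]}")
        if np.any(np.diff(self.de_pvalues) < 0):
            raise ValueError("rows must be sorted by ascending de_pvalue")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        de_results: Mapping[str, float],
        alpha: float = 0.05,
    ) -> "MembershipMatrix":
        """Read a membership TSV and re-rank rows from ``de_results``.

        The TSV dialect stores only the incidence structure; p-values come
        from a separate differential-expression result table.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        collection = GeneSetCollection(
            tuple(
                (str(p), frozenset(df.index[df[p] == 1].astype(str)))
                for p in df.columns
                if (df[p] == 1).any()
            )
        )
        return build_membership(collection, de_results, alpha=alpha)


@dataclass
class ImpactMatrix(GenePathwayMatrix):
    """Crosstalk-corrected assignment: exactly one pathway per gene.

    Same axes as the membership matrix it was derived from; every row has a
    single 1, placed in a column where the gene was originally a member.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if not (self.values.sum(axis=1) == 1).all():
            raise ValueError("every impact-matrix row must sum to exactly 1")

    def check_within(self, membership: GenePathwayMatrix) -> None:
        """Assert Z <= X elementwise (assignments stay within memberships)."""
        if (self.values > membership.values).any():
            raise ValueError("impact matrix assigns a gene outside its memberships")


def build_membership(
    collection: GeneSetCollection,
    de_results: Mapping[str, float] | Sequence[tuple[str, float]],
    alpha: float = 0.05,
) -> MembershipMatrix:
    """Build the membership matrix from a collection and per-gene p-values.

    Rows are ordered by ascending p-value; ties broken by lexicographic gene
    id (stable, reproducible).  Genes absent from every set are dropped; a
    gene present in a set but missing from ``de_results`` is an error.

    Parameters
    ----------
    collection : GeneSetCollection
        Gene sets, already restricted to the measured universe if desired.
    de_results : mapping or sequence of (gene, p)
        Differential-expression p-value per gene; must cover the collection.
    alpha : float
        DE threshold on the raw p-value (default 0.05).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    pvals = dict(de_results) if not isinstance(de_results, Mapping) else dict(de_results)
    genes = sorted(collection.genes)
    missing = [g for g in genes if g not in pvals]
    if missing:
        raise ValueError(
            f"{len(missing)} genes in the collection have no DE p-value, "
            f"e.g. {missing[:5]}"
        )
    order = sorted(genes, key=lambda g: (pvals[g], g))
    gene_pos = {g: i for i, g in enumerate(order)}
    k = len(collection)
    X = np.zeros((len(order), k), dtype=np.int8)
    for j, (_, members) in enumerate(collection):
        for g in members:
            X[gene_pos[g], j] = 1
    p = np.array([pvals[g] for g in order])
    return MembershipMatrix(
        gene_ids=order,
        pathway_ids=list(collection.pathway_ids),
        values=X,
        n_de=int((p < alpha).sum()),
        de_pvalues=p,
    )


def expand_with_modules(
    X: MembershipMatrix, modules: Sequence["Module"]
) -> MembershipMatrix:
    """Append intersection modules as new columns and carve them out of parents.

    For each module, its genes are zeroed in every *original* pathway column
    that shares at least one gene with the module, and one new column is
    appended holding the module.  Original columns left empty are retained
    (they simply score p = 1 in downstream enrichment), keeping column
    indexing stable.
    """
    if not modules:
        return X
    idx = X.gene_index()
    existing = set(X.pathway_ids)
    values = X.values.copy()
    k_orig = X.n_pathways
    new_cols = []
    new_ids = []
    for mod in modules:
        if mod.module_id in existing:
            raise ValueError(f"module id {mod.module_id!r} collides with a pathway id")
        existing.add(mod.module_id)
        unknown = [g for g in mod.gene_ids if g not in idx]
        if unknown:
            raise ValueError(
                f"module {mod.module_id!r} contains genes not in the matrix: "
                f"{sorted(unknown)[:5]}"
            )
        rows = np.array(sorted(idx[g] for g in mod.gene_ids))
        overlap_cols = np.flatnonzero(values[rows, :k_orig].any(axis=0))
        values[np.ix_(rows, overlap_cols)] = 0
        col = np.zeros(X.n_genes, dtype=np.int8)
        col[rows] = 1
        new_cols.append(col)
        new_ids.append(mod.module_id)
    out = np.column_stack([values] + new_cols).astype(np.int8)
    empties = [
        p for p, s in zip(X.pathway_ids, out[:, :k_orig].sum(axis=0)) if s == 0
    ]
    if empties:
        warnings.warn(
            f"{len(empties)} pathway column(s) emptied by module extraction "
            f"(retained, will score p=1): {empties[:5]}",
            stacklevel=2,
        )
    return MembershipMatrix(
        gene_ids=list(X.gene_ids),
        pathway_ids=list(X.pathway_ids) + new_ids,
        values=out,
        n_de=X.n_de,
        de_pvalues=X.de_pvalues.copy(),
    )
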