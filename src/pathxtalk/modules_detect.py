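"""Detection and merging of intersection modules.

When two pathways are each significant, their intersection is significant,
and neither pathway remains significant once the shared genes are removed,
the shared genes form an *intersection module*: a gene set that carries the
pair's significance and deserves to be tested as an independent unit.
Similar candidate modules (high overlap coefficient) are merged by
connected components.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .gene_sets import MembershipMatrix
from .ora import ora_pvalues

__all__ = [
    "Module",
    "candidate_modules",
    "jaccard_similarity",
    "merge_modules",
]


@dataclass(frozen=True)
class Module:
    """A named gene set extracted from the intersection of parent pathways."""

    module_id: str
    gene_ids: frozenset[str]
    parent_pathway_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("module gene set must be non-empty")


def _abbrev(pathway_id: str) -> str:
    """First three letters of the last name component, capitalised."""
    token = pathway_id.strip().split("_")[-1] if "_" in pathway_id else pathway_id
    token = token or pathway_id
    return token[:3].capitalize()


def module_name(parent_ids: frozenset[str], taken: set[str] | None = None) -> str:
    """``Intersection_<abbrev>_<abbrev>...`` from sorted parent abbreviations.

    Collisions with already-taken names get a numeric suffix.
    """
    base = "Intersection_" + "_".join(sorted(_abbrev(p) for p in parent_ids))
    if taken is None or base not in taken:
        return base
    i = 2
    while f"{base}_{i}" in taken:
        i += 1
    return f"{base}_{i}"


def jaccard_similarity(A: Module | frozenset[str], B: Module | frozenset[str]) -> float:
    """Overlap coefficient mJS = |A ∩ B| / min(|A|, |B|).

    (Called a Jaccard similarity in parts of the pathway literature, this is
    mathematically the Szymkiewicz–Simpson overlap coefficient.)
    """
    a = A.gene_ids if isinstance(A, Module) else frozenset(A)
    b = B.gene_ids if isinstance(B, Module) else frozenset(B)
    if not a or not b:
        raise ValueError("gene sets must be non-empty")
    return len(a & b) / min(len(a), len(b))


def candidate_modules(X: MembershipMatrix, alpha: float = 0.05) -> list[Module]:
    """Emit the intersection of every qualifying pathway pair.

    A pair (P_i, P_j) yields a candidate module iff
    (1) both pathways are ORA-significant at ``alpha``,
    (2) neither remainder P_i\\j nor P_j\\i is significant, and
    (3) the intersection itself is significant.
    Only pairs are examined; higher-order intersections arise through
    merging.
    """
    V = X.values.astype(np.int64)
    de, nde = V[: X.n_de], V[X.n_de :]
    a = de.sum(axis=0)
    b = nde.sum(axis=0)
    de_ov = de.T @ de
    nde_ov = nde.T @ nde
    n, m = X.n_de, X.n_nde
    p_orig = ora_pvalues(a, a + b, n, m)
    sig = p_orig < alpha

    out: list[Module] = []
    taken: set[str] = set()
    k = X.n_pathways
    for i in range(k):
        if not sig[i]:
            continue
        for j in range(i + 1, k):
            if not sig[j]:
                continue
            ov_size = de_ov[i, j] + nde_ov[i, j]
            if ov_size == 0:
                continue  # empty intersection can never be significant
            p_int = ora_pvalues(
                np.array([de_ov[i, j]]), np.array([ov_size]), n, m
            )[0]
            if p_int >= alpha:
                continue
            rem = ora_pvalues(
                np.array([a[i] - de_ov[i, j], a[j] - de_ov[i, j]]),
                np.array(
                    [a[i] + b[i] - ov_size, a[j] + b[j] - ov_size]
                ),
                n,
                m,
            )
            if (rem < alpha).any():
                continue
            rows_i = V[:, i].astype(bool)
            rows_j = V[:, j].astype(bool)
            genes = frozenset(
                g for g, keep in zip(X.gene_ids, rows_i & rows_j) if keep
            )
            parents = frozenset({X.pathway_ids[i], X.pathway_ids[j]})
            name = module_name(parents, taken)
            taken.add(name)
            out.append(Module(name, genes, parents))
    return out


def merge_modules(
    candidates: list[Module],
    threshold: float = 0.8,
    combine: str = "union",
) -> list[Module]:
    """Merge similar candidate modules transitively to a fixpoint.

    Candidates whose overlap coefficient exceeds ``threshold`` are linked;
    each connected component becomes one module whose gene set is the union
    (default) or common intersection of its constituents and whose parents
    are the union of constituent parents.  Merging is transitive: a chain
    A~B~C collapses even if A and C are dissimilar.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if combine not in ("union", "intersection"):
        raise ValueError("combine must be 'union' or 'intersection'")
    G = nx.Graph()
    G.add_nodes_from(range(len(candidates)))
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            if jaccard_similarity(candidates[i], candidates[j]) > threshold:
                G.add_edge(i, j)
    merged: list[Module] = []
    taken: set[str] = set()
    # deterministic order: components sorted by smallest member index
    comps = sorted(nx.connected_components(G), key=min)
    for comp in comps:
        members = [candidates[i] for i in sorted(comp)]
        if len(members) == 1:
            mod = members[0]
            if mod.module_id in taken:
                mod = Module(
                    module_name(mod.parent_pathway_ids, taken),
                    mod.gene_ids,
                    mod.parent_pathway_ids,
                )
            taken.add(mod.module_id)
            merged.append(mod)
            continue
        genes = frozenset.union(*(m.gene_ids for m in members))
        if combine == "intersection":
            genes = frozenset.intersection(*(m.gene_ids for m in members))
            if not genes:
                raise ValueError(
                    "intersection-combine produced an empty merged module"
                )
        parents = frozenset.union(*(m.parent_pathway_ids for m in members))
        name = module_name(parents, taken)
        taken.add(name)
        merged.append(Module(name, genes, parents))
    return merged


def modules_frame(modules: list[Module]) -> pd.DataFrame:
    """Modules as a table: id, parents and genes semicolon-joined."""
    return pd.DataFrame(
        {
            "module_id": [m.module_id for m in modules],
            "parents": [";".join(sorted(m.parent_pathway_ids)) for m in modules],
            "n_genes": [len(m.gene_ids) for m in modules],
            "genes": [";".join(sorted(m.gene_ids)) for m in modules],
        }
    )
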