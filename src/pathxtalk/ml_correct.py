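"""Maximum-impact estimation: EM assignment of each gene to one pathway.

The membership matrix is modelled as a finite mixture: each gene has one
latent "true" pathway drawn from weights pi, and its observed membership
row must cover that pathway.  EM alternates responsibilities
``r_ij = pi_j X_ij / sum_l pi_l X_il`` with weight updates
``pi_j = sum_i r_ij / sum_il r_il`` until the log-likelihood
``sum_i log sum_j pi_j X_ij`` stops improving.  The impact matrix Z places
each gene at its maximum-responsibility member pathway, so absent any
overlap Z equals X.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gene_sets import GenePathwayMatrix, ImpactMatrix

__all__ = ["EMState", "em_loglikelihood", "ml_correct"]


@dataclass
class EMState:
    """Snapshot of the EM fit: weights, responsibilities, log-likelihood."""

    pi: np.ndarray
    responsibilities: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        if (self.pi < 0).any() or not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must be a probability vector")


def em_loglikelihood(X: GenePathwayMatrix | np.ndarray, pi: np.ndarray) -> float:
    """Observed-data log-likelihood sum_i log(sum_j pi_j X_ij).

    Raises if any gene has zero coverage under ``pi`` (the likelihood would
    be -infinity).
    """
    V = X.values if isinstance(X, GenePathwayMatrix) else np.asarray(X)
    pi = np.asarray(pi, dtype=float)
    if (pi < 0).any() or not np.isclose(pi.sum(), 1.0):
        raise ValueError("pi must be a probability vector")
    coverage = V.astype(float) @ pi
    if (coverage <= 0).any():
        bad = int(np.flatnonzero(coverage <= 0)[0])
        raise ValueError(
            f"gene row {bad} has zero probability mass under pi "
            "(log-likelihood is -inf)"
        )
    return float(np.log(coverage).sum())


def _em_fit(V: np.ndarray, pi0: np.ndarray, tol: float, max_iter: int) -> EMState:
    pi = pi0.copy()
    ll_prev = -np.inf
    converged = False
    r = None
    it = 0
    for it in range(1, max_iter + 1):
        w = V * pi  # (genes, pathways)
        denom = w.sum(axis=1, keepdims=True)
        if (denom <= 0).any():
            raise ValueError("gene with all-zero membership row")
        r = w / denom
        ll = float(np.log(denom).sum())
        if ll + 1e-12 < ll_prev:  # EM guarantees monotone ascent
            raise AssertionError("log-likelihood decreased during EM")
        if ll - ll_prev < tol:
            ll_prev = ll
            converged = True
            break
        ll_prev = ll
        pi = r.sum(axis=0)
        pi /= pi.sum()
    return EMState(pi=pi, responsibilities=r, log_likelihood=ll_prev,
                   n_iter=it, converged=converged)


def _xlogx(c: float) -> float:
    return c * np.log(c) if c > 0 else 0.0


def _classification_refine(
    V: np.ndarray, assign: np.ndarray, max_rounds: int = 500
) -> np.ndarray:
    """Greedy polish of a hard assignment on the assignment likelihood.

    The likelihood of a complete assignment with column counts c is
    ``prod_j (c_j / N)^{c_j}`` (each gene at its pathway's maximum-likelihood
    weight).  The soft-EM argmax alone can fall short of the best hard
    assignment because the marginal optimum may split weight between
    pathways that no optimal hard assignment uses, so genes are moved
    one at a time to the member column with the largest strict gain in
    ``sum_j c_j log c_j`` until no move improves.  Deterministic: genes are
    scanned in row order and ties keep the current / lowest-index column.
    """
    g, k = V.shape
    assign = assign.copy()
    counts = np.bincount(assign, minlength=k).astype(float)
    members_of = [np.flatnonzero(V[i]) for i in range(g)]

    def single_pass() -> bool:
        changed = False
        for i in range(g):
            z = assign[i]
            drop = _xlogx(counts[z] - 1) - _xlogx(counts[z])
            best_j, best_delta = z, 0.0
            for j in members_of[i]:
                if j == z:
                    continue
                delta = _xlogx(counts[j] + 1) - _xlogx(counts[j]) + drop
                if delta > best_delta + 1e-12:
                    best_delta, best_j = delta, j
            if best_j != z:
                counts[z] -= 1
                counts[best_j] += 1
                assign[i] = best_j
                changed = True
        return changed

    def group_pass() -> bool:
        # genes with identical membership rows are interchangeable; moving
        # them one at a time can stall on a likelihood plateau that a
        # coordinated move of the whole block crosses
        changed = False
        blocks: dict[tuple, dict[int, list[int]]] = {}
        for i in range(g):
            key = V[i].tobytes()
            blocks.setdefault(key, {}).setdefault(int(assign[i]), []).append(i)
        for per_col in blocks.values():
            for z in list(per_col):
                rows = per_col.get(z)
                if not rows:
                    continue
                q = len(rows)
                best_j, best_delta = z, 0.0
                for j in members_of[rows[0]]:
                    if j == z:
                        continue
                    delta = (
                        _xlogx(counts[j] + q)
                        - _xlogx(counts[j])
                        + _xlogx(counts[z] - q)
                        - _xlogx(counts[z])
                    )
                    if delta > best_delta + 1e-12:
                        best_delta, best_j = delta, j
                if best_j != z:
                    counts[z] -= q
                    counts[best_j] += q
                    for i in rows:
                        assign[i] = best_j
                    per_col.setdefault(best_j, []).extend(rows)
                    per_col[z] = []
                    changed = True
        return changed

    for _ in range(max_rounds):
        moved = single_pass()
        moved = group_pass() or moved
        if not moved:
            break
    return assign


def _exact_assignment(V: np.ndarray) -> np.ndarray:
    """Exact maximum-likelihood assignment by count-vector dynamic programming.

    The assignment likelihood depends on the column counts only, so the
    reachable count vectors are enumerated gene by gene and the best final
    vector is backtracked to a concrete assignment.  Feasible only when the
    count-vector space is small; large problems use EM plus local search.
    Ties prefer lexicographically larger count vectors and lower column
    indices during backtracking (deterministic).
    """
    g, k = V.shape
    members_of = [np.flatnonzero(V[i]) for i in range(g)]
    reachable: list[set[tuple[int, ...]]] = [{(0,) * k}]
    for i in range(g):
        nxt: set[tuple[int, ...]] = set()
        for c in reachable[-1]:
            for j in members_of[i]:
                v = list(c)
                v[j] += 1
                nxt.add(tuple(v))
        reachable.append(nxt)
    best = max(
        reachable[-1], key=lambda c: (sum(_xlogx(x) for x in c), c)
    )
    assign = np.empty(g, dtype=int)
    cur = best
    for i in range(g - 1, -1, -1):
        for j in members_of[i]:
            if cur[j] > 0:
                prev = list(cur)
                prev[j] -= 1
                prev_t = tuple(prev)
                if prev_t in reachable[i]:
                    assign[i] = j
                    cur = prev_t
                    break
    return assign


_EXACT_STATE_LIMIT = 5000


def ml_correct(
    X: GenePathwayMatrix,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    seed: int | None = None,
    n_restarts: int = 0,
    return_state: bool = False,
) -> ImpactMatrix | tuple[ImpactMatrix, EMState]:
    """EM maximum-impact correction of a membership matrix.

    Starts from uniform pathway weights (deterministic); ``n_restarts``
    additional random initialisations (Dirichlet, seeded) keep the best
    log-likelihood, though the likelihood is concave in pi so restarts
    rarely change the result.  Each gene is assigned to its
    maximum-responsibility member pathway (ties break to the lowest column
    index) and the assignment is then polished by greedy local search on the
    assignment likelihood, so that Z maximises the single-pathway assignment
    likelihood rather than merely thresholding the marginal fit.  On small
    problems the assignment is computed exactly by dynamic programming over
    count vectors instead.
    """
    V = X.values.astype(float)
    if (V.sum(axis=1) == 0).any():
        raise ValueError("every gene must belong to at least one pathway")
    k = X.n_pathways
    best = _em_fit(V, np.full(k, 1.0 / k), tol, max_iter)
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            pi0 = rng.dirichlet(np.ones(k))
            state = _em_fit(V, pi0, tol, max_iter)
            if state.log_likelihood > best.log_likelihood:
                best = state
    if not best.converged:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations "
            f"(last improvement tolerance {tol:g}); returning current "
            "assignment",
            stacklevel=2,
        )
    from math import comb

    if comb(X.n_genes + k - 1, k - 1) <= _EXACT_STATE_LIMIT:
        assign = _exact_assignment(V)
    else:
        assign = np.argmax(best.responsibilities, axis=1)  # ties -> lowest index
        assign = _classification_refine(V, assign)
    Z = np.zeros_like(X.values, dtype=np.int8)
    Z[np.arange(X.n_genes), assign] = 1
    impact = ImpactMatrix(
        gene_ids=list(X.gene_ids),
        pathway_ids=list(X.pathway_ids),
        values=Z,
        n_de=X.n_de,
        de_pvalues=X.de_pvalues.copy(),
    )
    impact.check_within(X)
    return (impact, best) if return_state else impact
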