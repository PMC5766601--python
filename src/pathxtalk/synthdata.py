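"""Synthetic membership matrices and expression data with known ground truth.

The generator emulates the structure the correction methods assume:

* every gene has exactly ONE generating ("true") pathway, and may carry
  extra memberships -- the crosstalk.  Extra memberships come from two
  sources seen in curated collections such as KEGG: light random
  co-annotation spread across the collection, and a few large *shared
  cores* -- blocks of genes annotated wholesale to a small group of
  pathways (the pattern behind, e.g., the oxidative-phosphorylation /
  neurodegeneration overlap);
* expression follows a per-pathway latent-factor model: subjects draw one
  standard-normal factor per pathway, each gene tracks its true pathway's
  factor with loading ``factor_loading`` plus ``noise_sd`` Gaussian noise,
  and DE genes get a two-group mean shift of ``de_effect`` marginal
  standard deviations.

Because each gene has a single generating factor, the true assignment is a
fair recovery oracle for both the EM and the PC1-correlation corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .diffexpr import ExpressionMatrix
from .gene_sets import GeneSetCollection, MembershipMatrix, build_membership

__all__ = [
    "SynthesisSpec",
    "GroundTruth",
    "generate_membership",
    "generate_expression",
    "kegg_like_spec",
]

_MIN_PATHWAY_SIZE = 4


@dataclass(frozen=True)
class SynthesisSpec:
    """Parameters of the synthetic reference set.

    The default is a KEGG-like collection scaled to desk size: 30 pathways
    over 600 genes with log-normal size spread (median size ~24, total
    memberships close to the gene count), overlap concentrated in three
    3-pathway shared cores plus rare stray co-annotations, 40 subjects in
    two balanced groups, unit factor loading and noise sd 0.25.
    """

    n_pathways: int = 30
    universe_size: int = 600
    size_log_sigma: float = 0.5  # log-normal sd of pathway weight
    extra_rate: float = 0.05  # Poisson mean of random extra memberships/gene
    max_extra: int = 2
    n_shared_cores: int = 3
    core_group_size: int = 3  # pathways sharing each core
    core_frac: float = 0.4  # fraction of the seed pathway's genes in the core
    n_subjects: int = 40
    n_de: int = 100
    de_effect: float = 1.0  # two-group shift, in marginal-sd units
    noise_sd: float = 0.25
    factor_loading: float = 1.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pathways, self.universe_size, self.n_subjects) <= 0:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0 or self.factor_loading < 0:
            raise ValueError("noise_sd and factor_loading must be >= 0")
        if self.n_de > self.universe_size:
            raise ValueError("n_de cannot exceed the universe size")
        if self.universe_size < _MIN_PATHWAY_SIZE * self.n_pathways:
            raise ValueError("universe too small for the requested pathway count")
        if self.n_shared_cores > 0 and self.core_group_size > self.n_pathways:
            raise ValueError("core_group_size exceeds the number of pathways")
        if self.max_extra > self.n_pathways - 1:
            raise ValueError("max_extra exceeds the number of other pathways")

    def with_seed(self, seed: int) -> "SynthesisSpec":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Generating assignment and DE set behind a synthetic instance."""

    true_assignment: dict[str, str]  # gene -> generating pathway id
    de_genes: frozenset[str]
    memberships: dict[str, frozenset[str]] = field(repr=False, default_factory=dict)


def kegg_like_spec(scale: str = "small", seed: int = 0) -> SynthesisSpec:
    """Preset specs: ``"small"`` (30 pathways / 600 genes, the desk-scale
    reference) or ``"full"`` (186 pathways / 4801 genes, approximating the
    size of the KEGG collection restricted to an expression array)."""
    if scale == "small":
        return SynthesisSpec(seed=seed)
    if scale == "full":
        return SynthesisSpec(
            n_pathways=186,
            universe_size=4801,
            n_shared_cores=19,
            n_de=103,
            seed=seed,
        )
    raise ValueError(f"unknown preset scale {scale!r}")


def _pathway_ids(k: int) -> list[str]:
    width = max(2, len(str(k)))
    return [f"PW{j + 1:0{width}d}" for j in range(k)]


def _gene_ids(g: int) -> list[str]:
    width = max(4, len(str(g)))
    return [f"G{i + 1:0{width}d}" for i in range(g)]


def generate_membership(
    spec: SynthesisSpec,
) -> tuple[MembershipMatrix, GroundTruth]:
    """Draw a membership matrix with planted single-pathway ground truth.

    Pathway sizes follow a log-normal weight law; every gene is assigned one
    generating pathway, then extra memberships are added (random
    co-annotation plus shared cores).  DE status is planted uniformly at
    random and synthetic ordering p-values (uniform below / above ``alpha``)
    are attached so the matrix satisfies the DE-genes-first row convention.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng([1, spec.seed])
    k, g = spec.n_pathways, spec.universe_size
    pathways = _pathway_ids(k)
    genes = _gene_ids(g)

    weights = rng.lognormal(mean=0.0, sigma=spec.size_log_sigma, size=k)
    probs = weights / weights.sum()
    true = rng.choice(k, size=g, p=probs)
    # top up pathways below the minimum size from the largest ones
    counts = np.bincount(true, minlength=k)
    for j in np.flatnonzero(counts < _MIN_PATHWAY_SIZE):
        while counts[j] < _MIN_PATHWAY_SIZE:
            donor = int(np.argmax(counts))
            movable = np.flatnonzero(true == donor)
            true[rng.choice(movable)] = j
            counts = np.bincount(true, minlength=k)

    member_sets: list[set[int]] = [{int(true[i])} for i in range(g)]

    # rare random stray co-annotations, uniform over other pathways
    n_extra = np.minimum(rng.poisson(spec.extra_rate, size=g), spec.max_extra)
    for i in np.flatnonzero(n_extra):
        others = np.array([j for j in range(k) if j != true[i]])
        extras = rng.choice(others, size=int(n_extra[i]), replace=False)
        member_sets[i].update(int(e) for e in extras)

    # shared cores: blocks of one pathway's genes annotated to a small group
    for _ in range(spec.n_shared_cores):
        group = rng.choice(k, size=spec.core_group_size, replace=False)
        seed_pw = int(group[0])
        own = np.flatnonzero(true == seed_pw)
        n_core = max(2, int(round(spec.core_frac * len(own))))
        core = rng.choice(own, size=min(n_core, len(own)), replace=False)
        for i in core:
            member_sets[int(i)].update(int(j) for j in group)

    sets = tuple(
        (
            pathways[j],
            frozenset(genes[i] for i in range(g) if j in member_sets[i]),
        )
        for j in range(k)
    )
    collection = GeneSetCollection(sets)

    de_rows = rng.choice(g, size=spec.n_de, replace=False)
    is_de = np.zeros(g, dtype=bool)
    is_de[de_rows] = True
    pvals = np.where(
        is_de,
        rng.uniform(0.0, spec.alpha, size=g),
        rng.uniform(spec.alpha, 1.0, size=g),
    )
    de_results = {genes[i]: float(pvals[i]) for i in range(g)}
    X = build_membership(collection, de_results, alpha=spec.alpha)
    truth = GroundTruth(
        true_assignment={genes[i]: pathways[int(true[i])] for i in range(g)},
        de_genes=frozenset(genes[i] for i in np.flatnonzero(is_de)),
        memberships={
            genes[i]: frozenset(pathways[j] for j in member_sets[i]) for i in range(g)
        },
    )
    return X, truth


def generate_expression(
    X: MembershipMatrix, truth: GroundTruth, spec: SynthesisSpec
) -> ExpressionMatrix:
    """Latent-factor expression matrix consistent with a ground truth.

    Per subject, one standard-normal factor per pathway; gene *i* is
    ``factor_loading * f_true(i) + noise_sd * eps``.  DE genes additionally
    shift by ``de_effect`` marginal standard deviations in group 2.  Two
    balanced groups; requires at least four subjects.
    """
    if spec.n_subjects < 4:
        raise ValueError("at least four subjects required (two per group)")
    rng = np.random.default_rng([2, spec.seed])
    S = spec.n_subjects
    pw_index = X.pathway_index()
    true_col = np.array(
        [pw_index[truth.true_assignment[gid]] for gid in X.gene_ids]
    )
    F = rng.standard_normal((X.n_pathways, S))
    eps = rng.standard_normal((X.n_genes, S))
    values = spec.factor_loading * F[true_col] + spec.noise_sd * eps
    half = S // 2
    groups = ["group1"] * half + ["group2"] * (S - half)
    marginal_sd = float(np.hypot(spec.factor_loading, spec.noise_sd))
    shift = spec.de_effect * (marginal_sd if marginal_sd > 0 else 1.0)
    de_mask = np.array([gid in truth.de_genes for gid in X.gene_ids])
    values[np.ix_(de_mask, np.arange(half, S))] += shift
    return ExpressionMatrix(
        gene_ids=list(X.gene_ids),
        sample_ids=[f"S{s + 1:03d}" for s in range(S)],
        values=values,
        groups=groups,
    )
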