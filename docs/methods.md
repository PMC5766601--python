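# Methods

## Enrichment model

All enrichment tests are one-sided (enrichment-only) Fisher exact tests,
computed as exact upper-tail hypergeometric probabilities: for a pathway
with `a` DE and `b` non-DE members against a background of `n` DE and `m`
non-DE genes, `p = P(X >= a)` with `X ~ Hypergeom(n+m, n, a+b)`. An empty
pathway scores `p = 1`. No multiple-testing correction is applied anywhere:
the workflow's DE/significance conventions are raw `p < alpha` with
`alpha = 0.05` by default. A Benjamini–Hochberg layer can be added by the
caller; it is deliberately not part of the core pipeline.

The enrichment background is the *pathway universe*: genes that belong to
at least one set after intersecting the collection with the measured
genes. Genes outside every set are dropped from the matrix (and hence from
the background). Testing against the full measured array instead is
possible by passing a collection that includes a catch-all set, but the
pathway-universe background is the default and the convention used by all
built-in tooling.

## Membership matrix conventions

Rows are ordered by ascending DE p-value, ties broken by lexicographic
gene id, so the top `n_de` rows are exactly the nominal DE genes. Gene
identifiers match by exact, case-sensitive string equality; identifier
mapping is out of scope. All-zero pathway columns (possible after module
extraction) are retained to keep column indexing stable; they score
`p = 1` in every test.

## Crosstalk matrix

Cell `[i, j]` re-tests `P_i \ P_j` (the members of `P_i` not shared with
`P_j`). The background margins `(n, m)` are *not* reduced: genes are
removed from the pathway, not from the universe. The matrix is generally
asymmetric. Rows and columns are ordered by the original ORA p-values; the
heat map renders `-log10 p` on a red (significant) to green (null)
colormap, with a `top` parameter for the display subset only.

## Module detection and merging

A pathway pair emits a candidate module (its intersection) iff (1) both
pathways are significant, (2) neither remainder is, and (3) the
intersection is significant. Only pairs are examined; higher-order shared
cores arise through merging. Candidates are merged transitively (connected
components, via networkx) when their overlap coefficient
`mJS = |A ∩ B| / min(|A|, |B|)` exceeds the threshold (default 0.8 —
observed coefficients in curated collections cluster near 0 or near 1, so
any threshold in between behaves identically on such data; it is exposed
as `--jaccard-threshold` for collections where they do not). Merged gene
sets are the union of constituents by default; an intersection-combine
option exists because the union reading, while the only one consistent
with multi-parent cores spanning several pairwise intersections, is not
the sole conceivable semantics. Module expansion zeroes a module's genes
in every original column sharing at least one gene with the module and
appends the module as a new column, so the parents are re-tested without
their shared core.

## EM maximum-impact correction

The membership matrix is modelled as a finite mixture: each gene has one
latent generating pathway drawn from weights `pi`; its membership row must
cover that pathway. The marginal log-likelihood
`sum_i log(sum_j pi_j X_ij)` is concave in `pi`, so EM (uniform start,
tolerance 1e-8 on the log-likelihood, at most 10,000 iterations) reaches
the global soft optimum; random restarts are available but redundant.

The deliverable, however, is a *hard* assignment `Z`. The likelihood of a
complete assignment with column counts `c` is `prod_j (c_j / N)^{c_j}`,
and the argmax of the soft responsibilities does not always maximise it:
the marginal optimum may split weight between pathways that no optimal
hard assignment uses (smallest counterexample found: 4 genes, 3 pathways).
We therefore (a) solve the assignment exactly by dynamic programming over
reachable count vectors whenever the count-vector space is small (at most
5000 states — the likelihood depends on counts only, so genes with equal
rows are interchangeable), and (b) otherwise polish the EM argmax by
greedy local search: single-gene moves plus coordinated moves of
identical-row blocks, each accepted only on a strict likelihood gain.
The local search is deterministic (row order, lowest-column-index ties)
but heuristic; exactness is guaranteed only in the DP regime. Genes are
never assigned outside their original memberships, and a membership matrix
with no pairwise overlap is returned unchanged (`Z = X`).

## PC1-correlation (expression-based) correction

For each member gene `i` of pathway `j`, the pathway's expression block is
taken *without* gene `i` (leave-one-out, so a gene cannot vote for
itself), rows are mean-centered (no variance scaling — log-scale
expression rows share a scale), and the first principal component scores
(one per subject) summarise the block. `C[i, j]` is the Pearson
correlation between those scores and gene `i`'s own profile, in absolute
value by default: the sign of a principal component is arbitrary, and for
a fixed sample size ranking by |r| is equivalent to ranking by correlation
p-value. A `signed` option preserves raw correlations under the
sign convention that the largest-magnitude loading is positive. Non-member
cells are exactly 0, and the assignment argmax runs over member columns
only — with signed scores a gene's best member correlation could otherwise
lose to a structural zero.

Degenerate cases: singleton pathways (empty leave-one-out block) and
constant blocks or gene rows score a *flagged* 0, distinguished from a
true zero correlation; a gene whose every member score is flagged falls
back to its largest member pathway (logged).

## Error-rate simulation

For each focal pathway `P_i`, `required_de_count` scans for the smallest
`a` with `p(a, size-a) < alpha` against the `total_de` / rest background
(default 100 DE genes); infeasible pathways (e.g. spanning the whole
universe) are skipped and reported. Each replicate plants exactly `n_i` DE
genes uniformly inside `P_i` and `total_de - n_i` uniformly outside, then
tests every pathway with all enabled methods on the same draw. The focal
pathway is truly enriched by construction (uncorrected ORA power is
exactly 1); every other significant pathway is a false positive. Type-I
error is reported per pathway test (significant non-focal tests over all
non-focal tests), with the family-wise rate alongside; type-II is
`1 - power`. The EM and PCA impact matrices depend only on the membership
structure and expression — not on which genes are flagged DE — so each is
computed once per simulation and reused across replicates (asserted
equivalent in tests). Replicate-level re-detection of modules is not
supported: it would change the tested hypothesis set mid-simulation, and
no supported protocol exercises it; modules should be detected once and
the expanded matrix passed to the simulation.

## Synthetic reference sets

`synthdata` generates the structure the corrections assume:

* **Membership.** Pathway weights are log-normal (`sigma = 0.5`); every
  gene gets exactly one generating ("true") pathway. Overlap comes from
  two KEGG-like sources: a few *shared cores* — blocks comprising 40% of a
  seed pathway's genes, annotated wholesale to a group of three pathways
  (the pattern behind curated families such as the oxidative-
  phosphorylation / neurodegeneration cluster, whose observed shared core
  is roughly a third of each parent) — and rare stray co-annotations
  (Poisson mean 0.05 per gene). The desk-scale default is 30 pathways over
  600 genes (median size ~24, total memberships close to the gene count);
  a "full" preset scales the same recipe to 186 pathways / 4801 genes.
* **Expression.** Per subject, one standard-normal latent factor per
  pathway; gene `i` is `loading * f_true(i) + noise_sd * eps` with
  `loading = 1`, `noise_sd = 0.25` by default, 40 subjects in two balanced
  groups. DE genes shift by `de_effect` *marginal* standard deviations in
  group 2 (so the per-gene t-test power follows the noncentral-t closed
  form exactly when genes are independent).

Because every gene has a single generating factor, the true assignment is
a fair oracle: the PC1 correction recovers it perfectly at zero noise and
for >= 90% of multi-membership genes at noise 0.25.

What the generator does *not* emulate: probe-level and batch effects,
heavy-tailed microarray noise, count noise of RNA-seq, hub genes belonging
to many pathways, and — importantly — the dense overlap of real KEGG
(about two memberships per annotated gene). Passing tests on this
reference show the machinery is correct and that the corrections behave
directionally as intended; they do not certify error rates on real
collections.

## Problem sizes and observed rates

The shipped simulation summary (`scripts/acceptance.py`) pools five
generator seeds at 100 replicates per focal pathway on the 30 x 600
reference — 15,000 focal tests and 435,000 null tests per method, chosen
so the whole summary recomputes in minutes on one CPU. Under these
conditions it reports (seed 1): ORA power 100%, per-test type-I error
2.6%; EM correction type-I 2.4%, type-II 28.9%; PCA correction type-I
2.6%, type-II 27.7%.

Two structural effects dominate these numbers and are worth knowing
before comparing against other implementations or data:

* the discrete Fisher test is conservative at small pathway sizes, so the
  per-test null rate sits well below the nominal 5% and leaves little
  room between the uncorrected and corrected type-I rates unless overlap
  is pervasive;
* the planted signal is *minimal* (`n_i` is the smallest significant
  count), so a corrected focal pathway misses whenever the correction
  reassigns away even one or two of its planted genes. Aggregate type-II
  therefore tracks the fraction of (pathway, replicate) pairs touched by
  any reassignment, and membership-blind corrections pay this cost
  wherever overlap exists. An evidence-weighted assignment (one that sees
  which genes are DE) could retain significant pathways' genes and lower
  this substantially; that variant is intentionally out of scope here.

## Known limitations

* The EM hard assignment is exact only in the small-problem DP regime;
  at scale the local search can in principle return a locally optimal
  assignment.
* ORA on impact matrices keeps the original `(n, m)` background; genes
  reassigned away from all significant pathways still count in the
  margins.
* Module naming abbreviates parent ids to three letters; collisions get
  numeric suffixes, so names are stable only within one analysis.
* The t-test stage is a plain Student/Welch test on a complete matrix; no
  missing-value handling, no moderated variance.
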