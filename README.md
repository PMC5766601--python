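# pathxtalk

Detection and correction of **crosstalk effects** in pathway
overrepresentation analysis.

## The problem

Classical overrepresentation analysis (ORA) scores each pathway with a
one-sided Fisher exact test: given *n* differentially expressed (DE) and
*m* non-DE genes, a pathway containing *a* DE and *b* non-DE genes gets

&nbsp;&nbsp;&nbsp;&nbsp;*p* = P(X ≥ a),&nbsp;&nbsp;X ~ Hypergeometric(N = n + m, K = n, draw = a + b).

This treats pathways as independent — but curated collections such as KEGG
share genes freely. A block of genes sitting in several pathways lets one
truly enriched pathway drag its neighbours to significance (false
positives) or, conversely, dilute them (false negatives). That coupling
through shared genes is the *crosstalk effect*.

`pathxtalk` implements a complete workflow for transcriptomics studies
(bulk or single-cell pseudobulk) that:

1. builds the binary **membership matrix** `X` (genes × pathways, DE genes
   ranked first by p-value) from a GMT collection and per-gene DE p-values;
2. quantifies pairwise crosstalk: a k × k matrix whose cell [i, j] is the
   ORA p-value of pathway `P_i` after removing its intersection with `P_j`
   (with a red/green heat-map export);
3. detects **intersection modules** — shared cores that carry the
   significance of pathway pairs (both pathways significant, neither
   remainder significant, the intersection itself significant) — merges
   similar candidates by the overlap coefficient
   mJS = |M_i ∩ M_j| / min(|M_i|, |M_j|), and re-tests them as independent
   units;
4. corrects crosstalk by reassigning every gene to exactly **one** of its
   member pathways, producing an impact matrix `Z` (one 1 per row, Z ≤ X):
   * **ML / maximum impact** — a finite-mixture EM on the membership
     structure (E-step `r_ij = π_j X_ij / Σ_l π_l X_il`, M-step
     `π_j = Σ_i r_ij / Σ_il r_il`), with the final hard assignment
     maximising the assignment likelihood `Π_j (c_j / N)^{c_j}`;
   * **PCA / expression-based** — each gene is scored against every member
     pathway by |Pearson r| between its expression profile and the first
     principal component (eigengene) of the pathway's expression block
     *with the gene itself left out*, and assigned to the best-correlated
     member pathway;
5. estimates **power, type-I and type-II error** of all three approaches by
   a planted-signal simulation: for each feasible focal pathway the minimal
   significant DE count `n_i` is planted inside it, the remaining DE genes
   are scattered outside, and every pathway is re-tested.

A synthetic-data module generates KEGG-like membership matrices (log-normal
pathway sizes, shared-core overlap blocks) and latent-factor expression
data with known ground truth, so the whole pipeline is testable without any
download.

## Worked example

Everything is available as a library and as the `pathxtalk` CLI. A full
synthetic run:

```
$ pathxtalk pipeline --synthetic --seed 7 --method pca --outdir demo/run
pipeline artifacts written to demo/run

$ head -4 demo/run/ora.tsv
rank  pathway  de_in_pathway  pathway_size  p_value
1     PW01     15             35            0.0008458793761386799
2     PW24     12             25            0.0008630558482778529
3     PW27     4              7             0.028847599013903366

$ head -4 demo/run/corrected_ora.tsv
rank  pathway  de_in_pathway  pathway_size  p_value
1     PW01     15             31            0.00016001457267187164
2     PW24     10             18            0.0005553254015276698
3     PW27     3              4             0.024285611956017406
```

After the PCA correction each gene counts for exactly one pathway: PW01
shrinks from 35 to 31 members (its four genes shared with other pathways
were reassigned), and because the competing memberships are gone its
enrichment sharpens (p 8.5e-4 → 1.6e-4). The output directory also holds
`de_results.tsv`, `crosstalk.tsv` + `crosstalk_heatmap.png`, `modules.tsv`,
`membership_expanded.tsv`, `impact_pca.tsv` and a JSON run manifest.

The error-rate simulation on the same synthetic reference:

```
$ pathxtalk simulate --reps 100 --seed 1 --out sim.json
ora: power=1.000 type1=0.0272 type2=0.000
ml:  power=0.673 type1=0.0234 type2=0.327
pca: power=0.737 type1=0.0276 type2=0.263
```

ORA finds every planted focal pathway (power 1.0 by construction) and
flags 2.7% of the truly-null pathway tests; the corrections trade some
power for a lower false-positive rate on overlap-rich instances. See
`docs/methods.md` for what these numbers do and do not say.

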