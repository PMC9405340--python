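# Methods

`icdmir` implements an integration analysis for identifying miRNA:mRNA
regulatory modules specific to immunogenic cell death (ICD). The experimental
design it models is two cancer cell lines (a B-cell lymphoma, "Mino", and a
breast cancer line, "MDA") exposed to two ICD inducers — doxorubicin (DXR)
and retinoic acid combined with interferon-alpha (RA/IFNα) — and to gamma
irradiation (gIrr) as a non-ICD control, each contrasted against untreated
cells. The pipeline runs: expression filtering → per-contrast differential
testing → ICD-specific signature selection → seed-match target prediction →
inverse co-expression pair networks restricted to immune-system genes →
overlapping clique-based clustering → over-representation analysis.

## Differential expression

Counts are modelled as negative binomial with variance μ + αμ². The test for
one contrast (treatment vs untreated within a cell line) is deliberately
simple and fully documented rather than a DESeq2 replica:

- **Normalization** — median-of-ratios size factors over features positive in
  every sample, rescaled to geometric mean 1.
- **Dispersion** — per-feature method of moments on normalized counts, pooled
  across the two groups and floored at 1e−8, then moderated toward the
  cross-feature median with `prior_df = 10` prior degrees of freedom. The
  moderation is essential at this design's replicate counts (2–4 per group):
  raw three-sample moment estimates are so noisy that underestimated
  dispersions inflate the test statistic (anticonservative) while
  overestimated ones destroy power. `prior_df = 0` restores the raw
  per-feature estimator.
- **Statistic** — Wald statistic on the log2 fold change with a delta-method
  standard error, Var(group mean) = μ/s̃ + αμ²/n, referred to a Student t
  with (n_t − 1) + (n_c − 1) + prior_df degrees of freedom (the moderated-t
  convention). On a 2000-feature null simulation (α = 0.1, 3 vs 3, seed 0)
  the observed type-I error at p < 0.05 is 0.054.
- **Edge cases** — features at zero in both groups report log2FC 0 with a
  missing p; a single all-zero group receives a 0.5 pseudo-count on its
  normalized mean and is flagged. Multiple testing is Benjamini–Hochberg
  within each contrast; missing p-values pass through and do not count
  toward m.

Fold changes are reported both as log2 ratios and in the signed-ratio
convention of the published contrast tables (ratio r ≥ 1 printed as r, r < 1
as −1/r). Expression floors follow the study: an mRNA counts as expressed at
≥ 10 reads, a miRNA at ≥ 3, interpreted as "maximum over samples" (a
sum-over-samples switch exists). The ΔΔCt helper returns 2^−ΔΔCt for qPCR
relative quantities.

## ICD signature selection

A feature is *called* in a contrast when |signed FC| ≥ 1.3 **and** p ≤ 0.05
(boundaries significant; both conditions required — the published tables
contain a cell with p = 1.08e−4 but |FC| = 1.25 that is treated as no call).
Internally generated contrasts are thresholded on the BH-adjusted p by
default; imported contrast tables are thresholded on the p column they
carry, matching how the published tables print one p per contrast.

The ICD-specific rule keeps a feature in direction d when:

1. in **each** cell line it is called d under at least one ICD inducer
   (`inducer_rule="any"`, the default) — this is the selection the published
   table captions describe ("significantly different in DXR- **or**
   RA/IFNα-treated samples … in both cell lines") and the only reading
   consistent with every printed row (one published up-gene is significant
   under a single inducer in one line, at p = 5.28e−2 in the other); a
   stricter all-four-contrasts reading is available as `inducer_rule="all"`;
2. no gamma-irradiation contrast shows a call **in the same direction**.
   The exclusion is direction-specific because the published down-signature
   contains a miRNA with a strongly significant gIrr *up* call (FC 2.03,
   p = 2.11e−65); `strict_girr=True` excludes on any gIrr call instead.

Under the "any" rule a pathological table could qualify a feature for both
directions; such features are dropped from both branches and logged. UpSet
support computes exclusive intersections (elements belonging to exactly one
subfamily of the named sets), which provably partition the union.

## Target prediction

Machine-learned interaction scores of public prediction services cannot be
reproduced deterministically, so the predictor is a transparent canonical
seed-match score over the **complete transcript** (5′UTR + CDS + 3′UTR).
Site types are defined against the miRNA seed (nucleotides 2–8): 8mer
(reverse complement of 2–8 followed by A, score 1.00), 7mer-m8 (rc of 2–8,
0.95), 7mer-A1 (rc of 2–7 followed by A, 0.92), 6mer (rc of 2–7, 0.80). The
map is chosen so the conventional 0.9 score threshold keeps 7mer/8mer sites
and drops 6mer-only interactions. When matches of different types overlap
one locus only the highest-ranking type is reported. A prediction's score is
the maximum over its sites. Externally computed prediction tables can be
imported to drive the downstream stages at full fidelity.

## Pair networks and clustering

An immunogenic pair requires (a) opposite differential directions for miRNA
and gene, (b) a prediction score at or above the threshold, and (c) a gene
annotated to the immune-system-process term (GO:0002376). Gene directions
come from one designated contrast (default: RA/IFNα vs untreated in the
lymphoma line, the contrast the original analysis paired against). Pairs
form a bipartite miRNA–gene graph.

Clustering follows the EAGLE scheme for overlapping communities: maximal
cliques (pivoting Bron–Kerbosch) of at least `min_clique_size` vertices seed
the communities; cliques whose vertices all belong to other larger retained
cliques are subordinate and dropped; vertices in no retained clique enter as
singletons; the community pair with the largest modularity-style similarity
S(C₁,C₂) = (1/2m) Σ_{v∈C₁,w∈C₂,v≠w} [A_vw − k_v k_w/2m] is merged until one
community remains; the returned cover is the dendrogram level maximizing the
extended modularity EQ = (1/2m) Σ_i Σ_{v,w∈C_i} [A_vw − k_v k_w/2m]/(O_v O_w),
where O_v counts v's community memberships. Because a bipartite pair network
is triangle-free, `min_clique_size` defaults to 2 (edges as seeds) on
bipartite inputs and 3 otherwise. Determinism: communities iterate in sorted
order and similarity ties break toward the lexicographically smallest pair.
Connected components are agglomerated independently; EQ decomposes
additively over communities, so per-component cuts maximize the global
score. Clusters are reported ranked by node count, then induced edge count,
then name.

## Over-representation analysis

Enrichment of a query list against GMT terms uses the hypergeometric upper
tail P(X ≥ k) with BH correction across tested terms and gene-ratio (k/K)
reporting. The default universe is the union of all annotated genes; an
explicit universe may override. Terms are flat sets — no GO topology or
parent propagation.

## Synthetic data

The generator emulates the study design: 2 cell lines × 4 conditions ×
`n_replicates` (default 3) libraries for `n_mirna` = 100 miRNAs and
`n_mrna` = 500 mRNAs. Defaults: NB dispersion 0.05 shared across features;
per-feature abundances log-normal (σ = 1) around `library_size_mean /
n_features`; per-sample library factors log-normal (σ = 0.2) to exercise
normalization; 10 planted features per class (up/down × miRNA/gene) shifted
by ±2 log2 units under both ICD inducers in both lines and untouched under
gIrr; 5% of background features perturbed under gIrr only (the confounders
the exclusion rule must reject); every planted regulator linked to an
inversely regulated target gene by 2 embedded 8mer sites in a 500-nt
transcript; the immune term covering all planted genes plus background
genes. A rejection pass re-randomizes accidental canonical sites of planted
regulators in non-target transcripts so the planted truth table is exact.
All draws come from one seeded generator in a documented order, so equal
specs give byte-identical files.

What the generator does **not** emulate: batch effects, isoform structure,
read-level noise, dispersion heterogeneity across features (available as an
option but off so that recovery tests are not confounded), GC or length
bias, and correlated expression between features. Passing recovery tests
therefore demonstrates the pipeline's correctness under its own model
assumptions, not performance on real sequencing data.

At the default spec and seed 0, the full pipeline recovers the planted
regulator→target pairs with sensitivity 0.95 and FDR 0.0 (run by the test
suite); these simulation sizes keep the complete suite under a minute of
compute apart from the DESeq2 cross-check.

## Known limitations

- The NB test has no covariates, likelihood-ratio option, Cook's filtering
  or independent filtering; published contrast tables are the supported path
  for reproducing published signatures.
- The seed-match score is a semantic stand-in; its absolute values are not
  comparable with any external service's scores.
- Cluster-level modularities of the original analysis (≈ 0.5) depend on the
  full unpublished differential lists and an external prediction service and
  are treated as qualitative references only.
- g:SCS-style multiple-testing correction of some enrichment tools is not
  reproduced; BH is used throughout.
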