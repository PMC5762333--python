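# Methods

This note records the models, defaults, and design choices behind
`subspa`, and what the synthetic benchmark does and does not show.

## Subpathway reconstruction

Pathway topology is read from KGML. Only entries of type `gene`
become nodes; entry `name` tokens are kept verbatim (e.g.
`hsa:5290`), multi-gene entries are expanded so every member inherits
the entry's relations, `group` entries are flattened to their member
genes with a clique among them, and `map` entries are dropped. All
gene–gene relation subtypes are kept. Two gene entries sharing a
compound entry can optionally be bridged by a direct edge
(`bridge_compounds`, off by default): compound mediation is a real
topological link in metabolic maps, but inferring gene–gene adjacency
through it is an approximation, so it is opt-in.

A subpathway is a maximal gene set with pairwise unweighted
shortest-path distance ≤ *k*. These sets are exactly the maximal
cliques of the auxiliary graph obtained by thresholding the all-pairs
distance matrix at *k*; enumeration uses networkx's Bron–Kerbosch
implementation. Defaults: *k* = 3, minimum 3 genes and 2 embedded
lncRNAs per retained subpathway. Components of a disconnected pathway
are independent (cross-component distances are infinite). Overlapping
subpathways are *not* merged — ids are pathway-scoped, assigned over
the mined candidates ordered by descending size then lexicographic
member list, before size filtering, so an id never changes when
thresholds do (filtered lists may have ordinal gaps). The same gene
set mined from two pathways is kept separately under each parent.

Every lncRNA regulating at least one member gene (per the
regulation table) is embedded; the whole-pathway counterpart
(`<id>_whole`) applies the same embedding to the full gene set and
bypasses the size filter, for pathway-level vs subpathway-level
comparisons.

## Activity scoring

Within each sample the merged gene+lncRNA features are ranked
ascending by expression and weighted `w(r) = r·exp(sign·r/|N|)`. The
exponent sign defaults to `+1`; the ancestral decaying form (`-1`) is
available (`exponent_sign=-1` / `--faime-exponent neg`). Both are
monotone non-decreasing in the rank on r ∈ [1, |N|] (for the negative
sign, dw/dr = e^{-r/n}(1 − r/n) ≥ 0 on the valid range), so
order-based downstream statistics are insensitive to the choice.

Numerical policies:

- **Ties** get mid-ranks, hence identical weights — the score is
  invariant to input order within tied blocks. RPKM-like data contain
  many zeros, which makes this the only permutation-safe choice.
- **"Expressed" features**: all rows of the merged matrix are used;
  no abundance pre-filter is applied by default.
- **Unmeasured components** of a subpathway are ignored
  (intersection semantics) and counted; a subpathway with no measured
  component yields a missing activity that is excluded per-analysis,
  never zero-filled. An empty complement is an error.
- **Normalization** is the per-subpathway z-score across samples with
  the n−1 denominator; constant rows become all-zero and are flagged;
  a single-sample profile cannot be normalized.

## Statistics

- **Enrichment** pools genes and lncRNAs into one hypergeometric urn;
  the p-value is the upper tail P(X ≥ r_g + r_lnc) via scipy's
  survival function. With all lncRNA counts zero this is exactly the
  classical gene-only test. The universe defaults to the *measured*
  features, the only self-consistent choice when cohorts vary; a
  genome-scale universe can be supplied instead. BH correction uses
  statsmodels.
- **Differential activity** is the two-sided Wilcoxon rank-sum test.
  With both groups ≤ 10 samples the exact permutation distribution of
  the rank sum is enumerated over all group assignments of the pooled
  mid-ranked values — this handles ties exactly and gives p = 1 for
  identical groups; larger groups use the normal approximation with
  tie-corrected variance and continuity correction (scipy). Calls at
  level α (default 0.05) use the raw p; adjusted p is also emitted.
- **Per-type correlation** compares mean `sPA_norm` vectors between
  tumor types with Pearson r and its t-distribution p
  (df = #subpathways − 2).
- **Clustering** uses uncentered correlation distance
  d = 1 − Σxy/√(Σx²Σy²) with complete linkage; items are processed in
  sorted label order so merge ties resolve deterministically.
  All-zero vectors are rejected (the similarity is undefined).

## Survival analyses

Univariate Cox fits (lifelines) use each subpathway's `sPA_norm` as
the single continuous covariate — the profile carried through all
downstream analyses — with Efron tie handling and two-sided Wald
p-values; a flag can switch to raw sPA. Constant covariates or < 2
events yield a flagged, estimate-free result. The signature is all
subpathways with Wald p below the threshold (default 0.01). The
train/test split is a uniformly random equal partition (odd counts
favor training); stratification by event status is available behind a
flag but off by default. Risk groups come from Euclidean K-means
(scikit-learn, 25 restarts) on per-sample signature-activity vectors;
the group count is a user parameter (default 2) because no selection
criterion is prescribed. Group survival is compared with the k-group
log-rank test (k − 1 df).

## Synthetic cohorts

The generator emulates an RPKM-like two-condition cohort: connected
Erdős–Rényi pathway graphs, lncRNAs with uniformly drawn targets,
i.i.d. log-normal baseline expression, a multiplicative fold change
planted on the members of chosen subpathways in tumor samples, and
exponential survival with hazard
`h0 · exp(β · z)` where z is the planted subpathway's activity
z-scored within the tumor group; censoring is uniform on (0, m] with
m tuned by bisection to a target censored fraction. One master seed
(numpy `SeedSequence` spawning) fixes every artifact byte-for-byte.

Defaults: 3 pathways × 12 genes (edge probability 0.25), 40 lncRNAs
with 3 targets each, 30 tumor + 30 normal samples, fold 4, log-normal
(μ = 1, σ = 1), β = 0.8 per activity z-unit, baseline hazard
0.05/day, 30% censoring. These give subpathways of roughly 7–9 genes
and ~20 embedded lncRNAs — the same gene:lncRNA balance regime as
real reconstructions, at desk scale.

What the simulations do **not** model: read-count noise and library
size, correlated co-expression structure, miRNA-level mechanics,
condition-dependent censoring, or calibrated marginals of any real
cohort. Passing benchmarks therefore demonstrates correctness and
statistical calibration of the machinery, not performance on real
tumor data.

Benchmark problem sizes (chosen to exercise the asymptotics the
methods rely on): null calibration uses 60 + 60 samples per cohort
over 200 seeded replicates, so the Wald test operates in a regime
where its p-values are close to uniform; planted-effect detection
uses the default 30 v 30 cohorts over 100 replicates; hazard-slope
recovery uses 400 tumor samples over 100 replicates.

## Reproducibility

Every CLI command writes a manifest (parameters, seeds, SHA-256 input
checksums, relative paths). Timestamps honour the `SOURCE_DATE_EPOCH`
convention, making reruns byte-identical when it is set.

## Known limitations

- No merging of overlapping subpathways; highly redundant signatures
  can result (visible in the worked example, where three overlapping
  subpathways of the planted pathway enter the signature together).
- No multivariate or penalized Cox, no clinical-covariate adjustment,
  no time-dependent covariates.
- Identifier mapping (e.g. KEGG ids to symbols) is the caller's job.
- Serialized identifiers must avoid tab, comma, and hyphen (the
  subpathway-definition file's separators).
- The exact rank-sum path enumerates C(n1+n2, n1) assignments; it is
  capped at 10 + 10 samples by design.
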