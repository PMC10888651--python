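# Methods

## Scope and model

`connexsig` implements a five-step drug-connectivity workflow for
transcriptomics: (A) differential expression and signature extraction from
treated-vs-control experiments; (B) connectivity scoring of each signature
against a reference compendium of perturbation z-score profiles; (C) selection
of the top-ranked compounds; (D) consensus selection of signature genes the
compound modulates in the same direction; (E) correlation/clustering of the
dataset signatures and pathway enrichment of the consensus genes. The package
assumes gene-level inputs (identifiers are opaque, case-sensitive strings; no
probe collapsing or symbol normalization is attempted) and a strictly
two-group design per experiment.

## Differential expression

Inputs are log2-scale intensity matrices. Quantile normalization maps every
column onto the vector of row-wise means of the column-sorted values,
preserving within-column rank order; tied values receive the mean of the
reference values across their rank span, so the "identical multiset per
column" property holds exactly for tie-free columns and approximately at ties.

The moderated t-statistic shrinks each gene's pooled two-sample variance
s²_g (d_g = n₁+n₂−2 df) toward a prior: s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g),
tested on d₀+d_g df. The prior (d₀, s₀²) is fitted by method-of-moments on the
log sample variances using the exact moments of log-chi-square variables
(digamma/trigamma), i.e. E[log s²_g] and Var[log s²_g] are matched under the
scaled-inverse-chi-square hierarchy; the trigamma inverse is solved by Newton
iteration. On seeded fixtures this reproduces Bioconductor limma's `eBayes`
t-statistics to ~1e-13 relative error (the test suite runs that cross-check
through Rscript). When the observed log-variance dispersion is no larger than
the sampling component, d₀ is taken as infinite (all variances equal the
prior); when no positive variances exist at all, the fit falls back to the
ordinary t with a warning. Genes with zero logFC are assigned t = 0, p = 1;
zero variance with a nonzero shift yields ±∞ and p = 0.

BH correction is the standard step-up procedure
(statsmodels `fdr_bh`); DEG filtering uses the strict inequality q < 0.05.
The cutoff is configurable; "strict" was chosen because the published
threshold does not state ≤ or <.

## Signature construction

Up tags are the first `max_per_direction` genes with logFC > 0 in descending
logFC order; down tags the most negative first. logFC = 0 belongs to neither
direction. "Most down-regulated" means most negative logFC, not smallest
magnitude. Ties in logFC are broken by ascending q, then lexicographic
gene id. The optional allowed-gene filter (a BING-like query space) is applied
*after* top-k selection by default — so signatures may hold fewer than 150
tags per direction — with a `before_selection` mode provided, since either
reading of the published procedure is defensible. If a caller configures
2·max_per_direction > max_total, the longer list is trimmed from its tail
(ties drop a down tag); this is unreachable at the 150/150/300 defaults.

## Connectivity scoring

The similarity statistic is the classic unweighted KS enrichment score
(running-sum extreme) rather than a z-weighted GSEA variant: the choice keeps
the statistic exactly checkable against a brute-force evaluation, and the
workflow this package implements treats the scoring engine as a replaceable
component. Profile rankings are by descending z with ties broken by
lexicographic gene id. Signature tags absent from the reference are dropped
with a logged count; a query whose tags are entirely absent is an error.

WTCS = (ES_up − ES_down)/2 when the signs differ, else 0 (the published CMap
convention for incoherent up/down behaviour). A one-sided query (one empty
direction, which is legal since signatures keep tags only "when present") uses
half the available ES with its sign preserved, consistent with treating the
missing side as 0. NCS divides WTCS by the mean |WTCS| of same-sign records
within the same cell line; all-zero groups stay at zero.

tau = sign(NCS) · 100 · (fraction of a reference NCS bank, same cell line,
with |value| strictly below |NCS|). Note the verbal definition of tau in the
connectivity-map literature ("fraction of reference signatures with *greater*
similarity") conflicts with the published convention that +100 means the
strongest connection; this package implements the conventional complement
(fraction with *lower* similarity), so stronger connections score nearer
±100. The bank can be built once per compendium from random probe signatures
(`build_touchstone`, pooling profile-level NCS per cell line); when no bank is
attached, the query's own profile-level NCS values within each cell line serve
as the reference. Under the self-referential bank tau is a rank transform
whose ceiling is 100·(m−1)/m for m profiles in the cell line, which is why a
20-compound × 3-replicate compendium tops out at tau ≈ 98.3.

Replicate profiles of one (pert_id, cell_id) pair are collapsed to a single
representative — maximum |NCS| by default, or the record closest to the
median |NCS| (`aggregator="median"`). Records are sorted by descending tau
(ties: |NCS| descending, then pert_id); `connected` is |tau| > 90 and the
top-k default is 10. Results are restricted to compound perturbagens
(pert_type `trt_cp`) when that class is present.

## Consensus selection

The compendium subset keeps profiles matching the provided pert_id /
pert_iname / cell_id lists (every listed id must exist) and, by default, only
landmark genes (pr_is_lm). Support for an up tag is the fraction of the
compound's profiles with z > 0 (z = 0 supports neither direction); genes with
support ≥ 0.70 are retained. Support is computed **per compound** across its
selected cell lines and replicates; a `pooled` mode computing one support
value across all selected profiles is provided because the published wording
("all the samples") admits both readings.

## Clustering and enrichment

Dataset feature vectors are the signature logFC values restricted to the
union of consensus-selected genes, zero-filled for genes absent from a
dataset's DEG table; a z-score-vector variant can be substituted by the
caller since the published analysis does not define the vector. Pearson
correlation uses `pandas.DataFrame.corr`; clustering uses scipy's Ward
linkage on per-dataset standardized vectors (so Euclidean distance is
monotone in correlation). When the number of clusters is not given, the tree
is cut at the midpoint of the largest gap between consecutive merge heights
— with two well-separated blocks this recovers exactly two clusters.

Enrichment is the hypergeometric upper tail P[X ≥ overlap] with BH across all
tested sets and significance at q < 0.05. Gene sets and the query are
intersected with the universe first. The universe defaults to the landmark
gene space used by the consensus step (the measured space) and is
configurable, since the appropriate universe is analysis-specific.

## Synthetic data: what it emulates and what it does not

`simulate_experiment` draws per-gene baselines from N(7, 1.5²) (log2
intensity scale), adds i.i.d. N(0, noise_sd²) residuals, and shifts planted
genes by ±effect_size in the treated group. Defaults (5000 genes, 3 samples
per group, 400+400 planted genes, effect 2.0, noise 0.3) describe a clean,
strong-effect microarray experiment at the minimum replication the workflow
accepts. It does not model probe-level noise, correlated genes,
intensity-dependent variance, or batch effects — so the recovery tests
(sensitivity ≥ 0.9 at FDR ≤ 0.07) certify the statistics pipeline, not
performance on noisy real arrays.

`simulate_compendium` draws background z-scores i.i.d. standard normal (the
natural null for replicate-collapsed differential z-scores) and implements a
planted connection of strength s as a ±s·δ shift (δ = 3.0 by default, chosen
so strength 1 gives near-saturated but not degenerate enrichment) on the
query's tags across all of the compound's profiles. Gene metadata emulates
the reference compendium composition — 978 landmark genes within 12,328
total, with a BING-like flag on landmarks plus 80% of the remainder — but the
profile dimension stays at desk scale (tens to hundreds of profiles, not
~470k), and no attempt is made to model bead-level deconvolution, replicate
correlation structure, or cell-line-specific expression baselines.
`simulate_pathways` draws sets uniformly from the universe with one optional
planted set. All generators are bit-reproducible under a fixed seed.

## Numerical and interface choices

* Missing values are written as `NA` and any of NA/NaN/empty parses as
  missing; GCT text (1.2/1.3) is the primary matrix format, with the
  HDF5-backed GCTX dialect supported read-only, keeping artifacts diffable.
* Values round-trip through text at `%.10g`, i.e. better than 1e-9 relative.
* Pipeline defaults equal the workflow's published thresholds (q 0.05,
  150/150/300 tags, top-10, |tau| > 90, 70% consensus, enrichment q 0.05), so
  a zero-flag run is the reference parameterization.
* The problem sizes in the test suite and acceptance script (e.g. 500-gene /
  15-compound planted compendia, 20-seed recovery repeats, a 20 × 3 × 3
  compendium for the tau bound) are chosen so the full validation runs in
  seconds while every statistic is still exercised at non-trivial size.

## Known limitations

Two-group designs only (no paired or multi-factor models); no RNA-seq count
models; no live connectivity-service queries, and no attempt to reproduce a
proprietary touchstone compendium's tau values — tau percentiles are only as
representative as the local reference bank. Gene identifiers must already be
harmonized between experiments, compendium and pathway collections.
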