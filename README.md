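# connexsig

Signature-based drug connectivity analysis for transcriptomics. `connexsig`
takes treated-vs-control expression experiments, extracts a gene signature of
the drug response, scores it against a CMap-style reference compendium of
perturbation z-score profiles with a local Kolmogorov–Smirnov / tau engine,
selects the genes a candidate compound modulates coherently with the query,
and annotates them by clustering and pathway enrichment. It is aimed at
computational pharmacologists generating "guilt by association" hypotheses —
compounds that induce a transcriptional response similar to a drug of interest
are candidates for a shared mechanism of action and for synergy screening —
without depending on a web connectivity service: the whole query engine runs
locally against any compendium supplied in GCT/GCTX + sig_info/gene_info form,
and a synthetic-data module generates compendia with planted connections so
every stage can be validated against ground truth.

## The method

**Step A — signature.** Each experiment (log2 intensities, ≥3 samples per
condition) is optionally quantile-normalized, then tested gene-by-gene with an
empirical-Bayes moderated t-statistic: the pooled variance s²_g is shrunk
toward a prior, s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), with (d₀, s₀²) fitted by
method-of-moments on the log sample variances, and t̃_g tested on d_g + d₀
degrees of freedom. Genes at BH q < 0.05 are sorted by log₂ fold change and
the top 150 up- and 150 down-regulated genes (≤300 tags, optionally restricted
to an allowed query space such as the BING gene list) form the signature.

**Steps B–C — connectivity.** For each reference profile, genes are ranked by
descending z-score and each tag set receives the unweighted KS enrichment
score

    ES = a  if a > b else −b,   a = max_j [ j/t − V(j)/n ],  b = max_j [ V(j)/n − (j−1)/t ],

where V(j) are the ascending ranks of the t tags among n genes. The two-sided
combination WTCS = (ES_up − ES_down)/2 when the two scores disagree in sign
(else 0) is normalized per cell line to NCS = WTCS / mean|WTCS| over same-sign
records, and tau is the signed percentile of |NCS| within a reference bank for
that cell line, scaled to [−100, 100]. |tau| > 90 flags a connection;
replicate profiles of a (compound, cell line) pair are collapsed to the
representative with maximal |NCS|, and the top 10 compounds by tau move on.

**Step D — consensus.** The compendium is subset to the selected compounds,
the cell lines of interest and the 978 landmark genes; a signature gene is a
consensus gene for a compound when its z-score sign matches the signature
direction in at least 70% of the compound's profiles.

**Step E — annotation.** Dataset signatures are compared by Pearson
correlation of their logFC vectors over the consensus genes and clustered with
Ward linkage; per-compound consensus genes are tested for pathway
over-representation with the hypergeometric upper tail and BH correction
(q < 0.05).

## Worked example

The bundled synthetic scenario plants one connected compound per experiment
(strength 1) and one pathway made of the first query's landmark up-tags:

```sh
connexsig run-all --demo --seed 1 --out demo/
```

prints

```
expA: 313 DEGs, 150+150 tags, top compound BRD-S0000 (tau 93.75)
expB: 308 DEGs, 150+150 tags, top compound BRD-S0001 (tau 93.75)
```

— both planted compounds are recovered at connectivity rank 1 and flagged
connected (tau 93.75 > 90). `demo/out/expA.top10.tsv` holds the ranked table:

```
pert_id      cell_id  ncs      tau    connected
BRD-S0000    PC3      2.2900   93.75  True
BRD-S0000    MCF7     1.8664   93.75  True
BRD-S0000    A375     1.8484   93.75  True
...
```

`demo/out/consensus.tsv` lists the coherently modulated genes per compound
(support_fraction ≥ 0.7), `cluster.json` separates the two experiments into
two Ward clusters, and `enrichment.tsv` calls the planted pathway for the
planted compound (overlap 22, q ≈ 1.4e-19) while leaving it non-significant
elsewhere. Individual stages are also available as `connexsig
{simulate-experiment, simulate-compendium, simulate-pathways, deg, signature,
connect, consensus, cluster, enrich}`; see `--help` on each.

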