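# comireg

Context-specific miRNA regulation (CoMi) analysis: score each miRNA's
regulatory effect on annotated gene sets from expression data, build signed
miRNA → gene-set networks, rank drug perturbation profiles by signature
reversal, and predict treatment response from per-sample CoMi features.

## The problem and the method

A miRNA acts on a biological process by repressing its target genes *inside*
that process's gene set. `comireg` makes that idea quantitative in four
stages:

1. **Pattern discovery.** For miRNA *i* with target set *M_i* and gene set
   (e.g. a GO term) *G_j*, the overlap *M_i ∩ G_j* partitions *G_j* into
   target and non-target genes. If the overlap is significant by an
   upper-tail hypergeometric test against the measured gene universe, the
   pair becomes a *CoMi pattern* with a frozen target/non-target partition.
2. **CoMi index.** For a condition (case-vs-control log2 fold changes) or a
   single sample (raw expression), the index of a pattern is the Welch
   two-sample t statistic

   t = (mean(x_T) − mean(x_NT)) / sqrt(s²_T/n_T + s²_NT/n_NT)

   contrasting the pattern's n_T target genes against its n_NT non-target
   genes, with a two-sided p-value (Welch–Satterthwaite df). Positive t
   means the targets sit above the non-targets. The vector of indices over
   all patterns is a *CoMi profile*; indices with p < α form a signed
   bipartite miRNA → gene-set network (edge weight −log10 p).
3. **Drug screening.** The disease profile is condensed to a signature (top
   k up-regulated + bottom k down-regulated patterns, 5 ≤ k ≤ n/3). Each
   library instance is scored by the Spearman correlation between its
   statistics and the disease statistics over the signature patterns and
   instances are ranked ascending (most anti-correlated = most
   treatment-like first). Screen success is the signed KS enrichment of
   known-positive instances near the top of that ranking — the *Drug
   Screening Performance* (DSP) index — with a permutation p-value
   (positives placed uniformly at random, 1000 permutations, add-one
   estimator).
4. **Response prediction.** Patients are represented by their per-sample
   CoMi statistics. Within each training portion of a repeated stratified
   5-fold cross-validation the imbalanced cohort is under-sampled to
   balance, features are ranked by a per-feature Welch t test, and a
   classifier (logistic regression / Gaussian naive Bayes / linear SVM) is
   fit on the top features; performance is the held-out AUC averaged over
   repeats.

A seeded synthetic-data module generates the full input set — annotation
with controlled overlap, a paired tumor/normal cohort with planted
repressions, a drug library whose true drugs invert the disease
dysregulation among decoys, and an imbalanced patient cohort — so the whole
pipeline is testable without any download.

## Worked example

```bash
comireg simulate --seed 7 --out demo/
comireg network --profile demo/disease_profile.tsv --alpha 0.05 --format tsv -o demo/net.tsv
comireg screen --disease demo/disease_profile.tsv --library demo/library_manifest.tsv \
        --n-perm 1000 --seed 7 -o demo/dsp.tsv
comireg predict --cohort demo/cohort.tsv --classifier logistic \
        --n-features 10 --repeats 20 --seed 7 -o demo/report.json
```

prints (seed 7):

```
simulate: 80 patterns, 55 library instances, 178 patients -> demo
network: 7 edges (alpha=0.05) -> demo/net.tsv
screen: 22 window sizes, median KS 0.909 (IQR 0.909..0.909)
predict: mean AUC 1.000 (logistic)
```

Reading the numbers: 80 (miRNA, term) pairs pass the hypergeometric gate;
7 of them — the three planted repressions plus a handful of chance calls at
the nominal 5% level — change significantly between the simulated tumors
and normals and become network edges; across every admissible signature
window the five planted "true drugs" are so strongly anti-correlated with
the disease signature that the DSP index sits near its ceiling (KS ≈ 0.91,
permutation p at the 1/1001 floor); and the ten planted response patterns
separate responders so cleanly that cross-validated AUC is 1.0.

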