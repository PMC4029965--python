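# Methods

## Model

`comireg` treats a miRNA's regulation of an annotated biological process as a
two-sample contrast. A *CoMi pattern* fixes, for a (miRNA, gene set) pair,
the partition of the set into the miRNA's target genes (n_T of them) and the
remaining non-target genes (n_NT). The pattern exists only if the overlap is
significant by an upper-tail hypergeometric test — P(X ≥ k) for k observed
targets in the set, with population parameters (universe size N, total
targets K, set size n) — and if both partition halves are non-empty, since a
two-sample statistic is otherwise undefined.

The *CoMi index* of a pattern under a condition is the Welch
(unequal-variance) two-sample t statistic between the target and non-target
values, with Welch–Satterthwaite degrees of freedom and a two-sided p-value.
The contrasted values are per-gene log2 fold changes (case vs control) for a
condition-level index, or one sample's raw expression for a per-sample
index; the formula is identical, only the provenance of the values differs.
A positive statistic means targets are elevated relative to non-targets.
Because the statistic is a location contrast, it is exactly invariant to
adding a constant to all values and to positive rescaling.

Fold changes are differences of log-scale values: the per-pair difference
averaged over pairs for paired designs, or the difference of group means for
unpaired designs.

### Numerical edge cases

- Both halves constant with equal means → statistic 0, p = 1, direction
  `null`.
- Both halves constant with unequal means → the statistic is capped at
  ±1e6 and p is set to the smallest positive double; the index is flagged
  degenerate rather than returning ±inf.
- A singleton half (n = 1) yields a statistic (its variance contribution is
  taken as 0) but no degrees of freedom, so p is reported as 1 with the
  degenerate flag.
- Two-sided p-values throughout; the direction is carried by the sign, not
  folded into the p-value. No multiple-testing correction is applied by
  default: the significance gates are raw p < 0.05 at both the pattern and
  the network stage.

The hypergeometric tail is evaluated with `scipy.stats.hypergeom`; the test
suite checks it against exhaustive subset enumeration with exact rational
arithmetic for every parameter combination with N ≤ 12. The Welch statistic
is implemented directly (it is the core quantity of the method) and checked
against `scipy.stats.ttest_ind(equal_var=False)` to 1e-10 on random inputs.

## Networks

Indices with p < α become directed edges miRNA → term with weight
−log10(p) and a sign from the index direction. miRNAs carry out-degrees,
terms in-degrees; degree tables and degree histograms are computed exactly
from the edge list. Node ids are namespaced (`mir:` / `go:`) in exports so
the two sides can never collide. Exports: GraphML (attribute-complete,
round-trip tested), SIF (`mirna regulates term`), and a flat TSV edge list.

## Drug screen

A disease signature is the k most up-regulated plus k most down-regulated
patterns of the disease profile, 5 ≤ k ≤ floor(n/3). Ties at the window
boundary break lexicographically by pattern key, and the down-tag is drawn
from the patterns not already taken by the up-tag, so signatures are
deterministic. The connectivity score of a library instance is the Spearman
correlation (average ranks on ties) between disease and instance statistics
over the signature patterns present in both profiles; instances sharing
fewer than 3 signature patterns are excluded rather than imputed. Instances
are ranked ascending, so the most anti-correlated — most treatment-like —
instance has rank 1.

The DSP index is the signed two-sided KS enrichment of the positive
instances' ranks V(1) < … < V(t) in a list of length N:

    a = max_j [ j/t − V(j)/N ],  b = max_j [ V(j)/N − (j−1)/t ]
    DSP = a if a ≥ b else −b

positive when positives concentrate at the top. Its permutation p-value
places the t positives uniformly at random among the N ranks (default 1000
permutations) and uses the add-one estimator
(#{|KS_perm| ≥ |KS_obs|} + 1)/(n_perm + 1), which floors at 1/(n_perm+1) and
never returns 0. The `dsp_sweep` operation evaluates one DSP per admissible
k and summarizes the pooled KS distribution (median, quartiles);
`discriminative_features` unions the tags of the best-scoring signatures.

## Response prediction

Patients are feature vectors of per-sample CoMi statistics with a binary
outcome (pCR). Cross-validation is repeated stratified 5-fold (each fold ≈
20% held out, reconciling an 80/20 split with five folds); the default 100
repeats × 5 folds ≈ 1000 fold evaluations. Within every training portion,
and never touching held-out samples: the majority class is under-sampled to
the minority size (all minority samples kept), features are ranked by
ascending per-feature Welch-t p-value between the classes, and the
classifier is fit on the top n features (default 27, searchable). Held-out
decision scores are pooled per repeat into one AUC; the report averages AUCs
across repeats and keeps pooled ROC points for replotting. Classifiers are
scikit-learn defaults: `LogisticRegression(max_iter=1000)`, `GaussianNB`,
and linear-kernel `SVC` scored by its decision function (AUC is invariant to
monotone score transforms, so probabilities are unnecessary).

## Synthetic study conditions

The generator defaults encode the study conditions the pipeline is
calibrated for; all generators are pure functions of (spec, seed).

| parameter | default | rationale |
|---|---|---|
| n_genes / n_mirnas / n_terms | 800 / 10 / 40 | desk-scale universe yielding ~60–90 discovered patterns |
| target_density | 0.08 | ~64 targets per miRNA, typical of consolidated prediction sets at this scale |
| planted overlap / term size | 20 / 100 | the canonical n_T = 20, n_NT = 80 pattern |
| planted effects | 3 disease shifts of −1σ, 10 response shifts of +1σ | repression by the disease; induction marking responders |
| noise_sd / pair_effect_sd | 1.0 / 1.0 | log2-scale unit noise; between-subject baseline shared within a tumor/normal pair |
| n_case = n_control | 43 | paired-cohort size |
| n_patients / pcr_fraction | 178 / 26⁄178 | imbalanced clinical cohort (26 responders) |
| true drugs / decoys | 5 / 50 | screen prevalence ~9% |
| drug fold-change noise | noise_sd·√(2/n_case) | matches the sampling noise of a paired cohort of n_case pairs |

Expression is Gaussian on a log2-like scale. Paired samples share a
per-(gene, pair) baseline with independent within-tissue noise, so paired
fold changes cancel the baseline; planted effects are additive location
shifts restricted to the pattern's target-in-set genes. (Case tissues are
*not* literal copies of their controls: without independent noise every
fold change would be deterministic and the null calibration the module is
tested against could not hold.)

Design choices in the annotation generator that were genuinely open:

- **Planted isolation.** A planted term's forced target support prefers
  genes targeted only by the planted miRNA and not used by another planted
  effect; its non-target fill prefers genes no miRNA targets; and decoy
  terms avoid planted supports. Without this, chance sibling enrichments
  and duplicated supports make the planted effects unattributable to their
  own pattern, which defeats the purpose of planting them.
- **Controlled decoy overlap.** Non-planted terms are seeded with an
  above-threshold target overlap for a random subset of miRNAs
  (probability 0.3, at most two per term), giving a realistic number of
  non-planted patterns; purely independent draws would pass the 5% gate for
  only ~5% of pairs and leave profiles too small for a signature sweep.
- **True drugs** negate the *realized* disease fold-change vector (planted
  shifts plus sampling noise) with fresh instance noise — a drug that
  counteracts the full dysregulation, as in reference perturbation
  libraries. Decoys carry one random effect of comparable magnitude on a
  random pattern.

What the generator does **not** emulate: probe-level microarray artifacts,
batch effects, heavy-tailed or intensity-dependent noise, the GO DAG's
nested term structure, and correlated miRNA co-regulation. Passing tests
therefore demonstrate correctness and calibration of the statistics under
the assumed location-shift model, not performance on real microarray
cohorts.

## Problem sizes used in tests and the acceptance script

Oracle checks enumerate exhaustively up to N = 12 (hypergeometric and KS).
Calibration uses 1000 null pattern evaluations (type-I), 200 screens of
1000 permutations (DSP uniformity, checked at the deciles), and 100
label-permuted cross-validation repeats (null AUC). Recovery uses 100
screen runs, 500 power runs on the 20/80 pattern, and 20 independent
patient cohorts; the acceptance script uses the same conditions with 25
screen runs and 10 cohorts so a full rerun stays within a few CPU-minutes.

## Known limitations

- The KS enrichment functional form is the classic two-sided ranked-list
  enrichment; it is isolated behind `drug_screen.ks_score` so an
  alternative variant can be substituted in one place.
- Per-sample indices treat genes within a sample as exchangeable
  observations; gene–gene correlation inflates the nominal significance of
  per-sample p-values, which is why downstream prediction uses the
  statistics as features rather than trusting their p-values.
- The hypergeometric universe must be declared by the caller (the CLI uses
  the genes present in both the expression matrix and the gene-set
  collection); p-values are only comparable across runs with the same
  declared universe.
- `feature_list_overlap_p` requires an explicit universe size for the same
  reason; there is no defensible default.
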