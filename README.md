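# guildnet

Co-abundance guilds, co-occurrence networks and aging-trajectory signatures
for compositional microbiome count tables.

`guildnet` is aimed at microbiome researchers studying how a gut community
restructures across age groups — in particular three-generation cohort
designs with young (G3), elderly (G2) and centenarian (G1) participants
sampled from the same families.  Starting from a taxa-by-sample count table
and a sample metadata table, it provides a tested, reproducible
implementation of an analysis pipeline that is usually assembled ad hoc from
scripts:

* **SparCC basis correlations.**  Relative abundances are compositional
  (columns sum to 1), so naive correlations are distorted by the shared
  denominator.  SparCC works from the variances of pairwise log-ratios,
  t_ij = Var[ln(x_i/x_j)] = w_i + w_j − 2 ρ_ij √(w_i w_j), and solves for
  the basis variances w under the sparsity assumption Σ_j ρ_ij ≈ 0 via the
  linear system ((D−2)I + 11ᵀ) w = t·1, iteratively excluding strongly
  correlated pairs that violate the assumption.
* **Guild detection.**  Prevalent taxa (shared by ≥20% of samples) are
  clustered with Ward's method on the correlation distance d = 1 − ρ, and
  the tree is divided top-down: at every internal node a PERMANOVA on the
  node's distance submatrix tests whether the two child subtrees separate
  (9999 permutations, p ≤ .001 by default).  The resulting guilds — sets of
  taxa that rise and fall together — are aggregated and compared across
  groups (Kruskal–Wallis + pairwise Wilcoxon, BH-corrected).
* **Per-group co-occurrence networks.**  Spearman correlations between taxa
  within each age group (|ρ| ≥ 0.7 and BH q < .05 by default), with shared /
  group-specific edge counts and closeness + eigenvector centralities of the
  common nodes.
* **Trajectory signatures.**  Each taxon's three pairwise Wilcoxon tests
  classify it as *rejuvenation* (young ≈ centenarian, elderly distinct),
  *centenarian* (young ≈ elderly, centenarian distinct), monotone
  increase/decrease, or stable; differences are re-confirmed by a bootstrap
  (10 samples per group with replacement, 1000 replicates, 90% interval
  excluding zero).
* **Stable heritable species.**  Taxa present in at least half of the
  multi-generation families with no significant group difference
  (Kruskal–Wallis p ≥ .05).
* **Synthetic cohorts with planted truth.**  A generator producing
  compositional counts with planted guilds, trajectory classes, family
  effects and linked host covariates, so every stage can be validated
  against a known answer.

Diversity utilities (Shannon, observed richness, Bray–Curtis, PCoA, ANOSIM,
PERMANOVA, BH-FDR) are implemented from first principles and cross-checked
in the test suite against scikit-bio, scipy and statsmodels.

The two core steps are also exposed as scikit-learn estimators: `SparCC`
(fit samples × taxa, like the covariance estimators) and `GuildDetector`
(a feature-clustering transformer in the manner of `FeatureAgglomeration`:
`labels_` per taxon, `transform` pools member relative abundances per
guild), so they compose with sklearn pipelines and `clone`/`get_params`.

## Worked example

Simulate a default cohort (73 samples: 32 centenarian / 30 elderly / 11
young, 150 taxa, 8 planted guilds, 26 families) and run every stage:

```bash
guildnet simulate --seed 7 --out-dir cohort
guildnet run-all --counts cohort/counts.tsv --metadata cohort/metadata.tsv \
    --seed 7 --out-dir results
```

prints

```
wrote 150 taxa x 73 samples to cohort
6 stages complete -> results
```

and `results/manifest.json` records per stage (abridged):

```
diversity   {'anosim_R': 0.126, 'anosim_p': 0.001}
sparcc      {'n_taxa': 150, 'n_excluded_pairs': 10, 'converged': False}
guilds      {'n_guilds': 15}
network     {'G1': 222, 'G2': 288, 'G3': 19}
signatures  {'n_confirmed': 89, 'n_stable': 107}
```

Reading the numbers: the ANOSIM R of 0.126 (p = .001) says group membership
explains a small but detectable part of the between-sample Bray–Curtis
structure.  The guild stage recovers 15 guilds — the 8 planted co-abundance
blocks plus clusters formed by taxa sharing a planted trajectory (taxa that
shift together across age groups covary too).  `converged: False` on the
SparCC stage flags that strongly correlated pairs remained after the 10
exclusion rounds — expected when true guild correlations exceed the 0.8
exclusion threshold.  The per-group networks shrink dramatically in the
young group (19 edges at n = 11 versus 288 at n = 30) because rank tests
lose power at small n.  Of the 150 taxa, 107 satisfy the stable-species
rule and the signature table classifies the planted rejuvenation (10/10)
and centenarian taxa correctly:

```
{'stable': 110, 'centenarian': 15, 'rejuvenation': 10,
 'monotone_increase': 8, 'monotone_decrease': 4, 'other': 3}
```

Every output is a flat TSV (plus GraphML for networks) under `results/`,
and `manifest.json` carries sha256 hashes of every file: re-running with the
same seed reproduces them byte for byte.

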