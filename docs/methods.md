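# Methods

This note documents the statistical procedures `guildnet` implements, the
generative model behind its synthetic cohorts, the defaults and why they
were chosen, and the numerical conventions that make runs reproducible.

## Data model

The pipeline operates on a non-negative integer taxa × samples count table
(`CountTable`), optionally annotated with semicolon rank-prefixed lineages
(`k__...;p__...`), and a per-sample metadata table with an age-group label
(G1 centenarian, G2 elderly, G3 young), optional family id and generation,
and free numeric host covariates.  Relative abundances are total-sum scaled
per sample; an all-zero sample is an error, never a silent NaN.  The
internal orientation is fixed (taxa as rows); files in the other
orientation are transposed at the I/O boundary.

## SparCC basis correlations

Compositions carry no information about total load, so correlations between
relative abundances are biased by closure.  SparCC estimates the
correlations of the unobserved absolute abundances ("basis" correlations)
from log-ratio variances, which are closure-invariant:

    t_ij = Var_k[ ln(x_ik / x_jk) ] = w_i + w_j − 2 ρ_ij √(w_i w_j).

Under the sparsity assumption that correlations mostly cancel
(Σ_{j≠i} ρ_ij √(w_i w_j) ≈ 0), summing t_ij over j gives a linear system
for the basis variances w:

    Λ w = t·1,   Λ = (D − 2) I + 1 1ᵀ,

after which ρ_ij = (w_i + w_j − t_ij) / (2 √(w_i w_j)).  Pairs whose |ρ|
exceeds the exclusion threshold violate the sparsity assumption; the
strongest such pair is removed from the row sums and from Λ and the system
re-solved, up to `max_exclusion_rounds` times.  If fewer than four taxa
retain unexcluded partners, or the reduced system becomes singular, the
loop stops and the result is flagged unconverged.  Estimates outside
[−1, 1] — a known finite-sample behaviour — are clipped with a logged
warning.  For three taxa Λ inverts in closed form
(w_i = (t_ij + t_ik − t_jk)/2), which the test suite uses as an exact
oracle to 1e-10.

Defaults: pseudocount 0.5 added to all counts before closure; exclusion
threshold 0.8 with at most 10 rounds; deterministic single-pass estimation.
Setting `n_restarts > 1` averages ρ over per-sample Dirichlet(counts +
pseudocount) resamples of the fractions (seed-controlled); the default is
off so that the pipeline is deterministic end to end.

## Guild construction

1. **Prevalence filter** — keep taxa whose relative abundance is at least
   `min_rel_abundance` (default 0, i.e. presence) in at least
   ceil(`min_prevalence` · n) samples (default 20%).
2. **Ward tree** — correlation distance d = 1 − ρ (range [0, 2]); Ward
   minimum-variance agglomeration.  Taxa are sorted lexicographically
   before linkage so equal-height merges break ties identically for any
   input order.
3. **PERMANOVA division** — top-down from the root: at each internal node,
   a PERMANOVA over the node's d-submatrix compares the two child
   memberships.  The split is accepted when p ≤ alpha and the recursion
   continues; otherwise the node's taxa are emitted as one guild.  A child
   reached as a single taxon becomes a singleton guild.  Every tested node
   (sizes, pseudo-F, p, decision) is recorded in a division log.

The comparison is deliberately **inclusive** (p ≤ alpha): the add-one
permutation p-value has floor 1/(B + 1), so with the conventional B = 999
and alpha = .001 a strict inequality could never accept any split; the
inclusive rule accepts exactly the splits whose observed pseudo-F exceeds
every permuted one.  Defaults are B = 9999 and alpha = .001; the test suite
uses B = 999 for speed.

A caveat documented rather than hidden: the division tests the tree's own
children on the same distance matrix that built the tree, which is
anti-conservative under pure noise (clustering always finds its best
split).  With planted block structure this is immaterial — the spurious
splits appear below real blocks, not across them — but guild counts on
weakly structured data should be read as upper bounds.

Guild abundance is the **sum** of member relative abundances per sample
(so guild abundances over all prevalent taxa sum to ≤ 1).  Group-level
comparison runs Kruskal–Wallis across the three groups plus the three
pairwise Wilcoxon rank-sum tests per guild, BH-adjusted within each test
family across guilds.

## Co-occurrence networks and their discrepancy

Within each group, taxa passing the group-level abundance filter (default:
relative abundance ≥ 0.1% in ≥ 20% of the group's samples) are tested all
against all with mid-rank Spearman correlation; an edge requires both
|ρ| ≥ 0.7 and BH q < .05 over exactly the tested pair family.  Nodes carry
the group-mean relative abundance; unconnected taxa are omitted.

Comparing networks, edge identity is the unordered node pair with the sign
ignored (a sign flip between groups is reported in a separate *discordant*
bucket).  Shared edges appear in every group; specific edges in exactly
one; edges in more than one but not all groups are counted separately as
*partial*, so shared + Σ specific never exceeds the total.  For the nodes
present in all networks the table reports closeness centrality in the
Wasserman–Faust component-scaled form (the convention that remains
meaningful on disconnected graphs) and eigenvector centrality of the
unsigned (binary) adjacency, computed by exact symmetric
eigendecomposition — the fixed point power iteration would converge to —
reported as magnitudes normalised to max 1, plus within-group ranks.

Host-covariate association uses the same Spearman/BH machinery over every
(taxon, variable) pair with pairwise-complete observations; all-missing or
constant variables are excluded with a warning, never silently zeroed.

## Trajectory signatures

Each taxon gets three pairwise Wilcoxon rank-sum tests (G3 vs G2, G2 vs G1,
G3 vs G1), BH-adjusted per pair family across taxa, with direction the sign
of the older-group median minus the younger-group median.  "Similar" is
operationalised as *not significant at the same threshold used for
distinct* — there is no equivalence test, so a stable label is absence of
evidence, not evidence of absence.  Classification applies rules in
priority order:

| class | rule |
|---|---|
| rejuvenation | G3vG2 and G2vG1 significant, G3vG1 not |
| centenarian | G2vG1 and G3vG1 significant, G3vG2 not |
| monotone increase | both adjacent steps significant with positive direction, or only G3vG1 significant positive |
| monotone decrease | mirror image |
| stable | nothing significant |
| other | every remaining pattern |

The rules are exhaustive and mutually exclusive (asserted over all
significance × direction combinations).

**Bootstrap confirmation** re-tests flagged differences: per replicate, 10
samples are drawn with replacement from each group and the difference of
subsample means recorded; after 1000 replicates the difference is
confirmed when the central 90% percentile interval excludes zero.  Two
calibration properties matter.  First, the nominal 10% null exclusion rate
presumes the subsample size matches the group size — drawing 10 from a
group of 30 makes the interval much wider than the uncertainty of the
observed group difference, so the procedure turns conservative (near-zero
confirmations under the null).  Second, at n = 10 the percentile interval
is anti-conservative for strongly skewed taxa (~19% null exclusions for a
log-normal with unit log-sd).  Both are properties of the procedure itself;
the calibration tests therefore use groups of 10–11 samples with mildly
dispersed, approximately symmetric abundances, where the nominal rate
holds.

**Stable species**: eligible families are those with sampled members in at
least two age groups; a taxon is present in a family when any member
carries it (relative abundance > 0).  A taxon is stable when present in at
least half of the eligible families and Kruskal–Wallis across the three
groups gives p ≥ .05 (unadjusted by default, as befits an
absence-of-evidence criterion; `adjust=True` switches to BH q).

## Synthetic cohorts

The generator emulates the post-profiling stage of a three-generation
family cohort.  Latent log-abundance of taxon i in sample k:

    y_ik = μ_i + λ_i f_{g(i),k} + β_i(group_k)·δ + γ_{i,fam(k)} + ε_ik

with per-sample guild factors f ~ N(0, τ²) shared by a guild's members
(loadings λ ~ U(0.8, 1.2)), trajectory patterns β over (G3, G2, G1):
monotone up (0, ½, 1), monotone down (1, ½, 0), rejuvenation (0, 1, 0),
centenarian (0, 0, 1), stable (0, 0, 0), scaled by a single effect size δ;
a heritable effect γ ~ N(0, γ_sd²) drawn once per (taxon, family) for taxa
designated stable; and noise ε ~ N(0, σ²).  Compositions are the softmax of
y per sample; counts are multinomial at a log-normal sequencing depth
(optionally Dirichlet-overdispersed); host covariates are a link
coefficient times the mean latent log-abundance of their linked taxa plus
standard-normal noise.  A single seed drives every draw in a fixed order,
so identical (config, seed) reproduce outputs bit for bit, and the returned
truth object records the planted partition, classes, heritable taxa, latent
matrix, drawn depths and the model-implied basis correlation for the
realised design.

Default cohort: 150 taxa, 8 guilds of sizes 5–15 (80 taxa), group sizes
G1/G2/G3 = 32/30/11 (73 samples), 26 families, δ = 1.5, τ = 1, σ = 0.5,
γ_sd = 0.5, depth ~ LogNormal(ln 20000, 0.3).  Of the free taxa, 10 each
carry the four active trajectory classes and 20 are stable-heritable; two
host covariates track the first taxa of guilds 1 and 2 with coefficients
+1 and −1.  Families are filled round-robin so each family has at most one
member per group and every family spans at least two groups; samples
beyond the 26th of a group carry no family id — which reproduces a cohort
of 26 multi-generation families inside a larger sample.

Two generator choices deserve justification.  (1) Trajectory taxa receive a
−2 log-scale baseline offset: one-sided shifts (rejuvenation, centenarian)
on abundant taxa would move a large fraction of total composition and,
through closure, make *every* taxon's relative abundance differ across
groups — taxa planted flat would not be flat observably.  Placing
trajectory taxa in the low-abundance tail (where differential taxa sit in
real communities) keeps the planted truth true while leaving the shifts
trivially detectable.  (2) Host covariates link to guild members because
the shared guild factor gives the linked latent signal a standard deviation
near τ; linked to free taxa, a unit link coefficient against unit covariate
noise leaves the planted association marginal under multiplicity
correction.

What the generator does **not** emulate: sequencing or ASV-inference error,
taxonomy misassignment, between-subject covariates (diet, medication),
zero-inflation beyond multinomial sampling, or phylogenetic correlation.
Passing recovery tests therefore demonstrate correctness of the estimators
under the stated model, not performance guarantees on real cohorts.

## Statistical conventions

* Permutation p-values use the add-one estimator
  p = (1 + #{permuted ≥ observed}) / (1 + B), never zero, reproducible
  given (seed, B).  When every distinct relabelling can be enumerated
  within the budget (and n ≤ 12) the test switches to exact enumeration,
  where the same formula equals the exhaustive proportion.
* ANOSIM: R = (mean between-group rank − mean within-group rank) / (M/2),
  mid-ranks over all M = n(n−1)/2 pairwise distances.
* PERMANOVA: pseudo-F from squared distances,
  SS_total = Σ_{i<j} d²_ij / n, SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g,
  unrestricted label permutation (no strata).  All-equal distances return
  statistic 0, p = 1 rather than 0/0.
* PCoA: Gower double-centring and symmetric eigendecomposition; axes
  ordered by descending eigenvalue, negative eigenvalues reported but their
  axes dropped; requesting more axes than positive eigenvalues returns
  fewer with a truncation flag.
* Spearman: Pearson correlation of mid-ranks; two-sided p by t
  approximation, switching to exact permutation enumeration at n ≤ 9
  (relevant at the smallest group size, n = 11, only for subsets); pairs
  with fewer than 5 complete observations or a constant vector are flagged
  invalid and excluded from the BH family.
* BH step-up q-values are computed over exactly the tested family, capped
  at 1, order-invariant.
* Richness is observed richness (count > 0); "richness estimates" beyond
  that (Chao1 etc.) are out of scope.
* Every stage seed derives from the single run seed by hashing the stage
  name (sha256, reduced below 2³¹), so one integer reproduces a whole run;
  the run manifest records per-file sha256 hashes to make determinism
  checkable.

## Problem sizes used in the validation suite

The automated checks simulate cohorts at the default size (150 taxa, 73
samples) for guild/signature/stable-species recovery (5 seeds each, 999
permutations for tree division), n = 200 samples for SparCC recovery,
1000 replicates for PERMANOVA type-I calibration (n = 20, B = 199), 200
taxa for bootstrap calibration and 20 replicates of a 50-taxon null for
network sparsity — sizes at which each property is statistically decidable
while the whole suite runs in about a minute.

## Known limitations

* The tree-division p-values are nominal, not selection-adjusted (see
  above); guild counts on weakly structured data over-split.
* SparCC assumes sparsity of strong correlations; communities dominated by
  a few large blocks can bias basis variances even after pair exclusion.
* The bootstrap confirmation inherits the percentile interval's small-n
  behaviour (conservative when subsampling below the group size,
  anti-conservative for heavy skew at n ≈ 10).
* The stable-species rule treats non-significance as stability; with few
  samples it will also retain taxa that are merely under-powered.
* Closeness/eigenvector centralities are computed on the thresholded graph
  and are sensitive to the ρ and q cut-offs; they describe the drawn
  network, not the underlying correlation structure.
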