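# Methods

## Model and rationale

The package predicts substrates for orphan SLC transporters from three
observational signals measured across cancer cell-line panels, on the
premise that transport activity couples a transporter's expression level
to the intracellular concentration of its substrate and, with decaying
strength, to the substrate's biochemical derivatives.

**Correlation component.** Expression counts are normalised with
median-of-ratios size factors: genes whose total across samples falls
below 10 are dropped, genes containing any zero count are excluded from
factor estimation (but kept in the output), per-gene geometric means are
accumulated in log space, and each sample's factor is the exponential of
the median log-ratio. Spearman's ρ (average ranks, two-sided p from the
large-sample t approximation) is computed per (transporter, metabolite)
pair over the cell lines shared by the expression and metabolite
matrices, pairwise-complete, with pairs below a minimum overlap of 10
lines omitted. p-values are Benjamini–Hochberg adjusted within each
(transporter, panel) family. Because metabolites differ in how strongly
they correlate with expression in general, |ρ| is standardised per
metabolite across all transporters (the transformed ρ, ρ̃), making
correlation strength comparable between metabolites. The sign of ρ is
retained in the tables but only |ρ| enters ρ̃ — import and export both
produce coupling, with opposite signs.

**Dependency component.** Metabolite levels are z-scored within tissue
(sample SD) to remove tissue-specific abundance. For each transporter,
cell lines with positive gene-effect scores (knockout improves growth)
are excluded; the remaining lines are ranked by effect and the most
dependent and least dependent 20% (floor of 0.2·n, ties broken by line
id) are contrasted per metabolite with a two-sided Wilcoxon rank-sum
test — exact null distribution for tie-free groups of ≤ 10, otherwise
the tie-corrected normal approximation — BH-adjusted across metabolites
within the transporter. Transporters with fewer than 10 eligible lines
are skipped.

**Adjacency.** The reaction network is an undirected graph whose edges
are single conversion steps; pairwise distances are unweighted shortest
paths, with unreachable pairs non-adjacent. Undirectedness is a
deliberate choice: substrate–derivative similarity is symmetric for the
purpose of corroborating a candidate. Currency metabolites that
participate in very many reactions can be excluded via a degree cap
(`max_degree`) or an explicit exclusion list; there is no automatic
inference of "direct biosynthetic conversions", which would require
pathway semantics the edge list does not carry.

## The confidence score

For each source, a value is placed into the decile intervals of the
known-pair value distribution. Eleven knots q₀…q₁₀ are the deciles
(linear interpolation between order statistics, the "type 7" default) of
the known values **at or above the Threshold of Discovery**, with q₀ set
to the ToD itself. Restricting to discoverable known values is what
keeps the knot array monotone for any ToD inside the known distribution
— the default CCL180 ToD of 1.0 sits one SD above the metabolite mean,
well inside the known ρ̃ range. A value below ToD scores 0; q_{j−1} ≤ v
< q_j scores j; v ≥ q₁₀ is capped at 11.

The gene-dependency value is −log₁₀ of the adjusted p, scored against
the known pairs' −log₁₀ p deciles with q₀ = −log₁₀(CRISPR cutoff), and
only when the adjusted p clears the cutoff (default 0.16, a calibrated
operating point treated as configuration, not re-derived). If no known
pair clears the cutoff the decile scale is undefined and the component
contributes 0.

Neighbour correlations within the adjacency radius (default 2 steps)
are scored with a piecewise rule: 0 below ToD′, the decile interval
index above ToD, and one half point in between. With the default NCI60
and CCLE2019 parameters ToD′ (0.1) sits *above* ToD (0.0); the rule is
evaluated in that order, so the half-point band is empty and ToD′ acts
as a hard floor. A neighbour contributes once per panel in which it is
measured; the candidate substrate itself (distance 0) never contributes
to its own adjacency score. The total is the weighted sum
a·(panel sub-scores) + b·GeneDep + c·Adjacency with a = 3, b = c = 1.

## Benchmarking

The permutation null keeps the transporter column of the known-pair
table and reassigns each row a metabolite that transporter is not known
to transport (100 tables by default); no generated row may reproduce a
known pair. Recovery curves report the fraction of scores strictly
greater than each integer cutoff 1–100; the optimisation objective for
a ToD is the mean over cutoffs of (known recovery − mean random
recovery), ties broken toward the smaller candidate. ROC and
precision-recall AUCs are trapezoidal, with thresholds swept over the
pooled score set; per-transporter ranking uses descending confidence
among non-zero scores with average ranks for ties. Pathway
over-representation is a one-sided hypergeometric test per pathway,
restricted to the metabolite universe, BH-adjusted — a standard ORA
chosen because nothing stronger is warranted by the inputs. Train/test
cycles partition the known pairs 70/30 (train size = floor of 0.7·n, so
667 pairs split 466/201), optimise each panel's ToD on the training
pairs only, and report test-pair metrics against random test-sized
tables.

## Drug association

Cell lines are ranked by transporter expression; the top and bottom 20%
(floor, stable tie-break) form the high/low groups. Each group's
viability log-fold values across the 8-dose ladder are smoothed with a
locally weighted quadratic regression (tricube weights over the
span-nearest 75% of observations; span and degree configurable) and
evaluated on the inclusive log₁₀-dose grid −3.21 … 1.00 in steps of
0.01 — 422 points, a named constant asserted in tests. The smoother is
implemented in the package because no installed library provides
degree-2 local regression; observations at repeated doses are
aggregated into per-dose sufficient statistics, so each fit costs a
batch of 3×3 solves rather than a pass over every observation.

The curves are compared with a paired two-sided t-test across grid
points and by Spearman correlation of the pointwise difference with
dose (the dose-dependent effect). Because the smoothed curves are
nearly noise-free, the paired t statistic can be enormous and its
p-value underflows double precision; −log₁₀ p is therefore computed
exactly in log space via the incomplete-beta tail series, which keeps
the statistic finite and discriminative. Drug-specific null thresholds
come from 100 iterations of contrasting two disjoint random 20% groups
(degenerate iterations dropped; more than half degenerate is an error);
a (transporter, drug) pair is *predicted* only when both its −log₁₀ p
and absolute mean curve difference exceed the null mean by two null
SDs. The direction is *sensitising* when high expression lowers
viability (negative high-minus-low mean difference). The shortlist
ranks predicted pairs by the sum of descending ranks of |mean
difference| and |dose ρ|.

## Synthetic data

The generator emulates exactly the structure the method assumes and
nothing else. Counts are Poisson draws around per-gene log-normal
baselines modulated by a latent per-line expression z-score (log-SD
0.8) and a 16-fold library-size range, so median-ratio normalisation is
non-trivial. Three metabolite panels are drawn over partially
overlapping random 80% subsets of 200 cell lines. Each planted
(transporter, substrate) pair mixes the transporter's latent expression
with unit-variance noise (an iid part plus tissue offsets shared within
each of 4 tissues, weight 0.15); the noise is first residualised
against the signal and its admixture scale is then bisected until the
*realized* |Spearman ρ| equals the target (default 0.6), so every
planted pair carries the target correlation as realized, not merely in
expectation. Derivatives along each substrate's two 2-step reaction
chains are calibrated the same way at target·0.6 per step; background
metabolites (50) are pure noise with sparse background chemistry.
Gene-effect scores for planted transporters are negative with magnitude
tracking the latent expression (hence the substrate level); background
transporters get mildly negative noise. The drug panel follows a
logistic kill curve in log dose with Gaussian noise (SD 0.1); planted
(transporter, drug) pairs receive a vertical viability offset of
−δ·σ(8·z) (a near-step sigmoid of the expression z-score), which makes
the planted shift δ identifiable as the high-vs-low mean curve
difference. Defaults plant 12 substrate pairs — the decile construction
needs at least 11 known values — and 2 drug pairs with δ = 1.0.

What passing on this generator does **not** show: robustness to
metabolite–metabolite covariance beyond the planted derivative
structure, cancer-type-specific metabolic rewiring, non-monotone
expression–concentration relationships, or panel-specific measurement
technologies; real-data performance is far below the synthetic AUCs,
because real known-pair signal is much weaker than a planted ρ of 0.6.

## Numerical choices

- Every SD (tissue z-scores, ρ̃ denominator, bootstrap nulls) is the
  sample SD (n−1), kept as a single constant.
- Spearman p-values use the t approximation; exact permutation is
  impractical at panel scale and the approximation is shared by the
  reference implementations.
- Groups of size < 2, zero-spread groups and |ρ̃| groups with fewer than
  3 transporters yield missing values with logged warnings, never
  silent zeros; missing inputs contribute 0 to the confidence score.
- "Better than cutoff" is strictly greater, as a switchable constant.
- Tie-breaks in ranking and grouping are stable sorts on the id, so all
  outputs are deterministic under a seed; the CLI derives per-stage
  substreams from one root seed.
- The dose grid is inclusive of both endpoints (422 points); group
  sizes are always floor(frac·n) of the lines actually treated.

## Known limitations

Correlation cannot distinguish transport from co-regulation; the score
has no probabilistic calibration (it is a rank-integration device);
weights a, b, c are fixed rather than learned; the adjacency component
double-counts chemically clustered neighbourhoods; and the drug module's
paired t-test across smoothed grid points inherits pseudo-replication
from the dense grid — its p-values are meaningful only relative to the
drug-specific resampled null, which is exactly how the prediction rule
uses them.
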