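# Methods

This note documents the models, numerical choices, and limitations behind
`microslope`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design assumed throughout

Samples are rhizosphere communities from an ordered slope gradient: three
positions (top, middle, bottom) × replicate plots (6 each by default,
18 samples). Three kingdoms are co-measured per sample — bacteria (16S),
rhizobia (rpoB), AM fungi (18S) — each with its own marker gene, hence its
own per-sample sequencing depth and its own within-kingdom relative
abundances. Position is treated as an ordinal score (top = 1, middle = 2,
bottom = 3) because slope is an ordered environmental gradient.

## Multifunctionality

Functions are z-scored per column with the sample (n−1) standard deviation.
A constant function column raises an error naming the function rather than
being dropped: the 12-function panel is a fixed design and silent dropping
would bias the averaging index. The averaging index is the row mean of
z-scores (grand mean 0 by construction). Multidimensional functioning is
the PCA of the z-scored matrix — correlation- and covariance-PCA coincide
on z-scored columns, which resolves the ambiguity of which the original
analyses used. Axis orientation is fixed by making the largest-magnitude
loading of each axis positive; PCA orientation is otherwise arbitrary, and
any statement about the "direction" of an axis depends on it.

## Network inference

1. **Filtering.** Keep taxa occurring in strictly more than 25% of samples
   with mean relative abundance strictly above 10⁻⁵, computed within the
   taxon's own kingdom. Filtering precedes merging for cross-kingdom
   networks, so a kingdom's node set is identical in single- and
   cross-kingdom networks.
2. **CLR.** Pseudocount 1 for count tables, half the smallest positive
   value for non-integer absolute abundances (deterministic and
   scale-aware); close to proportions, log, center per sample. CLR is
   invariant to per-sample rescaling up to the pseudocount, which is the
   compositional robustness the method is chosen for.
3. **Neighborhood selection.** Each taxon's CLR profile is lasso-regressed
   on all others (sklearn's 1/(2n) objective scaling; `lambda_max` is the
   largest absolute off-diagonal of the empirical covariance, above which
   the model is empty). Edges are symmetrized with the OR rule (either
   direction selects; AND available via `rule="and"`). Edge sign and weight
   come from the mean of the two directed coefficients; an exact-zero mean
   drops the edge rather than assigning an arbitrary sign.
4. **StARS.** 50 subsamples (without replacement, 80% of samples) along a
   30-point log-spaced path from lambda_max to 0.01·lambda_max. Per-edge
   instability 2θ(1−θ) is averaged over pairs, monotonized along the path,
   and the smallest penalty with instability ≤ 0.05 is selected; if none
   qualifies the largest penalty is used and a warning is recorded in the
   provenance. The selected penalty, path, instabilities, and seed are all
   stored on the network object.

Small-p caveat: with very few taxa (≲ 8) a single flickering edge near
lambda_max can dominate the average instability and truncate the selection;
the chain-graph support checks therefore pin the penalty directly.

## Topology

Average path length and diameter are computed unweighted over connected
pairs only (0 when no pair is connected). Modules come from greedy
modularity maximization (deterministic for a given graph; the seed argument
is recorded for provenance uniformity). Zi–Pi: Z is the within-module
degree z-score with Z = 0 when a module's within-degrees are constant
(avoids ±∞); P = 1 − Σ (κ_im/k_i)², with P = 0 for isolated nodes; roles
use strict thresholds (2.5, 0.62), so boundary equality falls to
peripheral/connector. Hub centrality: on an undirected graph Kleinberg's
hub score equals the principal adjacency eigenvector; it is computed per
connected component, each component's scores scaled by its spectral radius
(denser components dominate, matching the global-eigenvector limit), then
globally max-normalized to 1 so the keystone threshold 0.7 is meaningful.

PPA/PNA association scores: for each sample, the sum over in-scope positive
(negative) edges of the product of the two endpoints' within-sample
relative abundances; absent endpoints contribute zero; the scores are
invariant to rescaling a sample's absolute abundances. The exact formula
inside published association-quantification tools is not documented; the
product rule is the most direct reading of "multiplying matrices of
abundances and connectedness", and an abundance × signed-degree variant is
exposed via `mode="degree"`.

## Assembly null models

βMNTD is the abundance-weighted symmetric mean of nearest-taxon patristic
distances. βNTI shuffles taxon labels across all tree tips (the standard
whole-tree randomization), 1000 rounds by default; βNTI is invariant to
global branch-length rescaling because the z-score cancels scale. Pairs
with zero null standard deviation (e.g. two identical communities) are
undefined and reported as missing with a warning — never silently zero —
and are excluded from process fractions with an excluded-pair count.

RC_Bray nulls preserve each sample's richness and total abundance: taxa are
drawn without replacement with probability proportional to occupancy, then
individuals assigned multinomially with probabilities proportional to
regional relative abundances. RC = 2·(fraction of null Bray–Curtis below
observed + half the ties) − 1, bounded in [−1, 1]; ties get half weight to
keep the bound symmetric.

Classification uses strict inequalities (|βNTI| > 2 deterministic;
RC > 0.95 / RC < −0.95 within the stochastic branch), resolving boundary
equality toward drift/stochasticity. The signed RC rules are the standard
QPEN convention; published prose sometimes conflates the signed thresholds
into |RC|, which cannot distinguish dispersal limitation from homogenizing
dispersal and is not followed here.

## Permutation statistics

All permutation p-values are (1 + #{perm ≥ obs})/(1 + n_perm), never 0;
permutations are over the whole sample set (plot-level strata are out of
scope). Mantel correlates lower triangles (Spearman default, matching the
convention of reporting rank correlations for driver screens) with
simultaneous row/column permutation of one matrix; rank transformation
commutes with that permutation, so triangles are ranked once. PERMANOVA
uses the distance-based sum-of-squares partition; R² = SS_between/SS_total
is reported alongside pseudo-F. Constrained PCoA embeds the distance matrix
(Lingoes correction when negative eigenvalues appear — Bray–Curtis is
generally non-Euclidean — recorded in the output), then projects on group
indicators; the constrained variance fraction and constrained axis scores
come from the fitted values' SVD. Variation partitioning uses the same
embedding with adjusted R² (Ezekiel correction); fractions can be slightly
negative and are reported unclipped.

## Synthetic generator: what it emulates, and what it does not

The generative model is a parameterized stand-in — the real data's
generative process is unknown — with these components:

* **Association structure.** A sparse symmetric precision matrix over all
  taxa of all kingdoms (cross-kingdom edges allowed), parameterized
  directly by partial-correlation magnitude (|pc| ~ U(0.35, 0.5), unit
  diagonal, sign positive with probability `positive_fraction` = 0.7,
  matching the positive-edge dominance typical of such networks). If the
  smallest eigenvalue falls below 0.1, all partial correlations are shrunk
  by a common factor, preserving support and signs. The signed truth
  network is read off the precision matrix (edge iff nonzero; sign of
  −Ω_ij/√(Ω_ii·Ω_jj)).
* **Habitat preference (selection scenario).** A deep-clade contrast (±1 by
  the root split of each kingdom tree) plus 0.3 × standardized Brownian
  motion, normalized to unit variance. Pure Brownian traits on Yule trees
  produce erratic clade structure; conserving preference at the deepest
  split mirrors the field observation that habitat filtering acts at deep
  phylogenetic levels, and gives βNTI its intended power. The preference
  multiplies the centered position score with strength 3 (log scale).
* **Neutral scenario.** Instead of preferences, per-taxon spatially
  autocorrelated plot effects with exponential distance decay along the
  slope coordinate (scale 1 position-unit, sd 1) — distance decay without
  phylogenetic structure.
* **Counts.** Latent log-abundances = per-taxon baseline (sd 1) + scenario
  term + 1.5 × MVN(0, Ω⁻¹) noise; abundances are Poisson draws on
  exp(latent) closed to a per-sample, per-kingdom depth (default 1000
  expected counts, log-normal ±20% across samples). Depth and baseline
  were chosen so per-sample occupancy resembles filtered ASV tables
  (roughly 40–80% presence among dominant taxa); identical-taxon overlap
  otherwise makes nearest-taxon null models structurally uninformative.
* **Functions.** Each of the 12 functions = coefficient-weighted sum of
  standardized AM-fungal richness, PPA, and PNA of the truth network (PNA
  entering negatively) + Gaussian noise (sd 0.5). Default coefficients
  (1.0, 0.5, 0.5) make AM-fungal diversity the dominant driver.

Not emulated: read-level error, chimeras, taxonomy, variable taxon loads
between kingdoms, plot microheterogeneity, temporal dynamics, and any
specific field values. A green test on synthetic data establishes that the
estimators recover planted structure under this model — not that the model
is a faithful description of any particular soil.

Default sizes for tests (60 bacterial, 25 rhizobial, 20 AM-fungal taxa)
keep module structure visible at minutes-scale runtimes; the recoverability
checks scale samples up to n = 200 instead of scaling taxa.

## Known limitations

* Neighborhood selection at small p (≤ 8 taxa) can truncate StARS at the
  sparse end of the path (see above).
* RC_Bray rounds non-integer absolute abundances to individual counts for
  the multinomial fill.
* Greedy modularity is one local optimizer; module boundaries (hence Zi–Pi
  roles) can differ from other algorithms' output.
* Average path lengths are unweighted; weighted-distance conventions that
  produce sub-1 averages are intentionally not reproduced.
* The constrained PCoA conditions only on the grouping indicators; no
  covariate conditioning.
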