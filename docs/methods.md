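# Methods

## Cohort life tables

A cohort census records, at uniform ages x = 0, Δ, 2Δ, … (Δ = 8 h by
default), the survivors n_x and the offspring born in the interval
starting at x.  Replicates are pooled by summing counts before the life
table is built — the package's primary path, matching how small culture
cohorts (10 individuals × 3 replicates) are usually analysed — while
per-replicate tables remain available for mean ± SE summaries of the
scalar parameters; both paths share the same code.

Conventions, chosen where the classical verbal definitions leave room:

- **Birth timing.** Births are interval counts; the age x entering R₀, T
  and the Euler–Lotka sum is the census age at the *start* of the
  interval in which the births were recorded.  No within-interval timing
  is imputed.
- **L_x.** Individual-time lived in an interval uses the trapezoidal
  convention L_x = Δ·(n_x + n_{x+1})/2, with n past the final census
  equal to zero.  T_x = Σ_{y≥x} L_y and e_x = T_x/n_x follow.  Under
  this convention a cohort fully alive at 0, 8 and 16 h and dead at 24 h
  has e₀ = 20 h exactly.
- **m_x.** Fecundity is births in the interval divided by n_x, set to 0
  where n_x = 0.

**Euler–Lotka solver.** r_m is the root of f(r) = Σ e^(−rx) l_x m_x − 1,
which is strictly decreasing in r whenever any reproduction occurs at
x > 0.  The solver starts from r-rough = ln R₀/T with a bracket of
±0.5 h⁻¹, expands the bracket geometrically until f changes sign and
finishes with Brent's method at machine precision; the returned residual
is checked against a 1e−10 tolerance.  Degenerate schedules (R₀ = 0, or
all reproduction at age 0) raise typed errors rather than returning
numbers.

**Population growth.** r = (ln N_{t₁} − ln N_{t₀})/(t₁ − t₀) per day
over a window (default days 2–6), computed per replicate and summarised
as mean ± SE; D_max is the per-replicate maximum with its day.  Units:
cohort ages and e₀/T/r_m in hours and h⁻¹ (consistent with generation
times of ~50–60 h and intrinsic rates of ~0.05–0.06 h⁻¹ in rotifer
cultures), density growth in d⁻¹.

## Group statistics

`anova_from_summary` rebuilds the one-way table from published group
summaries: ss_between = Σ nᵢ(ȳᵢ − ȳ)², ss_within = Σ (nᵢ−1)sᵢ² with
sᵢ² = nᵢ·SEᵢ² in SE mode (SD mode available, since published "±" values
are not always what the caption says).  With raw data the two routes
agree to 1e−10.

Post-hoc letters: SNK steps down the studentized-range ladder at fixed
α; Duncan uses the protected levels 1−(1−α)^(p−1); Games–Howell uses
Welch degrees of freedom and per-pair variances (no pooled MS), for
heteroscedastic groups.  The compact letter display is produced by the
insert-and-absorb algorithm, so letter sharing is transitive-consistent
with the pairwise decisions.  α = 0.05 throughout.  Logarithmic
pre-adjustment of non-normal data is an explicit caller decision, never
applied silently.

Levene's test defaults to the median-centred (Brown–Forsythe) statistic,
which is robust but conservative at n ≈ 10; the classic mean-centred
form is available via `center="mean"` and is the better-calibrated
choice for small normal samples.  Kruskal–Wallis enumerates the exact
permutation distribution of the tie-corrected H when the total sample
size is ≤ 10 and otherwise uses the χ² approximation.

## OTU pipeline

Cleaning order is fixed and logged: chloroplast removal (any lineage
containing a case-insensitive "chloroplast" token at any rank; token
list configurable) → singleton removal (total count of 1 across all
samples) → rarefaction.  Rarefaction is a multivariate hypergeometric
draw per sample (subsampling without replacement), to the minimum sample
total by default; an explicit depth drops shallower samples with a
warning.  Every filter is idempotent.

The >1% relative-abundance filter is strictly greater-than and judged
per sample ("any-sample") by default; mean mode and non-strict
comparison are flags, since printed OTU accountings rarely state which
convention produced them.  Venn presence is a nonzero total within a
group after normalization.  Taxonomy aggregation preserves unresolved
ranks as "unclassified <nearest classified parent>" so per-sample totals
are conserved and labels like "unclassified Alphaproteobacteria" survive
as their own taxa.

## Diversity

Shannon entropy uses natural log (the common mothur/QIIME default);
Chao1 uses the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)) to avoid
division by zero when no doubletons exist; Good's coverage is 1 − F₁/N;
Faith's PD is root-inclusive (branch lengths of the minimal subtree
connecting the observed tips to the root).  These four are delegated to
scikit-bio behind the module surface and validated against closed forms
and a union-of-root-paths oracle.

NMDS minimises Kruskal stress-1 by SMACOF majorization with isotonic
regression on dissimilarity ranks (scikit-learn's non-metric SMACOF),
best of `n_starts` seeded initialisations; stress above 0.2 is flagged
as a poor embedding but still returned.  ANOSIM is implemented
in-package: R = (r̄_between − r̄_within)/(M/2) on the ranked
dissimilarities with an add-one permutation p, vectorised and explicitly
seeded so large null calibrations are cheap and reproducible; it is
cross-checked against scikit-bio's implementation in the test suite.
Under label permutation the add-one p is exactly valid, and the suite
verifies rejection at α = 0.05 stays ≤ 0.06 over 2,000 null data sets.

## Co-occurrence networks

Spearman correlations (average-rank ties, t-approximation p with n−2 df)
are computed over the top-50 order-level taxa by mean relative
abundance.  Edges require |ρ| > 0.5 and p < 0.05 by default; absolute
thresholding is the default because negative co-exclusion edges are part
of these networks, with the literal ρ > 0.5 reading behind a flag.  No
multiple-testing correction is applied by default (Benjamini–Hochberg
available), matching common practice in this literature.  Zero-variance
taxa have undefined correlations and never form edges.

Node metrics are the normalized forms: degree/(n−1); closeness with
reachable-set scaling (thresholded graphs are routinely disconnected);
betweenness normalized by (n−1)(n−2)/2; local clustering as the closed
triple fraction.  Graph summaries report 2E/n, mean clustering, and
diameter / mean shortest path over the largest component.  All of these
are validated against exhaustive path-enumeration oracles on hundreds of
random graphs with n ≤ 12.

Keystone taxa use the combined top-k rule: thresholds at the k-th order
statistic of degree (≥), closeness (≥) and betweenness (≤); a node must
pass all three, and isolated nodes are excluded as part of the rule (so
the stored thresholds re-applied to the node table reproduce the
selection exactly).  The three criteria are intersected rather than
merged into one score — the reading that makes the published
per-criterion thresholds (e.g. degree above ~0.2 with betweenness below
~0.02) reproducible as order statistics.  Note the deliberate tension: a
pure star hub maximises degree and closeness but carries all
betweenness, so it fails the rule; keystones here are members of tight
co-varying cores, not bridges.

## Synthetic data

The generators emulate the study design the analysis assumes, not any
particular data set:

- **Cohorts.** Ten neonates × 3 replicates censused every 8 h.  Survival
  is a Bernoulli chain over an age-indexed hazard (zero for the first
  64 h, rising to certain death by 144 h); offspring are Poisson per
  surviving mother (first reproduction after 24 h, mid-life peak near
  2.4 per interval, senescent decline), with a zero-variance switch for
  exact tests; each offspring is mictic with probability 0.03.  The
  default schedules imply e₀ ≈ 88 h, R₀ ≈ 14, T ≈ 53 h, r_m ≈ 0.059 h⁻¹
  — the magnitude range reported for *B. calyciflorus* cultures.
- **Densities.** Logistic mean path (K = 250 ind/mL, N₀ = 2 ind/mL in
  the pipeline defaults) with multiplicative lognormal noise of unit
  mean, because densities are positive and counting error scales with
  abundance.
- **OTU tables.** 3 media groups × 4 growth stages × 4 replicates.
  Latent log-abundances are log-normal around a heavy-tailed base
  composition; a designated block is correlated through a Gaussian
  copula (Cholesky factor of the target correlation), which survives the
  multinomial observation layer as rank correlation; design effects add
  log shifts per group/stage block; a per-sample community-state
  gradient with order-coherent loadings makes whole orders co-vary so
  the order-level network has planted structure; 10% of OTUs carry a
  chloroplast lineage; rare group-exclusive blocks (5 SE-only, 10
  SEB-only, 15 NW-only) give the Venn partition the qualitative
  sterile < bacterioplankton < natural-water ordering of specific taxa.
  Counts are multinomial at a depth uniform on 5,000–10,000.
- **Trees.** Random bifurcating topologies from repeated pairwise joins
  with exponential branch lengths; the root carries no edge.

What the generator does *not* emulate: sequencing error and chimeras,
compositional zero-inflation beyond multinomial sampling, phylogenetic
signal in the composition (the tree is independent of abundances), and
any real taxon–taxon ecology.  Passing tests therefore demonstrate that
the estimators recover planted structure under the stated stochastic
model at study-like sizes — not that any particular biological claim
reproduces on real data.

## Problem sizes and numerical choices

The test suite runs at desk scale: parameter recovery uses cohorts of
n = 500 over 100 seeds (median relative error of R₀ and r_m is well
under 5%); network oracles cover 200 random graphs with n ≤ 12; the
ANOSIM null calibration uses 2,000 data sets of 12 samples with 99
permutations each (the add-one p is exact at any permutation count);
pipeline demonstrations use 48 samples × 150 OTUs.  Euler–Lotka roots
are bracketed and polished to ~1e−12 residual; ANOVA edge cases (zero
within-variance) return F = +∞ with p = 0 rather than failing; ties in
top-k selections break lexicographically so outputs are deterministic.

Known limitations: per-replicate life tables from 10 individuals are
noisy, and their SE understates schedule uncertainty; the summary-ANOVA
reconstruction inherits the rounding of published means; NMDS stress on
48 noisy samples typically lands near 0.15–0.2, at the edge of
conventional interpretability; exact Kruskal–Wallis is factorial in N
and therefore capped at N ≤ 10.
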