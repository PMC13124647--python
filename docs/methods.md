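# Methods

This note documents the models and procedures implemented in `limnotraj`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions that affect results.

## Data model and preprocessing

The central object is a samples × ASVs integer count matrix with unique
identifiers, non-negative integer cells and strictly positive row sums.
Sample metadata records lake, date (ISO-8601), water-column replicate
(W1–W3), a campaign-wide `month_index` and the meteorological season.
Chlorophyll-a is stored per (lake, month, replicate) in µg·L⁻¹.

**Lineage filtering.** ASVs whose 8-rank lineage contains any excluded
keyword are dropped before analysis. Matching is a case-insensitive
substring test at any rank, because the non-target groups (Metazoa,
Streptophyta, plastid and nucleomorph sequences, Bacteria, unassigned
reads) appear at different ranks depending on the classifier. ASVs without
taxonomy are treated as unassigned. A sample left with zero reads after
filtering is dropped with a logged warning rather than invalidating the
table.

**Rarefaction** subsamples each sample to a common depth *without*
replacement (a multivariate hypergeometric draw), preserving count support;
samples below the target depth are dropped and reported, mirroring standard
practice of removing under-sequenced libraries rather than padding them. A
single seeded draw is used; the seed makes the output bit-reproducible.

## Trophic classification

Carlson chlorophyll-a states use thresholds 2.6, 7.3 and 56 µg·L⁻¹ with
lower bounds inclusive, so the four bins form a partition:
oligotrophic < 2.6 ≤ mesotrophic < 7.3 ≤ eutrophic ≤ 56 < hypereutrophic.

A lake's campaign category is decided from its monthly replicate-mean
series, in order: (1) *eutrophic-to-hypereutrophic* if at least 4 monthly
states are hypereutrophic; (2) *oligotrophic-to-mesotrophic* if at least
half of the monthly states are oligo- or mesotrophic **and** the campaign
mean is below 7.3 µg·L⁻¹; (3) *mesotrophic-to-eutrophic* otherwise. Rule 1
encodes the published hypereutrophy criterion; rule 2 operationalises the
"stable low chlorophyll" notion so that lakes with campaign means of
3–5 µg·L⁻¹ land in the low category while fluctuating mid-gradient lakes do
not. Rule 2's mean condition deliberately dominates ties in the 50% test.

Trophic modes (phototroph, mixotroph, phagotroph, parasite) are assigned by
looking up the rank-4 (class) label in a user-editable two-column map; the
shipped `trophic_modes_example.tsv` is an illustrative curation covering
common freshwater classes, not an authoritative database. Class-level
assignment ignores within-class variability — the trade-off is coverage,
since class is the lowest rank reliably assigned for most ASVs.

## Community statistics

Shannon diversity uses the natural logarithm. Bray–Curtis is computed on
rarefied counts. PCoA double-centres −½D² (Gower), keeps axes with positive
eigenvalues (no Lingoes/Cailliez correction) and reports variance fractions
relative to the sum of positive eigenvalues; coordinates are eigenvectors
scaled by √λ. Eigenvalues below 10⁻⁹ × λ_max are treated as zero.

PERMANOVA partitions the distance-based sum of squares sequentially
(Type-I) over the terms in the order given (`lake`, `season`,
`lake:season` by default): SS of term *k* is tr((H_k − H_{k−1}) G) with G
the Gower-centred matrix and H_k the hat matrix of the design up to term
*k* (hat matrices via orthonormal bases, so redundant dummy coding is
harmless). P-values come from free permutation of rows,
p = (1 + #{F* ≥ F}) / (n_perm + 1), default 999 permutations. Sequential
partitioning was chosen because the design is balanced (term order then
barely matters) and it keeps R² additive: term R²s plus the residual sum to
1. An explicit permutation array can be supplied, enabling exact
enumeration at small n; the suite verifies that route against a brute-force
within/between-group decomposition at n = 6, and one-way results against
scikit-bio's PERMANOVA.

Spearman's ρ is the Pearson correlation of mid-ranks. For n ≤ 8 the
two-sided p-value is an exact enumeration over all rank permutations; above
that the t approximation with n − 2 degrees of freedom is used. Exact
enumeration at n = 9–10 would cost 0.4–3.6 M permutations per call for
little inferential gain, so the cutoff is 8 (configurable).

Environmental PCA z-scores columns (SD with n − 1), decomposes by SVD and
reports each variable's cos² — its squared correlation with each component
score — which sums to 1 across components per variable.

## Trajectory analysis (MOTA)

All lakes are embedded in **one** shared PCoA; per-lake trajectories are
comparable only because the space is common. The number of retained axes is
the smallest k whose cumulative variance fraction strictly exceeds 0.90 (if
the threshold is unreachable, all axes are used with a warning). Monthly
centroids average whatever replicates survived QC. Total length is the sum
of Euclidean distances between consecutive *available* monthly centroids —
a missing month contributes a single bridging segment — and lengths are
also reported normalised to the shortest lake (minimum exactly 1). A
`start_month` option drops early months so all lakes share a first time
point. Trajectory length is invariant under rotation/translation of the
ordination and unchanged by collinear intermediate centroids; both are
tested.

## Time-lag analysis (TLA)

For one lake, every unordered pair of sampling dates yields a point: lag in
days, and the mean of all replicate-to-replicate Bray–Curtis values between
the two dates (up to 3 × 3). The replicate-mean was chosen over
centroid-level distances for determinism and robustness to dropped
replicates. A per-day rate column (dissimilarity / lag) is also emitted,
but regressions run on raw dissimilarity versus lag, which is the
interpretable dose-response scale.

Ordinary least squares polynomials of degree 1–5 are compared by the
Gaussian AIC counting the variance parameter,
AIC = n ln(2π·RSS/n) + n + 2(p + 1) with p = degree + 1 coefficients, fixed
explicitly so model ranking is well defined; an exact fit (RSS = 0) is
assigned AIC = −∞. Degrees requiring more distinct lags than available are
skipped with a warning. The divergence verdict uses the degree-1 slope with
its two-sided t-test at α = 0.05: *diverging* if significantly positive,
*converging* if significantly negative, *stationary* otherwise. A purely
seasonal community yields a |sin|-shaped lag profile whose linear component
is intrinsically small relative to its own residual (|t| ≲ 0.65 even
noise-free over an 18-month window), which is why seasonal-but-stable lakes
are reliably called stationary.

## SparCC networks

Core ASVs of a lake reach relative abundance ≥ 1% (inclusive) in at least
one of its samples. SparCC is implemented from the log-ratio variance
formulation: per Dirichlet resample (counts + 1 posterior, 20 resamples),
t_ij = var(ln xᵢ/xⱼ) is formed from the log-fraction covariance, basis
variances solve the linear system implied by the sparsity assumption
(system matrix (m−2)I + 𝟙), correlations are
ρᵢⱼ = (ωᵢ² + ωⱼ² − tᵢⱼ) / (2ωᵢωⱼ) clipped to [−1, 1], and the single
strongest pair above 0.1 is excluded from the system and re-solved, up to
10 rounds (the algorithm's published defaults). If exclusions make the
system singular, the unexcluded solution is used with a warning. The final
matrix is the resample mean; everything is seeded.

Networks keep edges at |ρ| ≥ 0.6 (inclusive — "minimum correlation" read
as the smallest admissible value). All core ASVs are nodes, so component
counts include singletons; modules are components with ≥ 2 nodes. The
clustering coefficient is the global transitivity of the unweighted graph;
modularity is greedy modularity maximisation on absolute edge weights
(community-detection clusters are used *only* for the modularity score —
trophic statistics use modules-as-components, the quoted definition).
Per-mode percentages are over connected (degree ≥ 1) nodes; module trophic
richness counts distinct modes ignoring unassigned nodes. Category
aggregation reports the arithmetic mean and the sample SD (n − 1) per
category and overall; the n − 1 convention is verified against the
published nine-lake summary rows (e.g. SD 5.86 from counts 128/126/137).
Because the published per-lake cells are themselves rounded, recomputed
summary cells are asserted to one unit in the last printed digit.

## Synthetic generator

The generator emulates the survey design: 9 lakes × 18 monthly time points
× 3 water columns, chlorophyll-a in triplicate, one trophic level
τ ∈ [0, 1] per lake. Latent log-abundance of ASV i in lake l at month t:

    η = baseline_i(l) + α_i cos(2π(m_t − φ_i)/12) + W_it(l)

* `baseline` ~ N(0, γ(τ)) with γ(τ) = 1 + 2τ, plus a lake effect
  ~ N(0, 1): higher trophic level means a more uneven community.
* Seasonality: per-ASV amplitude α_i ~ U(0, 1.2) and random phase, so there
  is no artificial global synchrony; period fixed at 12 months.
* Drift: W_i(l) is a per-ASV mean-reverting random walk (AR(1), reversion
  1/24 per month) with lake-specific step SD σ_drift = 1.6τ. Two design
  points matter here. A *scalar* walk shared across ASVs cancels exactly in
  the softmax; and a *pure* (non-reverting) walk grows its cross-ASV spread
  as σ√t, occasionally collapsing a high-drift lake into a near-monoculture
  whose compressed Bray–Curtis scale shortens the trajectory — the opposite
  of the intended signal. Mean-reverting per-ASV walks keep "regime drift"
  bounded while still diverging over an 18-month campaign. The step SD is
  the recoverable ground truth for MOTA and TLA.
* Counts are Dirichlet-multinomial per replicate,
  Multinomial(depth, Dirichlet(θ·softmax(η))) with θ = 200 and depth
  12 287 (the rarefaction depth), carrying realistic water-column
  overdispersion.
* Chlorophyll-a is lognormal around ln median = ln 1.2 + 4.8τ plus a
  summer boost (e^cos-shaped, peaking in July), noise SD 0.3 on the log.
  These constants place τ ≈ 0.1 lakes at ~2–5 µg·L⁻¹ (oligo/meso),
  τ ≈ 0.4–0.5 at 10–25 µg·L⁻¹ (meso/eu), and give τ ≥ 0.75 lakes ≥ 4
  hypereutrophic months, so the default τ gradient (0.08…0.90) reproduces
  the 3 / 4 / 2 category grouping deterministically
  (`expected_ground_truth` computes it from noise-free medians).

A second fixture, `generate_correlated_counts`, plants basis (log-scale)
correlations between chosen taxon pairs in an otherwise independent
log-normal community, closes to fractions and samples a multinomial — the
canonical SparCC validation construction. Recovery of a planted 0.8
correlation is attenuated when a planted taxon sits at very low mean
abundance (zero counts flatten its log-fraction variance), so the recovery
experiments use a modest mean-log spread (0.5) and depth 10 000.

**What the generator does not emulate.** No mechanistic ecology
(predator–prey, nutrient budgets), no phylogenetic or taxonomic structure
(synthetic ASVs carry no lineages), no missing months (the real campaign
skipped December of the first year; gap-bridging is tested separately), and
no richness hump or core-ASV trend along the gradient — in fact stronger
dominance at high τ *reduces* the number of ≥ 1% core ASVs, opposite to the
published field pattern. Passing recovery tests therefore demonstrates that
the estimators invert the generative structure they target (drift,
seasonality, planted correlations, chlorophyll gradient), not that field
data behave like the generator.

## Problem sizes and expected recovery rates

The test and acceptance experiments use scaled designs chosen to isolate
each signal: PERMANOVA calibration at n = 20 (4 groups × 5, 500 null
replicates × 999 permutations, rejection rate in [0.03, 0.07]); SparCC at
50 taxa × 100 samples (planted 0.8 recovered within ±0.15 in ≥ 90% of 20
runs; < 1% spurious |ρ| ≥ 0.6 edges under the null); a drift-isolated MOTA
dose-response (5 step-SD levels 0–1.6 × 10 replicates, no seasonality,
pooled Spearman > 0.9 with strictly increasing level means); and TLA over
100 seeded single-lake campaigns per condition (≥ 90% correct stationary /
diverging verdicts; polynomial beats linear by AIC on strongly seasonal
data in ≥ 90%). On the full default gradient, the Spearman correlation
between trajectory length and mean chlorophyll-a averages ≈ 0.87 across
campaign realizations; individual 9-lake campaigns fall below 0.8 in
roughly a fifth of runs because the mid-gradient lakes' drift levels are
closely spaced relative to single-realization noise — the suite asserts
the mean, and the acceptance script reports both the mean and the
exceedance rate.

## Known limitations

* PERMANOVA assumes exchangeable samples under permutation; repeated
  measures within lakes are not modelled (no restricted permutation
  schemes).
* TLA inference ignores the non-independence of pairs sharing a date; the
  verdict should be read as descriptive, as in the field literature.
* SparCC's sparsity assumption biases estimates when many taxa are strongly
  inter-correlated; the exclusion heuristic mitigates but does not remove
  this.
* Published per-lake network metrics depend on a wrapper whose exact
  clustering/modularity definitions are not documented; only the
  aggregation arithmetic over those published cells is reproduced
  bit-for-bit (to printed precision), not the per-lake values themselves.
* The published overall mean/SD for module trophic richness (2.29/2.45) is
  inconsistent with its own nine per-lake values (recomputation gives
  2.02/0.36) and is excluded from the reproduction checks.
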