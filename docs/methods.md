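# Methods

This note records the models, conventions, and design choices behind
`funcdyn`, in the order the pipeline runs.

## Trait space

**Inputs.** A species × trait table with four compositional categories
(habitat use, stratum, diet, temporal activity) — each row a proportion
vector summing to 1 within 1e−6 (rows off by up to 1e−3 are renormalized;
worse is an error naming the species and category) — plus mean individual
biomass in grams.

**Biomass standardization.** log₁₀(mass) divided by the *sample* standard
deviation (ddof = 1) of log₁₀(mass); the log damps the influence of the few
large-bodied species, the scaling makes the univariate trait commensurate
with the multivariate blocks. Identical masses across all species are an
error (zero SD).

**Per-category reduction.** Each category yields a Euclidean distance
matrix over its proportion rows, reduced by classical PCoA (eigendecomposition
of the double-centered −½D² matrix). Axes are retained in descending
eigenvalue order until their cumulative share of **positive**-eigenvalue
variance reaches the retention threshold (default 0.75); negative
eigenvalues are excluded from the denominator. The attained share s_k is
recorded and becomes the block's inverse weight. Eigenvalue ties resolve to
the earlier axis index (deterministic `eigh` ordering by descending value).

**Weighted Gower combination.** g_ij = Σ_k W_k·D_ijk / Σ_k W_k with
W = 1 for biomass (D = absolute difference of standardized values, i.e.
1-D Euclidean) and W_k = 1/s_k for each reduced block (D = Euclidean in the
retained axes). By default every D_k is divided by its maximum before
weighting, so each trait's contribution lies in [0, 1] and g_ij ≤ 1; the
dissimilarities of different categories are otherwise on arbitrary,
incomparable scales, and a bounded G also gives the conventional "g_ij
below ~0.2 means redundant" reading a fixed meaning. The flag
`normalize=False` disables this for sensitivity analysis.

**Dendrogram.** Agglomerative clustering of G, average linkage (UPGMA) by
default — the usual choice for summarising a dissimilarity matrix when no
linkage is dictated — configurable to any scipy linkage method. Newick
export carries branch lengths derived from merge heights.

## Functional dispersion

FDis of an assemblage is the weighted mean distance of its species to
their weighted centroid. Because G is generally non-Euclidean, species are
first embedded by PCoA of G; if the double-centered matrix has negative
eigenvalues beyond 1e−10 (relative), the square-root correction is applied
(distances replaced by their square roots) before embedding — the default
correction of the standard distance-based FD routine — and any residual
negative axes are dropped. One embedding of the full pool serves all
assemblages; an assemblage is scored by zeroing the weights of absent
species. One consequence worth noting: under the correction, embedding
distances are √g ≥ g (for g ≤ 1), so FDis values are bounded by the
maximum *corrected* pairwise distance, not by max g_ij itself.

Weightings: FDo uses 1 for each present species; FDn the capture counts;
FDw counts × pool-level mean individual mass. Per-capture masses are not in
the data model, so FDw is an approximation of the relative captured
biomass that is exact when within-species mass variation is unstructured.
Assemblages with one species score 0 on all indices; empty records are
missing (NaN), not zero — no assemblage exists.

## Random-extinction null model

The pool is the full multi-species set over the whole study period, built
once, not per habitat or season (the per-habitat option exists but the
regional pool is the default). Each of n_traj (default 1000) trajectories
draws a uniform random removal order; the nested subsets of sizes
pool−1 … 1 are scored by occurrence-based FDis. Uniform removal makes
every r-subset equally likely at level r, so the per-level distribution
converges on exhaustive subset enumeration — the property the tests check
directly for small pools. Subset scores are memoised, so the default run
costs far fewer FDis evaluations than trajectories × levels.

Deviations are **raw differences** from the null mean at the observed
richness (the analysis plots differences, not standardized effect sizes).
The same occurrence-based null mean is subtracted from FDo, FDn and FDw:
it is the expectation for the latter two only at maximal evenness, so
their deviations deliberately fold in an evenness component. S = 1 records
get deviation 0 (both terms are exactly 0); S = 0 or S above the pool size
are missing.

The saturation index divides the mean marginal FDis gain over the last
half of the richness range by that over the first half: ≈1 for a linear
SFD (complementary pool, sensitive to loss), ≈0 for an asymptotic SFD
(redundant pool, resilient).

## Dynamics models

**Responses.** ΔS_t = log(S_t/S_{t−1}) (richness is a count; the log-ratio
makes the feedback model multiplicative and telescopes exactly over
gap-free runs), and ΔdFD*_t as arithmetic differences of the null-model
deviations — the extrinsic component of functional diversity, purged of
the richness-mediated SFD effect.

**Season bookkeeping.** The dry season (Nov–May) is labelled by the year
of its Jan–May span, so the chronological order is dry(y), wet(y),
dry(y+1)…; "previous season" for a wet-season record is the same year's
dry season and vice versa; t−2 is the same season one year back.
Monitoring gaps break lag chains: transitions spanning missing seasons are
dropped rather than splicing non-consecutive years together, because the
lag terms would otherwise misrepresent elapsed time.

**Design.** Per season, both habitats stacked; habitat coded 0/1 with the
alphabetically first (arroyo) as reference; requested interactions are
elementwise products and obey marginality. Lag columns: the response
parameter's own level at t−1 and t−2 (log richness for the ΔS model, the
deviation for ΔdFD models) plus lagged richness S_{t−1}, S_{t−2} as
candidates in the functional-diversity models; log total captures enters
as a sample-size covariate; Year is a linear-trend candidate only. The
anomaly dummy enters only the dry-season candidate set — the flagged event
is a dry-season one, and in wet-season rows the column is identically zero
(collinear with the intercept).

**Fitting and selection.** OLS via least squares with the textbook
covariance estimator; AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) with k
counting all regression coefficients (intercept included) plus 1 for the
residual variance — the standard least-squares convention. Backward
elimination deletes the single admissible term (interactions before their
main effects) whose removal most lowers AICc; stepwise refinement then
alternates single-term additions and deletions from the candidate pool
until no move improves. AICc strictly decreases along accepted moves, so
the search terminates; ties break to fewer parameters, then lexicographic
term order. All candidate columns are materialized up front so every model
in one search is compared on a common row set. Predictor importance is
R²_X = R² − R²₋X, refitting without X and every interaction containing X.
Residual inspection is left to the analyst: residuals are written per
selected model rather than auto-transformed.

With the default 19-year, two-habitat design this yields n ≈ 34 stacked
rows per season against full models of 11–12 terms — tight but estimable
(n > k + 1 throughout); the default full-model term sets were chosen with
that constraint in mind, with T_MAX, Year and S_{t−2} offered to the
stepwise phase rather than the full model.

## Synthetic study system

The generator's defaults *are* the study conditions: 13 species,
1990–2007 plus 2012, two habitats × two seasons, dominant-species capture
shares 0.90 (upland) and 0.55 (arroyo), wet-season rainfall 680 ± 240 mm
vs dry 170 ± 80 mm (≈850 mm annually, ~80% in the wet season), one
anomalous dry season (1992, +600 mm, flagged by the dummy), temperatures
27/24 °C with independently varying diurnal half-ranges (a fixed offset
would make T_MIN an affine function of T_MEAN and the design singular).

Traits: Dirichlet rows per category; species 1 concentrated on
ground/seeds/nocturnal; species 2–4 a planted near-identical cluster of
35–40 g arboreal herbivores (the redundancy regime); biomass log-normal
over ~4–300 g with guaranteed small (shrew-like) and large (skunk-like)
extremes. Abundance: per habitat, log expected totals follow
x_t = x_{t−1} + β·z_t + γ·(x_{t−1} − μ) + σ·ε with z_t the standardized
seasonal precipitation, γ = −0.5 (negative feedback), and habitat-specific
sensitivity and noise (β 0.35/0.15, σ 0.45/0.22 for upland/arroyo —
environmental forcing is stronger in the exposed habitat, and its
assemblage correspondingly less stable). Totals are Poisson draws
allocated to species by a dominance-weighted multinomial whose
non-dominant shares decay geometrically with biomass extremity, so
functionally extreme species are rare.

What the generator does **not** emulate: trap-level detection processes,
within-species mass variation, species-specific environmental responses
(all species share the habitat total's dynamics), immigration from outside
the pool, and spatial structure within habitats. Passing tests therefore
validate the estimators and the inferential machinery under the stated
generative model, not the field-sampling process.

## Problem sizes and numerics

Default runs use 1000 extinction trajectories (13-species pool), and the
validation experiments use: exhaustive enumeration vs 10,000 trajectories
on a 6-species pool; OLS bias over 200 replicates at n = 500; selection
recovery over 100 replicates at n = 200 with effect sizes of 1 residual SD
(one spurious full-model term, one withheld true term for the stepwise
phase to add). The full pipeline completes in about a second on one core.
Tolerances: symmetry/diagonal of G exact; embedding reproduction of
Euclidean distances 1e−8; FDis oracle agreement 1e−8; renormalization
tolerance 1e−3 on row sums. Degenerate inputs (single species, zero
weights, zero richness transitions, rank-deficient designs) raise typed
errors naming the offending record rather than propagating NaNs.

## Known limitations

- FDw approximates captured biomass via pool-level mean masses.
- The AICc search is greedy; it examines far fewer models than the full
  2^p space and can settle on a local optimum, as stepwise procedures do.
- OLS with lagged responses gives conditional least-squares estimates;
  small-sample bias of feedback coefficients (Hurwicz-type) is not
  corrected, though the recovery tests bound it under the default design.
- Deviations share one occurrence-based null; abundance-structured nulls
  (e.g. individual resampling) are out of scope.
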