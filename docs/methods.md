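# Methods

## Study design the package models

The pipeline targets one-summer bee-walk studies: a set of forest patches
(24 by default in the synthetic generator) each holding a permanent
100 m × 1 m transect, visited on an uneven number of days across June,
July and August. Each sampling day yields (i) visit records — pollinator
taxon, plant taxon, count — and (ii) a flower survey through ten
permanent 1 m² quadrats, with rare plants counted over the whole
transect. Because *Bombus lucorum* and *B. terrestris* cannot be
separated reliably in the field, they are lumped into one analysis taxon
by a user-editable alias map applied at read time.

## Flower metrics

Per-species density (floral units/m²) is the mean of the ten quadrat
counts, or transect total / 100 m² for species absent from the quadrats.
Daily patch density sums species densities; daily richness counts species
with strictly positive density (a species present but not flowering that
day contributes nothing). Monthly covariates are unweighted means over
sampled days — responses are modelled per month, and day-weighting is a
design choice with no obvious alternative; the day-mean matches the daily
definitions of the metrics.

## Effort standardization

Sampling effort differs between patches, so raw totals confound ecology
with effort. Standardization finds the minimum number of sampled days
n_min, then draws n_min days without replacement from each richer patch,
B = 1000 times, and averages abundance, richness and the summed daily
interaction matrices over replicates. Choices worth knowing:

* **Month scoping.** Abundance and richness are standardized per patch ×
  month; n_min is computed per month over the patches with at least one
  day that month, and patch × month cells with no sampled day are dropped
  (logged). Networks are standardized at season scope (one matrix per
  patch). A season-level n_min is available via `per_month=False`.
* **Identity at minimum effort.** A patch already at n_min is not
  resampled; its observed values are exact.
* **Seeding.** One master seed spawns an independent RNG stream per
  patch × scope (hash-derived), so adding or removing a patch never
  changes another patch's draws, and scalar and network standardization
  share identical day draws — hence the standardized network's grand
  total equals the standardized abundance exactly.
* **Without replacement.** This is day-subsampling (rarefaction), not a
  bootstrap; each replicate is a plausible reduced field season.

The replicate mean converges to the exhaustive subsampling expectation
(for totals, equal to n_min/n × grand total) with Monte-Carlo error
∝ 1/√B; both are verified against enumeration oracles in the tests.

## Network specialization H2′

H2 is the Shannon entropy of the interaction matrix read as a joint
distribution. With margins fixed, H2max is the entropy of the
outer-product table (continuous margins: exactly H_rows + H_cols);
H2min comes from a greedy packing heuristic that repeatedly assigns
min(remaining row, remaining column) to the cell with the largest product
of remaining totals (ties: larger row remainder, then larger column
remainder, then index). Integer margins use unit-respecting variants; for
H2max the integer table closest to the outer product is built by
largest-remainder apportionment followed by marginal repair (row fixes
move units within a column, column fixes within a row, so each pass
preserves the other margin). Both heuristics run on margins sorted in
descending order, which makes the bounds invariant to row/column
permutations of the input (tie-breaking would otherwise leak label order
into the result). H2′ = (H2max − H2)/(H2max − H2min).

Numerical policy: natural logarithms throughout (H2′ is a ratio, so the
base cancels); 0·ln 0 = 0; mode `auto` selects integer heuristics when
all weights are whole numbers, so rarefied (replicate-averaged,
non-integer) networks use continuous mode; if H2max − H2min < 1e-9 the
network is flagged degenerate and H2′ = 0; webs with fewer than two
pollinators or two plants return NaN and are excluded from the
regressions (counted in the log). On the exhaustively enumerable family
of 3×3 tables with margins (3,2,1)/(2,2,2) the heuristics attain the true
extrema; in general they are heuristics and the tests bound their gap.

## Competition indices

Müller's index d_ij = Σ_k (a_ik/A_i)(a_jk/C_k) is computed per patch
from the standardized web; rows sum to one. The intraspecific index of a
focal species is d_ff. The interspecific index aggregates the focal's
column over the other species; the default is the **mean** of d_i,f over
i ≠ f (the focal's average potential influence on each other species),
with `sum` and `max` as alternatives and both directions
(influence-on-others vs influence-from-others) exposed — the aggregation
used in the original field analyses is not fully specified, so it is a
configuration choice here, not an assertion. Focal species are those
present in at least half the patches (threshold configurable).

## Regression layer

Families follow response support: Poisson (log) for standardized counts
(rounded to integers, since replicate averages are not integral), Gamma
(log) for the strictly positive H2′ and interspecific indices, Gaussian
(identity) for intraspecific competition. Gamma responses equal to zero
(a perfectly generalized web) are nudged by ε = 1e-6 with a logged
warning; dropping them is available instead.

Fixed-effects fits delegate to statsmodels GLM; log-likelihoods are then
recomputed at the true maximum — Gaussian at the ML error variance,
Gamma at the profiled ML shape (legitimate because the Gamma mean score
does not involve the shape) — so AICc and LRTs compare genuinely
maximized likelihoods with k counting the dispersion/shape parameter.

The Poisson random-intercept model (patch identity absorbing
pseudoreplication of patch × month rows) maximizes the Gauss–Hermite
marginal likelihood (31 nodes) over (β, log σ_u) with BFGS and a
Nelder–Mead polish; k counts the random-effect variance as one
parameter. The fit is validated against an independent
adaptive-quadrature mixed-model implementation on a frozen fixture
(note that reference reports its log-likelihood relative to the
saturated model; the offset is the saturated Poisson log-likelihood).
Gaussian random intercepts delegate to MixedLM with ML estimation;
Gamma random intercepts are not supported (no response in the design
needs them).

Model selection enumerates all sub-models: forced terms always present
(month is forced into abundance/richness candidates — it is the seasonal
control of the design), interactions only with both parents (marginality),
and a cap on the number of non-forced main-effect predictors (2 for H2′,
1 for the competition indices, matching small-sample practice; the
abundance/richness cap defaults to 2 to keep desk-scale runtimes and is
configurable). Ranking is by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1);
alternatives within ΔAICc ≤ 2 are reported. Per-variable significance
comes from likelihood-ratio tests of the best model against itself minus
the variable (and any interaction containing it). VIF screening
(auxiliary-regression R², iteratively dropping the worst predictor above
3) precedes selection; predictors are z-scored before fitting so
coefficients are comparable and the optimizer well-conditioned.

## Synthetic data generator

The generator's defaults are the study conditions the pipeline is tested
under: 24 patches, sampling days per patch ~ Normal(15.62, 2.93)
truncated at 5 across June–August, nine bumblebee taxa with the rank
abundances of a southern-Norway community (two dominant generalists), and
baseline rates calibrated so a default season yields roughly 850 visits.

* **Landscape.** Centroids fall uniformly in a 1.2 km square, chosen so
  the realized mean-distance-to-5-nearest spans ~0–450 m; isolation is
  genuinely geometric, four random patches are corridor-connected
  (isolation 0), and shape complexity (+) and percent forest (−) are tied
  to the isolation z-score with strength `gradient_strength` (0 gives
  independent covariates, used in the recovery experiments to isolate a
  single true effect).
* **Flora.** Fifteen plant species with lognormal daily densities
  responding to shape complexity (+) and forest cover (−) plus a
  triangular phenology; abundant species are surveyed through Poisson
  quadrat totals thinned multinomially over ten squares, sparse ones
  through whole-transect Poisson counts.
* **Visitation.** Per patch/day/species totals are Poisson with
  log-linear predictor β0_s + β_iso·iso_z + β_forest,s·forest_z +
  β_fd[month]·fd_z + β_month + u_patch, u_patch ~ N(0, 0.3²). The
  flower-density term uses the day's realized density, log1p-transformed
  and standardized by fixed constants — raw density is heavy-tailed and
  would otherwise produce explosive rates. Totals are allocated to the
  plants actually flowering that day by the species' diet vector, drawn
  once per study from a symmetric Dirichlet over the plant pool and
  renormalized to the flowering subset; concentration near zero gives
  one-hot diets (specialists, standardized webs near-diagonal, H2′ → 1),
  large concentration gives generalists.

Because totals are generated at the patch/day/species level and then
allocated to plants, the Poisson GLM fitted downstream is the literally
true generating model for visit totals. What the generator does **not**
emulate: observer error and detectability, within-day weather, spatial
foraging movement, colony dynamics, inter-annual turnover, and
phylogenetic or morphological (tongue-length) structure in diets. Passing
recovery tests therefore show the estimators work when their assumptions
hold — not that field data satisfy those assumptions.

## Verification scale

The test suite runs recovery and calibration experiments at reduced but
informative sizes chosen as desk-scale defaults: sign and selection
recovery over 100 replicate studies of 100 patches with a standardized
isolation effect of −0.5; LRT null calibration with 1000 simulations per
family at n = 100 (empirical type-I error checked against the exact
binomial 95% interval around 0.05); Monte-Carlo error scaling across
B ∈ {100, 1000, 10000} with 30 independent repetitions per level; and one
full pipeline run at the default study scale (24 patches, B = 1000).

## Known limitations

* The entropy extrema are heuristic; H2′ can in principle fall slightly
  outside [0, 1] on adversarial margins (clamped by construction here,
  since the observed entropy is folded into the bounds).
* The interspecific aggregation is a documented choice; comparing
  absolute values across studies using a different aggregation is not
  meaningful.
* AICc uses the row count of the fitted table as n, which for mixed
  models overstates the effective sample size when the random-intercept
  variance is large.
* Buffer composition uses a cell-centre rule on a plain-text grid; very
  coarse grids discretize the disc visibly (the tests bound this at one
  cell-row).
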