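# Methods

This package studies how uncertainty in forest inventory data propagates
through a chain of models — stand growth and carbon balance, habitat
suitability, spatial conservation prioritisation — into the final
priority ranking of grid cells, and attributes the resulting ranking
variance back to the input variables. Everything runs on synthetic
landscapes so the full chain is exercisable and testable without any
external data.

## Synthetic landscape

The landscape is a regular grid (default 96 m cells) with a fraction of
water cells (default 10 %) carved out of a smooth random field. Land
cells are grouped into contiguous *segments* by randomised multi-source
region growing; a segment is the simulation unit — all its cells share
identical stand variables at all times. Land components unreachable
from a seed cell become extra segments, so contiguity is guaranteed and
the configured segment count is a target rather than exact.

Baseline stand variables per segment:

* dominant species — categorical (pine 0.45, spruce 0.35, deciduous
  0.20);
* site-fertility class 1..6 (1 = most fertile) — ordered cut of a
  latent field that mixes a smooth spatial component with segment noise,
  with class frequencies (0.08, 0.22, 0.30, 0.25, 0.10, 0.05);
* stand age — Gamma(2.2, 25) years (mean 55, long tail of old stands,
  as in a managed rotation landscape);
* mean height — a saturating Chapman–Richards curve of age
  (`hmax (1 − e^{−k·age})^m`, hmax 22–28 m by species adjusted ±5 % per
  fertility class, k = 0.035 yr⁻¹, m = 1.3) with lognormal noise
  (σ = 0.12);
* DBH and stem volume — height allometries (`1.25·H^1.05` cm,
  `0.65·H^1.85` m³ ha⁻¹) with lognormal noise;
* deciduous share — Beta draws truncated at 0.5 so the share is
  consistent with the dominant-species label (majority rule).

These choices give a landscape with mean height ≈ 18 m, mean volume
≈ 170 m³ ha⁻¹ and a right-skewed value distribution in which highly
suitable or carbon-rich cells are rare — the property that anchors the
top of a priority ranking in real prioritisations.

Static non-forest predictors (January temperature, growing degree days,
urban/agricultural indicators, water, shoreline) are generated once as
smooth random fields or indicator layers and held fixed across all
ensemble iterations.

## Uncertainty samplers

All samplers are pure functions of `(inputs, seed)`, draw **once per
segment** (never per cell), and derive their randomness from
per-iteration, per-sampler substreams of one master seed (CRC-32-hashed
key paths into a `SeedSequence`).

* **Structural errors.** One multivariate-normal error vector per
  segment over (height, DBH, volume, deciduous volume), default SDs
  (1.5 m, 2.5 cm, 25, 12 m³ ha⁻¹) with positive correlations (0.6
  height–DBH, 0.5 height/DBH–volume), magnitudes typical of
  segment-level remote-sensing inventories. Raw draws are
  post-processed by *quantile matching*: each value is carried through
  its normal quantile onto a truncated normal with the same segment
  mean and marginal SD, truncated at physical bounds (0–45 m, 0–90 cm,
  0–900 m³ ha⁻¹). The map is strictly monotone, so within-variable
  ranks (and hence the error covariance structure, up to the
  truncation) are preserved while impossible values are excluded.
  After matching, `dec_volume ≤ volume` is enforced and the dominant
  species re-derived by majority share; a segment losing deciduous
  dominance falls back to spruce on fertile sites (class ≤ 3),
  otherwise pine.
* **Site class.** An ordered-probit model on standardised volume,
  height and deciduous share (negative coefficients: productive stands
  sit on fertile classes) gives per-segment class probabilities from
  which the class is redrawn once per iteration and then held constant.
* **Age.** `age' ~ N(age, (0.10·age)²)`, truncated at zero.
* **Parameters.** Whole-vector bootstrap from a pool of 100 correlated
  lognormal multiplier vectors (growth rate, height asymptote, volume
  allometry, litter rate, soil decay) standing in for a joint posterior
  sample; drawing whole vectors preserves parameter correlations by
  construction. The crown-base-analogue column receives an extra
  N(1, 0.1²) multiplier at draw time, mirroring a parameter whose
  uncertainty comes from a separate empirical model. The pool is a
  frozen artifact generated from a fixed internal seed, like a
  published posterior.
* **Weather.** Annual growth-modifier scalars resampled with
  replacement from a pool of 46 historical years (lognormal, mean 1,
  σ = 0.08).

## Growth and carbon surrogate

Height advances along the Chapman–Richards curve in *effective age*:
each year the current height is inverted to an effective age, the
year's weather modifier is added, and the curve is re-evaluated. With
modifier 1 this reproduces the closed form exactly; modifiers stretch
or shrink a year's progress. DBH and volume follow the height
allometries multiplied by segment-specific offsets fixed at
initialisation, so perturbations of the initial inventory persist
through the simulation instead of being snapped back onto the curve.
The deciduous share drifts toward a cap of 0.5 at 0.004 yr⁻¹
(encroachment during undisturbed succession). Height, DBH, volume and
age are non-decreasing (no harvest); segment heights within a
(species, fertility) group converge toward the shared asymptote, so
growth evens out initial differences.

Carbon pools (kg C ha⁻¹):

* tree carbon = volume × wood density (0.41/0.38/0.49 t m⁻³) ×
  biomass expansion 1.7 × carbon fraction 0.5;
* soil carbon = single first-order pool, litter input 0.015 yr⁻¹ of
  tree carbon, decay 0.045 yr⁻¹, initialised at steady state. The pool
  represents the *dynamic* fraction of soil carbon (equilibrium one
  third of tree carbon, ~20-year response), not the large inert store;
* ground vegetation relaxes (0.10 yr⁻¹) toward a site-class equilibrium
  (1.8–3.6 t C ha⁻¹, higher on poor sites) shaded down exponentially
  with canopy volume (e-folding 400 m³ ha⁻¹).

NEP (g C m⁻² yr⁻¹, = 0.1 × kg C ha⁻¹ yr⁻¹) is defined as the annual
change of the summed pools — an exact mass balance, asserted to 1e-9
relative throughout the test suite. With these defaults the default
landscape has a T1 regional NEP around 110 g C m⁻² yr⁻¹ declining by
roughly a quarter by T3 as stands mature, with ~15 % of cells acting as
sources on average.

Outputs are averaged over three periods (2017–2025, 2026–2033,
2034–2050; simulation starts 2015 with a two-year initiation).
Categorical fields come from the period midpoint year. The carbon-sink
prioritisation feature zeroes cells whose mean annual NEP over
2017–2050 is ≤ 0 (ties count as sources; initiation years excluded);
the unzeroed NEP is kept for regional flux summaries.

## Habitat models

Each of six bird species (three hawks, three woodpeckers) gets a
logistic-linear suitability model over standardised predictors: stand
variables at the cell plus landscape-scale focal means (1 km radius for
hawks, 500 m for woodpeckers; shrinking circular window at grid edges)
and the fixed climate/land-use layers. Weights are hand-set to encode
each species' qualitative dependence structure — volume/age for the
goshawk and buzzards, deciduous volume for the white-backed and
lesser-spotted woodpeckers, height plus cold climate for the three-toed
woodpecker — and negative intercepts keep highly suitable cells rare.
The weights are configuration, not fitted quantities. Habitat area is
the sum of predicted values divided by the number of land cells.

## Prioritisation

Additive-benefit-function ranking: with `r_j` the remaining fraction of
feature `j` and benefit `v_j(r) = r^z` (z = 0.25 for biodiversity
features, following the species–area relationship; z = 1 for carbon),
cells are removed greedily by smallest aggregate marginal loss
`Σ_j w_j (r_j^z − (r_j − p_ij/P_j)^z)`, and a cell's rank is its
removal position divided by N. Batch removal (k cheapest cells per
pass; default ~N/200 in ensemble runs) is an accelerated approximation
of the exact greedy; agreement of the two on the top-10 % set (Jaccard
≥ 0.95) and exact equivalence of `batch=1` with an independent
brute-force greedy are test-suite checks. Marginal losses are
recomputed vectorised over all remaining cells each pass rather than
cached per cell; at the grid sizes this package targets the vectorised
sweep is faster and simpler than lazy invalidation. Ties are broken by
a random permutation drawn once per ensemble (so identical inputs give
identical rankings across iterations and the degenerate ensemble
reproduces its baseline bit-exactly), or by lowest cell index in
deterministic-ties mode, which the oracle tests use.

## Ensemble and metrics

One iteration draws each enabled uncertainty source once (site class
and parameters are sampled at the start and held constant for the whole
simulation), runs the growth/carbon simulation over the full horizon,
builds per-period features and ranks them under up to three variants
(combined 6+4 features, biodiversity-only, carbon-only). Iterations
are independent; the CLI writes per-iteration outputs atomically and
can resume.

Across iterations the package reports per-cell mean, range (max − min)
and population SD of rank values, the probability of falling in the
top-10 % set, probability-group class layers (default breaks 0, 0.02,
0.2, 0.4, 0.6, 0.8, 1; half-open bins, top bin closed), and regional
summary tables (means of forest variables, carbon totals in million
t C, habitat fractions).

## CCA attribution

For attribution, explanatory values (the ten prioritisation features,
or the six forest variables with site class as a numeric index and
deciduous share standing in for the categorical species) and the
priority rank are extracted at a fixed random sample of cells (default
10 000 or all land cells if fewer). Canonical correlation analysis is
computed classically from Cholesky-whitened cross-correlations; a
1e-8 ridge is applied to a within-set correlation matrix **only if its
unridged Cholesky fails**, so well-conditioned problems are exact and
the univariate-response identity Rd(response) = ρ₁² = OLS R² holds to
1e-8. Constant columns are dropped with a warning and reported as
Rd = 0. The per-variable redundancy index follows the Stewart–Love /
van den Wollenberg convention, Rd(v) = Σ_k loading(v,k)²·ρ_k².

One CCA is run per iteration with the rank of a single prioritisation
variant as a univariate response (default); a pooled mode stacking all
iterations and periods, and a joint mode treating the three variant
ranks as a multivariate response set, are available but non-default.
The top-10 % subset restricts rows to the sampled cells inside that
iteration's top mask and is skipped with a warning if fewer than
p + q + 1 rows remain.

## Validation experiments

Two controlled experiments validate the package's qualitative claims;
both are driven by `borealprio.experiments` and recomputed by the
acceptance script.

**Top-stability.** On the default synthetic ensemble (100×100 grid,
~600 segments, 50 iterations, combined variant, first period), cells
are ordered by mean rank; the median rank-SD of the top and bottom
deciles is compared with the median rank-SD of the middle three
quintiles (20th–80th percentile). Rare high feature values anchor the
top, worthless cells the bottom, and the interchangeable middle
reshuffles — so both extreme medians should be lower, in at least 9 of
10 master seeds.

**Rarity drives influence.** Two test features receive identical
additive perturbations (SD 0.10 of the feature scale, matching the
small input alterations the ensemble emulates): one confined to a
compact block covering 5 % of a 60×60 landscape, one near-uniform
everywhere. They are ranked together with four fixed smooth background
features representing the rest of the data pool. The background is
essential to the design: in a bare two-feature prioritisation the
feature covering the other 95 % of cells trivially drives the entire
ranking, and the confined feature's redundancy is capped near 0.13 by
the point-biserial ceiling of a 5 % indicator — the substitutability
mechanism being tested cannot operate. With background present, the
widespread feature's perturbations drown among equally good cells
(Rd ≈ 0.04) while the confined feature keeps pinning the top ranks
(Rd ≈ 0.13); the confined feature should win in at least 9 of 10
replicate ensembles.

## Problem sizes and numerical choices

* Default study grid 100×100 (≈9 000 land cells, ~600 segments); unit
  tests use 25×25–40×40 grids, the degenerate-ensemble and rarity
  checks 60×60. These sizes keep the full suite and the acceptance
  script to a few minutes while leaving every mechanism intact.
* Ranking ties: random permutation per ensemble (see above); exact-vs-
  brute-force comparisons use deterministic ties.
* Quantile matching clips normal quantiles to [1e-12, 1 − 1e-12]
  before inversion.
* Remaining feature fractions are clipped at zero; a deficit below
  −1e-12 raises an internal accounting error.
* Population (not sample) SD for per-cell rank statistics, as a
  descriptive quantity over the fixed set of iterations.
* MVN sampling uses an eigendecomposition square root, so singular
  (including all-zero) covariances are valid.

## Limitations

The synthetic landscape reproduces the *structure* of the real problem
(segment-shared variables, correlated errors, bounded marginals,
rare high values, fixed non-forest context), not any real geography:
absolute carbon totals and habitat fractions are not comparable to any
published region, and passing tests demonstrate properties of the
method chain, not predictions about real forests. The growth surrogate
has no photosynthesis model, soil chemistry, management or climate
forcing; its parameter pool is a stand-in with plausible, not fitted,
correlations. Habitat models are linear-logistic stand-ins for fitted
species distribution models. The prioritiser implements the additive
benefit-function rule only — no connectivity, condition layers or
hierarchical masks.
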