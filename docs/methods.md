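# Methods

## Spatial association

For an ordered species pair (focal *i*, other *j*) in a rectangular window,
two bivariate summary statistics are evaluated pointwise at radii
r ∈ {5, 30, 50} m by default:

**Pair correlation function.** The kernel estimator

    ĝ_ij(r) = Σ_{u∈i, v∈j} k_h(‖u−v‖ − r) / [(W−|Δx|)(H−|Δy|)] / (2πr λ_i λ_j)

with an Epanechnikov kernel k_h, translation edge correction (each pair
weighted by the reciprocal of the area over which its displacement vector is
observable) and intensities λ = n/area. The bandwidth follows the common
rule h = 0.15/√λ_j, clipped to [0.5 m, r/2]; both kernel and bandwidth are
arguments, and the calibration tests pass for any admissible choice because
the identical estimator is applied to observed and null patterns.

**Nearest-neighbour distribution.** D_ij(r) is the raw empirical fraction of
focal stems whose nearest *j* stem lies within r. It is deliberately left
without edge correction: the standardized effect size below compares it with
the same estimator on torus-shifted patterns, so the (small) edge bias
cancels instead of being modelled.

**Toroidal-shift null and SES.** The null hypothesis is independence of the
two species' patterns given their internal structure. Each replicate
translates the entire pattern of species *j* by an offset drawn uniformly on
[0, W) × [0, H) with wrap-around, keeping species *i* fixed; this preserves
each species' autocorrelation exactly (the torus translation is an isometry)
while breaking any cross-species dependence. With n_sim replicates (999 in
the full protocol; 99–199 in the desk-scale runs used by the test suite and
the acceptance script, chosen as a compute/precision compromise) the
standardized effect size is z = (S₀ − μ_null)/σ_null with the sample (n−1)
standard deviation. |z| > z_α (1.96 at α = .05, strict inequalities) is read
as attraction/repulsion. One uniform shift stream per ordered pair serves
every statistic and radius; SES classification is pointwise, so the induced
correlation between radii is immaterial. Replicates with zero null variance
(up to floating error) are flagged degenerate and excluded from proportions
and models, with a logged count.

Assumptions worth making explicit: the window is rectangular with continuous
coordinates; patterns are treated as first-order homogeneous (the torus
shift preserves any inhomogeneity of *j* but relocates it, which is exactly
the intended null); z is treated as approximately standard normal under the
null, which the calibration suite verifies empirically (rejection within
5% ± 3 points for Poisson and Thomas patterns at all radii and both
statistics).

## Trait distances

Absolute distance |t_i − t_j| (dissimilarity, niche-difference proxy) and
hierarchical distance t_i − t_j (rank difference, fitness proxy), focal
species first, for six traits — LA (cm²), SLA (cm²/g), LDMC (g/g), WD
(g/cm³), WDMC (g/g), H_max (m, the 99% quantile of per-stem heights with
linear order-statistic interpolation) — plus an integrated axis: species
scores on PCA axis 1 of the centred, unit-variance-scaled species × trait
matrix. The correlation (not covariance) matrix is used because the traits
carry heterogeneous units; values enter untransformed. PCA axis signs are
arbitrary, so axis 1 is oriented to make the SLA loading positive — any
directional statement about the integrated hierarchical distance is relative
to that convention. When both life stages are analysed the PCA is computed
separately per stage on that stage's species set, and distance
standardization (to mean 0, sd 1 with the sample sd) is likewise within
stage over the ordered pairs actually entering the model. Pairs missing a
trait value are excluded from that trait's model only, with a logged count.

## Association models

Per statistic × radius × trait × stage:

    z_ij = a + a_i + (b + b_i) · pred_ij + ε_ij

REML, grouping by focal species, random intercept and random slope with
unstructured covariance (BFGS first, then Powell and L-BFGS as fallbacks; a
diagonal random-effect structure replaces a singular unstructured fit and is
flagged). The screening stage uses the absolute distance as sole predictor:
a significantly positive fixed slope b indicates limiting similarity, a
negative one filtering or hierarchical competition. The comparison stage
fits the absolute and the hierarchical predictor in *separate*
single-predictor models (a joint two-predictor model with both random slopes
is available behind a switch; it is not the default because |t_i − t_j| and
t_i − t_j are exactly collinear within focal species whose rank is extreme,
which makes the joint decomposition of a one-sided signal unstable). The
strengths are the per-focal |b + b_i| with BLUP-shrunken random slopes —
the only scale on which fixed and per-species contributions combine
meaningfully — compared by a paired t-test across focal species. The
mechanism label follows the decision tree: significant positive b →
limiting similarity; significant negative b and larger mean |slope| for the
absolute predictor → environmental filtering; for the hierarchical predictor
→ hierarchical competition; no significant absolute effect → none detected.
The label keys on which mean strength is larger; the paired-t p-value and
significance tier (*** < .001, ** < .01, * < .05, '.' < .1, ns) are reported
alongside rather than gating the label, since an underpowered comparison
would otherwise default every borderline community to one side.

Conditional R² uses the fixed-plus-random variance partition:
R²_c = (var_fixed + var_random)/(var_fixed + var_random + σ²_ε), where
var_random averages zᵀGz over the observed random-effect design rows (so the
random-slope contribution is evaluated at the predictors' second moment).

## Synthetic communities

The generator's role is to give every downstream stage ground truth, not to
mimic any particular forest. Defaults describe one fixed study condition:
20 species × 150 candidate stems in a 250 × 250 m window; within-species
clustering from a Thomas process conditioned on the abundance (parent
intensity 2·10⁻⁴ m⁻², dispersal sd 15 m, both scattered log-uniformly across
species because real species differ widely in aggregation); interaction
strength 4 (dimensionless, strong), removal probabilities capped at 0.9;
interaction kernel sd 10 m. Species-mean traits are log-normal with a shared
latent axis (loading 0.6, acquisitive traits positive, tissue-density traits
negative), giving an integrated PCA axis that explains roughly 45% of trait
variance in expectation, with wide seed-to-seed variation at 20 species. All
interactions act on the community's realized PCA axis-1 score (the
"strategy axis"), so the trait the mechanisms use is exactly recoverable
from the trait table.

Scenario thinning rules (removal probability
p = 0.9·(1 − exp(−s·exposure)), exposure scaled to be dimensionless):

* **neutral** — no thinning; species patterns are independent by
  construction, which is what the calibration suite exploits.
* **filtering** — a sinusoidal habitat field E(x, y) ∈ [0, 1]
  (wavelength 125 m, random phases); exposure is the squared mismatch
  between E and the species' preference percentile, scaled by 1/6 (the a
  priori mean squared mismatch of independent uniforms).
* **hierarchical** — dominant species aggregate into fewer, larger stands
  (parent intensity scaled by e^(−rank percentile)); a patch-scale pressure
  field is built as Gaussian crowding (kernel 35 m) by heterospecific
  neighbours weighted by dominance (rank percentile cubed); exposure is the
  squared *inferiority* percentile times the pressure in excess of its lower
  quartile. Inferior species are displaced from the dominants' stands into
  shared refuges, so co-occurrence becomes assortative by competitive rank —
  a directional signature — while the rank gradient in displacement still
  depresses associations between dissimilar pairs, giving the negative
  dissimilarity slope the screening stage expects.
* **limiting similarity** — exposure is similarity-weighted heterospecific
  crowding (trait kernel sd 0.5 on the strategy axis) relative to mean total
  crowding, which concentrates removal where trait twins actually meet
  instead of blanket-thinning species with many similar competitors.

What the generator does *not* emulate: realistic species-abundance
distributions, demographic dynamics, dispersal limitation beyond the cluster
process, intraspecific trait variation, correlated habitat and trait
structure, or several mechanisms acting at once. Passing recovery tests
therefore show that the inference chain detects each mechanism's signature
when it acts alone and strongly — not that it would decompose mixtures in
real data.

The mechanism-recovery protocol used for validation analyses all stems (no
stage split, minimum 10 stems per species), the nearest-neighbour statistic
at r = 5 m with 99 null shifts, and the integrated PCA trait; D at the
neighbourhood scale is the natural readout because all three interactions
act within ~10–35 m and contact deficits/excesses are their most direct
footprint.

## Numerical choices and degenerate inputs

DBH stage bounds follow the protocol wording literally: saplings occupy the
closed interval [1, 3] cm, adults are strictly above 10 cm; species need 50
in-stage stems (configurable). Zero-variance predictors, empty patterns,
radii beyond half the shorter window side, constant trait columns and empty
height vectors raise errors; singular or non-converged mixed fits are
flagged and retained rather than discarded. Torus shifts, community
generation and null ensembles draw from seeded `numpy` Generators; identical
configurations reproduce byte-identical outputs, and the run manifest
records a content hash per output file.

## Known limitations

* With 20 focal species the mixed-model estimator pools within- and
  between-focal information; when the mean association of a focal species
  correlates with its own trait rank — which any rank-additive mechanism
  produces — the fixed hierarchical slope is attenuated. At the scale of
  hundreds of pairs per focal species this vanishes, but at desk scale it
  caps the power of the hierarchy-versus-dissimilarity comparison: across
  random seeds the hierarchical scenario is recovered in roughly half of
  communities (the acceptance script reports the realized rate), while
  filtering and limiting similarity are recovered in most.
* Bivariate pcf-based SES is symmetric in the pair by construction, so
  directional mechanisms are detectable only through their rank-assortative
  or abundance-mediated footprints; D, being focal-conditioned, carries
  slightly more directional information.
* No multiple-testing correction across pairs (pointwise α by design), no
  inhomogeneous-Poisson or pattern-reconstruction nulls, no spatial
  autocorrelation correction of model residuals, no phylogenetic structure.
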