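# spatrait

Inference of community-assembly mechanisms from stem-mapped forest censuses,
by linking pairwise spatial associations between tree species to the
dissimilarity and the hierarchy of their functional traits.

## The problem

In a fully mapped plot, every ordered species pair (focal *i*, other *j*) has
a spatial association: do *j* stems occur around *i* stems more or less often
than expected if the two species were placed independently? Competing
assembly mechanisms leave different fingerprints on how these associations
relate to trait differences:

* **limiting similarity** — functionally similar species exclude one another,
  so spatial association *increases* with absolute trait distance |t_i − t_j|;
* **environmental filtering** — similar species share habitat and co-occur,
  so association *decreases* with |t_i − t_j|, symmetrically in the pair;
* **hierarchical competition** — species with higher trait values
  competitively displace lower-ranked ones, which also makes similar species
  co-occur, but the signal rides on the *directional* (hierarchical) distance
  t_i − t_j rather than on the absolute one.

Filtering and hierarchical competition produce the same co-occurrence
pattern; they are separated by comparing the strengths of the two trait
predictors.

## The method

1. **Association.** For each ordered pair, two summary statistics at radii
   r ∈ {5, 30, 50} m: the bivariate pair correlation function g_ij(r)
   (Epanechnikov kernel, translation edge correction) and the bivariate
   nearest-neighbour distribution D_ij(r). Each observed value is compared
   with a toroidal-shift null (the whole pattern of species *j* translated by
   a uniform wrap-around offset, 999 shifts by default) through the
   standardized effect size

       z(r) = (S0(r) − μ_null(r)) / σ_null(r),

   classified as attraction (z > 1.96), repulsion (z < −1.96) or
   independence at pointwise α = .05.
2. **Trait distances.** Per ordered pair and trait (LA, SLA, LDMC, WD, WDMC,
   H_max, and an integrated PCA axis-1 score of all six), the absolute
   distance |t_i − t_j| and the hierarchical distance t_i − t_j, each centred
   and scaled to unit variance.
3. **Mixed models.** Per statistic × radius × trait, the association model

       z_ij = a + a_i + (b + b_i) · pred_ij + ε_ij

   fit by REML with a random intercept and random slope per focal species.
   The sign of the fixed slope on the absolute distance screens for limiting
   similarity (positive) versus filtering/hierarchical competition
   (negative); the per-focal-species |b + b_i| of the absolute and the
   hierarchical predictor are then compared with a paired t-test to separate
   the latter two.
4. **Validation.** A synthetic-community generator places clustered species
   (Thomas processes) in a rectangular window and thins candidate stems
   under each of the four mechanisms (neutral, filtering, hierarchical,
   limiting similarity), so the whole chain can be checked against ground
   truth.

## Worked example

```python
import spatrait as st

cfg = st.ScenarioConfig(scenario="hierarchical", seed=1)
census, traits, truth = st.simulate_community(cfg)
print("stems retained:", len(census), "of", cfg.n_species * cfg.abundance)

scores, share, _ = st.integrated_trait_scores(traits)
print(f"PCA axis 1 explains {100*share:.1f}% of trait variance")

label = st.infer_mechanism(census, traits, cfg.window, n_sim=99, seed=2)
print("inferred mechanism:", label)

recs = st.pairwise_association_analysis(
    census, cfg.window, radii=(5.0,), statistics=("D",), n_sim=99, seed=2)
frame = st.associations_to_frame(recs)
print(st.association_proportions(frame).to_string(index=False))
```

prints

```
stems retained: 1946 of 3000
PCA axis 1 explains 29.0% of trait variance
inferred mechanism: hierarchical_competition
statistic   r  attraction  repulsion  independence
        D 5.0    0.102632   0.005263      0.892105
```

A community assembled under strong hierarchical competition lost about a
third of its candidate stems to rank-based displacement; most ordered pairs
are still classified independent (as in real forests), the excess of
attraction over repulsion reflects the rank-assortative co-occurrence the
mechanism produces, and the screening-plus-comparison decision tree
recovers the generating mechanism.

The same pipeline runs from the shell on census/trait CSV files:

```bash
spatrait simulate --scenario filtering --seed 1 --outdir community
spatrait associations --census community/filtering_census.csv \
    --window community/filtering_window.json --n-sim 199 --seed 1
spatrait models --census community/filtering_census.csv \
    --traits community/filtering_traits.csv \
    --window community/filtering_window.json --stage sapling --min-abundance 10
spatrait run --config run.yaml     # full preset: both stages, both statistics
```

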