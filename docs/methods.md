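# Methods

## Scope and model

`ecostatus` implements a composite "ecological status" framework for
surface-ocean microbiomes and the machinery to project it under environmental
change:

1. **Marker-gene quantification.** Mapped reads against a reduced catalog of
   biogeochemical marker genes are normalized as reads per kilobase per
   genome equivalent,

       genome equivalent = library size (bp) / AGS (bp)
       RPKG = mapped reads / (gene length (kbp) x genome equivalent)

   where AGS is the community's average genome size (an input here; its
   estimation from single-copy genes is out of scope). Pathway potential is
   the **sum** of member-gene RPKG (a mean is available as an option); the
   sum preserves additivity of read evidence across markers of one pathway.
   Taxon tables are carried in the same RPKG units; an optional
   fraction-of-total transform exists for display. Shannon diversity uses
   natural log over strictly positive taxa; richness counts positive taxa;
   the coefficient of variation uses the sample (n-1) standard deviation.

2. **Community statistics.** Bray-Curtis dissimilarity between profiles;
   PERMANOVA (adonis-style) on a distance matrix via the Gower partition of
   squared distances, with the permutation p-value estimated by the add-one
   rule p = (1 + #{F_perm >= F_obs})/(n_perm + 1) — unbiased and never
   exactly zero. "Two-sided" is recorded as metadata; the test itself is the
   standard upper tail of pseudo-F under label permutation. Rank-based group
   comparisons combine the Kruskal-Wallis omnibus with Dunn's pairwise z
   (tie-corrected, Bonferroni-adjusted) and Cohen's d; pairs with adjusted
   p > 0.05 and |d| < 0.1 are flagged "not distinguishable".

3. **Status definition.** Each grid cell carries 25 features: the five
   dominant taxa (Cyanobacteria, Proteobacteria, Bacteroidetes, Ascomycota,
   Firmicutes), the Shannon index, and 19 biogeochemical pathway abundances.
   Richness is excluded throughout (no usable environment-driven model for
   it). Features are z-scored, then PCA keeps the smallest leading set of
   components with >= 95% cumulative variance; standardization before PCA is
   a package choice (the features mix incommensurate scales) and is
   switchable. Agglomerative clustering is tuned over k in 2..12, linkages
   {ward, complete, average} and metrics {euclidean, cityblock, cosine}
   (ward restricted to Euclidean); the silhouette score, computed in the
   same PCA space that was clustered, picks the configuration; ties prefer
   smaller k. Status labels 1..K are canonical: descending cluster size,
   ties by descending mean Cyanobacteria abundance. Out-of-sample points can
   be assigned by nearest centroid in PCA space, though projection normally
   goes through the classifier.

4. **Supervised models.** Per-index regressions (families: random forest,
   gradient-boosted trees, linear, L1-penalized linear, k-NN) are tuned by
   tenfold CV on an 80/20 split; the best family is refit and scored on the
   held-out 20%. An index whose best test R^2 falls below 0.1 is excluded
   with a recorded reason — one number that reproduces the observed
   keep/drop behavior (kept indices near 0.2, richness near 0). The status
   classifier (families: XGBoost, random forest, multinomial logistic, SVM)
   is trained on a balanced sample of exactly n cells per status (default
   3000, without replacement; strict by default, oversampling optional) and
   tuned by tenfold CV; the default XGBoost grid contains the reference
   best point (200 trees, depth 9, learning rate 0.3). Full published tuning
   grids do not exist for this kind of study, so the grids here are small
   and declared in `models.py`. XGBoost uses exact greedy splits: histogram
   binning cannot place a threshold inside a narrow empty gap between
   classes, which costs boundary accuracy. Feature importances are
   impurity-based for trees and |coefficient| x sd(feature) for linear
   models, normalized to sum to 1.

5. **Projection.** The classifier is applied to present and future
   environmental grids; the changed area is the set of ocean cells whose
   argmax status differs. Changed-area fraction and per-status composition
   default to plain cell-count weighting (grid-point proportions);
   cosine-latitude weighting is available because grid cells shrink
   poleward and the convention is otherwise unstated. Cells that are ocean
   in one scenario but masked in the other are excluded from both numerator
   and denominator, with a count reported. Latitude band means use 10-degree
   half-open bins [lo, hi) on cell centers.

6. **Driver attribution.** For each in-scope cell the per-status probability
   vector is computed once under the present environment and ten more times
   with a single factor swapped to its future value. The relative
   contribution of factor e is the L1 probability shift of its swap
   normalized by the sum of all ten shifts; contributions are soft
   (probabilities, not hard labels — the definition is stated in terms of P).
   Cells where no swap moves the probabilities are flagged non-attributable
   and never silently dropped. The dominant driver is the argmax, ties
   broken by the canonical factor order (temperature, salinity, pCO2, MLD,
   oxygen, nitrate, phosphate, silicate, carbonate, iron). Scope defaults
   to changed cells only; attribution is one-at-a-time by design — no
   interaction (Shapley-style) decomposition.

## Synthetic data: what it emulates and what it does not

The generator stands in for real ocean metagenome surveys and Earth-system
model fields, at desk scale:

- **Gene catalog / read tables.** 19 pathways x 3 marker genes, lengths
  uniform in 0.3–3.0 kbp. Read counts are constructed by inverting the RPKG
  definition for a chosen target, with per-sample library sizes (0.5–5 Gbp)
  and AGS (2–6 Mbp) drawn at random, so quantification has an exact ground
  truth up to integer rounding of reads.
- **Environmental grids.** Ten factors on a regular cell-centered lat/lon
  grid, each with a smooth latitudinal profile inside a documented range
  (e.g. temperature −2..30 °C decreasing poleward, phosphate 0..2.5 µmol/kg
  increasing poleward), a small zonal harmonic and a smoothed random field
  (5% of range each). A "future" scenario is the present field plus an
  additive perturbation, exactly. Land cells (smooth pseudo-continents,
  ~25% of cells) carry NaN and are never imputed.
- **Truth mapping.** A climate score s = w·z(env) (z-scored by fixed
  reference statistics derived from the factor ranges) is cut at
  equal-frequency thresholds into K latent statuses. By default the score
  weights phosphate alone — an axis-aligned rule chosen because phosphate is
  the dominant predictor of status in the real-ocean setting, and because an
  axis-aligned boundary is exactly learnable by tree models. Each status has
  a 25-feature archetype centroid; centroids are scaled so the minimum
  pairwise distance is `separation` (default 8) times the total within-class
  standard deviation. Within a class, features vary smoothly with the
  environment (a bounded tanh modulation) plus optional isotropic noise.
  Richness is generated independent of the environment — constant at zero
  noise, pure noise otherwise — mirroring its real-world unpredictability.
- **Labeled samples for classification experiments** are drawn uniformly in
  the factor ranges; with `margin > 0`, draws whose score falls within
  `margin` x (narrowest band) of a status threshold are rejected, so latent
  classes are separated by empty buffer zones — the "well-separated
  archetypes" regime under which zero-noise recovery is exact. Label noise
  flips labels to a uniformly random other class.
- **Constructed scenario change.** `perturbation_for_changed_fraction`
  computes the uniform negative offset on one factor that pushes a requested
  fraction of ocean cells across their nearest lower status boundary, and
  returns the analytic changed-cell mask, giving the end-to-end projection a
  known answer.

Not emulated: ocean physics and circulation, seasonal/monthly structure,
spatial autocorrelation of the microbiome beyond what the environment
induces, factor cross-correlations other than shared latitudinal structure,
taxonomic composition realism, and real-world effect sizes. Passing recovery
tests therefore demonstrate the correctness and internal consistency of the
pipeline machinery — not that real ocean statuses are this separable, nor
that real projections would achieve these accuracies. Reproduction of the
real-data headline figures requires the original survey metagenomes and
Earth-system model fields and is explicitly out of scope.

## Problem sizes and numerical choices

- Default desk-scale grids: 40x90 cells (4°x4°, ~2700 ocean cells) for
  recovery experiments; 30x60 for the end-to-end smoke run. These sizes keep
  every experiment on a single CPU in minutes while leaving class sizes in
  the hundreds per status.
- Classifier recovery uses 26 000 labeled samples, balanced training of
  3000/class, margin 0.15, label noise {0, 5%}. Regressor recovery uses
  n = 1000 with 5%-of-SD target noise.
- PERMANOVA null calibration: 200 replicates x 999 permutations on 6
  samples; uniformity judged by a KS test at alpha 0.01.
- All randomness flows through explicit integer seeds (`numpy.random.
  default_rng`); no global RNG state. Reruns with the same config hash
  reproduce identical artifacts (verified via per-file SHA-256 in the
  pipeline manifest).
- Degenerate inputs have defined behavior: all-zero abundance profiles give
  Shannon 0 with a warning; all-zero profile pairs give Bray-Curtis 0 with
  a warning; constant regression targets are excluded with a reason;
  identical scenarios give zero changed area and non-attributable cells.
- Silhouette ties prefer smaller k; dominant-driver ties follow the
  canonical factor order; cluster numbering is by size then Cyanobacteria
  abundance. All three are determinism conventions, not scientific claims.

## Known limitations

- The synthetic environment-to-status rule is one-dimensional by default;
  multi-factor rules are supported (`status_weights`) but oblique boundaries
  are not exactly learnable by tree ensembles, so zero-noise recovery is
  only approximate there.
- PERMANOVA p-values are discrete (multiples of 1/(n_perm+1)); the KS
  uniformity check treats them as continuous, adequate at 999 permutations.
- Area weighting by cos(latitude) treats cells as points at their centers;
  no spherical-polygon areas.
- The SVM classifier family is available but quadratic in sample count;
  prefer the tree families at the default training sizes.
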