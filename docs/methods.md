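# Methods

## The problem

In a combinatorial nanodroplet screen, bacterial species are grown alone
(monoculture) and in all pairs (coculture) across many carbon environments.
The directed effect of species B on species A in carbon c is

    effect(A <- B, c) = ln( Y_co(A|B, c) / Y_mono(A, c) )

where Y are endpoint growth yields averaged over replicates.  Negative
effects are inhibition, positive facilitation; the two directions of a pair
classify the interaction as competition (-,-), mutualism (+,+) or
parasitism (mixed).  `pairfx` predicts the sign (classification) and
strength (regression) of these directed effects from information that is
much cheaper to obtain than cocultures: the species' phylogeny and their
monoculture growth profiles.

## Effect computation

Replicate yields are arithmetic-averaged before the log because mono- and
coculture droplets are unpaired; a per-replicate log-ratio would require an
arbitrary pairing.  The log is natural; the base only rescales effects and
every downstream metric is scale-aware (NRMSE normalizes by the test-set
standard deviation, sign is base-invariant).  Conditions represented by
fewer than `min_reps = 3` replicates are dropped, as are records whose
mono- or coculture mean is zero — no pseudo-counts are introduced.  An
effect of exactly 0 is labeled negative-class (`sign = positive` iff
`effect > 0`); exact zeros have measure zero on real fluorescence data, and
the rule is deterministic and documented so users can flip it.

## Features

One row per directed (affected, affecting, carbon) record:

- `mono_affected`, `mono_affecting` — the two species' mean monoculture
  yields in the focal carbon (raw scale by default; `log_mono` switches to
  the log scale).  These per-row features are never imputed: rows whose
  yields are missing correspond to dropped screen combinations and are
  excluded.
- `metab_dist` — Euclidean distance between the two species' monoculture
  yield profiles across all carbons.
- `affected_phylo_pc1/2`, `affecting_phylo_pc1/2` — each species' row of
  the phylogenetic distance matrix, column-centered, projected on the top
  two principal components.  This is plain PCA on the matrix rows, not
  classical MDS/PCoA (no double-centering), matching how the distance
  matrix is treated as a feature table.
- `carbon_pc1..4` — each carbon's metabolic profile (the vector of all
  species' monoculture yields in it), column-centered PCA over carbons.
  The fit returns a reusable projection (center + loadings); a held-out
  environment is embedded by projecting its profile, never by refitting.

Profile-based features (carbon PCs, `metab_dist`) impute a species'
missing yields with its mean yield across carbons.  Eigenvector signs are
pinned by scaling each component so its largest-magnitude loading is
positive, making all PCA output reproducible across runs and platforms.
Optional blocks: carbon one-hot, user-supplied carbon chemistry columns,
a species x pathway binary block (always a precomputed input, never
inferred), and the measured opposite-direction effect
(`reciprocal_effect`).

## Models

Gradient-boosted trees (XGBoost), random forest, k-nearest neighbors and
linear/logistic models share one contract: seeded random hyperparameter
search (`budget` draws, default 2,500; the analysis scripts and tests use
50 for desk-scale runtime), 5-fold cross-validation scored by Matthews
correlation (sign) or RMSE (strength), refit of the winner on the full
training set.  Features are standardized for the kNN and linear families
only; trees are scale-invariant.  Prediction refuses feature tables whose
column schema differs from training.

Naive baselines:

- **null** — most frequent training sign / mean training effect.
- **threshold** — a single-feature decision rule; candidate thresholds are
  midpoints between consecutive sorted distinct values plus +/- infinity,
  both inequality directions are searched (a large metabolic distance
  predicting inhibition is a hypothesis, not a given), and training
  accuracy is maximized.  Ties prefer the smaller threshold, then the
  ">= predicts negative" direction.  A constant feature degrades to the
  null model with a warning.
- **phylogenetic copy** — for an "uncultured" species, return the recorded
  effect of the phylogenetically closest species with data, same partner
  and carbon; if that record is missing, fall back to the next closest
  (dropping instead would shrink test sets non-comparably); ties break
  lexicographically.
- **metabolic copy** — the same along the environment axis, with carbons
  ranked by Euclidean distance between metabolic profiles.  The held-out
  carbon's own monoculture profile is used for the ranking (the
  "monoculture available" information tier).

Two-way prediction trains a multilabel model on canonical (affected <
affecting) rows with the target pair [effect on affected, effect on
affecting], compared against applying the one-way model twice.

## Evaluation

The 80/20 split is stratified by sign by default (stabilizes MCC under the
~3:1 negative:positive imbalance); a plain random split is available.  The
default split treats A→B and B→A as independent records, so reciprocal
leakage between train and test is possible; a pair-grouped split option is
provided for users who want to exclude it.  NRMSE = RMSE / population SD
(ddof=0) of the observed test effects, so the test-mean predictor scores
exactly 1.  MCC with a zero denominator is reported as 0 with a warning.
ROC-AUC is reported only for families that expose scores.

Leave-one-out ablations hold out every record involving one species (or
one carbon) and train three feature variants on the rest: all features
("no coculture"), without `mono_affected`/`mono_affecting`/`metab_dist`
("no monoculture"), and phylogenetic PCs only.  A hard leakage guard
asserts that no training row references the held-out unit.  For a held-out
carbon the carbon-PC space is refit without it and its profile embedded by
projection.  The full-information reference is the ordinary split model
scored on the held-out unit's records inside the global test split.  LOO
fits reuse the globally tuned hyperparameters (re-tuning per held-out unit
is a flag); this keeps 60-120 fits per axis tractable and matches how a
practitioner would deploy one tuned model.

## Interpretation

Attributions are interventional Shapley values: a coalition's value is the
model's expected output with coalition features set to the explained row
and the rest drawn from a seeded background sample of training rows (100
rows by default).  Exact enumeration is available up to 12 features;
otherwise seeded permutation sampling is used, whose telescoping sums make
local accuracy (base + sum of attributions = prediction) exact by
construction; it is checked against `tol` regardless.  The implementation
is model-agnostic on purpose — it touches only `predict`, never tree
internals — so every model family and both naive models with scores can be
attributed identically.

The maximal information coefficient (MIC) quantifies dependence between
reciprocal effects: mutual information maximized over axis-aligned grids
with at most B(n) = n^0.6 cells (floored at 4 so the 2x2 grid is always
admissible), normalized by log of the smaller grid dimension.  The
standard heuristic equipartitions one axis and optimizes the other by
dynamic programming over clumps (candidate boundaries capped at c*k with
c = 15), in both orientations; the DP core is numba-compiled.  Screens
with more than 2,000 reciprocal pairs are subsampled deterministically
(the grid budget grows with n^0.6 and dominates runtime).  An exhaustive
mode enumerating every admissible grid exists for n <= 12 and serves as an
oracle in the tests.  MIC depends on the data only through value order and
is therefore invariant to strictly monotone transformations.

## The synthetic screen

The generator is phenomenological — no consumer-resource or genome-scale
simulation — and plants exactly the statistical regularities the analysis
relies on, so that every pipeline stage is testable without any download.

- **Phylogeny**: a random ultrametric tree; each of 2 clades is a random
  coalescent with tip merge heights below 0.45 and all clades join at the
  root (height 1), so within-clade patristic distances (< 0.9) are always
  smaller than between-clade distances (= 2).
- **Monoculture yields** (log scale): mean 1.0 + species intercept
  (sd 0.3) + carbon intercept (sd 0.15) + sd-0.6 noise that mixes a
  phylogenetically correlated component (Ornstein-Uhlenbeck-style kernel
  K = exp(-d/0.5) across species, drawn per carbon) with iid noise at
  strength `yield_phylo_corr` (default 0.7).  Close species thus have
  similar growth profiles; yields are log-normal and strictly positive.
- **Effects**: latent effect = intercept + beta_affected * z(log mono of
  affected) + beta_affecting * z(log mono of affecting) + conserved + iid
  noise, where z is per-carbon standardization (making the betas
  comparable across carbons), beta_affected = -0.8 (species that grow well
  alone are inhibited more), beta_affecting = +0.2, and the conserved
  component (sd 0.35) has separable covariance K[A,A'] x K[B,B'] per
  carbon: phylogenetically close species both exert and receive similar
  effects.  The kernel is continuous in distance rather than shared
  discretely within a clade, because the copy-model analyses measure a
  graded error-versus-distance trend on both the affected and the
  affecting slot of a record; a clade-level step component would plant
  neither.  Idiosyncratic noise sd is 0.35.  The intercept is calibrated
  by bisection so the realized negative-sign fraction hits the target
  (default 0.76) — exactly achievable for any continuous effect
  distribution; a fully constant distribution (degenerate configs) pins
  effects at zero with a warning instead of erroring.
- **Replicates and missingness**: coculture yield of the affected species
  = its monoculture yield x exp(effect), and each replicate is perturbed
  by mean-one multiplicative log-normal noise with CV 0.1; 7% of directed
  pair x carbon combinations are deleted uniformly at random.  The
  generator emits a replicate-level growth table that flows through the
  real replicate filter and effect computation, so with CV 0 the recovered
  effects equal the latent ones exactly.

What the generator does *not* emulate: structured missingness (real
dropouts cluster by species and carbon), replicate outliers, measurement
floor/saturation, and any mechanistic link between carbon chemistry and
growth.  Passing tests therefore demonstrate that the pipeline recovers
planted structure of the kind the analysis assumes — not that the models
would reach any particular accuracy on real screens.

## Problem sizes and numerical choices

The analysis scripts and the acceptance checks run the default conditions
(20 species x 40 carbons, ~14,000 directed effects) with a search budget
of 50 draws and LOO fits reusing the tuned hyperparameters; attribution
uses 120-150 test rows, 20-25 permutations and a 25-30 row background.
These sizes were chosen so a full sweep runs on a laptop core in minutes;
budgets and sizes are flags everywhere.  Determinism: every stochastic
step takes a seed derived from the experiment seed via fixed
`SeedSequence` spawn keys (stage counter), XGBoost runs single-threaded
with `tree_method="hist"`, and CSVs are written with fixed float formats —
re-running a config byte-reproduces the metrics tables.  Dataset CSVs use
the `%.17g` format and round-trip parsing so serialization is bit-exact.

## Known limitations

- The copy models and ablations assume every species appears in the
  monoculture table; fully unobserved species are only reachable through
  the phylogenetic-copy path.
- The MIC heuristic is a lower bound on the exhaustive grid search (it
  scans a subset of admissible grids); the exact mode is exponential and
  capped at n = 12.
- Sampling Shapley variance grows with feature correlation; the default
  permutation count targets rank stability of the top features, not tight
  per-row values.
- The threshold and copy models report no ROC-AUC (no graded scores).
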