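# Methods

## Molecular graphs and edge partitions

All descriptors operate on the hydrogen-suppressed simple graph of a
molecule: heavy atoms are vertices, bonds are edges.  Bond order,
aromaticity, formal charge and metal coordination are ignored — every
bond is one edge and degrees are taken in this skeleton.  This is the
only convention under which the Oxaliplatin reference partition
(a platinum complex) is reproducible, and it is the convention the
descriptor formulas assume.  Disconnected graphs are accepted with a
warning rather than rejected: every index is edge-local, so
connectivity is never used.  Isolated atoms and self-loops are invalid.

Because each index weight φ depends on an edge only through its
endpoint degrees, a graph enters the computation only through its edge
partition {n_ij}: the counts of edges with degree pair (i, j), i ≤ j.
Partitions can therefore be supplied directly (CSV `du,dv,count`),
which is how printed literature values are entered without
reconstructing structures.

## Descriptors

Ten degree-based weights are implemented (ABC, F, GA, H, ISI, M1, M2,
S, SO, R).  The entropy of weight φ is the Shannon entropy of the
distribution p_e = φ_e / T over edges, computed in O(#cells) as
ln T − (1/T) Σ n_ij φ ln φ with **natural logarithms**; the base is
fixed by the reference value Ent_F(Oxaliplatin) = 2.7843, which only
ln reproduces.  Agreement with the explicit per-edge Shannon form is a
tested invariant (1e−12), not an implementation path.

Degenerate case: the ABC weight is 0 on a (1,1) edge (isolated
two-atom component).  The entropy term φ ln φ is extended by continuity
to 0 and a warning is raised; a partition whose *total* ABC weight is
zero has no defined entropy and raises an error.

Values are held at full floating precision; the 4-decimal rounding
conventional in published tables is applied only at serialization.

Known reference-data notes, retained verbatim in the packaged fixtures
rather than corrected: the published GA total for Oxaliplatin (16.3826)
differs from the formula value 16.3821 (its entropy 2.8323 reproduces
regardless); the Ent_GA entries for Carboplatin (3.3295) and
Fluorouracil (2.888) exceed the ln m bound any plausible structure
permits and are flagged in `datasets.GA_ANOMALIES` — fits through that
column are correspondingly off and excluded from reference checks.

## Regression families and statistics

Five families in one descriptor x: polynomial of degree 1–3,
logarithmic (y on ln x), exponential (ln y on x, reported as
y = a·e^{b1 x}).  All are ordinary least squares; for transformed
families every statistic (r, r², SE, F, p) is reported on the
transformed scale, the convention of classic curve-estimation software
and of the published tables this package reproduces.  The exponential
family is read as y = a·exp(b1·x) even where the literature writes
y = a·b^x: only that reading reproduces the published a = 32.1 with
b1 = 0.8 and r² = 0.808 for molecular weight on Ent_ABC.

With k slope coefficients and n points: r² = 1 − SSE/SST;
r = sign(b1)·√r² for single-predictor families and +√r² for
polynomials; adjusted R² = 1 − (1−r²)(n−1)/(n−k−1);
SE = √(SSE/(n−k−1)); F = (r²/k)/((1−r²)/(n−k−1)) with p the upper tail
of F(k, n−k−1); coefficient CIs use t(0.975, n−k−1).  The standardized
beta b1·sd(x)/sd(y) is reported for single-predictor families only.
p-values are exposed raw — no multiple-testing correction is applied,
matching the source analysis.

### Collinearity guard

On a narrow positive descriptor range (entropies of drug-sized
molecules span roughly 2.2–4.1) the cubic design {x, x², x³} is nearly
singular: the tolerance of x² given the other terms is ~3e−5 for the
packaged study data.  Curve-estimation software conventionally refuses
to enter a term whose entry would push any in-model term's tolerance
below a minimum (typically 1e−4), and published cubic QSPR tables
reflect that: they are fits of {1, x², x³} with the linear term
excluded (verified: this reproduces the published a, b2, b3, r², SE
and F exactly, with F at k = 2).

`fit_model(..., collinearity_tol=1e-4)` reproduces the convention:
polynomial terms are offered highest-degree-first and a candidate is
skipped if the resulting minimum tolerance would fall below the
threshold.  The default is `None` — plain full-design OLS — so that the
fitter satisfies the textbook properties (exact recovery of noiseless
polynomial truth, monotone r² nesting, exact CI coverage) on
well-conditioned data.  Report generation (`fit_report`, the `fit` and
`report` CLI commands) enables the guard by default to mirror the
published tables.  For a guarded fit, k is the number of terms actually
entered, `FitResult.excluded` lists the refused terms, and the
corresponding `b` slots are `None` (treated as 0 when predicting).

One consequence is deliberate: published "cubic" equations that carry a
b1 term alongside the {x², x³} coefficients cannot all have come from
one least-squares fit.  For external validation such printed equations
are taken verbatim as first-class models rather than re-derived, so
the validation tables reproduce independently of any fitting
convention.

### Model selection

`best_model` picks the family with the highest r² per
(descriptor, property), breaking ties toward fewer parameters.  On the
packaged study data the cubic family wins for molecular weight,
complexity, molar volume, polarizability and molar refractivity;
topological surface area and density stay below r² = 0.4 in every
family and are flagged not significant for prediction.

## External validation

`predict` evaluates a family equation at a descriptor value;
`validation_table` crosses a set of models (fitted or printed) with a
held-out descriptor table and optional experimental values, reporting
calculated values, experimental values and residuals
(experimental − calculated).  Rounding to 2 decimals happens only at
serialization.  `residual_table` returns training-set residuals (on the
log scale for the exponential family) with mean residual and RMSE; for
any intercept OLS fit the mean is 0 and RMSE = SE·√((n−k−1)/n).

## Synthetic data

`gen_graph` grows a degree-capped random tree (each new atom attaches
uniformly to an atom with free valence) and then attempts one ring
closure per atom, each with the configured probability, between a
rejection-sampled non-adjacent pair with free valence.  Graphs are
connected and simple with degrees in [1, cap]; with cap 4 the degree
mix resembles organic skeletons.  Not modelled: elements, valence
rules, bond orders, realistic ring-size statistics — so passing tests
demonstrate correctness of the *pipeline*, not chemical realism of the
generator.

`gen_dataset` computes all twenty descriptor columns per compound and
simulates y = family(h; coefficients) + N(0, σ²) on the chosen
descriptor h.  Defaults are the study conditions: 14 compounds, 8–40
atoms (the size span of the study drugs), degree cap 4, ring
probability 0.3, cubic truth with the published molecular-weight
coefficients (323.0, 18.4, −75.9, 24.7) on Ent_ABC, and σ = 40,
comparable to the study's cubic residual scale (~66).  Determinism: one
integer seed; compound i draws from `default_rng([seed, i])`, so a
compound's data is independent of how many compounds are generated.

Parameter-recovery tests fit the *unguarded* cubic: OLS confidence
intervals have exact nominal coverage whatever the design conditioning,
whereas the guard (by design) changes the model on near-collinear
designs.  The Monte-Carlo coverage check uses 200 replicates at n = 50
with σ = 4 (≈1% of the response range), a size chosen to finish in
seconds while leaving binomial noise on the coverage estimate well
inside the asserted 90–99.5% band.

## ML stage

Preprocessing standardizes each feature to mean 0, sd 1 and drops
zero-variance columns with a warning.  Feature selection is recursive
feature elimination under a linear model (returning ranked names) or
PCA projection (returning scores and explained-variance ratios).
`cv_evaluate` runs seeded, shuffled k-fold cross-validation for Random
Forest (200 trees), RBF-kernel SVR (C = 10) and gradient boosting at
scikit-learn defaults otherwise, reporting per-fold and mean MSE, RMSE
and R².  No published numbers exist for this stage, so its guarantees
are property-based: determinism under seed, and cross-validated R² on
real signal strictly exceeding a permuted-target baseline.  With only
14 real compounds any real-data ML output is labelled exploratory.

## Problem sizes in the default test run

Graph-property tests use 100 random graphs of 4–30 atoms; oracle
agreement is asserted to 1e−12.  Regression oracles run on 10–20 point
random datasets; the coverage study is 200 × 50 compounds; ML checks
use 100–200 synthetic compounds.  These sizes keep the whole suite
under a minute on one CPU while leaving each statistical assertion far
from its decision boundary.

## Known limitations

- Descriptors are degree-based only; distance-based or vertex-weighted
  indices (Wiener, eccentricity, reverse-degree variants) are out of
  scope.
- Only single-descriptor curvilinear models are fitted; no
  multi-descriptor linear models, regularization or robust regression.
- SMILES perception (aromaticity, tautomers) follows RDKit; structures
  regenerated from SMILES may legitimately differ from literature
  descriptor tables if the original perception differed, which is why
  the study tables ship as fixtures.
- The collinearity guard reproduces a software convention, not a
  statistical optimum; for prediction purposes the full cubic (guard
  off) generally has higher in-sample r².
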