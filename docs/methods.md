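# Methods

This note documents the models implemented in `greenaccess`, the
choices made where the method leaves room, and what the synthetic data
can and cannot establish.

## Gaussian-based 2SFCA accessibility

Park capacity is area divided by a per-capita area standard by park
type (comprehensive 60, theme 50, community 40, amusement 30
m²/person, following the Chinese park-design code's classes I–IV).
Both catchment steps use the same travel-time threshold t₀, 15 minutes
by default for walking *and* driving — the "15-minute life circle"
convention — with a per-mode override in the configuration.

Numerical conventions:

* **Travel time to a park is the minimum over its entrances.**
  Entrances are the physical access points; a large park is as close
  as its nearest gate.
* **Empty catchments.** A park with no populated cell within t₀ has an
  undefined supply–demand ratio; we set R_j = 0, flag the park as
  unreached, and warn. This deliberately breaks the capacity-
  conservation identity Σ P·A = Σ S, which therefore only holds (and
  is only tested) when no park is flagged.
* **Zero-population cells** keep their A_i (they cost nothing in step
  1); zone aggregation and Gini handle them per their own rules.
* **Zone means** default to the simple (unweighted) mean over member
  cells; a population-weighted mean is available by configuration.
* The decay weight is exactly 0 at t = t₀ and the weight function is
  continuous there, so catchment membership at the boundary is
  numerically irrelevant.

## Lorenz/Gini equity

Units are demand cells. The service mass of a cell defaults to
A_i·P_i, so "perfect equality" means identical *per-capita*
accessibility; the alternative convention (A_i alone, ignoring how
many people share it) is available as `service_mass="access"`. Units
are sorted ascending by per-capita service before cumulation — the
standard Lorenz construction, which guarantees Y_k ≤ X_k — and
zero-population cells are excluded because their per-capita service is
undefined. The trapezoid formula G₁ = 1 − Σ(X_k − X_{k−1})(Y_k +
Y_{k−1}) is algebraically identical to the population-weighted
mean-absolute-difference Gini; the test suite verifies the identity to
1e−9 against an independent implementation. Tiny negative round-off is
clipped to 0.

## Gradient-boosted regression trees

The engine is written from first principles (external libraries appear
only as cross-checks in tests):

* **Initialisation** f₀ = mean(y), the squared-loss minimiser.
* **Per iteration** a CART tree is fitted to the residuals (the
  negative gradient of squared loss); leaf values are residual means,
  which is the closed-form line-search solution for this loss, so no
  separate step-length search is needed.
* **Update** f_m = f_{m−1} + ξ·h_m with ξ ∈ (0, 1].
* **Splits** maximise squared-error reduction
  sum_L²/n_L + sum_R²/n_R − sum²/n, searched over midpoints of
  consecutive distinct sorted values. Ties break to the lowest feature
  index, then the lowest threshold, making fits bit-reproducible and
  row-order invariant. Gains below 1e−12 of the parent SSE count as
  zero (guards float noise on constant responses).
* **Defaults**: M = 5000 trees, ξ = 0.001, quintuple (k = 5)
  cross-validation; tree depth 3 and minimum leaf size 5 (unstated in
  common descriptions of this configuration; chosen as standard
  boosting practice and configurable). No stochastic subsampling.
* **Cross-validation** shuffles rows once with the configured seed and
  cuts contiguous folds; validation R² uses the held-out fold's own
  mean as baseline and can legitimately be negative on uninformative
  data.
* **Importance** is the per-feature sum of split improvements across
  all trees, normalised to percentages summing to 100. A model with no
  splits returns zeros with a warning. Importance is computed from the
  full-data fit; cross-validation quality is reported separately.

Test- and desk-scale runs use reduced settings (typically M = 300,
ξ = 0.05, or M ≈ 40–100 in the fastest paths); with an effective
learning mass M·ξ of the same order, the fits are statistically
comparable and run in seconds on one CPU. The configuration defaults
remain the full-scale values above.

## Partial dependence and smoothing

PD(v) is the mean prediction with one feature clamped to v over a grid
of 50 points confined to the feature's 1st–99th percentile range —
tails are where clamped averages are least reliable. The raw curve is
smoothed by a locally weighted linear regression (tricube kernel over
a span of 0.5 of the grid by default) whose weights are multiplied by
the per-bin sample density, down-weighting estimates supported by few
observations. A custom smoother is used rather than a stock lowess
because stock implementations do not accept those density weights;
local *linear* fitting reproduces straight-line inputs exactly, which
the tests rely on. Key variables are those contributing strictly more
than 7 % of relative importance.

The OLS baseline is an ordinary least-squares fit (via statsmodels) of
the same response on all 15 predictors, reported alongside the boosted
model's cross-validated R². On any nonlinear generative relationship
the boosted model's CV R² exceeds the OLS R²; on purely linear data
the two agree closely.

## Scenario classification

Streets are labelled by crossing mean accessibility with the street
Gini: high accessibility means strictly above 10 (walking) or 1
(driving); low equity means Gini strictly above 0.5. Values exactly at
a cutoff are classed low-accessibility / high-equity because the rules
are strict inequalities. The labels partition the streets by
construction.

## Synthetic city: what it emulates, and what it does not

The generator emulates the *structure* of a central-city study area:

* a square grid of 500 m cells (default 30×30 = 900 cells);
* population allocated by a mixture of a uniform floor and a few
  Gaussian "city-core" kernels (default 3 cores, bandwidth one sixth
  of the span, clustering weight 4), then apportioned by largest
  remainder so cell populations are integers summing *exactly* to the
  configured total (default 1.65 million ≈ 1 800 per cell, a typical
  central-city density at this grid size);
* four park types whose default counts (5/4/30/49) follow the observed
  36:31:236:395 proportions of a large park system, scaled to desk
  size; areas drawn log-uniformly from type ranges (comprehensive
  0.1–1 km² down to amusement 2 000–30 000 m²); 1–4 entrances on the
  footprint-circle boundary;
* travel times as straight-line distance to the nearest entrance times
  a detour factor of 1.2, at 5 km/h walking and 30 km/h driving
  (typical planning values; all configurable);
* streets as 5×5-cell tiles and districts as 2×2-street tiles.

It does **not** emulate road-network routing, river/terrain geography,
building-level population apportionment, or administrative boundary
shapes. Consequently, passing tests demonstrate the correctness and
statistical behaviour of the *methods* — conservation, equivalences,
effect recovery — not any empirical claim about a real city. Reported
real-city magnitudes (district Ginis, specific importance percentages,
specific thresholds such as a population-density plateau) depend on
non-public administrative data and are outside what the synthetic
conditions can or should reproduce; the walking-much-less-equal-than-
driving ordering does emerge from the synthetic geometry.

The street-level feature table draws the 15 predictors from marginals
calibrated to published street-level descriptive statistics (lognormal
for the skewed positive variables, clipped normal for bounded ones).
In pipeline runs the four predictors that are derivable from the
generated city (PCAR, PTN, SAD, PD) are computed from its geometry
instead of drawn. For effect-recovery experiments the response is a
configurable additive function of the predictors — linear, ramp-then-
plateau, Gaussian peak, or null per predictor — plus Gaussian noise,
and the noiseless ground truth is stored alongside, so that importance
ranking and partial-dependence threshold detection can be validated
against a known truth (e.g. a plateau in the residential-land share PR
at 0.35 with effect size 2 and noise s.d. 0.1 on 500 streets).

## Pipeline determinism

One integer seed governs a run; stage streams are derived with fixed
offsets (city = seed, features = seed + 1, boosting = seed + 2) so
changing boosting settings never perturbs the generated city. No
artefact embeds a timestamp, so identically configured runs are
byte-identical — a property the acceptance suite checks file by file.

## Known limitations

* Straight-line-with-detour travel times understate variance relative
  to true network routing, especially for driving.
* The smoother's span and the PD grid size are pragmatic defaults, not
  optimised choices; very sharp generative thresholds are broadened by
  roughly one smoothing window.
* The boosting engine is exact but quadratic-free and histogram-free;
  it is intended for street-scale tables (hundreds to thousands of
  rows), not large-scale machine learning.
* Pseudo-parks anchored at road intersections (sometimes used to
  represent small roadside green spaces) have no defined capacity and
  are not modelled; real-data users must supply areas for every park.
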