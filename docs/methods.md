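# Methods

## Scope and data

The package analyzes a three-factor designed extraction experiment: pH
(4–6), enzyme addition (1.5–4.5 %) and ultrasonic time (40–80 min), with
extraction yield (%) as the response. The packaged `bbd17` fixture holds
the reference study's printed 17-run Box-Behnken design (12 edge runs plus
5 center replicates) with observed and model-predicted yields; the
`single_factor` fixture holds the handful of univariate screening yields
quoted in its prose. The reference publication prints two contradictory
factor-level tables; the fixture uses the levels of the run table, because
the printed yields and predictions belong to those runs (the alternative
levels are retained in the fixture annotations).

## Response-surface model

The full second-order polynomial in coded units is fit by ordinary least
squares on the 10-column model matrix (1, A, B, C, AB, AC, BC, A², B², C²).
For the Box-Behnken geometry the linear and interaction columns are
mutually orthogonal, so their Type III sums of squares reduce to the closed
forms 8b² and 4b²; the intercept/quadratic block is non-orthogonal and the
general form SS = b²/c_jj (c_jj the coefficient's diagonal entry of
(X'X)⁻¹) is used throughout. Pure error is the within-group sum of squares
over replicated design points; lack of fit is the remainder of the
residual. F statistics test each term against the residual mean square, and
lack of fit against pure error, with upper-tail p values from the F
distribution. Significance marks follow the source table's convention
(* at p < 0.05, *** at p < 0.001). A residual sum of squares below 1e−12 of
the total is treated as a perfect fit and the F statistics are flagged
infinite rather than reported as enormous finite numbers.

Diagnostics are the hat-matrix leverages, internally studentized residuals,
Cook's distances with p = 10 model terms, and normal-probability pairs
using Blom plotting positions ((i − 0.375)/(n + 0.25)); the source names no
plotting convention, so the conventional choice is stated here.

Surface optimization solves ∇Y = 0 directly. If the stationary point lies
in the box and the Hessian is negative definite it is returned as the
maximizer; otherwise (saddle, ridge, singular Hessian, or exterior
stationary point) a deterministic coarse-to-fine grid refinement (21 nodes
per axis, shrinking to a 10⁻³ coded-unit resolution) locates the boxed
maximum, so results are bit-reproducible without a stochastic optimizer.

### Documented misprints in the reference equation

The fitted coefficients reproduce the reference's printed predicted-yield
column at all 17 runs to 3 decimals and its entire ANOVA to the printed
precision. The printed regression equation itself, however, shows
+0.730 AB and +1.660 AC where the fit gives −0.730 and −1.660, and 3.511 B²
where the fit gives 3.551. The ANOVA confirms the fit, not the equation:
SS(AB) = 2.13 = 4·0.730² is sign-blind, but the predicted column is not,
and SS(B²) = 53.09 equals 3.551²/0.2375, not 3.511²/0.2375. These are
treated as typographical errors. Similarly, the printed R² of 0.8358 is not
the ratio of the printed ANOVA sums (614.36/738.95 = 0.8314); the package
returns the SS-ratio definition. The reference's printed surface optimum
(pH 5.997, enzyme 3.825 %, time 79.895 min, 27.95 %) is not the maximizer
of its own fitted surface (stationary point at coded (0.267, 0.243, 0.177),
predicted 28.52 %); it was likely produced by undocumented vendor-software
settings and is recorded in the fixture annotations, not emulated.

## Neural surrogate

Topology 3–h–1 with tanh hidden units and a linear output; h defaults to
10, consistent with the empirical sizing rule round(sqrt(n_in + n_out)) + a
at a = 8. (The source prints this rule in a dimensionally impossible form;
the square-root reading is the standard one in this literature and is the
only one that yields the stated 10 neurons.) Inputs and the output are
min-max scaled to [−1, 1].

Training is full-batch gradient descent with momentum on the scaled-output
MSE, from seeded uniform(−0.5, 0.5) initial weights. The data are split
70/15/15 into train/validation/test by a seeded permutation; validation and
test sizes are the fractions rounded to the nearest integer with train
taking the remainder (33 → 23/5/5, 17 → 11/3/3). Early stopping monitors
validation MSE each epoch and restores the best-epoch weights after
`patience` epochs without improvement.

Defaults are learning rate 0.1, momentum 0.9, patience 300, max 8000
epochs. The patience is deliberately large: with plain full-batch descent
the validation error on a 3-point split fluctuates for hundreds of epochs,
and small patience values halt training before the network has fit anything
(verified to leave overall correlations near 0.3). Training the 3-10-1 net
to stop takes well under a second, so the large budget costs nothing.

A 17-run experiment is a hard regime for a 51-parameter surrogate: with
70/15/15 splitting, the held-out runs include design corners the network
has never seen and center replicates whose observed yields span 23.3–31 %
at identical inputs. Overall prediction-observation correlations around
0.86 are the realistic ceiling here; correlations above 0.9 — the regime
the reference reports for its (unpublished) 33-run dataset — are reached on
the synthetic 33-run analogue, and this is how the property is tested.
Analysis drivers that need one network select among 10 seeded restarts by
pooled train+validation MSE; the test subset never participates in
selection.

## Genetic algorithm

Real-coded, since the decision variables are continuous lab conditions.
Per generation: elitist carry-over (default 1), size-2 tournament
selection, arithmetic blend crossover with a per-gene uniform mixing weight
(probability 0.8), and per-gene uniform-reset mutation (probability 0.1),
all within the actual-unit factor box. Population 50, budget 600
generations (an optional stagnation patience can stop earlier). Elitism
makes the best-fitness trace non-decreasing, which is asserted as an
invariant. Non-finite fitness values cause the individual to be resampled
uniformly and counted; a generation that cannot produce any finite-fitness
individual is an error. All draws come from one seeded generator, so runs
are reproducible. The GA-BP pipeline injects the experiment's input rows
into generation 0 — the surrogate is most trustworthy near its training
data — and samples the rest uniformly.

On the fitted quadratic (a known surface), the GA's 600-generation best is
required to match the deterministic grid/analytic optimum within 0.05
yield-%; this stands in for the reference's initialization-dependent GA-BP
optimum, which no fixed seed can reproduce.

## Comparison metrics

R² = 1 − SSE/SST, RMSE = sqrt(SSE/n), and AAD in two conventions: absolute
(mean |o − p|, yield-% units, the default) and relative-% (mean of
100·|o − p|/o), because the source never writes its AAD formula and the
absolute convention is the one closest to its printed magnitudes.
Validation records carry the squared error and relative error of one
confirmation run per model; the reference's GA-BP row is confirmed exactly
by (28.42 − 28.35)² = 0.0049, while its other two rows print squared errors
that are not the square of their own predicted−actual differences (0.3410
vs 0.3481, 0.1616 vs 0.1681) and are recomputed, not emulated. Its Table of
R²/RMSE/AAD values was computed on the unpublished 33-run set and is kept
as annotation only. Models are ranked by (R² descending, RMSE ascending).

## Synthetic data

`SurfaceTruth` holds 10 true coded-unit coefficients, a homoscedastic
Gaussian noise SD, and the factor definitions. `generate` adds i.i.d.
noise to the true surface at each design point, with independent draws at
replicated centers — exactly the error structure the pure-error ANOVA
assumes, and the only noise model derivable from the replicate-based
analysis. The default study conditions take the fitted reference surface as
truth and noise SD sqrt(9.52) ≈ 3.08, the square root of the fixture's
pure-error mean square. `generate_mixed33` appends to the 17-run BBD a
16-run univariate block (4 pH levels, 5 enzyme levels, 5 time levels swept
through the center, plus 2 extra center replicates), emulating the
reference's 33-group mixed dataset, whose non-BBD rows were never
published; no claim is made that the synthetic rows match the originals.
Gaussian noise can produce physically impossible negative yields at the
low-yield corner (true value 8.6, SD 3.08); these are warned about but kept
unclipped so that refits remain unbiased.

What passing simulation tests show: unbiased coefficient recovery, correct
t-interval coverage, and an unbiased pure-error mean square under the
assumed error model. What they do not show: robustness to heteroscedastic
or non-Gaussian noise, factor-setting error, or model misspecification —
none of which the 17-run reference experiment can identify either.

## Numerical choices and limitations

- OLS via `numpy.linalg.lstsq`; rank-deficient designs raise an error
  naming the collinear columns (from the SVD null space). The independent
  cross-checks in the test suite use statsmodels.
- Problem sizes throughout (17–33 runs, 200 simulation replicates, 500
  pure-error replicates, 600 GA generations) keep the entire suite and all
  drivers in the tens of seconds while leaving Monte-Carlo error well below
  the asserted tolerances.
- The split-size rounding rule cannot simultaneously produce 13/2/2 on 17
  points and 23/5/5 on 33 points; nearest-integer rounding (giving 11/3/3
  and 23/5/5) was chosen to match the 33-group description.
- Coded-unit coding assumes the center is the midpoint of (low, high);
  asymmetric printed levels are accepted with a warning.
- The CLI derives every stage seed deterministically from one master seed;
  artifacts contain no timestamps, so repeated runs are byte-identical.
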