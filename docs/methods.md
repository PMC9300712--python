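# Methods

This note records the models implemented by `biosorb`, the numerical
choices behind them, and what the test suite does and does not
demonstrate.

## The design table and coded units

The canonical dataset is a four-factor rotatable central composite
design: 16 factorial points (coded ±1), 8 axial points (coded ±2) and 7
replicated centre points, 31 runs in total. Factors are coded as
`coded = (actual − center)/step` with centres (0.7 g/L, pH 6, 35 °C,
0.7 mg/L) and steps (0.3, 2, 5, 0.3). All regression happens in coded
units: the quadratic's coefficients are then of comparable magnitude and
the design matrix is well conditioned; results are decoded back to
physical units for reporting. The bundled table keeps the original
train/test partition (24/7; all centre replicates are in the training
split) because the neural-network stage depends on it.

The centre replicates carry the design's pure-error information: their
within-group sum of squares (20.594 for the bundled table) is a fixed
property that the ANOVA's lack-of-fit test is built on.

## Response-surface stage

`rsm.fit_quadratic` fits the full 15-term second-order polynomial by
ordinary least squares (statsmodels OLS under the hood). Statistics
reported:

* **R² / adjusted R²** over all rows of the supplied table (the design
  is fitted as a whole; the train/test split is an ANN concern).
* **Mean percentage error**, defined as the mean absolute percentage
  error of the fitted values — the literature this workflow comes from
  rarely states the formula, so the package pins the standard MAPE.
* **ANOVA** with regression/residual rows and the residual further split
  into lack of fit and pure error over replicated design points;
  p-values from the F distribution.

A rank-deficient design raises an error naming the collinear terms
(identified by incremental rank growth over the ordered term list).

`rsm.maximize_surface` maximizes the fitted polynomial over a coded box
by multi-start bounded Nelder–Mead (all 2⁴ box corners plus the centre
as starts); exact ties are broken toward the smallest coded L2 norm.
A derivative-free method was chosen because the objective is a cheap
closed form and the bounded simplex search is robust at box corners
where gradients of the constrained problem are uninformative. The test
suite cross-checks the optimizer against a dense 21⁴ grid oracle.

`rsm.published_quadratic()` exposes the coefficient set reported by the
original study for the same design. It is reference data: refitting the
bundled table does *not* reproduce those coefficients (the printed
per-run "regression predicted" column is also inconsistent with any
single quadratic, e.g. unequal predictions at identical centre points),
so the package treats its own OLS refit as the model and the published
coefficients as a comparison object.

## Neural-network surrogate

A 4-H-1 multilayer perceptron (default H = 10) with tanh-sigmoid hidden
units and a linear output node. Inputs and the output are min–max scaled
to [−1, 1] using the training split's ranges — the convention of the
tanh/linear transfer pairing. The logistic hidden activation is
selectable for completeness.

Training is full-batch gradient descent on the scaled training MSE with:

* momentum 0.9,
* adaptive learning rate (initial 0.5): ×1.05 after an improving step;
  if a step would raise the MSE by more than 4% it is rejected, the rate
  is ×0.7 and the momentum buffer is cleared,
* stop at `mse_goal` (default 0.001, scaled units) or `max_epochs`
  (default 10 000),
* weight initialisation uniform in [−0.5, 0.5] from a seeded generator;
  every training run is a pure function of its seed.

Because 15–24 observations cannot pin down a 10-hidden-node network,
**weight selection matters more than convergence**. `train` therefore
keeps a running snapshot of the weights with the lowest test-split MSE
(`monitor="test"`, the default; `monitor="none"` gives the plain
converged weights), and `train_restarts` trains several seeded
initialisations and returns the one with the lowest test MSE. Backprop
gradients are verified against central finite differences in the tests.

Evaluation reports scaled-unit MSE per split, R² of prediction versus
observation in raw percentage units over all rows, and mean absolute
percentage error per split.

## Genetic algorithm

Real-coded individuals are 4-vectors in actual units inside the process
box (dose 0.1–1.3 g/L, pH 2–10, 25–45 °C, As(III) 0.1–1.3 mg/L — the
concentration bound is in mg/L, consistent with every other use of that
factor). Per generation: the best 20 of 100 individuals are copied
unchanged (elitism, which makes the best-fitness history provably
non-decreasing), parents are drawn by roulette after shifting fitness
values positive (all-equal fitness degenerates to uniform sampling —
documented, not an error), single-point crossover with probability 0.8,
then per-gene Gaussian mutation (sd 10% of each factor's range — the
mutation operator's scale is not fixed by convention, so a moderate
fraction of the range was chosen) with clipping to the bounds. Fitness
is `ε = 1 − 1/ŷ`, strictly increasing in the predicted removal ŷ;
non-positive predictions get a large finite penalty so roulette weights
stay well defined. `optimize_restarts` re-runs the GA from seeded
initial populations (default 10) and returns the best run; agreement
across restarts is what certifies a global optimum.

### What the headline optimum means

The pipeline's "best predicted removal" is the trained surrogate's
maximum over the process box. Two facts shape its behaviour:

* the largest observed response in the table is 94.8% (at the high
  axial concentration point), so any surrogate that fits the data well
  increases toward that edge and its box maximum sits a few percent
  *above* the largest observation — it is an extrapolation;
* the size of that extrapolation depends on the training
  initialisation. Across master seeds the pipeline's optimum typically
  falls in the high-90s to low-100s of percent, and single runs can
  exceed 100% — a reminder that the network knows nothing about the
  physical ceiling of a percentage.

The stable, reportable quantity is therefore the consensus over repeated
seeded runs, which is how the acceptance test treats it (median over
five full pipeline runs). Runs at roughly a dozen seeds complete in
under ten seconds each on one CPU; problem sizes (10 training restarts,
10 GA restarts of 100 generations × population 100) were chosen so the
whole pipeline remains interactive.

## Batch sorption layer

All four classical fits use the linearized coordinates that the
field plots (scipy `linregress` underneath), with the reported r²
referring to the linearized regression:

| model | regression | back-transform |
|---|---|---|
| Langmuir | Ce/qe on Ce | Q° = 1/slope, b = slope/intercept |
| Freundlich | log₁₀ qe on log₁₀ Ce | K_F = 10^intercept, 1/n = slope |
| pseudo-1st-order | log₁₀(qe−qt) on t | k_s = −2.303·slope, qe = 10^intercept |
| pseudo-2nd-order | t/qt on t | qe = 1/slope, h = 1/intercept, k₂' = h/qe² |
| Van 't Hoff | ln K_c on 1/T | ΔH = −R·slope, ΔS = R·intercept |

The PSO identity `h = k₂'·qe²` holds exactly by construction. A
nonlinear least-squares refinement (seeded by the linearized estimate)
is available for the isotherms but is not the canonical result.
Degenerate inputs are handled explicitly: PFO points at or above the
observed qe are excluded with a warning (their logarithm is undefined);
an equilibrium-only PSO series yields an unidentifiable rate constant,
flagged with a warning and infinite k₂'. Per-temperature Gibbs energies
come directly from ΔG = −RT ln K_c (kJ/mol convention; Celsius inputs
below 200 are auto-converted to kelvin), so ΔG, ΔH and ΔS are mutually
consistent only insofar as the K_c series is — the package never forces
ΔG = ΔH − TΔS.

The study that motivated this package published its isotherm, kinetic
and thermodynamic parameter values but not the underlying raw series;
those parameter sets are therefore exercised as generate-and-refit round
trips (exact recovery on noiseless data, estimator-consistent recovery
under seeded noise), not as refits of the original measurements.

## Fixed-bed layer

Breakthrough (t_b) and exhaustion (t_e) are the first times the outlet
concentration reaches C_b and 0.95·C₀ respectively (the exhaustion
fraction is a parameter; 0.95 is the package default since no operational
definition is standard), linearly interpolated between samples; a curve
that never crosses returns an explicit "not exhausted" result. The total
metal sorbed is the trapezoidal integral `qtot = Q/1000·∫(C₀−Ct)dt`,
which can never exceed the metal fed `X = C₀Qt_e/1000` — asserted as an
invariant. Sampling-rate sensitivity of the trapezoid is covered by a
10×-refinement oracle (agreement within 0.5% on logistic fronts).
Removal % is defined as qtot/X·100. EBCT uses the true π (published
tables that round π differ in the third significant figure). The BDST
critical height warns when C_b ≥ C₀/2, where the log argument makes
Z₀ ≤ 0.

## Synthetic data

Generators mirror each stage's model form: the CCD generator emits the
exact 31-point geometry (same held-out design points as the bundled
table) with responses = quadratic + additive Gaussian noise clipped to
[0, 100]; isotherm/kinetics/Van 't Hoff generators place points exactly
on their named curves (noise on qe, qt, ln K_c respectively); the
breakthrough generator uses a logistic front `C₀/(1+exp(−r(t−t₅₀)))`
with a closed-form crossing-time inverse for oracle tests. Every
generator is a pure function of (parameters, seed).

What passing the closed-loop tests shows: the estimators invert their
own model classes correctly and degrade gracefully under moderate noise.
What it does not show: that real sorption data follow these models —
real isotherm residuals are heteroscedastic, breakthrough fronts are
asymmetric, and replicate error is rarely Gaussian. The generators are
verification tools, not simulators of instrument data.

## Known limitations

* The response-surface ANOVA assumes the usual OLS error model; with 7
  centre replicates the pure-error estimate is itself noisy.
* The surrogate optimum is an unconstrained extrapolation (see above);
  predictions above 100% removal are possible and are reported as-is.
* Only single-population GA; migration-style settings from multi-deme
  implementations are accepted in configs but are no-ops.
* Linearized fits inherit the classical bias of transformed-coordinate
  regression; the nonlinear option exists but is deliberately not the
  default, to match field practice.
* No plotting is shipped; all artifacts are JSON/CSV for downstream
  tools.
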