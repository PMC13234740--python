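# Methods

## Scope and model

The package optimizes a scalar extraction response — total flavonoid
content (TFC), mg of rutin-equivalent flavonoid per g of dry material —
over continuous process factors. All modelling happens in *coded* units:
each factor x is mapped to X = (x − center)/half-range so its working
range becomes [−1, 1]. The two regression models are the standard
design-of-experiments polynomials,

    first order:   Y = β0 + Σ βi Xi
    second order:  Y = β0 + Σ βi Xi + Σ βii Xi² + Σ_{i<j} βij Xi Xj

fitted by ordinary least squares. Both assume additive, homoscedastic,
independent Gaussian measurement error; the Box–Behnken center replicates
provide the pure-error estimate that the lack-of-fit test compares against
the model-form residual.

## Factors and default levels

| factor | units | center | half-range | notes |
| --- | --- | --- | --- | --- |
| solid-to-liquid ratio | mL/g | 20 | 5 | "1:20" is represented as 20.0 so the factor is continuous |
| ultrasonic time | min | 60 | 15 | screening stage only |
| ultrasonic temperature | °C | 50 | 10 | |
| ultrasonic power | W | 200 | 50 | screening stage only |
| ethanol volume fraction | % | 70 | 10 | |

The Box–Behnken levels (15/20/25 mL/g, 40/50/60 °C, 60/70/80 %) are
package defaults chosen so that the reference quadratic's stationary point
decodes exactly to the reference optimum (21.26 mL/g, 48.39 °C, 69.16 %);
they are configurable (`DesignSpace.from_dict`) and should be treated as
inferred, not measured, values. The screening stage's two-level settings
bracket the single-factor optima; by orthogonality of the Plackett–Burman
contrasts the actual settings affect decoded reporting only.

## Designs

* **Plackett–Burman (N=12)**: canonical cyclic generator row
  (+ + − + + + − − − + −), 11 shifted rows plus an all-minus row. Real
  factors take the first k generator columns; the rest are retained as
  dummy contrast columns. Run order is fixed; randomizing it changes no
  estimate.
* **Box–Behnken (k=3)**: all 12 (±1, ±1) pairs with the third factor at 0,
  plus n_center (default 5) center replicates.
* **Latin hypercube**: scipy's `qmc.LatinHypercube` (one uniform draw per
  equal-width stratum per dimension, random pairing), scaled to [−1, 1];
  no space-filling optimization is applied.

## ANOVA conventions

Term sums of squares are partial (Type III), computed as
β̂j²/[(X'X)⁻¹]jj — on the orthogonal screening and Box–Behnken columns
these coincide with sequential SS, matching what DOE packages print.
Lack-of-fit groups are rows with exactly equal coded coordinates (only the
center points replicate here). Fit statistics: R² = 1 − SSres/SStot;
adjusted R² penalizes by residual df; predicted R² uses leave-one-out
PRESS via leverages, with leverage-1 rows excluded and flagged; CV% =
100·√MSres/mean(Y); adequate precision = (max ŷ − min ŷ)/√(p·MSres/n)
with p the number of model coefficients. p-values below 1e-4 are rendered
"< 0.0001" in formatted output only; stored values stay numeric.

Pareto standardized effects are |t| = |β̂|/se(β̂); the reference limit is
the two-sided t quantile at α (0.05 → 2.45 on 6 df). The Bonferroni limit
divides α by the number of candidate effects m. For the 12-run screening
design m = 11 (all generator contrasts), which gives 4.45 on 6 df —
interpretive, since no m in 5..11 reproduces a published 4.40 exactly at
two decimals; the choice affects only the displayed guard line, never the
p-values.

## Quadratic optimization

Writing the fitted surface as Y = c + b'x + x'Ax (A symmetric, Aii = βii,
Aij = βij/2), the stationary point solves 2Ax = −b and is classified by
the eigenvalues of the Hessian 2A (all negative → maximum; |λ| < 1e-10 →
degenerate, flagged, fall back to box search). The box-constrained global
maximum over [−1,1]^k is found *exactly* by recursing over box faces: each
face pins one coordinate at a bound and leaves a lower-dimensional
quadratic, so the candidate set (interior stationary points of every face
down to the vertices) is finite and complete. This is testable against a
brute-force grid oracle to machine-level agreement, which a generic
numeric optimizer would not be. Optima are reported to 2 decimals in
actual units. Note the decoded temperature optimum is 48.39 °C while the
reference value is quoted as 48.40 — a 0.01 rounding discrepancy we
document rather than force.

## Neural-network surrogate

Topology 3-4-1: tanh hidden units, linear output, min–max normalization of
inputs and output to [−1, 1] computed on the full supplied dataset (21
free parameters). Training is damped least squares (Levenberg–Marquardt):
per epoch, solve (J'J + μI)δ = J'r on the training split; μ×10 on a
rejected step, μ÷10 on acceptance; abort on μ > 1e10. Defaults: 1000 max
epochs, goal 1e-6 (normalized training MSE), initial damping 0.01 (the
conventional "learning rate 0.01" setting — LM has no learning rate, so it
is interpreted as the initial damping), 70/15/15 train/validation/test
split (n = 51 → 36/8/7, remainder to training), early stop after 6
consecutive epochs without a new best validation MSE, returning the
best-validation weights. Weights initialize uniformly in [−0.5, 0.5] under
the seed — chosen for exact reproducibility over initialization-scheme
fidelity. A plain gradient-descent fallback exists behind
`TrainConfig.optimizer="gd"`.

Metrics (MSE, MAE, RMSE, R², Pearson R) default to the original mg/g
scale; the normalized scale is available because mixed-scale reporting is
common in the surrogate literature and the two are not interchangeable.

## Genetic algorithm

Real-coded, maximizing: tournament selection (size 2), BLX-α crossover
(α = 0.5) with probability 0.7, per-gene Gaussian mutation (probability
0.15, sd = 0.1 × box width), clipping to bounds, 1 elite. Population 30,
50 generations. The specific operator set is a standard real-coded choice;
all pieces are configurable. Randomness streams per generation from
(seed, generation), so raising the generation cap replays the identical
prefix — the returned best value is monotone in the cap.

## Synthetic ground truth

`GroundTruth` couples three deterministic surfaces with i.i.d. Gaussian
noise (default σ = √0.0631 = 0.2512 mg/g, the replicate pure-error SD of
the reference response-surface experiment):

* first-order screening truth
  Y = 18.95 + 1.2·A + 0.1457·B − 0.7075·C + 0.0810·D + 0.3185·E;
* quadratic truth Y = 20.74 + 0.6146·A − 0.4384·C − 0.6933·E + 0.2776·AC
  + 0.4901·AE − 0.3598·CE − 1.05·A² − 1.05·C² − 3.04·E²
  (A = ratio, C = temperature, E = ethanol, coded);
* single-factor scan curves: concave quadratics through each factor's
  reference peak (ratio 20 mL/g → 19.44 mg/g; time 60 min → 19.24;
  temperature 50 °C → 19.38, anchored by 14.64 at 30 °C; power 200 W;
  ethanol 70 % → 20.30). Only the temperature curve has a second
  reference value; the other curvatures are illustrative and marked so.

What the generator emulates: the mean structure of both designed
experiments, replicate scatter consistent with the pure-error mean square,
and seeded reproducibility. What it does not emulate: run-order drift,
heteroscedasticity, non-Gaussian outliers, block effects, and any
model-form misfit (the truth *is* polynomial, so lack-of-fit is calibrated
non-significant by construction). Green tests therefore certify the
statistical machinery and its calibration under the assumed error model,
not the behavior of any particular plant extract.

## Calibration and known limitations

* Under the default noise, the quadratic refit recovers all ten
  coefficients within 3 true-σ standard errors in ≈99 % of replicates, and
  the lack-of-fit test is non-significant in ≈95 % — the generator and the
  ANOVA agree about the error model.
* The screening truth's time coefficient (0.1457) lies ≈2 standard errors
  (σ/√12 = 0.0725) from zero, so at p < 0.05 it is flagged in roughly a
  third of replicates. The significance *set* {ratio, temperature,
  ethanol} is therefore reproduced only ~55–60 % of the time; the
  pipeline's actual selection rule — the top three significant effects by
  |t| — identifies that trio in ≈98 % of seeds and is the robust contract.
* The ANN–GA chain's optimum carries intrinsic surrogate variance: the GA
  locates the trained network's true argmax (verified against a dense grid
  of the surrogate itself), but with 36 noisy training points a
  21-parameter tanh network's argmax scatters by ~1 mL/g / ~2 °C across
  seeds, occasionally sliding to a box face along the shallow temperature
  direction. A quadratic refit of the same sample is far more stable; the
  surrogate's value is flexibility when the true surface is *not*
  quadratic, not precision when it is.
* Problem sizes throughout (12/17/51 runs, 10-seed sweeps, 200–2000
  replicate calibration loops) are the workflow's own study sizes; the
  whole suite runs in well under a minute apart from the replicate loops.
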