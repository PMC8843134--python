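# Methods

`fertopt` models a replicated full-factorial fertilizer trial — three dose
factors (N, K, Mg in grams per plant) against three banana traits (fruit
yield FY in kg/plant, fruit length FL in cm, rows per spike NRPS) — with
two surrogate regressors, compares them under shared 5-fold
cross-validation, and maximizes the better surrogate over the dose box
with a real-coded genetic algorithm. This note records the model choices,
the defaults and why, and what the tests do and do not establish.

## Data model

The packaged fixture is the 36-treatment 3×4×3 factorial
(N ∈ {0,100,200}, K ∈ {0,100,200,300}, Mg ∈ {0,50,100}) with treatment
means and SEMs from 3 replications. Only means ± SEM are published, so
replicate-level observations, when a stage needs them, are reconstructed
as moment-matched normal draws: three draws per treatment × trait,
affinely corrected so the sample mean equals the printed mean exactly and
the sample SD equals SEM·√3 (the SD↔SEM identity). Reconstruction is
deterministic given a seed and preserves the first two moments to 1e-9.

## Fitting granularity

Because the kernel surrogate weights exemplars only by their inputs,
replicates sharing a dose triple enter every prediction through their
mean — a GRNN fit to replicates is *identical* to one fit to treatment
means. Granularity therefore matters only for the evaluation targets.
With replicate-level targets, the pooled training R² is capped by the
fixed within-treatment variance at 1 − 6·ΣSEM²/SS_tot, which evaluates
to 0.8905 for FY — below the published training value (0.925), so
replicate-level evaluation cannot reproduce the reference analysis.
Evaluating on the 36 treatment means, with a CV-selected bandwidth
(below), gives training/testing R² ≈ 0.96/0.73 for FY and ≈ 0.97 training
for NRPS, matching the published pattern. The pipeline therefore
**defaults to treatment means** (`fit_granularity="means"`);
replicate-level fitting remains available in config.

## Preprocessing

* **Box-Cox on targets only.** λ is chosen by maximum likelihood over
  [−5, 5] per trait (`scipy.stats.boxcox_llf`), with an automatic
  positive shift only if a target is non-positive (never needed for the
  fixture). Inputs are designed doses and are not power-transformed.
  Predictions are always inverted back to trait units before any metric.
* **Feature scaling.** Doses are min-max mapped onto [0,1]³ using the
  *design bounds* (0–200, 0–300, 0–100 g), not data extrema — constants
  of the design, so no train/test leakage is possible. Values outside
  the bounds are not clipped.
* **Outlier screen.** Rows of [doses | trait means] are standardized,
  projected onto principal components retaining ≥ 95% variance, and
  gated on the Mahalanobis score distance. The `threshold_sd` parameter
  (default 3) is expressed in per-axis SD units and converted to the
  chi-square quantile with the same two-sided normal tail mass, so the
  per-row false-positive rate (≈ 0.27%) is independent of the retained
  dimension. Default action is flag-and-report; removal (which drops
  flagged treatments from the fitting data only) is opt-in, because with
  36 treatments silent removal would change results invisibly. No
  treatment of the fixture is flagged at the default threshold.
* **Folds.** One random 5-fold partition of the 36 treatments (sizes
  8/7/7/7/7), shared by both model families for a paired comparison.
  Replicates, when used, inherit their treatment's fold.

## GRNN

Prediction is the normalized Gaussian-kernel weighted mean of training
targets, ŷ(x) = Σᵢ yᵢ exp(−Dᵢ²/2σ²) / Σᵢ exp(−Dᵢ²/2σ²) with squared
Euclidean distance Dᵢ² in scaled-feature space and a single isotropic
width σ. The largest exponent is subtracted before exponentiation, which
leaves the ratio unchanged and makes underflow impossible; a test
verifies equality with the naive formula to 1e-9 wherever the naive form
is computable. Consequences used elsewhere: predictions are convex
combinations of training targets (so the GA's best predicted FY can never
exceed the largest observed mean, 119.1 kg/plant); σ→0 interpolates;
σ→∞ returns the training mean.

σ is selected by minimizing cross-validated RMSE (in transformed target
units) over 20 log-spaced candidates in [0.01, 2] — spanning
interpolation to oversmoothing on the unit cube — with ties broken
toward the smoother model. On the fixture the selection lands near
0.21–0.28 depending on trait.

## MLP

One hidden tanh layer (identity output), trained full-batch by
Levenberg-Marquardt on the mean squared error with an analytic residual
Jacobian (checked against central finite differences to 1e-4 relative).
Damping starts at 1e-3, ×10 on a rejected step, ÷10 on an accepted one;
stopping at 1000 iterations, gradient ∞-norm < 1e-8, or damping > 1e10;
weights initialized uniformly in [−0.5, 0.5] from a seed; the best-SSE
weights ever visited are returned. The hidden size is chosen over
candidates 1–10 by the median CV-RMSE of 5 seeded restarts (LM on tiny
data is initialization-sensitive; the median makes trial-and-error
architecture search reproducible), ties toward the smaller network.
Architecture ranking uses a 200-iteration budget per fit, which is ample
at this problem size.

## Metrics

RMSE = √(mean(o−p)²), MBE = mean(p−o) (predicted minus observed — fixed
so that RMSE ≥ |MBE| holds), R² = 1 − SS_res/SS_tot about the observed
mean. Under 5-fold CV, the "training" row pools each fold's in-fold
fitted predictions and the "testing" row pools the held-out predictions,
both after inverse-transforming to trait units; pooling is the
determinate aggregation when a single training/testing value per
model × trait is reported alongside 5-fold CV, and is invariant to fold
relabelling.

## Genetic algorithm

Real-coded 3-gene chromosomes (doses in grams) inside the box
[0,200]×[0,300]×[0,100]; population 200, 1000 generations, crossover
rate 0.7, mutation rate 0.04. Roulette-wheel selection uses the
non-negative shift fᵢ − min f + 0.01·range(f), the standard fix for
negative or tied fitness. Two-point crossover draws an ordered cut pair
from the gene boundaries {1..L} and swaps the enclosed segment — on
three genes the pairs (1,2), (1,3), (2,3), the determinate real-coded
reading of the operator. Uniform mutation redraws each gene from its
bound interval with probability 0.04. One elite individual is carried
over per generation (configurable to 0), which guarantees a
non-decreasing best-fitness history and best-ever-semantics for the
reported optimum. Non-finite objective values are demoted to
worst-in-generation with a warning. The GA objective for each trait is
the family with the higher pooled testing R² (configurable override),
refit on all data with the CV-selected hyperparameter; predictions are
inverse-transformed so the GA maximizes in trait units.

## Synthetic experiments

The generator emulates the trial's phenomenology with a quadratic
surface plus an N×K interaction: strong N and K main effects with
diminishing returns, positive N×K synergy, weak non-monotone Mg. The
default FY-like spec spans ≈ 42–114 kg/plant over the box with
replicate noise SD 6 kg (SEM ≈ 3.5 kg — the fixture's scale); FL- and
NRPS-like specs are provided at their trait scales. Replicates are
Gaussian i.i.d.; the known optimum is located by brute force on a
201-per-axis grid with an L-BFGS-B polish (lexicographic tie-break).
What the generator does *not* emulate: heteroscedastic and correlated
replicate errors, trait-trait correlation within treatment, non-quadratic
plateaus, or any temporal structure of split fertilizer applications —
so passing recovery tests demonstrate correctness of the estimators and
optimizer under clean conditions, not robustness to real-data pathology.

## Numerical choices and degenerate inputs

Ties in argmax/selection are broken deterministically (lexicographic
doses; smoother σ; smaller hidden size). Zero-SEM treatments reconstruct
to constant replicates. Zero-variance observations make R² undefined
(reported missing with a warning). Degenerate scaled features map to 0
with a warning. Box-Cox on all-equal non-positive input is an error.
UPGMA clustering standardizes each trait column by its across-treatment
SD — the published figure caption divides by "standard error", which for
clustering differs only by a per-column scale; column SD is the
determinate reading and is recorded as a deliberate choice — then
agglomerates z-scored profiles by average linkage on Euclidean distance.

## Reproducibility

Every stochastic stage derives its seed from the single run seed by a
fixed offset (reconstruction +1, folds +2, MLP +3, GA +10+trait-index);
re-running a config reproduces every output. Problem sizes throughout
are those of the study: 36 treatments, 5 folds, GA at 200×1000.

## Known limitations

* The MLP extrapolates freely outside the design region; combined with
  inverse Box-Cox its GA maxima can be unphysical (the bounded GRNN is
  the intended optimization surrogate, as in the reference analysis).
* The CV-selected σ is chosen on the same folds later used for the
  reported metrics (a deliberate, documented reuse; the alternative —
  nested CV — is not part of the reference protocol).
* The GRNN-GA optimum for NRPS (~13.3 rows) and the near-zero dose
  reductions for FY reflect this pipeline's surrogate, whose maximum
  necessarily tracks the best observed treatments; see the README's
  reproduction notes for how these quantities are recomputed.
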