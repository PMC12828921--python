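# Methods

`strabplan` implements a prescriptive multi-task pipeline for horizontal
strabismus surgery planning: from fourteen routine pre-operative predictors
it simultaneously selects which of the eight horizontal muscle–procedure
options (right/left × medial/lateral rectus × recession/resection) to
perform and predicts the recession/resection dose in millimetres for each.
Because the patient data such a model would be trained on are private, the
package ships a synthetic-cohort simulator calibrated to the published
baseline statistics of a 634-patient surgical cohort; every downstream
stage is developed and validated against that generative model.

## The synthetic cohort

Each simulated patient carries: age (lognormal, μ = ln 15, σ = 0.547 —
median 15 y, mean ≈ 17.4 y, IQR ≈ 11–23 y, truncated to 2–65 y), the
deviating eye (OD/OS, Bernoulli ½), a signed prism-cover deviation
(positive = exotropia with probability 0.532; |deviation| per type is
truncated normal — exotropes 31 ± 11 Δ, esotropes 24 ± 9 Δ, support
5–140 Δ), per-eye axial length (patient mean N(24.0, 1.2) mm, inter-ocular
difference N(0, 0.6) mm, rejection-sampled into 18–32 mm), per-eye
spherical equivalent (mean N(−1.3, 2.4) D, difference N(0, 1.2) D), per-eye
BCVA (point mass at 0.00 logMAR with probability 0.55, otherwise
half-normal σ = 0.15), and an equal-vision flag, defined here as
|BCVA(OD) − BCVA(OS)| ≤ 0.1 logMAR. Rejection sampling (not clipping)
keeps records inside the clinical bounds so no boundary spikes appear.

### The expert plan rule

Real surgeons' decision rules are not published, so the simulator uses a
deterministic rule with the right marginal structure:

* |deviation| ≤ 10 Δ — single recession of the acting muscle (lateral
  rectus for exotropia, medial rectus for esotropia) on the deviating eye;
* otherwise two muscles share the correction: symmetric **bilateral
  recession** when vision is equal, **recess–resect** on the deviating
  (amblyopic) eye when it is not.

Per-muscle dose follows the shared-correction nomogram
`dose = clip(|deviation| / (slope × n_muscles) + ε, 0.5, 10)` with
ε ~ N(0, 0.3 mm). The slope default is 2.15 Δ per mm: published
surgical tables for two-muscle corrections correspond to roughly 2.1–2.7 Δ
of correction per millimetre on each muscle, while the classical
single-muscle approximation is ≈ 2. With this slope the recession doses
cluster in the 6–7 mm histogram bin, matching the dose distribution the
pipeline is meant to emulate; the neighbouring bins (5–6, 7–8, and the
9–10 bin that collects the 10 mm saturation of very large angles) lie
within a few percent of the mode, so the histogram check in the test suite
uses 40 000 patients.

After the rule assigns labels and doses, each of the eight labels is
independently flipped with probability 0.02 (recording noise) and doses are
re-zeroed wherever the final label is 0. The flip rate makes the selection
task noisy but learnable (AUC ceiling ≈ 0.95); the 0.3 mm dose noise puts
the Bayes-optimal operated-dose MAE at σ√(2/π) ≈ 0.24 mm, well below the
0.5 mm clinical acceptability bound.

### What the generator does and does not emulate

It reproduces the printed cohort marginals (exotropia fraction, deviation
means, axial length, age, label prevalences ≥ 5%) and a plausible dose
distribution. It does **not** emulate: three- and four-muscle surgeries
(very large angles simply saturate at the 10 mm ceiling, so recessions and
resections share one dose scale and synthetic resections cluster with the
recessions rather than slightly above them), A/V patterns, vertical
deviations, re-operations, correlated measurement error, or any real joint
distribution between predictors and plans beyond the rule above.
Consequently, green pipeline results here demonstrate that the machinery is
correct and well-calibrated on a cohort with this structure — not that the
model would reach the same numbers on real patients.

An important consequence of the design was discovered during development:
if the number of muscles sharing the correction changes in a dense region
of the deviation distribution, the per-muscle dose becomes discontinuous
exactly where most patients live, and no model of the network's size (nor
gradient boosting) can then reach a 0.5 mm operated-dose MAE from ~600
training patients. The rule above is therefore smooth in deviation
everywhere except the rare (≈ 4%) single-muscle branch.

## Preprocessing

Quality screening enforces age 2–65 y, axial length 18–32 mm and
|deviation| ≤ 140 Δ; missing fields raise immediately (complete-case).
Features are the ten model inputs: age, deviating-eye code, signed
deviation, axial-length mean and signed OD−OS difference, spherical
equivalent mean and difference, both BCVA values and the equal-vision flag.
Winsorisation clips at the empirical 1st/99th percentiles (linear
interpolation between order statistics) and z-scoring uses the winsorised
training-fold mean/SD — all statistics come from training rows only and are
tagged with the row count used, so leakage is testable. Constant columns
fall back to SD 1 with a warning.

## The multi-task network

A fully connected trunk (10 → 109 → 35, batch normalisation, ReLU, dropout
0.20) feeds a classification head (8 sigmoid outputs) and a regression head
(8 linear outputs, clipped to 0–10 mm at inference). Weights are
Xavier-uniform; biases zero. With the ten default inputs the parameter
count is 5 949 and is reported by `Results.summary()`; the architecture is
configurable, and no straightforward reading of the 109→35 trunk reproduces
any other externally quoted count, so the package simply reports its own.

The regression head is hierarchical: one shared base column plus per-slot
deltas (algebraically still eight linear outputs). Weight decay shrinks the
deltas toward zero, so the rare resection slots borrow strength from the
common recessions — without this, their dose error roughly doubles.

**Loss.** Weighted binary cross-entropy (positive class of label *j*
weighted by (n − n_j)/n_j, capped at 20) plus λ × MSE on a standardised
dose scale. Two choices matter and were fixed after ablation on the
generative model:

* **Masked dose regression is the default**: the MSE runs over operated
  slots only, so the head models "dose, given this muscle is operated".
  Training the head against 0 mm for unoperated muscles (offered via
  `ModelConfig(mask_regression=False)`) makes its optimum the
  probability-shrunk conditional mean; at n = 634 no learner we tried
  (this network, a scikit-learn MLP, gradient boosting) generalises that
  gated product to better than ≈ 0.75 mm operated MAE, far above the
  0.5 mm bound, while masking reaches ≈ 0.45 mm.
* **λ = 10**: the masked MSE covers ~2 of 8 slots per patient and the
  class weights inflate the BCE term, so λ = 1 underweights dosing;
  λ ∈ [3, 20] all work, with 10 the flattest optimum.

**Optimisation.** Adam (lr 2.95 × 10⁻³, weight decay 10⁻⁴ applied to
weight matrices), global gradient-norm clipping at 1.0, early stopping with
patience 20 on the held-out loss. After the stopper fires, training
restores the best checkpoint, multiplies the learning rate by 0.2 and
continues for up to two further rounds (reduce-on-plateau); two independent
initialisations are trained and the one with the better held-out loss kept.
Both refinements exist because patience-20 alone leaves the dose head
under-converged. Batch normalisation uses running statistics at inference;
dropout is inference-disabled. Divergent (non-finite) loss aborts with a
diagnostic. `max_epochs` defaults to 500.

Hyper-parameter tuning (`random_search`) samples layer widths, dropout,
log-uniform learning rate and batch size, scoring each draw by mean best
validation loss over inner stratified folds; the default pipeline uses the
default configuration without search, which already meets every bound.

## Internal validation

`multilabel_stratified_kfold` runs iterative stratification (rarest label
first, ties by fold desire then seeded jitter) followed by a greedy
size-preserving swap refinement that directly minimises the certificate —
the maximum over all (fold, label) cells of |fold prevalence − overall
prevalence|, in percentage points — until it is ≤ 2 points (retries with
fresh sub-seeds up to 50, keeping the best split and flagging it if the
tolerance is still exceeded). The certificate is recomputable from the
emitted fold indices alone.

Within each training fold, `SurgicalPlanModel.fit` holds out 20% (an inner
stratified split) for early stopping, and fits calibration and thresholds
on that held-out split's predictions — never on the outer validation fold
and never on the network's own training targets. Out-of-fold predictions
therefore cover each patient exactly once with no leakage; per-fold seeds
derive deterministically from the run seed.

Confidence intervals use the percentile bootstrap (default B = 1000),
resampling patients (not muscle slots) so the within-patient correlation of
the eight outputs is preserved; resamples on which a statistic is undefined
are redrawn and counted.

## Calibration and decision policy

Logits are temperature-scaled (1-D bounded NLL search on [0.05, 20]) and
then beta-calibrated: m(p) = sigmoid(c + a·ln p − b·ln(1−p)) with a, b ≥ 0
fitted by bounded L-BFGS on the logistic likelihood — the order
"temperature first, beta on its output" is fixed. Calibration is per label;
labels with fewer than 20 positives on the calibration split share
parameters fitted on all labels pooled. Both maps are strictly monotone, so
AUC is unchanged. Diagnostics: expected calibration error over equal-count
decile bins, reliability tables, and the calibration slope (logistic
coefficient of logit(p); separation reported as ∞).

Per-label decision thresholds maximise the Matthews correlation coefficient
over midpoints of consecutive sorted unique probabilities (ties toward the
higher threshold; single-class labels fall back to 0.5 with a flag). The
decision rule is inclusive (p ≥ τ). Feasibility resolution: if both members
of a recession/resection pair are selected, the higher-probability member
prevails and the other's decision and dose are zeroed; exact ties keep the
recession (clinically conservative). Doses of unselected labels are zero; a
selected muscle whose predicted dose falls below 0.5 mm is floored at
0.5 mm and flagged, since a selected muscle cannot receive a 0 mm
procedure. Plan assembly is idempotent.

## Evaluation

Per-label and macro AUC (Mann–Whitney rank statistic with tie correction) /
F1 / MCC, exact-match accuracy against the majority baseline (frequency of
the modal reference decision vector); pooled ECE and slope; dose MAE, RMSE,
R² and fraction-within-±0.30 mm, reported both over all eight slots and
over operated slots only ("truly operated" = recorded dose > 0, which
excludes flip-on label noise); Bland–Altman bias and 1.96·SD limits of
agreement; tiered plan agreement (tier 1: identical decisions and operated
doses within the 0.5 mm planning quantum; tier 2: identical decisions with
exactly one muscle off by more than the quantum but ≤ 1 mm); decision-curve
net benefit NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t) against treat-all and
treat-none; subgroup (exotropia vs esotropia) recomputation with absolute
gaps; and permutation feature importance (metric degradation when one raw
feature column is shuffled through the full predict path, mean ± SD over
repeats) as the model-agnostic attribution method.

## Problem sizes and reproducibility

The standard profile mirrors the study: n = 634, k = 10 folds, B = 1000
bootstrap resamples; a full cross-validated run takes well under a minute
on one CPU. The demo profile (n = 200, k = 5, B = 200) finishes in a few
seconds. All randomness flows from a single integer seed through
`numpy.random.SeedSequence`; identical configuration and seed reproduce
cohorts, splits, fits and metrics bit-identically. Run artefacts (config
snapshots, seed manifest, fold indices, checkpoints, metrics JSON/Markdown,
reliability and decision-curve tables) carry the seed and a config hash and
are sufficient to replay the run.

## Known limitations

* The simulator's plan rule is an invention with plausible marginals; its
  joint structure is far simpler than surgical reality, and the pipeline's
  synthetic headline numbers (macro-AUC ≈ 0.94, operated MAE ≈ 0.46 mm,
  ECE ≈ 0.02, exact match ≈ 0.8) characterise this synthetic world only.
* Resection doses in the simulator do not sit above recessions as real
  dose-distribution figures suggest; with a single shared nomogram slope
  both procedures in a recess–resect share the same dose.
* Calibration for rare labels leans on pooled parameters; with fewer than
  ~10 positives in a calibration split even that is fragile.
* The masked dose head predicts a plausible dose for *any* slot; doses for
  unselected slots are meaningful only after the decision policy zeroes
  them.
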