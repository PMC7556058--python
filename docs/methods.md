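# Methods

## Model

The map has 28 concepts: the 27 risk factors C1–C27 (grouped as personal,
diet/food, systemic-condition and stomach-condition factors) and the GC
outcome concept C28. Activations live in [0, 1] and evolve by the
synchronous rule

    A_i(k+1) = f( A_i(k) + Σ_{j≠i} ω_ji · A_j(k) ),

all concepts updated from the previous state. The transfer function is the
logistic sigmoid `f(x) = 1/(1 + exp(−λx))`; λ defaults to 1 and is
configurable per model. A sigmoid (rather than a hyperbolic tangent or a
piecewise clip) keeps activations strictly inside (0, 1), which the
concept-value semantics require. Self-edges are structurally excluded — the
bare `A_i(k)` carry-over term in the update is not an edge and the weight
matrix diagonal must be zero.

**Clamping.** The generic dynamical core leaves every concept free by
default. The gastric-cancer bundle, however, clamps all 27 feature concepts
at their encoded values during inference: a patient's measured factors are
observations, not quantities the map should re-estimate. Without clamping,
every concept with no incoming edge relaxes to the universal fixed point of
`x = f(x)` (≈ 0.6590 at λ = 1) within a handful of iterations, erasing the
patient record before the outcome can integrate it and collapsing every
assessment to a single class. Clamping is a per-model configuration flag,
so the free-running variant remains available for dynamical studies.

**Steady state.** Inference iterates the update rule until the max-norm
change of the state falls below `eps` (default 0.002, mirroring the
training threshold e) or 100 iterations elapse; non-convergence is reported
alongside the last state rather than raised. With clamped inputs the
outcome concept solves `x = f(x + S)` with constant net input
`S = Σ ω_j·a_j`, a contraction that converges in a few iterations.

## Linguistic weights

Expert judgments use five levels (very low … very high) modeled as
triangular membership functions with peaks at 0.1, 0.3, 0.5, 0.7, 0.9 and
half-width 0.25, evaluated on a fixed grid over [0, 1] with step 1e-4.
Aggregation is the SUM technique — unclipped pointwise addition — because
the centroid is insensitive to overall scale and clipping at 1 would
discard multiplicity (how many experts agree); a bounded-sum mode is
available as an option. Defuzzification is the centroid
`∫x·μ(x)dx / ∫μ(x)dx` by trapezoidal quadrature; against a 10× finer
reference grid the error is below 1e-6. The two extreme triangles extend
past the [0, 1] domain and are truncated by it, so they are not symmetric
and their centroids sit inward of their peaks (0.13293 and 0.86707 rather
than 0.1 and 0.9); the three interior levels return their peaks exactly.
Signs are elicited separately from magnitudes: the sign of an edge is a
strict majority vote across experts (a tie is reported as a consensus
error, never guessed), while all experts' terms pool into one magnitude.

## The shipped gastric-cancer bundle

The default weight fixture (38 edges: 27 factor→GC, 11 factor→factor) is a
documented, plausible expert-style configuration — the original study never
published its learned matrix in machine-readable form, and this fixture
makes no claim to reproduce it. Magnitudes take the linguistic centroid
values 0.7/0.9 for factor→GC edges (the 27 factors were selected as major
risk factors, so every direct effect is rated high or very high) and
0.3–0.7 for factor interactions; signs follow the published risk
directions (vegetables, fruit, milk, allergy history, cardiovascular
history and physical activity are protective, everything else promotes).
Whether the original map contained factor→factor edges at all is unknown;
the 11 shipped interactions (e.g. infection → mucosa → inflammation) are an
explicit modeling choice, and because inputs are clamped they do not affect
inference — they exist as knowledge structure and are exercised by
training.

Categorical levels are encoded equally spaced on [0, 1] in ascending
*intensity* order (the edge sign carries the risk direction); binary
features map to {0, 1}. The outcome concept starts at 0.

**Thresholds.** The mostly positive edge mass gives a mean net input to the
outcome of ≈ +4.5, so converged GC activations concentrate in [0.78, 1.0] —
an intrinsic property of a map with [0,1] activations, no bias term, and
predominantly promoting factors. The tertile cutoffs (1/3, 2/3) that the
generic `classify` function defaults to would therefore label every record
high. The bundle instead ships cutoffs (0.9914, 0.9980), calibrated once on
a 10,000-record synthetic cohort (seed 12345) so that the three classes
occur in the published risk-score proportions (13.2% low, 33.2% medium,
53.6% high). They are configuration, not clinical claims. The
classification bands double as the per-class output-target ranges for
training, with the low band clipped below at the calibration cohort's
0.5th-percentile activation (0.9351): without the clip the low-class
midpoint (≈ 0.50) is unreachable and the F1 monitor degenerates into a
reward for indiscriminate weight decay.

## NHL training

Only expert-declared (nonzero) weights are updated. The recurrence for edge
j → i is `ω ← γ·ω + η·A_i·(A_j − sgn(ω)·ω·A_i)` with defaults η = 0.045,
γ = 0.98 (the best pair of the original grid search) and hard bounds
η ∈ (0, 0.1), γ ∈ (0.9, 1); a relaxed mode admits the no-learning limit
(η = 0, γ = 1) for contract tests. Updates are clipped to [−1, 1], and
sweeps additionally floor each magnitude at 1e-6 on the expert side of
zero: the raw update can carry a small negative weight across zero (its
Hebbian term is positive whenever A_j > |ω|·A_i), whereas expert-declared
signs and the zero pattern are treated as hard structural knowledge.

Training is record-level: per epoch, records are visited in a seed-shuffled
order; each record initializes the activations and then one synchronous
state step alternates with one weight sweep (both using the pre-step
activations, matching the recurrence's indices) until the output-concept
change satisfies F2 (< e, strictly) or a 100-iteration cap. An epoch's F1
is the mean squared distance of the converged outputs from their class-
target midpoints, measured under the epoch-end weight snapshot in a
separate inference-only pass, so every F1 value — including the epoch-0
baseline, the untouched starting matrix — scores one well-defined matrix.
Training stops when F1 fails to improve by more than 1e-6 for 3 consecutive
epochs, when all records reach F2 and the matrix has stabilized, or at the
epoch cap; the minimum-F1 snapshot is returned, which operationalizes
"stop once F1 is minimized".

Two properties of this regime are worth knowing. First, the Hebbian
dynamics are unsupervised — class labels enter only the F1 monitor — so
training cannot pull a perturbed matrix back toward a specific ground
truth; what the F1-selected snapshot provides is protection against the
second property: with ~4 inner iterations per record and 392 records per
epoch, the decay factor compounds ≈ 1600× per epoch and drives all weights
to a label-independent equilibrium within a single epoch, which the monitor
usually (not always — see Limitations) rejects in favor of the starting
matrix.

## Synthetic cohorts

Each factor is drawn independently from its published per-level frequency
(count / total); no between-factor correlation is modeled because only
marginals were ever published, and a user-supplied dependency model can be
substituted at the `MarginalTable` boundary. Counts are kept exactly as
published, including internal inconsistencies: the baking-dish levels
cover 421 of 560 records (the residual 139 form an explicit "other" level)
and the BMI counts sum to 558 (marginals normalize by their own total).
Labels come from running the ground-truth bundle on each record, so a
labeled synthetic cohort is exactly consistent with a known weight matrix.
The 70/30 split (392/168 at n = 560) delegates to scikit-learn's
`train_test_split`, with optional stratification. Summaries report
truncated (floored) percentages — the arithmetic convention of the source
tables (85/560 → 15.17) — with a 1e-9 guard against binary float noise.

Passing tests on these cohorts demonstrates internal consistency of the
pipeline (generator → encoding → inference → training → evaluation), not
clinical validity: real risk factors are correlated, real label noise is
not generated by any FCM, and the private study cohort cannot be compared
against.

## Evaluation

Confusion matrices are 3×3, rows predicted / columns actual, class order
high, medium, low. Accuracy is 100·trace/total; per-class recall divides
the diagonal by the column (actual) sum and precision by the row
(predicted) sum — the one-vs-rest generalization that reproduces the
published two-class formulas' printed values. MAE is `(1/N)·ΣΣ|Δ|` (per
record, summed over outputs) and RMSE is `sqrt((1/(N·C))·ΣΣΔ²)`. A zero
row or column yields NaN (undefined metric), not an error. All published,
self-consistent metric cells of the original study's five classifiers and
its η/γ grid are reproduced exactly under the truncation convention; three
printed cells are inconsistent with their own printed matrices (one Naïve
Bayes precision, and the MLP accuracy and low-class recall, whose matrix
column was misprinted) and are asserted at their recomputed values instead.

## Numerical choices

- Inference convergence: max-norm < 0.002 (reusing e), cap 100 iterations.
- Integration grid step 1e-4; oracle comparisons at 1e-5, tolerance 1e-6.
- Percentage truncation guard: `floor(x·10^dp + 1e-9)/10^dp`.
- Training sign floor 1e-6; per-record iteration cap 100; plateau patience
  3 epochs at δ = 1e-6.
- All stochastic procedures (sampling, shuffling, splitting, perturbation)
  take explicit integer seeds; the study driver derives independent child
  streams from one master seed via `SeedSequence`.
- Study problem sizes: cohorts of 560 records (the published cohort size)
  for end-to-end runs, 10,000 for marginal-fidelity checks and one-off
  threshold calibration, 30 records for the 50-epoch training-invariant
  check.

## Known limitations

- The outcome activation is saturated (99% of cohort mass above 0.97), so
  the classification bands are narrow and the F1 monitor discriminates
  weakly between matrices of very different accuracy; for some perturbation
  draws it selects a collapsed matrix over the better starting matrix. This
  is intrinsic to the model family (no bias term to recenter the net
  input), not to the implementation.
- Parameter recovery is bounded by perturbation robustness, not by
  learning: NHL cannot re-estimate specific weights from labels. Expected
  held-out accuracy after ±0.2 elicitation noise is ≈ 85–90% under the
  shipped conditions, varying several points with the noise draw.
- The weight fixture, thresholds and target ranges are documented
  configuration, calibrated on synthetic data only; nothing here is
  clinically validated, and the tool is a research artifact, not a medical
  device.
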