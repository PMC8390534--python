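# Methods

This note records the models, numerical choices and limitations behind
`gbopt`, in the order the pipeline runs them.

## Orthogonal design

The 4-factor, 7-level experiment uses the strength-2 orthogonal array
OA(49, 7⁴, 2) generated over GF(7): with block index `a` and within-block
index `b` (both 0..6), the level-index columns are `a`, `b`, `(a+b) mod 7`
and `(2a+b) mod 7`, rows emitted a-major. Because the generator
coefficients (1,1) and (2,1) are linearly independent over GF(7), every
unordered pair of columns contains every ordered level pair exactly once;
`verify_strength2` checks this exhaustively (6 column pairs × 49 ordered
pairs) rather than trusting the construction. This particular generator is
used (rather than any other OA(49, 7⁴)) because it reproduces the packaged
reference experiment row-for-row, so design and data stay aligned.

Level indices are 0-based internally and 1-based in reports. Factor levels
are stored as plain floats with display units carried as strings; the time
column is deliberately unsorted (5, 45, 20, 30, 60, 120, 180 min), and
level order is preserved as configured.

## Range analysis

K[l, f] is the arithmetic mean of the response over the 7 runs at level
`l` of factor `f`; R[f] is the max−min of the K column; factors are ranked
by descending R with ties broken by factor order. In a balanced design
each K column averages to the grand mean — this is asserted as an
invariant. The packaged dataset's printed K table contains one
inconsistent cell (level 2 of temperature) that equals the level *sum*
rather than the mean; the loader keeps the raw yields and all statistics
are recomputed, so the package reports the mean (0.6637).

## Yield surrogate

A single-hidden-layer perceptron, ŷ = W₂·tanh(W₁x + b₁) + b₂. All four
inputs and the target are linearly mapped to [−1, 1] by training-set
min/max (the convention of the classic neural-network toolboxes this
workflow descends from). Training is full-batch gradient descent on the
MSE with:

- **momentum** 0.9 (velocity `v ← μv − η∇`),
- **adaptive learning rate**: initial η = 0.01; after each epoch the
  tentative step is rejected if MSE grows by more than `max_perf_inc`
  = 1.04 relative to the previous epoch (weights restored, velocity
  zeroed, η ×0.7), otherwise accepted with η ×1.05 on strict improvement;
- stopping at goal MSE 10⁻⁴ (normalized scale) or 2000 epochs.

Velocity is zeroed on rejection so a rejected step cannot propagate
through the momentum term; the accepted-epoch MSE sequence is therefore
bounded by `max_perf_inc` per step and ends at or below its start, which
the tests assert. Gradients are analytic backprop, verified against
central finite differences to 10⁻⁶ relative error.

**Initialization** defaults to Nguyen-Widrow (hidden-unit weight rows
scaled to 0.7·H^(1/4) with biases spreading the active regions over the
input cube), the standard initializer for tanh networks on [−1, 1] data;
seeded uniform U(−0.5, 0.5) is available via `TrainConfig(init="uniform")`.
Identical config + seed gives bit-identical trajectories.

**Hidden width** is selected by k-fold cross-validation (default 5 folds,
candidates H ∈ {2..14}); validation MSE is measured on the original yield
scale so folds are comparable. Candidates within 5% of the minimum CV
error — or below the training-goal MSE rescaled to yield units, where
differences are converged-fit noise — are treated as tied and the smallest
network wins.

**Metrics.** R² = 1 − SS_res/SS_tot on the original yield scale; since
some conventions report the squared Pearson correlation instead, both are
returned.

### What the reference data can and cannot show

On the packaged 49-run dataset, held-out R² from random 43/6 splits is
intrinsically high-variance: a 6-point test set either contains one of the
few high-yield runs (which the network must extrapolate) or consists of
near-baseline yields (tiny SS_tot, so small absolute errors still tank
R²). Across 100 seeded (split, init) pairs the median held-out R² is
≈ 0.44 with best cases above 0.99; a fully converged reference fit
(scikit-learn's 4-8-1 tanh MLP trained by LBFGS) shows the same median on
the same splits, so this is an information limit of six-point test sets on
a spiky response, not a property of the trainer. Similarly, the true
5-fold CV error curve (averaged over 30 CV replicates) is a shallow basin
over H ≈ 7–14, so single-CV width selections scatter widely; any width in
the basin is defensible, and 8 is used as the default.

## Genetic algorithm

Real-valued genomes over the experimental box. Per generation: the single
best individual (elitism 1) is copied unchanged — making the per-generation
best monotone, which is asserted — and offspring are produced by roulette
selection (P(i) ∝ f(i) − min f + 10⁻¹², the shift making weights
non-negative and the ε avoiding an all-zero wheel), single-point crossover
with probability 0.75 (cut uniform over the 3 interior positions),
and gene-wise mutation with probability 0.05 that resamples the gene
uniformly within its bounds (so feasibility holds by construction).
Initial population uniform in the box; fixed 100 generations, no stall
criterion; the best-ever individual is returned. NaN fitness raises with
the offending point.

Predictions are not capped during the search: the surrogate may (and
does) extrapolate above the largest measured yield, so the "predicted
maximum" is a model statement whose excess over the data is an
extrapolation artifact. Replicated searches (10 seeded train/search
pairs) summarize this as a median.

## Assay arithmetic

Activity: U/mL = D·10³·(ΔA₁−ΔA₂)·V_t / (e·V_s·d), linear in net
absorbance and dilution, inverse in enzyme volume, absorptivity and path
length. The kit-specific molar absorption coefficient has no default and
must be supplied. Standard curves are ordinary least squares
(scipy.stats.linregress) with inversion (reading − intercept)/slope.
Mole conversions use geniposide M = 388.37 g/mol and glycine
M = 75.07 g/mol.

## Synthetic surfaces

Per-factor effects, each normalized to peak at 1 inside the box:
Gaussian temperature bump (default centre 87 °C, width 18 °C), Michaelis
saturation for both substrate doses (half-saturation 120 and 3 dose
units), and saturating-rise time effect (τ = 60 min). The default
combination is the **product** of effects × amplitude (default 20 μg/mL,
matching the magnitude of observed peak yields) so that any unfavourable
factor collapses yield, as in the real chemistry where no substrate means
no pigment; an additive mean is available for robustness checks.
Measurement noise is additive Gaussian (default σ = 0.5 μg/mL ≈ 2.5% of
amplitude), truncated at zero. Ground truth is the argmax on a 25⁴ grid —
unambiguous to one grid step and cheap (~0.4 M vectorized evaluations).

What the generator does *not* emulate: run-order drift, heteroscedastic
noise (real photometric error grows with signal), batch effects, and any
mechanistic kinetics of geniposide hydrolysis. Passing recovery tests
therefore show the pipeline can locate optima of smooth product-structured
surfaces from 49 noisy runs — not that it is robust to those artifacts.

## Pipeline and reproducibility

`run_full_pipeline` chains range analysis → (optional) CV width selection
→ a seeded uniform 43/6 split → training → held-out evaluation → GA
search. All stage seeds derive from one master seed
(`DEFAULT_SEED = 20210824`); no global RNG state is used anywhere, so
summaries are byte-identical across runs with the same seed. CV
re-selection is opt-in (`run_cv=True`) since the default width 8 sits in
the CV basin and a full 13-candidate × 5-fold CV costs ~65 trainings.
Reports round to 4 decimals for display and keep full precision under a
`raw` key. Replicate counts (10 seeded replicates for the fit and search
summaries) keep the full acceptance recomputation under a few seconds
while giving stable medians.

## Known limitations

- Six-point held-out sets make single-split R² nearly uninformative (see
  above); medians over seeds are reported instead.
- The surrogate is a global fit with no uncertainty estimate; the GA
  optimum inherits its extrapolation bias, typically overshooting the
  observed yield range by 15–40% on this dataset.
- CV width selection on 49 runs is noise-dominated across H ≈ 7–14.
- The trainer implements exactly one schedule (momentum + adaptive rate);
  no Levenberg–Marquardt or Adam, one hidden layer only, no early
  stopping beyond the error goal.
- Box constraints only in the GA; no mixed-integer or multi-objective
  support.
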