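# Methods

This note records the models, parameter choices and numerical decisions behind
`ecgbbb`, and what its synthetic experiments do and do not demonstrate.

## Synthetic ECG model

Each beat is a sum of Gaussian wave components on a time axis centred at the
R apex (placed at 1/3 of the beat vector, matching the segmentation
convention).  Defaults, in mV and seconds at 360 Hz:

| class  | components |
|--------|------------|
| NORMAL | P (0.12, −0.20 s, FWHM 0.10), Q (−0.15, −0.055, 0.025), R (1.0, 0, FWHM = `qrs_width_normal` = 0.08 s), S (−0.20, 0.055, 0.025), T (0.30, 0.30, 0.16) |
| LBBB   | P as above, broad R (1.0, 0, FWHM = `qrs_width_bbb` = 0.14 s), discordant T (−0.30, 0.32, 0.16) |
| RBBB   | P as above, R (1.0, 0, 0.045), S notch (−0.25, 0.035, 0.02), R′ (0.70, 0.085, 0.05), inverted T (−0.30, 0.30, 0.16) |

The config enforces the diagnostic rule by construction: `qrs_width_bbb`
must exceed 0.12 s and `qrs_width_normal` must stay below it, so generated
LBBB/RBBB complexes are at least 0.12 s wide at half maximum and the RBBB
R–R′ pair forms exactly two peaks above half maximum.  Amplitudes are free
parameters of a nominal single lead — no published amplitudes exist for this
reduced model — and are chosen to give realistic R-to-T ratios.

Records concatenate beats with RR intervals drawn from Normal(`mean_rr` =
0.833 s, sd 0.04 s) truncated at ±3 sd, then add a single-sinusoid baseline
drift (0.15 mV at 0.3 Hz, the respiration band) and white noise (0.03 mV).
One passed `numpy` generator carries all randomness; identical configs are
bit-identical.

What this emulates: class-discriminating QRS/T morphology, baseline wander,
mild broadband noise, annotated R peaks.  What it does not: multi-lead
geometry, beat-to-beat morphology drift, ectopy, electrode artifacts, or
rhythm disturbances.  Tests passing on this generator show the chain is
correct and identifiable under these conditions, not that the paper-scale
accuracies transfer to clinical recordings.

## Baseline removal

The baseline estimate is a Savitzky–Golay smooth of the signal itself,
subtracted from it.  The polynomial order is 3.  The window default is 2.4 s:
the smoother's frequency response at that window passes >92% of a 0.3 Hz
drift while responding weakly near the ~1.2 Hz beat fundamental, which keeps
the filtered beat train correlated >0.99 with the drift-free signal.  A 1.2 s
window — the other natural choice — has response 0.31 at 1.2 Hz and visibly
distorts beats (correlation ≈0.95), which is why the longer window is the
default.  A polynomial smoother's stopband ripple is a few percent by
construction, so baseline removal is not exactly idempotent: a second pass
changes the output by ~7% RMS on synthetic fixtures, which the tests document
as the honest bound rather than asserting a no-op.

## Segmentation, resampling, counting

Beat windows use 0-based, half-open indices `[p − round((p−q)/3),
p + round(2(s−p)/3))` for an interior peak `p` with neighbours `q`, `s`.
The first and last annotated beats of each record are dropped (no
previous/next RR), and only N/L/R symbols produce beats; the beat counter
applies the same interior rule so its totals match what the classifier
pipeline actually consumes.  Resampling is linear interpolation onto 200
equally spaced points — deterministic, endpoint-preserving, ring-free.
With constant RR the R apex lands at resampled index ≈ 67 (one third of 200),
which is why class-discriminating energy concentrates around columns 50–90.

## Optimizers

All four optimizers share box constraints (clip + zero the velocity component
on the clipped dimension), seed determinism, and a non-increasing global-best
trace (gbest is a historical minimum over personal bests).

- **Chemotaxis**: a tumble draws a uniform direction in the unit ball
  (normalized to unit length, so every step has Euclidean norm exactly `C`);
  the tumble step is always taken, then up to `Ns` swim steps repeat the same
  direction while fitness strictly improves — a failed swim evaluation is
  charged but reverted.  The chemotaxis displacement divides by the direction
  norm (not its square): each step then has length `C`, the behaviour the
  step-size parameter is meant to control.
- **Budget accounting**: populations are not objective-evaluated at
  initialization (fitness starts at +inf and the first unconditional tumble
  establishes it), so BFO/BFPSO evaluation counts respect the closed-form
  bound `S·Nc·(Ns+1)·Nre·Ned` exactly.
- **Reproduction** sorts by health (fitness accumulated over the epoch, lower
  = healthier, ties by agent index), duplicates the better half, resets all
  healths.  **Elimination–dispersal** re-draws each agent uniformly with
  probability `Ped`, keeping its personal-best memory.
- **BFPSO** applies the PSO velocity + position update to every agent after
  each chemotactic sweep (a per-step variant is available via
  `pso_per_step`), without an extra objective evaluation — the next sweep's
  tumble refreshes fitness — so hybrid and plain BFO share the same budget
  bound, which makes paired comparisons budget-fair.
- Defaults (overridable): ω decayed linearly 0.9 → 0.4, C1 = C2 = 2.0,
  velocity clamp 0.2 of the range, C = 0.1·(hi − lo), Nc = 50, Ns = 4,
  Nre = 4, Ned = 2, Ped = 0.25, S = 30.  These are package choices, not
  literature constants.
- The Rosenbrock function is provided as a benchmark objective (it is also
  the cell-signaling expression quoted in the bacterial-foraging literature);
  no cell-to-cell swarming penalty is added to fitness.

## Wrapper feature selection

Positions live in `[1, 200]^20`; decoding rounds, clamps, and moves
duplicates to the nearest unused index (smaller distance, then smaller
index), so already-integer distinct positions decode to themselves and the
reported subsets use the 1-based column numbering of the beat samples.
The score is `100 − mean 3-fold stratified-CV accuracy (%)` of a 1-NN
surrogate on the candidate columns, memoized per decoded subset; using the
full LM network inside the search loop would cost ~100× more for no change in
ranking on these fixtures.  The `select_features` search default is S = 20,
Nc = 10, Ns = 2, Nre = 2, Ned = 8, Ped = 0.25, velocity clamp 0.1 (≈4800
evaluations): for subset search, many short elimination–dispersal epochs that
keep re-injecting coordinate diversity outperform deep local refinement,
because a converged swarm has no mechanism to carry a coordinate across the
flat regions between informative columns.

### The localized-difference dataset

`localized_beat_dataset` builds the recovery fixture: three classes whose
smooth random templates (Gaussian-smoothed white draws, correlation length
1.5 columns, effect 0.7) are confined to 1-based columns 55–85; outside that
window all classes share the same background.  Noise is heteroscedastic —
sd 0.6 inside the window, 2.5 outside — mirroring how signal quality is
distributed over a real resampled beat: the high-amplitude QRS region has
high SNR while the flat segments are dominated by residual wander and muscle
artifact.  Under a nearest-neighbour scorer this makes each out-of-window
column an active liability (high-variance distance dilution) and each
in-window column a graded gain, so cross-validated accuracy keeps improving
until essentially the whole 20-column subset sits inside the window — the
regime in which wrapper selection is identifiable and the selected-index
histogram concentrates around the R-apex columns.  Homoscedastic variants
either saturate (no selection pressure past ~12 columns) or leave the
out-of-window landscape gradient-free (the search stalls); both failure modes
are documented in the test-design history and motivated this noise model.

## Classifiers and metrics

The network is `n_features`-10-`n_classes` with tanh hidden and linear output
on one-hot targets.  `mlp_lm` trains it by full-batch Levenberg–Marquardt
with an analytic Jacobian: solve `(JᵀJ + λI)δ = Jᵀr`, accept on MSE decrease
(λ ← λ/10), reject and retry otherwise (λ ← 10λ), stop at MSE ≤ 0.001,
1000 iterations, or λ > 1e10.  Weights initialize from a seeded generator at
scale `1/√fan_in`, so training is bit-deterministic given `train_seed`.
`mlp_scg` is an alternative trainer behind the same interface that minimizes
the identical MSE loss by conjugate gradients.  k-NN and SVM come from
scikit-learn.

Metrics are one-vs-rest with the normal class designated positive: TP counts
correctly classified normal beats, TN correctly classified abnormal beats.
An empty denominator yields `nan` — an explicit undefined marker — never a
silent 0 or 100.  Per-class accuracies are the one-vs-rest accuracy of each
class in turn.  `run_experiment` uses a stratified, seeded train/test split
(default 65% train) because the source experiment's split is not fully
specified; the fraction is a parameter, not a claim.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen as the package's own
defaults: records of 10–60 beats, datasets of ~240 beats, optimizer budgets
of 10³–10⁵ objective evaluations, and 10-seed replications for the paired
BFPSO-vs-BFO and window-recovery experiments.  The full suite and the
acceptance script each complete in a few minutes on one CPU.

## Known limitations

- The WFDB layer implements the subset of the format family the chain needs
  (single-channel use, formats 16/212, beat annotations with SKIP/AUX
  handling); it is not a general replacement for a full WFDB library.
- R-peak detection is a simple thresholded peak picker with a refractory
  constraint, intended only for records without annotations.
- The Savitzky–Golay baseline estimator inherently leaks a few percent of
  beat-band energy (see above); applications needing stricter linear-phase
  behaviour should use a dedicated high-pass design.
- Reported classification numbers on synthetic fixtures are upper bounds on
  difficulty, not estimates of clinical performance.
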