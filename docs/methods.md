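# Methods

## Scope and objects

The toolkit operates on `TrainingTrace` objects: per-epoch records of
training/validation loss and accuracy, optionally with test accuracies on a
record-level hold-out (`test_acc_subset`, records from subjects also seen
in training) and a subject-level hold-out (`test_acc_novel`, entirely
unseen subjects). Epochs are 1-based consecutive integers. Stopping rules
consume a trace and emit a `StopDecision`: the epoch at which the rule
fired (or none), and the epoch of the model it keeps. All rules share the
same selection semantics — keep the epoch of minimum validation loss among
the epochs observed before stopping, ties to the earliest epoch (an earlier
model is cheaper and no worse). A rule that never fires falls back to the
oracle over the full horizon, matching post-hoc usage. Rules scan the
prefix of the trace only, so online replay and post-hoc application agree
exactly; this is property-tested.

## Stopping rules

**Generalization loss (GL).** `GL(t) = 100·(E_va(t)/E_opt(t) − 1)` with
`E_opt(t)` the running minimum of validation loss; stop when GL exceeds a
threshold (default 5, i.e. 5%). If `E_opt(t) = 0`, GL is defined as 0 when
the current loss equals the minimum and is an error otherwise (the
relative statistic is undefined). A second mode, `fraction_of_initial`,
compares the absolute excess `E_va(t) − E_opt(t)` against
`threshold · E_va(1)` (threshold then a fraction such as 0.05). The two
modes exist because "a threshold of 5% of the initial loss" admits both
readings; relative-percent is the default and the other is one flag away.

**Progress quotient (PQ_N).** The mean of GL over the last `N` epochs,
compared to the same threshold; the window is only defined from epoch `N`
onward. This is deliberately the strip-mean of GL — a smoothed GL — not a
training-progress-normalized quotient; presets `pq3` and `pq6` match the
common strip lengths.

**Patience_n.** A counter of consecutive epochs without a strictly lower
validation loss; stop when it reaches `n` (presets 3 and 6). Equal loss
counts as stalled, otherwise a flat plateau would never stop training.

**Deng–Kwok dynamic patience.** A budget `p` starts at
`dk_initial_patience` (default 10 — the scheme needs *some* finite start,
and the source heuristic does not fix one; it is exposed prominently for
that reason). At epoch `t`, if the validation loss is below
`dk_multiplier = 0.996` times the minimum over earlier epochs, the budget
grows by `dk_increment·t = 0.3·t`; after the update, training stops if
`p < t`. Two conventions were genuinely open: we update before comparing,
and epoch 1 earns no increment because no earlier minimum exists. Under
steady geometric improvement the budget grows quadratically and the rule
never stops; under a plateau it stops at the first epoch exceeding the
initial budget. Both limits are unit-tested.

**Information ceiling.** Stop at the first epoch where the monitored
accuracy reaches `ceiling − margin`. The monitored metric defaults to
*training* accuracy: the argument is that apparent skill beyond the
direct channel's attainable accuracy must be memorization, and training
accuracy is where memorization shows first; validation accuracy is
available as an option. The margin acknowledges that a real indirect
channel loses some information, so a ceiling slightly below the direct
accuracy can be prudent. `establish_ceiling` packages the direct-channel
accuracy together with a corroboration check: an independent, much simpler
model (logistic regression after recursive feature elimination) should
reach about the same accuracy if the direct channel has truly been learned
to saturation; disagreement beyond the tolerance flags the ceiling as
unreliable (a warning, not an error).

## Synthetic population

The generator emulates a two-class repeated-measures design: class sizes
35 and 42 subjects, and per-subject record counts drawn from a rounded
Normal(22.63, 7.13) truncated to ≥ 1. The truncated-Normal dispersion model
is our choice — group-level record totals constrain the mean but not the
per-subject spread. Records are generated as

```
x = mu_y + u_s + e,    u_s ~ N(0, tau²·I),  e ~ N(0, sigma²·I)   (direct)
z = A·x + eps,         eps ~ N(0, channel_noise²·I)              (indirect)
```

The subject effect enters *before* the channel transform, so the indirect
channel inherits it — the surrogate signal is downstream of the same
physiological state. Marginally, both channels are homoscedastic Gaussian
problems, so the Bayes-optimal accuracy is `Φ(Δ/2)` with Δ the Mahalanobis
separation of the class means under the channel's covariance
(`(σ²+τ²)·I` direct; `A(σ²+τ²)Aᵀ + c²·I` indirect). Isotropic covariances
keep this closed form exact; general covariances and unequal priors are
served by the Monte-Carlo path, which applies the optimal linear rule to
simulated draws. Because the indirect covariance contains the image of the
direct one plus extra noise, `bayes(indirect) ≤ bayes(direct)` for every
valid spec — the computable form of the data-processing inequality,
property-tested over random specs. `calibrate_separation` rescales
`mu1 − mu0` to hit a requested direct-channel accuracy exactly
(`Δ = 2·Φ⁻¹(target)`); the default study population is calibrated to 0.97.

The default indirect channel keeps 8 of 12 coordinates and adds unit
noise: a transparent, genuinely lossy surrogate (indirect Bayes ≈ 0.874
against the direct 0.97).

One seed feeds named independent substreams (subject effects, record
counts, record noise, channel noise), so changing one stage of the
simulation does not perturb the others.

What the generator does *not* emulate: non-Gaussian physiology, class-
dependent covariances, drifting measurement scale, missing records, or any
raw-waveform structure — it works at the extracted-feature level.
Passing tests therefore demonstrate the logic of the ceiling principle
under its stated assumptions, not its robustness on real recordings.

## Parametric loss curves

For deterministic rule tests, `simulate_loss_curve` builds
`val_loss(t) = a + b·e^(−t/τ₁) + c·(1 − e^(−t/τ₂)) + noise`, a fast
fitting term plus a slow overfitting term; with `b, c > 0` and `τ₂ > τ₁`
the noiseless minimum is at
`t* = ln(b·τ₂/(c·τ₁)) / (1/τ₁ − 1/τ₂)`, checked against a brute-force
scan. Training loss decays monotonically, and accuracies use the proxy
`acc = 1/(1 + loss)` — monotone and bounded; only the ordering of values
matters to any rule. Noisy losses are clipped at zero to remain valid
losses.

## Training harness

The trainer is a ReLU multilayer perceptron (six hidden layers of width
32 by default) optimized by Adam on binary cross-entropy, learning rate
0.01, batch size 32, driven one shuffled minibatch at a time so that loss
and accuracy on every partition are recorded after each epoch.
`hidden_layers=0` degenerates to logistic regression fit by minibatch SGD
on the log loss. Hidden width and activation are configuration defaults,
not claims of protocol fidelity. No data augmentation and no outlier
removal are applied — by not being implemented.

Features are standardized to the *training partition's* mean and SD, and
that frozen scaler is applied to validation and test sets. Normalizing to
a grand mean over all partitions would leak test statistics into training;
the leak-free reading is deliberate, and a perturbation test verifies that
modifying test data leaves the training trace byte-identical.

The RFE comparator standardizes, ranks features by iteratively dropping
the smallest-|coefficient| one, refits logistic regression for each
candidate feature count, and keeps the count with the best validation
accuracy (ties to fewer features — the stopping criterion for elimination
is otherwise unspecified in the source heuristic).

## The experiment pipeline

`run_experiment` samples the population, splits it, trains the direct
model, establishes the ceiling, trains the indirect model, and replays all
rules on the indirect trace.

**Split design.** Both test flavours must exist: a record-level hold-out
(subset) and a subject-level one (novel). The split is two-stage: first
25% of subjects per class (largest-remainder rounding, stratified) are
held out whole as `test_novel`; the remaining records are split
80/16/4 into train/val/`test_subset`. The novel share is the dominant
design choice: records within a subject are correlated through the
subject effect, so the variance of the measured ceiling scales with the
number of held-out *subjects*, not records. With ~20 novel subjects the
measured ceiling tracks the true Bayes rule's realized accuracy on the
same records to within ~0.005; with 3 subjects (a naive 4% share) it is
unusable.

**Ceiling measurement.** The direct model's novel-test accuracy is read
from its trace at the epoch of minimum validation loss — the toolkit
records metrics per epoch rather than checkpointing weights, so the trace
value at the selected epoch *is* the selected model's accuracy. The
logistic+RFE comparator corroborates within a tolerance of 0.02. Note the
measured ceiling estimates the *realized* accuracy attainable on the
specific held-out subjects, which fluctuates around the population value
(SD ≈ 0.015–0.02 at 20 subjects) — an honest property of small-cohort
studies that the synthetic world reproduces.

## Numerical and engineering choices

- Trace floats are written with shortest round-tripping `repr` and read
  back with round-trip float parsing, so write→read is lossless and
  repeated report generation is byte-identical.
- Largest-remainder rounding makes split sizes exact partitions
  (no record lost or duplicated), stratified by class.
- Monte-Carlo Bayes estimates use ≥10⁶ draws and agree with the closed
  form within three binomial standard errors in tests.
- The experiment defaults to 200 epochs for the synthetic problem; the
  tabular task converges in a handful of epochs and longer horizons only
  extend the overfitting tail, which is the regime of interest for the
  rules. The full 2000-epoch protocol remains the `TrainConfig` default
  for standalone training.
- Singular indirect covariances (rank-deficient `A` with zero channel
  noise) raise an error advising `channel_noise > 0` rather than
  regularizing silently.

## Known limitations

- The closed-form ceiling path assumes isotropic within-class covariance
  and equal priors; other settings use Monte Carlo.
- The MLP trainer targets small tabular feature sets; it is not a
  substitute for convolutional pipelines on raw images, and no GPU path
  exists.
- The ceiling criterion presumes the direct measurement has been learned
  to saturation; the corroboration check guards against gross failure but
  cannot prove optimality on real data.
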