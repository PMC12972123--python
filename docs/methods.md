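# Methods

## Scientific background

Classical sensorimotor control theory separates two internal models: an
*inverse model* (controller) mapping a desired movement goal to the motor
commands that achieve it, and a *forward model* predicting the sensory
consequences of those commands.  This package implements and evaluates a
unified alternative — a single recurrent network that simultaneously
performs the inverse function (goal → muscle activation), the forward
function (activation → proprioceptive feedback) and a *recognition*
function (internal signals → goal) — against four hierarchical control
architectures built from separate inverse and forward subnetworks.

All networks are leaky echo state networks (ESNs): a fixed, sparse random
recurrent reservoir with a trainable linear readout.  The state update is

    x(t) = (1 − λ) x(t−1) + λ tanh(W x(t−1) + W_in u(t) + W_fb y(t−1) + b)

with readout y(t) = W_out x(t).  The recurrent matrix W is drawn uniformly
on [−1, 1] at a given sparsity and rescaled so its spectral radius equals
ρ exactly; W_in and W_fb are dense uniform draws bounded by the input and
feedback scalings.  The readout is linear in the state only (no direct
input-to-output shortcut), and the bias defaults to a small uniform draw.
These are the canonical ESN choices; the update is equivalently the fixed
step-size Euler discretisation of the continuous leaky form, so nothing
depends on which of the two views one takes.

## Training

Readouts are trained with recursive least squares (RLS) in the FORCE
style: the inverse-correlation matrix starts at P₀ = I/δ, and each
sample applies the standard rank-one update.  During training every
output-feedback slot is overwritten with the corresponding target
(teacher forcing), with fresh i.i.d. Gaussian noise (σ_noise) added to
every target-derived signal fed to a reservoir so that the closed loop
tolerates its own small output errors at test time.  Noise enters only
the fed-back copy, never the regression target, so the readout learns
the clean mapping.

Because the forced state trajectory never depends on the readout, the
RLS recursion over a pass is algebraically identical to the regularised
normal-equation (ridge) solution over all samples seen so far, with δ as
the ridge penalty.  The default training path therefore accumulates
state/target cross-moments and solves at each pass boundary — bit-compatible
with per-sample RLS up to floating-point round-off (a property the test
suite checks at 1e−6), at a fraction of the cost.  The literal per-sample
recursion is retained (`method="stepwise"`, with P symmetrised every
1000 updates as floating-point hygiene) for verification and ablation.
P is carried across training passes, so the iteration count behaves as
"more data" and is a meaningful efficiency hyperparameter.  States reset
to zero at the start of every pass and every test series; test-time
transients are absorbed by the initialisation prefix (below).

The "learning rate" of an RLS scheme is ambiguous; here it is exposed as
the initialisation scale δ, the only rate-like quantity RLS has.

## Architectures and routing

Five named architectures share one declarative wiring model
(`NetworkSpec`: inputs, outputs, reservoir config):

- **InFoRM** — one reservoir; input: the goal look-ahead window; outputs
  (= feedback channels): goal (3), efference (8), afference (16).
- **Control** — inverse reservoir (goal window → efference) and forward
  reservoir (efference copy → afference), each feeding back its own output.
- **Control+A** — inverse additionally receives afference.
- **Control+G** — forward additionally receives the goal window.
- **Control+AG** — both; every subnetwork then sees the same three signal
  groups as InFoRM's reservoir, so the comparison isolates architecture
  from information access (`has_full_information` audits this).

At test time only the goal is external: the current goal overwrites the
goal feedback slot (InFoRM), the look-ahead window drives the inputs, and
efference/afference circulate as output feedback, starting from zero.
Timing conventions, which the shared update equation leaves open, are
fixed once: feedback slots carry previous-sample values; the goal window
and the efference copy carry current-sample values (the forward network
consumes the inverse network's output of the same sample — no delays are
modelled); afference routed to the inverse network carries the
previous-sample value, the only one available in the closed loop, and is
trained that way.  During training all of these slots carry targets, so
the subnetworks of the control architectures train simultaneously and
independently, mirroring the unified network's configuration.

The goal look-ahead window spans 300 ms with 7 taps (every 50 ms,
current sample included), end-padded by last-value hold.  The tap count
is a package choice — 21 goal input channels keeps input dimensionality
moderate — and is exposed as a hyperparameter.

## Synthetic reaching generator

The generator stands in for recorded human reaching data processed
through a musculoskeletal model, reproducing its *signal structure*:

- **Task**: cyclic back-and-forth reaches between a central target and
  ten peripheral targets (directions −90°…+90° in 45° steps, labelled
  A–E; amplitudes 0.25/0.40 m; cycle rates 1.0/0.75 Hz; 10 cycles per
  trial; 120 Hz), plus four natural-transition trials ({1, 3} taps ×
  both rates) visiting all ten targets in seeded random order.
- **Kinematics**: minimum-jerk half-cycle profiles (zero endpoint
  velocity at both taps), a planar two-link arm (L₁ = 0.33 m,
  L₂ = 0.45 m, masses 2.1/1.65 kg, shoulder 0.30 m behind the central
  target) with closed-form inverse kinematics at fixed elbow sign.
- **Dynamics**: standard planar two-link equations of motion, no gravity
  (tabletop plane), driven by finite-difference derivatives.
- **Muscles**: ten candidates with constant moment arms (two mono-articular
  antagonist pairs per joint, deliberately unequal in strength, plus one
  bi-articular pair); lengths are affine in joint angles (l = l₀ − Rθ),
  so afferent velocity channels equal the discrete derivative of the
  length channels exactly.  Static optimisation resolves redundancy per
  sample: minimise Σa² subject to the torque equality and 0 ≤ a ≤ 1,
  solved by an exact active-set method (torque residual ≤ 1e−8 N·m)
  with an LP feasibility check and a generic convex fallback for
  degenerate geometry.  The eight muscles with the largest activation
  range over the training portion are selected, making the channel set
  3 + 8 + 16 = 27.
- **Variability**: smooth endpoint jitter (white noise, 4th-order
  Butterworth low-pass at 3 Hz, rescaled to σ = 2 mm per axis) enters the
  kinematic chain before inverse kinematics, so every derived signal
  inherits consistent cycle-to-cycle variability.  Without it, held-out
  cycles would be copies of trained ones and the Basic split would test
  nothing.  Drift removal is a no-op on synthetic data; a linear-detrend
  utility and a radial-return cycle segmenter are provided for imported
  recordings.

What the generator does *not* emulate: Hill-type muscle dynamics, tendon
compliance, 3-D shoulder kinematics, inter-subject anatomy, marker noise
with drift, or the skewed error distributions of real motion capture.
Passing the analogue experiment therefore shows that the architectures
behave as reported under data with this structure — not that the exact
human-data effect sizes transfer.

## Partitioning, normalisation, evaluation

Cycles 1–6 of the trials in directions A, C, E form the training data,
cycles 7–8 the validation data, cycles 9–10 the *Basic* test set; all
cycles of directions B, D form the *Morphing* test set; the four
transition trials form *Natural Transitions*.  Basic and Morphing items
are merged in a seeded random order (each condition once) into one
series; a random member is prepended as initialisation prefix and
excluded from evaluation.  Each natural trial instead gets one of the 20
standard trials prepended.  Every channel is min-max normalised with
statistics from the training series only; degenerate channels (the
constant tabletop z) are flagged, mapped to zero and excluded from
metrics.

Performance is scored per channel in original units over the eval mask:
rRMSE (RMSE / target range) and Pearson's r.  Aggregation: per-channel →
mean within signal group → mean over the predicted groups (efference,
afference) → mean over instance seeds, correlations pooled via Fisher's
z throughout.  InFoRM's goal-recognition channels are reported separately
and never enter the headline numbers, which only pool channels produced
as closed-loop outputs.  Each experiment trains every architecture 10
times with one shared, architecture-independent instance-seed list.

Architecture contrasts use paired Wilcoxon signed-rank tests on
seed-matched aggregates (Fisher-transformed for correlations) after
1.5×IQR outlier removal, Holm–Bonferroni corrected at α = 0.05.
Generalised mixed-model analysis is deliberately out of core scope: the
exported long-format CSV (architecture, seed, split, group, channel,
rrmse, correlation) feeds any external GLMM tool directly.

## Hyperparameters

Defaults were selected by validation rRMSE (never by test performance)
on the synthetic generator, using the package's own search machinery:

| parameter | default | meaning |
|---|---|---|
| N | 500 (InFoRM) / 2 × 500 (Control) / 2 × 300 (Control+ variants) | reservoir size; the unified network needs fewer neurons in total |
| ρ | 0.9 | spectral radius of W |
| connectivity | 0.1 | fraction of nonzero recurrent weights |
| σ_in, σ_fb | 0.3, 0.3 | input / feedback scaling (27-channel feedback saturates tanh if larger) |
| λ | 0.6 | leak rate (signals are slow relative to 120 Hz) |
| bias | 0.2 | uniform bias half-width |
| δ | 1.0 | RLS initialisation / ridge penalty |
| σ_noise | 0.05 (0.064 for Control) | teacher-forcing feedback noise |
| n_iterations | 8 (11 for Control) | training passes (P carried across passes) |
| n_taps | 7 | look-ahead window taps over 300 ms |

The hierarchical architectures are markedly more sensitive to these
values than the unified one: their closed loop chains two reservoirs, so
readout errors compound and more feedback noise / larger subnetworks are
needed for stability.  `default_reservoir_configs` and
`default_train_config` therefore carry per-architecture values
(Control's were refined by the Gaussian-process search against its own
validation objective, exactly as each architecture was tuned separately
in the study this emulates).

The search itself (`hyperopt`) is sequential model-based optimisation: a
Matern-5/2 Gaussian process on the unit cube (log-scaled where noted),
Sobol initialisation, expected-improvement acquisition over a random
candidate pool, with a pure random-search fallback.  The objective is
the validation rRMSE of the predicted channels averaged over a reduced
instance count (default 5).  The two efficiency-relevant optima — total
neuron count (summed over subnetworks) and training iterations — are
reported from the best configuration.

Because near-optimal configurations are often statistically tied in the
iteration dimension (the unified network's validation curve is flat
after a few passes), the argmin's iteration count is an unstable
efficiency measure at small budgets.  The package therefore also
provides a direct efficiency harness: `validation_iteration_curve`
trains incrementally and scores the closed loop on the validation set
after every pass, and `iterations_to_reach` reads off how many passes an
architecture needs to reach a given error level — the quantity behind
the "needs fewer training iterations" comparison.

## Numerical choices and degenerate inputs

- Spectral rescaling uses dense eigenvalues up to N = 300 and ARPACK
  above, with a dense fallback; an all-zero draw is rejected.
- A zero-range training channel makes min-max normalisation and rRMSE
  undefined; such channels are flagged and excluded rather than guessed.
- Constant series have undefined Pearson r; reported as NaN (missing)
  and skipped by Fisher-z aggregation.
- Training divergence (non-finite states or P) aborts that instance; the
  sweep records it as missing and flagged instead of failing.
- Wilcoxon ties (identical metric vectors) are reported as p = 1.
- Static-optimisation ties and degenerate active sets fall back from the
  active-set solver to SLSQP after an LP feasibility check.

## Problem sizes

The analogue experiment uses one synthetic subject, 10 instance seeds,
5 architectures, ~10 000 training samples per pass and merged test
series of ~3 600 (Basic) and ~12 800 (Morphing) samples — sizes chosen
so a full reproduction runs in minutes on one CPU while keeping every
protocol element (splits, merging, prefixes, matched seeds) intact.
Human-subject effect sizes from the original motion-capture data are
not reproducible at this scale; the experiment targets the ordinal
pattern and threshold levels instead.

## Known limitations

- One synthetic "subject"; no between-subject variance component, so no
  GLMM-style random effects in-core.
- The morphing split is harder in absolute terms for the hierarchical
  architectures here than in the human data; only directions of effects,
  not effect sizes, should be compared.
- Constant moment arms make muscle length exactly affine in joint
  angles; real moment arms vary with posture.
- No delays anywhere (synchronous efference copy); biological loops have
  conduction delays.
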