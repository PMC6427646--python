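# Methods

## Scope and model

`spiketempo` decodes the class of a stimulus from one trial of
multi-channel spike times. The decoder is a two-layer spiking network:
N input channels (one per recorded unit) project with plastic weights
onto C groups of G leaky integrate-and-fire output neurons, one group
per class. Output neurons fire at most one spike per trial, so no
reset or refractory dynamics are modeled; all learning quantities are
computed from the *unshunted* voltage trace and its maximum.

The postsynaptic kernel is the double exponential
`K(Δt) = V₀ (e^{−Δt/τ} − e^{−Δt/τs})` for Δt ≥ 0 and zero otherwise.
`V₀ = 1 / (e^{−t*/τ} − e^{−t*/τs})` with peak lag
`t* = τ τs/(τ−τs) · ln(τ/τs)` normalizes the peak to exactly 1, so a
weight of 1 on a single spike produces a unit voltage excursion and the
firing threshold θ = 1 has a natural scale. τ > τs is required; the
degenerate τ = τs kernel (no positive peak) is rejected.

## Learning rules

**Classic (error-gated).** Each neuron is trained one-vs-rest: on a
trial of its own class it should fire, on others stay silent. On an
error, the weight of channel i changes by
`±λ Σ_{tᵢ<t_max} K(t_max − tᵢ)`, the kernel-weighted credit of that
channel's spikes at the voltage maximum. Correctly behaving neurons are
untouched, so an epoch with zero neuron-level errors leaves the weights
bit-identical — this gating is tested exactly.

**Voltage-regulated (VR).** The error gate is replaced by the factor
F′ derived from softplus-transformed voltage maxima across groups
(`f(V) = ln(eᵛ+1)`, which keeps every transformed voltage positive and
every denominator nonzero): positive for the target group, negative for
the rest, applied to every neuron on every presentation. The n-th
neurons of the C groups form one interacting set; factors are computed
within each such set. Algebraically this is stochastic gradient ascent
on `ln(f(V_target)/Σₘ f(Vₘ))`, a log-softmax-like margin objective, so
improvement continues — deliberately — after training accuracy has
saturated.

A consequence we found important in practice: **VR must not be
early-stopped on a training-accuracy plateau.** Its generalization
benefit accrues precisely in the post-plateau phase in which classic
training would have nothing left to do. The trainer therefore runs VR
for the full epoch budget, while classic mode stops at a zero-error
epoch (provably frozen from there) or after `early_stop_patience`
epochs without training-accuracy improvement. Final-epoch weights are
returned in both modes; no best-epoch snapshotting is done.

## Readout

Per trial, each neuron's maximal voltage is compared with θ; the class
whose group has the most firing neurons wins. Ties — including the
common all-silent case early in training and after heavy truncation —
fall back to the largest summed voltage maximum over the tied groups'
neurons, then to the lowest class index. The fallback makes the readout
total and deterministic.

## Numerics

The voltage maximum of a weighted kernel sum lies between events, so
`max_voltage` evaluates V on the union of all spike times and a uniform
grid (default step 1 ms, a fifth of the smallest τs in the default CV
grid), then refines around the best grid point with bounded scalar
minimization (tolerance 1e−6 s). The trial boundary is part of the
grid because the maximum can sit at the end of a truncated window. Ties
in the argmax break toward the earliest time.

Training uses a fast path: each trial is compiled once into a matrix
`P[g, c] = Σ_{tᵢ<t_g} K(t_g − tᵢ)` of per-channel kernel sums on the
evaluation grid, so every neuron's trace is a single matrix product
`P·w` reused across all epochs, and the update credit at t_max is just
the corresponding row of P. The golden-section refinement is skipped
here; at the 1 ms grid the residual t_max error is far below the kernel
time scale (τs ≥ 12.5 ms in the default grid) and has no measurable
effect on updates.

Default hyperparameters, all exposed in `TrainConfig`/`LIFParams`:
λ = 5e−3, G = 5 neurons per group, Gaussian(0, 0.01²) weight
initialization with an independent seeded stream per neuron,
max_epochs = 200, patience 60 (classic only), θ = 1, V_rest = 0. τ is
meant to be selected by the cross-validation harness from
{0.05, 0.1, 0.2, 0.5, 1.0} s with τs = τ/4 (the classic convention);
experiments here default to τ = 0.2 s.

## Bin-count baselines

The conventional pipeline counts spikes per channel in half-open bins
`[b·h, (b+1)·h)` over an analysis window that must divide evenly by the
bin width (the experiment sweeps only offer widths that do), and
concatenates channel-major. Decision tree, KNN, LDA and both SVMs are
scikit-learn; the diagonal-Gaussian maximum-likelihood classifier is
implemented here because a full covariance is singular at these sample
sizes (tens of trials against N·M features); its variances are floored
at 1e−6.

## Synthetic data

The generator emulates the geometry of trial-based olfactory-bulb
recordings: 11 channels, 4 classes, 20 trials per class, 5 s trials.
Class structure is injected two ways. Each class owns per-channel
latency templates (6 spikes drawn once from Uniform(0, duration)),
jittered per trial with Gaussian sd 10 ms — a precise-timing code.
Independently, background activity is homogeneous Poisson per channel
(2 Hz default), optionally scaled per class by `rate_contrast`. With
`rate_contrast = 0` the expected spike counts are identical across
classes, making the classes separable *only* by timing; this is the
regime used to demonstrate that single-bin rate features are blind to
the code while the spiking decoders are not. The 2 Hz / 6-spike /
10 ms operating point was fixed once as a regime where timing signal
and Poisson clutter are comparable in volume (110 background vs 66
template spikes per trial), so decoding is noisy but feasible.

What the generator does *not* emulate: breathing-locked rhythms,
inter-neuron correlations, odor-concentration dependence, slow drift
across recording days, and non-stationary firing during the stimulation
window. Passing tests therefore show that the implementation realizes
the intended computations and their relative behaviors on a latency
code with Poisson clutter — not that any absolute accuracy carries over
to real recordings.

Jittered template times are clipped to the trial window; exact
duplicate times (possible after clipping) are nudged apart by +1 µs to
preserve strictly increasing spike times.

## Evaluation protocols

The reference protocol repeats a stratified split (default 16 train /
4 test per class), trains a fresh decoder per repetition, and averages
held-out accuracy; 100 repetitions by default, reducible everywhere.
Splits derive from a master seed via spawned substreams and never
depend on the decoder, so different decoders compared at the same seed
see identical splits. Hyperparameter selection uses a stratified 20%
holdout of the training set, scored per grid point, ties to the earlier
entry, winner refit on the full training set. Sweeps rerun the
protocol along bin width, number of training sample groups (one trial
of each class per group), or truncation window; in the time-period
sweep both training and test trials are truncated, since a deployed
quick detector only ever sees the short window.

Two statistical cautions are built into the test suite and worth
stating here. First, repeated splits of one fixed dataset produce
correlated accuracy estimates, so chance bands use the number of
distinct trials, pooled over independently generated datasets, rather
than the raw number of predictions. Second, the VR-vs-classic
comparison is dominated by dataset-level variance; the directional
claim is therefore assessed paired over many independent dataset draws
(8 draws × 6 shared splits at 2 training groups per class in the
suite). Under these synthetic conditions the measured advantage is
small (≈ +1–2 accuracy points); the mechanism is the margin growth
described above, and the effect grows as training sets shrink.

## Problem sizes used in the shipped checks

The suite and the acceptance script scale the protocols to desk size as
the package's own defaults for routine verification: ≤ 8 synthetic
datasets of 80 trials, ≤ 6 repetitions per dataset, 200-epoch budgets.
All are parameters; nothing in the library caps larger studies.

## Known limitations

- VR's advantage here is demonstrated directionally on synthetic data;
  absolute margins on real recordings cannot be validated without them.
- The multi-spike Tempotron family, conductance-based synapses, and
  alternative neuron models are out of scope.
- `max_voltage` is exact only up to the grid-plus-refinement scheme;
  pathological weight vectors with near-flat maxima can resolve t_max
  to a different near-tied location than an infinite-precision search.
- The file format stores one row per spike; datasets with millions of
  events would want a binary container instead.
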