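# Methods

This note documents the model, the fitting procedure, the synthetic input
generator, and the numerical and design choices made where the problem was
genuinely open. Units are ms, mV and Hz throughout unless stated.

## Forward model

Time is discretized on a uniform grid, default `dt = 1 ms`; bin *k* spans
`[t0 + k·dt, t0 + (k+1)·dt)`. Spike trains are binned to counts and
convolved with sampled kernels (direct convolution for short kernels, FFT
otherwise); a per-spike direct-summation implementation is kept as the
test oracle. Continuous-time (event-driven) evaluation is out of scope.

**Kernels.** Each synapse group has an alpha-function kernel
`κ(t;τ) = H(t)(t/τ)e^{−t/τ}` with amplitude `w` (mV per spike, negative
for inhibition), time constant `τ` and delay `Δ`. Excitatory kernels may
carry a second, slow component; by default its time constant is coupled to
the fast one as `τ_slow = 10.4 + 2.8·τ_fast`, which captures fast+slow
receptor mixtures with one fewer parameter. Kernel support is truncated at
`Δ + 10·max(τ)`; the discarded alpha tail is `(1 + 10)e^{−10} < 10⁻³` of
the kernel mass (closed form, verified in tests). Delays are rounded to
the nearest bin: sub-bin delays are unidentifiable at the grid resolution.
Because bin rounding makes delays non-differentiable, the optimizer holds
them fixed at their initial values; they are still model parameters and
are included in parameter counts.

**Subunits.** A subunit sums its groups' filtered signals plus its
children's coupled outputs and applies a unit-slope logistic sigmoid
`σ(y − θ)` or the identity. The sigmoid slope is fixed by construction —
the effective gain of a subunit is carried by the synaptic weights and the
coupling `c`, so a free slope would be redundant. Couplings and time
constants are optimized in log space, which enforces positivity exactly.
Multiplexed subunits run two parallel channels over the same spike trains;
child-subunit outputs enter the first channel (the convention must be
fixed somewhere; routing children into one channel preserves the
single-channel equations unchanged).

**Parameter counting.** For the canonical configuration (single kernels,
nonlinear outputs) the count is `N_p = 1 + 3·N_syn + 2·M` (offset;
amplitude/time-constant/delay per group; coupling and threshold per
subunit). `count_params` generalizes this by explicit enumeration — an
extra amplitude per two-component kernel, an extra time constant when the
slow component is uncoupled, no threshold for linear subunits. The
enumeration in the optimizer's `Parameterization` is the source of truth
for what is actually fitted (it shares delays per subunit, holds them
fixed, and drops the root coupling when the root is linear, where it is
redundant with the weights).

**Somatic response amplitudes.** The somatic impact of one synapse is its
weight times the gain of every subunit on the path to the root,
`a_ji = w_ji · c_j σ'(ȳ_j − θ_j) · Π_k c_k σ'(ȳ_k − θ_k)`. The operating
point ȳ is taken as the mean of each subunit's total-input distribution
under the training input ("resting" slope); this is configurable, and the
midpoint slope 1/4 is used when no input is supplied.

## Fitting

The objective is the mean squared deviation between target and model
voltage, optionally plus a log-normal penalty (below). Gradients are
analytic: a reverse sweep through the tree computes the adjoint
`∂v/∂y` per channel, and kernel gradients convolve the binned counts with
the kernel's τ-derivative. Finite-difference agreement to 1e-5 relative on
every parameter class is enforced in the test suite. The optimizer is
L-BFGS (a quasi-Newton method; any gradient-based optimizer honoring the
descent contract can stand behind the same interface); tolerances default
to `gtol = 1e-7`, 400 iterations, both configurable since no canonical
values exist.

The error surface is non-convex, so fitting proceeds in stages:

1. **Coupled stage.** A single-subunit linear model in which all
   excitatory synapses share one (amplitude, τ) pair — two in double-kernel
   mode — and all inhibitory synapses another. Amplitudes and offset are
   first solved in closed form by linear least squares at the initial time
   constants, then everything is refined jointly. Delays stay at their
   configured (bin-rounded) values, default 0.
2. **Pre-tuning.** The target architecture inherits the coupled kernels,
   and each sigmoid is initialized to approximate linear integration:
   proceeding from the leaves, the inputs to each nonlinear channel
   (kernel amplitudes, child couplings) are rescaled by `α = 1/(ρ·SD(y))`,
   the threshold is set to the rescaled input mean, and the subunit
   coupling is multiplied by the old local gain divided by `0.25·α` — so
   the linearized end-to-end gain, and with it every per-synapse somatic
   amplitude, is preserved exactly; `v0` absorbs the constant offset.
   Larger ρ means a more linear operating regime; the scan over
   ρ ∈ {1,…,8} keeps the candidate with the lowest post-optimization
   training error, ties going to the smaller ρ. Pre-tuning is defined for
   single-channel subunits; multiplexed architectures are initialized from
   a pre-tuned single-channel fit by cloning the channel at reduced weight
   (`add_multiplexing`).
3. **Decoupling.** Kernel parameters are untied down to synapse groups
   (the proximal/middle/distal position classes) and re-optimized. When
   there are more groups than subunits, a log-normal prior guards against
   overfitting: quadratic penalties on `log|w|` and `log τ` centered on
   the coupled-stage values, SD 0.5 log-units each, with a weight (default
   0.1 mV² per squared log-unit) converting the penalty into the units of
   the MSE. The penalty is placed on the kernel amplitudes rather than on
   the somatic response amplitudes directly; because the staged
   initialization preserves somatic amplitudes, the two coincide at the
   initialization point, and the penalty gradient stays independent of the
   input distribution. The reference variance of somatic responses that
   would ideally calibrate the prior SD requires per-synapse stimulation
   experiments, so the SD is exposed as configuration.

Because each stage starts from the previous stage's solution (pre-tuned to
reproduce it in the linear regime) and the optimizer never returns an
iterate worse than its start, training error is non-increasing across
stages, and a simpler model's training error bounds the richer model's
from above — a machine-checked invariant. The bound is meaningful when the
data are at least as rich as the richest fitted class; fitting the
generating class itself drives training error to numerical zero.

**Cross-validation.** When no explicit test set is supplied, the last 20%
of the trace is held out. The first 500 ms of a held-out segment are
excluded from the variance-explained score: the target there still carries
kernel tails of spikes before the segment boundary, which the prediction
cannot see, and scoring them would charge the model for an edge artifact.
Protocol-level evaluation over ten independent segments (default 48 s
each) is supported by the evaluation module and the CLI.

## Spiking extension

The subthreshold response drives an inhomogeneous Poisson process through
`λ(t) = λ₀ exp(β v(t))`. Post-spike adaptation adds
`Σ_j γ_j ψ_j(t)` to the root subunit's input, where ψ_j are N_Ψ = 10
raised-cosine bumps `½[cos(a·log(τ+c) − φ_j) + 1]` with a = 3.75,
c = 0.01 and centers φ uniform on [3, 22], each convolved with the output
spike train. The bump lag τ is in **milliseconds**: with these constants
the supports then span ≈1 ms to ≈0.8 s — the range of spike-frequency
adaptation — whereas reading τ in seconds would put them at 1–800 s.
Adaptation weights γ are unconstrained in sign (suppression and
facilitation both occur) and are fitted with the subthreshold parameters;
for a linear root this is an exact linear least-squares solve. (λ₀, β) are
fitted by maximizing the discrete-time Poisson likelihood, which is
concave in (log λ₀, β). Spikes are sampled by per-bin thinning with at
most one spike per millisecond bin; absolute refractoriness is not modeled
— suppression comes only from negative adaptation weights.

## Input generator

The generator emulates the synaptic input of a visual-cortex L2/3
pyramidal cell during drifting-grating stimulation. Defaults are the study
conditions: 13 excitatory ensembles; background 5 Hz and elevated 20 Hz;
switch-on rate tuned between 0.5 and 14 Hz by stimulus orientation;
switch-off rate 20 Hz; active states capped at 150 ms; OU rate
fluctuations with τ = 500 ms and stationary SD 2.5 Hz (background) /
10 Hz (elevated), shared within an ensemble and clipped at 0 Hz; an
inhibitory population (default 540 synapses: 120 dendritic plus 420
perisomatic in the reference cell) whose rate tracks the instantaneous
mean excitatory rate affinely from 20 Hz (all background) to 30 Hz (all
elevated); 3 s blocks of each of 16 orientations (48 s sessions); ensemble
preferred orientations from Normal(0°, 33°) rounded to the 22.5° wheel.

Open choices, decided as follows:

- **Tuning curve.** Only a sinusoidal orientation dependence is specified;
  implemented as `Ω_on(Δθ) = mid + half·cos(2Δθ)` (period 180° on the
  orientation circle), anchored at 14 Hz (preferred) and 0.5 Hz
  (orthogonal).
- **Duration truncation.** Active durations are exponential draws capped
  at 150 ms (rejection-free), so the 150 ms bound is hard; capping piles
  the tail mass at the cap rather than redistributing it as resampling
  would.
- **OU discretization and clipping.** Exact one-step discretization
  `r_{k+1} = eq + (r_k − eq)e^{−dt/τ} + sd·√(1−e^{−2dt/τ})·ξ`; clipping at
  0 Hz introduces a bias that is negligible at the default SDs (the
  background equilibrium sits 2 SD above zero).
- **Inhibitory tracking.** "Instantaneous mean" is read as the
  OU-fluctuating mean rate, not the state equilibrium, so inhibition
  inherits the slow fluctuations.
- **Ensembles and morphology.** Ensemble membership is metadata only
  (`ensemble_id`); the morphology-based clustering of synapses on dendritic
  subtrees is not modeled.
- Within a stimulus schedule the switching chain runs per-bin with
  piecewise-constant Ω_on (transition probability `1 − e^{−Ω dt}`), which
  keeps the duration cap exact across block boundaries; for a fixed Ω_on
  an event-driven sampler with exact exponential durations is used.

**What passing generator tests show.** The generator reproduces the
specified rate, switching, fluctuation and tracking statistics; it does
not reproduce biophysical features of real input — conductance dynamics,
spatial clustering on a morphology, or spike-timing correlations beyond
the shared rate processes. Fits that succeed on these inputs demonstrate
correctness of the estimation machinery under the intended input
statistics, not performance on in vivo recordings.

## Evaluation statistics

`variance_explained` is `1 − MSE/Var(v)`. Plateau probability is the
fraction of bins strictly above a threshold, default −35 mV.
The autocorrelation timescale is estimated by a least-squares fit of
`e^{−lag/τ}` to the normalized autocorrelation (mean over segments),
default lags 0–500 ms (0–2000 ms when validating the OU inputs, whose
τ = 500 ms needs a longer window); no canonical estimator exists, so the
fit range is exposed. Voltage histograms use 1 mV bins by default.

## Problem sizes

The test suite and the acceptance script use desk-scale simulations chosen
to make the Monte-Carlo error bands small relative to the tested effects:
48 s sessions with 100 synapses for fitting contracts, 200 s for
state-conditional rates (3-SE bands), 500 s for spiking-parameter
recovery, 1,000 s for OU fluctuation statistics, 10,000 draws for the
duration cap. Deeper hierarchies than two layers fit with the same code
but need longer data for comparable parameter-recovery precision; the
recovery bounds asserted in tests apply to the single-subunit and
two-layer configurations exercised there.

## Known limitations

- Instantaneous nonlinearities only: dendritic spike generation and
  propagation dynamics are outside the model class.
- Delays are not optimized (fixed at bin-rounded initial values).
- Pre-tuning covers single-channel subunits; multiplexed fits rely on the
  clone-and-perturb initialization.
- The spiking mechanism predicts rates; spike-timing precision is limited
  by the Poisson assumption.
- Architecture search is manual: candidate architectures are supplied,
  not learned.
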