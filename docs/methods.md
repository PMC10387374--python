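# Methods

## Scientific setting

Neurons in a recorded population express a shared latent dynamical system:
the population state x(t) evolves under learned dynamics perturbed by
unobserved external inputs u(t), and single-trial activity is a noisy,
indicator-filtered readout of that state. The scientific question this
package operationalizes is whether the latent system behaves as a **line
attractor** — a one-dimensional continuum of fixed points along which
reward evidence is summed and stored across trials — or as a **point
attractor**, where every perturbation decays and nothing accumulates.
The package provides (i) a ground-truth simulator for both regimes, (ii) a
causal sequential variational autoencoder that fits a generator RNN to
trial-structured fluorescence, (iii) fixed-point analysis of the trained
generator, (iv) targeted dimensionality reduction, (v) in-silico
reward-probability titration, (vi) the session-statistics battery for nested
neural data, and (vii) fiber-photometry preprocessing.

## Ground-truth simulator (`calfads.synth`)

Discrete-time linear latent dynamics at the analysis bin size (200 ms):
x_{t+1} = A x_t + p_t. For a line system, A has exactly one eigenvalue at 1
(eigenvector = the integration mode) and all remaining moduli ≤ 0.9; for a
point system all moduli ≤ 0.9. Trials consist of a pre-cue baseline, a cue
pulse in a direction transverse to the integration mode, and an outcome
pulse ~1 s after cue onset: the rewarded pulse has cosine 0.9 with the
integration mode (so rewards integrate), the unrewarded pulse is orthogonal
to it (so omissions do not). The latent state carries over between trials by
default, so reward history accumulates and pre-cue baselines ramp across a
session — the signature the downstream statistics detect. Rates are an
affine readout with strictly positive loadings on the integration mode
(accumulated evidence raises bulk activity, as a photometry signal would
show); fluorescence is the rate sequence filtered by a causal
single-exponential calcium kernel (τ = 0.6 s, unit DC gain, initialized at
the pre-session equilibrium) plus i.i.d. Gaussian noise (SD 0.2 in units
where baseline rates are ~1).

Default amplitudes (cue 0.03, outcome 0.05 split over two bins) were chosen
once so that roughly one hundred rewarded trials span a several-fold change
of bulk activity over a session, matching the within-session dynamic range
typical of head-fixed reward-task recordings. What the generator does *not*
emulate: spiking discreteness, per-neuron indicator nonlinearity, slow
drifts unrelated to reward, behavioural covariates, and non-stationary
noise. Passing parameter-recovery tests on these sessions therefore shows
the inference machinery is correct and well-calibrated for this model
class, not that real recordings satisfy the model.

## Network and objective (`calfads.model`)

The model is a sequential VAE in the LFADS lineage with two changes suited
to continuous fluorescence: a Gaussian emission with a learned per-neuron,
time-independent variance, and strictly causal encoding (forward-only
encoder GRU; every inferred quantity at bin t is a function of observations
at bins ≤ t, enforced by a property test). The generator GRU evolves from a
per-trial initial condition g0 and receives a 1-dimensional inferred input
u(t); factors and per-neuron means are linear readouts.

Posteriors are diagonal Gaussians. The g0 prior is N(0, I). The input prior
is a stationary **AR(1) process** (correlation time 0.2 s = one bin,
stationary variance 1). The short-memory prior is load-bearing: with an
i.i.d. wide prior the posterior can carry slowly varying drive for free, and
the generator then has no incentive to store slow structure in its own
dynamics — inferred inputs become persistent, attractor structure degrades,
and condition-averaged inputs lose trial-type specificity. The AR(1) KL and
its gradients are closed-form (`ar1_sequence_kl`) and are verified against
an independent full-covariance Gaussian KL oracle in the tests.

Training maximizes the ELBO with Adam (full batch, learning rate 5e-3
decaying by 0.997/epoch with a floor of 2e-4), linear KL warm-up over the
first 50 epochs, gradient clipping by global norm (10), dropout on encoder
inputs and generator outputs (keep rate 0.98), and an L2 penalty on the two
recurrent weight matrices. Odd trials (1-based session order) train, even
trials validate; early stopping keeps the parameters with the best
validation ELBO (evaluated every 5 epochs, always at full KL weight).
Encoder inputs are standardized per neuron using training-set statistics;
emissions are on the raw fluorescence scale. All gradients are hand-derived
backpropagation through time, checked against central finite differences
for every parameter group.

Trial indexing for the odd/even split is 1-based in session order. The
controller is a per-bin MLP on the causal encoder state (no factor
feedback); this keeps inference strictly causal, keeps the ELBO exact, and
is the simplest wiring consistent with a forward-only architecture. The
initial-condition posterior is read from the encoder state after the first
bin — the only choice that preserves causality at every bin — which makes
g0 weakly determined; the AR(1) prior confines the resulting correction
drive to the first few bins of a trial, and condition-averaged input
windows are taken relative to a cue placed ≥ 1 s after segment start so the
boundary transient stays outside them.

Paper-scale defaults (256 generator units, 32 factors, 256-unit encoder and
controller) are documented in `ModelConfig`; synthetic experiments use
`ModelConfig.test_scale()` (64/8/1/64/64), which is the scale at which all
tests and the acceptance script run.

## Fixed-point analysis (`calfads.fixed_points`)

The generator is a discrete-time map, so fixed points satisfy F(h, u*) = h
and the minimized objective is the squared one-step speed
q(h) = ‖F(h, u*) − h‖² with no ½ factor; the thresholds 3e-4 and 1e-3 are
interpreted on this convention. The reference input u* is the trial-averaged
pre-cue inferred input. Search: 512 initializations subsampled from
posterior-derived generator trajectories with Gaussian jitter (0.1 × state
SD), vectorized Adam descent with the exact gradient 2(J−I)ᵀ(F(h)−h)
computed by a vector-Jacobian product. Candidates above threshold are
discarded; survivors merge greedily within a tolerance (0.01 × RMS state
norm), keeping each cluster's lowest-speed representative. Jacobians are
exact (analytic GRU derivative), validated against central finite
differences.

**Relevant fixed points.** Slow regions far from any visited state say
nothing about the dynamics the network actually uses, and retaining them
dilutes the principal-component structure of the point cloud. When
reference trajectories are supplied, retained points are therefore
restricted to those within 0.5 × (mean per-dimension state SD) of a visited
posterior state; the filter never empties a nonempty set.

Classification (frozen): *line* iff ≥ 5 retained points, PC1 of the cloud
explains ≥ 90% of variance, and the median count of Jacobian eigenvalues
with modulus within 0.05 of 1 equals 1; *point* iff all survivors merge to
a single cluster with no near-unit eigenvalue; otherwise *other*.

Known limitation, measured in this implementation: generator RNNs trained
on line-attractor sessions here routinely carry a *second* marginal
direction (second eigenvalue modulus ≈ 0.999) — a redundant internal
integrator that reconstruction does not penalize and the mild recurrent L2
does not remove. The slow-point cloud is nonetheless strongly
one-dimensional after proximity filtering (PC1 ≥ 0.9). Under the frozen
rule the extra marginal mode pushes the median near-unit count to 2, so
such models classify "other" rather than "line"; point-attractor models
classify "point" cleanly. This is reported as-is rather than absorbed by
loosening the rule.

The line-attractor mode is the unit-norm first principal component of the
retained points, signed to project positively on the total-activity
direction.

## Targeted dimensionality reduction (`calfads.geometry`)

Three ordered directions — total-activity (all ones), condition-independent
(mean activity in the 1 s reward period minus the 1 s pre-cue period), and
line-attractor (PC1 of the slow points) — orthonormalized by classical
Gram-Schmidt in that order before projection. All three modes are computed
in reconstructed per-neuron rate space; generator states and fixed points
are mapped there through the model's linear readouts (the all-ones vector
is only meaningful in neuron space, while fixed points live in generator
space — computing everything in rate space reconciles the two). Activity is
not z-scored before projection; denoised means are used as-is.

## In-silico titration (`calfads.insilico`)

The trained generator runs as a standalone system: per trial, the
condition-averaged inferred input (window −1 s to +3 s around cue) of a
Bernoulli(p_reward)-sampled trial type, then 1 s of exactly zero input for
inter-trial relaxation; a session stops after the relaxation of the 10th
rewarded trial or at a 40-trial cap (the cap terminates low-p sessions; the
stop rule alone would not). Initial conditions are sampled uniformly along
the segment spanned by the retained slow points. The photometry proxy is
the rate-space trajectory projected on the total-activity mode; the
accumulation curve indexes its mean over each rewarded trial's 1 s reward
period by n-th rewarded trial, and the slope is the OLS slope of that
curve, averaged over sessions.

Limitation: at this problem scale the trained models attribute most of the
across-trial drift to a trial-type-independent component of the inferred
input, so rewarded and unrewarded rollouts shift bulk activity by similar
amounts and the titration slope scales like 1/p rather than increasing
with p. The acceptance suite reports this failure honestly; see the README
note on reproducing results.

## Session statistics (`calfads.stats`)

* Wilcoxon signed-rank: zeros dropped, average ranks for ties. Exact p for
  n ≤ 25 via a dynamic program over sign assignments of doubled ranks
  (exactness with ties is why this is hand-written); normal approximation
  with tie correction and continuity correction above. Two-sided p doubles
  the smaller tail, capped at 1.
* Benjamini-Hochberg step-up FDR (statsmodels backend), validated against a
  definitional O(m²) oracle.
* Task modulation: 1 s pre-cue baseline vs four sequential 1 s windows from
  cue onset, per trial type; a neuron is modulated iff any window is
  significant at 0.01 after BH pooled across all neurons × windows.
* Recovery time: 2 s pre-perturbation baseline vs sequential 0.5 s windows;
  recovery at the earliest window start whose three consecutive windows are
  all non-significant (BH pooled across neurons × windows at 0.01, matching
  the task-modulation pooling); NaN if none qualifies.
* Ramping: OLS of 2 s pre-cue baseline rate on trial index; two-sided
  t-based p on the slope at 0.05; direction by slope sign. Guard: ≥ 10
  trials (≥ 5 pairs for Wilcoxon) — minimum-n guards are ours, chosen for
  test validity.
* Hierarchical bootstrap: resample sessions with replacement to the
  original session count; within each drawn session its own neuron count of
  neurons; within each drawn neuron its own trial count of trials ("matching
  the size of the original dataset" read as matching the nested shape;
  a flat-count reading would break per-session structure). 100 iterations;
  SEM = SD of resampled means; one-sided p in the direction of the observed
  statistic with add-one smoothing (k+1)/(B+1) so p is never exactly 0 — a
  deliberate, documented deviation from the raw fraction.
* Integration statistic: per-trial 2 s baseline subtraction, mean over the
  5–7 s post-onset window, hierarchical bootstrap of the grand mean.

## Photometry (`calfads.photometry`)

Control correction: the 405 nm channel is resampled to 60 Hz (polyphase),
low-pass filtered (zero-phase 2nd-order Butterworth, 2 Hz cutoff — filter
family and cutoff are frozen choices, the workflow names neither),
resampled back to the acquisition rate, fitted to the 490 nm channel by
affine least squares (gain + offset), and subtracted. The chain is centered
before resampling so it is exactly affine-equivariant: rescaling the
control channel leaves ΔF unchanged to machine precision. %ΔF/F divides by
(session-mean F − rig baseline F); z-scores use the window from the first
trial start to 10 s after the last trial end and are applied to the whole
series.

## Problem sizes and determinism

Synthetic experiments run at 30 neurons, 120 trials, 32–40 bins per trial
(200 ms bins, cue at bin 10), 4 latent dimensions, and the 64/8 model
scale; training runs up to 1000 epochs (400 for point-attractor sessions,
which converge faster), and titrations use 100 sessions per probability.
These sizes were chosen so the full pipeline runs in minutes on one CPU
while keeping every qualitative contrast (line vs point, ramping vs flat)
well resolved. Every stochastic step takes an explicit seed; the pipeline
fans a master seed out to stages via `numpy.random.SeedSequence.spawn`, and
end-to-end runs are bitwise reproducible given the master seed.
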