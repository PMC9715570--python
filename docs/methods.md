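# Methods

This note documents the models implemented in `hiermotion`, the choices
made where the design was genuinely open, and what the synthetic tests do
and do not establish.

## Generative model

A scene is a tree of latent motion sources.  Each component `m` owns one
source per spatial dimension (translational components; self-motion is a
translational component with coefficient −1 at every visual input and +1
at the vestibular input) or a geometry-defined set of sources
(location-indexed polar components).  Sources follow independent
Ornstein–Uhlenbeck processes `ds = −s/τ_s dt + λ dW` with stationary
variance `τ_s λ²/2` per dimension — a slow-velocity prior.  Observed
velocities are frame-sampled sums `v ~ N(C s, σ_obs²/δt I)`; the `1/δt`
scaling keeps the stream's information rate independent of the frame
rate.  Sources are integrated with the exact AR(1) discretization
(`a = e^{−δt/τ_s}`, matched innovation variance), so stationary statistics
are unbiased at any frame rate.

Polar components (fixed input locations only):

- vertical-axis rotation: one source `s_rot` (angular velocity, CCW
  positive seen from above), with `v_x = −R_k sin(φ_k) s_rot`, `v_y = 0`
  (frontal view; the depth component is unobserved);
- fovea-centered motion: a pair `(s_r, s_φ)` under one strength, with
  `v_x = s_r cos ϑ_k − s_φ R_k sin ϑ_k`,
  `v_y = s_r sin ϑ_k + s_φ R_k cos ϑ_k`.

Column norms use the raw geometric coefficients; no extra normalization is
applied.  Coordinates: x rightward, y upward, angles counter-clockwise
from +x.

## Online inference

The algorithm alternates, in continuous time, a filtering step for the
sources (with the structure held fixed) and a slow update of the squared
strengths (from the filtered sources):

    dλ_m²/dt = −λ_m²/τ_λ + α_m ⟨μ² + f_Σ(λ²)⟩_cols + β_m
    dμ/dt    = −μ/τ_s + f_Σ(λ²) ⊙ Cᵀ ε,   ε_k = (v_k − (Cμ)_k)/σ_k².

The adiabatic posterior variance `f_Σ` is the stationary solution of the
per-source Riccati equation with off-diagonal covariance dropped.  With
heterogeneous per-input noise, the ratio `‖c_m‖²/σ_obs²` generalizes to
the precision-weighted column norm `g_m = Σ_k C_km²/σ_k²` (this reduces
exactly to the uniform-noise closed form and is what contrast
manipulations and the vestibular channel use).

**Dimensions and priors.** `⟨·⟩_cols` averages the statistic over a
component's source columns.  Each column contributes an independent
observation of `λ²`, so the prior's weight relative to the data shrinks
with the number of columns `D`; the low-pass constants are

    α_m = 2 / (τ_s² (2/D + ν_m + τ_λ/τ_s)),
    β_m = ν_m κ_m² / (τ_λ (2/D + ν_m + τ_λ/τ_s)).

Under this bookkeeping `ν = −2/D` yields an exactly unbiased (uniform
prior) fixed point, which is the self-motion default in location-indexed
settings (`ν_self = −1` for D = 2); all other components use the Jeffreys
prior `ν = κ² = 0`, which promotes sparse structures.  For D = 1 the
constants reduce to the familiar one-dimensional expressions.

**Estimator bias.** At the fixed point the strength estimate carries a
multiplicative shrinkage `λ̂²/λ*² ≈ r/(2/D + r)` with `r = τ_λ/τ_s`
(Jeffreys), plus a smaller self-consistency loss from running the filter
at `λ̂ < λ*`.  Parameter recovery is therefore tested at `r = 10`, where
the residual bias is well below the 20% criterion; at `r ≈ 3` (the
defaults, chosen for responsiveness rather than asymptotic consistency)
the shrinkage alone approaches that level.

**Integration.** Observations are held constant within frames.  Two
integrators are provided: SciPy's adaptive RK45 restarted at each frame
(reference) and a vectorized classic RK4 with a stability-driven substep
count (default), which batches hundreds of trials at once and matches RK45
to <1e−3 on test streams.  The substep count bounds the stiffest rate of
the coupled `μ` dynamics by the Gershgorin row sums of the
precision-weighted Gram matrix `CᵀWC` — with shared inputs, coupled
columns add up, and a per-column bound is not sufficient.  `λ²` is clipped
at zero after every substep; components can die permanently under the
Jeffreys prior (the gate `f_Σ(0) = 0` closes benignly).

**Duplicated components.** Exactly duplicated columns receive identical
input, so their strengths evolve identically: noise cannot break the tie.
The symmetric state is weakly unstable — a small initial asymmetry grows
into winner-take-all, within ~2 minutes of stimulus under high observation
noise (strong reliance on the sparsity prior) but only on ~10-minute
timescales at low noise, where the duplicates share the strength almost
indefinitely.  The sparsity test seeds a 1% initial asymmetry and uses the
high-noise regime.

**Calibration.** For a single source the adiabatic variance is exact: the
frame-sampled residual variance of `s − μ` equals the discrete Kalman
predicted variance (`f_Σ` plus the one-frame innovation `λ²δt`).  For
trees with shared inputs the diagonal approximation ignores the (strong)
anti-correlation between a shared component and its children and
underestimates the per-source residual variance by up to ~2×; the
uncertainty remains of the right order, and this is an inherent property
of the diagonal adiabatic model, not an implementation artifact.

## Default parameters

| quantity | object-indexed | location-indexed | network |
|---|---|---|---|
| τ_s (s) | 0.300 | 0.100 | 0.100 |
| τ_λ (s) | 1.000 | 0.333 | 0.333 |
| δt (s) | 1/60 | 1/60 | 1/120 |
| σ_obs | 0.05 | 0.05/3 | 0.05/3 |
| λ_m(0) | 0.5 | 0.5 | 0.5 |
| ν_m | 0 | 0 (self: −1) | 0 |
| σ_vst | — | 0.05 | — |
| τ_ε (s) | — | — | 0.050 |

The vestibular channel is drawn i.i.d. `N(0, σ_vst²)` per frame (a nearly
constant zero signal) while the inference weights it with precision
`1/σ_vst²` — less trusted than the visual inputs, which is what permits
illusory self-motion.

## Psychophysics protocols

All protocols feed *velocities* to the model; positions play no role.
Sampling adds per-frame noise of variance `σ_obs²/δt` to the deterministic
velocity functions.

- **Johansson 3-dot** (object-indexed): 0.5 Hz sinusoids, horizontal
  position amplitude `2√τ_s` for all dots, vertical amplitude
  `cos 45° · 2√τ_s` for the central dot only.
- **Duncker wheel**: hub `(2π, 0)` /s, rim `(2π + 2π cos 2πt,
  −2π sin 2πt)`; runs with `σ_obs = 0.15` and `λ(0) = 0.1` to expose the
  gradual component discovery.
- **Motion direction repulsion (MDR)**: two dot groups at `±γ/2` with
  speed `v₀ = 2√τ_s`, plus the vestibular input; tree = self + shared +
  two group components.  Contrast divides the second group's noise
  variance by a factor `f ∈ [0.001, 10]`; the speed variant multiplies its
  speed by 0–2.  Bias = perceived minus true angle, from perceived
  velocities averaged over the last 10 s of 30-s trials across
  repetitions (vector average before angle extraction).
- **Surround MDR**: two inner and two outer (annulus) groups; outer noise
  SD divided by 6; four-level tree (self → shared → inner/outer group →
  four individual).  Trials last 5 s (the structure estimate settles
  within ~2 s; the reference protocol states only "trial end") and
  percepts are read at the final frame.
- **Lorenceau**: two groups of ten dots oscillating at 0.83 Hz with a 90°
  phase shift consistent with global clockwise rotation; "motion noise"
  multiplies the visual σ_obs by 25.  The rotation indicator is the sign
  of the time-averaged cross product `v_p × dv_p/dt` of the group-averaged,
  200-ms-box-smoothed perceived velocities over the first 2 s (clean) or
  5 s (noisy).

## Structure-from-motion

Cylinders are rings in the x–z plane observed at seven fixed
receptive-field x-positions (five for the nested inner cylinder); each
covering cylinder contributes two overlapping surface points (front/back)
per RF, with `v_x = −R sin φ · s_rot` and `v_y = 0`.  Visual noise is the
location-indexed default ×20 (single) or ×30 (nested).  The correspondence
problem is solved by a local assignment process: per frame and RF,
independently keep the previous assignment with probability 0.7, otherwise
enumerate all permutations of the RF's overlapping observations (2 or 24)
and take the Euclidean-distance minimizer against `Cμ`; all RFs are
decided against the same state snapshot before integration, so the process
is order-independent.

Switch statistics: the perceptual threshold is the Freedman–Diaconis
histogram mode of `|μ_rot|` (its exact value is uncritical — verified by a
binning-robustness test); a switch requires crossing the *opposite*-sign
threshold (hysteresis).  Durations are fitted by maximum-likelihood Gamma
(location 0) with a method-of-moments fallback for degenerate
near-constant durations, and checked by a KS test.  The bistability
criterion runs 2,000 s (the reference protocol used 10,000 s; the shorter
run still yields hundreds of switches).

## Structure classification

Trials: three dots, one-dimensional angular velocities at 50 Hz for 4 s,
drawn from the generative model under structures I/G/C/H with uniform
probability and uniform cluster-pair choice; no observation noise is added
to the presented velocities (σ_obs is an inference parameter only).
Strengths solve the equal-marginal-variance constraint with a per-dot
squared budget of 4, of which 1.5 is individual "motion noise" present in
every structure (the reference experiment's design motif); this puts a
truth-trained classifier at ~2/3 held-out accuracy — human-scale
difficulty.  The exact strengths of the original behavioral experiment are
external and can be supplied via `lambda_table`.

Inference initializes each `λ_m` at its average ground-truth value across
structures.  The five features condense the 7-vector `λ` into
permutation-symmetric dominance ratios; degenerate 0/0 ratios return the
all-equal value (1/M for the global share, 1/3 for three-way shares, 1/2
for the two-way share).  The classifier is an L1-regularized multinomial
logistic regression with the regularization strength chosen by internal
cross-validation.  The choice model mixes a lapse with a temperature- and
bias-adjusted softmax of log structure probabilities; `σ_obs` and the
lapse are shared across participants (grid search) and `(β, b_G, b_C,
b_H)` are per-participant MLEs, optionally leave-one-out cross-validated.

Note that purely random responses are explained equally well by full lapse
(`π_L = 1`) or zero temperature (`β = 0`); the two are not identifiable
from such data.

The quantitative per-participant confusion matrices and the fitted
`σ_obs`/lapse values of the original study require its published
behavioral dataset, which is not shipped; `load_external_dataset` gates
that path.  The synthetic pipeline substitutes with above-chance accuracy
and structured confusion (global motion highly recognizable; hierarchical
trials misread as clustered more than as global).

## Network realization

Input populations are MT-like: 16 preferred directions × 12 preferred
speeds per input, speed centers `ρ_min + d_ρ n^1.25` (denser at slow
speeds), von Mises direction tuning (κ = 1/0.35²) × Gaussian-in-log-speed
tuning (σ² = 0.35²), rate scale ψ = 0.1, and gain ∝ 1/σ_obs² (contrast).
A least-squares linear readout recovers `v/σ_obs²` and `1/σ_obs²`; with
only 12 speed centers the slow end of the range is sparsely tiled (log-gaps
up to ~1.6 vs tuning width 0.35), so the readout is accurate to <1% for
the velocity channels on well-covered speeds (ρ ≳ 1) but degrades below
ρ ≈ 0.5 — an inherent property of this slow-speed-biased grid, and the
reason network/algorithm comparisons are reported as time-RMS rather than
worst-single-frame deviations.

The distributed population (100 neurons) represents `x = (λ², μ, ε)`
through random standard-normal readout rows `A`; the adjoint
`G = Aᵀ(AAᵀ)⁻¹` satisfies `A G = I` to <1e−8.  With rates
`r = r_null + G x` (`r_null` a baseline in the null space of `A`) and
dynamics `τ_r dr/dt = −(r − r_null) + G(x + τ_r F(x))`, the decoded state
obeys the online-EM equations exactly and is independent of the random
readout realization (verified to ~1e−9).  The source update uses the
instantaneous precision-weighted error (a quadratic interaction of input
and distributed rates); the *represented* `ε` — the linearly decodable
quantity — is its τ_ε = 0.05 s low-pass.  Driving the update through the
lagged `ε` instead would make the loop strongly underdamped (loop gain
`√(λ²g)` ~ hundreds/s against a 20 Hz lag) and was rejected.  The 1-to-1
population applies the activation `f_Σ` to the decoded `λ²` with
`Σ_m = 0.001 r_m`.  Constants not fixed by the reference protocols:
distributed τ_r = 0.02 s, 1-to-1 τ = 0.01 s, baseline 50 (a.u.; rates may
transiently go negative — activations are linear around baseline).

The shared-motion-fraction experiment presents generative stimuli with
`λ_shared² = 4q`, `λ_ind² = 4(1−q)` (constant total, so marginal input
statistics are identical across `q`), trains a linear regression on
per-frame distributed rates of the extreme fractions (second half of each
run), and decodes the intermediate fractions.

## Problem sizes used in the shipped checks

The default test suite runs the MDR sweeps at 5 repetitions (sign pattern
and flatness), the bistability run at 2,000 s, calibration/recovery runs
at 300–400 s, and the network equivalence on 2-s streams; the acceptance
script runs the MDR sweeps at full scale (35 angles and 9 speed factors,
20 repetitions × 30 s each).

## Known limitations

- The diagonal adiabatic covariance underestimates per-source uncertainty
  in strongly coupled trees (see Calibration above).
- Strength estimates are biased low by `~(2/D)/(τ_λ/τ_s)`; the defaults
  favor responsiveness over asymptotic consistency.
- The MT decoder cannot represent slow speeds accurately with the printed
  12-center grid.
- Object-indexed correspondence (which velocity belongs to which object)
  is assumed solved; the assignment process addresses only the
  location-indexed front/back ambiguity.
- Learning the component matrix `C`, anisotropic or object-dependent
  observation noise, per-component time constants, and interaction priors
  between components are out of scope.
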