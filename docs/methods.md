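# Methods

This note records the modeling choices behind `agifsim`: the equations
implemented, how estimation is discretized, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
matter for reproducing results. Units are mV, ms, pA, nS, pF throughout
(so τ_mem = C/g_l is in ms directly).

## Single-neuron models

The GIF subthreshold equation is integrated by forward Euler at
dt = 0.1 ms (matching a 10 kHz recording). Spiking follows an
inhomogeneous Poisson (escape-rate) rule: the intensity
λ = λ₀ exp[(V − V_T* − Σγ − θ)/ΔV] with λ₀ fixed at 1 Hz is evaluated
from the state at each sample, and a spike is drawn in that bin with
probability 1 − exp(−λ dt). After a spike the voltage is clamped at
V_reset for an absolute refractory period T_ref (6.5 ms for 5-HT,
4.0 ms for SOM and mPFC, equal to the post-spike exclusion windows used
in fitting), during which no spikes can occur but the h gate and the
adaptation filters keep evolving.

The spike-triggered filters η (adaptation current) and γ (threshold
movement) are sums of exponentials on fixed timescales
{10, 30, 100, 300, 1000, 3000} ms, log-spaced to span sub-second AHPs
through multi-second adaptation; the basis is configurable. They are
carried as per-timescale state variables incremented at each spike — a
spike at sample s contributes w·exp(−(k−s)dt/τ) at samples k > s, with
no instantaneous self-interaction. The fitting module reproduces this
convention exactly, which is what makes parameter recovery on surrogate
data exact rather than merely approximate.

The aGIF adds I_A = ḡ_A·m∞(V)·h·(V−E_K) and I_K = ḡ_K·n∞(V)·(V−E_K)
with instantaneous m and n gates and a single voltage-independent
inactivation time constant τ_h; h is advanced by the exponential
integrator h' = h∞ + (h − h∞)e^(−dt/τ_h), which is exact for constant V
within a step and unconditionally stable. E_K = −101 mV is the
room-temperature default (−89.1 mV is provided for near-physiological
fits). The iGIF's θ relaxes toward a piecewise-constant θ∞(V) with
N_step = 5 voltage bins.

The toy model is the nondimensionalized LIF + I_A (time in units of
τ_mem, conductance relative to g_l), integrated at dt = 0.001·τ_mem
with a deterministic threshold (V_T = −45 on the mV scale) and instant
reset; stochasticity enters only through optional white background
current noise, independent per neuron. The reference configuration is
ḡ_A′ = 10 and τ_h/τ_mem = 1.2.

## Fitting

Stage 1 regresses the forward-difference dV/dt on {V, 1, I, η-basis
regressors} (plus the two potassium regressors for the aGIF, with
gating and τ_h fixed from voltage clamp so the maximal conductances are
linear coefficients), excluding samples within (−1.5, +T_ref) ms of
each detected spike. Because the exclusion window covers the refractory
clamp, only genuine dynamics samples enter the regression. V_reset is
estimated as the mean recorded voltage one refractory period after
spike onset — a convention chosen to be consistent with the fitting
windows, since recordings do not pin the reset directly.

Stage 2 maximizes the exact per-bin Bernoulli likelihood of the spike
train: P(spike) = 1 − exp(−λ dt) with log λ linear in the natural
parameters (1/ΔV, V_T*/ΔV, γ_j/ΔV, and θ_j/ΔV for the iGIF). This is a
complementary-log-log GLM whose log-likelihood is concave, so L-BFGS
ascent converges globally; using the exact Bernoulli form (rather than
the first-order log λ dt approximation) matters because it matches the
generative discretization, removing a small threshold bias. The
subthreshold voltage is reconstructed with spikes clamped to the data,
and refractory bins are excluded from the likelihood. For the iGIF, θ
bin edges sit at the quintiles of the reconstructed subthreshold
voltage and τ^(θ) is selected from {1, 3, 5, 10, 30, 100} ms by
validation (or training) likelihood.

QC excludes recordings whose validation spike counts correlate with
sweep index above r = 0.9 (drift) or whose intrinsic reliability falls
below 0.1.

## Metrics

Md* = 2·n_dm/(n_dd* + n_mm). A coincidence count c(ref, pred) is the
number of predicted spikes within ±8 ms of any reference spike; the
analytic chance expectation n_pred·(1 − exp(−2Δ·n_ref/T)) — exact when
the reference train is homogeneous Poisson — is subtracted per pair.
All three terms are means over every ordered sweep pair, the within-set
terms including self-pairs, and n_dd* is floored at zero (the
small-sample correction). Two properties motivated this estimator: a
predicted set that reproduces the validation set exactly scores 1
identically, and statistically independent predictions score 0 in
expectation with low variance (measured: 0.002 ± 0.04 over 200 draws).
The cost is a conservative bias at small sweep counts: a perfect-but-
stochastic model scores N·v/(u + (N−1)·v) < 1, approaching 1 as the
number of sweeps N grows or reliability v/u rises. Intrinsic
reliability is the mean pairwise coincidence factor Γ over distinct
sweeps with the same chance correction.

## Synthetic data

The generator emulates the structure of a frozen-noise current-clamp
experiment: 60 s of frozen OU training noise and a different 10 s
frozen OU validation stimulus, repeated across sweeps, with exact OU
discretization. Surrogate sweeps mark spike bins with a +30 mV AP peak
so threshold-crossing detection behaves as on real data; optional white
Gaussian observation noise is added to V only. What it deliberately
does not emulate: action-potential waveforms, electrode/access
artifacts, slow drift, temperature effects, or any cell-to-cell
correlation structure beyond independent parameter jitter — so passing
recovery tests demonstrates estimator consistency under the model
class, not robustness to real-recording artifacts.

Cell templates pin the measured membrane statistics (5-HT:
R = 1.16 GΩ, C = 67 pF; SOM: 1.07 GΩ, 43.5 pF; mPFC: 0.188 GΩ,
160.6 pF) and the 5-HT gating parameters. Values the source data do not
pin directly were set once: E_l = −70 mV (5-HT/mPFC) and −65 mV (SOM);
V_T* a little above rest per cell type; ΔV = 1.0 mV (typical of fitted
escape-rate sharpness in this model family, and giving surrogate
validation reliability ≈ 0.5); 5-HT ḡ_A = 8 nS (slightly below the
≈12 nS implied by the mean voltage-clamp peak current, reflecting that
fitted somatic models carry less than the full whole-cell conductance,
and bracketed by the 0/10 nS manipulation endpoints); adaptation
magnitudes qualitative — 5-HT potent and protracted (η integral
≈ 9.5 pA·s plus a large γ), SOM and mPFC weaker — calibrated so
stationary f/I gains land in the tens-of-Hz/nA range observed for
these cell types. OU stimulus parameters default to μ/σ of 65/55 pA
(5-HT), 15/30 pA (SOM) and 100/200 pA (mPFC) with τ = 3 ms, tuned once
so every template fires at 2–10 Hz under the training stimulus.
Heterogeneity is mean-preserving lognormal jitter for positive
parameters (CVs from the measured dispersions; R is jittered and
inverted so the bank's mean resistance is unbiased) and normal jitter
for potentials, with systematically larger CVs for SOM.

## Network

SOM spikes drive biexponential conductances normalized to unit peak
(so g_peak = 0.3 nS is the literal single-event peak; the waveform
maximum occurs 4.41 ms after the 2 ms delay) summed linearly and
propagated through Bernoulli connectivity. Each trial draws fresh
independent background OU noise (μ = 0 — the stimulus carries the mean;
σ configurable, default 10 pA for steps and 5 pA for ramps where sharper
thresholds matter; τ = 3 ms). Trial-averaged population rates are
spike-count histograms normalized to Hz/neuron, which conserves total
spike count exactly at any bin width.

The time-resolved gain fits a rectified-linear IO function
r = a·max(0, I − I₀) per 20 ms post-onset bin; the transient gain is
the peak within the first 100 ms after step onset, the stationary gain
the mean over the final 25% of the step. Because the gain curve decays
monotonically from onset peak to stationary plateau, the gain ratio is
computed as transient/stationary — equal to max/min in the noiseless
limit but robust to per-bin noise at the population sizes used here.
Ramp analyses read the peak of the boxcar-smoothed trial-averaged 5-HT
rate and regress it on the ramp slope per baseline; the smoothing width
is reported with the result.

## Problem sizes

Tests and benchmarks run on deliberately scaled-down versions of the
study conditions so the whole suite completes on a laptop-class single
core: network checks use 60 SOM → 100 5-HT models (connection
probability raised to 8/60 to preserve the expected in-degree of 8),
4–12 trials, 2 s steps and 1.5 s ramps; banks of 40 models; the fit
recovery uses one 60 s training sweep and ten 10 s validation sweeps.
Directions and tolerances are unchanged from the full-scale protocols.

## Known limitations

- The Md* estimator's self-pair normalization is conservative for small
  sweep counts (see Metrics); comparisons across models with equal N
  are unaffected.
- The ramp derivative-encoding contrasts are small effects at these
  population sizes; the I_A-removal linearity comparison in particular
  sits close to realization noise (it holds at the pinned protocol but
  not for every alternative network/noise realization probed during
  development).
- The subthreshold regression assumes the recorded voltage is clean;
  with observation noise, forward-difference dV/dt inflates the noise
  floor and the estimates acquire attenuation bias. No instrumental-
  variable correction is implemented.
- Gating curves treat the activation/inactivation protocol as already
  leak-subtracted and normalized; the voltage-clamp protocol itself is
  a package construction (hold −90 mV, steps to −20 mV).
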