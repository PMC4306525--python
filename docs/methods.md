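# Methods

`dcmerf` replays, on synthetic data with known ground truth, the
computational chain used to ask whether reaction-time variation in a
perceptual decision task is better explained by the intrinsic gain of
pyramidal cells (a proxy for the estimated precision of ascending sensory
evidence) or by the strength of extrinsic forward connections between
cortical areas. This note documents the models, the numerical choices, and
what the synthetic studies do and do not establish.

## Neural-mass source model

Each cortical source is a three-population column: input-receiving spiny
stellate cells, pyramidal cells (two kernel compartments, excitatory and
inhibitory), and inhibitory interneurons. Every population obeys a
second-order synaptic kernel written as two first-order equations

    v' = i,     i' = (H/tau) m - (2/tau) i - v/tau^2,

where `m` is the presynaptic drive, `H` the kernel amplitude (mV) and `tau`
the kernel time constant. Population firing is the centred sigmoid
`S(v) = 1/(1+exp(-rho1 (v - rho2))) - 1/(1+exp(rho1 rho2))`, so `S(0) = 0`
and rest is an exact fixed point. Drives are

- stellate: `gamma1 S(v_pyr)` + extrinsic forward input + stimulus drive,
- pyramidal excitatory compartment: `gamma2 S(v_stellate)` + backward/lateral input,
- inhibitory interneurons: `gamma3 S(v_pyr)` + backward/lateral input,
- pyramidal inhibitory compartment: `gamma4 S(v_inhibitory)`.

Pyramidal depolarisation (excitatory minus inhibitory compartment) is the
source output. Defaults are the standard constants of this model family:
`H_e = 3.25 mV`, `H_i = 22 mV`, `tau_e = 10 ms`, `tau_i = 20 ms`,
`(gamma1..4) = (135, 108, 33.75, 33.75)`, `rho1 = 2`, `rho2 = 1`. These are
conventions, not empirical estimates; all are configurable per source.
Internally the kernels are integrated with `tau` in seconds — the
convention under which these constants give a stable column (DC loop gain
`gamma1 gamma2 (H_e tau_e)^2 S'(0)^2 ~ 0.7 < 1`); with `tau` read in
milliseconds the same equations are unstable by three orders of magnitude.

Extrinsic forward connections excite stellate cells; backward connections
drive the pyramidal and inhibitory populations; lateral connections drive
both target types. Base strengths are 32 (forward), 16 (backward), 4
(lateral), scaled per edge by a free log-parameter. Conduction delays are
available (`delay_ms`) but off by default: delays are not the hypothesis
axis here and the pure-ODE system integrates faster.

Condition effects enter as `exp(beta * x_c)` multiplying a declared site —
the `gamma2` of a named source, or a named forward edge — with design codes
`x = (0, 1, 2)` for the slowest, middle and fastest reaction-time bin, so
`beta > 0` means faster trials carry higher gain.

The stimulus is a sustained cumulative-Gaussian drive
`amplitude * Phi((t - onset)/dispersion)` delivered to the input sources.

Integration is fixed-step RK4 (internal step 1 ms, subsampled to the output
grid) from zero initial states. A compiled (numba) kernel and a pure-numpy
reference path implement identical arithmetic; the test suite asserts their
agreement to 1e-12 and step-halving convergence to 1e-6 relative. Because
the activation saturates, finite parameters cannot drive the states to
infinity; the divergence diagnostic (which names the first bad time point)
guards against non-finite inputs.

## Forward model and containers

Source output maps to sensors through a synthetic lead field: seeded
Gaussian topographies circularly smoothed on a virtual sensor ring (default
smoothing ring/16), unit-normalised, full column rank. Sensor data are
reduced to orthonormal spatial modes — the top left singular vectors of the
grand-average data, computed once and shared across subjects and models so
that evidences are comparable. Mode signs are fixed (largest-magnitude
entry positive) to make the decomposition deterministic. Evoked responses
live in a conditions x channels x time container with a uniform time axis
in ms relative to stimulus onset; on disk this is a directory of per-
condition CSV matrices plus a JSON sidecar (or a single HDF5 file with the
same schema). Baseline correction subtracts the per-channel mean over the
pre-stimulus window and is idempotent.

## Variational inversion

Free parameters are log-scalings around defaults (forward edges, per-source
output gains, stimulus dispersion) with priors N(0, 1/16), the stimulus
onset mean in ms with prior N(onset, 256), and one modulation `beta` per
declared site, prior N(0, 1/16). Baseline intrinsic gains are not freed by
default: condition differences identify `beta`, and freeing the shared
baseline as well mostly trades against the output gains. Noise is i.i.d.
Gaussian in mode space with a single log-precision hyperparameter `lambda`
(Gaussian hyperprior centred on the data log-variance, variance 16);
temporal autocorrelation is ignored — a documented simplification for
band-limited, mode-reduced averages.

The free energy is accuracy minus complexity,

    F = E_q[ln p(y|theta, lambda)] - KL(q(theta)||p(theta)) - KL(q(lambda)||p(lambda)),

with the Laplace posterior `Sigma = (e^lambda J'J + Pi0)^{-1}`. Both the
expected log-likelihood (including its trace term) and the KL are kept in
full, so F equals the closed-form evidence exactly for linear-Gaussian
models — the suite asserts agreement to 1e-3 nats against the conjugate
formula. Optimisation is Gauss-Newton/Levenberg-Marquardt ascent:
Jacobians by central finite differences (step 1e-3 of each prior SD,
evaluated in one batched integration), damping initialised at 1e-2,
doubled on rejection, halved on acceptance; `lambda` updated by a few
Newton steps between parameter steps. Convergence is declared after three
consecutive improvements below 0.01 nats (cap 128 iterations); the best-F
iterate is returned, and a fit that cannot improve on the prior within
eight iterations returns the prior-centred posterior with a warning flag.
Everything is deterministic for fixed inputs.

## Model comparison

Fixed-effects comparison sums free energies over conditions/subjects and
applies a softmax under a uniform model prior. Random-effects comparison
uses the variational Dirichlet scheme over model frequencies; family
concentrations are within-family sums. Because the three families have 6,
3 and 1 members, per-model prior concentrations are set to 1/(family size)
so each family carries equal prior mass. Caveat: under near-tied evidence
the mean-field assignment step overweights small families (the digamma of
a fractional concentration is strongly negative), which is conservative
for the scientific question — ambiguous data drift toward the null family
rather than toward the large gain family. Exceedance probabilities are
Monte-Carlo estimates from the family-level Dirichlet (default 1e5
samples, seeded).

Bayesian model averaging applies Occam's window (posterior odds >= 0.05
against the best model), renormalises, and mixes the Gaussian posteriors:
exact mixture mean, sampling-based mixture covariance (seeded). Parameters
absent from a model are treated at their prior-fixed value (zero).
Predicted-response reconstruction weights each family model's simulated
source output (at its posterior mean) by the subject's softmax of free
energies restricted to the family — the per-subject weighting choice left
open by the study description — then normalises each region by its maximum
absolute level, averages hemispheres, and averages subjects.

## Study pipeline

Behavioural trial tables are filtered (errors and non-responses out) and
split into three contiguous RT-ordered bins whose sizes differ by at most
one (larger bins first, stable ties); the within-coherence variant bins
inside each coherence level and pools the j-th bins, so bin contrasts are
orthogonal to coherence by construction. Choice behaviour is summarised by
a logistic fit of P(right) on direction-signed coherence (statsmodels
Newton/IRLS behind the module surface, with a perfect-separation guard).
Group tests are Wilcoxon signed-rank (scipy behind the surface): exact null
distribution for up to 12 non-zero differences, normal approximation with
continuity correction above; region tests are one-tailed on the modulation
log-scaling (> 0, i.e. multiplicative scaling > 1), Bonferroni-corrected
for three regions, with two-tailed pairwise region contrasts likewise
corrected. Testing log-scalings one-tailed is the only convention under
which a scaling slightly below 1 is maximally non-significant, which is how
the estimates are reported (`exp(beta)` per bin step).

Network-structure selection fits each candidate structure (no modulation)
separately per condition on grand-average data and pools by summation; the
shipped builder provides ten structures (serial and parallel hierarchies,
inter-hemispheric laterals, dual-input and reciprocal permutations) at both
bilateral and desk scales, all editable. The input-timing check refits with
the onset prior mean shifted and compares evidences.

The sensitivity analysis perturbs one site by +5%, simulates baseline and
perturbed responses at the group-average BMA parameters, and reports the
difference for a region divided by the region's maximum absolute baseline
response. At the default constants the two perturbation types decorrelate
clearly (r ~ 0.8) and only the forward perturbation changes sign inside the
window, but the gain profile is not monotone to the end of the epoch: gain
acts as a rate constant, so the perturbed response peaks slightly earlier
and the difference collapses near the response peak, which falls inside any
window long enough to show the forward dip. A monotone gain profile over a
full window requires dynamics still ramping at the window's end — a
property of parameters fitted to real recordings, not of the default
constants. Known limitation.

## Synthetic data

The behaviour generator places four coherence levels so a logistic observer
with slope 18 (per unit coherence fraction) hits roughly 55/70/85/95 %
accuracy, over three 112-trial sessions with the eight trial types balanced
and shuffled. Reaction times follow
`RT = 1050 + 700 exp(-9 c) + lognormal(median 150 ms, sigma 0.6)`,
truncated at 3000 ms (truncations and a 2 % lapse rate become
non-responses); the implied group means span ~1.37-1.86 s and decrease in
coherence while accuracy increases, with faster RT bins carrying higher
mean coherence.

The evoked-field generator jitters each subject's physiological
log-parameters (SD 0.1) and onset (SD 5 ms) around truth — the modulation
`beta` is applied exactly, so a null ground truth generates genuinely
condition-free data — simulates the three RT-bin conditions, projects
through the shared lead field, and adds white sensor noise calibrated so
mode-space signal variance over noise variance equals the requested SNR
(white noise is isotropic, so the per-mode noise variance equals the sensor
variance). A silent pre-stimulus segment provides the baseline window.
Unstable jittered subjects are redrawn (five attempts). Datasets are
regenerable bit-identically from the manifest.

The desk-scale study uses a unilateral VC -> MT -> PPC chain, 16 sensors,
4 spatial modes, stimulus onset 50 ms on a 0-250 ms epoch at 200 Hz, 12
subjects at SNR 4 and true `beta = 0.3` — sizes chosen so the full
ten-model-per-subject analysis runs in well under a minute while leaving
the family inference decisively powered. The paper-scale bilateral
six-source network (64 sensors, 8 modes, onset 200 ms, 0-500 ms) is
available through the same builders. What the passing studies show:
recovery, specificity and ordering hold under the generator's assumptions
(white noise, shared lead field, log-normal subject variation, exact RK4
dynamics as the data-generating process). They do not establish robustness
to head-model error, correlated sensor noise, or dynamics outside this
model family.

## Reported ramping

Reconstructed, normalised PPC activity from the winning gain family shows
condition-ordered ramping: the linear slope over the ramp portion of the
epoch (100-250 ms at desk scale, the analogue of the late window at paper
scale) is strictly greater for faster-RT conditions, as expected when
faster trials carry higher stellate -> pyramidal gain.
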