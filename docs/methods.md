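# Methods

`audconn` implements, end to end, the analysis chain of an auditory
figure-ground / speech-in-noise (SPIN) effective-connectivity study:
stimulus synthesis, adaptive psychophysics, forward modeling of
sparse-sampled BOLD in eight auditory-cortex parcels, variational-Laplace
model inversion, and hierarchical group inference with Bayesian model
reduction (BMR) and averaging (BMA).  Because no raw neuroimaging data ship
with the package, a synthetic-experiment module generates complete
multi-subject datasets with the statistical structure the analysis assumes;
everything below is exercised by the test suite on those datasets.

## Stimuli

A stochastic figure-ground (SFG) stimulus is 62 abutting 50-ms chords
(3.1 s).  Each chord holds 5–15 background tones drawn independently per
chord from a logarithmic grid between 179 and 7246 Hz in 1/24-octave steps
(129 frequencies).  The figure is 3 frequencies drawn once per trial
(without replacement, overlap with the background permitted) and repeated
unchanged in chords 10–51 (onset 500 ms, duration 2.1 s).  On
gap-in-figure trials the figure is omitted from 4 consecutive chords
(200 ms); on gap-in-background trials 3 background tones are removed from
each of 4 consecutive chords instead, so 12 tone slots are removed either
way; the gap onset is uniform on chords 20–42 after stimulus onset, clipped
to lie inside the figure.  Tones are sinusoids with 10-ms raised-cosine
ramps; the target-to-masker ratio (TMR) is applied as the RMS ratio of the
summed figure tones to the summed background tones, in dB.  The rendered
waveform is peak-normalized to 0.9 and written as 32-bit float WAV at
44.1 kHz.

## Adaptive psychophysics

Thresholds come from a weighted up-down staircase on TMR with an up:down
step ratio R, which drifts to the level where p(correct) = R/(R+1) — 90%
for the 9:1 preset, 6/7 ≈ 86% for 6:1 (the protocol's pairing of 6:1 with
"60%" is not the weighted up-down equilibrium; the ratio is exposed as a
free parameter and no 6:1 → 60% mapping is asserted).  Tracks start at
0 dB, terminate after 10 reversals, estimate the threshold as the median of
the last 6 reversal levels, and blocks average 2 interleaved runs.

The protocol sentence "the step size began at 1 dB and decreased to 0.5 dB
after 3 reversals" does not say which leg of the 9:1 ratio is the 1-dB
step.  We scale the *up* (incorrect) leg: up = 1 → 0.5 dB, down = up/9.
The alternative (down = 1 → 0.5 dB, up = 9 → 4.5 dB) makes the
reversal-median estimator sit roughly half an up-jump above the turnaround
levels; simulated against a logistic listener it recovers a level where the
listener is ~96% correct — a procedure one could not honestly describe as
estimating a 90% threshold.  With the up leg scaled, the simulated
estimator lands within 0.1–0.4 dB of the 90% point.

Simulated listeners are logistic:
p(correct | x) = γ + (1 − γ − λ) / (1 + exp(−k(x − m))), defaults γ = 0,
λ = 0.02, k = 1/dB, midpoint m = −3 dB.  The default midpoint puts the
90%-correct point (−0.6 dB) near the protocol's fixed 0-dB starting TMR —
the regime the procedure is designed for.  **Limitation:** with termination
fixed at 10 reversals, tracks whose equilibrium lies several dB from the
start terminate before the transient has fully decayed; at a midpoint of
−6 dB the residual bias is ≈ +0.4 dB (≈ +2.3 percentage points).  Longer
tracks, not implemented here because the protocol fixes 10 reversals, would
remove this.

In-scanner yes/no behavior is summarized by d′ and criterion c with the
loglinear correction (0.5 added to each cell, 1 to each total), which keeps
both finite under perfect performance.  No-response trials must be folded
into misses/false alarms by the caller.  Spearman rank correlations between
thresholds get Fisher-z confidence intervals with SE 1/√(n−3) (a standard
approximation; the exact small-sample distribution of r_s is not used).

## Forward model

Neural activity z in R regions follows the bilinear equation
dz/dt = Ā(u) z + C u.  Off-diagonal entries of Ā are A_ik + Σ_j u_j B_j,ik
(Hz); diagonal (self) entries are −0.5 · exp(ã_ii + Σ_j u_j b_j,ii), so
self-connections are always inhibitory and a negative modulation b is a
disinhibition (slower decay, higher gain).  Four inputs: an all-trials
boxcar, and effect-coded task (SPIN = +½, SFG = −½), difficulty
(60%-threshold TMR = +½, 90% = −½), and their product (±¼).  All four
drive every node; difficulty and the interaction also modulate all
intrinsic and extrinsic connections.  Events are boxcars of the stimulus
duration (3.1 s; the protocol does not state the neural input duration).

Each region's z drives a balloon/windkessel cascade: vasodilatory signal s,
inflow f, venous volume v, deoxyhemoglobin q, with constants κ = 0.64 s⁻¹,
γ = 0.32 s⁻¹, τ = 2.0 s, α = 0.32, E₀ = 0.4, V₀ = 0.04, ε = 1 (canonical
values; the study cites the model without printing constants).  BOLD is
y = 100·V₀·(k₁(1−q) + k₂(1−q/v) + k₃(1−v)) percent with
k₁ = 4.3·ν₀·E₀·TE, k₂ = ε·r₀·E₀·TE, k₃ = 1−ε, ν₀ = 40.3 Hz, r₀ = 25 Hz,
TE = 30 ms.

Integration is fixed-step RK4.  Because at most one trial is active at a
time, the input vector takes at most five distinct values, so the
input-dependent coupling matrices are precomputed per condition and the
inner loop (numba-compiled, batched over parameter vectors) reduces to a
matrix-vector product plus element-wise balloon updates.  Runs are
integrated independently from rest; BOLD is read off only at the
acquisition times (one volume per 8-s trial, starting 4.64 s into the
trial).  Event edges are quantized to 0.1 s so the realized inputs are
identical under step halving; with that convention the sampled BOLD changes
by ~1e-8 (relative) between dt = 0.05 and 0.025 s, and simulation defaults
to dt = 0.05 s (inversion-heavy studies in the tests use dt = 0.1 s, the
largest admissible step, which is accurate to ~1e-6 here).  A pure-numpy
reference integrator built from the public derivative functions
cross-validates the compiled kernel to machine precision.  Divergent
parameter sets are flagged and reported with the largest coupling entry.

## Subject-level inversion (variational Laplace)

The forward model is fit by Gauss–Newton ascent on the variational free
energy F = ⟨ln p(y|θ)⟩_q − KL(q‖p) − penalty(λ), with a Gaussian prior and
posterior over parameters and per-region noise log-precisions λ.  Steps
use Levenberg–Marquardt damping and are accepted only if F (recomputed at
the fresh expansion point) exceeds the best so far, so the recorded F
trajectory is monotone; λ gets per-region Newton updates with backtracking.
Jacobians come from central finite differences (step 1e-4) evaluated as one
batched call of the compiled integrator.  Convergence: |ΔF| < 0.01 nats on
3 consecutive iterations, or 64 iterations.  Run intercepts (and motion
series if supplied) are projected out of both the data and the model
predictions.

Priors (the study does not print its software's values): off-diagonal
A ~ N(0, 1/64); self log-scalings ã ~ N(0, 1/256); C ~ N(0, 1); per-region
log-scalings of τ and κ ~ N(0, 1/256); other hemodynamic constants fixed.
Modulations B ~ N(0, 1): wide enough that a modulation of plausible size
(~0.5 Hz) is not dominated by its complexity cost.  This matters for model
comparison — with B ~ N(0, 1/16), a true modulation of −0.5 pays ~3.9 nats
of complexity per subject while a collinear proxy column needing only a
~0.2 coefficient pays ~0.6, and the search then systematically
mis-attributes effects to whichever column needs the smallest coefficient.
Noise: per-region precisions exp(λ_r)/var(y_r), λ ~ N(0, 1) — wide enough
not to bias the noise estimate at SNR 2, where the true λ is ln 5 ≈ 1.6.

On linear-Gaussian instances with fixed noise, the scheme reproduces the
conjugate posterior to 1e-6 and the exact log evidence to 1e-4 (the
Laplace bound is tight there); the tests assert both.

## Group inference (PEB, BMR, BMA)

Subject posteriors over the modulations enter a second-level GLM: subject
i's B-vector ~ N((x_i ⊗ I)β, S_i + Γ), β ~ N(0, diag), with Γ the
between-subject covariance.  The group design's first column is the mean;
further columns are the subject's absolute condition TMRs, mean-centered.
With 8 subjects, four covariate columns cannot be estimated meaningfully
(chance correlation with any subject-varying quantity is large), so the
pipeline includes covariates only when subjects outnumber design columns
at least fourfold; the desk-scale studies therefore use the group mean
only.  β's prior variance is 1 on the mean column (matching the
subject-level width) and 1/16 on covariate columns (per-dB effects are
small).  Γ is diagonal with one log-scaling exp(γ_k)·(1/16) per modulatory
input, γ_k ~ N(0, 1); for fixed γ the evidence and β posterior are exact
Gaussian expressions, and the γ_k are optimized by coordinate
golden-section search (profiled empirical Bayes).

BMR scores any nested model analytically from the fitted Gaussians: a
parameter is switched off by shrinking its prior to variance 1e-8 at 0,
and the reduced posterior/evidence follow in closed form (tests verify
equality with a direct reduced-prior refit to 1e-6).  The greedy search
prunes one parameter at a time (exact rank-one evidence updates), then
hill-climbs with single toggles and one-for-one swaps: pure pruning is
path-dependent when columns are collinear — an early removal can strand a
shared effect on the wrong carrier — and the exchange moves repair such
paths (measured: on one seeded group the true model scored 3.7 nats above
the pruning endpoint yet was unreachable by removals alone).  Finally the
8 parameters with the smallest evidence contribution to the full model are
enumerated over all 2^8 = 256 on/off combinations; the BMA weights these
models by the softmax of their free energies, takes Gaussian-mixture
moments, and reports each parameter's posterior probability Pp of being on.
Parameters are reported as retained at Pp ≥ 0.95.

## Synthetic experiments

The design generator reproduces the scanning protocol: 8 runs × 24 trials,
6 per condition pseudorandomly interleaved, 8-s trials with one 3.36-s
volume at the end of each, stimuli jittered uniformly 0.4–2.4 s after the
previous scan ends.

Subject thresholds are drawn from a 4-variate Gaussian whose correlations
target Spearman 0.55 within task and 0.35 between tasks (Pearson set via
2·sin(πr/6)); means (−8, −4, −6, −2) dB for (SFG-60, SFG-90, SPIN-60,
SPIN-90) with SD 2 dB, draws violating the 60-below-90 ordering redrawn.
Each subject's logistic observer is solved to pass exactly through
(t60, 0.6) and (t90, 0.9), so prescan thresholds and in-scanner accuracy
are mutually consistent; in-scanner responses are Bernoulli draws from that
observer at the fixed condition TMRs with targets present on half the
trials and unbiased responding.

Ground-truth connectivity: within each hemisphere an auditory hierarchy
(core Te1.0 → belts Te1.1/Te1.2 → parabelt Te3, 0.2 Hz forward, 0.1 Hz
back; homotopic 0.05 Hz when bilateral).  Difficulty disinhibits left
Te1.0 (−0.47) and left Te1.1 (−0.51) intrinsically; every interaction
modulation is exactly zero.  Between-subject variation is Gaussian
(SD 0.1) on the modulations present in the group mean.  The all-trials
drive is core-weighted (0.35/0.22/0.22/0.12 Hz for Te1.0/Te1.1/Te1.2/Te3)
and the task input follows a speech-preference gradient (−0.10/0.10/0.22/
0.30 Hz) consistent with higher regions responding more to speech than to
tone clouds.  This regional heterogeneity is the identifiability condition
of the synthetic study: with homogeneous drives, every region's timecourse
is proportional after hemodynamic smoothing and one-volume-per-trial
sampling, all modulation columns converging on a region are collinear
(measured |r| = 0.99–1.00), and no inference scheme could attribute a
modulation to a specific connection.

Observation noise is white Gaussian per region with std(signal)/std(noise)
equal to the stated SNR (sparse sampling justifies serial independence).
Motion covariates, when simulated, are smooth low-amplitude nuisance series
entering the design only.  All randomness flows from one master seed
through named substreams; a dataset is reproducible byte-for-byte from
(config, seed).

## What the synthetic studies do and do not show

Measured over ten seeded groups (8 subjects, 4 left-hemisphere regions,
4 runs, SNR 2, dt 0.1 s — desk-scale sizes chosen so the whole study runs
in minutes):

- a difficulty modulation is retained in 10/10 seeds and the null model is
  always decisively rejected (localizing the difficulty effect);
- the retained difficulty modulations target a truly modulated region in
  10/10 seeds;
- no interaction modulation reaches Pp ≥ 0.95 in 7/10 seeds (the
  shared-versus-task-specific discrimination the analysis is designed
  for);
- but the *exact* carrier — intrinsic self-modulation versus a modulation
  of an incoming connection to the same region — is recovered in only a
  minority of seeds.  Scoring hand-picked reduced models directly shows
  wrong-carrier models genuinely reaching higher evidence on most seeds:
  after hemodynamic smoothing, sparse sampling, and hierarchical
  (between-subject) dilution, the group evidence margin between carriers
  is ~5–10 nats, comparable to chance fluctuations across ~150 candidate
  parameters.  This is a property of the design at this scale, not of the
  optimizer: resolving it needs the real study's sample size (44) or a
  narrower model space.

Subject-level parameter recovery is assessed separately under the
generative support (intrinsic modulations free, full 8-run sessions):
pooled posterior means then correlate with ground truth at r ≈ 0.87 over
20 seeds.  Without support knowledge a posterior *mean* cannot carry the
flat-ridge (collinear) component of an effect at any SNR — the mode is
minimum-norm along flat directions — even though the bundle total is
tightly encoded in the posterior covariance; attribution is therefore a
model-comparison question, not an estimation question.

Passing tests therefore certify the machinery (exact conjugate behavior,
correct search mechanics, calibrated simulators) and the coarse scientific
discriminations, not carrier-exact structure learning at desk scale.  Real
data differ from the generator in ways the tests cannot probe: regionally
varying hemodynamics, structured (non-white) noise, imperfect parcellation,
and between-subject variability in average connectivity.

## Numerical choices

RK4 with dt ≤ 0.1 s (default 0.05 s); event quantization 0.1 s; FD step
1e-4; VL tolerance 0.01 nats, patience 3, max 64 iterations; LM damping
adapted ×½ / ×10 on accept/reject; curvature matrices symmetrized and
jittered (logged) if singular; switched-off prior variance 1e-8; BMA
weights computed from max-shifted free energies.  Degenerate inputs raise
(`StabilityError` for divergent dynamics, rank errors for deficient
designs, domain errors for nonpositive hemodynamic states).
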