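# Methods

## Problem and scope

The pipeline asks whether a single prefrontal EEG channel, recorded during a
short auditory cognitive battery, carries enough information to (a) classify
subjects by dopaminergic status (F-DOPA-positive vs negative/healthy) and
(b) expose group- and load-dependent differences in band powers and
machine-learned scalar features. The original recordings are not available,
so the package pairs a faithful implementation of the analysis chain with a
synthetic cohort generator that encodes the reported effect structure; every
claim the tests make is therefore about the pipeline's behaviour under a
known generative process, not about patients.

## Protocol model

The battery is modelled as an ordered list of blocks: rest (45 s), three
90 s detection-level-1 trials (3 s melody, 5–6 repetitions, 10–18 s
silences), three detection-level-2 trials (1.5 s tunes, 6–8 melodies, 8–14 s
silences, target 2–3 times; block length follows the realized content since
the protocol does not fix it), one 90 s 0-back block (9 trials, 6–11 s
silences), two 90 s 1-back blocks (12–14 trials, 4–6 s silences, target
fraction constrained to 30–40 %), rest (60 s). Trial counts and silences are
drawn uniformly from these ranges. Two numerical choices are worth noting:

* In the worst corner of the printed ranges the drawn content can exceed a
  fixed 90 s block (e.g. 9 trials × (1.5 + 11) s = 112.5 s); silences are
  then rescaled proportionally so the printed trial counts always fit.
* Block order is fixed (rest → detection → n-back → rest) because the source
  protocol does not state one; it is configurable.

Cognitive load is coded ordinally: rest = 0, detection-1 = 0-back = 1,
detection-2 = 1-back = 2. Clicker responses are not modelled; only stimulus
timing matters to the simulator.

## Synthetic cohort generator

One recording is the sum of

* a 1/f Gaussian background (FFT-synthesized, exponent 1.0, RMS 3 µV);
* five band-limited Gaussian processes (white noise through 4th-order
  Butterworth band-passes at the five analysis bands) with RMS amplitudes
  8/4/3/2/1 µV (Delta…Gamma) and group-dependent amplitude gains:
  healthy ×1.25 on Delta, ×1.03 elsewhere;
* a latent slow component (1.5–4 Hz) whose **power** grows linearly with
  load in healthy subjects (amplitude 3.5·√load µV) and sits at a constant,
  load-insensitive level in PD subjects (2.5 µV) — the elevated resting slow
  activity reported for that population. The square-root amplitude law makes
  the rest→high contrast large while mid→high stays modest, matching the
  saturating post-hoc pattern of the reference results;
* a slow (≤ 0.1 Hz) log-normal global amplitude modulation shared by all
  neural components, with log-SD 0.30 (PD) vs 0.12 (healthy). This is the
  connectivity signature the classifier exploits: a stronger common
  modulation uniformly raises correlations among a subject's BAF time
  courses, in line with reports of elevated resting-state synchrony and
  slowing in PD. It is normalized to zero log-mean so dB-scale outcomes are
  not shifted between groups;
* white measurement noise (SD 1 µV).

Between-subject variability is a log-normal jitter (SD 0.18) on every band
and latent gain and (SD 0.36) on the modulation strength. Condition changes
are applied through 1 s raised-cosine crossfades at block boundaries.
Zero-phase filters are run on guard-padded noise (16–60 s pads, trimmed)
because their edge transients span several seconds at low frequencies and
both rest blocks sit exactly at the recording edges; without the guard the
transient masquerades as condition-dependent power.

Default effect sizes were calibrated once so that, at the study's 26-vs-26
size, the mixed-model group effect on Delta is detected with power ≳ 0.9 and
the healthy-only load modulation is recoverable; they are deliberately
modest. Ages in the metadata are Normal(65, 10) truncated to [45, 90] for
realism only — no age effect is injected.

What the generator does **not** emulate: artifacts (blinks, EMG, motion),
non-Gaussian and non-stationary background dynamics, medication effects,
age/sex effects, inter-session variability, and any genuine physiological
coupling between frequency bands beyond the shared modulation. Passing tests
therefore demonstrate that the pipeline recovers the structure it targets
when that structure is present — not that real recordings contain it.

## Decomposition

Windows are 2,048 samples advanced by 500 (the nominal "4 s window, 1 s
step, 75 % overlap" of the recording system; 2,048 is kept over 4 × 500 =
2,000 because the window length is tied to the dyadic tree). The wavelet is
Daubechies-4 with periodized boundary handling, making every tree level an
orthogonal transform — Parseval holds to machine precision, which the tests
assert at ≤ 1e-8 relative error. The best basis minimizes the summed
Shannon entropy of per-window-normalized squared coefficients, selected
bottom-up (keep a node if its cost is at most its children's best total;
ties favour the coarser node). Tree depth defaults to 7 (≤ 128 leaves); the
original system's 121 components are understood as that corpus's outcome,
not a constraint. BAF values are log10(ε + atom energy) with ε = 1e-12 so
silent windows stay finite. Band powers use rectangular-window periodograms
(no taper is part of the modelled system), 10·log10 of the mean band-bin
power.

## Features, connectivity, predictor

The A0/L1 weights of the original system are proprietary; the analogues are
Fisher discriminants (pooled covariance with Ledoit–Wolf shrinkage, needed
because atoms can outnumber per-class windows) trained on calibration-cohort
windows: A0 on any-load vs rest, L1 on high-load vs rest. Weights are
trained on **healthy** calibration subjects only — the original features
come from prior task corpora of unimpaired participants, and training on a
mixed cohort lets group-specific resting differences leak into the load
contrast. The 0–100 normalization anchors (1st/99th percentile of
projections) are taken over the whole calibration cohort so the other
group's projections are not clipped.

Connectivity is the whole-recording Pearson correlation between BAF time
courses (the simplest single-channel reading of fMRI-style functional
connectivity; lagged and causal variants are out of scope). Correlations are
clipped to ±(1 − 1e-7) before Fisher z. Zero-variance atoms are flagged and
zeroed. PCA is a centered SVD with a deterministic sign convention
(largest-magnitude loading entry positive), k = 10 by default, bounded by
n_train − 1. The ensemble is ten scikit-learn logistic regressions
(lbfgs, tol 1e-10) with C = 1/λ, λ = 1…10; the signed score is the member
mean of 2p̂ − 1 and a score of exactly 0 is labelled negative (only scores
strictly above the cutoff are positive).

## Statistics

* **Welch t** with Satterthwaite df (scipy).
* **LMM**: Gaussian `value ~ group + load` with random intercept + random
  load slope per subject, ML fit (statsmodels MixedLM), Wald z and normal
  CIs. The reported z statistics motivate the Gaussian reading of the
  original "GLMM". A singular random-effects covariance (slope variance at
  the boundary) keeps the fixed effects but clears the convergence flag;
  non-finite standard errors trigger a flagged random-intercept-only refit.
  Simulation calibration (30 subjects, ~1,000 observations per replicate, 50
  replicates): type-I of the group Wald test ≈ 0.02–0.10, 95 % CI coverage
  ≈ 0.92–0.98.
* **Post-hocs**: paired t-tests between load levels within group,
  BH-adjusted within each group's family of three. The default BH rule is
  the capped step-up; `cap=False` reproduces the raw p·m/rank values some
  software prints (the reference table contains one such uncapped value
  above 1). BH step-up is order-equivariant and bounded but *not*
  idempotent; the tests check the true properties.
* **Bayesian Mann–Whitney U**: latent normal scores constrained to the
  observed pooled ranking (tie groups mutually unconstrained), group means
  ±δ/2, Cauchy(0, 1/√2) prior on δ. Gibbs alternates checkerboard
  truncated-normal updates of the latents with an independence-MH update of
  δ from its conditional normal; BF10 is the Savage–Dickey ratio with a
  Rao-Blackwellized (Gauss–Hermite) posterior density at δ = 0. Defaults: 5
  chains × 1,000 iterations, burn-in 100 (capped at half the chain).
  Split-R̂ > 1.1 sets a warning flag rather than failing — complete
  separation of the samples legitimately slows δ mixing. Under the null
  (n = 25/25) most draws favour the null (BF01 > 1); at a 2-SD shift BF10
  exceeds 10 by orders of magnitude.

## Orchestration and problem sizes

`reproduce()` simulates a calibration cohort (10 + 10) and an evaluation
cohort (26 + 26), selects the basis on calibration windows, trains features
and the ensemble on calibration subjects, scores the evaluation cohort
(cutoff 0), and runs the statistical stage: half-split Welch validation
within the healthy group, four LMMs (Delta, Theta, A0-, L1-analogue),
L1 post-hocs, and a Bayesian U test between the prediction scores of the
two true groups. `run_reproduction()` writes every table plus a
content-hash manifest; identical configs give identical manifests.

Repeated-simulation studies (the 20-cohort accuracy sweep, the end-to-end
pattern run, the calibration experiments) use the compact schedule (one
block per condition, ≈ 8 min of signal) and depth-6 decomposition: these
sizes give the same qualitative behaviour as the full battery at depth 7
while keeping a complete validation run to a few minutes on one core. The
full battery at depth 7 is the default for `run_reproduction` drivers
(`analysis/06_full_reproduction.py --full`).

## Known limitations

* The generator's effect structure is an idealization; its parameters are
  calibration choices, exposed in `GeneratorConfig`, not estimates from
  data.
* The best basis, feature weights and classifier are re-trained analogues;
  numeric outputs of the original proprietary system (its 121 atoms, A0/L1
  values, per-subject scores) are not reproduced.
* "Connectivity" is instantaneous correlation; directed or lagged coupling
  is not estimated.
* The Bayesian rank test's R̂ flag is informative at extreme separation;
  interpreting BF magnitudes there should rely on the flag.
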