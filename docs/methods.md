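# Methods

`lexidcm` re-implements, as a tested and fully synthetic-testable pipeline,
a dynamic-causal-modelling (DCM) analysis of MEG evoked responses in a
reading-training study, together with the behavioural reading measures that
accompany such a study.  No patient data ship with the package; every stage
is validated by generate-and-recover studies against known ground truth.
This note documents the models, the defaults and why they were chosen, the
numerical choices, and what the synthetic validation does and does not show.

## The reading network and its model space

The network contains six sources — occipital cortex (OCC), ventral
occipitotemporal cortex (vOT) and inferior frontal gyrus (IFG), bilaterally —
at MNI prior locations (±15, −95, 2), (±44, −58, −15) and (±48, 28, 0) mm,
arranged in a three-level hierarchy OCC < vOT < IFG.  A directed connection
is classified purely from its endpoints: forward (same hemisphere, up the
hierarchy — level-skipping OCC→IFG included), backward (down), lateral
(between hemispheres, same level), diagonal (between hemispheres, different
levels) or self.  Six sources give 30 directed connections.

Condition-specific modulation is constrained by three rules: diagonal
connections are excluded; each forward/backward connection switches together
with its opposite-hemisphere mirror; each lateral connection switches
together with its reciprocal.  This yields nine independent connection
groups and a model space of 2^9 = 512 binary modulation patterns, ordered by
little-endian binary counting so model indices are reproducible.
Self-connections are not among the nine switches; their condition gains are
estimated in every model (they scale a source's sensitivity to its inputs).
For small test networks an optional joint self-modulation switch can be
added, which is how the two-source desk configuration reaches its 8-model
space (forward, backward, self).

## Source dynamics

Each source is a three-population neural mass: spiny stellate cells,
pyramidal cells and inhibitory interneurons, coupled with second-order
synaptic kernels `v'' = H k u − 2 k v' − k² v` (k = 1/τ) and a sigmoid
firing function bounded in (0, 2·e0).  Firing is expressed as deviation from
baseline so the origin is a fixed point and simulations start at rest.
Laminar targeting of extrinsic inputs: forward connections drive the
stellate population, backward connections drive the pyramidal and inhibitory
populations, lateral connections drive all three.  The source output is the
pyramidal depolarization (mV).

Defaults (all config-overridable) are the classic published constants of
this model family: H_e = 3.25 mV, H_i = 22 mV, τ_e = 10 ms, τ_i = 20 ms,
e0 = 2.5 s⁻¹, v0 = 6 mV, r = 0.56 mV⁻¹, intrinsic couplings
(135, 108, 33.75, 33.75).  Extrinsic strengths default to 32/16/4
(forward/backward/lateral).  Exogenous input is a Gaussian bump peaking at
60 ms peristimulus (SD 16 ms) delivered to the occipital sources; its
amplitude default (150) places peak deflections near 3 mV, inside the mildly
nonlinear range of the sigmoid.  The inter-source conduction delay is
uniform, 16.7 ms — exactly 8 samples at the 480 Hz recording grid, so the
delayed coupling is grid-exact at the default step.

Integration is fixed-step classical Runge-Kutta at dt = 1/480 s with the
delayed firing linearly interpolated at half steps; a convergence test
against dt/4 bounds the step error below 1% of the signal range.  Divergence
beyond a 1000 mV guard raises an explicit instability error naming the
offending parameters.  Stochastic innovations are not modelled: the
generative mean is deterministic and noise enters at the sensors.

Condition structure: every connection carries a baseline strength A and a
condition gain B, applied multiplicatively in the modulated (trained-word)
condition when the connection's group is switched on in the model.  B = 1
means the two conditions are indistinguishable on that connection.

## Forward model and dipole fitting

Source activity maps to sensors through the closed-form field of a current
dipole in a homogeneous conducting sphere (radius 110 mm, enclosing the
source priors), evaluated along each sensor's orientation.  The axial
gradiometer array is approximated as 275 radially oriented point
magnetometers on a 130 mm helmet cap; desk configurations use smaller
arrays (32 sensors).  This analytic spherical model replaces a realistic
single-shell head model: it is dependency-free, exact, and adequate for
synthetic recovery, but it does not reproduce realistic field topographies
over a real head.  Source orientations are fixed tangential unit vectors
(radial moments are externally silent in a sphere).  One unit of source
activity (1 mV) is scaled to 10 nA·m of dipole moment.

Equivalent-current-dipole fitting is a MAP simplification of the variational
Bayesian dipole fit: dipole moments are profiled out linearly, locations are
optimized by Nelder-Mead from 100 restarts jittered around the prior means
(Gaussian, SD 6 mm per axis), with a Gaussian location penalty (SD 10 mm)
added to the normalized residual power.  Fits are deterministic given the
seed; a warning is issued when two fitted dipoles come within 2 cm.

## Preprocessing

The chain mirrors a standard evoked-response pipeline at 480 Hz: 1 Hz
high-pass, epoching −100..1000 ms with prestimulus baseline correction,
30 Hz low-pass, robust trial averaging, then the 30 Hz low-pass repeated to
remove any high-frequency structure the weighting introduces.  Filters are
5th-order Butterworth applied forward-backward (zero phase); the filter
family is a package choice.  Robust averaging uses bisquare weights per
sensor and time sample across trials (tuning constant 4.685 × MAD, MAD
rescaled to Gaussian SD, max 8 iterations, tolerance 1e−6 on weight change),
with the weights smoothed along time over a 0.2 s window so clean data are
not chased sample by sample; samples with no spread beyond float noise keep
full weight.  Global field power is the sum over sensors of squared
amplitude (literal sum of squares, not RMS).  Pointwise group comparisons
are per-sample t-tests, uncorrected, with contiguous significant samples
merged into windows.  Eye-artifact correction is out of scope; epoch
containers carry a provenance field recording cleaning status.

## Inversion

One model = one modulation pattern, fitted jointly to the baseline and
modulated evoked responses over 1–200 ms.  Free parameters are log-scaling
factors, so positivity is structural: extrinsic strengths (one per
connection group, tied within mirrored pairs), condition gains on
switched-on groups, per-node self gains (always estimated in the standard
space), and the input amplitude.  Priors are Gaussian on the log scale with
mean 0 and variance 1/16 — conventional shrinkage for this model class; the
noise log-precisions (one per condition) carry a broad Gaussian prior
(variance 32).  Data and predictions are rescaled by the data RMS so the
precision hyperparameters are dimensionless.

Optimization is Gauss-Newton ascent on the variational free energy
F = accuracy − KL(posterior‖prior) − precision penalty, with
Levenberg-Marquardt damping, finite-difference Jacobians (forward
differences, step 1e−3 on the log scale), closed-form Newton updates of the
noise log-precisions (capped at e^32), max 64 iterations, convergence when
ΔF < 0.01 on three consecutive accepted steps or when no step improves F by
more than the tolerance.  Rejected steps are rolled back, so F is
non-decreasing over accepted iterations; singular curvature is
ridge-regularized.  Non-convergence returns the last iterate flagged, never
an exception.  No sensor-mode reduction is applied by default (synthetic
arrays are small); both conditions are fitted in a single model, the
standard two-condition design.

## Group inference

Per-subject free energies enter a variational Dirichlet estimate of the
population model frequencies (fixed-point iteration on responsibilities
∝ exp(F + ψ(α_k) − ψ(Σα)), uniform Dirichlet prior α0 = 1); model
exceedance probabilities are Monte-Carlo argmax frequencies over 10,000
seeded Dirichlet draws.

Bayesian model averaging pools connection gains by sampling: per round, each
subject draws a model from its group-reweighted model probabilities (the
final responsibilities) and a parameter vector from that model's Gaussian
posterior; draws pool across subjects and rounds to at least 10,000.
Connections unmodulated in the drawn model contribute the null gain 1 — the
generative meaning of an absent modulation.  No Occam's window is applied:
all models contribute.

Each pooled gain is tested against 1 with the sampling-based proportion
test: 10,000 Gaussian draws at the pooled mean and SD; if more than 90% fall
on one side of 1 the connection is significant, with direction
stronger-trained (gain > 1) or stronger-untrained (gain < 1) and Bayes
factor P/(1−P).  The Monte-Carlo estimate converges to
max(Φ(z), 1−Φ(z)), z = (mean−1)/SD, and is verified to stay within 0.015 of
it at 10,000 draws.

## Behavioural measures

Reading-trial analysis excludes voice-key failures throughout.  Per length
bin (3–6 letters), reaction times of correctly read words are trimmed once
at ±2 sample SDs (a guard against positive skew; the trim is single-pass and
per-bin — the package choice where a grand-mean reading was also possible)
and averaged.  The word-length effect is the OLS slope of mean RT on letter
length, equivalent to the average per-letter increase for equally spaced
lengths.  Accuracy scores correct = 1, error/omission = 0, self-correction
or false start = 0.5, as a percentage of valid trials.  Text speed is
60·words/seconds.  Inclusion thresholds are control mean + 2 SD; from the
printed control statistics these are 663.9 ms (three-letter word RT) and
19.9 ms/letter (WLE — printed elsewhere as 20.0, presumably from unrounded
inputs; the package returns the computed value).

N-gram indices decompose a word into all contiguous bigrams/trigrams
(duplicates kept), count every occurrence of each in a reference list
(type-in-token counting; within-list indices exclude the word's own entry
once), and divide by the word's n-gram count, making the index independent
of word length.  Partial correlations residualize both variables on the
covariate by least squares and correlate the residuals; a variable perfectly
explained by the covariate contributes correlation 0.

The adaptive training ladder moves a word one difficulty level up on a
single correct 'different'-trial response and one level down on a single
error, saturating at easy and hard (the endpoints are a package choice; only
interior transitions are externally specified).  Each correct test response
earns one pence.  Word-pair difficulty statistics use multiset letter
intersection.

## Synthetic data: what it emulates and what it does not

Word lists: two disjoint lists (default 500 words each, lengths 3–6,
matched length histograms) of pronounceable-ish alternating
consonant-vowel strings; a zero-overlap mode uses disjoint alphabets,
forcing the between-list bigram index to exactly 0.  Real lists are matched
on frequency, imageability and part of speech; the generator controls only
length and orthographic overlap.

Reading trials: 128 trials per timepoint (t1, t2 pre-training; t3
post-training; t4 follow-up), balanced over 4 lengths × 2 lists.  RTs are
lognormal (naming latencies are right-skewed) around a subject baseline
(default 1308 ms, between-subject log-SD 0.25) plus a per-letter slope
(default 173 ms/letter) — values typical of the impaired readers the
pipeline targets.  The trained list shrinks multiplicatively at t3 by the
training effect (default 11.5%), with a per-letter interaction centred on
the mean length so the collapsed effect is preserved while longer words
benefit more; at t4 half the effect remains (retention 0.5 — no external
value exists; configurable).  Outcome rates default to 3.2% voice-key
failures and ~88% correct.  The generator does not model item-level
difficulty, practice effects, or fatigue.

MEG: per subject, both conditions are simulated from the true network
(condition gains shared across subjects — the random-effects target;
extrinsic strengths jittered log-normally, SD 0.1, for population
heterogeneity), projected to sensors, and repeated over trials (default 50
per condition, plus labelled catch trials) with i.i.d. Gaussian sensor noise
at a configured clean-RMS/noise-SD ratio (default SNR 10 per trial).
Real MEG noise is spatially and temporally correlated and nonstationary;
i.i.d. noise makes the robust-averaging and inversion tests cleaner than
reality.  Passing recovery tests therefore demonstrates the correctness and
calibration of the chain, not its performance on real sensor noise,
head-model error, or source-localization error — the spherical forward model
is shared between generation and inversion, which removes model mismatch by
construction.

## Desk-scale validation

The default validation configuration keeps everything at desk scale: a
two-source single-hemisphere network (OCC, vOT), the 8-model space
(forward, backward, self switches), 8 subjects, 32 sensors, epochs
−100..250 ms, 50 trials per condition at SNR 10, and a true gain of 1.5 on
the forward connection.  The full chain — robust averaging, inversion of
all 8 models per subject, Dirichlet model selection, model averaging,
proportion tests — flags the true connection (P > 0.9) and no null
connection in 10 of 10 seeded replicates, recovering the gain to about 1%;
the 512-model six-source space is supported by the same code paths but is
not exercised by the default suite.  The behavioural round trip recovers
the 11.5% generated effect within two percentage points over 50 replicates.
These problem sizes were chosen so the whole suite runs in about two
minutes on one CPU.

## Known limitations

* The spherical forward model and fixed source orientations are shared
  between generation and inversion; realistic head-model error is absent.
* The ECD fit is MAP with a location prior, not a full variational
  treatment; dipole-count model evidence is not computed.
* Sensor noise is i.i.d. Gaussian; no spatial covariance modelling.
* The inversion estimates scaling parameters only; synaptic constants and
  input timing are fixed at their defaults.
* Repeated-measures ANOVAs on the behavioural measures are intentionally
  out of scope — the measures are exported as tidy tables for any stats
  package.
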