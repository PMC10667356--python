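# Methods

This note documents the models, defaults and design choices behind
`nirspt`, and what the synthetic test bed does and does not establish
about real recordings.

## Trial design and timing

A session is a fixed 24-cell multiset: each of the six unordered
pairings of {book, bottle, glass, plate} appears four times, with each
member of the pair twice on the participant's left and twice on the
right; the reached-for object defines the target, and the face-to-face
geometry ties the agent's hand to the opposite side in the participant's
frame (12 right-hand/participant-left, 12 left-hand/participant-right).
Four agents are each assigned to six trials.  Randomization is a uniform
permutation of trial order plus an independent permutation of the agent
multiset — the seed never changes any marginal count.  Two points were
genuinely open and are package choices: the reached-for object is taken
to be the queried target (configurable via `target_is_reached`), and
agent-by-pairing combinations are constrained only by their marginals.

Timing: 0.5 s fixation, 0.5 s blank, stimulus until response, then an
inter-trial interval drawn uniformly from [5, 7] s (only the range is
prescribed; the uniform law is our choice).  Stimulus onsets therefore
chain as onset(k+1) = onset(k) + RT(k) + ITI(k) + 1 s.

## Behavioral coding and grouping

Coding is the pure congruence rule on (target side, key).  Grouping is
the majority perspective over all 24 trials; sub-grouping uses the
≥ 23-of-24 count rule for consistency.  Where the two natural phrasings
of inconsistency (switch-count vs trial-count) disagree, the explicit
count threshold is operative; the switch count is still computed and
reported per participant.  An exact 12–12 tie is not covered by the
majority rule: it falls back to a configured default (egocentric, the
no-transformation side) and is flagged in the output.  The 3-SD RT
exclusion uses the participant's own mean and sample SD in a single
pass and affects only RT analyses, never grouping.

## Synthetic cohort

The generator's defaults emulate the structure of a 117-participant
implicit-SPT cohort: subgroup sizes 64/9/31/13
(egocentric-consistent/-inconsistent, altercentric-consistent/
-inconsistent), giving 73 egocentric vs 44 altercentric participants
(62 %/38 %).  Behavior policies hold a base perspective and switch away
from it with per-trial probability 0.02 (consistent) or 0.2
(inconsistent) — high enough that the 23-of-24 rule recovers the
inconsistent label, low enough that the intended majority perspective is
essentially never overturned, preserving the 73/44 group structure.  RTs are lognormal (log-mean 7.85, log-SD 0.45 in ms)
with additive log-scale costs of 0.18 for altercentric responses and
0.15 for switch trials; the switch cost is symmetric, so the planted
group × response interaction on log RT is exactly 2 × 0.15 = 0.3.
PFT scores are drawn per subgroup (means 7.69/6.44/7.23/6.46, matching
the consistent > inconsistent spatial-ability pattern), clipped to 0–10.

Hemodynamics are a linear forward model: ΔO2Hb = β_ROI × (HRF-convolved
onset train) + noise, ΔHHb = −r·ΔO2Hb + independent 1/f noise with
r = 0.5 by default — the anticorrelation CBSI exploits, with the ratio
configurable.  Noise components (all independently disableable; all
amplitudes are free simulator parameters, *not* estimates of any real
recording): 1/f drift (SD 0.3), cardiac 1.1 Hz (0.2), respiratory
0.3 Hz (0.1), Mayer 0.1 Hz (0.15), a shared global 1/f component
(SD 0.5) whose channel weights vary smoothly over the montage
(length scale 80 mm, so the σ = 40 mm spatial filter can separate it by
construction), per-channel gain jitter (5 %), and biexponential spike
transients injected into the *optical densities* (0.5/min), since
teeth-clenching contaminates the raw measurement.  Planted ROI
activations default to the four-subgroup pattern in which the
altercentric-inconsistent subgroup carries the largest left-IFG,
left-DLPFC and left-MC values (z-units, roughly one tenth of
beta-scale group means reported for this paradigm class), with
between-subject scatter SD 0.75 chosen once so the planted interaction
is clearly detectable at the study's cell sizes.  Participant
substreams are spawned from the master seed, so enlarging a later
subgroup never changes earlier participants.

The forward Beer-Lambert step uses editable defaults: extinction
coefficients (mM⁻¹cm⁻¹) 0.30/1.85 at 695 nm and 0.974/0.693 at 830 nm
for O2Hb/HHb, DPF 6.0 at both wavelengths, 30 mm source-detector
separation.  Only the wavelengths are study-prescribed; coefficients
are approximate literature values and any invertible set round-trips
exactly.

What the simulator does **not** model: photon transport through layered
tissue, scalp/systemic physiology distinct from the shared global
component, serially correlated measurement noise beyond 1/f, response
errors or omissions, and learning/fatigue trends.  Passing tests
therefore demonstrate correctness of the computational chain and its
statistical behaviour under the stated generative model — not
performance claims on real data.

## Preprocessing

Stages run in the fixed order MBLL → band-pass 0.001–0.2 Hz → CBSI →
component correction → channel interpolation → band-pass 0.01–0.2 Hz →
global-signal reduction → z-standardization; each optional stage can be
toggled and the composite equals the composition of stages.

Numerical choices:

- **Filters** are zero-phase forward-backward Butterworth of order 3
  (bands only are prescribed).  The effective gain is |H(f)|², verified
  against the analytic frequency response.
- **CBSI** uses whole-session SDs (no windowing); α > 0 by
  construction and a zero-variance HHb channel is a hard error.
- **Component correction**: the choice between ICA and PCA
  operationalizes artifact severity — robust-z (median/MAD) spike
  samples above 5 on more than 1 % of samples routes to PCA, any
  spiking at all above 0.1 % routes to ICA, otherwise no correction.
  Components are removed when their time-course excess kurtosis
  exceeds 10 or correlates |r| > 0.8 with the detected spike train;
  this automates what is normally a visual amplitude-plot judgment and
  is a stated stand-in for it.  Removing > 10 % of components excludes
  the subject, and the pipeline stops there for that subject.
- **Deviant channels** are flagged when peak-to-peak amplitude exceeds
  k = 3 times the median peak-to-peak of the other channels, then
  replaced by the unweighted mean of good montage neighbours (channels
  sharing an optode); an isolated bad channel is an error, not a guess.
- **Global-signal reduction** smooths the SVD spatial loadings over
  2-D scalp coordinates with a Gaussian kernel of σ = 40 (interpreted
  in millimetres — the montage's coordinate unit) and subtracts the
  smooth reconstruction.  A spatially uniform signal is removed
  entirely; a single-channel transient survives with ≳ 90 % amplitude
  on this montage.  On a *noise-free* session the task pattern itself
  is partially smooth, so this stage removes task signal too — the
  end-to-end noise-free validation therefore toggles it off, and its
  behaviour is tested separately on constructed global/local mixtures.
- **z-standardization** uses the sample SD and refuses constant
  channels by name.

## GLM

The canonical HRF is a peak-normalized double gamma sampled at 10 Hz:
positive lobe with gamma shape 6 and mode at the configured peak time
(default 6.5 s, appropriate for sensorimotor paradigms), undershoot
with shape 16, mode 16 s, amplitude ratio 1/6.  Events are impulses at
stimulus onset with a single regressor for all 24 trials; no
derivative, autocorrelation or nuisance terms.  Because the signal is
z-standardized per channel, a planted amplitude B is recovered as a
strictly increasing — not identity — function of B; the monotonicity is
what the end-to-end test asserts.  ROI activations are unweighted means
of member-channel betas; the default channel → ROI map is a synthetic
stand-in that carves each 3×5 probe grid into plausible IFG/DLPFC/MC/
IPL blocks and must be replaced by a registration-derived map for any
real dataset.

## Inference layer

t-tests are pooled-variance Student tests (a homogeneity-of-variance
setting; Welch is available by flag), d = Δmean/pooled SD.  The 2×2
ANOVAs use Type III sums of squares under sum-to-zero contrasts —
statsmodels' OLS/anova_lm provides the fit and an independent
model-comparison oracle (full vs reduced OLS) verifies every F to
1e-8 — with partial η² = SS_effect/(SS_effect+SS_error) and error df
N − 4.  χ² is Pearson's without continuity correction (trial counts are
large; Yates available upstream).  RTs are transformed with the natural
log.

The mixed model fixes group, response and their interaction on log RT
and is estimated by ML.  The prescribed random structure (crossed trial
intercepts plus by-subject response slopes) is realized in statsmodels
MixedLM as by-subject intercept + response slope with trial intercepts
as a variance component within subject — MixedLM does not support
efficient fully crossed designs — which leaves the fixed effects (the
tested quantities) unbiased: 200 simulated cohorts at the study's
9 + 13 inconsistent-subgroup sizes recover the planted 0.3 interaction
with mean 0.294 ± 0.007.  R²m/R²c follow the variance-partition
definitions, with the slope's contribution averaged over the observed
response distribution.  Note that applying the 3-SD RT exclusion before
this model clips the slow lognormal tail asymmetrically across
conditions and attenuates the measured interaction by about 0.03 — a
property of the exclusion procedure; the estimator-validation suites
therefore feed the model all coded trials.

## Validation problem sizes

The replicated studies run at sizes chosen to pin the relevant
statistical property precisely while staying desk-scale: mixed-model
recovery uses 200 cohorts of 22 subjects × 24 trials; detection and
type-I rates use 200 planted and 200 null cohorts of participant-level
ROI activations at the full 64/9/31/13 cell sizes (the distribution the
GLM stage estimates — replicating the optical chain per cohort adds
runtime but no information about the group statistics under test);
determinism and report-shape checks run the complete optical pipeline
on 12–20-participant cohorts, and the full 117-participant optical run
remains a single-command operation (`nirspt run-all`).

## Known limitations

- The component-removal selector and the ICA/PCA routing thresholds are
  automated surrogates for expert visual inspection.
- The default ROI map is a geometric stand-in, not an anatomical
  registration.
- Fixed-effect p-values from MixedLM are Wald/normal-based; no
  Satterthwaite/Kenward-Roger correction is applied.
- The simulator's noise magnitudes are free parameters; conclusions
  about real-data sensitivity require calibrating them to actual
  recordings.
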