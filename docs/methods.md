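# Methods

`biovad` detects speech from wearable biosignals that do not record sound:
respiration belts (inductance plethysmography), thoracic impedance
pneumography, and a sternal accelerometer/gyroscope unit.  Speech is a
respiratory act — the voice rides on a prolonged expiration after a quick
inhalation — and vocal-fold vibration (85–255 Hz) propagates to the chest
surface.  Both signatures survive in cheap wearable channels, which makes
privacy-preserving speech annotation of ambulatory physiology possible.

## Laboratory protocol model

The packaged protocol (`protocol.make_default_protocol`) alternates
vocalised and silent versions of everyday speech tasks across postures:
three 180-s silent baselines (supine/sitting/standing), reading a neutral
text (90 s aloud + 90 s silent per posture), a semi-structured conversation
(18 questions of 30 s, alternating aloud/in-thought, six per posture),
reading while walking on a treadmill (90 s + 90 s), and seated serial
subtraction (6 × 30 s alternating).  Every block is a multiple of 30 s, so
30-s windowing is exact: 1980 s and 66 windows per subject, 24 of them
(36.4 %) speech.  Windows are half-open `[t, t + w)` with 0-based sample
indexing; 3-s re-windowing gives 660 windows per subject.

## Synthetic cohort generator

The generator's purpose is to carry the statistical structure the detector
exploits, with known ground truth — not to render physiologically complete
waveforms.

**Respiration.**  Breaths are drawn per block: expiratory time Te ~
N(Te_base, σ_Te,state), inspiratory/expiratory ratio Ti/Te ~
N(IE_state, σ_IE,state), with Te_base = (60/RR_state)/(1 + IE_state) so the
mean cycle duration matches the state's respiratory rate.  Defaults: silent
RR 16 breaths/min, IE 0.85, σ_Te 0.15 s; speech RR 14.5, IE 0.65, σ_Te
0.30 s (twice the silent variability).  Each breath renders as a half-cosine
rise over Ti and fall over Te — smooth, differentiable, a single unambiguous
peak per cycle — scaled by a per-breath amplitude draw (arbitrary units:
none of these channels is volume-calibrated in practice, so no volume claim
is made).  Additive Gaussian noise (σ = 0.02) and slow sinusoidal drift
(0.08 a.u. at 0.01 Hz) sit below/outside the analysis band.  The
impedance-style variant adds a 1.2-Hz sinusoid at 5 % of breath amplitude —
a cardiac artifact that exercises the 0.55-Hz low-pass edge of the
impedance filter.  Thorax, abdomen (80 % amplitude) and impedance channels
render the *same* breath-cycle sequence, so cross-channel alignment and
dual-band concatenation are meaningful.

**Sternal vibration.**  All six channels carry white noise (σ = 0.02).
During speech blocks, voiced bursts switch on and off with exponential
on/off durations tuned to the subject's voicing duty cycle (default ≈ 0.5);
each burst adds a harmonic stack at f0, 2f0, … with amplitudes halving per
harmonic.  The stack is strongest on the sagittal accelerometer axis (gain
1.0) versus 0.35 medial-lateral/superior-inferior and 0.12 on the gyroscope
channels — the gyroscope carries the same information at much lower SNR and
consequently never wins feature selection, the asymmetry observed with real
sensors.  Walking blocks add gait components at 1.8 and 3.6 Hz to every
channel regardless of speech; both are far below the 75-Hz high-pass.
Population draws: 75 % female (f0 uniform 165–255 Hz) / 25 % male
(85–155 Hz); harmonics are capped below the 500-Hz Nyquist of the 1000-Hz
sensors, and a stack that would alias raises instead of wrapping.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sensor-specific noise spectra and motion
artifacts in the voiced band (e.g., cable strikes), postural changes of the
respiratory waveform shape, coughing/laughing/subvocal speech, fragmented
speech inside a window (the lab blocks are pure; an optional free-living
mode produces partial-speech windows but carries no acceptance weight), and
any coupling between respiration and voicing phase.  Synthetic performance
is therefore an upper bound that validates the *pipeline*, not a claim
about field accuracy.

## Signal processing

Respiration is band-passed with a zero-phase (forward–backward) 2nd-order
Butterworth filter: 0.05–0.60 Hz for belt channels, 0.05–0.55 Hz for
impedance.  Breath peaks are local maxima at least 1.65 s apart (overridable
per subject for unusually fast breathers); troughs are minima between
consecutive peaks plus the minimum before the first and after the last
peak.  The event sequence must start at a trough and strictly alternate;
boundary cycles that cannot be completed are dropped, and a minimum that
falls exactly on the segment edge is treated as ambiguous rather than
trusted.  A window with fewer than two complete cycles yields a missing
feature row (imputed within subject), never a silent drop.

Vibration channels get a zero-phase 2nd-order Butterworth high-pass at
75 Hz, which removes gait and posture content (< 10 Hz) by ~80 dB while
leaving the voiced band untouched.

Device alignment estimates a single constant lag by maximising the
cross-correlation of z-scored respiration channels after polyphase
resampling to the lower rate; the lag found on the respiration channel of a
device is applied to all channels of that device.  A peak correlation below
0.5 triggers a warning (alignment unreliable).  Clock drift beyond one
constant offset is out of scope.

## Feature banks

**Respiratory (21 per band; 42 when thorax and abdomen are concatenated
with `thx_`/`abd_` prefixes, no cross-band composites).**  From per-cycle
Ti, Te, D = Ti + Te, inspiratory amplitude A_in (peak − preceding trough)
and expiratory amplitude A_ex (peak − following trough): mean and SD of
IE = Ti/Te, Te, Ti; mean duty cycle Ti/D; mean/SD of A_in, A_ex and of the
flows A_in/Ti, A_ex/Te (amplitude-per-time, not volumetric); RRV = RMSSD of
cycle durations √(mean(ΔD²)); mean |ΔTe| (absolute successive differences —
the signed mean telescopes to an endpoint difference and carries no
variability information); RR = 60/mean(D), robust to window truncation;
minute amplitudes = mean amplitude × RR; and peak–trough symmetry, the mean
fraction of the cycle occupied by the trough-to-peak limb.  With that
(documented, configurable) formula the symmetry coincides with the duty
cycle; it is retained as a named feature so alternative rise–decay
definitions can be swapped in.  SDs are sample SDs (ddof = 1).

**Vibration (14 per channel × 6 = 84).**  Eight frame-averaged descriptors
over rectangular 2048-sample frames hopped by 512 (2.048 s / 0.512 s at
1000 Hz): spectral centroid Σf·|X|/Σ|X|, bandwidth √(Σ|X|(f−c)²/Σ|X|),
roll-off at 25/50/85 % of cumulative magnitude, flatness (geometric over
arithmetic mean of the *power* spectrum), zero-crossing rate per sample, and
RMS.  Six whole-segment FFT descriptors: Shannon entropy (bits) of the
magnitude-normalised spectrum, crest (max |X| / Σ|X|), skewness and kurtosis
as magnitude-weighted 3rd/4th frequency moments about the centroid
normalised by bandwidth³/⁴, unweighted variance of bin magnitudes, and mean
bin magnitude.  All spectra are one-sided with the DC bin excluded (DC is
meaningless after the high-pass); magnitude weighting is used throughout
except flatness, whose standard definition is on power.  No window taper is
applied by default.

## Evaluation design

Subjects are split 80/20 at the subject level; the same test subjects are
reused for every method.  On the training partition only, the ten features
with the highest estimated mutual information with the speech label are
kept.  Selection happens once, *before* nested CV — deliberately mirroring a
common applied design; it is a known source of mild optimism in the
generalization estimate and is documented rather than silently corrected.

Nested CV: the outer loop is leave-one-subject-out (all segments of one
subject held out together, testing between-subject generalization); the
inner loop is a 5-fold grid search on the outer-train segments, stratified
over segments (a subject-grouped inner variant is available by flag —
whether grouping is preferable is genuinely open), scoring mean accuracy
(configurable).  The winning configuration is refit on the full outer-train
data and scored on the held-out subject: AUC (Mann–Whitney rank, ties ½),
accuracy, sensitivity and specificity at a fixed 0.5 threshold.  Summaries
report mean ± SD and a normal 95 % CI (mean ± 1.96·SD/√n, clipped to
[0, 100]).  A held-out subject with a single class has no defined AUC and is
excluded from summaries with a warning.  The final model per method uses
the per-parameter *mode* of the outer-loop selections (ties break toward the
more regularized value: smaller depth/learning rate/C, `None` depth counting
as least regularized) and is trained on all training subjects.

Default grids are small published-default spaces (trees {100, 300}, depth
{2, 3, 5}, learning rate {0.05, 0.1}; L2 strength C ∈ {0.01, 0.1, 1, 10});
runtime-constrained end-to-end runs use reduced grids (one tree count, two
depths).  The packaged synthetic study uses 20 subjects, gradient boosting
for all four methods, and the reduced grids — about three minutes on one
CPU; these sizes are the package's own defaults and scale up by argument.

A permutation-null run shuffles labels *within subject*, reruns selection
and nested CV (with the fast linear model) and averages three permutations;
a leak-free pipeline scores at chance (50 %).  Three permutations bring the
Monte-Carlo SD of the null mean AUC to ~1 percentage point.

## ROC statistics

AUC uses the Mann–Whitney rank formulation with midranks for ties.  The
paired DeLong test estimates var(AUC_a), var(AUC_b) and their covariance
from midrank structural components (the placement of each positive among
negatives and vice versa) and refers Z = (AUC_a − AUC_b)/√(var_a + var_b −
2 cov) to a standard normal, two-sided.  Identical score vectors return
Z = 0, p = 1; a degenerate variance (e.g., both models separating
perfectly with different scores) raises with a diagnostic rather than
reporting a meaningless Z.  Significance defaults to α = 0.01, uncorrected
across method pairs.

Numerical note: the DeLong variance and a stratified-bootstrap variance of
ΔAUC are different finite-sample estimators of the same asymptotic
quantity; at n = 20 they disagree by several percent (the bootstrap runs
slightly high for rank statistics because resamples contain ties).  The
agreement test therefore compares them at n = 100 with a 300-replicate
bootstrap, where Monte-Carlo error dominates the residual estimator bias,
and tolerates the occasional 3-SE exceedance expected from taking 50
three-SE comparisons.

## I/O and degenerate inputs

Raw recordings interchange as EDF, one file per device, 16-bit quantized,
with block annotations in a JSON sidecar; reading goes through `mne`,
writing through a minimal plain-EDF writer (no EDF writer is otherwise
available in the dependency set).  A long-format CSV writer exists for
spreadsheet workflows.  Feature tables are CSV or Parquet.  Degenerate
inputs fail loudly: constant signals cannot be min–max normalized (the
robust variant excludes > 4.5 SD outliers from the range estimate, so
clipped spikes may map outside [0, 1]); all-zero segments have no spectrum;
windows that do not divide a block raise; a subject with no valid value for
a feature cannot be imputed.

## Known limitations

Synthetic validation only (no deposited human recordings exist to ship);
single constant inter-device lag; selection-before-CV optimism; fixed 0.5
decision threshold; the free-living generator mode is exploratory and
untuned.  Performance numbers printed by the study runner describe the
synthetic conditions above, nothing more.
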