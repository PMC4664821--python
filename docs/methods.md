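# Methods

This note documents the models, conventions and defaults behind `rtg`: what
the synthetic generator emulates, how each estimator is defined, which
choices were genuinely open, and what the verification experiments do and do
not establish.

## Signal model and preprocessing

Position channels are filtered with a zero-phase (forward–backward)
4th-order Butterworth low-pass at 20 Hz before any differentiation.  The
filter order is a convention of upper-limb kinematics; forward–backward
application squares the magnitude response (at 50 Hz, 2.5× the cutoff, the
residual amplitude is `1/(1 + 2.5^8) ≈ 7e-4`) and cancels phase lag.  Edges
use odd-reflection padding of 3× the filter order, so outputs are
reproducible bit-for-bit; series must exceed 12 samples, and shorter input
raises an error naming that minimum.  Velocity uses central finite
differences (one-sided at the endpoints) on the filtered wrist channels,
then the Euclidean norm; aperture is the per-sample thumb–index distance on
the filtered finger channels.  Filtering the raw aperture series directly
instead is available as a config switch (`filter_aperture_directly`); the
two conventions differ negligibly for band-limited movement but are not
identical, so the choice is explicit.

## Movement window

Termination is the sample nearest the object-lift switch time, ties resolved
toward the later sample.  Initiation is defined as the first bin of a
continuous rise of at least 3 data points in transport velocity.  The
literal, threshold-free rule (`detect_initiation`) is kept as a pure
function: the smallest index *i* whose next three increments are all strict
rises, scanning at or after the cue; "first bin"
means the local minimum preceding the rise, equality breaks a run, and both
the run length and strictness are parameters.

Applied verbatim to filtered data, however, the rule fires on arbitrarily
small monotone fluctuations: the acausal precursor that zero-phase filtering
spreads ahead of movement onset (a few samples, ~1e-5 m/s), or pre-movement
sensor noise just after the cue.  The pipeline therefore locates the window
with a robust composite (`robust_initiation`): find the first crossing of
20 % of the trial's peak velocity after the cue — safely above the noise
floor of differentiated 0.5 mm sensor noise — and walk backward through the
rise, treating increments below `1e-4 ×` peak velocity as flat.  The
returned sample is the first bin of the continuous rise that carries the
velocity past the floor, i.e. the same construct with a numerical-noise
guard.  On noise-free trials this recovers the injected onset exactly; with
default sensor noise onset lands a few samples into the true rise, a known
and documented bias that is common to all cells and cancels in
within-subject contrasts.  Both fractions are config keys.

## Kinematic measures

Within the inclusive window `[start, end]`: TMT `= (end − start)/fs`; peak
velocity / aperture are maxima at sample resolution (no sub-sample
interpolation), ties resolving to the earliest sample; peak times are
expressed as `100·(argmax − start)/(end − start)` percent of TMT.  Features
are invariant to time shifts of the whole trial; scaling positions by *k*
scales `V_max` and `A_max` by *k* and leaves the percent-times unchanged.

## Coordination estimator

For integer lags `k` in `[−L, L]`, `L = floor(0.5 × window length)`, the
estimator computes the Pearson correlation between `v[0:n−k]` and `a[k:n]`
(mirrored for negative `k`), normalizing over each overlap's own means and
SDs so every lag yields a true correlation in `[−1, 1]`.  Overlaps below
50 % of the window are excluded to prevent spurious maxima; both fractions
are config keys.  The reported `r_max` is the signed maximum over lags (a
`use_abs` flag switches to maximum magnitude; with velocity and aperture
positively coupled in this task the two agree).  Ties within 1e-12 resolve
to the smallest `|k|`, then to positive `k`.  Positive lag means transport
velocity leads aperture; the lag is reported in ms.  Series are not
time-normalized or resampled before correlation.

Trial coefficients are aggregated as `tanh(mean(atanh(r_i)))`; the Fisher
transform rejects `|r| ≥ 1` unless clipping (to `|r| = 0.999999`, with a
logged warning) is requested.  Aggregated coefficients always lie between
the per-trial extremes.

A resolution caveat: the argmax of a smooth correlation surface at 120 Hz
sampling is an integer-valued estimator whose precision is limited by the
curvature of `r(k)` near its apex.  For the broad, near-symmetric profiles
of this task the apex is well defined; for strongly asymmetric profile pairs
near perfect synchrony the surface can become bimodal and the lag construct
itself loses identifiability (see Limitations).

## MEP analysis

Peak-to-peak amplitude is `max − min` of the EMG within a fixed
post-stimulus window, default 10–60 ms — a standard latency band for a
forearm extensor target that excludes the stimulus artifact; the window is
configurable.  No software re-filtering is applied (the acquisition bandpass
is a hardware property of the recordings).  Session values are the
arithmetic mean of the 10 sweeps.  The packaged participant table ships as a
CSV fixture with the printed values verbatim; its paired pre/post MEP
comparison reproduces at printed precision.

## Statistical battery

- **Paired t**: `t = mean(d)/(sd(d)/√n)`, df `n − 1`, two-sided; zero
  variance of differences is an error rather than an infinite statistic.
- **Wilcoxon signed-rank**: zero differences dropped; for n ≤ 12 the
  two-sided p comes from full enumeration of the `2^n` sign patterns on the
  actual (mid)ranks, which is exact under ties; the continuity- and
  tie-corrected normal `z` is always reported as the statistic, matching
  z-style reporting.
- **2 × 2 within-subject ANOVA**: classical decomposition on one value per
  subject × condition × time cell, each effect tested against its own
  subject-by-factor error term with df (1, n − 1).  With two-level factors
  sphericity holds trivially (ε = 1), which the report states instead of
  running a vacuous Mauchly test.  The 10 trials of a block are averaged to
  the cell value before the ANOVA (the conventional repeated-measures unit);
  trial-level analysis remains possible on the features table.  Coordination
  enters on the Fisher-z scale and is back-transformed only for reporting.
  Missing or duplicated cells raise an error listing the offending cells.
- **Excitability–behavior correlation**: Shapiro–Wilk on both change scores
  at α = 0.05 selects Pearson (both normal) or Spearman; the chosen method
  is part of the report.
- α = 0.05 two-sided throughout; no multiplicity correction, matching the
  study design.

The ANOVA implementation is verified in the test suite against pingouin's
two-way repeated-measures ANOVA and against the identity
`F_interaction = t²` of the paired t on difference-of-differences.

## Synthetic generator

The generator's defaults are the study conditions; everything the study does
not fix is chosen once for realism and documented here.

**Geometry and sampling** (fixed by the task): 30 cm reach, dowel diameters
1.2 / 7.2 cm, kinematics at 120 Hz, EMG at 2000 Hz, 9 subjects, 10 trials
per block, real/sham × pre/post × small/large design.

**Transport**: minimum-jerk displacement
`x(τ) = D(10τ³ − 15τ⁴ + 6τ⁵)` along the reach axis — chosen for analytic
checkability (peak speed `15D/8T` at mid-movement, zero boundary velocity
and acceleration).  Base movement times 1.3 s (small) / 1.1 s (large)
reflect stroke-like slowing with the harder small target slower; both land
on whole samples at 120 Hz.

**Aperture**: a beta-density-shaped unimodal profile with mode at the
configured peak-time fraction (default 0.5, aligning the aperture peak with
the velocity peak before any lag is injected), rescaled piecewise — rising
limb from a near-closed 5 mm baseline to `diameter + margin`, closing limb
from the peak down to the object diameter at lift-off (a raw beta density
would close back to baseline, which a grasped object forbids).  Default
margin 30 mm gives peak apertures of 42 mm (small) and 102 mm (large).
Thumb and index paths split symmetrically about the wrist path by half the
aperture, so recomputing aperture from the finger sensors reproduces the
generative profile exactly at zero noise.

**Coupling lag**: realized by delaying the aperture profile.  Because the
closing limb is asymmetric, a raw delay equal to the desired lag would leave
a systematic offset between the injected shift and the cross-correlation
construct (+4 samples small, +14 large at zero shift).  The generator
therefore calibrates the shift: on a clean mini-trial pushed through the
exact production chain (filtering, windowing, the estimator itself) it
searches the whole-sample shift whose noise-free construct lag matches the
request, caching results per (duration, object, margin, lag) key.  Shifts
are whole samples so the aperture peak stays on the sample grid.  Each
trial records both the requested lag and `lag_achieved`, the noise-free
construct value actually realized — the correct ground truth for recovery
experiments, since achievable construct lags are integers.  Baseline lags:
180 ms (small) and 100 ms (large), straddling the 80–125 ms band of
nondisabled adults from outside; the real-rTMS effect shortens the small
object lag by 60 ms post stimulation.

**Noise model**: additive Gaussian position noise, SD 0.5 mm, on all nine
channels (electromagnetic-tracker precision scale); a smooth low-frequency
aperture-shape perturbation (two random-phase sinusoids under a half-sine
envelope, default 2 mm amplitude) representing trial-to-trial variability of
grasp formation — this is what gives per-trial `r_max` a realistic ~0.90–0.99
spread and the coordination effect something to act on; lognormal
multiplicative MEP noise (CV 10 %, unit mean) plus 3 µV background EMG.
Between-subject and between-session dispersions (movement-time CV 10 %,
session/trial jitters of time, margin and lag) are defaults, not calibrated
values: the study reports no trial-level variability.

**Injected rTMS effects** (real × post × small only): TMT −0.15 s, peak
aperture +8 mm, lag −60 ms, and a halving of the aperture-shape noise
(raising `r_max`); MEP amplitudes suppressed by 42 %, the ratio implied by
the packaged participant table.  Reaction time (cue → hand lift) is
simulated (350 ± 50 ms) but not analyzed.

## Verification experiments and problem sizes

`rtg.simulations` backs both the test suite and `scripts/acceptance.py`;
every experiment derives all randomness from one integer seed via
`SeedSequence.spawn`.

- **Round trip** (zero noise, every design cell at its defaults): injected
  TMT and peak aperture recover exactly; lag within 1 sample.
- **Lag grid** (zero noise, small object, injected lags −10…+10 samples):
  recovery within 1 sample at every grid point.
- **Noisy lag recovery** (200 trials, sensor noise at its default): fraction
  of trials whose estimated lag is within 1 sample of the trial's
  `lag_achieved`.  Shape variability is excluded here — it changes the
  trial's true transport–grasp relation rather than its measurement — and
  the rate with it enabled is reported as a separate number.
- **Type-I calibration** (500 replicates) and **power** (200 replicates) of
  the small-object TMT condition × time interaction, each replicate running
  the full generator → filter → window → ANOVA chain with 9 subjects; a
  fast stats-level null (subject effects + unit noise) additionally checks
  the uniformity of the interaction p-value distribution.
- **Coupling direction** (200 replicates): bivariate-normal subject changes
  with correlation −0.75 between MEP change and coordination-z change; the
  normality-gated correlation recovers a negative sign.

These sizes keep the whole verification run in a few minutes on one core
while leaving Monte-Carlo error well inside the asserted bands.

What passing does and does not show: the generator shares the analysis
chain's *structure* (profiles, noise, effects are injected at known
places), so green tests establish internal consistency, calibration and
power under the stated model — not that real electromagnetic-tracker data
meet these assumptions.  Real recordings have sensor dropout, trunk
compensation, non-Gaussian artifacts and reaction-time/strategy drift that
the generator deliberately omits (see Non-goals in the module docstrings).

## Known limitations

- The study's printed kinematic F values, Wilcoxon z values and the −0.75
  exploratory correlation are not numerically reproducible without the
  unpublished raw recordings; the pipeline covers them with calibration,
  power and direction-of-effect checks instead.  (The printed interaction
  df (1, 16) also differs from the df (1, 8) a fully within-subject 2 × 2
  with 9 subjects yields; the package reports its df transparently.)
- Lag estimation is integer-valued at 120 Hz; near-synchronous, strongly
  asymmetric profile pairs (the large object near zero lag) make the
  correlation surface bimodal and the lag construct non-identifiable within
  ±2 samples.  At the study's actual operating points (lags ≥ 100 ms) the
  construct is well defined.
- Onset detection on noisy data is biased a few samples into the rise by
  construction; absolute TMT is accordingly conservative, while all
  within-subject contrasts are unaffected.
- The ANOVA assumes complete balanced designs; incomplete data fail loudly
  rather than being imputed.
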