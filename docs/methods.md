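# Methods

## Problem setting

A directional DBS lead carries eight contacts on four levels; the middle
two levels are each split into three 120°-spaced segments (contacts 2/3/4
ventral, 5/6/7 dorsal; segments sharing an angle on adjacent levels are
"aligned"). The package asks whether the spatial distribution of beta-band
(13–35 Hz) LFP power across the six segments, recorded at rest, predicts
which segment a later monopolar review will identify as clinically best.
Segment angles are abstract labels (0/120/240): physical orientation in the
skull is never needed because every quantity in the analysis depends only on
*relative* direction between contacts and the putative beta source.

## Spectral estimation and the normalized-beta statistic

Spectra are Welch averaged periodograms: 1-s Hann windows (1 Hz resolution,
enough to separate low from high beta), 50% overlap, constant detrend,
density scaling (µV²/Hz). A ~2-minute recording yields ≳230 windows, so the
integrated PSD tracks signal variance to well under 5% (enforced by a
Parseval test). Spectrograms use the same windows so that their time
average reproduces the PSD.

The aperiodic background is a log–log linear (power-law) fit over 5–45 Hz
with 13–35 Hz masked out. A beta peak is a local PSD maximum inside
13–35 Hz standing ≥ 3 dB above that fit; among several candidates the most
elevated wins. 3 dB (a factor 2 in power) is a deliberately conservative
default: estimation noise with ≥100 windows stays well below 1 dB, so
false peaks on peakless spectra are rare while genuine narrowband
oscillations clear the bar easily. The peak band is the peak frequency
± 3 Hz clipped to 13–35 Hz; peaks at or below 20 Hz are classified "low",
above "high".

Normalized beta is the trapezoid-integrated power in the peak band divided
by the integrated 13–35 Hz power; without a peak the numerator band is
13–20 Hz and the value is flagged as a fallback. Band edges between grid
points are linearly interpolated, so on a flat spectrum the ratio equals
the bandwidth ratio exactly. The peak decision is made **once per
hemisphere** — on the contact with maximal raw beta power — and its band is
reused for all six contacts. Ranking contacts against each other requires a
common numerator band; detecting a band per contact would confound band
choice with the power differences the ranking is supposed to measure.

Two details are configurable because the underlying convention is genuinely
ambiguous in the field: the statistic can be reported as band *power*
(default) or band *amplitude* (square root of the power ratio — the two
orderings are identical, only the scale differs), and an optional 50/60 Hz
notch exists but is off by default since line noise lies outside every band
the analysis integrates.

## Clinical scoring and inclusion rules

Clinical efficacy is 100 × (baseline − on-stim rigidity)/baseline divided by
the stimulation current, in %/mA. The denominator is the fixed test current
at which rigidity was scored (config `current_basis: fixed`); dividing by
the effect threshold instead is supported (`threshold`) since review
protocols differ. Therapeutic window is side-effect threshold minus effect
threshold in mA — the standard monopolar-review definition; a side-effect
threshold never provoked is capped at the maximum tested current (default
5 mA, logged), and negative windows are clipped to 0 and flagged.

Hemispheres enter the group analysis only if baseline upper-limb rigidity
is ≥ 2 points (below that, improvement cannot be graded without floor
effects) and the efficacy spread across the six contacts exceeds
5 %/mA — with a near-flat response profile there is no "best contact" for
either strategy to find, and such hemispheres only add noise to the match
rates. The 5 %/mA default is a package choice (a quarter of the typical
simulated spread); it is exposed in config and every exclusion is logged
with its reason. Rigidity is the only clinical item scored: it is the sign
most sensitive to stimulation and the only one a review assesses
systematically at every contact.

## Ranking and screening curves

Contacts are ranked by normalized beta, ties broken toward the lower
contact id (deterministic reporting matters more than tie-unbiasedness;
exact ties have measure zero on real spectra, and every tie-break is
logged). The best clinical contact under a criterion (max efficacy, or max
TW — assessed independently) uses the same tie rule. The LFP strategy curve
at *k* is the fraction of hemispheres whose best clinical contact lies in
the beta top-*k*; it is nondecreasing and reaches 1 at *k* = 6. The random
baseline is analytic: screening *k* of 6 contacts uniformly without
replacement contains the single best contact with probability exactly
*k*/6 — no Monte Carlo, the printed 0.17-per-contact increment is this
value rounded. Curves are computed for all hemispheres and for the subset
with a detected beta peak.

The top-2-vs-rest comparison averages a clinical metric over the two
highest-beta contacts and over the remaining four, per hemisphere, and
tests the paired difference. The level tally maps the ring level of the
max-beta contact to an STN zone (lead level 3 → dorsal, level 2 → middle;
ventral is structurally impossible for segments, matching leads whose
segmented levels sit in mid/dorsal STN).

## Statistics

Spearman rho is the Pearson correlation of midranks (average ranks on
ties), computed from the definition; with n = 6 contacts its granularity is
coarse, which is why inference happens across hemispheres: a one-sample t
of the per-hemisphere rhos against 0. The paired t is the one-sample t of
the differences. t statistics are mean/SEM with the unbiased (n−1) standard
deviation; only the Student-t CDF for two-sided p-values comes from scipy.
All tests are two-sided and uncorrected for multiplicity — the battery is
small, fixed in advance, and reported in full. Degenerate inputs (zero rank
variance, zero sample variance off the null) raise or flag rather than
silently returning a number.

## Synthetic cohort generator

Each hemisphere draws a beta source: angle uniform on [0°, 360°), level
uniform on [2.4, 3.0] (dorsal-biased, reflecting the dorsolateral motor STN
sitting near the upper segmented level), center frequency uniform on
15–30 Hz. Signal model per segmented contact:

* background: independent Gaussian noise with one-sided PSD
  10/f^1.5 + 0.05 µV²/Hz (FFT-shaped), a generic aperiodic LFP spectrum;
* oscillation: one shared narrowband noise process (white noise band-passed
  ±2 Hz around the source frequency, unit RMS — amplitude-modulated like
  real beta, not a sine) scaled per contact by
  exp(−0.012·Δangle) · exp(−1.5·Δlevel), then multiplied by 6 µV RMS.
  The exponential decay is not a biophysical claim; the pipeline only
  requires a monotone spatial gradient, which any decay shape provides.
  Because the oscillation is shared, aligned contacts carry correlated
  beta — the motif of a dominant contact trailed by its aligned partner.

A hemisphere has a clear peak with probability 12/19. Peakless hemispheres
keep a faint, broad oscillation (amplitude fraction 0.25, halfwidth ±6 Hz)
— too weak and diffuse to clear the 3 dB criterion, but still spatially
graded, emulating hemispheres whose low-beta activity reflects the source
without a discrete spectral peak.

Clinic: with proximity s_c = attenuation rescaled to max 1, expected
efficacy is 12 + coupling·40·s_c %/mA (coupling ∈ [0, 1], default 0.7,
noise SD 5 %/mA; improvement truncated to [−50, 100]%), the effect
threshold is 2.0 − 1.2·s_c mA and TW is 0.7 + 1.2·s_c mA (noise SDs
0.2/0.25 mA); a side-effect threshold exceeding the 5 mA ceiling becomes
"not reached". Review tables are back-computed from these targets
(baseline rigidity an integer ≥ 2, fixed 2 mA test current) so the clinical
module recovers the generative scores exactly when noise is zero. At
coupling = 0 the clinic is independent of the electrophysiology, giving an
exact null for calibration tests.

Cohorts are deterministic given the seed (per-hemisphere substreams from a
spawned SeedSequence). A score-level mode skips waveform synthesis and
derives beta scores from the generative power plus 10% relative
measurement noise; it preserves the ranking structure and is used for
large replicate studies of the ranking layer (500-cohort null calibration,
coupling monotonicity), where re-estimating thousands of spectra would add
cost but no information. The full waveform path is used everywhere the
spectral estimator itself is under test, including the 500-hemisphere
parameter-recovery run at the default 120 s / 1 kHz recording conditions.

What the generator does **not** emulate: volume conduction and common
reference artefacts, stun-effect drift, bursting/nonstationary beta
dynamics, tremor-dominant phenotypes, rater noise structure beyond i.i.d.
Gaussians. Passing tests therefore demonstrate that the pipeline recovers a
spatially coherent beta source under realistic spectra and noise — not that
it is robust to every artefact of operating-room data.

## Numerical choices and degenerate inputs

Trapezoid integration with edge interpolation for all band powers; NaN
samples are rejected naming the channel; recordings shorter than one
window, bands outside spectral support, zero in-band denominators, zero
test currents and unknown level labels all raise with specific messages.
Background fits ignore zero-power bins and declare "no peak" when fewer
than two usable bins remain (an all-zero or noiseless spectrum cannot
support a dB criterion). All tie-breaks are by lower contact id and logged.

## Known limitations

* The statistic compares contacts within one lead only; absolute normalized
  beta is not comparable across patients (by design — the normalization
  removes gain, not physiology).
* With six contacts, match rates on a 19-hemisphere cohort move in steps of
  1/19; simulated headline fractions carry that granularity.
* The time-saving model (20 min/contact, screen top-2 per side) is an
  arithmetic illustration, configurable, not an empirical measurement.
* EDF reading requires the optional `mne` dependency; the native format is
  delimited text.
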