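# Methods

`eegfnirs` simulates and analyzes co-located EEG-fNIRS recordings of the
kind produced by a forehead-worn dual-modal patch: two prefrontal EEG
channels (Fp1, Fp2 of the 10-20 system, 1 kHz) and dual-wavelength
(760/850 nm) optical channels (100 Hz) measured at the same scalp sites.
Every analysis stage is paired with a synthetic generator that retains its
ground truth, so the whole chain is verifiable without recorded data.

## Hemodynamic forward model and inversion

Concentration changes of oxygenated and deoxygenated hemoglobin map to
optical-density changes through the modified Beer-Lambert law

    dOD(lambda, t) = [eps_HbO2(lambda) dHbO2(t) + eps_HbR(lambda) dHbR(t)] * d * DPF(lambda),

with source-detector separation `d` (default 30 mm, standard adult
forehead spacing) and differential pathlength factor `DPF` (default 6.0
at both wavelengths, configurable per wavelength).  Extinction
coefficients come from the standard Prahl/Cope hemoglobin compilation,
converted to 1/(mM*mm); at the default wavelength pair the 2x2 matrix has
condition number ~3, and pairs with condition number above 1e6 are
rejected.  Optical density uses log base 10 with the reference intensity
I0 estimated as the mean over a baseline window (default the first 10 s,
i.e. the pre-task waiting period), or supplied explicitly when a
calibrated source intensity is known.  The inversion solves the 2x2
system per sample; `dHbT` is always returned as the elementwise sum, so
that identity is exact by construction.  With a known I0 the
forward/inverse round trip is exact to ~1e-15 relative error; with an
estimated I0 the residual baseline offset equals the mean concentration
over the baseline window, which the detrending stage removes anyway.

## Synthetic acquisition

**Task schedule.** Stroop sessions follow a waiting / task / rest layout
(defaults 30 s / ~32 s / 60 s).  Thirty trials show a stimulus for
500 ms with inter-stimulus intervals uniform in 350-750 ms; one third of
trials are congruent (rounding toward congruent), order uniformly random
under the seed.

**Hemodynamics.** Neural activation is the boxcar stimulus train
convolved with a canonical double-gamma HRF (peak 6 s, undershoot 16 s,
ratio 1/6), normalized to unit peak and scaled to `amp_hbo2` (default
1 uM); `dHbR` uses -25% of that amplitude, matching the convention that
the deoxygenated change is smaller and opposite in sign.  Physiological
noise is additive sinusoids with random phases: Mayer waves (0.1 Hz,
0.1 uM), respiration (0.25 Hz, 0.1 uM), cardiac (1 Hz, 0.15 uM), plus a
random linear drift (up to +/-0.5 uM over the session) and white noise
(0.03 uM sd).  These amplitudes are fixed package defaults chosen as
plausible for forehead fNIRS; they put single-session activation SNR
high enough that one session's block response is visible, which real
event-related recordings often are not — conclusions from passing tests
therefore concern the machinery, not field-strength effect sizes.

**Motion artifacts.** Spikes are Gaussian transients (default width
0.3 s FWHM) and baseline shifts are steps persisting to the end of the
record.  Session runs draw 2 spikes (5-10 sigma of the signal) and one
shift (2-4 sigma) uniformly inside the task period — participant motion
in a key-press task happens while the task runs — and log every event
for recovery scoring.  A 0.3 s FWHM Gaussian has only ~45% of its energy
below 0.5 Hz, so a derivative-domain corrector cannot remove a spike
completely; the remainder is handled by the hemodynamic band-pass.

**EEG.** Background is 1/f-shaped noise (RMS 10 uV by default, exponent
configurable; 0 gives white noise), with optional alpha and 50 Hz mains
sinusoids.  Stimulus-locked templates are added identically on both
channels at each onset.  Templates longer than the shortest gap trigger
an overlap warning rather than an error, since overlap is a property of
rapid designs, not a fault.

**Template calibration.** The ERP measurement chain (epoch, baseline
correction, trial average, 0.8-17 Hz zero-phase band-pass, window mean)
is linear but not transparent: it attenuates an isolated 50-100 ms bump
by a factor of 2-4.  `calibrate_erp_template` therefore builds one Hann
bump per component window and solves the 3x3 linear system so that the
*measured* component amplitudes of the noise-free template equal the
requested window means (defaults -2.7, -4.0, -2.0 uV for P450/N500/P600
— all three components of the prefrontal Stroop response are reported
negative-going, and the package keeps signed window means without
forcing polarity).  Noise-free recovery is then exact by linearity and
noisy recovery converges to the targets as trials accumulate.

**Crosstalk.** LED time-division multiplexing couples into the EEG
channel as a zero-mean rectangular pulse train (AC coupling removes any
DC term) at the switching frequency, default 125 Hz with 10 uV peak.
Phase is accumulated as `k * f mod fs` in a single rounding so switching
frequencies commensurate with the sample grid produce exactly periodic
trains.  Requesting a switching frequency at or above Nyquist raises an
aliasing error.

**Forearm occlusion.** A piecewise closed form: flat baseline; linear
dHbO2 decrease (-0.02 uM/s) and dHbR increase (+0.008 uM/s) during the
cuff; after release a fast/slow double exponential
`(depth - C) exp(-u/2s) + C exp(-u/12s)` that rebounds, overshoots the
baseline by `C` (0.4 uM for dHbO2) and decays back.  The closed form is
exported so recovered series can be checked against it analytically.

## fNIRS cleaning chain

Default order: first-order polynomial detrend, then temporal derivative
distribution repair (TDDR), then a third-order Butterworth band-pass at
0.01-0.08 Hz.  The order is configurable but the default is the
reference chain.

TDDR follows its original formulation: split the signal at 0.5 Hz; take
first differences of the slow part; iteratively reweight the centered
derivatives with the Tukey biweight (c = 4.685, robust sigma =
1.4826 * MAD) until the location estimate stabilizes (relative tolerance
sqrt(machine epsilon), at most 50 iterations — non-convergence returns
the best iterate with a warning); rescale, integrate, recenter, and add
back the untouched fast fluctuation.  Two properties worth knowing:
TDDR removes linear trends by construction (the weighted mean derivative
is subtracted), and it slightly shrinks any smooth component whose
derivative is comparable to the bulk derivative scale — on the default
sessions the clean-signal correlation is 0.98-0.997 per session (mean
~0.993).  It is near-identity only relative to signals with a
well-populated derivative distribution; on a noiseless isolated ramp it
would remove the ramp itself, which is why it runs on realistic
contaminated series, not on bare model output.

The band-pass is applied forward-backward (zero phase, doubling the
effective attenuation; realized single-pass -3 dB points are reported in
the cleaning report).  The ERP band filter applies full-length
even-reflection padding because a 1 s epoch is short relative to the
0.8 Hz high-pass time constant; with the default short padding,
out-of-band residue (e.g. switching crosstalk) leaks ~0.1 uV of edge
transient into the component windows, and even reflection suppresses
that by an order of magnitude without measurably changing passband
waveforms.

Response peaks are local extrema (maxima and minima separately) within
the task+rest window with prominence at least 10% of the in-window
range, ordered by time; "first/second peak" selects by extremum kind,
not value sign, so ripple that keeps a minimum slightly positive does
not misclassify it.

## EEG chain and ERP analysis

The acquisition front end is modeled as a causal second-order
Butterworth low-pass at 50 Hz (one active op-amp stage), a x1000 gain,
and additive input-referred noise; the output is referred back to input
microvolts.  Epochs span -250..+750 ms around onsets (trials whose
window exceeds the record are dropped and counted), baseline correction
subtracts the pre-stimulus mean per trial and channel, trials are
averaged first and the average is then band-passed at 0.8-17 Hz
(4th-order Butterworth, zero phase).  Component amplitudes are signed
window means over P450 (400-450 ms), N500 (450-550 ms) and P600
(600-700 ms); the mean (rather than a peak) makes amplitudes linear in
the data and the across-participant mean +/- SD table interpretable.

## Quality metrics

Input-referred noise is the RMS of the mean-removed zero-input chain
output (>=10 s required).  Amplitude distortion fits a sinusoid at the
known test frequency by least squares (bench practice against a signal
generator) and reports the percent amplitude error; frequency distortion
locates the spectral peak with quadratic interpolation on a Hann-windowed
spectrum and requires resolution <=0.1% of the test frequency.  The
crosstalk residual passes clean and crosstalk-bearing records through
the chain, band-limits the difference to 0-50 Hz with 8th-order
zero-phase Butterworth edges (a brickwall would make the metric
leakage-dominated and non-monotone), and reports
`100 * RMS(in-band residual) / RMS(injected)` plus the equivalent
rejection in dB.  With the default chain the residual falls
monotonically from ~85% at 30 Hz switching to <0.2% at 125 Hz — the
quantitative form of the statement that switching above 100 Hz is
separable from the 0-50 Hz EEG band by the low-pass alone.

## Coupling statistics

Sessions (virtual participants, default 13) are the unit of analysis.
Participant variability is one shared activation gain (N(1, 0.25^2))
scaling both the hemodynamic amplitude and the ERP template — the
mechanism that makes electrical and hemodynamic amplitudes covary.
Pearson r between component amplitudes and dHbR peak values uses the
exact t-transform (n-2 dof) for p; the Fp1-vs-Fp2 comparison is a
two-level repeated-measures ANOVA computed through its exact paired-t
equivalence (F = t^2, identical p), which avoids a general mixed-model
solver for a case with a closed form.  With n = 13 the correlation
estimate is noisy: across cohort seeds r for the N500/P600 vs dHbR-peak
pairings ranges roughly 0 to 0.7.  Degenerate inputs (zero variance, a
constant nonzero paired difference) raise errors rather than returning
arbitrary numbers.

## Verification design and problem sizes

The test suite checks each stage against an independent oracle: a
per-sample Cramer solve for the MBLL inversion, the prewarped analog
closed form for Butterworth magnitudes, periodograms for injected
sinusoids and pulse trains, the 1/sqrt(n) averaging law for trial
averaging, a Parseval noise-bandwidth integral for the filtered-noise
RMS, hand-computed covariance/t statistics for the coupling layer, and
the exported closed form for the occlusion run.  Batch checks use 20
sessions (cleaning recovery, TDDR, ERP recovery) and 2000 replicates
(type-I calibration); these sizes keep each battery under a couple of
minutes on one CPU while leaving comfortable statistical margins.  ERP
recovery batteries use 160 trials spaced >=1.0 s apart so that the 1 s
epoch windows of consecutive trials do not overlap; under the rapid
0.85-1.25 s Stroop spacing the previous trial's response intrudes into
the baseline window and biases P450 by ~0.2 uV, a property of the design
rather than of the measurement chain.

## Known limitations

- MBLL-level optics only: no photon-transport modeling, no partial
  volume or short-channel regression, no ADC/TIA/wireless modeling.
- Physiological noise is sinusoidal with random phase, not broadband;
  real Mayer/respiratory activity is band-limited noise, so TDDR and
  filter behavior on real data will differ in degree.
- The hemodynamic band-pass (0.01-0.08 Hz) necessarily reshapes a
  single block response whose fundamental is near 0.008 Hz; correlation
  with the unfiltered ground truth saturates near 0.85 even for perfect
  cleaning.
- The virtual cohort couples modalities through a single gain factor;
  real neurovascular coupling is regionally and temporally structured.
- CSV/TSV/JSON are the interchange formats; there is no SNIRF or EDF
  export.
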