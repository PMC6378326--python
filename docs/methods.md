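# Methods

`ripplelock` implements the event-locked analysis chain used to study how
a large-scale 3–5 Hz slow oscillation constrains neocortical fast ripples
(FRs) in unilateral hippocampal epilepsy: detection of FRs and multiunit
activity (MUA), baseline-normalized time–frequency analysis, circular
phase statistics, phase–amplitude coupling (PAC), inter-regional phase
synchrony and lags, and directed connectivity from a time-varying
autoregressive model. Because the underlying animal recordings are not
public, the package ships a synthetic-recording generator that emulates
the study's signal structure with full ground truth, and every analysis
stage is validated by recovery of that ground truth.

## Signal primitives

All filtering is zero-phase (forward–backward order-2 Butterworth,
`scipy.signal.sosfiltfilt`); every analysis downstream is phase-sensitive,
so group delay must be zero. The effective magnitude response is the
squared one-pass response — tests validate tone gains against that closed
form.

Instantaneous phase and envelope come from the Hilbert analytic signal of
the band-passed trace; phase 0 falls at local maxima (cosine convention).

The Stockwell transform uses the classic frequency-domain formulation
with the frequency-dependent Gaussian window of scale σ(f) = 1/f; the
fast implementation (one inverse FFT per frequency row) is tested to
1e−9 against a brute-force O(N²) evaluation of the same definition.
The Morlet transform uses a unit-L2-norm complex Morlet of 7 cycles
(σ_t = 7/(2πf)); the default grid is 199 bins spanning 1–100 Hz.
Transform inputs are reflection-padded by one window length and the pad
discarded, which keeps edge ringing out of 1 s analysis windows.

Epoch slicing is half-open `[onset + w_lo, onset + w_hi)` in samples with
the onset mapped to the nearest sample at or before the event time, so
all epochs have identical length and concatenating an epoch reproduces
the source slice exactly.

The bipolar montage differences successive contacts of each probe,
ordered superficial-first (probes are numbered from the top contact
down); bipolar channel metadata records the ordered source pair. Phase
analyses refuse monopolar input unless explicitly overridden, since a
shared reference would fabricate synchrony.

## Synthetic recordings

`SynthConfig` defaults are the study conditions: 16 kHz sampling, three
regions (left/right hippocampus LH/RH, frontal cortex FC) with 16-contact
probes, ~800 ms epileptic complexes containing a slow oscillation at
4.5 Hz (inside the 3–5 Hz band, the coupling phase frequency), an IED
burst at 27 Hz whose amplitude follows `(1 + d·cos(φ_slow − φ_pref))/2`
with coupling depth d = 0.8, one FR burst (200–550 Hz, default 450 Hz,
8 cycles, 5× background SD) starting at slow phase 1.57 rad, MUA locked
to the slow phase by a von Mises intensity (κ 1.08 / mean 0.56 rad during
events vs 0.32 / 0.18 rad at baseline), hippocampi leading frontal cortex
by 64 ms (LH) and 52 ms (RH), and a causal slow-band drive from each
hippocampal common mode into FC. A desk profile (4 kHz, 60 s, 30
complexes, 4 contacts) keeps the FR band under Nyquist while making full
pipeline runs take seconds; problem sizes in tests use this profile.

Design choices the data do not pin down:

* **Background** is Gaussian 1/f^α (α = 1), per-channel independent plus
  a per-region common mode (weight 0.2), channel SD 1 μV. FR amplitude is
  therefore specified relative to background SD.
* **FR burst envelope** is a Tukey(0.25) taper: pathological
  high-frequency bursts rise quickly, and a slow-rising envelope would
  make the notion of a burst onset ill-defined at the millisecond scale.
* **Laminar gain profile**: field components scale linearly from +1
  (superficial) to −0.5 (deep) across contacts, emulating the
  depth-dependent polarity of laminar LFPs. Without it every field
  component would cancel exactly in the bipolar montage, which no real
  recording does.
* **Region specificity**: the slow oscillation and FR waveforms propagate
  across regions (identical, shifted by the lag); the IED carrier phase
  is redrawn per region, so only the slow oscillation is coherent across
  regions — matching the observation that inter-regional synchrony peaks
  in the slow band, not the IED band.
* **Ongoing slow oscillation**: each region carries a weak (0.5× SD)
  ~4 Hz background oscillator with slow frequency drift (0.4 Hz SD,
  low-passed at 0.3 Hz), independent across regions. It keeps baseline
  MUA phase-locking measurable in the LFP while leaving the regions
  incoherent outside complexes.
* **Directed drive**: a causal AR(2)-resonator-filtered (4.5 Hz, poles at
  r = 0.97) copy of each hippocampal common mode enters the FC channels
  delayed by the regional lag, with an envelope that is weak (0.25) at
  baseline and full around complexes. The deterministic complex waveform
  itself carries no innovation, so the stochastic drive is what a Granger
  framework can genuinely attribute; modulating it reproduces the
  increase of hippocampus→cortex driving around the events.
* **MUA** spikes are injected into a dedicated wideband channel group of
  the FC probe (as in dual LFP/spike-stream acquisition), with
  depth-dependent down-state suppression (deep layers suppressed more in
  the −180 to −30 ms window) and a deep-leading onset boost (5 ms/unit
  depth) around FR onset.

What the generator does **not** emulate: biophysical (conductance-based)
dynamics, seizures, artifacts and line noise, electrode drift,
single-unit identity, and the across-animal variability of the real
data. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated signal model, not performance on real
recordings.

## Event detection

**Fast ripples.** The trace is band-passed to 200–550 Hz; candidate
segments are samples with |x| above 3× a robust global scale
(median(|x|)/0.6745), merged across gaps < 10 ms. Each candidate is
re-tested against the SD of its ±250 ms surrounding baseline with the
candidate's own samples excluded (a large event must not inflate its own
baseline). Suprathreshold positive and negative extrema are found by
derivative sign changes; extrema separated from the main cluster by more
than ~1.5 half-cycles of the band's low edge are trimmed (isolated noise
excursions may not claim the onset), consecutive same-sign extrema are
collapsed, and the event requires at least four positive and four
negative extrema. The onset is the first suprathreshold extremum;
detection is invariant to signal scaling by construction. On the desk
profile the detector reaches sensitivity 1.0 with zero false positives
and sub-millisecond median onset error; on pure 1/f noise the false
positive rate is below 0.1/min.

**MUA.** Threshold `4·median(|x|)/0.6745` on the 300–6000 Hz band
(0.6745 is the median of |N(0,1)|, making the threshold 4 robust-SD units
for Gaussian noise); crossings are reported at the local extremum with a
1 ms dead time. If the band does not fit under Nyquist the upper edge
falls back to 0.45·fs and the metadata records the reduction.

**IED association** requires maximal z > 2 within 20–30 Hz of the
event's z-scored spectrogram; **band onsets** are the earliest time at
which the across-event median of band-averaged z exceeds 5 (a sentinel
`None` is returned when the threshold is never crossed).

## Baseline-normalized spectrograms

Baseline epochs of the same duration as the analysis window are sampled
uniformly outside all catalogued field-potential events plus a 1 s guard
(the seizure exclusion of the original protocol is replaced by event
exclusion; MUA spikes tile the whole recording and are not excluded).
Per-frequency-bin, time-resolved mean and SD across baseline Stockwell
magnitudes define the z-score; a time-collapsed option exists. The SD is
floored at 1e−12. Averaged z maps carry a significance contour at z > 5.
Z-scoring is affine-invariant when the baseline is recomputed on the
scaled data.

## Circular statistics

Concentration κ is estimated from the mean resultant length by Fisher's
piecewise ML approximation (capped at 1e8 as R → 1). The Rayleigh test
uses Z = nR² with the standard finite-n correction; the Watson–Williams
test uses the F statistic with the 1 + 3/(8κ̂) correction and carries a
validity flag when the pooled resultant is below 0.45. For equal
concentration the package uses the concentrated-sample F-ratio test when
both resultants exceed 0.7 and otherwise the Wallraff rank-sum test on
angular deviations from each sample's own circular mean (the
concentrated test's validity range excludes κ values like 0.32, so a
single method cannot cover the use cases; the hand-coded U statistic is
cross-checked against an independent rank-test implementation in the
tests). Monte-Carlo calibration holds the type-I error of all three
tests inside [0.04, 0.06] at α = 0.05.

The phase-locking factor is `PLF(f,t) = |mean_events e^{iφ(f,t)}|` from
Morlet phases, with a per-event, per-frequency control obtained by a
seeded shuffle of phases along time, and an equal-concentration test per
cell Bonferroni-corrected by the number of (f, t) cells. Per-cell method
selection matters at desk scale: with few tens of events a rank
statistic cannot reach Bonferroni-level p at all, while the F-ratio test
is valid exactly in the concentrated cells that matter. PLF maps may be
decimated in time (`time_decim`) — phases vary on the wavelet's time
scale, so nothing is lost and the multiple-comparison burden drops.

The synchrony scan band-passes both (bipolar) signals at 1–100 Hz
centres (3 Hz bandwidth, 1 Hz step), pools the Hilbert phase differences
over all POI windows and all baseline windows, and reports κ for each
pool, their ratio, and an equal-concentration p. The phase difference of
a 3 Hz-wide band decorrelates over ~1/bandwidth, so the test is run on
values subsampled at half that interval — using every sample would
inflate the nominal n by orders of magnitude and make the test wildly
anticonservative on null data.

## Phase–amplitude coupling

The modulation index follows the five-step KL procedure: mean amplitude
per 18 phase bins (half-open over (−π, π]), normalized to a probability
vector p, `MI = KL(p‖uniform)/log 18 ∈ [0, 1]`. Zero bins contribute 0
to the KL sum (the exact 0·log 0 limit), so MI(uniform) = 0 and
MI(single bin) = 1 at machine precision. MI is computed per event and
averaged by default (a pooled option exists).

Band extraction for PAC uses FFT-domain selection (raised-cosine 1 Hz
edges, reflection padding, one inverse FFT per band yielding the
analytic signal directly). The phase band is the nominal 3 Hz wide band.
The amplitude band is widened per phase row to `bandwidth + 2·f_phase`:
an amplitude band that cannot contain the modulation side components at
f_c ± f_p carries no amplitude modulation at f_p at all, and a band
holding the carrier together with only one side component shows
spuriously deep beat modulation centred on the side components rather
than on the carrier. The widening is the minimal choice that holds the
full triplet; it reduces to the nominal bandwidth as f_phase → 0. With
steep band edges this makes the comodulogram peak sharply at the true
(f_phase, f_amp) of the generated coupling; with the nominal narrow
bands (any implementation, IIR, FIR or wavelet) the peak lands on the
upper side component instead — an identifiability failure of the
narrow-band estimator, not of the data.

Epochs must span at least 3 cycles of the lowest phase frequency; the
pipeline clamps the default 2–20 Hz phase grid accordingly (4 Hz for the
0.8 s period of interest).

## Connectivity

The TVAR model is estimated per sample by a Kalman filter with
random-walk coefficient dynamics: state = stacked AR coefficients,
shared regressor across sink channels (one covariance recursion serves
all sinks), state-noise rate c (default 0.02), inputs normalized per
channel for conditioning and coefficients rescaled afterwards. As
c → 0 the time-averaged coefficients converge to the least-squares VAR
solution (verified on three rates); stability of the companion form is
monitored and flagged.

`A(f,t) = I − Σ_m a_m(t) e^{−i2πfm/fs}` by default (a bare-transform
variant exists), and the normalized directed quantity is
`|A_ij|²/Σ_k|A_ik|²` — the denominator sums over the entries of row i
(sink normalization), with the standard PDC column/source normalization
available behind a flag. The band-integrated iAPDC is the mean of the
normalized quantity over the frequency grid inside [f1, f2]. The
normalization identity (rows summing to 1) holds at machine precision.

The pipeline runs connectivity on region-averaged signals decimated to
100 Hz with order 8: the model's lag window must span the
tens-of-milliseconds inter-regional delays (at 1 kHz an order-5 model
sees only 5 ms and attributes nothing). Condition comparison
(POI vs baseline medians, percent difference, Kruskal–Wallis) is a thin
contract wrapper over the standard rank test.

Cross-correlation lags are computed on band-limited (3–5 Hz) signals
with filter edge transients trimmed; the sign convention is that a
negative lag means the second signal is delayed relative to the first.
The estimator is antisymmetric, and recovers a constructed 64 ms delay
exactly at 1 kHz.

## Peri-event analyses

PSTHs pool spike counts in fixed bins across events. Laminar firing
ratios normalize counts in the down-state window (−180 to −30 ms) and
the FR window (−30 to +20 ms) by the preceding-baseline rate
(−500 to −200 ms; channels with zero baseline spikes are flagged and
excluded). The laminar chronology smooths the pooled binary spike train
with a unit-area 10 ms Hanning window (making it a rate estimate) and
takes the first time within ±30 ms of FR onset exceeding 3 SD of the
preceding baseline; channels never crossing carry a null onset and are
excluded from the ranking, ties share a rank. Precedence analysis
reports, per region, the fraction of reference FRs preceded by an FR of
that region within a 10 ms and a 500 ms window, against a matched
−1000 to −500 ms baseline window with a Wilcoxon signed-rank contract.

## Numerical and scale choices

Analysis rate for LFP-band work is 1 kHz (anti-aliased decimation);
detection runs at the acquisition rate. Test and pipeline problem sizes
use the desk profile (60–90 s, 12–30 complexes, 4 contacts); detector
validation runs at the full 30-complex density while baseline-dependent
stages use 12 complexes in 90 s so that event-free baseline epochs exist
under the 1 s guard.

## Known limitations

* The equal-concentration test on pooled phase differences treats
  subsampled values as independent; residual dependence makes the test
  mildly conservative rather than exact.
* κ estimated from LFP phase at spike times is attenuated relative to
  the generating concentration because measurement phase noise
  convolves the von Mises distribution; orderings and contrasts are
  preserved, absolute κ values are biased low.
* The comodulogram's adaptive amplitude bandwidth restores peak
  identifiability but departs from a fixed nominal 3 Hz amplitude
  bandwidth; with fixed narrow bands the peak systematically lands one
  modulation frequency above the carrier.
* The reported conversion of a mean-angle difference to milliseconds via
  a 35 Hz cycle, mentioned in the source literature's discussion, is
  internally inconsistent and is not implemented.
* Ratio-of-κ synchrony profiles are noisy wherever both κs are near
  zero; κ of the POI pool itself is the more stable peak locator at
  small event counts.
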