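# Methods

This note documents the models, numerical choices and limitations behind
`specscore`. Units: frequencies in Hz, durations in seconds, amplitudes
in µV, powers in dB (relative dB once the nightly baseline is removed).

## Time–frequency decomposition

The spectrogram is a continuous wavelet transform with zero-mean complex
Morlet wavelets. The frequency grid is 100 log-spaced points on
[0.1, 100] Hz; log spacing matches both the ~1/f organisation of EEG and
the log-frequency axis the spectrogram is displayed on. The cycle count
grows from 3 at 0.1 Hz to 30 at 100 Hz, linearly in log₁₀ f — the
simplest smooth monotone rule through both endpoints — giving each
frequency a proportionate time/frequency-resolution trade-off
(σ_t = cycles/(2πf), σ_f = f/cycles).

Each wavelet is applied in the frequency domain as its exact Gaussian
response 2·(G(f−f₀) − κ·G(f)), κ = exp(−f₀²/2σ_f²), evaluated over
signed frequencies and truncated only beyond 8σ_f (relative ~1.3·10⁻¹⁴).
Two consequences worth knowing:

* The κ term makes the wavelet exactly zero-mean, and *not* cutting the
  response at 0 Hz keeps the wavelet Gaussian-compact in time, so the
  transform is shift-equivariant to ~10⁻¹² dB. The cost is that the
  lowest-frequency wavelets (few cycles) are not strictly analytic; for
  3 cycles this contributes a ripple below 1% of amplitude.
* The gain is 2 at f₀, so a unit-amplitude real sinusoid yields unit
  peak power (0 dB); doubling an amplitude adds 10·log₁₀ 4 ≈ 6.02 dB.

Because only one output per 0.5-s hop is needed, the product spectrum is
folded modulo the decimated length and inverted with a short FFT; this
equals the full convolution sampled at each hop-window centre exactly,
and makes an 8-h, 500-Hz night decomposable in ~10 s. Power is floored
at 10⁻¹² before the log so silence stays finite (−120 dB). Bins whose
wavelet (±5σ_t) overhangs the record are computed against zero padding
and flagged in `edge_mask`. A config switch (`db_mode="amplitude"`)
logs the magnitude instead of the squared magnitude; relative-dB
features differ only by a factor 2, so staging is essentially
unaffected.

## Noise epochs and baseline

A 0.5-s bin is "noise" when the robust z-score (median/1.4826·MAD) of
either feature exceeds 4 in absolute value: dB total spectrogram power
per bin, and dB RMS of the raw signal in a 2-s window. Both features are
first detrended by a centred 10-min rolling median. The detrending is
what distinguishes a transient artifact from sleep's own dynamics: a
×20 movement artifact rises ~26 dB above its local context, while
slow-wave sleep runs 12–16 dB above the *whole-night* median for tens
of minutes at a time — extreme globally, ordinary locally. Without the
local reference, entire deep-sleep periods would be masked and the EM
step starved of exactly the epochs the method is most interested in.
Log-scale features make the mask invariant to rescaling the record; a
constant feature (MAD = 0) contributes no flags and warns.

The baseline is the per-frequency mean over unmasked bins, subtracted
from every bin (masked ones included, so everything stays on one
relative-dB scale). Display artifacts from mains interference are
handled separately: rows between 50 and 70 Hz are replaced by
log-frequency interpolation of the neighbouring rows for rendering, and
the gamma scoring band simply excludes that range.

## Band features and refinement

Epoch features are means of the baselined spectrogram over each band's
grid rows and the epoch's time bins; 30-s epochs by default, any length
≥ 10 s supported (below ~10 s momentary spindle or delta bursts start
flipping the hypnogram). A trailing partial epoch is dropped. Scoring
uses unsmoothed epoch means; the 40-s moving average is applied only to
the display spectrogram and the dominant-frequency trace (argmax over
frequency per bin, ties to the lower frequency).

After a first-pass scoring, the spindle peak is sought in 9–16 Hz over
the mean spectrum of Light-scored epochs, and the low-beta peak in
15–30 Hz over REM-scored epochs (windows chosen to bracket the default
bands with margin). Peaks are refined to sub-bin precision by parabolic
interpolation in log-frequency, then Light becomes [p−1, p+1.5] Hz and
REM [p−2, p+2] Hz. A stage absent from the first pass leaves its band
at the default.

## HMM staging

Each spectral stage is an HMM state with a diagonal-covariance Gaussian
emission over the 5 relative-dB features — dB band powers are roughly
Gaussian within a stage, and a diagonal covariance keeps EM stable on a
single night (~900 epochs). Initialisation is deterministic: epochs are
provisionally labelled by their largest band feature (band k defines
stage k), stage moments come from those labels, and the transition
matrix from labelled transition counts plus 5 diagonal pseudo-counts
(stages persist across 30-s epochs). The initial distribution puts 0.8
on Wake. Baum–Welch then runs to a relative log-likelihood improvement
below 10⁻⁶ or 50 iterations; variances are floored at 0.25 dB².
Noise-flagged epochs (≥ 50 % masked bins) are decoded normally but
carry zero weight in the emission statistics; a state left with no
effective data keeps its previous parameters, and if the (unweighted)
likelihood ever decreases — possible only through that weighting or a
binding floor — the previous model is kept and iteration stops, so the
reported trace is non-decreasing.

Decoding assigns each epoch the state with maximal forward–backward
posterior (scaled, probability-space recursions), *not* the most
probable path; ties break by the fixed order Wake > REM > Light >
Hi Deep > Lo Deep. Both EM passes (default and refined bands) rerun the
same fit from the same deterministic initialisation, so scoring is
bit-reproducible.

## Correction rules

Thresholds live on the relative-dB scale so one set of defaults
transfers across recordings: θ_ratio = 2 (beta minus spindle),
θ_spindle = 0 (spindle power below the night baseline is "relatively
low"), θ_total = 3 above the night median, θ_delta = θ_spindle_high = 2.
Rule order (Deep→REM/Wake, Deep→Wake, Deep→Light, then post-onset
Wake→Hi Deep/Light) is applied in a single pass; the first rule to fire
wins, epochs already carrying a change marker are skipped, and sleep
onset (first run of ≥ 10 consecutive non-Wake epochs, i.e. 5 min) is
computed once from the input hypnogram — together these make the
operation idempotent. Rule 2's per-epoch "total power" is the *median*
of the five band features rather than the mean: the rule targets
broadband noise ("not sleep"), and a median demands elevation across
bands where a mean is captured by a single strong delta band, which
would wrongly convert genuine deep sleep. Where a deep epoch's
beta-to-spindle ratio triggers rule 1, Wake is chosen over REM when the
gamma feature exceeds the beta feature.

## Synthetic nights

The generator exists so the full pipeline is testable without any
recording: pink noise (1/f, 10 µV RMS) plus per-segment stage
signatures — broadband 40–95 Hz gamma at 3 µV (Wake), narrowband
~20 Hz low-beta at 5 µV (REM), 13-Hz spindles as 1-s Hann bursts every
4–6 s at 8 µV (Light), 1–3 Hz delta at 40 µV (Hi Deep), and 0.3–0.9 Hz
slow oscillations at 60 µV with mild spindle content (Lo Deep, matching
the K-complex/spindle milieu of slow-wave sleep). The amplitude ordering
(slow large, fast small) follows human sleep EEG; spindles as sparse
bursts rather than a continuous rhythm deliberately stress the epoch
averaging. Identical seeds give bit-identical nights.

What the generator does *not* emulate: eye movements, EMG/ECG
contamination, electrode pops beyond gain artifacts, stage transitions
that evolve gradually, and the overlapping, drifting band peaks of real
subjects. Passing the end-to-end recovery tests therefore demonstrates
the internal consistency of the pipeline — that the five-band HMM
recovers stages whose spectral definitions hold — not clinical accuracy
on real recordings, which can only be established against scored PSG.

## Problem sizes and runtime choices

End-to-end checks score five synthetic nights of 7.5 h (five 90-min
Wake→Light→Hi Deep→Lo Deep→Light→REM cycles) at 500 Hz — long enough
for every stage to recur across cycles and for the 10-min detrending
window to be exercised, while keeping a full acceptance run around a
minute. Oracle checks use deliberately tiny sizes (≤ 8 epochs, 3 states)
where exhaustive path enumeration is exact.

## Known limitations

* N1 has no spectral equivalent; comparisons keep the visual N1 row but
  the spectral vocabulary cannot produce it.
* Epoch alignment between hypnograms is by index from a common start;
  sub-epoch offsets between devices are out of scope.
* The EDF writer covers plain 16-bit EDF (one record duration, no
  annotations); EDF+ annotation channels are ignored on read.
* Emission covariances are diagonal; correlated band fluctuations (e.g.
  broadband arousals) are modelled only through the stage means.
* Thresholded corrections are heuristics: on recordings whose baseline
  is itself contaminated, the relative-dB defaults may need adjusting
  via the YAML config.
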