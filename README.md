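# specscore

Automatic sleep staging from a single channel of EEG, using the spectral
content of the signal as the stage definition itself rather than as a
proxy for what a human scorer would see in the time domain.

The package targets forehead recordings (e.g. FP1-AFz / FP2-AFz from an
adhesive patch, 500 Hz, no hardware filters), where classical posterior
alpha and frontal theta cues are unreliable, and is aimed at sleep
researchers and engineers who want an objective, reproducible hypnogram
plus the whole-night spectrogram to verify it against. Everything is also
exercisable without any recording through a synthetic sleep-EEG generator.

## Method

1. **Morlet wavelet spectrogram.** Each channel is decomposed into power
   at 100 log-spaced frequencies spanning 0.1–100 Hz, every 0.5 s, with a
   gradient of 3 cycles at the lowest frequency to 30 at the highest
   (linear in log₁₀ f). Power is the squared magnitude of the complex
   coefficient, in dB (10·log₁₀).
2. **Baseline removal.** Noise bins — extreme windowed RMS or total power
   relative to the local background (robust z > 4) — are excluded from a
   whole-night per-frequency mean, which is subtracted everywhere. All
   features are then relative dB for that night. Line noise (50–70 Hz) is
   masked for display and ignored by the gamma band.
3. **Five-band features.** Each 30-s epoch becomes the 5-vector of mean
   relative dB in Wake (40–95 Hz), REM (~17–26 Hz), Light (~11–15.5 Hz),
   Hi Deep (1–3 Hz) and Lo Deep (0.1–1 Hz). The REM and Light bands are
   re-centred on each night's own low-beta and spindle peaks after a
   first pass (peak −1/+1.5 Hz for Light, ±2 Hz for REM).
4. **HMM staging.** The five stages are states of a hidden Markov model
   with diagonal-Gaussian emissions over the band features, initialised
   from an argmax-band labelling, refined by Baum–Welch EM, and decoded
   by **maximal posterior probability per epoch** (forward–backward
   marginals γₜ(k), not the Viterbi path).
5. **Post-HMM corrections.** Four ordered rules repair irregular
   expressions (noisy "Deep" that is wake, deep-scored epochs whose
   spindles say Light, post-onset wake whose delta/spindles say NREM),
   recording each epoch's pre-correction stage as a change marker.
6. **Comparison statistics.** Hypnograms are compared via 5×5 confusion
   matrices (visual wake/N1/N2/N3/REM × spectral stages), percentages
   along rows and columns, cell-wise medians across subjects, cell-wise
   averaging of channel pairs, and per-stage durations.

## Worked example

`examples/simulate_and_score.py` builds a two-hour synthetic night from a
stage script, scores it, and prints:

```
simulated 120 min at 250 Hz, 240 epochs
epoch agreement with ground truth: 100.0%
epochs changed by correction rules: 0
hours per stage (spectral scoring):
  WAKE    0.33 h
  REM     0.33 h
  LIGHT   0.67 h
  HIDEEP  0.42 h
  LODEEP  0.25 h
```

The agreement line compares the decoded hypnogram with the script the
night was generated from; zero corrections on clean sleep is expected —
the repair rules exist for ambiguous real recordings. The stage hours
equal the scripted durations (e.g. 1200 s of scripted REM = 0.33 h).

The other examples tour the spectrogram layer
(`examples/spectrogram_tour.py`: tone localisation on the grid, the
+6.02 dB amplitude-doubling law) and the comparison statistics
(`examples/compare_hypnograms.py`: confusion counts, bidirectional
percentages, pooled medians).

A command-line interface wraps the same pipeline:

```bash
specscore simulate --seed 7 --out night.edf --truth truth.csv
specscore score night.edf --channel SYN1 --out hyp.csv --report report.png --ref truth.csv
specscore compare truth.csv hyp.csv --direction both --out confusion
```

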