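# cardioformant

Formant-based phonocardiogram analysis for pulmonary artery hypertension
(PAH) screening.

The package re-implements a speech-inspired heart-sound pipeline: mono
stethoscope recordings are resampled to 8 kHz, split into 32-ms frames and
fit with 8th-order linear predictive coding; the four strongest spectral
resonances per frame form four formant tracks, which drive a sine-wave
replica (four time-varying sinusoids).  Each replica waveform is summarized
by spectral features — entropy (sum of log squared spectrogram magnitudes),
energy, and a relative-band-power comparator.  Cohorts of subjects grouped
by mean pulmonary artery pressure (PAH: mPAp >= 25 mmHg with wedge pressure
<= 15 mmHg) are compared with pooled two-sample t-tests per recording site
and formant, corrected with Holm-Bonferroni; a window-length sweep (1-20 s)
picks the most discriminative segment length, and a one-dimensional linear
discriminant with leave-one-out cross-validation reports sensitivity and
specificity.  A post-hoc power calculation (normal approximation or
noncentral-t) estimates the required per-group sample size.

Because no patient recordings ship with the package, a synthetic cohort
generator (`cardioformant.simulate`) produces multi-site heart-sound WAV
cohorts with a planted, site-specific vowel-like tonal signature in the
hypertensive group, so the whole pipeline is testable end to end.

## Layout

| module | role |
| --- | --- |
| `cardioformant.pcg_io` | WAV read/write, resampling, framing, cohort metadata |
| `cardioformant.formants` | per-frame LPC fits and formant-track extraction |
| `cardioformant.replica` | sine-wave replica synthesis from formant tracks |
| `cardioformant.features` | spectrograms, entropy/energy/band-power features |
| `cardioformant.cohort_stats` | t-tests, Holm-Bonferroni, ranking, sweeps, power |
| `cardioformant.classify` | 1-D LDA, leave-one-out CV, sensitivity/specificity |
| `cardioformant.simulate` | synthetic multi-site heart-sound cohorts |
| `cardioformant.pipeline` / `cli` | end-to-end orchestration and CLI |

## CLI

```sh
# generate a 60-subject synthetic cohort (WAVs + metadata.tsv)
cardioformant simulate --out cohort/ --seed 1

# run the full pipeline: features -> site/formant ranking -> window sweep -> LDA/LOO
cardioformant run --metadata cohort/metadata.tsv --out run/

# individual stages
cardioformant extract cohort/wavs/P001_2LICS.wav track.tsv
cardioformant features --metadata cohort/metadata.tsv --out features.tsv -L 10
cardioformant cohort-test --features features.tsv --out ranking.tsv
cardioformant classify --features features.tsv --site 2LICS --formant 1 -L 10
cardioformant power --mean-null 4.75e5 --mean-alt 4.56e5 --sd 9.85e3
```

`run` writes `features.tsv`, `site_formant_tests.tsv`, `window_sweep.tsv`,
`predictions.tsv`, `summary.json` and a `manifest.yaml` echoing every
parameter plus input hashes, so a run is reproducible from the manifest.

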