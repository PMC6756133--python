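# envtrack

Neural envelope tracking of speech from EEG: how well the amplitude
envelope of running speech can be linearly reconstructed from a listener's
EEG, as a function of stimulus signal-to-noise ratio (SNR) and attentional
state. The reconstruction correlation is an objective proxy for speech
processing, usable to estimate a neural speech reception threshold (SRT)
without a behavioral response — of interest to auditory neuroscientists and
audiologists working toward objective measures of speech understanding.

The package implements the full analysis chain:

* **Envelope extraction** — 28-channel ERB-spaced gammatone filterbank
  (50–5000 Hz), per-sample `|x|^0.6` compression, subband averaging.
* **EEG preprocessing** — 500 µV glitch blanking with linear
  interpolation, multichannel-Wiener-filter ocular artifact suppression
  (5× frontal power detection), average re-referencing, zero-phase
  Chebyshev-II band-pass (delta 0.5–4 Hz / theta 4–8 Hz, 80 dB effective
  stopband), polyphase resampling (native → 256 → 128 Hz).
* **Backward decoding** — ridge regression over 64 channels × post-stimulus
  lags (0–75 or 0–500 ms),

  ŝ(t) = Σₙ Στ g(n,τ) R(t+τ,n),  g = (RRᵀ + λI)⁻¹ RSᵀ,  λ = max|RRᵀ|,

  scored by moving-block-bootstrapped Spearman correlation ρ(s, ŝ).
* **Forward TRF** — the per-channel temporal response function mapping
  envelope to EEG, with P1/N1/P2 peak extraction.
* **Statistics** — logistic psychometric (SRT) fits with optional free
  guess/lapse rates, k-means SNR binning, Hittner's test for dependent
  correlations, paired sign-flip permutation tests with Holm–Bonferroni,
  Brown–Forsythe, and cluster-based permutation testing of TRF differences
  over channels × lags.
* **Synthetic study generator** — Matrix-sentence timelines (2 s sentences,
  0.8–1.2 s gaps), modulated envelopes (2.5 / 4.1 Hz), condition-specific
  P1/N1/P2 response kernels (attenuated right-frontal P2 for a distracted
  "movie" condition), SNR-dependent tracking gain, 1/f noise, blinks and
  glitches — so every stage is testable with known ground truth.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

```python
from envtrack import (SyntheticStudyConfig, AnalysisConfig,
                      gen_study, run_study)

study = gen_study(SyntheticStudyConfig(
    n_subjects=4, snr_grid=(-12.5, -9.5, -6.5, 2.5, None),
    repetitions=1, story_duration_s=120.0, seed=7))
report = run_study(study, AnalysisConfig(lags_ms=(0, 75), n_boot=100,
                                         n_perm=1000, seed=7))

for cond, (rho, p) in report.snr_correlations.items():
    print(f"{cond}: SNR-tracking Spearman rho = {rho:.2f} (p = {p:.1e})")
print("attention SRT: %.2f dB" % report.psychometric["attention"].alpha)
print(report.tracking.head(5).to_string(index=False))
```

prints

```
attention: SNR-tracking Spearman rho = 0.91 (p = 1.0e-06)
movie: SNR-tracking Spearman rho = 0.95 (p = 3.2e-08)
attention SRT: -9.28 dB
subject condition  bin_center      rho   ci_low  ci_high
 sub-01 attention       -12.5 0.121470 0.068173 0.202738
 sub-01 attention        -9.5 0.181123 0.106369 0.266257
 sub-01 attention        -6.5 0.352797 0.295171 0.403061
 sub-01 attention         2.5 0.409528 0.344025 0.469624
 sub-01 attention         inf 0.473737 0.441456 0.507605
```

Tracking rises with SNR in both conditions (Spearman ρ ≈ 0.91–0.95 against
bin center over subjects × bins), saturating toward the quiet condition
(`bin_center = inf`); the psychometric fit to the attention-condition
correlations puts the neural SRT near the generator's −9.15 dB gain
midpoint. With more subjects the report also carries the per-SNR paired
permutation contrasts between attention and movie, the dependent-correlation
comparison, and the cluster-based TRF analysis, which localizes the
injected attention effect to right-frontal channels around 140–190 ms.

The same stages are scriptable from a shell:

```bash
envtrack simulate --subjects 4 --seed 7 -o study/
envtrack run study/ --seed 7 -o results/
envtrack envelope stimulus.wav --fmin 50 --fmax 5000 -o envelope.npz
```

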