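# Methods

`envtrack` measures neural envelope tracking: how faithfully the amplitude
envelope of running speech can be reconstructed from simultaneous EEG, as a
function of stimulus signal-to-noise ratio (SNR) and of the listener's
attentional state. This note documents the models, the estimation choices,
the synthetic-data generator that stands in for real recordings, and the
known limitations.

## Envelope extraction

The auditory envelope of a speech waveform is computed with a gammatone
filterbank followed by a power law. Center frequencies are spaced one
equivalent rectangular bandwidth (ERB) apart on the Glasberg–Moore scale

    E(f) = 21.4 · log10(0.00437 · f + 1),

from 50 Hz up to (not exceeding) 5000 Hz, which yields 28 channels. Each
subband is a 4th-order IIR gammatone filter (scipy's realization, applied
causally in second-order sections for numerical stability at low center
frequencies). The subband envelope is `|x|^0.6` sample-by-sample — the
exponent approximates cochlear compressive growth — and the single-channel
envelope is the unweighted mean of the 28 subband envelopes. Compression is
applied to the raw subband samples, not to a Hilbert envelope; the choice
is config-exposed through the `exponent` argument only.

## EEG preprocessing

Applied in this order, mirroring a standard envelope-tracking chain:

1. **Glitch blanking.** Samples with |amplitude| > 500 µV are replaced by
   linear interpolation between the nearest surviving samples on the same
   channel (edge runs are held at the nearest surviving value). Applied at
   the native rate, before any filtering, so filter ringing cannot smear
   glitches.
2. **Resampling to 256 Hz** (anti-aliased polyphase, `padtype="line"`).
3. **Ocular artifact suppression** with a multichannel Wiener filter
   (MWF). Detection: any sample whose instantaneous power on one of the
   eight forehead channels (Fp1, AF7, AF3, Fpz, Fp2, AF8, AF4, AFz)
   exceeds 5× that channel's time-averaged power. Detected samples are
   consolidated into *events* (gaps ≤ 10 ms merged; events must span
   ≥ 50 ms and contain an unbroken ≥ 25 ms core) because isolated
   threshold crossings occur by chance in any Gaussian-tailed signal and
   carry no artifact subspace. Covariances of the ±3-sample delay-stacked
   data are estimated over event vs clean samples; the generalized
   eigendecomposition gives the filter, keeping components with
   artifact-to-clean eigenvalue > 1 (Wiener gain 1 − 1/λ). The artifact
   estimate is subtracted inside the event windows (dilated 100 ms, with
   raised-cosine ramps). Subtracting only inside events, rather than
   globally, is a deliberate design choice: it bounds the distortion of
   artifact-free stretches at exactly zero, at the cost of leaving any
   undetected artifact untouched.
4. **Average re-referencing** (idempotent projection).
5. **Band-pass filtering**: zero-phase Chebyshev type-II, stopband edges
   10% outside the passband. The design target is 40 dB per pass; the
   forward–backward application squares the magnitude response, so the
   effective attenuation is 80 dB. Bands: delta 0.5–4 Hz, theta 4–8 Hz,
   spanning the Matrix-sentence word rate (2.5 Hz) and syllable rate
   (4.1 Hz). The same code path filters EEG and envelope, so both see
   bit-identical responses.
6. **Resampling to 128 Hz** for decoding.

## Backward decoder

The decoder reconstructs the envelope s(t) from all channels over a window
of post-stimulus lags τ:

    ŝ(t) = Σ_n Σ_τ g(n, τ) · R(t + τ, n)

with R the lagged neural data (zero-padded at the boundary so the number
of time rows is preserved). The weights solve the ridge-regularized normal
equations g = (R Rᵀ + λI)⁻¹ R Sᵀ with λ equal to the maximal absolute
entry of the autocorrelation matrix R Rᵀ. EEG channels and envelope are
z-scored before fitting, which makes this λ rule scale-free (the maximal
entry is then the number of samples); both the normalization and λ can be
overridden. Lag windows: 0–75 ms (weakly attention-dependent early
responses, the default for SNR tracking) and 0–500 ms. Note that the
0–500 ms backward design has 64 × 65 = 4160 columns; on long recordings
its Gram matrix is expensive, which is one reason the early window is the
tracking default.

Tracking strength is the median Spearman correlation between the measured
and reconstructed envelopes under a moving-block bootstrap (5 s blocks
resampled with replacement, 1000 replicates by default, 2.5–97.5
percentile interval). Block resampling preserves the within-block
autocorrelation of band-limited signals; plain i.i.d. resampling of
samples would not.

The decoder is always trained on a separate continuous "story" stimulus
and applied to the Matrix test trials — train/test stimulus separation is
enforced by the pipeline.

## Forward TRF

The temporal response function h(c, τ) predicts each EEG channel from
lagged envelope copies, with the same ridge rule applied to the envelope
autocorrelation. After fitting on z-scored data the kernel is rescaled to
physical units (µV per unit envelope) so TRFs are comparable across
conditions with different response power. TRFs are estimated on broadband
(unfiltered) data. Peaks are located on the channel-averaged kernel:
P1 = maximum in 20–70 ms, N1 = minimum in 60–120 ms, P2 = maximum in
120–250 ms (windows config-exposed).

## Statistics

* **Psychometric fit.** score(SNR) = guess + (1 − guess − lapse) /
  (1 + exp(−(SNR − α)/β)); α is the speech reception threshold (SRT, dB
  SNR), β the spread (dB). The reported slope is the derivative at the
  midpoint, 100·(1 − guess − lapse)/(4β) %/dB. Behavioral word scores are
  fitted by binomial maximum likelihood with guess = lapse = 0; neural
  tracking-vs-SNR data are fitted by least squares with both rates free,
  so the asymptotes absorb the correlation floor and ceiling.
  Non-convergence is reported through `fit_ok`, never silently.
* **SNR binning**: 1-D k-means (k = 7 by default, capped at the number of
  distinct SNRs), deterministic under seed, centers sorted.
* **Dependent correlations**: Hittner's back-transformed-average Fisher-z
  test for two overlapping dependent correlations (the two conditions'
  SNR–tracking correlations share the SNR variable).
* **Per-SNR condition contrast**: paired sign-flip permutation test on the
  mean paired difference (t-statistic selectable), exact enumeration when
  2^n_subjects fits in the permutation budget, Holm–Bonferroni across
  bins.
* **Spread comparison**: Brown–Forsythe (Levene with median centering).
* **TRF topography contrast**: cluster-based permutation test over
  channels × lags. Paired t-values are thresholded at the two-sided
  t-quantile (cluster alpha 0.05); supra-threshold same-sign cells are
  clustered under channel adjacency (template BioSemi-64 montage,
  4 cm distance threshold) and lag contiguity; cluster mass is the summed
  t; the null is the distribution of the maximum |mass| over random
  subject sign flips; p = (1 + #{null ≥ mass}) / (1 + n_perm). An empty
  adjacency degenerates to per-channel clustering along lags.

Permutation procedures are deterministic under their seed. Exact
enumeration is invariant to subject ordering; Monte-Carlo permutation
p-values are exchangeable but not bit-identical under reordering.

## Synthetic study generator

Real envelope-tracking recordings cannot be shared, so the generator
emulates their structure with known ground truth:

* **Timeline**: concatenated Matrix lists — 2 s sentences, uniform random
  0.8–1.2 s gaps; the standard two-list trial has exactly 80 s of speech
  in ≈ 120 s.
* **Envelope**: inside sentences, a DC pedestal (1.0) plus sinusoidal
  modulators at 2.5 and 4.1 Hz (depth 0.45 each, random phases) plus
  band-limited 0.3–30 Hz Gaussian modulation (depth 0.8), rectified at
  zero; exactly zero in gaps. The stochastic component reproduces the
  broadband irregularity of real speech envelopes; without it the
  envelope's quasi-periodic autocorrelation, combined with the heavy ridge
  rule above, visibly biases estimated TRF peak latencies.
* **Response kernels**: per-channel sums of Gaussian bumps (σ = 12 ms) —
  P1 at 50 ms (+, central topography), N1 at 80 ms (−, frontocentral),
  P2 at 160 ms (+, right-frontal-weighted topography). The movie-condition
  kernel is identical except P2 is scaled ×0.4, so the attention−movie
  difference is a late, right-frontal effect. The default reference kernel
  amplitude is 10 µV per unit envelope; the study generator uses 1.5 µV
  (see below).
* **EEG**: gain · (kernel ⊛ envelope) + 1/f Gaussian noise (20 µV RMS,
  channel-independent) + blinks (300 ms raised cosines, 150 µV,
  frontal topography, 10/min) + optional single-sample ±800 µV glitches
  (0/min by default; the glitch-heavy "Tetris-like" condition is obtained
  by raising the rate).
* **Tracking gain**: logistic in SNR with spread 2 dB and per-condition
  midpoints −9.15 dB (attention) and −6.96 dB (movie), so the conditions
  separate at low SNR and converge toward gain 1 in quiet. Quiet trials
  (SNR = None) have gain 1.
* **Study layout**: per subject, one quiet story trial (≈ 300 s, attention
  kernel) for decoder training plus, per condition × SNR, the configured
  number of Matrix presentations (3 by default, as in a constant-stimuli
  design). The same stimulus is reused across repetitions and conditions
  of a given SNR, as it would be in a real constant-stimuli session; EEG
  noise and artifacts are fresh per trial. Studies are generated lazily
  (subject by subject) so arbitrarily large configurations analyze in
  bounded memory; identical seeds give bit-identical data.
* **Behavior**: binomial word scores from the logistic psychometric
  function.

Calibration of the defaults: the study kernel amplitude (1.5 µV against
20 µV noise) puts the quiet-condition tracking correlation near 0.5 and
the lowest-SNR correlations near the noise floor. This was chosen once so
that (a) the tracking-vs-SNR curve stays in its quasi-linear regime, where
the logistic midpoint of the injected gain is recoverable from the
psychometric fit on correlations (at high ceilings the concave
correlation-vs-gain saturation biases the fitted SRT downward by > 1 dB),
and (b) condition contrasts at low SNR remain detectable with desk-scale
subject counts. These correlation levels are higher than typical real
recordings; the generator trades absolute fidelity for testability.

One emergent property worth noting: because the movie kernel carries less
total response power (attenuated P2), its reconstruction correlation is
slightly lower even in quiet, where both conditions have gain 1. The
attention−movie difference at high SNR is therefore small but not exactly
zero — consistent with attention effects being detectable in quiet with
long integration windows.

## What the generator does not emulate

Spatially correlated background EEG, subject-specific head geometry and
kernel variability, non-stationary attention drift within trials, real
Matrix-sentence acoustics (no speech synthesis), eye movements other than
blinks, and motor artifacts beyond point glitches. Passing tests therefore
demonstrate correctness of the estimation machinery and recoverability of
injected effects under realistic noise types — not performance on any real
recording.

## Problem sizes used by the test suite

The suite runs the full pipeline on a deliberately desk-scale study:
8 subjects, SNRs {−12.5, −9.5, −6.5, −3.5, +2.5} dB plus quiet, two
presentations per stimulus, 240 s training stories, 100 bootstrap
replicates, 1000 permutations. Statistical calibration checks use 1000
pure-noise replications on reduced channel × lag grids. The acceptance
script (`scripts/acceptance.py`) uses 10 minutes of synthetic EEG for TRF
recovery and 19 simulated behavioral subjects for the psychometric
recovery, each regenerated from scratch from the command-line seed.

## Numerical choices and degenerate inputs

* Ridge solves use Cholesky (`assume_a="pos"`); λ = 0 on a singular Gram
  matrix raises rather than silently pseudo-inverting.
* Lag windows are inclusive integer sample ranges inside the stated
  millisecond window (0–500 ms at 128 Hz → 65 lags; 0–75 ms → 10 lags).
* Constant signals raise on correlation; zero-variance columns are left
  unscaled by the z-scorer.
* k-means binning refuses k larger than the number of distinct values;
  Brown–Forsythe returns (0, 1) when every group has zero spread; the
  cluster test refuses fewer than 5 subjects (sign-flip resolution).
* Filters: band edges must lie strictly inside (0, Nyquist); blanking
  refuses a channel with no surviving samples.
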