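"""Synthetic study generator with known ground truth.

The real study presented Flemish Matrix sentences (2 s each, two 20-sentence
lists separated by random 0.8-1.2 s gaps, 80 s of speech per trial) at SNRs
from -12.5 dB up to +2.5 dB and in quiet, while 64-channel EEG was recorded
under an active-listening ("attention") condition and a silent-movie
distractor condition.  Those recordings cannot be shared, so this module
emulates their statistical structure with full control of the ground truth:

* a sentence/gap timeline with the Matrix timing,
* a non-negative envelope amplitude-modulated at the Matrix word rate
  (2.5 Hz) and syllable rate (4.1 Hz) during sentences and zero in gaps,
* condition-specific multichannel response kernels with P1 (50 ms),
  N1 (80 ms) and P2 (160 ms) peaks — the movie kernel has an attenuated P2,
  and the attention-minus-movie difference is concentrated on right-frontal
  channels,
* EEG formed as gain x (kernel * envelope) + 1/f noise + frontal blink
  artifacts + optional high-amplitude glitches, with an SNR-dependent
  tracking gain (logistic in SNR, steeper/lower midpoint for attention),
* binomial behavioral word scores from a logistic psychometric function.

Every operation is deterministic under its seed.
"""

from __future__ import annotations

import json
from collections.abc import Mapping
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from .channels import biosemi64_labels, channel_positions
from .containers import EEGRecording, EnvelopeSignal

__all__ = [
    "StimulusTimeline",
    "gen_matrix_timeline",
    "gen_envelope",
    "ReferenceKernel",
    "make_reference_kernel",
    "NoiseConfig",
    "ArtifactConfig",
    "gen_eeg",
    "gen_behavioral_scores",
    "SyntheticStudyConfig",
    "tracking_gain",
    "Trial",
    "SyntheticStudy",
    "gen_subject_trials",
    "gen_study",
    "write_study",
    "load_study",
]

#: Matrix-sentence modulation rates in Hz (word rate, syllable rate).
MOD_RATES = (2.5, 4.1)

#: Logistic midpoints (dB SNR) of the per-condition tracking gain.  The
#: attention midpoint sits below the movie midpoint, so the conditions
#: separate most at low SNR and converge in quiet.
GAIN_MIDPOINTS = {"attention": -9.15, "movie": -6.96}
GAIN_SPREAD_DB = 2.0


# ---------------------------------------------------------------------------
# Stimulus timeline and envelope
# ---------------------------------------------------------------------------

@dataclass
class StimulusTimeline:
    """Onsets and durations of the Matrix sentences within a trial."""

    sentence_onsets: np.ndarray  # seconds
    sentence_duration: float
    gap_bounds: tuple
    total_duration: float

    def __post_init__(self):
        self.sentence_onsets = np.asarray(self.sentence_onsets, dtype=float)
        if self.sentence_onsets.size and np.any(
                np.diff(self.sentence_onsets) <= 0):
            raise ValueError("sentence onsets must be strictly increasing")

    @property
    def n_sentences(self) -> int:
        return self.sentence_onsets.size

    @property
    def speech_time(self) -> float:
        return self.n_sentences * self.sentence_duration

    def speech_mask(self, fs: float, n_samples: int = None) -> np.ndarray:
        """Boolean mask, True while a sentence is playing."""
        if n_samples is None:
            n_samples = int(round(self.total_duration * fs))
        t = np.arange(n_samples) / fs
        mask = np.zeros(n_samples, dtype=bool)
        for onset in self.sentence_onsets:
            mask |= (t >= onset) & (t < onset + self.sentence_duration)
        return mask


def gen_matrix_timeline(n_lists: int = 2, sentences_per_list: int = 20,
                        gap_bounds: tuple = (0.8, 1.2),
                        sentence_duration: float = 2.0,
                        seed: int = 0) -> StimulusTimeline:
    """Concatenated Matrix lists: 2 s sentences with uniform random gaps.

    The default (two 20-sentence lists, gaps uniform on [0.8, 1.2] s) gives
    80 s of speech and roughly 120 s total.
    """
    if n_lists < 1 or sentences_per_list < 1:
        raise ValueError("counts must be >= 1")
    lo, hi = gap_bounds
    if lo > hi or lo < 0:
        raise ValueError("require 0 <= gap_min <= gap_max")
    n = n_lists * sentences_per_list
    rng = np.random.default_rng(seed)
    gaps = rng.uniform(lo, hi, size=n - 1)
    onsets = np.concatenate([[0.0],
                             np.cumsum(sentence_duration + gaps)])
    total = onsets[-1] + sentence_duration
    return StimulusTimeline(sentence_onsets=onsets,
                            sentence_duration=sentence_duration,
                            gap_bounds=(lo, hi), total_duration=total)


def gen_envelope(timeline: StimulusTimeline, fs: float = 128.0,
                 mod_rates: tuple = MOD_RATES, seed: int = 0,
                 pedestal: float = 1.0, mod_depth: float = 0.45,
                 noise_depth: float = 0.8) -> EnvelopeSignal:
    """Synthetic speech envelope for a timeline.

    During sentences the envelope is a DC pedestal plus sinusoidal
    modulators at the word and syllable rates (random phases per trial)
    plus a band-limited (0.3-30 Hz) stochastic modulation that mimics the
    broadband irregularity of real speech envelopes; it is exactly zero in
    the gaps.  The result is clipped at zero (rectified), so it is
    non-negative by construction, and its periodogram has local maxima at
    the two modulation rates, which stand as spectral lines above the
    stochastic floor.
    """
    if fs < 2 * max(mod_rates):
        raise ValueError(
            f"fs={fs} Hz cannot represent modulation at {max(mod_rates)} Hz")
    n = int(round(timeline.total_duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 2 * np.pi, size=len(mod_rates))
    mod = pedestal * np.ones(n)
    for f, ph in zip(mod_rates, phases):
        mod += mod_depth * np.sin(2 * np.pi * f * t + ph)
    if noise_depth > 0:
        from scipy.signal import butter, sosfiltfilt

        hi = min(30.0, 0.45 * fs)
        sos = butter(4, [0.3 / (fs / 2), hi / (fs / 2)], btype="bandpass",
                     output="sos")
        rough = sosfiltfilt(sos, rng.standard_normal(n))
        sd = rough.std()
        if sd > 0:
            mod += noise_depth * rough / sd
    env = np.clip(mod, 0.0, None) * timeline.speech_mask(fs, n)
    return EnvelopeSignal(samples=env, fs=fs)


# ---------------------------------------------------------------------------
# Reference response kernels
# ---------------------------------------------------------------------------

@dataclass
class ReferenceKernel:
    """Ground-truth multichannel response kernel (microvolts per unit
    envelope) with labeled P1/N1/P2 components."""

    kernel: np.ndarray  # (n_channels, n_lags)
    lag_ms: np.ndarray
    fs: float
    condition: str
    labels: list
    peak_spec: list  # (label, latency_ms, sign, weight map over channels)


def _scalp_map(labels, center_label, sigma_m=0.05, floor=0.0):
    """Smooth non-negative topography peaking at ``center_label``."""
    xyz = channel_positions(labels)
    center = xyz[labels.index(center_label)]
    d = np.linalg.norm(xyz - center, axis=1)
    return floor + (1 - floor) * np.exp(-d ** 2 / (2 * sigma_m ** 2))


#: (label, latency ms, signed amplitude, topography center, spatial sigma m)
_PEAKS = (
    ("P1", 50.0, 1.0, "Cz", 0.07),
    ("N1", 80.0, -1.3, "FCz", 0.07),
    ("P2", 160.0, 1.2, "F4", 0.06),
)

#: Attenuation of the P2 component in the movie condition.
MOVIE_P2_SCALE = 0.4

#: Temporal width of each peak (Gaussian sigma, ms).
PEAK_SIGMA_MS = 12.0


def make_reference_kernel(condition: str = "attention", fs: float = 128.0,
                          duration_ms: float = 300.0,
                          amplitude_uv: float = 10.0,
                          labels=None) -> ReferenceKernel:
    """Condition-specific ground-truth kernel.

    Peaks are Gaussian bumps (sigma 12 ms) at 50 ms (positive, central),
    80 ms (negative, frontocentral) and 160 ms (positive, right-frontal
    topography).  The movie kernel is identical except the P2 amplitude is
    scaled by 0.4, so the attention-minus-movie difference is a purely
    right-frontal P2-latency effect.  ``amplitude_uv`` scales the whole
    kernel (microvolts per unit envelope for the largest component).
    """
    if condition not in ("attention", "movie"):
        raise ValueError(f"unknown condition {condition!r}")
    if labels is None:
        labels = biosemi64_labels()
    n_lags = int(round(duration_ms * fs / 1000.0)) + 1
    lag_ms = np.arange(n_lags) * 1000.0 / fs
    kernel = np.zeros((len(labels), n_lags))
    peak_spec = []
    for name, latency, amp, center, sigma_m in _PEAKS:
        if condition == "movie" and name == "P2":
            amp = amp * MOVIE_P2_SCALE
        wmap = _scalp_map(labels, center, sigma_m, floor=0.15)
        bump = np.exp(-(lag_ms - latency) ** 2 / (2 * PEAK_SIGMA_MS ** 2))
        kernel += amp * amplitude_uv * wmap[:, None] * bump[None, :]
        peak_spec.append((name, latency, np.sign(amp), wmap))
    return ReferenceKernel(kernel=kernel, lag_ms=lag_ms, fs=fs,
                           condition=condition, labels=list(labels),
                           peak_spec=peak_spec)


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

@dataclass
class NoiseConfig:
    """1/f background noise: PSD proportional to f^-exponent, RMS in uV."""

    exponent: float = 1.0
    amplitude_uv: float = 20.0


@dataclass
class ArtifactConfig:
    """Ocular and glitch artifact rates and amplitudes."""

    blink_rate_per_min: float = 10.0
    blink_amplitude_uv: float = 150.0
    blink_duration_s: float = 0.3
    glitch_rate_per_min: float = 0.0
    glitch_amplitude_uv: float = 800.0


def _pink_noise(n_ch, n, exponent, rng):
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    noise = np.fft.irfft(spec * scale[None, :], n=n, axis=1)
    rms = noise.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return noise / rms


def gen_eeg(envelope: EnvelopeSignal, kernel: ReferenceKernel,
            gain: float = 1.0, noise_cfg: NoiseConfig = None,
            artifact_cfg: ArtifactConfig = None, fs: float = None,
            seed: int = 0) -> EEGRecording:
    """Synthesize EEG as ``gain * (kernel * envelope) + noise + artifacts``.

    The neural part is the causal convolution of the (mean-removed)
    envelope with each channel's kernel, scaled by ``gain`` in [0, 1].
    Background noise is channel-independent 1/f noise; blinks are 300 ms
    raised-cosine deflections with a frontal topography; glitches are
    single-sample spikes exceeding the usual 500 uV blanking threshold.
    """
    if not 0 <= gain <= 1:
        raise ValueError("gain must lie in [0, 1]")
    fs = fs or envelope.fs
    if fs != envelope.fs or fs != kernel.fs:
        raise ValueError("envelope, kernel and output rates must match")
    if noise_cfg is None:
        noise_cfg = NoiseConfig()
    if artifact_cfg is None:
        artifact_cfg = ArtifactConfig()
    rng = np.random.default_rng(seed)
    env = envelope.samples - envelope.samples.mean()
    n = env.size
    n_ch = kernel.kernel.shape[0]

    neural = fftconvolve(env[None, :], kernel.kernel, axes=1)[:, :n]
    data = gain * neural
    if noise_cfg.amplitude_uv > 0:
        data = data + noise_cfg.amplitude_uv * _pink_noise(
            n_ch, n, noise_cfg.exponent, rng)

    labels = kernel.labels
    duration_min = n / fs / 60.0
    if artifact_cfg.blink_rate_per_min > 0 and artifact_cfg.blink_amplitude_uv > 0:
        n_blinks = rng.poisson(artifact_cfg.blink_rate_per_min * duration_min)
        blink_len = int(round(artifact_cfg.blink_duration_s * fs))
        shape = np.hanning(max(blink_len, 3))
        topo = _scalp_map(labels, "Fpz", sigma_m=0.04)
        for _ in range(n_blinks):
            start = rng.integers(0, max(n - blink_len, 1))
            amp = artifact_cfg.blink_amplitude_uv * rng.uniform(0.7, 1.3)
            seg = slice(start, min(start + blink_len, n))
            data[:, seg] += amp * topo[:, None] * shape[:seg.stop - seg.start]
    if artifact_cfg.glitch_rate_per_min > 0:
        n_glitch = rng.poisson(artifact_cfg.glitch_rate_per_min * duration_min)
        for _ in range(n_glitch):
            ch = rng.integers(0, n_ch)
            pos = rng.integers(0, n)
            data[ch, pos] += rng.choice([-1, 1]) * artifact_cfg.glitch_amplitude_uv
    return EEGRecording(data=data, fs=fs, labels=list(labels))


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def gen_behavioral_scores(alpha: float, beta: float, snrs, n_words: int = 40,
                          seed: int = 0):
    """Binomial word scores from the logistic psychometric function.

    At each SNR, the number of correctly repeated words out of ``n_words``
    is drawn binomially with success probability
    ``1 / (1 + exp(-(snr - alpha) / beta))``.

    Returns a pandas DataFrame with columns snr, n_words, n_correct, score.
    """
    import pandas as pd

    if beta <= 0:
        raise ValueError("beta must be positive")
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    snrs = np.asarray(snrs, dtype=float)
    rng = np.random.default_rng(seed)
    p = 1.0 / (1.0 + np.exp(-(snrs - alpha) / beta))
    correct = rng.binomial(n_words, p)
    return pd.DataFrame({"snr": snrs, "n_words": n_words,
                         "n_correct": correct,
                         "score": correct / n_words})


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

def tracking_gain(snr, condition: str = "attention",
                  midpoints: dict = None, spread_db: float = GAIN_SPREAD_DB
                  ) -> float:
    """Logistic SNR -> [0, 1] tracking gain; ``snr=None`` means quiet
    (gain 1)."""
    if snr is None:
        return 1.0
    if midpoints is None:
        midpoints = GAIN_MIDPOINTS
    mid = midpoints[condition]
    return float(1.0 / (1.0 + np.exp(-(snr - mid) / spread_db)))


@dataclass
class SyntheticStudyConfig:
    """Study-level generation parameters.

    ``snr_grid`` entries are dB SNR values; ``None`` denotes the
    speech-in-quiet trial (tracking gain 1).  Each subject additionally
    receives one long "story" trial in quiet, generated with the attention
    kernel, which the pipeline uses for decoder training.
    """

    n_subjects: int = 10
    snr_grid: tuple = (-12.5, -9.5, -6.5, -3.5, -0.5, 2.5, None)
    conditions: tuple = ("attention", "movie")
    repetitions: int = 3
    fs: float = 256.0
    trial_lists: int = 2
    sentences_per_list: int = 20
    include_story: bool = True
    story_duration_s: float = 300.0
    gain_midpoints: dict = field(default_factory=lambda: dict(GAIN_MIDPOINTS))
    gain_spread_db: float = GAIN_SPREAD_DB
    kernel_amplitude_uv: float = 1.5
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)
    seed: int = 0

    def __post_init__(self):
        if not self.snr_grid:
            raise ValueError("snr_grid must be non-empty")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise.amplitude_uv < 0 or \
                self.artifacts.blink_amplitude_uv < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass(eq=False)
class Trial:
    """One synthetic recording with its metadata and ground truth."""

    subject: str
    condition: str
    snr: float | None  # None = quiet
    repetition: int
    role: str  # "train" (story) or "test" (Matrix)
    eeg: EEGRecording
    envelope: EnvelopeSignal
    gain: float


def _story_timeline(duration_s, fs, rng_seed):
    # A story is emulated as wall-to-wall "sentences" with tiny gaps, giving
    # a near-continuous envelope suitable for decoder training.
    n_sent = int(np.ceil(duration_s / 2.2))
    return gen_matrix_timeline(n_lists=1, sentences_per_list=n_sent,
                               gap_bounds=(0.15, 0.25), seed=rng_seed)


def gen_subject_trials(config: SyntheticStudyConfig,
                       subject_index: int) -> list:
    """Generate all trials of one subject (deterministic in config.seed).

    The subject receives one quiet story trial (role "train", attention
    kernel) and, per condition and SNR, ``repetitions`` Matrix trials whose
    neural gain is the condition's logistic tracking gain at that SNR.  As
    in the real design, the same stimulus (timeline and envelope) is used
    for every presentation of a given SNR — across repetitions and across
    conditions — while the EEG noise and artifacts are fresh per trial.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise IndexError("subject index out of range")
    kernels = {c: make_reference_kernel(c, fs=config.fs,
                                        amplitude_uv=config.kernel_amplitude_uv)
               for c in config.conditions}
    train_kernel = kernels.get("attention") or make_reference_kernel(
        "attention", fs=config.fs, amplitude_uv=config.kernel_amplitude_uv)
    subj_ss = np.random.SeedSequence(config.seed).spawn(
        config.n_subjects)[subject_index]
    n_noise = len(config.conditions) * len(config.snr_grid) * config.repetitions
    seeds = subj_ss.generate_state(2 + len(config.snr_grid) + n_noise) % (2 ** 31)
    stim_seeds = seeds[2:2 + len(config.snr_grid)]
    noise_seeds = seeds[2 + len(config.snr_grid):]

    subject = f"sub-{subject_index + 1:02d}"
    trials = []
    if config.include_story:
        tl = _story_timeline(config.story_duration_s, config.fs, int(seeds[0]))
        env = gen_envelope(tl, fs=config.fs, seed=int(seeds[0]))
        eeg = gen_eeg(env, train_kernel, gain=1.0, noise_cfg=config.noise,
                      artifact_cfg=config.artifacts, seed=int(seeds[1]))
        trials.append(Trial(subject=subject, condition="story", snr=None,
                            repetition=0, role="train", eeg=eeg,
                            envelope=env, gain=1.0))
    stimuli = {}
    for j, snr in enumerate(config.snr_grid):
        tl = gen_matrix_timeline(config.trial_lists,
                                 config.sentences_per_list,
                                 seed=int(stim_seeds[j]))
        stimuli[j] = gen_envelope(tl, fs=config.fs, seed=int(stim_seeds[j]))
    k = 0
    for cond in config.conditions:
        for j, snr in enumerate(config.snr_grid):
            for rep in range(config.repetitions):
                g = tracking_gain(snr, cond, config.gain_midpoints,
                                  config.gain_spread_db)
                env = stimuli[j]
                eeg = gen_eeg(env, kernels[cond], gain=g,
                              noise_cfg=config.noise,
                              artifact_cfg=config.artifacts,
                              seed=int(noise_seeds[k]))
                trials.append(Trial(subject=subject, condition=cond,
                                    snr=snr, repetition=rep, role="test",
                                    eeg=eeg, envelope=env, gain=g))
                k += 1
    return trials


class SyntheticStudy(Mapping):
    """Lazy subject -> trials mapping.

    Trials are generated on access (and not cached), so arbitrarily large
    studies can be analyzed subject-by-subject in bounded memory; identical
    seeds give bit-identical trials on every access.
    """

    def __init__(self, config: SyntheticStudyConfig):
        self.config = config
        self._names = [f"sub-{i + 1:02d}" for i in range(config.n_subjects)]

    def __getitem__(self, subject):
        try:
            idx = self._names.index(subject)
        except ValueError:
            raise KeyError(subject) from None
        return gen_subject_trials(self.config, idx)

    def __iter__(self):
        return iter(self._names)

    def __len__(self):
        return len(self._names)


def gen_study(config: SyntheticStudyConfig) -> SyntheticStudy:
    """Generate the full synthetic study as a lazy subject mapping."""
    return SyntheticStudy(config)


# ---------------------------------------------------------------------------
# On-disk interchange format
# ---------------------------------------------------------------------------

def write_study(study: dict, root, config: SyntheticStudyConfig = None):
    """Write a study as one directory per subject.

    Each trial becomes ``<name>.npz`` (EEG in uV, envelope, rates, labels)
    plus a ``<name>.json`` metadata sidecar; the study config, if given, is
    stored as ``config.json`` at the root.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    if config is not None:
        cfg = asdict(config)
        with open(root / "config.json", "w") as fh:
            json.dump(cfg, fh, indent=1, default=str)
    for subject, trials in study.items():
        sdir = root / subject
        sdir.mkdir(exist_ok=True)
        for i, tr in enumerate(trials):
            name = f"trial-{i:03d}"
            np.savez(sdir / f"{name}.npz", eeg=tr.eeg.data,
                     envelope=tr.envelope.samples)
            meta = {"subject": tr.subject, "condition": tr.condition,
                    "snr": tr.snr, "repetition": tr.repetition,
                    "role": tr.role, "fs": tr.eeg.fs,
                    "labels": tr.eeg.labels, "gain": tr.gain}
            with open(sdir / f"{name}.json", "w") as fh:
                json.dump(meta, fh)


def load_study(root) -> dict:
    """Load a study written by :func:`write_study`."""
    root = Path(root)
    study = {}
    for sdir in sorted(p for p in root.iterdir() if p.is_dir()):
        trials = []
        for meta_path in sorted(sdir.glob("trial-*.json")):
            with open(meta_path) as fh:
                meta = json.load(fh)
            arrs = np.load(meta_path.with_suffix(".npz"))
            eeg = EEGRecording(data=arrs["eeg"], fs=meta["fs"],
                               labels=meta["labels"])
            env = EnvelopeSignal(samples=arrs["envelope"], fs=meta["fs"])
            trials.append(Trial(subject=meta["subject"],
                                condition=meta["condition"], snr=meta["snr"],
                                repetition=meta["repetition"],
                                role=meta["role"], eeg=eeg, envelope=env,
                                gain=meta["gain"]))
        if trials:
            study[sdir.name] = trials
    return study
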