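"""Speech envelope extraction with a gammatone filterbank and a power law.

The auditory-inspired envelope is obtained by passing the audio through a
bank of 4th-order gammatone filters with center frequencies spaced by one
equivalent rectangular bandwidth (ERB) between 50 and 5000 Hz, compressing
each subband sample-wise with ``|x| ** 0.6``, and averaging the subband
envelopes into a single channel.  The power-law exponent approximates the
compressive growth of loudness in the healthy cochlea.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .containers import EnvelopeSignal

__all__ = [
    "FilterbankSpec",
    "erb_space",
    "erb_rate",
    "inverse_erb_rate",
    "gammatone_filterbank",
    "extract_envelope",
    "read_wav",
]

# Glasberg & Moore (1990) ERB-rate constants.
_ERB_A = 21.4
_ERB_B = 0.00437


def erb_rate(f):
    """ERB-rate (ERB-number) of frequency ``f`` in Hz."""
    return _ERB_A * np.log10(_ERB_B * np.asarray(f, dtype=float) + 1.0)


def inverse_erb_rate(e):
    """Frequency in Hz at ERB-rate ``e``."""
    return (10.0 ** (np.asarray(e, dtype=float) / _ERB_A) - 1.0) / _ERB_B


@dataclass
class FilterbankSpec:
    """ERB-spaced gammatone filterbank design."""

    f_min: float = 50.0
    f_max: float = 5000.0
    spacing: float = 1.0
    center_freqs: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.center_freqs is None:
            self.center_freqs = _erb_centers(self.f_min, self.f_max, self.spacing)
        self.center_freqs = np.asarray(self.center_freqs, dtype=float)

    @property
    def n_channels(self) -> int:
        return self.center_freqs.size


def _erb_centers(f_min, f_max, spacing):
    if f_min <= 0 or f_max <= 0:
        raise ValueError("frequencies must be positive")
    if f_min > f_max:
        raise ValueError("f_min must not exceed f_max")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    e_lo, e_hi = erb_rate(f_min), erb_rate(f_max)
    # Successive `spacing`-ERB steps starting at f_min, never above f_max.
    n = int(np.floor((e_hi - e_lo) / spacing + 1e-9)) + 1
    return inverse_erb_rate(e_lo + spacing * np.arange(n))


def erb_space(f_min: float = 50.0, f_max: float = 5000.0,
              spacing: float = 1.0) -> FilterbankSpec:
    """Design an ERB-spaced filterbank between ``f_min`` and ``f_max``.

    Center frequencies are placed at successive ``spacing``-ERB steps on the
    Glasberg-Moore ERB-rate scale, starting at ``f_min`` and not exceeding
    ``f_max``.  The default design (50-5000 Hz, 1 ERB) has 28 channels.
    """
    return FilterbankSpec(f_min=f_min, f_max=f_max, spacing=spacing,
                          center_freqs=_erb_centers(f_min, f_max, spacing))


def gammatone_filterbank(audio, fs, spec: FilterbankSpec = None) -> np.ndarray:
    """Filter ``audio`` through the gammatone bank; returns (n_bands, n)."""
    if spec is None:
        spec = erb_space()
    if fs <= 2 * spec.f_max:
        raise ValueError(
            f"sampling rate {fs} Hz too low for f_max={spec.f_max} Hz"
        )
    audio = np.asarray(audio, dtype=float).ravel()
    if not np.all(np.isfinite(audio)):
        raise ValueError("audio contains non-finite samples")
    out = np.empty((spec.n_channels, audio.size))
    for i, cf in enumerate(spec.center_freqs):
        b, a = sps.gammatone(cf, "iir", fs=fs)
        # second-order sections: numerically stable at low center frequencies
        out[i] = sps.sosfilt(sps.tf2sos(b, a), audio)
    return out


def extract_envelope(audio, fs, spec: FilterbankSpec = None,
                     exponent: float = 0.6) -> EnvelopeSignal:
    """Extract the single-channel speech envelope.

    Each gammatone subband is compressed sample-wise (absolute value raised
    to ``exponent``) and the subband envelopes are averaged with equal
    weights.  Output has the same length and rate as the input.
    """
    subbands = gammatone_filterbank(audio, fs, spec)
    env = np.mean(np.abs(subbands) ** exponent, axis=0)
    return EnvelopeSignal(samples=env, fs=fs)


def read_wav(path):
    """Read a WAV file; returns (samples as float in [-1, 1], fs)."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(fs)
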