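"""EEG and envelope conditioning.

The cleaning chain applied before decoding is: glitch blanking with linear
interpolation, ocular-artifact suppression with a multichannel Wiener
filter (MWF), average re-referencing, zero-phase Chebyshev type-II
band-pass filtering (delta 0.5-4 Hz or theta 4-8 Hz), and polyphase
resampling.  The identical band-pass code path serves both the EEG and the
envelope so the two signals see the same phase and magnitude response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import linalg as sla
from scipy import signal as sps

from .channels import FRONTAL_OCULAR
from .containers import EEGRecording, EnvelopeSignal

__all__ = [
    "ArtifactMask",
    "blank_and_interpolate",
    "mwf_denoise",
    "rereference_average",
    "bandpass",
    "resample",
    "BANDS",
]

#: Analysis bands (Hz).  Delta spans the Matrix-sentence word rate (2.5 Hz);
#: theta spans the syllable rate (4.1 Hz).
BANDS = {"delta": (0.5, 4.0), "theta": (4.0, 8.0)}


@dataclass
class ArtifactMask:
    """Boolean per-sample artifact mask."""

    mask: np.ndarray
    source: str = "ocular"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_flagged(self) -> int:
        return int(self.mask.sum())


def blank_and_interpolate(eeg: EEGRecording,
                          threshold: float = 500.0) -> EEGRecording:
    """Blank samples exceeding ``threshold`` microvolts (absolute value) and
    linearly interpolate across them, per channel.

    Samples within threshold are left bit-identical.  Supra-threshold runs
    at the recording edges are held at the nearest surviving value.  A
    channel with no surviving sample raises ``ValueError``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = eeg.copy()
    data = out.data
    for ch in range(data.shape[0]):
        bad = np.abs(data[ch]) > threshold
        if not bad.any():
            continue
        good = ~bad
        if not good.any():
            name = eeg.labels[ch] if eeg.labels else str(ch)
            raise ValueError(f"channel {name} entirely above {threshold} uV")
        idx = np.arange(data.shape[1])
        data[ch, bad] = np.interp(idx[bad], idx[good], data[ch, good])
    return out


def _delay_stack(data: np.ndarray, span: int) -> np.ndarray:
    """Stack delayed copies of each channel: (C*(2*span+1), T), zero padded."""
    n_ch, n = data.shape
    delays = range(-span, span + 1)
    out = np.zeros((n_ch * len(delays), n))
    for k, d in enumerate(delays):
        block = out[k * n_ch:(k + 1) * n_ch]
        if d == 0:
            block[:] = data
        elif d > 0:
            block[:, d:] = data[:, :-d]
        else:
            block[:, :d] = data[:, -d:]
    return out


def _sustained_events(mask: np.ndarray, merge_gap: int, min_len: int,
                      core_len: int) -> np.ndarray:
    """Consolidate flagged samples into artifact events.

    Runs separated by <= merge_gap samples are merged; a merged run
    qualifies as an event only if it spans >= min_len samples AND contains
    an unbroken flagged run >= core_len samples.  Isolated chance
    threshold crossings (ubiquitous in Gaussian noise) satisfy neither.
    """
    closed = np.convolve(mask.astype(float), np.ones(2 * merge_gap + 1),
                         mode="same") > 0
    out = np.zeros_like(mask)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], closed.view(np.int8),
                                                   [0]])))
    for start, stop in edges.reshape(-1, 2):
        lo = max(start + merge_gap, 0)
        hi = min(stop - merge_gap, mask.size)
        if hi - lo < min_len:
            continue
        seg = mask[lo:hi].astype(np.int8)
        seg_edges = np.flatnonzero(np.diff(np.concatenate([[0], seg, [0]])))
        longest = max((b - a for a, b in seg_edges.reshape(-1, 2)),
                      default=0)
        if longest >= core_len:
            out[lo:hi] = True
    return out


def mwf_denoise(eeg: EEGRecording, frontal_labels=FRONTAL_OCULAR,
                power_factor: float = 5.0, delay_span: int = 3,
                max_cov_samples: int = 20000, margin_s: float = 0.1,
                min_event_s: float = 0.05,
                ) -> tuple[EEGRecording, ArtifactMask]:
    """Suppress ocular artifacts with a spatio-temporal multichannel
    Wiener filter.

    Artifact samples are detected on the frontal channels: any sample whose
    instantaneous power on one of ``frontal_labels`` exceeds
    ``power_factor`` times that channel's time-averaged power is flagged.
    Covariance matrices of the delay-stacked data (delays ``-delay_span`` to
    ``+delay_span``) are estimated separately over artifact and clean
    samples; the filter follows from their generalized eigendecomposition,
    keeping only components whose artifact-to-clean power ratio exceeds one.

    Ocular artifacts are episodic, so flagged samples are consolidated into
    sustained events (gaps up to 10 ms merged, events shorter than
    ``min_event_s`` discarded as chance threshold crossings) and the
    artifact estimate is subtracted inside those event windows (dilated by
    ``margin_s`` to cover blink flanks, with raised-cosine ramps to avoid
    discontinuities) rather than over the whole recording; outside the
    windows the data pass through untouched.

    With no flagged samples or no sustained events the input is returned
    unchanged (with a warning), since there is nothing to estimate the
    artifact subspace from.
    """
    data = eeg.data
    if eeg.labels:
        rows = [eeg.channel_index(lbl) for lbl in frontal_labels
                if lbl in eeg.labels]
        if not rows:
            raise ValueError("none of the frontal labels found in recording")
    else:
        rows = list(range(min(len(frontal_labels), data.shape[0])))
    frontal = data[rows]
    power = frontal ** 2
    mask = np.any(power > power_factor * power.mean(axis=1, keepdims=True),
                  axis=0)
    if not mask.any() or mask.all():
        if mask.all():
            warnings.warn("every sample flagged as artifact; MWF skipped")
        else:
            warnings.warn("no artifact samples found; MWF skipped")
        return eeg.copy(), ArtifactMask(np.zeros(data.shape[1], bool))

    events = _sustained_events(mask,
                               merge_gap=max(int(round(0.01 * eeg.fs)), 1),
                               min_len=max(int(round(min_event_s * eeg.fs)),
                                           1),
                               core_len=max(int(round(0.5 * min_event_s
                                                      * eeg.fs)), 1))
    if not events.any():
        warnings.warn("no sustained artifact events; MWF skipped")
        return eeg.copy(), ArtifactMask(mask, source="ocular")
    margin = max(int(round(margin_s * eeg.fs)), 1)
    dilated = np.convolve(events.astype(float), np.ones(2 * margin + 1),
                          mode="same") > 0
    if (~dilated).mean() < 0.2:
        # dense events: dilation would swallow the clean segments
        margin = 1
        dilated = np.convolve(events.astype(float), np.ones(3),
                              mode="same") > 0
    stacked = _delay_stack(data, delay_span)

    def _cov(cols):
        # subsample columns for the covariance estimate only
        if cols.size > max_cov_samples:
            cols = cols[:: int(np.ceil(cols.size / max_cov_samples))]
        x = stacked[:, cols]
        x = x - x.mean(axis=1, keepdims=True)
        return (x @ x.T) / max(cols.size - 1, 1)

    ryy = _cov(np.flatnonzero(dilated))
    rvv = _cov(np.flatnonzero(~dilated))
    # Regularize the clean covariance slightly for numerical stability.
    rvv = rvv + 1e-9 * np.trace(rvv) / rvv.shape[0] * np.eye(rvv.shape[0])
    lam, vecs = sla.eigh(ryy, rvv)  # ryy V = rvv V diag(lam), V^T rvv V = I
    gain = np.where(lam > 1.0, 1.0 - 1.0 / np.maximum(lam, 1.0), 0.0)
    # MMSE artifact estimate d = V^{-T} diag(gain) V^T y; only the central
    # (zero-delay) block of rows is needed for the output channels.
    n_ch = data.shape[0]
    center = delay_span * n_ch
    b = sla.solve(vecs.T, np.diag(gain))
    m = b[center:center + n_ch] @ vecs.T
    ramp = np.hanning(2 * margin + 1)
    gate = np.clip(np.convolve(dilated.astype(float), ramp / ramp.sum(),
                               mode="same") * (2 * margin + 1), 0.0, 1.0)
    cleaned = data - gate[None, :] * (m @ stacked)
    return eeg.copy(data=cleaned), ArtifactMask(mask, source="ocular")


def rereference_average(eeg: EEGRecording) -> EEGRecording:
    """Re-reference to the average of all channels (idempotent)."""
    data = eeg.data - eeg.data.mean(axis=0, keepdims=True)
    return eeg.copy(data=data, reference="average")


def _design_bandpass(band, fs, attenuation_db=40.0, ripple_db=1.0,
                     edge_factor=0.1):
    low, high = band
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band {band} outside (0, {nyq}) Hz")
    wp = [low / nyq, high / nyq]
    ws = [low * (1 - edge_factor) / nyq, high * (1 + edge_factor) / nyq]
    order, wn = sps.cheb2ord(wp, ws, gpass=ripple_db, gstop=attenuation_db)
    return sps.cheby2(order, attenuation_db, wn, btype="bandpass",
                      output="sos")


def bandpass(signal, band, fs=None, attenuation_db: float = 40.0):
    """Zero-phase Chebyshev type-II band-pass filter.

    ``band`` is a (low, high) pair in Hz or a named band from :data:`BANDS`.
    Stopband edges sit 10% outside the passband.  ``attenuation_db`` is the
    single-pass design target; the forward-backward (zero-phase)
    application squares the magnitude response, doubling the stopband
    attenuation in dB.  Accepts an :class:`EEGRecording`,
    :class:`EnvelopeSignal`, or bare array (then ``fs`` is required) and
    returns the same type — one code path for EEG and envelope.
    """
    if isinstance(band, str):
        band = BANDS[band]

    def _filt(x, rate):
        sos = _design_bandpass(band, rate, attenuation_db)
        n = x.shape[-1]
        # generous padding: the low cutoff implies seconds-long transients
        padlen = int(min(n - 2, max(3 * (sos.shape[0] + 1),
                                    np.ceil(10 * rate / band[0]))))
        return sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen)

    if isinstance(signal, EEGRecording):
        return signal.copy(data=_filt(signal.data, signal.fs))
    if isinstance(signal, EnvelopeSignal):
        return signal.copy(samples=_filt(signal.samples, signal.fs),
                           band=tuple(band))
    if fs is None:
        raise ValueError("fs is required for bare arrays")
    return _filt(np.asarray(signal, dtype=float), fs)


def resample(signal, fs_out, fs_in=None):
    """Anti-aliased polyphase resampling to ``fs_out`` Hz."""
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")

    def _do(x, fs):
        if fs == fs_out:
            return np.asarray(x, dtype=float)
        frac = Fraction(fs_out / fs).limit_denominator(10000)
        return sps.resample_poly(np.asarray(x, dtype=float), frac.numerator,
                                 frac.denominator, axis=-1, padtype="line")

    if isinstance(signal, EEGRecording):
        return signal.copy(data=_do(signal.data, signal.fs), fs=float(fs_out))
    if isinstance(signal, EnvelopeSignal):
        return signal.copy(samples=_do(signal.samples, signal.fs),
                           fs=float(fs_out))
    if fs_in is None:
        raise ValueError("fs_in is required for bare arrays")
    return _do(signal, fs_in)
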