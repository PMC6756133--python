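"""Backward decoding and forward TRF estimation with ridge regression.

The backward model reconstructs the speech envelope ``s(t)`` as a linear
combination of all EEG channels over a window of post-stimulus lags,

    s_hat(t) = sum_n sum_tau g(n, tau) R(t + tau, n),

where ``R`` holds the lagged neural responses.  The decoder ``g`` solves
the ridge-regularized normal equations ``(R R^T + lambda I)^{-1} R S^T``
with the regularization parameter chosen as the maximal absolute entry of
the autocorrelation matrix ``R R^T``.  The forward model (temporal response
function, TRF) uses the same machinery in the opposite direction — lagged
copies of the envelope predict each EEG channel — and its per-channel
kernels exhibit the P1/N1/P2 morphology familiar from late auditory evoked
potentials.

EEG channels and the envelope are z-scored before either fit, which makes
the ``lambda = max |R R^T|`` rule scale-free; both the normalization and
the lambda rule can be overridden.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import stats as sstats

from .containers import EEGRecording, EnvelopeSignal

__all__ = [
    "LagSpec",
    "LAGS_EARLY",
    "LAGS_FULL",
    "lag_matrix",
    "BackwardDecoder",
    "train_backward",
    "reconstruct",
    "TrackingScore",
    "bootstrap_spearman",
    "ForwardTRF",
    "train_forward",
    "trf_peaks",
    "PEAK_WINDOWS",
]

#: Default peak search windows in ms (label -> (lo, hi)).
PEAK_WINDOWS = {"P1": (20.0, 70.0), "N1": (60.0, 120.0), "P2": (120.0, 250.0)}


@dataclass(frozen=True)
class LagSpec:
    """Post-stimulus lag window in milliseconds at a given sampling rate."""

    start_ms: float
    end_ms: float
    fs: float

    def __post_init__(self):
        if not 0 <= self.start_ms < self.end_ms:
            raise ValueError("require 0 <= start_ms < end_ms")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def lags(self) -> np.ndarray:
        """Lag offsets in samples (inclusive integer range inside the window)."""
        lo = int(np.ceil(self.start_ms * self.fs / 1000.0 - 1e-9))
        hi = int(np.floor(self.end_ms * self.fs / 1000.0 + 1e-9))
        return np.arange(lo, hi + 1)

    @property
    def n_lags(self) -> int:
        return self.lags.size

    @property
    def lag_ms(self) -> np.ndarray:
        return self.lags * 1000.0 / self.fs


def LAGS_EARLY(fs):
    """0-75 ms integration window (weakly attention-dependent lags)."""
    return LagSpec(0.0, 75.0, fs)


def LAGS_FULL(fs):
    """0-500 ms integration window (includes attention-sensitive lags)."""
    return LagSpec(0.0, 500.0, fs)


def _delay_embed(x: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Columns are ``x[t + lag]`` for each lag, zero-padded at the edges."""
    n = x.size
    out = np.zeros((n, lags.size))
    for j, lag in enumerate(lags):
        if lag == 0:
            out[:, j] = x
        elif lag > 0:
            if lag < n:
                out[:-lag, j] = x[lag:]
        else:
            if -lag < n:
                out[-lag:, j] = x[:lag]
    return out


def lag_matrix(eeg: EEGRecording, lagspec: LagSpec) -> np.ndarray:
    """Design matrix of shifted neural responses, shape (T, N * n_lags).

    Column ``(n, tau)`` holds channel ``n`` advanced by ``tau`` samples: row
    ``t`` contains ``R[n, t + tau]``, so EEG at ``t + tau`` predicts the
    envelope at ``t``.  Out-of-range entries are zero-padded, keeping the
    number of rows equal to the recording length.  Columns are grouped by
    channel (all lags of channel 0 first).
    """
    if eeg.fs != lagspec.fs:
        raise ValueError("lag spec rate does not match recording rate")
    lags = lagspec.lags
    if lags[-1] >= eeg.n_samples:
        raise ValueError("lag window longer than recording")
    cols = [_delay_embed(eeg.data[ch], lags) for ch in range(eeg.n_channels)]
    return np.concatenate(cols, axis=1)


def _zscore_cols(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


@dataclass
class BackwardDecoder:
    """Envelope-reconstruction weights g(n, tau) with its ridge parameter."""

    weights: np.ndarray  # (n_channels, n_lags)
    lam: float
    lagspec: LagSpec
    band: tuple | None = None
    labels: list = field(default_factory=list)
    normalize: bool = True

    def to_json(self, path=None):
        obj = {
            "weights": self.weights.tolist(),
            "lambda": self.lam,
            "lags": {"start_ms": self.lagspec.start_ms,
                     "end_ms": self.lagspec.end_ms, "fs": self.lagspec.fs},
            "band": list(self.band) if self.band else None,
            "labels": list(self.labels),
            "normalize": self.normalize,
        }
        text = json.dumps(obj)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path):
        try:
            obj = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                obj = json.load(fh)
        spec = LagSpec(**obj["lags"])
        return cls(weights=np.asarray(obj["weights"]), lam=obj["lambda"],
                   lagspec=spec,
                   band=tuple(obj["band"]) if obj["band"] else None,
                   labels=obj["labels"], normalize=obj["normalize"])


def train_backward(eeg: EEGRecording, env: EnvelopeSignal, lagspec: LagSpec,
                   lam: float = None, normalize: bool = True,
                   band=None) -> BackwardDecoder:
    """Train the backward (envelope-reconstruction) decoder.

    Solves ``(R R^T + lambda I)^{-1} (R S^T)``; by default ``lambda`` is the
    maximal absolute value of the autocorrelation matrix ``R R^T`` computed
    on z-scored data.  Pass ``lam=0`` to disable regularization (raises on a
    singular autocorrelation matrix).
    """
    if eeg.fs != env.fs:
        raise ValueError("EEG and envelope rates differ")
    if eeg.n_samples != env.n_samples:
        raise ValueError("EEG and envelope durations differ")
    x = lag_matrix(eeg, lagspec)
    s = env.samples
    if normalize:
        x = _zscore_cols(x)
        s = _zscore_cols(s[:, None])[:, 0]
    c = x.T @ x
    if lam is None:
        lam = float(np.max(np.abs(c)))
    xs = x.T @ s
    if lam == 0:
        try:
            w = sla.solve(c, xs, assume_a="pos")
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "autocorrelation matrix singular with lambda=0")
    else:
        w = sla.solve(c + lam * np.eye(c.shape[0]), xs, assume_a="pos")
    weights = w.reshape(eeg.n_channels, lagspec.n_lags)
    return BackwardDecoder(weights=weights, lam=float(lam), lagspec=lagspec,
                           band=band, labels=list(eeg.labels),
                           normalize=normalize)


def reconstruct(decoder: BackwardDecoder, eeg: EEGRecording) -> EnvelopeSignal:
    """Apply the decoder: ``s_hat(t) = sum_n sum_tau g(n,tau) R(t+tau, n)``."""
    if eeg.n_channels != decoder.weights.shape[0]:
        raise ValueError("channel count does not match decoder")
    if eeg.fs != decoder.lagspec.fs:
        raise ValueError("recording rate does not match decoder lag spec")
    x = lag_matrix(eeg, decoder.lagspec)
    if decoder.normalize:
        x = _zscore_cols(x)
    s_hat = x @ decoder.weights.ravel()
    return EnvelopeSignal(samples=s_hat, fs=eeg.fs, band=decoder.band)


@dataclass
class TrackingScore:
    """Bootstrapped Spearman correlation between envelope and reconstruction."""

    rho_median: float
    ci_low: float
    ci_high: float
    n_boot: int

    def __post_init__(self):
        if not (-1 - 1e-12 <= self.ci_low <= self.rho_median + 1e-12
                and self.rho_median <= self.ci_high + 1e-12 <= 1 + 1e-12):
            raise ValueError("inconsistent correlation bounds")


def bootstrap_spearman(a, b, n_boot: int = 1000, seed: int = 0,
                       block_s: float = 5.0, fs: float = None
                       ) -> TrackingScore:
    """Median and 95% CI of the Spearman correlation under a moving-block
    bootstrap.

    Paired blocks of ``block_s`` seconds are resampled with replacement
    (block starts uniform over the recording), preserving the
    autocorrelation of the band-limited signals within blocks.  Inputs may
    be :class:`EnvelopeSignal` (rate taken from the signal) or bare arrays
    with ``fs`` given; without any rate, the pair is split into 20 blocks.
    """
    if isinstance(a, EnvelopeSignal):
        fs = fs or a.fs
        a = a.samples
    if isinstance(b, EnvelopeSignal):
        fs = fs or b.fs
        b = b.samples
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("inputs must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant input")
    n = a.size
    block = int(round(block_s * fs)) if fs else max(n // 20, 1)
    block = min(max(block, 1), n)
    if n < 2 * block:
        raise ValueError("need at least two blocks of data")
    n_blocks = int(np.ceil(n / block))
    rng = np.random.default_rng(seed)
    rhos = np.empty(n_boot)
    for i in range(n_boot):
        starts = rng.integers(0, n - block + 1, size=n_blocks)
        idx = (starts[:, None] + np.arange(block)[None, :]).ravel()[:n]
        rhos[i] = sstats.spearmanr(a[idx], b[idx]).statistic
    lo, med, hi = np.percentile(rhos, [2.5, 50.0, 97.5])
    return TrackingScore(rho_median=float(med), ci_low=float(lo),
                         ci_high=float(hi), n_boot=n_boot)


@dataclass
class ForwardTRF:
    """Per-channel kernel h(c, tau) mapping the envelope to EEG."""

    kernel: np.ndarray  # (n_channels, n_lags)
    lag_ms: np.ndarray
    fs: float
    lam: float = 0.0
    labels: list = field(default_factory=list)

    def channel_mean(self, channels=None) -> np.ndarray:
        if channels is None:
            return self.kernel.mean(axis=0)
        idx = [self.labels.index(c) for c in channels]
        return self.kernel[idx].mean(axis=0)

    def to_json(self, path=None):
        obj = {"kernel": self.kernel.tolist(), "lag_ms": self.lag_ms.tolist(),
               "fs": self.fs, "lambda": self.lam, "labels": list(self.labels)}
        text = json.dumps(obj)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path):
        try:
            obj = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                obj = json.load(fh)
        return cls(kernel=np.asarray(obj["kernel"]),
                   lag_ms=np.asarray(obj["lag_ms"]), fs=obj["fs"],
                   lam=obj["lambda"], labels=obj["labels"])


def train_forward(env: EnvelopeSignal, eeg: EEGRecording, lagspec: LagSpec,
                  lam: float = None, normalize: bool = True) -> ForwardTRF:
    """Estimate the forward TRF: lagged envelope copies predict each channel.

    The model is ``r_c(t) = sum_tau h(c, tau) s(t - tau)``; the same ridge
    rule as the backward decoder is applied to the envelope autocorrelation
    matrix.
    """
    if eeg.fs != env.fs or eeg.fs != lagspec.fs:
        raise ValueError("rates of envelope, EEG and lag spec must match")
    if eeg.n_samples != env.n_samples:
        raise ValueError("EEG and envelope durations differ")
    d = _delay_embed(env.samples, -lagspec.lags)  # column tau: s(t - tau)
    y = eeg.data.T
    if normalize:
        sd_d = d.std(axis=0)
        sd_d[sd_d == 0] = 1.0
        sd_y = y.std(axis=0)
        sd_y[sd_y == 0] = 1.0
        d = (d - d.mean(axis=0)) / sd_d
        y = (y - y.mean(axis=0)) / sd_y
    c = d.T @ d
    if lam is None:
        lam = float(np.max(np.abs(c)))
    rhs = d.T @ y
    w = sla.solve(c + lam * np.eye(c.shape[0]), rhs, assume_a="pos")
    kernel = w.T
    if normalize:
        # undo the scaling so the kernel is in microvolts per unit envelope
        kernel = kernel * sd_y[:, None] / sd_d[None, :]
    return ForwardTRF(kernel=kernel, lag_ms=lagspec.lag_ms, fs=eeg.fs,
                      lam=float(lam), labels=list(eeg.labels))


@dataclass
class TRFPeak:
    label: str
    latency_ms: float
    amplitude: float


def trf_peaks(trf: ForwardTRF, windows: dict = None,
              channels=None) -> list:
    """Locate P1/N1/P2 peaks on the channel-averaged kernel.

    Positive peaks (P1, P2) are the maxima, N1 the minimum, inside each
    search window.  ``channels`` restricts the average to a channel subset
    (e.g. a frontocentral cluster).
    """
    if windows is None:
        windows = PEAK_WINDOWS
    mean_kernel = trf.channel_mean(channels)
    peaks = []
    for label, (lo, hi) in windows.items():
        sel = (trf.lag_ms >= lo) & (trf.lag_ms <= hi)
        if not sel.any():
            raise ValueError(f"window {label} {lo}-{hi} ms is empty "
                             "on this lag axis")
        seg = mean_kernel[sel]
        lags = trf.lag_ms[sel]
        idx = np.argmin(seg) if label.upper().startswith("N") else np.argmax(seg)
        peaks.append(TRFPeak(label=label, latency_ms=float(lags[idx]),
                             amplitude=float(seg[idx])))
    return peaks
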