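"""Core in-memory containers shared across the pipeline.

An :class:`EEGRecording` holds a channels-by-samples matrix in microvolts
together with its sampling rate and channel labels; an
:class:`EnvelopeSignal` holds the single-channel speech envelope.  Both are
deliberately thin: all signal processing lives in the functional modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["EEGRecording", "EnvelopeSignal"]


@dataclass
class EEGRecording:
    """Multichannel EEG in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Channel names (10-20 style, e.g. the BioSemi-64 set).
    reference : {"raw", "average"}
        Referencing state of the data.
    """

    data: np.ndarray
    fs: float
    labels: list = field(default_factory=list)
    reference: str = "raw"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be 2-D (channels x samples)")
        if self.labels and len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.fs

    def copy(self, **changes) -> "EEGRecording":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        return out

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None


@dataclass
class EnvelopeSignal:
    """Single-channel speech envelope at a stated rate.

    ``band`` records the pass band (Hz) once the envelope has been
    band-pass filtered; the raw (unfiltered) envelope is non-negative.
    """

    samples: np.ndarray
    fs: float
    band: tuple | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def copy(self, **changes) -> "EnvelopeSignal":
        out = replace(self, **changes)
        if "samples" not in changes:
            out.samples = self.samples.copy()
        return out
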