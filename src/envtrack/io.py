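"""Reading EEG recordings from disk.

Two sources are supported: the package's own array container (``.npz``
with ``eeg`` in microvolts, ``fs`` and ``labels``, as written by the
synthetic study writer) and BioSemi/European data formats (``.bdf`` /
``.edf``), which are delegated to mne's readers and converted from volts
to microvolts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .containers import EEGRecording

__all__ = ["load_recording"]


def load_recording(path) -> EEGRecording:
    """Load an EEG recording from .npz, .bdf or .edf."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npz":
        arrs = np.load(path, allow_pickle=True)
        labels = [str(x) for x in arrs["labels"]] if "labels" in arrs else []
        return EEGRecording(arrs["eeg"], fs=float(arrs["fs"]), labels=labels)
    if suffix in (".bdf", ".edf"):
        import mne

        reader = mne.io.read_raw_bdf if suffix == ".bdf" \
            else mne.io.read_raw_edf
        raw = reader(path, preload=True, verbose="error")
        picks = mne.pick_types(raw.info, eeg=True)
        data = raw.get_data(picks=picks) * 1e6  # volts -> microvolts
        labels = [raw.ch_names[i] for i in picks]
        return EEGRecording(data, fs=float(raw.info["sfreq"]), labels=labels)
    raise ValueError(f"unsupported recording format: {path.suffix!r}")
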