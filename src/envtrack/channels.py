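"""BioSemi-64 channel geometry: labels, template positions, adjacency.

Positions come from the standard BioSemi-64 template montage (idealized
spherical head, no individual digitization).  The channel adjacency used by
the cluster-based permutation test is a distance-thresholded graph on those
template coordinates.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "biosemi64_labels",
    "channel_positions",
    "build_adjacency",
    "FRONTAL_OCULAR",
    "RIGHT_FRONTAL",
]

#: Channels used to detect ocular artifacts (forehead row).
FRONTAL_OCULAR = ("Fp1", "AF7", "AF3", "Fpz", "Fp2", "AF8", "AF4", "AFz")

#: Right-frontal region where attention effects on the TRF concentrate.
RIGHT_FRONTAL = ("F2", "F4", "F6", "F8", "AF4", "AF8", "FC2", "FC4", "FC6", "FT8")


@lru_cache(maxsize=None)
def _montage_positions() -> dict:
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    pos = montage.get_positions()["ch_pos"]
    return {name: np.asarray(p, dtype=float) for name, p in pos.items()}


def biosemi64_labels() -> list:
    """The 64 BioSemi channel labels in montage order."""
    return list(_montage_positions().keys())


def channel_positions(labels=None) -> np.ndarray:
    """Template 3-D positions (meters, head frame) for ``labels``."""
    pos = _montage_positions()
    if labels is None:
        labels = list(pos.keys())
    return np.array([pos[lbl] for lbl in labels])


def build_adjacency(labels=None, max_dist: float = 0.04) -> dict:
    """Neighbor graph on template coordinates.

    Two channels are adjacent when their template positions lie within
    ``max_dist`` meters (default 4 cm, giving 4-8 neighbors per channel on
    the BioSemi-64 layout).

    Returns
    -------
    dict mapping each label to the set of its neighbors (symmetric,
    irreflexive).
    """
    if labels is None:
        labels = biosemi64_labels()
    xyz = channel_positions(labels)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    adj = {}
    for i, lbl in enumerate(labels):
        near = np.flatnonzero((d[i] <= max_dist) & (np.arange(len(labels)) != i))
        adj[lbl] = {labels[j] for j in near}
    return adj


def adjacency_edge_list(adj: dict) -> list:
    """Flatten an adjacency dict to a sorted list of (a, b) edges, a < b."""
    edges = set()
    for a, nbrs in adj.items():
        for b in nbrs:
            edges.add((a, b) if a < b else (b, a))
    return sorted(edges)
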