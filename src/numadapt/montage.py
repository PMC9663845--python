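"""30-channel 10-20 montage used throughout the package.

Channel positions come from the standard 10-20 template montage shipped
with MNE-Python, projected onto the unit sphere (spherical-spline
interpolation and the synthetic topography model both work on the sphere).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: Recording montage: 30 gel electrodes in 10-20 layout.
CHANNELS_30: tuple[str, ...] = (
    "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "C3", "Cz", "C4",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "O2",
)

#: Electrode clusters used for the posterior ERP analyses.
CLUSTERS: dict[str, tuple[str, ...]] = {
    "posterior": ("P3", "P4", "P7", "P8", "PO3", "PO4", "PO7", "PO8", "O1", "O2"),
    "left": ("P3", "P7", "PO3", "PO7", "O1"),
    "right": ("P4", "P8", "PO4", "PO8", "O2"),
}

# MNE's template spells the frontopolar pair "Fp1"/"Fp2".
_MNE_ALIAS = {"FP1": "Fp1", "FP2": "Fp2"}


@lru_cache(maxsize=None)
def channel_positions(channels: tuple[str, ...] = CHANNELS_30) -> np.ndarray:
    """Unit-sphere 3D positions, shape (n_channels, 3).

    Head-size scaling is irrelevant for spline interpolation and for the
    Gaussian topography weights, so positions are normalised to radius 1.
    """
    import warnings

    import mne

    with warnings.catch_warnings():
        # montage template was renamed upstream; either name is fine here
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    out = np.empty((len(channels), 3))
    for i, name in enumerate(channels):
        p = np.asarray(pos[_MNE_ALIAS.get(name, name)], dtype=float)
        out[i] = p / np.linalg.norm(p)
    return out


def cluster_indices(cluster: str | tuple[str, ...], channel_names) -> np.ndarray:
    """Indices of a named cluster (or explicit channel tuple) in *channel_names*."""
    names = CLUSTERS[cluster] if isinstance(cluster, str) else tuple(cluster)
    lookup = {c: i for i, c in enumerate(channel_names)}
    missing = [c for c in names if c not in lookup]
    if missing:
        raise ValueError(f"channels not in montage: {missing}")
    if not names:
        raise ValueError("empty cluster")
    return np.array([lookup[c] for c in names], dtype=int)
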