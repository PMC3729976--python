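"""Idealized 64-channel EEG cap layout.

Coordinates are 2-D top-view positions on the unit head disc (nose up,
left ear at negative x), laid out row-by-row in the 10-10 naming scheme.
They are schematic — good enough to define channel adjacency, occipital
regions of interest, and smooth topographic weight maps — and are
generated here rather than shipped as a data file.
"""

from __future__ import annotations

import numpy as np

# (y coordinate, labels left -> right).  64 channels total.
_ROWS: list[tuple[float, list[str]]] = [
    (0.90, ["Fp1", "Fpz", "Fp2"]),
    (0.72, ["AF7", "AF3", "AF4", "AF8"]),
    (0.54, ["F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"]),
    (0.33, ["FT9", "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8", "FT10"]),
    (0.00, ["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"]),
    (-0.33, ["TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10"]),
    (-0.54, ["P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8"]),
    (-0.72, ["PO9", "PO7", "PO3", "POz", "PO4", "PO8", "PO10"]),
    (-0.90, ["O1", "Oz", "O2"]),
]

#: Occipital region of interest used throughout the ERP analysis.
OCCIPITAL_ROI: tuple[str, ...] = ("O1", "Oz", "O2", "PO9", "PO10", "PO7", "PO8")


def standard_layout(n_channels: int = 64) -> tuple[list[str], np.ndarray]:
    """Return ``(names, positions)`` for the idealized cap.

    positions is an ``(n_channels, 2)`` float array on the unit disc.
    For ``n_channels < 64`` the posterior-most rows are kept preferentially
    so that the occipital ROI always exists; this is used by small test
    configurations.
    """
    names: list[str] = []
    pos: list[tuple[float, float]] = []
    for y, labels in _ROWS:
        half_width = 0.95 * float(np.sqrt(max(1.0 - y * y, 0.05)))
        k = len(labels)
        if k == 1:
            xs = np.array([0.0])
        else:
            xs = np.linspace(-half_width, half_width, k)
        names.extend(labels)
        pos.extend((float(x), y) for x in xs)
    positions = np.asarray(pos, dtype=float)
    if n_channels == len(names):
        return names, positions
    if n_channels > len(names):
        raise ValueError(
            f"layout defines {len(names)} channels; {n_channels} requested"
        )
    # keep posterior rows (largest index first ordering preserved)
    order = np.argsort(positions[:, 1])  # most posterior first
    keep = np.sort(order[:n_channels])
    return [names[i] for i in keep], positions[keep]


def gaussian_topography(
    positions: np.ndarray,
    center: tuple[float, float] = (0.25, -0.75),
    sigma: float = 0.55,
) -> np.ndarray:
    """Smooth spatial weight map, default occipito-parietal with a
    right-hemisphere bias, normalized to a peak weight of 1."""
    d2 = np.sum((positions - np.asarray(center)) ** 2, axis=1)
    w = np.exp(-d2 / (2.0 * sigma**2))
    return w / w.max()
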