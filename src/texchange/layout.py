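"""Idealized 129-channel geodesic sensor layout.

A deterministic stand-in for a sponge-based geodesic net: 128 recording
electrodes placed on a spherical-cap Fibonacci lattice (near-uniform
coverage down to roughly 125 degrees of polar angle, i.e. below the ears)
plus the vertex reference Cz.  Coordinates are unit vectors in a
right-handed head frame (x right, y anterior, z up).  The layout is
synthetic: channel indices do not reproduce any vendor's numbering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "N_CHANNELS",
    "REFERENCE_NAME",
    "idealized_layout",
    "sensorimotor_sites",
    "nearest_channels",
    "write_layout_csv",
    "read_layout_csv",
]

N_CHANNELS = 129
REFERENCE_NAME = "Cz"

#: polar-angle extent of the cap (rad); ~125 deg matches a full EEG net
_CAP_THETA = 2.18

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def idealized_layout() -> tuple[list[str], np.ndarray]:
    """Return (names, positions) for the 129-channel idealized net.

    Channels "E1".."E128" on a Fibonacci cap, plus "Cz" at the vertex
    (last index).  Positions are unit vectors, shape (129, 3).
    """
    n = N_CHANNELS - 1
    i = np.arange(n)
    # cap from just below the vertex (Cz occupies the pole) to _CAP_THETA
    z_top = np.cos(0.12)
    z_bot = np.cos(_CAP_THETA)
    z = z_top - (z_top - z_bot) * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    phi = i * _GOLDEN_ANGLE
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pos = np.vstack([pos, [0.0, 0.0, 1.0]])
    names = [f"E{k + 1}" for k in range(n)] + [REFERENCE_NAME]
    return names, pos


def sensorimotor_sites() -> dict[str, np.ndarray]:
    """Canonical left/right/central sensorimotor direction vectors.

    Approximate 10-10 positions used to place simulated mu/beta rhythm
    sources: C3 (left), C4 (right), Cz-adjacent central site.
    """
    s = np.sqrt(0.5)
    return {
        "C3": np.array([-s, 0.0, s]),
        "C4": np.array([s, 0.0, s]),
        "Cz": np.array([0.0, 0.0, 1.0]),
    }


def nearest_channels(positions: np.ndarray, target: np.ndarray, k: int = 3) -> np.ndarray:
    """Indices of the ``k`` channels closest (by angle) to a unit vector."""
    t = np.asarray(target, dtype=float)
    t = t / np.linalg.norm(t)
    ang = np.arccos(np.clip(positions @ t, -1.0, 1.0))
    return np.argsort(ang)[:k]


def write_layout_csv(path, names=None, positions=None) -> None:
    """Write the layout as delimited text (name, x, y, z)."""
    if names is None or positions is None:
        names, positions = idealized_layout()
    pd.DataFrame(
        {
            "name": names,
            "x": positions[:, 0],
            "y": positions[:, 1],
            "z": positions[:, 2],
        }
    ).to_csv(path, index=False, float_format="%.9f")


def read_layout_csv(path) -> tuple[list[str], np.ndarray]:
    """Read a layout CSV written by :func:`write_layout_csv`."""
    df = pd.read_csv(path)
    pos = df[["x", "y", "z"]].to_numpy(dtype=float)
    norms = np.linalg.norm(pos, axis=1, keepdims=True)
    return df["name"].astype(str).tolist(), pos / norms
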