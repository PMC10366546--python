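"""Core data containers shared by all analysis stages.

Conventions used throughout the package:

* images are 2D ``numpy`` arrays indexed ``[row, col]``; the image origin is
  the top-left pixel, x runs rightward along columns, y downward along rows;
* all heights and in-plane lengths are in nanometres, the mica support
  defines height zero;
* angles are in degrees; the orientation of a lattice vector is measured
  from the image x-axis toward positive y.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = ["Topograph", "Lattice2D"]


@dataclass
class Topograph:
    """One AFM height map.

    Parameters
    ----------
    heights:
        2D array of heights in nm (float).
    pixel_size:
        Lateral sampling in nm per pixel (square pixels).
    timestamp:
        Acquisition time of the frame in seconds.
    """

    heights: np.ndarray
    pixel_size: float
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2D array")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.heights.shape

    @property
    def extent_nm(self) -> Tuple[float, float]:
        """(width, height) of the field of view in nm."""
        rows, cols = self.heights.shape
        return cols * self.pixel_size, rows * self.pixel_size

    def with_heights(self, heights: np.ndarray) -> "Topograph":
        return replace(self, heights=np.asarray(heights, dtype=float))


@dataclass(frozen=True)
class Lattice2D:
    """A primitive 2D (monoclinic) lattice: cell vectors a, b and angle gamma.

    ``a_len`` and ``b_len`` are the cell-vector lengths in nm, ``gamma`` the
    interaxial angle in degrees (reported obtuse when an obtuse representative
    exists), ``orientation`` the angle of vector a relative to the image
    x-axis, and ``origin`` an anchor point in nm image coordinates.
    """

    a_len: float
    b_len: float
    gamma: float
    orientation: float = 0.0
    origin: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.a_len > 0 and self.b_len > 0):
            raise ValueError("cell vector lengths must be positive")
        if not (0.0 < self.gamma < 180.0):
            raise ValueError("gamma must lie strictly between 0 and 180 degrees")

    @property
    def a_vec(self) -> np.ndarray:
        th = np.deg2rad(self.orientation)
        return self.a_len * np.array([np.cos(th), np.sin(th)])

    @property
    def b_vec(self) -> np.ndarray:
        th = np.deg2rad(self.orientation + self.gamma)
        return self.b_len * np.array([np.cos(th), np.sin(th)])

    @property
    def a_hat(self) -> np.ndarray:
        return self.a_vec / self.a_len

    @property
    def stripe_normal(self) -> np.ndarray:
        """Unit vector perpendicular to a (the stripe direction)."""
        ax, ay = self.a_hat
        return np.array([-ay, ax])

    @property
    def row_pitch(self) -> float:
        """Perpendicular distance between consecutive stripe rows, b*sin(gamma)."""
        ax, ay = self.a_hat
        bx, by = self.b_vec
        return float(abs(ax * by - ay * bx))

    def site_position(self, row: int, slot: int) -> np.ndarray:
        """Centre of dimer slot ``slot`` in stripe row ``row`` (nm).

        Slots tile the a direction at a pitch of a/3 (three dimers per cell).
        """
        return (
            np.asarray(self.origin, dtype=float)
            + (slot + 0.5) * self.a_vec / 3.0
            + row * self.b_vec
        )

    @property
    def slot_pitch(self) -> float:
        return self.a_len / 3.0
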