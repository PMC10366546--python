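"""Temporal stability of the assembly: frame averages and SD maps.

A stable crystal region shows near-zero per-pixel standard deviation over a
frame range, while regions of ongoing association/dissociation (typically
near the membrane edge) fluctuate.  No drift correction is applied (frames
are assumed registered); a flag reserves the option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .core import Topograph
from .profiles import extract_profile

__all__ = ["StabilityMaps", "stability_maps", "line_stability"]


@dataclass
class StabilityMaps:
    """Per-pixel mean and population-SD topographs over a frame range."""

    mean: Topograph
    sd: Topograph
    frame_range: Tuple[int, int]
    duration: float  # s spanned by the range


def _select(stack: Sequence[Topograph], frame_range: Optional[Tuple[int, int]]):
    if frame_range is None:
        frame_range = (0, len(stack))
    lo, hi = frame_range
    frames = list(stack[lo:hi])
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    shape = frames[0].shape
    px = frames[0].pixel_size
    if any(f.shape != shape or f.pixel_size != px for f in frames):
        raise ValueError("frames must share shape and pixel size")
    return frames, (lo, lo + len(frames))


def stability_maps(
    stack: Sequence[Topograph],
    frame_range: Optional[Tuple[int, int]] = None,
    register: bool = False,
) -> StabilityMaps:
    """Per-pixel mean and population SD over ``frame_range`` (half-open).

    ``register`` is reserved for drift correction and must stay False.
    """
    if register:
        raise NotImplementedError("drift correction is not implemented")
    frames, frame_range = _select(stack, frame_range)
    data = np.stack([f.heights for f in frames])
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=0)
    duration = frames[-1].timestamp - frames[0].timestamp
    px = frames[0].pixel_size
    return StabilityMaps(
        mean=Topograph(mean, px, frames[0].timestamp),
        sd=Topograph(sd, px, frames[0].timestamp),
        frame_range=frame_range,
        duration=float(duration),
    )


def line_stability(
    stack: Sequence[Topograph],
    p0: Sequence[float],
    p1: Sequence[float],
    width: int = 1,
    frame_range: Optional[Tuple[int, int]] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean profile and SD band along a line across a frame range.

    Returns (positions nm, mean heights, population SD).  Because profile
    extraction is linear in the heights, the mean profile equals the profile
    of the mean frame.
    """
    frames, _ = _select(stack, frame_range)
    profiles = [extract_profile(f, p0, p1, width=width) for f in frames]
    H = np.stack([p.heights for p in profiles])
    return profiles[0].positions, H.mean(axis=0), H.std(axis=0, ddof=0)
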