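"""Height profiles, protrusion detection and notched-box statistics.

A profile is sampled bilinearly along a line segment (optionally averaged
over parallel offsets).  Protrusions along a crystal stripe are local maxima
labelled cyclically 1, 2, 3, 1*, 2*, 3*, ... — three dimers per repeat unit —
and the pairwise height differences between consecutive protrusions are
summarised with notched box statistics (the notch half-width
1.57*IQR/sqrt(n) approximates a 95% confidence interval of the median).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage, signal

from .core import Topograph

__all__ = [
    "Profile",
    "ProtrusionSeries",
    "BoxStats",
    "extract_profile",
    "detect_protrusions",
    "phase_align",
    "height_difference_stats",
    "notched_box",
]

logger = logging.getLogger(__name__)

PAIRINGS = ("1-2", "2-3", "3-1*")


@dataclass
class Profile:
    """Heights sampled along a line segment; positions in nm from the start."""

    positions: np.ndarray
    heights: np.ndarray
    averaging_width: int = 1

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0])

    @property
    def length(self) -> float:
        return float(self.positions[-1] - self.positions[0])


@dataclass
class ProtrusionSeries:
    """Detected peaks along one profile with cyclic period-3 labels."""

    positions: np.ndarray  # nm
    heights: np.ndarray  # nm

    def __len__(self) -> int:
        return len(self.positions)

    def label(self, i: int) -> str:
        return f"{i % 3 + 1}" + "*" * (i // 3)


@dataclass(frozen=True)
class BoxStats:
    """Notched box-plot summary of one sample."""

    median: float
    q1: float
    q3: float
    notch: float  # half-width of the ~95% CI of the median
    min: float
    max: float
    n: int


def _sample_segment(
    topo: Topograph, p0: Sequence[float], p1: Sequence[float], width: int
) -> Tuple[np.ndarray, np.ndarray]:
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    seg = p1 - p0
    seg_len = float(np.hypot(*seg))
    if seg_len == 0:
        raise ValueError("profile endpoints coincide")
    d = seg / seg_len
    n_hat = np.array([-d[1], d[0]])
    n_samples = int(np.floor(seg_len / topo.pixel_size)) + 1
    positions = np.arange(n_samples) * topo.pixel_size
    offsets = (np.arange(width) - (width - 1) / 2.0) * topo.pixel_size

    rows, cols = topo.shape
    acc = np.zeros(n_samples)
    for off in offsets:
        pts = p0[None, :] + positions[:, None] * d[None, :] + off * n_hat[None, :]
        # nm -> pixel-centre coordinates
        px = pts / topo.pixel_size - 0.5
        if (
            px[:, 0].min() < -1e-9
            or px[:, 1].min() < -1e-9
            or px[:, 0].max() > cols - 1 + 1e-9
            or px[:, 1].max() > rows - 1 + 1e-9
        ):
            raise ValueError("profile segment (with averaging width) leaves the image")
        acc += ndimage.map_coordinates(
            topo.heights, [px[:, 1], px[:, 0]], order=1, mode="nearest"
        )
    return positions, acc / width


def extract_profile(
    topo: Topograph,
    p0: Sequence[float],
    p1: Sequence[float],
    width: int = 1,
    reference: float = 0.0,
) -> Profile:
    """Bilinear height profile from ``p0`` to ``p1`` (nm image coordinates).

    Sampled at pixel_size steps and averaged over ``width`` parallel lines
    one pixel apart; heights are reported relative to ``reference`` (the
    mica level, 0, by default).  Bilinear sampling is exact on affine height
    fields.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    positions, heights = _sample_segment(topo, p0, p1, width)
    return Profile(positions=positions, heights=heights - reference,
                   averaging_width=width)


def detect_protrusions(
    profile: Profile, min_separation: float = 2.0, min_prominence: float = 0.05
) -> ProtrusionSeries:
    """Local maxima of a profile with the stated prominence/spacing rules.

    Of any two peaks closer than ``min_separation`` (nm) the higher is kept.
    Peaks are labelled cyclically (1, 2, 3, 1*, ...) from the profile start.
    """
    if profile.length <= 2 * min_separation:
        raise ValueError("profile shorter than twice min_separation")
    distance = max(int(round(min_separation / profile.step)), 1)
    idx, _ = signal.find_peaks(
        profile.heights, distance=distance, prominence=min_prominence
    )
    return ProtrusionSeries(
        positions=profile.positions[idx], heights=profile.heights[idx]
    )


def phase_align(series: ProtrusionSeries, period: int = 3) -> ProtrusionSeries:
    """Shift the label phase so that label-3 peaks are the lowest on average.

    The cyclic labels 1, 2, 3 are conventionally assigned so that the
    recurrently lowered protrusion (the neck dimer in alternate repeat
    units) carries label 3; experimentally this assignment is made by eye.
    Trims 0..period-1 leading peaks to realise the phase.
    """
    if len(series) < 2 * period:
        return series
    means = []
    for k in range(period):
        h3 = series.heights[k + period - 1 :: period]
        means.append(h3.mean())
    k = int(np.argmin(means))
    return ProtrusionSeries(
        positions=series.positions[k:], heights=series.heights[k:]
    )


def height_difference_stats(
    series_list: Sequence[ProtrusionSeries],
) -> Dict[str, BoxStats]:
    """Pooled paired height differences between consecutive protrusions.

    For each repeat unit the differences h(1)-h(2), h(2)-h(3) and h(3)-h(1*)
    are collected across all series; series with fewer than 4 peaks are
    skipped with a log entry.  Returns one BoxStats per pairing.
    """
    pools: Dict[str, List[float]] = {p: [] for p in PAIRINGS}
    for k, series in enumerate(series_list):
        if len(series) < 4:
            logger.warning("series %d has %d peaks (<4); skipped", k, len(series))
            continue
        h = series.heights
        for i in range(len(h) - 1):
            pools[PAIRINGS[i % 3]].append(float(h[i] - h[i + 1]))
    out: Dict[str, BoxStats] = {}
    for pairing, values in pools.items():
        if values:
            out[pairing] = notched_box(values)
    return out


def notched_box(values: Sequence[float]) -> BoxStats:
    """Median, Tukey-hinge quartiles and McGill notch of a sample.

    The hinges include the overall median in both halves for odd n; the
    notch half-width is 1.57*(Q3-Q1)/sqrt(n).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    median = float(np.median(x))
    if n == 1:
        q1 = q3 = median
    else:
        half = n // 2
        lower = x[: half + (n % 2)]
        upper = x[half:]
        q1 = float(np.median(lower))
        q3 = float(np.median(upper))
    notch = 1.57 * (q3 - q1) / np.sqrt(n)
    return BoxStats(median=median, q1=q1, q3=q3, notch=notch,
                    min=float(x[0]), max=float(x[-1]), n=int(n))
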