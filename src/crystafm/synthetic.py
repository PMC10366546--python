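"""Ground-truthed synthetic HS-AFM movies of 2D crystal growth on a membrane.

The generator emulates the assembly of an aegerolysin (OlyA6-like) 2D crystal
on a supported lipid bilayer as seen by high-speed AFM: a mica level at 0 nm,
a bilayer patch ~7 nm above mica, and protein stripes of a monoclinic lattice
(three dimers per unit cell along a) that grow and shrink dimer-by-dimer at
stripe ends.  Every association/dissociation event is logged, so downstream
estimators can be scored against exact ground truth.

The repeat unit carries three elliptical protrusion footprints (dimers AB and
CD forming the "head", dimer EF the "neck"); EF is lowered by a configurable
amount in alternate repeat units, producing a second, longer periodicity
along each stripe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import Lattice2D, Topograph

__all__ = [
    "EllipseFootprint",
    "RepeatUnitTemplate",
    "LayerModel",
    "GrowthParams",
    "ScanParams",
    "Stripe",
    "OccupancyMovie",
    "MovieConfig",
    "simulate_growth",
    "render_topograph",
    "generate_movie",
    "default_config",
    "rectangle_mask",
    "allowed_sites",
]

DIMER_NAMES = ("AB", "CD", "EF")


@dataclass(frozen=True)
class EllipseFootprint:
    """Elliptical protrusion footprint of one dimer.

    ``major``/``minor`` are full axis lengths in nm.  ``angle`` is the angle
    of the major axis relative to the lattice a direction, in degrees.
    ``offset`` is the centre offset from the slot centre, in fractional
    lattice coordinates (da along a, db along b).
    """

    major: float
    minor: float
    angle: float = 0.0
    offset: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.major > 0 and self.minor > 0):
            raise ValueError("ellipse axes must be positive")


def _default_footprints() -> Dict[str, EllipseFootprint]:
    # AB and CD are congruent halves of the ~6.5 x 5.1 nm head section, major
    # axis across the stripe; EF is the 5.1 x 2.8 nm neck, major axis along b
    # (a visibly different orientation, as in the imaged crystal).
    return {
        "AB": EllipseFootprint(major=5.1, minor=3.4, angle=90.0),
        "CD": EllipseFootprint(major=5.1, minor=3.4, angle=90.0),
        "EF": EllipseFootprint(major=5.1, minor=2.8, angle=100.0),
    }


@dataclass(frozen=True)
class RepeatUnitTemplate:
    """Protrusion geometry of one hexameric repeat unit (three dimers).

    ``ef_alternate_drop`` lowers the EF (neck) dimer in alternate repeat
    units along each stripe; ``ef_drop_phase`` selects which parity is
    lowered and ``row_stagger`` shifts that parity between adjacent rows.
    """

    protrusion_footprints: Dict[str, EllipseFootprint] = field(
        default_factory=_default_footprints
    )
    protrusion_height: float = 5.0
    ef_alternate_drop: float = 0.3
    ef_drop_phase: int = 0
    row_stagger: int = 1

    def __post_init__(self) -> None:
        missing = set(DIMER_NAMES) - set(self.protrusion_footprints)
        if missing:
            raise ValueError(f"missing footprints for dimers: {sorted(missing)}")
        if self.protrusion_height <= 0:
            raise ValueError("protrusion_height must be positive")
        if self.ef_alternate_drop < 0:
            raise ValueError("ef_alternate_drop must be >= 0")

    def ef_lowered(self, row: int, repeat_index: int) -> bool:
        return (repeat_index + self.row_stagger * row + self.ef_drop_phase) % 2 == 1


@dataclass
class LayerModel:
    """Vertical layering of the sample: mica (0) / bilayer / protein."""

    membrane_thickness: float = 7.0
    protein_height: float = 5.0
    membrane_mask: Optional[np.ndarray] = None  # bool, image shape; None = full

    def __post_init__(self) -> None:
        if self.membrane_thickness <= 0:
            raise ValueError("membrane_thickness must be positive")
        if self.protein_height <= 0:
            raise ValueError("protein_height must be positive")

    def mask_for(self, shape: Tuple[int, int]) -> np.ndarray:
        if self.membrane_mask is None:
            return np.ones(shape, dtype=bool)
        mask = np.asarray(self.membrane_mask, dtype=bool)
        if mask.shape != tuple(shape):
            raise ValueError("membrane_mask shape does not match image shape")
        return mask


@dataclass(frozen=True)
class GrowthParams:
    """Kinetic parameters of stripe growth.

    Rates are expressed as net observable dimer events per stripe end per
    frame interval (the default 2 s frame time of the experiment); opposing
    events within one interval cancel before they can be observed.
    """

    k_assoc: float = 1.0
    k_dissoc: float = 0.3
    k_nucleate: float = 0.05
    edge_instability_factor: float = 1.0
    frame_interval: float = 2.0
    deterministic: bool = False

    def __post_init__(self) -> None:
        for name in ("k_assoc", "k_dissoc", "k_nucleate"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.edge_instability_factor < 1:
            raise ValueError("edge_instability_factor must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")


@dataclass(frozen=True)
class ScanParams:
    """Instrument response of the virtual scanner."""

    pixel_size: float = 0.5
    image_shape: Tuple[int, int] = (256, 256)
    tip_blur_sigma: float = 0.5
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.tip_blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("sigmas must be >= 0")


@dataclass
class Stripe:
    """A contiguous run of occupied dimer slots in one lattice row."""

    stripe_id: int
    row: int
    slot_lo: int
    slot_hi: int  # exclusive

    def __post_init__(self) -> None:
        if self.slot_hi <= self.slot_lo:
            raise ValueError("stripe must occupy at least one slot")

    @property
    def n_slots(self) -> int:
        return self.slot_hi - self.slot_lo

    def slots(self) -> range:
        return range(self.slot_lo, self.slot_hi)


@dataclass
class OccupancyMovie:
    """Ground-truth occupancy: per frame, the set of stripes on the lattice."""

    lattice: Lattice2D
    frames: List[List[Stripe]]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def total_slots(self, frame: int) -> int:
        return sum(s.n_slots for s in self.frames[frame])


def _event(frame: int, stripe_id: int, event: str, slots: int, pitch: float) -> dict:
    return {
        "frame": frame,
        "stripe_id": stripe_id,
        "event": event,
        "slots": slots,
        "length_nm": slots * pitch,
    }


def simulate_growth(
    lattice: Lattice2D,
    growth: GrowthParams,
    n_frames: int,
    seed: int,
    init_stripes: Optional[Sequence[Stripe]] = None,
    slot_limits: Tuple[int, int] = (0, 10_000),
    row_limits: Tuple[int, int] = (0, 10_000),
    edge_rows: Optional[Iterable[int]] = None,
) -> Tuple[OccupancyMovie, pd.DataFrame]:
    """Stochastic dimer-level growth of crystal stripes.

    Stripes extend/retract at their two ends (longitudinal growth); the
    transversal direction grows only by nucleation of single-dimer stripes in
    rows adjacent to existing stripes.  An end sitting at a slot limit is
    inactive.  Stripes whose row is in ``edge_rows`` dissociate faster by
    ``edge_instability_factor`` (membrane-edge instability).

    Returns the occupancy movie (frame 0 is the initial state) and the event
    log, one row per net event: frame, stripe_id, event in
    {assoc, dissoc, nucleate}, slots, length_nm.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    lo_lim, hi_lim = slot_limits
    row_lo, row_hi = row_limits
    edge = frozenset(edge_rows) if edge_rows is not None else frozenset()
    rng = np.random.default_rng(seed)
    pitch = lattice.slot_pitch

    if init_stripes is None:
        mid_slot = (lo_lim + hi_lim) // 2
        mid_row = (row_lo + row_hi) // 2
        init_stripes = [Stripe(0, mid_row, mid_slot - 1, mid_slot + 2)]
    stripes: List[Stripe] = [replace(s) for s in init_stripes]
    next_id = max((s.stripe_id for s in stripes), default=-1) + 1

    frames: List[List[Stripe]] = [[replace(s) for s in stripes]]
    events: List[dict] = []

    def draw(rate: float) -> int:
        if growth.deterministic:
            return int(round(rate))
        return int(rng.poisson(rate)) if rate > 0 else 0

    for frame in range(1, n_frames):
        survivors: List[Stripe] = []
        for s in stripes:
            kd = growth.k_dissoc
            if s.row in edge:
                kd *= growth.edge_instability_factor
            lo, hi = s.slot_lo, s.slot_hi
            # net change per end; an end at the allowed-slot limit is frozen
            for end in ("left", "right"):
                at_limit = (lo <= lo_lim) if end == "left" else (hi >= hi_lim)
                if at_limit:
                    continue
                net = draw(growth.k_assoc) - draw(kd)
                if net == 0:
                    continue
                if end == "left":
                    new_lo = lo - net
                    new_lo = max(new_lo, lo_lim)  # clamp growth at the limit
                    applied = lo - new_lo
                    if new_lo >= hi:  # dissolved from the left
                        applied = -(hi - lo)
                        new_lo = hi
                    lo = new_lo
                else:
                    new_hi = hi + net
                    new_hi = min(new_hi, hi_lim)
                    applied = new_hi - hi
                    if new_hi <= lo:
                        applied = -(hi - lo)
                        new_hi = lo
                    hi = new_hi
                if applied > 0:
                    events.append(_event(frame, s.stripe_id, "assoc", applied, pitch))
                elif applied < 0:
                    events.append(_event(frame, s.stripe_id, "dissoc", -applied, pitch))
                if hi <= lo:
                    break
            if hi > lo:
                survivors.append(Stripe(s.stripe_id, s.row, lo, hi))
        stripes = survivors

        for _ in range(draw(growth.k_nucleate)):
            if stripes:
                parent = stripes[int(rng.integers(len(stripes)))]
                row = parent.row + int(rng.choice([-1, 1]))
                slot = int(rng.integers(parent.slot_lo, parent.slot_hi))
            else:
                row = (row_lo + row_hi) // 2
                slot = (lo_lim + hi_lim) // 2
            if not (row_lo <= row < row_hi and lo_lim <= slot < hi_lim):
                continue
            if any(t.row == row and t.slot_lo <= slot < t.slot_hi for t in stripes):
                continue
            stripes.append(Stripe(next_id, row, slot, slot + 1))
            events.append(_event(frame, next_id, "nucleate", 1, pitch))
            next_id += 1

        frames.append([replace(s) for s in stripes])

    columns = ["frame", "stripe_id", "event", "slots", "length_nm"]
    log = pd.DataFrame(events, columns=columns)
    return OccupancyMovie(lattice=lattice, frames=frames), log


def _paint_ellipse(
    heights: np.ndarray,
    center_nm: np.ndarray,
    fp: EllipseFootprint,
    angle_deg: float,
    value: float,
    pixel_size: float,
) -> np.ndarray:
    """Raise pixels inside the ellipse to at least ``value`` (max-combine).

    Returns the boolean membership mask of the ellipse (for layer checks).
    """
    rows, cols = heights.shape
    ca, sa = np.cos(np.deg2rad(angle_deg)), np.sin(np.deg2rad(angle_deg))
    ra, rb = fp.major / 2.0, fp.minor / 2.0
    reach = max(ra, rb)
    cx, cy = center_nm
    c0 = max(int((cx - reach) / pixel_size) - 1, 0)
    c1 = min(int((cx + reach) / pixel_size) + 2, cols)
    r0 = max(int((cy - reach) / pixel_size) - 1, 0)
    r1 = min(int((cy + reach) / pixel_size) + 2, rows)
    if c0 >= c1 or r0 >= r1:
        return np.zeros_like(heights, dtype=bool)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    px = (xx + 0.5) * pixel_size - cx
    py = (yy + 0.5) * pixel_size - cy
    u = px * ca + py * sa
    v = -px * sa + py * ca
    inside = (u / ra) ** 2 + (v / rb) ** 2 <= 1.0
    sub = heights[r0:r1, c0:c1]
    sub[inside] = np.maximum(sub[inside], value)
    mask = np.zeros_like(heights, dtype=bool)
    mask[r0:r1, c0:c1] = inside
    return mask


def render_topograph(
    occupancy_frame: Sequence[Stripe],
    template: RepeatUnitTemplate,
    layers: LayerModel,
    lattice: Lattice2D,
    scan: ScanParams,
    timestamp: float = 0.0,
) -> Topograph:
    """Forward-model one frame: layers + protrusions, tip blur, noise.

    With blur and noise disabled the output takes only the discrete values
    {0, membrane, membrane + protrusion_height (- ef_alternate_drop)} up to
    ellipse-edge discretisation.  Deterministic given ``scan.seed``.
    """
    shape = tuple(scan.image_shape)
    mask = layers.mask_for(shape)
    heights = np.zeros(shape, dtype=float)
    heights[mask] = layers.membrane_thickness

    top = layers.membrane_thickness + layers.protein_height
    for s in occupancy_frame:
        for slot in s.slots():
            dimer = DIMER_NAMES[slot % 3]
            repeat = slot // 3
            value = top
            if dimer == "EF" and template.ef_lowered(s.row, repeat):
                value = top - template.ef_alternate_drop
            fp = template.protrusion_footprints[dimer]
            center = lattice.site_position(s.row, slot) + (
                fp.offset[0] * lattice.a_vec + fp.offset[1] * lattice.b_vec
            )
            fp_mask = _paint_ellipse(
                heights,
                center,
                fp,
                lattice.orientation + fp.angle,
                value,
                scan.pixel_size,
            )
            if np.any(fp_mask & ~mask):
                raise ValueError(
                    f"occupied site (row {s.row}, slot {slot}) extends outside "
                    "the membrane mask; protein binds the membrane only"
                )

    if scan.tip_blur_sigma > 0:
        heights = ndimage.gaussian_filter(
            heights, sigma=scan.tip_blur_sigma / scan.pixel_size, mode="nearest"
        )
    if scan.noise_sigma > 0:
        rng = np.random.default_rng(scan.seed)
        heights = heights + rng.normal(0.0, scan.noise_sigma, size=shape)
    return Topograph(heights=heights, pixel_size=scan.pixel_size, timestamp=timestamp)


def rectangle_mask(
    shape: Tuple[int, int], pixel_size: float, x0: float, y0: float, x1: float, y1: float
) -> np.ndarray:
    """Boolean membrane patch covering the nm rectangle [x0,x1) x [y0,y1)."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    px = (xx + 0.5) * pixel_size
    py = (yy + 0.5) * pixel_size
    return (px >= x0) & (px < x1) & (py >= y0) & (py < y1)


def allowed_sites(
    layers: LayerModel,
    lattice: Lattice2D,
    template: RepeatUnitTemplate,
    scan: ScanParams,
) -> Dict[int, Tuple[int, int]]:
    """Per-row slot ranges whose footprints lie fully inside the membrane mask.

    Scans candidate rows/slots with centres inside the field of view and
    checks each dimer footprint against the mask numerically; returns for
    each admissible row the maximal contiguous (slot_lo, slot_hi) range
    around the row centre.
    """
    shape = tuple(scan.image_shape)
    mask = layers.mask_for(shape)
    width, height = shape[1] * scan.pixel_size, shape[0] * scan.pixel_size
    diag = math.hypot(width, height)
    max_row = int(diag / lattice.row_pitch) + 1
    max_slot = int(diag / lattice.slot_pitch) + 1

    def fits(row: int, slot: int) -> bool:
        dimer = DIMER_NAMES[slot % 3]
        fp = template.protrusion_footprints[dimer]
        center = lattice.site_position(row, slot) + (
            fp.offset[0] * lattice.a_vec + fp.offset[1] * lattice.b_vec
        )
        probe = np.zeros(shape, dtype=float)
        fp_mask = _paint_ellipse(
            probe, center, fp, lattice.orientation + fp.angle, 1.0, scan.pixel_size
        )
        return bool(fp_mask.any()) and not np.any(fp_mask & ~mask)

    out: Dict[int, Tuple[int, int]] = {}
    for row in range(-max_row, max_row + 1):
        ok = [s for s in range(-max_slot, max_slot + 1) if fits(row, s)]
        if not ok:
            continue
        # keep the longest contiguous run
        runs: List[List[int]] = [[ok[0]]]
        for s in ok[1:]:
            if s == runs[-1][-1] + 1:
                runs[-1].append(s)
            else:
                runs.append([s])
        best = max(runs, key=len)
        out[row] = (best[0], best[-1] + 1)
    return out


@dataclass
class MovieConfig:
    """Full configuration of a synthetic movie."""

    lattice: Lattice2D = field(
        default_factory=lambda: Lattice2D(a_len=10.8, b_len=6.6, gamma=100.0)
    )
    template: RepeatUnitTemplate = field(default_factory=RepeatUnitTemplate)
    layers: LayerModel = field(default_factory=LayerModel)
    growth: GrowthParams = field(default_factory=GrowthParams)
    scan: ScanParams = field(default_factory=ScanParams)
    n_frames: int = 20
    init_stripes: Optional[List[Stripe]] = None
    edge_band_rows: int = 0  # rows within this count of the row limits are "edge"


def default_config(seed: int = 0) -> MovieConfig:
    """Demo conditions: a 128 x 128 nm field with a central membrane patch,
    a pre-formed multi-row crystallite (the analyses target the already
    crystallised stage of assembly), 20 frames at the experimental 2 s
    frame interval."""
    scan = ScanParams(seed=seed)
    shape = scan.image_shape
    fov = shape[1] * scan.pixel_size
    mask = rectangle_mask(shape, scan.pixel_size, 10.0, 10.0, fov - 10.0, fov - 10.0)
    lattice = Lattice2D(a_len=10.8, b_len=6.6, gamma=100.0, origin=(16.0, 60.0))
    cfg = MovieConfig(
        lattice=lattice,
        layers=LayerModel(membrane_mask=mask),
        scan=scan,
        growth=GrowthParams(k_assoc=1.0, k_dissoc=0.3, k_nucleate=0.1,
                            edge_instability_factor=3.0),
        n_frames=20,
        edge_band_rows=1,
    )
    sites = allowed_sites(cfg.layers, cfg.lattice, cfg.template, cfg.scan)
    rows = sorted(sites)
    mid = len(rows) // 2
    seed_rows = rows[max(mid - 4, 0) : mid + 5]
    init = []
    for k, r in enumerate(seed_rows):
        lo, hi = sites[r]
        c = (lo + hi) // 2
        init.append(Stripe(k, r, max(c - 8, lo), min(c + 8, hi)))
    cfg.init_stripes = init
    return cfg


def generate_movie(
    config: MovieConfig, seed: Optional[int] = None
) -> Tuple[List[Topograph], OccupancyMovie, pd.DataFrame]:
    """Simulate growth and render every frame.

    Returns the topograph stack (timestamps at ``frame_interval`` spacing),
    the ground-truth occupancy movie and the event log.
    """
    if seed is None:
        seed = config.scan.seed
    sites = allowed_sites(config.layers, config.lattice, config.template, config.scan)
    if not sites:
        raise ValueError("membrane patch admits no lattice sites")
    rows = sorted(sites)
    row_lo, row_hi = rows[0], rows[-1] + 1
    # conservative common slot range so ends stay on the membrane in any row
    slot_lo = max(sites[r][0] for r in rows)
    slot_hi = min(sites[r][1] for r in rows)
    if slot_hi <= slot_lo:
        raise ValueError("membrane patch admits no common slot range")

    init = config.init_stripes
    if init is None:
        mid_row = rows[len(rows) // 2]
        mid = (slot_lo + slot_hi) // 2
        init = [Stripe(0, mid_row, mid - 2, mid + 3)]
    band = config.edge_band_rows
    edge_rows = [r for r in rows if r < row_lo + band or r >= row_hi - band]

    movie, log = simulate_growth(
        config.lattice,
        config.growth,
        config.n_frames,
        seed=seed,
        init_stripes=init,
        slot_limits=(slot_lo, slot_hi),
        row_limits=(row_lo, row_hi),
        edge_rows=edge_rows,
    )
    stack = []
    for i, frame in enumerate(movie.frames):
        scan_i = replace(config.scan, seed=(seed + 77_003 * i) % (2**31))
        stack.append(
            render_topograph(
                frame,
                config.template,
                config.layers,
                config.lattice,
                scan_i,
                timestamp=i * config.growth.frame_interval,
            )
        )
    return stack, movie, log
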