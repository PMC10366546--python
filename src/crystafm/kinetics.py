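"""Stripe tracing and growth kinetics across frames.

Crystal stripes are ridges of protein running along the lattice a direction.
Each frame is reduced to per-row occupied slot intervals (slot pitch a/3);
between consecutive frames the interval algebra of each row yields the
association (new length) and dissociation (lost length) events, the exact
quantity the growth simulator logs.  Event lengths are projections onto the
a-axis, quantised to the slot pitch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .core import Lattice2D, Topograph
from .profiles import BoxStats, notched_box

__all__ = [
    "StripeTrace",
    "KineticsRecord",
    "CoverageSeries",
    "trace_stripes",
    "match_and_measure",
    "cumulative_coverage",
    "unit_size_stats",
    "gaussian_fit",
    "GaussianFitResult",
]

logger = logging.getLogger(__name__)


@dataclass
class StripeTrace:
    """One traced stripe in one frame."""

    frame: int
    stripe_id: int
    row: int
    slot_lo: int
    slot_hi: int  # exclusive
    polyline: np.ndarray  # (2, 2) endpoints in nm image coordinates
    length: float  # nm along the a-axis

    @property
    def interval(self) -> Tuple[int, int]:
        return self.slot_lo, self.slot_hi


@dataclass
class KineticsRecord:
    """Association/dissociation lengths for one stripe between two frames."""

    frame_t: int
    frame_t1: int
    stripe_id: int
    association: List[float] = field(default_factory=list)
    dissociation: List[float] = field(default_factory=list)


@dataclass
class CoverageSeries:
    """Accumulated crystal size over time (running sum of net growth)."""

    coverage: np.ndarray  # nm, one value per frame pair, starting increment
    timestamps: np.ndarray  # s


def trace_stripes(
    topo: Topograph,
    lattice: Lattice2D,
    min_length: float = 0.0,
    protein_min_height: float = 2.5,
    frame: int = 0,
) -> List[StripeTrace]:
    """Trace crystal stripes as runs of occupied dimer slots per lattice row.

    Pixels more than ``protein_min_height`` nm above the modal (membrane)
    level are protein; they select the candidate lattice rows and slot
    ranges.  A slot counts as occupied when the mean height inside a
    quarter-pitch disc around the slot centre (a disc that fits inside every
    dimer footprint) exceeds the protein threshold.  Contiguous occupied
    slots form one trace; traces shorter than ``min_length`` (nm) are
    discarded.
    """
    heights = topo.heights
    # modal level = centre of the most populated 0.1 nm bin
    lo, hi = float(heights.min()), float(heights.max())
    nbins = max(int((hi - lo) / 0.1), 1)
    counts, edges = np.histogram(heights, bins=nbins)
    mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
    threshold = mode + protein_min_height

    rows_px, cols_px = np.nonzero(heights > threshold)
    traces: List[StripeTrace] = []
    if rows_px.size == 0:
        return traces

    origin = np.asarray(lattice.origin, dtype=float)
    pts = (
        np.column_stack([cols_px, rows_px]).astype(float) + 0.5
    ) * topo.pixel_size - origin
    a_hat = lattice.a_hat
    n_hat = lattice.stripe_normal
    pitch = lattice.slot_pitch
    row_pitch = lattice.row_pitch
    # remove the oblique component of b along a so slot indices are row-independent
    b_along_a = float(np.dot(lattice.b_vec, a_hat))

    rho = pts @ n_hat / row_pitch * np.sign(np.dot(lattice.b_vec, n_hat))
    row_idx = np.round(rho).astype(int)
    t_along = pts @ a_hat

    # disc sampler around a slot centre (radius = quarter pitch)
    n_rows_img, n_cols_img = heights.shape
    disc_r = pitch / 4.0

    def disc_mean(center_nm: np.ndarray) -> float:
        k = int(disc_r / topo.pixel_size) + 1
        c = center_nm / topo.pixel_size - 0.5
        ci, ri = int(round(c[0])), int(round(c[1]))
        r0_, r1_ = max(ri - k, 0), min(ri + k + 1, n_rows_img)
        c0_, c1_ = max(ci - k, 0), min(ci + k + 1, n_cols_img)
        if r0_ >= r1_ or c0_ >= c1_:
            return -np.inf
        yy, xx = np.mgrid[r0_:r1_, c0_:c1_]
        d2 = ((xx + 0.5) * topo.pixel_size - center_nm[0]) ** 2 + (
            (yy + 0.5) * topo.pixel_size - center_nm[1]
        ) ** 2
        inside = d2 <= disc_r**2
        if not inside.any():
            return -np.inf
        return float(heights[r0_:r1_, c0_:c1_][inside].mean())

    next_id = 0
    for row in np.unique(row_idx):
        sel = row_idx == row
        t = t_along[sel] - row * b_along_a
        slots = np.floor(t / pitch).astype(int)
        occupied = []
        for s in range(int(slots.min()) - 1, int(slots.max()) + 2):
            center = origin + ((s + 0.5) * pitch + row * b_along_a) * a_hat + (
                row * row_pitch * n_hat * np.sign(np.dot(lattice.b_vec, n_hat))
            )
            if disc_mean(center) > threshold:
                occupied.append(int(s))
        if not occupied:
            continue
        occupied.sort()
        runs: List[List[int]] = [[occupied[0]]]
        for s in occupied[1:]:
            if s == runs[-1][-1] + 1:
                runs[-1].append(s)
            else:
                runs.append([s])
        for run in runs:
            lo_s, hi_s = run[0], run[-1] + 1
            length = (hi_s - lo_s) * pitch
            if length < min_length:
                continue
            p_start = origin + (lo_s * pitch + row * b_along_a) * a_hat + row * row_pitch * (
                n_hat * np.sign(np.dot(lattice.b_vec, n_hat))
            )
            p_end = p_start + (hi_s - lo_s) * pitch * a_hat
            traces.append(
                StripeTrace(
                    frame=frame,
                    stripe_id=next_id,
                    row=int(row),
                    slot_lo=lo_s,
                    slot_hi=hi_s,
                    polyline=np.array([p_start, p_end]),
                    length=float(length),
                )
            )
            next_id += 1
    return traces


def _row_intervals(traces: Sequence[StripeTrace]) -> Dict[int, List[StripeTrace]]:
    rows: Dict[int, List[StripeTrace]] = {}
    for t in traces:
        rows.setdefault(t.row, []).append(t)
    return rows


def _segments(intervals: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge integer intervals into disjoint sorted segments."""
    segs: List[Tuple[int, int]] = []
    for lo, hi in sorted(intervals):
        if segs and lo <= segs[-1][1]:
            segs[-1] = (segs[-1][0], max(segs[-1][1], hi))
        else:
            segs.append((lo, hi))
    return segs


def _difference(a: Sequence[Tuple[int, int]], b: Sequence[Tuple[int, int]]):
    """Connected components of (union a) minus (union b), as intervals."""
    out: List[Tuple[int, int]] = []
    for lo, hi in _segments(a):
        cur = lo
        for blo, bhi in _segments(b):
            if bhi <= cur or blo >= hi:
                continue
            if blo > cur:
                out.append((cur, blo))
            cur = max(cur, bhi)
            if cur >= hi:
                break
        if cur < hi:
            out.append((cur, hi))
    return out


def match_and_measure(
    traces_t: Sequence[StripeTrace],
    traces_t1: Sequence[StripeTrace],
    max_lateral_offset: float = 0.0,
    lattice: Optional[Lattice2D] = None,
    frame_t: Optional[int] = None,
    frame_t1: Optional[int] = None,
) -> List[KineticsRecord]:
    """Association/dissociation lengths between two traced frames.

    Traces are compared row by row (``max_lateral_offset`` must be smaller
    than the row pitch for rows to be distinct; row identity is already
    discrete here).  Within a row, the connected components of the set
    difference of occupied slot intervals give the events: components of
    t+1 minus t are associations, components of t minus t+1 dissociations
    (a gap forming inside a stripe is thus one dissociation of the gap
    length).  Each event is attributed to the frame-t stripe it touches;
    events touching none (new stripes) get fresh ids.  Ambiguities are
    resolved largest-overlap-first, deterministically.
    """
    pitch = lattice.slot_pitch if lattice is not None else None
    ft = frame_t if frame_t is not None else (traces_t[0].frame if traces_t else 0)
    ft1 = frame_t1 if frame_t1 is not None else (
        traces_t1[0].frame if traces_t1 else ft + 1
    )

    def nm(n_slots: int, any_trace: StripeTrace) -> float:
        if pitch is not None:
            return n_slots * pitch
        return n_slots * any_trace.length / max(any_trace.slot_hi - any_trace.slot_lo, 1)

    rows = sorted(set([t.row for t in traces_t]) | set([t.row for t in traces_t1]))
    rows_t = _row_intervals(traces_t)
    rows_t1 = _row_intervals(traces_t1)
    records: Dict[int, KineticsRecord] = {}
    next_new_id = max([t.stripe_id for t in traces_t], default=-1) + 1

    def get_record(stripe_id: int) -> KineticsRecord:
        if stripe_id not in records:
            records[stripe_id] = KineticsRecord(ft, ft1, stripe_id)
        return records[stripe_id]

    for row in rows:
        at = rows_t.get(row, [])
        bt = rows_t1.get(row, [])
        a_iv = [t.interval for t in at]
        b_iv = [t.interval for t in bt]
        assoc = _difference(b_iv, a_iv)
        dissoc = _difference(a_iv, b_iv)

        def owner(seg: Tuple[int, int]) -> Optional[StripeTrace]:
            # frame-t stripe touching the segment, largest overlap/contact first
            best, best_key = None, None
            for tr in at:
                ov = min(seg[1], tr.slot_hi) - max(seg[0], tr.slot_lo)
                if ov >= 0:  # overlap or contact
                    key = (-ov, tr.stripe_id)
                    if best_key is None or key < best_key:
                        best, best_key = tr, key
            return best

        ref = (at + bt)[0]
        for seg in assoc:
            tr = owner(seg)
            if tr is None:
                sid = next_new_id
                next_new_id += 1
            else:
                sid = tr.stripe_id
            get_record(sid).association.append(nm(seg[1] - seg[0], ref))
        for seg in dissoc:
            tr = owner(seg)
            sid = tr.stripe_id if tr is not None else next_new_id
            if tr is None:
                next_new_id += 1
                logger.warning("dissociation segment with no owning stripe")
            get_record(sid).dissociation.append(nm(seg[1] - seg[0], ref))
    return sorted(records.values(), key=lambda r: r.stripe_id)


def cumulative_coverage(
    records_by_pair: Sequence[Sequence[KineticsRecord]],
    frame_interval: float = 2.0,
) -> CoverageSeries:
    """Running sum of (total association - total dissociation) per frame pair.

    ``records_by_pair`` holds one record list per consecutive frame pair, in
    frame order (a flat sequence of records is also accepted and grouped by
    frame pair).  Increments may be negative when dissociation dominates.
    """
    if records_by_pair and isinstance(records_by_pair[0], KineticsRecord):
        groups: Dict[Tuple[int, int], List[KineticsRecord]] = {}
        for r in records_by_pair:  # type: ignore[assignment]
            groups.setdefault((r.frame_t, r.frame_t1), []).append(r)
        records_by_pair = [groups[k] for k in sorted(groups)]
    increments = []
    times = []
    for k, records in enumerate(records_by_pair):
        inc = sum(sum(r.association) - sum(r.dissociation) for r in records)
        increments.append(inc)
        t = records[0].frame_t1 * frame_interval if records else (k + 1) * frame_interval
        times.append(t)
    coverage = np.cumsum(increments) if increments else np.array([])
    return CoverageSeries(coverage=np.asarray(coverage, dtype=float),
                          timestamps=np.asarray(times, dtype=float))


def unit_size_stats(
    records: Sequence[KineticsRecord],
) -> Dict[str, Optional[BoxStats]]:
    """Notched-box summaries of pooled event lengths per class.

    Classes: ``association``, ``dissociation`` and ``both`` (pooled).  An
    empty class maps to None.
    """
    if not records:
        raise ValueError("need at least one kinetics record")
    assoc = [x for r in records for x in r.association]
    dissoc = [x for r in records for x in r.dissociation]
    both = assoc + dissoc
    return {
        "association": notched_box(assoc) if assoc else None,
        "dissociation": notched_box(dissoc) if dissoc else None,
        "both": notched_box(both) if both else None,
    }


@dataclass(frozen=True)
class GaussianFitResult:
    amplitude: float
    center: float
    width: float
    offset: float
    residual_norm: float


def gaussian_fit(x: Sequence[float], y: Sequence[float]) -> GaussianFitResult:
    """Least-squares 4-parameter Gaussian fit y = o + A*exp(-(x-c)^2/(2w^2)).

    Raises RuntimeError on non-convergence (no parameters are returned then).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 points for a 4-parameter fit")

    def model(x, A, c, w, o):
        return o + A * np.exp(-((x - c) ** 2) / (2.0 * w**2))

    o0 = float(y.min())
    A0 = float(y.max() - y.min()) or 1.0
    c0 = float(x[np.argmax(y)])
    w0 = float((x.max() - x.min()) / 6.0) or 1.0
    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=[A0, c0, w0, o0], maxfev=10_000)
    except RuntimeError as exc:  # non-convergence
        raise RuntimeError(f"Gaussian fit did not converge: {exc}") from exc
    resid = float(np.linalg.norm(y - model(x, *popt)))
    A, c, w, o = (float(v) for v in popt)
    return GaussianFitResult(amplitude=A, center=c, width=abs(w), offset=o,
                             residual_norm=resid)
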