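"""Lattice geometry from height images: smoothing, autocorrelation, FFT.

The 2D crystal shows up in a height image as two families of periodic
features: the inter-stripe spacing b*sin(gamma) and the repeat structure
along the stripes.  Both are extracted here via the power spectrum and the
autocorrelation function (ACF); the unit cell (a, b, gamma) is fitted from
the ACF peak lattice by basis reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import Lattice2D, Topograph

__all__ = [
    "PeriodicitySet",
    "AcfPeaks",
    "gaussian_smooth",
    "autocorrelation",
    "estimate_periodicities",
    "acf_peaks",
    "fit_unit_cell",
    "fit_unit_cell_from_image",
]


@dataclass(frozen=True)
class Peak:
    """One power-spectrum peak: real-space spacing, direction and power."""

    spacing: float  # nm
    direction: float  # degrees of the wave vector in the image frame
    power: float


@dataclass
class PeriodicitySet:
    """Dominant periodicities, sorted by descending spectral power."""

    peaks: List[Peak]

    def spacings(self) -> np.ndarray:
        return np.array([p.spacing for p in self.peaks])

    @property
    def dominant(self) -> Optional[Peak]:
        return self.peaks[0] if self.peaks else None


@dataclass
class AcfPeaks:
    """Non-zero-lag local maxima of the ACF as (dx, dy) nm lag vectors."""

    vectors: np.ndarray  # (n, 2) nm
    values: np.ndarray  # ACF value at each peak

    def __len__(self) -> int:
        return len(self.vectors)


def gaussian_smooth(topo: Topograph, sigma: float) -> Topograph:
    """Gaussian-filter a topograph; ``sigma`` in nm.  sigma=0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return topo.with_heights(topo.heights.copy())
    out = ndimage.gaussian_filter(topo.heights, sigma=sigma / topo.pixel_size,
                                  mode="nearest")
    return topo.with_heights(out)


def _hann2d(shape: Tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def autocorrelation(topo: Topograph) -> Topograph:
    """Normalised 2D autocorrelation of the (mean-subtracted, Hann-windowed)
    image, computed through the power spectrum.

    The returned topograph lives in the lag domain with zero lag at the
    centre pixel and value 1 there; the ACF is even under lag negation.
    """
    h = topo.heights - topo.heights.mean()
    if np.allclose(h, 0):
        raise ValueError("constant image has no autocorrelation (zero variance)")
    w = _hann2d(h.shape)
    num = np.fft.fftshift(np.fft.ifft2(np.abs(np.fft.fft2(h * w)) ** 2).real)
    den = np.fft.fftshift(np.fft.ifft2(np.abs(np.fft.fft2(w)) ** 2).real)
    r0, c0 = h.shape[0] // 2, h.shape[1] // 2
    # window compensation (unbiased estimate); clamp den to keep the far
    # corners, where the window overlap vanishes, finite
    acf = num / np.maximum(den, den[r0, c0] * 1e-3)
    acf = acf / acf[r0, c0]
    return topo.with_heights(acf)


def _local_maxima(img: np.ndarray) -> np.ndarray:
    """Boolean map of strict 8-neighbourhood local maxima."""
    mx = ndimage.maximum_filter(img, size=3, mode="constant", cval=-np.inf)
    return (img >= mx) & np.isfinite(img)


def estimate_periodicities(
    topo: Topograph, n_peaks: int = 5, min_spacing: Optional[float] = None
) -> PeriodicitySet:
    """Dominant non-DC periodicities from the 2D power spectrum.

    Peaks are strict local maxima of the Hann-windowed periodogram exceeding
    both 5x the median power and a Bonferroni-style noise ceiling
    mean*(ln N + 3) (the maximum of N exponential noise bins concentrates
    near mean*ln N, so a white-noise image yields an empty set).  Peak
    positions are refined by a 3x3 power-weighted centroid; conjugate pairs
    are reported once.  Invariant to adding a constant height.
    """
    h = topo.heights - topo.heights.mean()
    n_rows, n_cols = h.shape
    w = _hann2d(h.shape)
    P = np.abs(np.fft.fft2(h * w)) ** 2
    P = np.fft.fftshift(P)
    qy = np.fft.fftshift(np.fft.fftfreq(n_rows, d=topo.pixel_size))
    qx = np.fft.fftshift(np.fft.fftfreq(n_cols, d=topo.pixel_size))
    r0, c0 = n_rows // 2, n_cols // 2

    # exclude the DC mainlobe (Hann leakage spans ~2 bins)
    dc_excl = 3
    yy, xx = np.mgrid[0:n_rows, 0:n_cols]
    near_dc = (np.abs(yy - r0) <= dc_excl) & (np.abs(xx - c0) <= dc_excl)
    Pm = np.where(near_dc, -np.inf, P)

    valid = P[~near_dc]
    floor = max(5.0 * np.median(valid), valid.mean() * (math.log(valid.size) + 3.0))

    cand = _local_maxima(Pm) & (Pm > floor)
    if min_spacing is None:
        min_spacing = 2.0 * topo.pixel_size  # Nyquist
    peaks: List[Peak] = []
    for r, c in zip(*np.nonzero(cand)):
        # keep one representative per conjugate pair (upper half-plane)
        if qy[r] < 0 or (qy[r] == 0 and qx[c] < 0):
            continue
        # 3x3 power-weighted centroid refinement
        rs = slice(max(r - 1, 0), min(r + 2, n_rows))
        cs = slice(max(c - 1, 0), min(c + 2, n_cols))
        win = P[rs, cs]
        wy = qy[rs]
        wx = qx[cs]
        tot = win.sum()
        qyc = float((win.sum(axis=1) * wy).sum() / tot)
        qxc = float((win.sum(axis=0) * wx).sum() / tot)
        qnorm = math.hypot(qxc, qyc)
        if qnorm == 0:
            continue
        spacing = 1.0 / qnorm
        if spacing <= min_spacing:
            continue
        peaks.append(
            Peak(spacing=spacing,
                 direction=math.degrees(math.atan2(qyc, qxc)),
                 power=float(P[r, c]))
        )
    peaks.sort(key=lambda p: (-p.power, p.spacing))
    return PeriodicitySet(peaks=peaks[:n_peaks])


def acf_peaks(
    acf: Topograph,
    min_lag: float = 2.0,
    max_lag: Optional[float] = None,
    rel_threshold: float = 0.2,
) -> AcfPeaks:
    """Locate non-zero-lag local maxima of an ACF topograph.

    ``min_lag`` (nm) excludes the zero-lag mainlobe; ``rel_threshold``
    discards maxima weaker than that fraction of the strongest non-zero-lag
    peak (noise ripples).  Peak positions are refined to sub-pixel precision
    by a 3x3 value-weighted centroid.
    """
    img = acf.heights
    n_rows, n_cols = img.shape
    r0, c0 = n_rows // 2, n_cols // 2
    yy, xx = np.mgrid[0:n_rows, 0:n_cols]
    dx = (xx - c0) * acf.pixel_size
    dy = (yy - r0) * acf.pixel_size
    lag = np.hypot(dx, dy)
    if max_lag is None:
        max_lag = min(n_rows, n_cols) * acf.pixel_size / 4.0
    ok = _local_maxima(img) & (lag >= min_lag) & (lag <= max_lag)
    if not ok.any():
        return AcfPeaks(vectors=np.empty((0, 2)), values=np.empty(0))
    vmax = img[ok].max()
    vecs, vals = [], []
    for r, c in zip(*np.nonzero(ok)):
        if img[r, c] < rel_threshold * vmax:
            continue
        rs = slice(max(r - 1, 0), min(r + 2, n_rows))
        cs = slice(max(c - 1, 0), min(c + 2, n_cols))
        win = np.clip(img[rs, cs], 0.0, None)
        tot = win.sum()
        if tot > 0:
            rc = float((win.sum(axis=1) * np.arange(rs.start, rs.stop)).sum() / tot)
            cc = float((win.sum(axis=0) * np.arange(cs.start, cs.stop)).sum() / tot)
        else:
            rc, cc = float(r), float(c)
        vecs.append([(cc - c0) * acf.pixel_size, (rc - r0) * acf.pixel_size])
        vals.append(float(img[r, c]))
    return AcfPeaks(vectors=np.array(vecs), values=np.array(vals))


def _lagrange_reduce(v1: np.ndarray, v2: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Gauss/Lagrange reduction of a 2D lattice basis (v1 shortest)."""
    v1, v2 = v1.copy(), v2.copy()
    if np.linalg.norm(v2) < np.linalg.norm(v1):
        v1, v2 = v2, v1
    while True:
        m = round(float(np.dot(v1, v2) / np.dot(v1, v1)))
        v2 = v2 - m * v1
        if np.linalg.norm(v2) >= np.linalg.norm(v1):
            break
        v1, v2 = v2, v1
    return v1, v2


def _acf_value_at(acf: Topograph, point: np.ndarray) -> float:
    """Largest ACF value within one pixel of a predicted lag point."""
    n_rows, n_cols = acf.heights.shape
    r0, c0 = n_rows // 2, n_cols // 2
    r = r0 + point[1] / acf.pixel_size
    c = c0 + point[0] / acf.pixel_size
    ri, ci = int(round(r)), int(round(c))
    if not (1 <= ri < n_rows - 1 and 1 <= ci < n_cols - 1):
        return float("nan")
    return float(acf.heights[ri - 1 : ri + 2, ci - 1 : ci + 2].max())


def _dedupe_signs(vectors: np.ndarray) -> np.ndarray:
    """One representative per +/- pair (both ACF and spectrum are even)."""
    reps = np.asarray(vectors, dtype=float).copy()
    flip = (reps[:, 1] < 0) | ((reps[:, 1] == 0) & (reps[:, 0] < 0))
    reps[flip] *= -1
    _, idx = np.unique(np.round(reps, 9), axis=0, return_index=True)
    reps = reps[sorted(idx)]
    return reps[np.argsort(np.linalg.norm(reps, axis=1))]


def _index_residuals(M: np.ndarray, both: np.ndarray):
    ij = np.rint(np.linalg.solve(M, both.T)).T
    pred = ij @ M.T
    resid = np.linalg.norm(both - pred, axis=1)
    nonzero = np.abs(ij).sum(axis=1) > 0
    return ij, resid, nonzero


def _refine_once(M: np.ndarray, both: np.ndarray, rel_tol: float) -> np.ndarray:
    ij, resid, nonzero = _index_residuals(M, both)
    tol = rel_tol * min(np.linalg.norm(M[:, 0]), np.linalg.norm(M[:, 1]))
    good = (resid < tol) & nonzero
    if good.sum() >= 4:
        A, _, _, _ = np.linalg.lstsq(ij[good], both[good], rcond=None)
        return A.T
    return M


def _explained(M: np.ndarray, both: np.ndarray, rel_tol: float = 0.25) -> int:
    """Number of vectors indexing as integer combinations of basis ``M``."""
    ij, resid, nonzero = _index_residuals(M, both)
    tol = rel_tol * min(np.linalg.norm(M[:, 0]), np.linalg.norm(M[:, 1]))
    return int(((resid < tol) & nonzero).sum())


def _is_detected(v: np.ndarray, both: np.ndarray) -> bool:
    d = np.linalg.norm(both - v[None, :], axis=1)
    return bool(d.min() < 0.25 * np.linalg.norm(v))


def _harmonic_support(g: np.ndarray, both: np.ndarray, kmax: int = 3) -> bool:
    """True if some detected peak sits at an integer multiple k*g (k >= 2).

    A genuine lattice direction shows higher diffraction orders (or higher
    ACF repeats); an isolated stray peak (noise, the envelope lobe of a
    finite patch) does not.
    """
    for k in range(2, kmax + 1):
        d = np.linalg.norm(both - k * g[None, :], axis=1)
        if d.min() < 0.25 * np.linalg.norm(g):
            return True
    return False


def _fit_basis(
    vectors: np.ndarray,
    collinear_tol: float = 0.08,
    prefer_dense: bool = False,
) -> np.ndarray:
    """Reduced basis generating a set of lattice vectors.

    Candidate bases are Lagrange-reduced pairs of the shortest vectors whose
    reduced generators are themselves detected peaks with higher-order
    support.  Each candidate is refined once by least squares and scored by
    how many vectors it explains at a strict tolerance; the best-scoring
    basis wins and is refined again with outlier rejection.  Stray vectors
    (noise, envelope sidelobes of a finite patch) are thereby outvoted.

    Ties are broken by cell area: ``prefer_dense=False`` favours the smaller
    cell (appropriate in the real/lag domain), ``prefer_dense=True`` the
    larger determinant (appropriate in reciprocal space, where the finer
    real cell corresponds to the coarser reciprocal basis being wrong).
    """
    vecs = _dedupe_signs(vectors)
    if len(vecs) < 2:
        raise ValueError("need at least two non-degenerate peak vectors")
    both = np.vstack([vecs, -vecs])
    n_cand = min(len(vecs), 8)
    candidates = []
    seen = set()
    for i in range(n_cand):
        for j in range(i + 1, n_cand):
            v1, v2 = vecs[i], vecs[j]
            cross = abs(v1[0] * v2[1] - v1[1] * v2[0])
            if cross / (np.linalg.norm(v1) * np.linalg.norm(v2)) <= collinear_tol:
                continue
            r1, r2 = _lagrange_reduce(v1.copy(), v2.copy())
            # both reduced generators must themselves be detected peaks;
            # a short difference vector of two nearby strays is not, and
            # would otherwise seed an over-dense basis explaining anything
            if not (_is_detected(r1, both) and _is_detected(r2, both)):
                continue
            if not (_harmonic_support(r1, both) and _harmonic_support(r2, both)):
                continue
            key = (
                round(float(np.linalg.norm(r1)), 2),
                round(float(np.linalg.norm(r2)), 2),
                round(float(abs(r1[0] * r2[1] - r1[1] * r2[0])), 2),
            )
            if key in seen:
                continue
            seen.add(key)
            candidates.append(np.column_stack([r1, r2]))
    if not candidates:
        raise ValueError("all peaks are collinear; lattice is degenerate")

    # consensus at strict tolerance on the raw candidate (refining before
    # scoring would let a spurious basis drift onto near-miss strays such
    # as the envelope lobes of a finite patch)
    def score(B: np.ndarray):
        n = _explained(B, both, rel_tol=0.08)
        det = abs(np.linalg.det(B))
        return (n, det if prefer_dense else -det)

    M = max(candidates, key=score)
    M = _refine_once(M, both, rel_tol=0.25)
    for _ in range(2):
        M = _refine_once(M, both, rel_tol=0.08)
    return M


def _cell_from_basis(v1: np.ndarray, v2: np.ndarray) -> Lattice2D:
    """Canonical Lattice2D from two generators: a >= b, gamma obtuse when an
    obtuse representative exists, orientation of a in (-90, 90]."""
    v1, v2 = _lagrange_reduce(np.asarray(v1, float), np.asarray(v2, float))
    b_vec, a_vec = (v1, v2) if np.linalg.norm(v2) >= np.linalg.norm(v1) else (v2, v1)
    a_len = float(np.linalg.norm(a_vec))
    b_len = float(np.linalg.norm(b_vec))
    cosg = float(np.dot(a_vec, b_vec) / (a_len * b_len))
    if cosg > 0:  # choose the obtuse representative
        b_vec = -b_vec
        cosg = -cosg
    gamma = math.degrees(math.acos(np.clip(cosg, -1.0, 1.0)))
    orientation = math.degrees(math.atan2(a_vec[1], a_vec[0]))
    if orientation > 90.0 or orientation <= -90.0:
        orientation = orientation - 180.0 if orientation > 0 else orientation + 180.0
    return Lattice2D(a_len=a_len, b_len=b_len, gamma=gamma, orientation=orientation)


def fit_unit_cell(peaks: AcfPeaks, collinear_tol: float = 0.08) -> Lattice2D:
    """Fit the primitive cell (a, b, gamma) from ACF lag vectors.

    Selects the two shortest non-collinear lag vectors, Lagrange-reduces
    them and refines the basis by least squares over all integer-indexing
    peaks; reports a >= b, gamma as the obtuse representative in (90, 180]
    when one exists, and the image-frame orientation of a.

    Note: the ACF of a crystal whose motif contains congruent sub-units also
    shows partial-overlap maxima at fractions of the cell (e.g. at a/3 for
    three similar dimers per cell along a).  If such pseudo-peaks are present
    in ``peaks`` the fit returns the sublattice they generate; for raw
    images prefer :func:`fit_unit_cell_from_image`, which works from the
    power spectrum, where a perfect crystal has no fractional peaks.
    """
    if len(peaks) < 2:
        raise ValueError("need at least two ACF peaks to fit a unit cell")
    M = _fit_basis(np.asarray(peaks.vectors, dtype=float), collinear_tol)
    return _cell_from_basis(M[:, 0], M[:, 1])


def fit_unit_cell_from_image(
    topo: Topograph,
    n_peaks: int = 30,
    collinear_tol: float = 0.08,
    max_spacing: float = 20.0,
) -> Lattice2D:
    """Fit the unit cell of a crystal image via its reciprocal lattice.

    The power spectrum of a 2D crystal is supported on the reciprocal
    lattice only — even weak Bragg orders (e.g. the (1,0) reflection of a
    cell whose three dimers are nearly, but not exactly, equivalent) appear
    as sharp peaks, and the partial-overlap pseudo-maxima that complicate
    the autocorrelation domain are absent.  The reciprocal basis Q fitted
    from the spectrum peaks is inverted (A = Q^{-T}) to the real-space cell.

    ``max_spacing`` (nm) bounds the largest credible lattice vector: spectrum
    peaks at larger real-space spacings (the broad envelope lobes of a
    finite, partially covered crystal patch) are excluded from the fit.
    """
    pset = estimate_periodicities(topo, n_peaks=n_peaks)
    peaks = [p for p in pset.peaks if p.spacing <= max_spacing]
    if len(peaks) < 2:
        raise ValueError("need at least two spectrum peaks to fit a unit cell")
    qvecs = np.array(
        [
            [
                math.cos(math.radians(p.direction)) / p.spacing,
                math.sin(math.radians(p.direction)) / p.spacing,
            ]
            for p in peaks
        ]
    )
    Q = _fit_basis(qvecs, collinear_tol, prefer_dense=True)
    A = np.linalg.inv(Q.T)
    return _cell_from_basis(A[:, 0], A[:, 1])
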