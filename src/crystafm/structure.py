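"""Atomic-structure operations: PDB input, Kabsch superposition, vertical
extent, 2D-crystal tiling, pseudo-AFM rendering and depth contours.

Structure files are in angstroms; every topograph this module produces is in
nm (conversion happens only at the module boundary).  The pseudo-AFM image
is the grayscale dilation of the molecular hard-sphere upper envelope by a
sphere-capped-cone tip, the standard model of tip convolution.
"""

from __future__ import annotations

import math
import string
import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .core import Lattice2D, Topograph

__all__ = [
    "AtomicStructure",
    "TipModel",
    "ContourSet",
    "read_structure",
    "kabsch_rmsd",
    "vertical_extent",
    "tile_crystal",
    "pseudo_afm",
    "depth_contours",
    "BONDI_RADII",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Bondi van der Waals radii, angstroms; fallback 1.7 for unlisted elements.
BONDI_RADII: Dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "ZN": 1.39, "MG": 1.73, "NA": 2.27, "K": 2.75,
}


@dataclass
class AtomicStructure:
    """Flat atom table: labels plus coordinates in angstroms."""

    element: np.ndarray
    atom_name: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    coord: np.ndarray  # (n, 3) angstrom

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.ndim != 2 or self.coord.shape[1] != 3:
            raise ValueError("coord must be (n, 3)")
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.coord)

    def select(self, mask: np.ndarray) -> "AtomicStructure":
        return AtomicStructure(
            element=self.element[mask],
            atom_name=self.atom_name[mask],
            res_name=self.res_name[mask],
            res_id=self.res_id[mask],
            chain_id=self.chain_id[mask],
            coord=self.coord[mask],
        )

    def chain(self, chain_id: str) -> "AtomicStructure":
        return self.select(self.chain_id == chain_id)

    def backbone(self) -> "AtomicStructure":
        return self.select(np.isin(self.atom_name, BACKBONE_ATOMS))

    @property
    def chains(self) -> List[str]:
        seen: List[str] = []
        for c in self.chain_id:
            if c not in seen:
                seen.append(str(c))
        return seen


def _from_atom_array(arr: bst.AtomArray) -> AtomicStructure:
    return AtomicStructure(
        element=np.asarray(arr.element, dtype="U4"),
        atom_name=np.asarray(arr.atom_name, dtype="U6"),
        res_name=np.asarray(arr.res_name, dtype="U5"),
        res_id=np.asarray(arr.res_id, dtype=int),
        chain_id=np.asarray(arr.chain_id, dtype="U8"),
        coord=np.asarray(arr.coord, dtype=float),
    )


def read_structure(path) -> AtomicStructure:
    """Read a PDB file; altlocs resolved to the highest-occupancy variant."""
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise ValueError(f"no atoms in PDB file {path}")
    return _from_atom_array(arr)


def _pair_by_identity(
    ref: AtomicStructure, mobile: AtomicStructure
) -> Tuple[np.ndarray, np.ndarray]:
    """1:1 correspondence by (residue number, atom name); error on mismatch."""

    def keys(s: AtomicStructure) -> List[Tuple[int, str]]:
        return [(int(r), str(a)) for r, a in zip(s.res_id, s.atom_name)]

    kr, km = keys(ref), keys(mobile)
    if len(set(kr)) != len(kr) or len(set(km)) != len(km):
        raise ValueError("duplicate (residue, atom) keys; select a single chain")
    only_ref = sorted(set(kr) - set(km))
    only_mob = sorted(set(km) - set(kr))
    if only_ref or only_mob:
        raise ValueError(
            "correspondence failure; unmatched residues/atoms: "
            f"ref-only={only_ref[:10]} mobile-only={only_mob[:10]}"
        )
    order_m = {k: i for i, k in enumerate(km)}
    idx_m = np.array([order_m[k] for k in kr], dtype=int)
    return ref.coord, mobile.coord[idx_m]


def common_backbone(
    ref: AtomicStructure, mobile: AtomicStructure
) -> Tuple[AtomicStructure, AtomicStructure]:
    """Restrict both structures to backbone atoms of shared residue numbers."""
    r = ref.backbone()
    m = mobile.backbone()
    rk = set(zip(r.res_id.tolist(), r.atom_name.tolist()))
    mk = set(zip(m.res_id.tolist(), m.atom_name.tolist()))
    common = rk & mk
    rmask = np.array([(i, a) in common for i, a in zip(r.res_id, r.atom_name)])
    mmask = np.array([(i, a) in common for i, a in zip(m.res_id, m.atom_name)])
    return r.select(rmask), m.select(mmask)


def kabsch_rmsd(
    ref: AtomicStructure,
    mobile: AtomicStructure,
    atom_names: Optional[Sequence[str]] = None,
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Optimal rigid superposition (Kabsch) of ``mobile`` onto ``ref``.

    Atoms are matched 1:1 by (residue number, atom name) after the optional
    ``atom_names`` filter.  Returns (RMSD in angstroms, rotation matrix R,
    translation t) such that mobile*R^T + t superposes onto ref; R is a
    proper rotation.
    """
    if atom_names is not None:
        ref = ref.select(np.isin(ref.atom_name, list(atom_names)))
        mobile = mobile.select(np.isin(mobile.atom_name, list(atom_names)))
    if len(ref) == 0 or len(mobile) == 0:
        raise ValueError("empty selection")
    P, Q = _pair_by_identity(ref, mobile)  # P: ref, Q: mobile
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = Q0.T @ P0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = Q0 @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - P0) ** 2, axis=1))))
    t = pc - qc @ R.T
    return rmsd, R, t


def vertical_extent(
    s: AtomicStructure,
    axis: Optional[Sequence[float]] = None,
    exclude_n_term: int = 0,
    exclude_c_term: int = 0,
    atom_names: Sequence[str] = BACKBONE_ATOMS,
) -> float:
    """Extent of the (backbone) atoms along ``axis``, in nm.

    ``exclude_n_term``/``exclude_c_term`` drop that many residues from each
    terminus (flexible tails).  With ``axis=None`` the principal axis of the
    selected atoms (largest-variance eigenvector) is used — for an elongated
    beta-sandwich monomer this is the membrane-normal height direction.
    """
    sel = s.select(np.isin(s.atom_name, list(atom_names)))
    if len(sel) == 0:
        raise ValueError("empty selection")
    res = np.unique(sel.res_id)
    keep = res
    if exclude_n_term:
        keep = keep[exclude_n_term:]
    if exclude_c_term:
        keep = keep[: len(keep) - exclude_c_term]
    if keep.size == 0:
        raise ValueError("all residues excluded")
    sel = sel.select(np.isin(sel.res_id, keep))
    coords = sel.coord
    if axis is None:
        centred = coords - coords.mean(axis=0)
        cov = centred.T @ centred
        w, v = np.linalg.eigh(cov)
        axis = v[:, np.argmax(w)]
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    proj = coords @ axis
    return float((proj.max() - proj.min()) / 10.0)  # angstrom -> nm


def _chain_labels(n: int) -> List[str]:
    letters = list(string.ascii_uppercase)
    if n <= len(letters):
        return letters[:n]
    return [f"{i:03d}" for i in range(n)]


def tile_crystal(
    unit: AtomicStructure, lattice: Lattice2D, m: int, n: int
) -> AtomicStructure:
    """Tile ``unit`` on the lattice: m copies along a, n along b.

    Lattice vectors (nm) are converted to angstroms and applied in the xy
    plane.  Chains are re-labelled uniquely per copy (single letters while
    they suffice, numeric labels beyond).
    """
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    a3 = np.append(lattice.a_vec * 10.0, 0.0)
    b3 = np.append(lattice.b_vec * 10.0, 0.0)
    n_copies = m * n
    base_chains = unit.chains
    labels = _chain_labels(n_copies * len(base_chains))
    parts: List[AtomicStructure] = []
    k = 0
    for i in range(m):
        for j in range(n):
            shift = i * a3 + j * b3
            copy = AtomicStructure(
                element=unit.element.copy(),
                atom_name=unit.atom_name.copy(),
                res_name=unit.res_name.copy(),
                res_id=unit.res_id.copy(),
                chain_id=unit.chain_id.copy(),
                coord=unit.coord + shift,
            )
            relabel = {c: labels[k * len(base_chains) + ci]
                       for ci, c in enumerate(base_chains)}
            copy.chain_id = np.array([relabel[str(c)] for c in copy.chain_id],
                                     dtype="U8")
            parts.append(copy)
            k += 1
    return AtomicStructure(
        element=np.concatenate([p.element for p in parts]),
        atom_name=np.concatenate([p.atom_name for p in parts]),
        res_name=np.concatenate([p.res_name for p in parts]),
        res_id=np.concatenate([p.res_id for p in parts]),
        chain_id=np.concatenate([p.chain_id for p in parts]),
        coord=np.concatenate([p.coord for p in parts]),
    )


@dataclass(frozen=True)
class TipModel:
    """Sphere-capped conical tip: apex radius R (nm), cone half-angle theta
    (degrees), lateral scan step (nm)."""

    radius: float = 0.5
    half_angle: float = 8.0
    scan_step: float = 0.25

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if not (0.0 < self.half_angle < 90.0):
            raise ValueError("half_angle must be in (0, 90)")
        if self.scan_step <= 0:
            raise ValueError("scan_step must be positive")

    def height(self, r: np.ndarray) -> np.ndarray:
        """Tip surface height above the apex at lateral distance r (nm).

        Spherical cap out to r = R cos(theta), then the tangent cone.
        """
        r = np.asarray(r, dtype=float)
        R = self.radius
        th = math.radians(self.half_angle)
        r_t = R * math.cos(th)
        sphere = R - np.sqrt(np.maximum(R**2 - np.minimum(r, r_t) ** 2, 0.0))
        cone = R - R * math.sin(th) + (r - r_t) / math.tan(th)
        return np.where(r <= r_t, sphere, cone)

    def support_radius(self, z_range: float) -> float:
        """Lateral radius at which the tip rises above ``z_range``."""
        R = self.radius
        th = math.radians(self.half_angle)
        r_t = R * math.cos(th)
        if z_range <= R - R * math.sin(th):
            return r_t
        return r_t + (z_range - (R - R * math.sin(th))) * math.tan(th)


def rasterize_envelope(
    s: AtomicStructure, step: float, pad: float = 2.0
) -> Topograph:
    """Hard-sphere upper envelope of the structure on a grid (heights in nm).

    Each atom contributes z + sqrt(r_vdw^2 - d^2) inside its van der Waals
    disc; height zero is the lowest point of the envelope's supporting
    plane (min over atoms of z - r_vdw).
    """
    if len(s) == 0:
        raise ValueError("empty structure")
    xyz = s.coord / 10.0  # nm
    radii = np.array(
        [BONDI_RADII.get(str(e).upper(), 1.7) for e in s.element]
    ) / 10.0
    x0, y0 = xyz[:, 0].min() - pad, xyz[:, 1].min() - pad
    x1, y1 = xyz[:, 0].max() + pad, xyz[:, 1].max() + pad
    z0 = float((xyz[:, 2] - radii).min())
    n_cols = int(math.ceil((x1 - x0) / step)) + 1
    n_rows = int(math.ceil((y1 - y0) / step)) + 1
    heights = np.zeros((n_rows, n_cols))
    for (x, y, z), r in zip(xyz, radii):
        ci = int(round((x - x0) / step))
        ri = int(round((y - y0) / step))
        k = int(math.ceil(r / step))
        rs = slice(max(ri - k, 0), min(ri + k + 1, n_rows))
        cs = slice(max(ci - k, 0), min(ci + k + 1, n_cols))
        yy, xx = np.mgrid[rs, cs]
        d2 = (xx * step + x0 - x) ** 2 + (yy * step + y0 - y) ** 2
        inside = d2 <= r**2
        zsurf = np.where(inside, z + np.sqrt(np.maximum(r**2 - d2, 0.0)) - z0, 0.0)
        heights[rs, cs] = np.maximum(heights[rs, cs], zsurf)
    return Topograph(heights=heights, pixel_size=step)


def pseudo_afm(
    source: Union[AtomicStructure, Topograph], tip: TipModel
) -> Topograph:
    """Tip-convolved (grayscale-dilated) image of a surface or structure.

    out(x) = max_u [surface(u) - tip(u - x)]: the height at which the tip
    apex first touches the surface when centred at x.  Dilation is extensive
    (out >= surface) and leaves a flat surface unchanged.
    """
    if isinstance(source, AtomicStructure):
        surf = rasterize_envelope(source, tip.scan_step)
    else:
        surf = source
    h = surf.heights
    if h.size == 0:
        raise ValueError("empty source")
    z_range = float(h.max() - h.min())
    r_sup = tip.support_radius(z_range)
    k = int(math.floor(r_sup / surf.pixel_size))
    if k < 1:
        return surf.with_heights(h.copy())
    yy, xx = np.mgrid[-k : k + 1, -k : k + 1]
    rr = np.hypot(xx, yy) * surf.pixel_size
    kernel = -tip.height(rr)
    out = ndimage.grey_dilation(h, structure=kernel, mode="nearest")
    return surf.with_heights(out)


@dataclass
class ContourSet:
    """Iso-height polylines at depths below the surface top."""

    levels: List[float]  # nm below top, increasing depth
    polylines: List[List[np.ndarray]]  # per level, list of (k, 2) nm (x, y)
    top: float  # absolute top height, nm
    empty_levels: List[float]


def depth_contours(
    topo: Topograph,
    levels: Sequence[float],
    exclude_mask: Optional[np.ndarray] = None,
) -> ContourSet:
    """Contours at ``top - level`` for each depth in ``levels`` (nm below top).

    ``top`` is the global maximum height (after applying an optional
    exclusion mask).  A level below the global minimum yields an empty
    contour list and is flagged in ``empty_levels``.
    """
    from skimage import measure

    h = topo.heights
    if np.allclose(h, h.flat[0]):
        raise ValueError("constant topograph has no contours")
    hm = h if exclude_mask is None else np.where(exclude_mask, -np.inf, h)
    top = float(np.max(hm))
    levels = [float(l) for l in levels]
    if any(l < 0 for l in levels):
        raise ValueError("levels are depths below the top and must be >= 0")
    polylines: List[List[np.ndarray]] = []
    empty: List[float] = []
    for depth in levels:
        z = top - depth
        if z < h.min():
            warnings.warn(f"contour level {depth} nm below top is under the "
                          "global minimum; empty contour")
            polylines.append([])
            empty.append(depth)
            continue
        cs = measure.find_contours(h, z)
        # (row, col) pixel indices -> (x, y) nm at pixel centres
        polys = [
            np.column_stack([(c[:, 1] + 0.5) * topo.pixel_size,
                             (c[:, 0] + 0.5) * topo.pixel_size])
            for c in cs
        ]
        polylines.append(polys)
        if not polys:
            empty.append(depth)
    return ContourSet(levels=levels, polylines=polylines, top=top,
                      empty_levels=empty)
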