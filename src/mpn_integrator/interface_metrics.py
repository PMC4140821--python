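"""Interface geometry: solvent-accessible surface area (Shrake–Rupley),
buried area, residue contact maps, interface membership and the
Lawrence–Colman shape-complementarity statistic.

All operations work on heavy atoms only and are deterministic: sphere
sampling uses a Fibonacci point set, so repeated calls on the same
coordinates give bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._geometry import fibonacci_sphere
from .errors import RadiusError, UndefinedInterfaceError
from .structure_io import Structure, combine

#: van der Waals radii, Å (Chothia-like set)
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "H": 1.20, "D": 1.20,
}
DEFAULT_RADIUS = 1.70
PROBE_RADIUS = 1.4
N_POINTS = 960

ResidueKey = tuple[str, int, str | None]


@dataclass
class SasaResult:
    per_atom: np.ndarray          # Å², parallel to heavy-atom iteration order
    per_residue: dict[ResidueKey, float]
    total: float
    atom_keys: list[tuple[ResidueKey, str]]


def _radii_for(structure: Structure, default_radius: float | None = DEFAULT_RADIUS):
    coords, radii, keys, residues = [], [], [], []
    missing = []
    for res, atom in structure.atoms(heavy_only=True):
        el = atom.element.upper()
        r = VDW_RADII.get(el)
        if r is None:
            if default_radius is None:
                missing.append(f"{res.key}/{atom.name}({atom.element})")
                continue
            r = default_radius
        coords.append(atom.coord)
        radii.append(r)
        keys.append((res.key, atom.name))
        residues.append(res.key)
    if missing:
        raise RadiusError("no van der Waals radius for atoms: " + ", ".join(missing))
    return np.asarray(coords, dtype=float), np.asarray(radii, dtype=float), keys, residues


def canonical_orientation(coords: np.ndarray) -> np.ndarray:
    """Deterministic molecule-frame rotation (principal axes, covariant sign
    fix via the atom farthest from the centroid). Sampling spheres oriented
    by this frame make Shrake–Rupley areas exactly rigid-transform invariant."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        return np.eye(3)
    c = coords - coords.mean(axis=0)
    w, v = np.linalg.eigh(c.T @ c)
    v = v[:, ::-1]  # descending variance
    far = c[int(np.argmax((c**2).sum(axis=1)))]
    for k in range(3):
        d = float(v[:, k] @ far)
        if d < 0:
            v[:, k] = -v[:, k]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return v


def _sasa_areas(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float,
    n_points: int,
    orientation: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom Shrake–Rupley accessible area for pre-extracted spheres."""
    n = len(coords)
    if n == 0:
        return np.empty(0)
    if orientation is None:
        orientation = canonical_orientation(coords)
    sphere = fibonacci_sphere(n_points) @ orientation.T
    ext = radii + probe_radius
    tree = cKDTree(coords)
    areas = np.empty(n)
    rmax = ext.max()
    for i in range(n):
        pts = coords[i] + ext[i] * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], ext[i] + rmax) if j != i]
        if neigh:
            nc = coords[neigh]
            nr = ext[neigh]
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nr**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * ext[i] ** 2
    return areas


def sasa(
    s: Structure,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_POINTS,
    default_radius: float | None = DEFAULT_RADIUS,
    orientation: np.ndarray | None = None,
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area over heavy atoms.

    `orientation` overrides the canonical sampling-sphere frame; pass one
    shared frame when areas of parts and whole must cancel exactly.
    """
    coords, radii, keys, residues = _radii_for(s, default_radius)
    areas = _sasa_areas(coords, radii, probe_radius, n_points, orientation)
    per_res: dict[ResidueKey, float] = {}
    for rk, a in zip(residues, areas):
        per_res[rk] = per_res.get(rk, 0.0) + float(a)
    return SasaResult(areas, per_res, float(areas.sum()), keys)


def buried_area(
    a: Structure,
    b: Structure,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_POINTS,
    both_sides: bool = True,
) -> float:
    """Total interface area SASA(a) + SASA(b) − SASA(a∪b), Å² (both sides)."""
    ab = combine(a, b, id="ab")
    ori = canonical_orientation(ab.coords(heavy_only=True))
    total = (
        sasa(a, probe_radius, n_points, orientation=ori).total
        + sasa(b, probe_radius, n_points, orientation=ori).total
        - sasa(ab, probe_radius, n_points, orientation=ori).total
    )
    total = max(total, 0.0)
    return total if both_sides else total / 2.0


def per_residue_dsasa(
    a: Structure,
    b: Structure,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_POINTS,
) -> tuple[dict[ResidueKey, float], dict[ResidueKey, float]]:
    """ΔSASA per residue of each partner upon complexation."""
    ab = combine(a, b, id="ab")
    ori = canonical_orientation(ab.coords(heavy_only=True))
    free_a = sasa(a, probe_radius, n_points, orientation=ori).per_residue
    free_b = sasa(b, probe_radius, n_points, orientation=ori).per_residue
    bound = sasa(ab, probe_radius, n_points, orientation=ori).per_residue
    da = {k: v - bound.get(k, 0.0) for k, v in free_a.items()}
    db = {k: v - bound.get(k, 0.0) for k, v in free_b.items()}
    return da, db


def contact_pairs(a: Structure, b: Structure, cutoff: float = 5.0):
    """Residue × residue matrix of heavy-atom contact counts within `cutoff` Å.

    Returns (DataFrame indexed by residue keys of `a`, columns keys of `b`,
    total count). Rows/columns appear in structure order.
    """
    keys_a, coords_a, owner_a = [], [], []
    for res in a.residues():
        keys_a.append(res.key)
        for atom in res.heavy_atoms():
            coords_a.append(atom.coord)
            owner_a.append(len(keys_a) - 1)
    keys_b, coords_b, owner_b = [], [], []
    for res in b.residues():
        keys_b.append(res.key)
        for atom in res.heavy_atoms():
            coords_b.append(atom.coord)
            owner_b.append(len(keys_b) - 1)
    mat = np.zeros((len(keys_a), len(keys_b)), dtype=int)
    if cutoff > 0 and coords_a and coords_b:
        ta = cKDTree(np.asarray(coords_a))
        tb = cKDTree(np.asarray(coords_b))
        for ia, neigh in enumerate(ta.query_ball_tree(tb, cutoff)):
            for ib in neigh:
                mat[owner_a[ia], owner_b[ib]] += 1
    df = pd.DataFrame(
        mat,
        index=pd.Index(keys_a, tupleize_cols=False),
        columns=pd.Index(keys_b, tupleize_cols=False),
    )
    return df, int(mat.sum())


def interface_residues(
    a: Structure,
    b: Structure,
    dsasa_min: float = 1.0,
    contact_cutoff: float = 5.0,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_POINTS,
) -> tuple[set[ResidueKey], set[ResidueKey]]:
    """Residues interfacial by ΔSASA > dsasa_min OR any heavy-atom contact
    within contact_cutoff (union rule)."""
    da, db = per_residue_dsasa(a, b, probe_radius, n_points)
    set_a = {k for k, v in da.items() if v > dsasa_min}
    set_b = {k for k, v in db.items() if v > dsasa_min}
    contacts, _ = contact_pairs(a, b, contact_cutoff)
    arr = contacts.to_numpy()
    for i, k in enumerate(contacts.index):
        if arr[i, :].any():
            set_a.add(k)
    for j, k in enumerate(contacts.columns):
        if arr[:, j].any():
            set_b.add(k)
    return set_a, set_b


# ---------------------------------------------------------------------------
# shape complementarity


def surface_dots(
    s: Structure,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_POINTS,
    default_radius: float | None = DEFAULT_RADIUS,
    orientation: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Accessible surface dots and outward unit normals for one molecule.

    Dots sit on probe-extended atom spheres and are kept when not occluded
    by any other atom of the same molecule.
    """
    coords, radii, _, _ = _radii_for(s, default_radius)
    if orientation is None:
        orientation = canonical_orientation(coords)
    sphere = fibonacci_sphere(n_points) @ orientation.T
    ext = radii + probe_radius
    tree = cKDTree(coords)
    dots, normals = [], []
    rmax = ext.max() if len(ext) else 0.0
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], ext[i] + rmax) if j != i]
        keep = np.ones(len(pts), dtype=bool)
        if neigh:
            nc = coords[neigh]
            nr = ext[neigh]
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            keep = ~(d2 < (nr**2)[None, :]).any(axis=1)
        if keep.any():
            dots.append(pts[keep])
            normals.append(sphere[keep])
    if not dots:
        return np.empty((0, 3)), np.empty((0, 3))
    return np.vstack(dots), np.vstack(normals)


def sc_from_dots(
    dots_a: np.ndarray,
    normals_a: np.ndarray,
    dots_b: np.ndarray,
    normals_b: np.ndarray,
    w: float = 0.5,
) -> float:
    """Lawrence–Colman statistic from explicit buried-dot sets.

    For each dot x of one side with nearest partner dot x' (distance d),
    S(x) = (n_x · −n'_x) · exp(−w d²); the statistic is the mean of the two
    per-side medians and lies in [−1, 1] (1 = perfectly apposed surfaces).
    """
    if len(dots_a) == 0 or len(dots_b) == 0:
        raise UndefinedInterfaceError("no buried dots on one side of the interface")

    def side(d1, n1, d2, n2):
        tree = cKDTree(d2)
        dist, idx = tree.query(d1)
        s = np.einsum("ij,ij->i", n1, -n2[idx]) * np.exp(-w * dist**2)
        return float(np.median(s))

    return 0.5 * (side(dots_a, normals_a, dots_b, normals_b)
                  + side(dots_b, normals_b, dots_a, normals_a))


def shape_complementarity(
    a: Structure,
    b: Structure,
    w: float = 0.5,
    band: float = 1.5,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_POINTS,
) -> float:
    """Shape complementarity of the a/b interface.

    Buried dots of each side are accessible-surface dots lying within `band`
    Å of the partner's dot set; the statistic is computed over those.
    """
    ori = canonical_orientation(combine(a, b, id="ab").coords(heavy_only=True))
    da, na = surface_dots(a, probe_radius, n_points, orientation=ori)
    db, nb = surface_dots(b, probe_radius, n_points, orientation=ori)
    if len(da) == 0 or len(db) == 0:
        raise UndefinedInterfaceError("a molecule exposes no surface dots")
    ta, tb = cKDTree(da), cKDTree(db)
    dist_ab, _ = tb.query(da)
    dist_ba, _ = ta.query(db)
    sel_a = dist_ab <= band
    sel_b = dist_ba <= band
    if not sel_a.any() or not sel_b.any():
        raise UndefinedInterfaceError("no buried surface dots: partners not in contact")
    return sc_from_dots(da[sel_a], na[sel_a], db[sel_b], nb[sel_b], w=w)


@dataclass
class InterfaceReport:
    buried_area_total: float
    contact_matrix: pd.DataFrame
    contact_total: int
    interface_residues_a: set[ResidueKey]
    interface_residues_b: set[ResidueKey]
    sc: float | None


def interface_report(
    a: Structure,
    b: Structure,
    dsasa_min: float = 1.0,
    contact_cutoff: float = 5.0,
    n_points: int = N_POINTS,
) -> InterfaceReport:
    """Bundle of the interface metrics for one pair of partners."""
    ba = buried_area(a, b, n_points=n_points)
    matrix, total = contact_pairs(a, b, contact_cutoff)
    ia, ib = interface_residues(a, b, dsasa_min, contact_cutoff, n_points=n_points)
    try:
        sc = shape_complementarity(a, b, n_points=n_points)
    except UndefinedInterfaceError:
        sc = None
    return InterfaceReport(ba, matrix, total, ia, ib, sc)
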