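"""Density maps: CCP4/MRC I/O, Gaussian map simulation from models,
cross-correlation scoring and rigid-body fitting.

A map is a 3-D scalar grid with per-axis voxel size and an origin giving the
Å position of the center of voxel (0,0,0), axes ordered x,y,z. Simulated
maps place one isotropic Gaussian per atom with FWHM equal to the nominal
resolution and amplitude proportional to the atomic number. Rigid fitting
scans translations by FFT cross-correlation on a coarse rotation grid and
polishes the best placement with a derivative-free 6-parameter refinement
of the local (model-proximal) correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy import fft as sfft
from scipy import ndimage, optimize
from scipy.spatial import cKDTree

from ._geometry import dedup_rotations, euler_zyz_to_matrix, axis_angle_to_matrix
from .errors import DensityError
from .structure_io import Pose, Structure, apply_pose

SIGMA_PER_RESOLUTION = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM = resolution


@dataclass
class DensityMap:
    grid: np.ndarray                 # (nx, ny, nz) float
    voxel_size: np.ndarray           # Å per axis (3,)
    origin: np.ndarray               # Å position of voxel (0,0,0) center
    resolution: float | None = None  # nominal Å

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float).ravel(), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.grid.ndim != 3:
            raise DensityError(f"grid must be 3-D, got shape {self.grid.shape}")
        if np.any(self.voxel_size <= 0):
            raise DensityError(f"voxel size must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.grid)):
            raise DensityError("grid contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        n = self.grid.shape[axis]
        return self.origin[axis] + self.voxel_size[axis] * np.arange(n)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.voxel_size

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.voxel_size.copy(), self.origin.copy(), self.resolution)


def read_map(path, resolution: float | None = None) -> DensityMap:
    """Read a CCP4/MRC map; axes normalized to x,y,z order.

    The origin honors the ORIGIN header record when nonzero, else
    nxstart × voxel.
    """
    try:
        m = gemmi.read_ccp4_map(str(path), setup=True)
    except (RuntimeError, ValueError, OSError) as exc:
        raise DensityError(f"cannot read map {path}: {exc}") from exc
    grid = np.array(m.grid, copy=True).astype(float)
    cell = m.grid.unit_cell
    n = np.array(grid.shape, dtype=float)
    voxel = np.array([cell.a, cell.b, cell.c]) / n
    header_origin = np.array([m.header_float(i) for i in (50, 51, 52)], dtype=float)
    if np.any(header_origin != 0.0):
        origin = header_origin
    else:
        nstart = np.array([m.header_i32(i) for i in (5, 6, 7)], dtype=float)
        origin = nstart * voxel
    return DensityMap(grid, voxel, origin, resolution)


def write_map(m: DensityMap, path) -> None:
    nx, ny, nz = m.shape
    g = gemmi.FloatGrid(nx, ny, nz)
    g.spacegroup = gemmi.find_spacegroup_by_name("P1")
    g.set_unit_cell(
        gemmi.UnitCell(
            nx * m.voxel_size[0], ny * m.voxel_size[1], nz * m.voxel_size[2],
            90, 90, 90,
        )
    )
    np.array(g, copy=False)[:] = m.grid.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = g
    ccp4.update_ccp4_header()
    for i, v in zip((50, 51, 52), m.origin):
        ccp4.set_header_float(i, float(v))
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# simulation


def _atomic_weights(s: Structure) -> tuple[np.ndarray, np.ndarray]:
    coords, weights = [], []
    for _, a in s.atoms(heavy_only=True):
        coords.append(a.coord)
        weights.append(float(gemmi.Element(a.element).atomic_number) or 6.0)
    if not coords:
        raise DensityError("structure has no heavy atoms to simulate")
    return np.asarray(coords), np.asarray(weights)


def add_gaussians(
    grid: np.ndarray,
    origin: np.ndarray,
    voxel: np.ndarray,
    coords: np.ndarray,
    weights: np.ndarray,
    sigma: float,
    cutoff_sigmas: float = 4.0,
) -> None:
    """Accumulate w·exp(−|v−x|²/2σ²) for each atom into `grid` in place."""
    half = cutoff_sigmas * sigma
    shape = grid.shape
    for x, w in zip(coords, weights):
        lo = np.maximum(np.ceil((x - half - origin) / voxel).astype(int), 0)
        hi = np.minimum(np.floor((x + half - origin) / voxel).astype(int), np.array(shape) - 1)
        if np.any(lo > hi):
            continue
        ax = [origin[d] + voxel[d] * np.arange(lo[d], hi[d] + 1) - x[d] for d in range(3)]
        r2 = (
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        )
        grid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += w * np.exp(
            -r2 / (2.0 * sigma**2)
        )


def simulate_map(
    s: Structure,
    resolution: float,
    voxel_size: float,
    pad: float = 10.0,
    on_grid: DensityMap | None = None,
) -> DensityMap:
    """Simulate a density map from a structure at the given nominal resolution.

    σ = resolution / (2√(2 ln 2)) so the kernel FWHM equals the resolution.
    When `on_grid` is given the density is accumulated on that map's grid
    geometry (values ignored); otherwise a padded bounding-box grid is built.
    """
    if on_grid is None and voxel_size > resolution / 2.0:
        raise DensityError(
            f"voxel {voxel_size} Å undersamples resolution {resolution} Å (limit {resolution / 2:.2f})"
        )
    coords, weights = _atomic_weights(s)
    sigma = resolution * SIGMA_PER_RESOLUTION
    if on_grid is not None:
        origin = on_grid.origin
        voxel = on_grid.voxel_size
        grid = np.zeros(on_grid.shape)
    else:
        lo = coords.min(axis=0) - pad
        hi = coords.max(axis=0) + pad
        voxel = np.full(3, float(voxel_size))
        shape = np.ceil((hi - lo) / voxel).astype(int) + 1
        origin = lo
        grid = np.zeros(tuple(shape))
    add_gaussians(grid, origin, voxel, coords, weights, sigma)
    return DensityMap(grid, voxel, origin, resolution)


# ---------------------------------------------------------------------------
# correlation


def _resample_onto(target: DensityMap, source: DensityMap) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear resample of `source` values at `target` voxel centers.

    Returns (values, validity mask for voxels inside the source grid).
    """
    idx = [
        (target.voxel_centers_axis(d) - source.origin[d]) / source.voxel_size[d]
        for d in range(3)
    ]
    I, J, K = np.meshgrid(idx[0], idx[1], idx[2], indexing="ij")
    coords = np.vstack([I.ravel(), J.ravel(), K.ravel()])
    vals = ndimage.map_coordinates(source.grid, coords, order=1, mode="constant", cval=np.nan)
    vals = vals.reshape(target.shape)
    valid = np.isfinite(vals)
    return np.where(valid, vals, 0.0), valid


def model_proximal_mask(m: DensityMap, s: Structure, radius: float = 5.0) -> np.ndarray:
    """Boolean grid: voxels whose center lies within `radius` Å of any heavy atom."""
    coords = s.coords(heavy_only=True)
    if len(coords) == 0:
        raise DensityError("structure has no heavy atoms for masking")
    ax = [m.voxel_centers_axis(d) for d in range(3)]
    I, J, K = np.meshgrid(ax[0], ax[1], ax[2], indexing="ij")
    centers = np.column_stack([I.ravel(), J.ravel(), K.ravel()])
    tree = cKDTree(coords)
    d, _ = tree.query(centers, distance_upper_bound=radius)
    return np.isfinite(d).reshape(m.shape)


def ccc(
    a: DensityMap,
    b: DensityMap,
    mask: np.ndarray | None = None,
    structure: Structure | None = None,
    radius: float = 5.0,
) -> float:
    """Pearson cross-correlation of two maps on `a`'s grid.

    `mask` (boolean, on a's grid) or `structure` (model-proximal mask of
    voxels within `radius` Å of its atoms — the "local" correlation)
    restrict the voxel set.
    """
    if a.shape == b.shape and np.allclose(a.voxel_size, b.voxel_size) and np.allclose(a.origin, b.origin):
        vals, valid = b.grid, np.ones(a.shape, dtype=bool)
    else:
        vals, valid = _resample_onto(a, b)
    sel = valid
    if structure is not None:
        sel = sel & model_proximal_mask(a, structure, radius)
    if mask is not None:
        sel = sel & mask
    x = a.grid[sel]
    y = vals[sel]
    if x.size < 2:
        raise DensityError("empty overlap/mask: ccc undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise DensityError("zero variance in masked region: ccc undefined")
    return float((xc * yc).sum() / denom)


# ---------------------------------------------------------------------------
# rigid fitting


@dataclass
class RigidFitResult:
    pose: Pose
    ccc: float
    candidates: list[tuple[Pose, float]] = field(default_factory=list)  # (pose, scan score)


def _correlation_peaks(corr: np.ndarray, n_peaks: int, min_sep_vox: int) -> list[tuple[tuple[int, int, int], float]]:
    """Greedy non-maximum suppression over an FFT correlation volume."""
    flat = np.argsort(corr.ravel())[::-1]
    shape = corr.shape
    peaks: list[tuple[tuple[int, int, int], float]] = []
    half = np.array(shape) / 2.0
    for fi in flat[: 50 * n_peaks]:
        ijk = np.array(np.unravel_index(fi, shape))
        # wrapped displacement comparison against accepted peaks
        ok = True
        for (p, _) in peaks:
            d = np.abs(ijk - np.array(p))
            d = np.minimum(d, np.array(shape) - d)
            if np.all(d < min_sep_vox):
                ok = False
                break
        if ok:
            peaks.append((tuple(int(v) for v in ijk), float(corr[tuple(ijk)])))
        if len(peaks) >= n_peaks:
            break
    return peaks


def _shift_to_vector(ijk, shape, voxel) -> np.ndarray:
    s = np.array(ijk, dtype=float)
    s = np.where(s > np.array(shape) / 2.0, s - np.array(shape), s)
    return s * voxel


def rigid_fit(
    s: Structure,
    m: DensityMap,
    resolution: float | None = None,
    rot_step_deg: float = 30.0,
    local_refine: bool = True,
    n_peaks: int = 3,
    peak_min_sep: float = 8.0,
    mask_radius: float = 5.0,
) -> RigidFitResult:
    """Fit a subunit rigidly into a map.

    An exhaustive FFT translation scan of the simulated subunit density
    against the map is run for every orientation of a z-y-z Euler grid at
    `rot_step_deg` (duplicate rotations removed); the best-scoring
    placements are re-scored by local ccc and the winner optionally refined
    over all six rigid parameters with Nelder–Mead. Deterministic.
    """
    resolution = resolution or m.resolution
    if resolution is None:
        raise DensityError("resolution needed to simulate the subunit density")
    coords, weights = _atomic_weights(s)
    extent = coords.max(axis=0) - coords.min(axis=0)
    if np.any(extent > np.array(m.shape) * m.voxel_size):
        raise DensityError("subunit larger than the map along some axis")
    center_lig = coords.mean(axis=0)
    map_center = m.origin + m.voxel_size * (np.array(m.shape) - 1) / 2.0
    sigma = resolution * SIGMA_PER_RESOLUTION

    target = m.grid - m.grid.mean()
    Ft = sfft.rfftn(target)

    step = np.deg2rad(rot_step_deg)
    phis = np.arange(0.0, 2 * np.pi - 1e-9, step)
    thetas = np.arange(0.0, np.pi + 1e-9, step)
    psis = np.arange(0.0, 2 * np.pi - 1e-9, step)
    mats = [euler_zyz_to_matrix(p, t, q) for p in phis for t in thetas for q in psis]
    mats = [mats[i] for i in dedup_rotations(mats, tol=1e-6)]

    raw_candidates: list[tuple[np.ndarray, np.ndarray, float]] = []
    for R in mats:
        rc = (coords - center_lig) @ R.T + map_center
        lig = np.zeros(m.shape)
        add_gaussians(lig, m.origin, m.voxel_size, rc, weights, sigma)
        lig -= lig.mean()
        corr = sfft.irfftn(Ft * np.conj(sfft.rfftn(lig)), s=m.shape)
        sep_vox = max(int(np.ceil(peak_min_sep / float(m.voxel_size.min()))), 1)
        for ijk, score in _correlation_peaks(corr, n_peaks, sep_vox):
            shift = _shift_to_vector(ijk, m.shape, m.voxel_size)
            raw_candidates.append((R, shift, score))

    raw_candidates.sort(key=lambda c: -c[2])
    # dedup across rotations by final ligand-center placement
    picked: list[tuple[np.ndarray, np.ndarray, float]] = []
    for R, shift, score in raw_candidates:
        center = map_center + shift
        if all(np.linalg.norm(center - (map_center + s2)) >= peak_min_sep
               or np.linalg.norm(R - R2) > 1e-6
               for R2, s2, _ in picked) or not picked:
            if all(np.linalg.norm(center - (map_center + s2)) >= peak_min_sep for _, s2, _ in picked):
                picked.append((R, shift, score))
        if len(picked) >= max(n_peaks, 3):
            break
    if not picked:
        raise DensityError("translation scan produced no candidate placements")

    def pose_from(R, shift):
        t = map_center + shift - R @ center_lig
        return Pose(R, t)

    def local_ccc(pose: Pose) -> float:
        placed = apply_pose(s, pose)
        sim = simulate_map(placed, resolution, float(m.voxel_size[0]), on_grid=m)
        return ccc(m, sim, structure=placed, radius=mask_radius)

    scored = [(pose_from(R, sh), sc, local_ccc(pose_from(R, sh))) for R, sh, sc in picked[:3]]
    scored.sort(key=lambda x: -x[2])
    best_pose, _, best_ccc = scored[0]

    if local_refine:
        R0, t0 = best_pose.rotation, best_pose.translation

        def objective(p):
            ang = np.linalg.norm(p[:3])
            dR = np.eye(3) if ang < 1e-12 else axis_angle_to_matrix(p[:3], ang)
            pose = Pose(dR @ R0, dR @ t0 + p[3:])
            try:
                return -local_ccc(pose)
            except DensityError:
                return 1.0

        # explicit simplex: ~6° rotation steps, one-voxel translation steps
        steps = np.array([0.1, 0.1, 0.1, *m.voxel_size])
        simplex = np.vstack([np.zeros(6), np.diag(steps)])
        res = optimize.minimize(
            objective,
            np.zeros(6),
            method="Nelder-Mead",
            options={"maxiter": 400, "xatol": 1e-3, "fatol": 1e-7, "initial_simplex": simplex},
        )
        if -res.fun > best_ccc:
            p = res.x
            ang = np.linalg.norm(p[:3])
            dR = np.eye(3) if ang < 1e-12 else axis_angle_to_matrix(p[:3], ang)
            best_pose = Pose(dR @ R0, dR @ t0 + p[3:])
            best_ccc = float(-res.fun)

    cands = [(pose, float(sc)) for pose, sc, _ in scored]
    return RigidFitResult(best_pose, float(best_ccc), cands)
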