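"""Rigid-body docking pose handling: grid generation, ZDOCK-style tables,
experiment-constrained filtering, composite re-ranking and pose clustering.

The generator is a desk-scale Euler-grid sampler (it places the ligand in
touching contact along the center-center axis for every unique orientation);
it exists so the filtering/re-ranking pipeline can be exercised without an
external FFT docking engine. Filtering applies hard experimental
constraints — passive residues that must stay out of the interface,
required residues that must be in it, a buried-area window and a shape
complementarity floor — and the survivors are re-ranked by a weighted
z-score composite of the interfacial metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._geometry import dedup_rotations, euler_zyz_to_matrix
from .errors import ConstraintError, FormatError, ParameterError
from .interface_metrics import (
    ResidueKey,
    contact_pairs,
    sasa,
    sc_from_dots,
    surface_dots,
)
from .structure_io import Pose, Structure, apply_pose, combine


@dataclass
class PoseSet:
    receptor: Structure
    ligand: Structure
    poses: list[Pose] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.pose_id for p in self.poses]
        if len(ids) != len(set(ids)):
            raise ValueError("pose ids not unique")

    def posed_ligand(self, pose: Pose) -> Structure:
        return apply_pose(self.ligand, pose)


@dataclass
class ConstraintSet:
    """Experimental docking constraints.

    passive_residues must not be interfacial (tolerance = allowed count of
    violations); required residues per partner must all be interfacial;
    buried area must fall in the window; sc must reach sc_min.
    """

    passive_residues: set[ResidueKey] = field(default_factory=set)
    required_receptor: set[ResidueKey] = field(default_factory=set)
    required_ligand: set[ResidueKey] = field(default_factory=set)
    buried_area_window: tuple[float, float] = (1200.0, 1800.0)
    sc_min: float = 0.5
    passive_tolerance: int = 0
    weights: dict[str, float] = field(
        default_factory=lambda: {"sc": 1.0, "buried": 1.0, "conservation": 1.0, "contacts": 1.0}
    )

    def __post_init__(self) -> None:
        lo, hi = self.buried_area_window
        if lo > hi:
            raise ParameterError(f"buried-area window min {lo} > max {hi}")

    def validate_against(self, receptor: Structure, ligand: Structure) -> None:
        keys = {r.key for r in receptor.residues()} | {r.key for r in ligand.residues()}
        for name, group in (
            ("passive", self.passive_residues),
            ("required_receptor", self.required_receptor),
            ("required_ligand", self.required_ligand),
        ):
            missing = [k for k in group if k not in keys]
            if missing:
                raise ConstraintError(f"{name} constraint references missing residues: {missing}")


# ---------------------------------------------------------------------------
# pose generation


def touch_along_axis(
    receptor: Structure,
    ligand: Structure,
    rotation: np.ndarray,
    axis: np.ndarray | None = None,
    sep_window: tuple[float, float] = (3.0, 4.5),
    pose_id: int = 0,
) -> Pose:
    """Pose rotating the ligand about its centroid and sliding it along the
    receptor→ligand center axis until the minimal heavy-atom separation
    falls inside `sep_window`."""
    rec = receptor.coords(heavy_only=True)
    lig = ligand.coords(heavy_only=True)
    c_r = rec.mean(axis=0)
    c_l = lig.mean(axis=0)
    if axis is None:
        axis = c_l - c_r
    axis = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(axis)
    axis = np.array([0.0, 0.0, 1.0]) if nrm < 1e-9 else axis / nrm
    rotated = (lig - c_l) @ np.asarray(rotation).T
    tree = cKDTree(rec)

    def min_sep(t: float) -> float:
        d, _ = tree.query(rotated + c_r + t * axis)
        return float(d.min())

    t_lo, t_hi = 0.0, 1.0
    while min_sep(t_hi) < sep_window[1] and t_hi < 1e4:
        t_hi *= 2.0
    # converge to the window midpoint so every pose touches identically
    target = 0.5 * (sep_window[0] + sep_window[1])
    for _ in range(60):
        mid = 0.5 * (t_lo + t_hi)
        if min_sep(mid) < target:
            t_lo = mid
        else:
            t_hi = mid
        if t_hi - t_lo < 1e-9:
            break
    t = 0.5 * (t_lo + t_hi)
    translation = c_r + t * axis - np.asarray(rotation) @ c_l
    return Pose(np.asarray(rotation), translation, pose_id=pose_id)


def generate_poses(
    receptor: Structure,
    ligand: Structure,
    euler_step_deg: float = 15.0,
    contact_mode: str = "touch",
    seed: int = 0,
) -> PoseSet:
    """Euler-grid orientations (z-y-z, θ ∈ [0, 180°], duplicates removed by
    quaternion comparison), each placed in touching contact."""
    if euler_step_deg <= 0:
        raise ParameterError(f"euler_step_deg must be > 0, got {euler_step_deg}")
    _ = seed  # placement is deterministic; kept for interface stability
    step = np.deg2rad(euler_step_deg)
    phis = np.arange(0.0, 2 * np.pi - 1e-9, step)
    thetas = np.arange(0.0, np.pi + 1e-9, step)
    psis = np.arange(0.0, 2 * np.pi - 1e-9, step)
    mats = [euler_zyz_to_matrix(p, t, q) for p in phis for t in thetas for q in psis]
    mats = [mats[i] for i in dedup_rotations(mats)]
    poses = []
    for i, R in enumerate(mats):
        if contact_mode == "touch":
            poses.append(touch_along_axis(receptor, ligand, R, pose_id=i))
        else:
            raise ParameterError(f"unknown contact_mode {contact_mode!r}")
    return PoseSet(receptor, ligand, poses)


# ---------------------------------------------------------------------------
# ZDOCK-style tables (documented dialect)
#
#   line 1: <grid_size:int> <spacing:float>
#   line 2: <phi0> <theta0> <psi0>   initial ligand rotation, z-y-z radians
#   rows  : <phi> <theta> <psi> <tx> <ty> <tz> <score>
#
# Row transform: R = Rzyz(phi,theta,psi) · Rzyz(init); translation = wrap(t)·spacing
# where grid indices above grid_size/2 wrap negative.


def read_zdock_table(path, receptor: Structure, ligand: Structure) -> PoseSet:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: truncated header")
    try:
        head = lines[0].split()
        grid_size, spacing = int(head[0]), float(head[1])
        init = [float(v) for v in lines[1].split()]
        if len(init) != 3:
            raise ValueError("initial rotation needs 3 angles")
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: bad header: {exc}") from exc
    R_init = euler_zyz_to_matrix(*init)
    poses = []
    for line_no, ln in enumerate(lines[2:], start=3):
        parts = ln.split()
        if len(parts) != 7:
            raise FormatError(f"{path}: line {line_no}: expected 7 fields, got {len(parts)}")
        try:
            phi, theta, psi, tx, ty, tz, score = (float(v) for v in parts)
        except ValueError as exc:
            raise FormatError(f"{path}: line {line_no}: {exc}") from exc
        t = np.array([tx, ty, tz])
        t = np.where(t > grid_size / 2.0, t - grid_size, t) * spacing
        R = euler_zyz_to_matrix(phi, theta, psi) @ R_init
        poses.append(Pose(R, t, pose_id=len(poses), source_score=score))
    return PoseSet(receptor, ligand, poses)


def _matrix_to_zyz(R: np.ndarray) -> tuple[float, float, float]:
    theta = float(np.arccos(np.clip(R[2, 2], -1.0, 1.0)))
    if abs(np.sin(theta)) < 1e-12:
        phi = float(np.arctan2(R[1, 0], R[0, 0]))
        psi = 0.0
    else:
        phi = float(np.arctan2(R[1, 2], R[0, 2]))
        psi = float(np.arctan2(R[2, 1], -R[2, 0]))
    return phi, theta, psi


def write_zdock_table(ps: PoseSet, path, grid_size: int = 128, spacing: float = 1.0) -> None:
    with open(path, "w") as fh:
        fh.write(f"{grid_size} {spacing}\n0.0 0.0 0.0\n")
        for p in ps.poses:
            phi, theta, psi = _matrix_to_zyz(p.rotation)
            t = p.translation / spacing
            score = p.source_score if p.source_score is not None else 0.0
            fh.write(
                f"{phi:.9f} {theta:.9f} {psi:.9f} {t[0]:.9f} {t[1]:.9f} {t[2]:.9f} {score:.6f}\n"
            )


# ---------------------------------------------------------------------------
# scoring / filtering / ranking


class PoseScorer:
    """Computes interfacial metrics for many poses of one receptor/ligand
    pair, caching everything rigid-transform invariant (free SASA, surface
    dot clouds)."""

    def __init__(
        self,
        receptor: Structure,
        ligand: Structure,
        n_points: int = 240,
        dsasa_min: float = 1.0,
        contact_cutoff: float = 5.0,
        sc_band: float = 1.5,
        sc_w: float = 0.5,
        conservation_scores: dict[ResidueKey, float] | None = None,
    ):
        self.receptor = receptor
        self.ligand = ligand
        self.n_points = n_points
        self.dsasa_min = dsasa_min
        self.contact_cutoff = contact_cutoff
        self.sc_band = sc_band
        self.sc_w = sc_w
        self.conservation_scores = conservation_scores
        # one fixed sampling frame for every SASA/dot evaluation: parts and
        # complex then cancel exactly regardless of pose
        self._frame = np.eye(3)
        self._rec_sasa = sasa(receptor, n_points=n_points, orientation=self._frame)
        self._lig_sasa = sasa(ligand, n_points=n_points, orientation=self._frame)
        self._rec_dots, self._rec_normals = surface_dots(receptor, n_points=n_points, orientation=self._frame)
        self._lig_dots0, self._lig_normals0 = surface_dots(ligand, n_points=n_points, orientation=self._frame)
        self._cache: dict[bytes, dict] = {}
        # surface residues of the free partners (for conservation enrichment)
        self.surface_residues = {
            k for k, v in {**self._rec_sasa.per_residue, **self._lig_sasa.per_residue}.items() if v > 5.0
        }

    def metrics(self, pose: Pose) -> dict:
        key = np.round(np.hstack([pose.rotation.ravel(), pose.translation]), 9).tobytes()
        if key in self._cache:
            return self._cache[key]
        posed = apply_pose(self.ligand, pose)
        bound = sasa(combine(self.receptor, posed, id="ab"), n_points=self.n_points,
                     orientation=self._frame)
        # free ligand SASA is evaluated in the posed frame: the identical
        # point sampling then cancels exactly in ΔSASA far from contact
        lig_free = sasa(posed, n_points=self.n_points, orientation=self._frame)
        free = {**self._rec_sasa.per_residue, **lig_free.per_residue}
        dsasa = {k: free[k] - bound.per_residue.get(k, 0.0) for k in free}
        buried = max(sum(dsasa.values()), 0.0)
        cmat, contact_total = contact_pairs(self.receptor, posed, self.contact_cutoff)
        iface_a = {k for k in self._rec_sasa.per_residue if dsasa[k] > self.dsasa_min}
        iface_b = {k for k in lig_free.per_residue if dsasa[k] > self.dsasa_min}
        arr = cmat.to_numpy()
        for i, k in enumerate(cmat.index):
            if arr[i, :].any():
                iface_a.add(k)
        for j, k in enumerate(cmat.columns):
            if arr[:, j].any():
                iface_b.add(k)
        # shape complementarity from cached dot clouds
        ld = pose.apply_to_points(self._lig_dots0)
        ln = self._lig_normals0 @ pose.rotation.T
        ta, tb = cKDTree(self._rec_dots), cKDTree(ld)
        dist_ab, _ = tb.query(self._rec_dots)
        dist_ba, _ = ta.query(ld)
        sel_a = dist_ab <= self.sc_band
        sel_b = dist_ba <= self.sc_band
        if sel_a.any() and sel_b.any():
            sc = sc_from_dots(
                self._rec_dots[sel_a], self._rec_normals[sel_a], ld[sel_b], ln[sel_b], w=self.sc_w
            )
        else:
            sc = float("nan")
        enrichment = float("nan")
        if self.conservation_scores:
            iface = iface_a | iface_b
            surf = self.surface_residues - iface
            iv = [self.conservation_scores[k] for k in iface if k in self.conservation_scores]
            sv = [self.conservation_scores[k] for k in surf if k in self.conservation_scores]
            if iv and sv:
                enrichment = float(np.mean(iv) - np.mean(sv))
        out = {
            "buried_area": buried,
            "sc": sc,
            "contact_total": contact_total,
            "iface_conservation_enrichment": enrichment,
            "interface_receptor": iface_a,
            "interface_ligand": iface_b,
        }
        self._cache[key] = out
        return out


def filter_poses(
    ps: PoseSet,
    c: ConstraintSet,
    scorer: PoseScorer | None = None,
    n_points: int = 240,
    conservation_scores: dict[ResidueKey, float] | None = None,
) -> pd.DataFrame:
    """Score every pose and flag constraint compliance.

    A pose passes iff passive violations ≤ tolerance AND every required
    residue is interfacial AND buried area lies in the window AND sc ≥
    sc_min. The returned table records metrics, pass/fail and reason codes.
    """
    c.validate_against(ps.receptor, ps.ligand)
    scorer = scorer or PoseScorer(
        ps.receptor, ps.ligand, n_points=n_points, conservation_scores=conservation_scores
    )
    rows = []
    for pose in ps.poses:
        m = scorer.metrics(pose)
        iface = m["interface_receptor"] | m["interface_ligand"]
        passive_violations = len(c.passive_residues & iface)
        req_rec = len(c.required_receptor & m["interface_receptor"])
        req_lig = len(c.required_ligand & m["interface_ligand"])
        reasons = []
        if not iface:
            reasons.append("empty-interface")
        if passive_violations > c.passive_tolerance:
            reasons.append("passive-violation")
        if req_rec < len(c.required_receptor) or req_lig < len(c.required_ligand):
            reasons.append("required-missing")
        lo, hi = c.buried_area_window
        if not (lo <= m["buried_area"] <= hi):
            reasons.append("buried-area-window")
        if not (m["sc"] >= c.sc_min):  # NaN fails
            reasons.append("sc-floor")
        rows.append(
            {
                "pose_id": pose.pose_id,
                "buried_area": m["buried_area"],
                "sc": m["sc"],
                "contact_total": m["contact_total"],
                "iface_conservation_enrichment": m["iface_conservation_enrichment"],
                "passive_violations": passive_violations,
                "required_satisfied": req_rec + req_lig,
                "passes": not reasons,
                "reasons": ",".join(reasons),
            }
        )
    return pd.DataFrame(rows)


def constraints_from_pose(
    ps: PoseSet,
    pose: Pose,
    scorer: PoseScorer | None = None,
    n_required: int = 3,
    window_frac: float = 0.25,
    sc_margin: float = 0.05,
    n_points: int = 240,
) -> ConstraintSet:
    """Derive a self-consistent constraint set from one (e.g. native) pose.

    Passive residues are the receptor's solvent-accessible residues outside
    that pose's interface; required residues are its strongest-contact
    interface residues on each partner; the buried-area window brackets the
    pose's value by ±window_frac and sc_min sits sc_margin below its sc.
    """
    scorer = scorer or PoseScorer(ps.receptor, ps.ligand, n_points=n_points)
    m = scorer.metrics(pose)
    posed = apply_pose(ps.ligand, pose)
    cmat, _ = contact_pairs(ps.receptor, posed, scorer.contact_cutoff)
    row_counts = cmat.sum(axis=1)
    col_counts = cmat.sum(axis=0)
    req_rec = set(
        row_counts[row_counts > 0].sort_values(ascending=False).head(n_required).index
    ) & m["interface_receptor"]
    req_lig = set(
        col_counts[col_counts > 0].sort_values(ascending=False).head(n_required).index
    ) & m["interface_ligand"]
    rec_surface = {k for k, v in scorer._rec_sasa.per_residue.items() if v > 5.0}
    passive = rec_surface - m["interface_receptor"]
    ba = m["buried_area"]
    sc_min = (m["sc"] - sc_margin) if np.isfinite(m["sc"]) else -1.0
    return ConstraintSet(
        passive_residues=passive,
        required_receptor=req_rec,
        required_ligand=req_lig,
        buried_area_window=(ba * (1 - window_frac), ba * (1 + window_frac)),
        sc_min=sc_min,
    )


def _hinge(buried: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    out = np.zeros_like(buried, dtype=float)
    out = np.where(buried < lo, -(lo - buried) / 100.0, out)
    out = np.where(buried > hi, -(buried - hi) / 100.0, out)
    return out


def rank_poses(
    table: pd.DataFrame,
    weights: dict[str, float] | None = None,
    buried_area_window: tuple[float, float] = (1200.0, 1800.0),
) -> pd.DataFrame:
    """Composite re-ranking of passing poses.

    composite = Σ w_m·z_m over {sc, buried-area hinge, conservation
    enrichment, contact_total}, z-scored over the passing poses; ties break
    to the lower pose_id; rank 1 is best. Failing poses are ranked after
    all passing ones, by pose_id.
    """
    w = {"sc": 1.0, "buried": 1.0, "conservation": 1.0, "contacts": 1.0}
    if weights:
        w.update(weights)
    t = table.copy().reset_index(drop=True)
    passing = t["passes"].to_numpy(dtype=bool)
    metrics = {
        "sc": t["sc"].to_numpy(dtype=float),
        "buried": _hinge(t["buried_area"].to_numpy(dtype=float), buried_area_window),
        "conservation": t["iface_conservation_enrichment"].to_numpy(dtype=float),
        "contacts": t["contact_total"].to_numpy(dtype=float),
    }
    composite = np.zeros(len(t))
    n_pass = int(passing.sum())
    if n_pass < 2:
        if n_pass == 1:
            import warnings

            warnings.warn("fewer than 2 passing poses: composite uses raw metric values", stacklevel=2)
        for name, vals in metrics.items():
            v = np.nan_to_num(vals, nan=0.0)
            composite += w[name] * v
    else:
        for name, vals in metrics.items():
            ref = vals[passing]
            ref = ref[np.isfinite(ref)]
            mu = ref.mean() if len(ref) else 0.0
            sd = ref.std() if len(ref) else 0.0
            z = (np.nan_to_num(vals, nan=mu) - mu) / sd if sd > 0 else np.zeros(len(t))
            composite += w[name] * z
    t["composite"] = composite
    # round so symmetric float cancellation ties break by pose_id as specified
    comp_key = np.round(composite, 9)
    order = sorted(
        range(len(t)),
        key=lambda i: (not passing[i], -comp_key[i] if passing[i] else 0.0, int(t["pose_id"].iloc[i])),
    )
    ranks = np.empty(len(t), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    t["rank"] = ranks
    return t


def cluster_poses(
    ps: PoseSet,
    table: pd.DataFrame,
    rmsd_cutoff: float = 5.0,
) -> tuple[pd.DataFrame, list[int]]:
    """Greedy leader clustering of poses on ligand-Cα RMSD in the receptor
    frame, visiting poses in rank order; the representative of each cluster
    is its best-ranked member. Returns (table with 'cluster', leader ids)."""
    ca0 = ps.ligand.ca_coords()
    by_id = {p.pose_id: p for p in ps.poses}
    t = table.sort_values("rank").reset_index(drop=True)
    leaders: list[tuple[int, np.ndarray]] = []
    assignment: dict[int, int] = {}
    for pid in t["pose_id"]:
        pose = by_id[int(pid)]
        ca = pose.apply_to_points(ca0)
        placed = False
        for ci, (_, lead_ca) in enumerate(leaders):
            rmsd = float(np.sqrt(((ca - lead_ca) ** 2).sum(axis=1).mean()))
            if rmsd <= rmsd_cutoff:
                assignment[int(pid)] = ci
                placed = True
                break
        if not placed:
            assignment[int(pid)] = len(leaders)
            leaders.append((int(pid), ca))
    out = table.copy()
    out["cluster"] = [assignment[int(p)] for p in out["pose_id"]]
    return out, [pid for pid, _ in leaders]
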