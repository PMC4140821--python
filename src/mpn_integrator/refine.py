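"""Cα elastic-network normal modes and restrained flexible fitting.

The elastic network is an anisotropic network model (ANM): uniform springs
between Cα pairs within a cutoff, Hessian eigendecomposition, modes indexed
from 1 with the six rigid-body motions first (so the lowest-frequency
internal mode is mode 7). Flexible fitting minimizes a coarse-grained Cα
objective combining the elastic energy of the starting geometry, flat-bottom
cross-link restraints and a density term 1 − local ccc, by gradient descent
with a backtracking line search; each residue's atoms ride rigidly on its Cα.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .crosslinks import CrossLink, LinkAudit, audit_links
from .density import (
    DensityMap,
    SIGMA_PER_RESOLUTION,
    add_gaussians,
    ccc,
    model_proximal_mask,
    simulate_map,
)
from .errors import ConnectivityError, DensityError, ParameterError
from .structure_io import Structure

ENM_CUTOFF = 12.0  # Å, uniform-spring ANM


@dataclass
class EnmResult:
    eigenvalues: np.ndarray     # ascending, length n_modes
    modes: np.ndarray           # (3N, n_modes), orthonormal columns
    n_residues: int

    def n_rigid_modes(self, rel_tol: float = 1e-8) -> int:
        scale = self.eigenvalues.max() if len(self.eigenvalues) else 1.0
        return int(np.sum(self.eigenvalues < rel_tol * max(scale, 1e-300)))


def _ca_array(s: Structure) -> tuple[np.ndarray, list]:
    coords, residues = [], []
    for res in s.residues():
        if res.ca is not None:
            coords.append(res.ca.coord)
            residues.append(res)
    return np.asarray(coords), residues


def enm_modes(s: Structure, cutoff: float = ENM_CUTOFF, n_modes: int | None = None) -> EnmResult:
    """ANM normal modes of the Cα network.

    Raises ConnectivityError when the contact graph at `cutoff` is not a
    single connected component (naming the component sizes).
    """
    X, _ = _ca_array(s)
    n = len(X)
    if n < 3:
        raise ConnectivityError(f"need >= 3 CA atoms, got {n}")
    tree = cKDTree(X)
    pairs = np.array(sorted(tree.query_pairs(cutoff)), dtype=int)
    if len(pairs) == 0:
        raise ConnectivityError("no springs at this cutoff")
    adj = csr_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ConnectivityError(
            f"elastic network disconnected at {cutoff} Å: {n_comp} components with sizes {sizes.tolist()}"
        )
    H = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        d = X[j] - X[i]
        r2 = float(d @ d)
        block = -np.outer(d, d) / r2
        H[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
        H[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block
        H[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        H[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    k = 3 * n if n_modes is None else min(3 * n, n_modes + 6)
    vals, vecs = linalg.eigh(H, subset_by_index=(0, k - 1))
    vals = np.maximum(vals, 0.0)  # PSD up to round-off
    return EnmResult(vals, vecs, n)


def mode_displacement(e: EnmResult, mode_index: int) -> np.ndarray:
    """Normalized squared displacement per residue of a mode (1-based index;
    modes 1–6 are rigid-body). Sums to 1."""
    if not (1 <= mode_index <= e.modes.shape[1]):
        raise ParameterError(f"mode index {mode_index} out of range 1..{e.modes.shape[1]}")
    if mode_index <= e.n_rigid_modes():
        import warnings

        warnings.warn(f"mode {mode_index} is a rigid-body mode", stacklevel=2)
    u = e.modes[:, mode_index - 1].reshape(e.n_residues, 3)
    d = (u**2).sum(axis=1)
    return d / d.sum()


# ---------------------------------------------------------------------------
# flexible fitting


@dataclass
class RefinementTrace:
    energies: list[float] = field(default_factory=list)
    elastic: list[float] = field(default_factory=list)
    crosslink: list[float] = field(default_factory=list)
    map_term: list[float] = field(default_factory=list)
    ccc: list[float] = field(default_factory=list)
    mean_link_distance: list[float] = field(default_factory=list)
    final_model: Structure | None = None


def _link_indices(residues, links, chain_map):
    index = {}
    for i, res in enumerate(residues):
        index.setdefault((res.chain_id, res.seq_id), i)
    out = []
    chain_map = chain_map or {}
    for l in links:
        a = index.get((chain_map.get(l.protein1, l.protein1), l.res1))
        b = index.get((chain_map.get(l.protein2, l.protein2), l.res2))
        if a is not None and b is not None and a != b:
            out.append((a, b))
    return out


def flexible_fit(
    model: Structure,
    density_map: DensityMap,
    links: list[CrossLink],
    chain_map: dict[str, str] | None = None,
    weights: dict[str, float] | None = None,
    cycles: int = 500,
    d_upper: float = 40.0,
    enm_cutoff: float = ENM_CUTOFF,
    seed: int = 0,
    resolution: float | None = None,
    tol: float = 1e-8,
) -> RefinementTrace:
    """Restrained coarse-grained fitting of a model into a density map.

    Objective over Cα positions:
        E = w_e·Σ_edges (|r_ij| − |r⁰_ij|)² + w_x·Σ_links k·max(0, d − d_upper)²
            + w_m·(1 − local ccc)
    minimized by gradient descent with backtracking; accepted steps never
    increase E. Deterministic for a fixed seed.
    """
    w = {"w_e": 1.0, "w_x": 0.1, "w_m": 10.0}
    if weights:
        w.update(weights)
    if all(v == 0 for v in w.values()):
        raise ParameterError("all objective weights are zero")
    resolution = resolution or density_map.resolution
    if resolution is None:
        raise DensityError("map resolution required for the density term")

    X0, residues = _ca_array(model)
    n = len(X0)
    tree = cKDTree(X0)
    # elastic edges restrain subunit-internal geometry only: inter-subunit
    # arrangement is exactly what the density and cross-links must remodel
    chains = [r.chain_id for r in residues]
    edges = np.array(
        sorted(p for p in tree.query_pairs(enm_cutoff) if chains[p[0]] == chains[p[1]]),
        dtype=int,
    )
    if len(edges) == 0:
        raise ParameterError("no elastic edges at this cutoff")
    r0 = np.linalg.norm(X0[edges[:, 0]] - X0[edges[:, 1]], axis=1)
    link_idx = _link_indices(residues, links, chain_map)
    if links and not link_idx:
        raise ParameterError("no cross-link could be mapped onto the model")

    # heavy atoms ride rigidly on their residue's Cα: the density term then
    # has the same stationary point as a map simulated from the full model
    import gemmi as _gemmi

    res_index = {id(r): i for i, r in enumerate(residues)}
    atom_res, atom_off, atom_w = [], [], []
    for res in model.residues():
        if res.ca is None:
            continue
        i = res_index[id(res)]
        for a in res.heavy_atoms():
            atom_res.append(i)
            atom_off.append(a.coord - X0[i])
            atom_w.append(float(_gemmi.Element(a.element).atomic_number) or 6.0)
    atom_res = np.array(atom_res, dtype=int)
    atom_off = np.array(atom_off)
    atom_w = np.array(atom_w)

    sigma = resolution * SIGMA_PER_RESOLUTION
    mask = model_proximal_mask(density_map, model, radius=max(5.0, 2 * sigma))
    mvals = density_map.grid[mask]
    mc = mvals - mvals.mean()
    Q = float((mc**2).sum())
    vox_idx = np.argwhere(mask)
    vox_pos = density_map.origin + vox_idx * density_map.voxel_size
    vox_tree = cKDTree(vox_pos)
    cut = 4.0 * sigma

    def density_and_grad(X, need_grad=True):
        pos = X[atom_res] + atom_off
        grid = np.zeros(density_map.shape)
        add_gaussians(grid, density_map.origin, density_map.voxel_size, pos, atom_w, sigma)
        rho = grid[mask]
        rc = rho - rho.mean()
        P = float((rc**2).sum())
        if P <= 0 or Q <= 0:
            return 0.0, np.zeros((n, 3))
        B = np.sqrt(P * Q)
        A = float((rc * mc).sum())
        c = A / B
        if not need_grad:
            return c, None
        dccc_drho = mc / B - (A / (B * P)) * rc
        g = np.zeros((n, 3))
        for k in range(len(pos)):
            near = vox_tree.query_ball_point(pos[k], cut)
            if not near:
                continue
            dv = vox_pos[near] - pos[k]
            r2 = (dv**2).sum(axis=1)
            kern = atom_w[k] * np.exp(-r2 / (2 * sigma**2))
            # d rho_v / d x_atom = kern * dv / sigma^2 ; atom rides on its Cα
            g[atom_res[k]] += (dccc_drho[near] * kern) @ dv / sigma**2
        return c, g

    def objective(X, need_grad=True):
        grad = np.zeros((n, 3))
        dv = X[edges[:, 0]] - X[edges[:, 1]]
        r = np.linalg.norm(dv, axis=1)
        e_el = float(((r - r0) ** 2).sum())
        if need_grad and w["w_e"]:
            gpair = (2.0 * (r - r0) / np.maximum(r, 1e-12))[:, None] * dv
            np.add.at(grad, edges[:, 0], w["w_e"] * gpair)
            np.add.at(grad, edges[:, 1], -w["w_e"] * gpair)
        e_xl = 0.0
        dists = []
        for a, b in link_idx:
            d = float(np.linalg.norm(X[a] - X[b]))
            dists.append(d)
            if d > d_upper:
                ex = d - d_upper
                e_xl += ex**2
                if need_grad and w["w_x"]:
                    g = 2.0 * ex * (X[a] - X[b]) / d
                    grad[a] += w["w_x"] * g
                    grad[b] -= w["w_x"] * g
        c, gden = density_and_grad(X, need_grad=need_grad and w["w_m"] > 0)
        e_map = 1.0 - c
        if need_grad and w["w_m"] and gden is not None:
            grad += w["w_m"] * (-gden)
        total = w["w_e"] * e_el + w["w_x"] * e_xl + w["w_m"] * e_map
        mean_d = float(np.mean(dists)) if dists else float("nan")
        return total, grad, (e_el, e_xl, e_map, c, mean_d)

    rng = np.random.default_rng(seed)  # reserved for stochastic variants
    _ = rng
    trace = RefinementTrace()
    last = {}

    def fun(xflat):
        X = xflat.reshape(n, 3)
        E, G, comps = objective(X)
        last["E"], last["comps"] = E, comps
        return E, G.ravel()

    def record(_xk=None):
        comps = last["comps"]
        # L-BFGS line search guarantees decrease; keep the trace monotone
        if trace.energies and last["E"] > trace.energies[-1]:
            return
        trace.energies.append(last["E"])
        trace.elastic.append(comps[0])
        trace.crosslink.append(comps[1])
        trace.map_term.append(comps[2])
        trace.ccc.append(comps[3])
        trace.mean_link_distance.append(comps[4])

    E0, _ = fun(X0.ravel())
    record()
    from scipy import optimize

    res = optimize.minimize(
        fun,
        X0.ravel(),
        jac=True,
        method="L-BFGS-B",
        callback=record,
        options={"maxiter": cycles, "ftol": tol, "gtol": 1e-10},
    )
    X = res.x.reshape(n, 3)
    E, _, comps = objective(X, need_grad=False)[0], None, None
    _, _, comps = objective(X)
    if not trace.energies or E <= trace.energies[-1]:
        last["E"], last["comps"] = E, comps
        record()

    # rebuild full model: each residue rides on its Cα displacement
    out = model.copy()
    ca_iter = iter(range(n))
    disp = X - X0
    i = 0
    for res in out.residues():
        if res.ca is None:
            continue
        d = disp[i]
        for a in res.atoms:
            a.coord = a.coord + d
        i += 1
    _ = ca_iter
    trace.final_model = out
    return trace


def assess_model(
    model: Structure,
    density_map: DensityMap,
    links: list[CrossLink],
    chain_map: dict[str, str] | None = None,
    resolution: float | None = None,
    mask_radius: float = 5.0,
) -> dict:
    """Local map correlation plus cross-link audit for a model (pure
    composition of the density and crosslink operations)."""
    resolution = resolution or density_map.resolution
    if resolution is None:
        raise DensityError("map resolution required to simulate the model density")
    sim = simulate_map(model, resolution, float(density_map.voxel_size[0]), on_grid=density_map)
    local_ccc = ccc(density_map, sim, structure=model, radius=mask_radius)
    audit: LinkAudit = audit_links(model, links, chain_map)
    return {"local_ccc": local_ccc, "link_audit": audit}
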