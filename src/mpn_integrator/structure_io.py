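"""Macromolecular structure containers and PDB/mmCIF input/output.

The in-memory model is a light chain → residue → atom hierarchy with Å
coordinates and author numbering, backed by gemmi for file parsing and
writing. Rigid-body placements are represented by :class:`Pose` (a proper
rotation plus translation) so that docking poses and map fits share one
transform type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import (
    EmptySelectionError,
    EmptyStructureError,
    InvalidPoseError,
    SelectionError,
    StructureIOError,
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: common modified residues → parent, used only when map_modified=True
MODIFIED_PARENTS = {"MSE": "M", "SEP": "S", "TPO": "T", "PTR": "Y", "CSO": "C", "MLY": "K"}


@dataclass
class Atom:
    """A single atom with Å coordinates."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.name!r}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str | None = None

    @property
    def key(self) -> tuple[str, int, str | None]:
        return (self.chain_id, self.seq_id, self.insertion_code)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.get_atom("CA")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def one_letter(self, map_modified: bool = False) -> str:
        if self.res_name in THREE_TO_ONE:
            return THREE_TO_ONE[self.res_name]
        if map_modified and self.res_name in MODIFIED_PARENTS:
            return MODIFIED_PARENTS[self.res_name]
        return "X"


class Structure:
    """Ordered chains of residues; the substrate of every geometric operation."""

    def __init__(self, id: str = "model", metadata: dict | None = None):
        self.id = id
        self.chains: dict[str, list[Residue]] = {}
        self.metadata: dict = metadata or {}

    # -- construction -------------------------------------------------
    def add_residue(self, res: Residue) -> None:
        self.chains.setdefault(res.chain_id, []).append(res)

    # -- iteration / access -------------------------------------------
    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residues(self, chain_id: str | None = None):
        if chain_id is not None:
            if chain_id not in self.chains:
                raise SelectionError(f"chain {chain_id!r} not in structure {self.id!r}")
            yield from self.chains[chain_id]
        else:
            for residues in self.chains.values():
                yield from residues

    def atoms(self, heavy_only: bool = False):
        for res in self.residues():
            for a in res.atoms:
                if heavy_only and not a.is_heavy:
                    continue
                yield res, a

    def get_residue(self, chain_id: str, seq_id: int, insertion_code: str | None = None) -> Residue | None:
        for res in self.chains.get(chain_id, []):
            if res.seq_id == seq_id and res.insertion_code == insertion_code:
                return res
        return None

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        pts = [a.coord for _, a in self.atoms(heavy_only=heavy_only)]
        if not pts:
            return np.empty((0, 3))
        return np.vstack(pts)

    def ca_coords(self, chain_id: str | None = None) -> np.ndarray:
        pts = [r.ca.coord for r in self.residues(chain_id) if r.ca is not None]
        if not pts:
            return np.empty((0, 3))
        return np.vstack(pts)

    def copy(self, id: str | None = None) -> "Structure":
        out = Structure(id or self.id, dict(self.metadata))
        for res in self.residues():
            out.add_residue(
                Residue(
                    res.chain_id,
                    res.seq_id,
                    res.res_name,
                    [Atom(a.name, a.element, a.coord.copy()) for a in res.atoms],
                    res.insertion_code,
                )
            )
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray, id: str | None = None) -> "Structure":
        out = self.copy(id)
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float).reshape(3)
        for _, a in out.atoms():
            a.coord = R @ a.coord + t
        return out

    def validate(self) -> None:
        if self.n_atoms == 0:
            raise EmptyStructureError(f"structure {self.id!r} has no atoms")
        seen = set()
        for res in self.residues():
            if not res.atoms:
                raise ValueError(f"residue {res.key} has no atoms")
            if res.key in seen:
                raise ValueError(f"duplicate residue identifier {res.key}")
            seen.add(res.key)
            if res.res_name in THREE_TO_ONE and res.ca is None:
                warnings.warn(f"standard residue {res.key} lacks a CA atom", stacklevel=2)


@dataclass
class Pose:
    """Rigid transform x ↦ R·x + t placing a ligand relative to a fixed receptor."""

    rotation: np.ndarray
    translation: np.ndarray
    pose_id: int = 0
    source_score: float | None = None

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.validate()

    def validate(self, tol: float = 1e-8) -> None:
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=tol):
            raise InvalidPoseError(f"pose {self.pose_id}: rotation not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > tol:
            raise InvalidPoseError(f"pose {self.pose_id}: det(R) != +1 (improper rotation)")

    @classmethod
    def identity(cls, pose_id: int = 0) -> "Pose":
        return cls(np.eye(3), np.zeros(3), pose_id=pose_id)

    def apply_to_points(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "Pose", pose_id: int = 0) -> "Pose":
        """Pose equivalent to applying `other` first, then `self`."""
        return Pose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
            pose_id=pose_id,
        )


# ---------------------------------------------------------------------------
# file I/O


def _detect_format(path: Path, format: str) -> str:
    if format != "auto":
        return format
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def read_structure(path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file.

    Altloc groups are resolved to the highest-occupancy conformer (ties break
    to the alphabetically first altloc id). Author chain ids and residue
    numbering are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise StructureIOError(f"no such file: {path}")
    fmt = _detect_format(path, format)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureIOError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureIOError(f"cannot parse {path}: {exc}") from exc

    out = Structure(st.name or path.stem)
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    for chain in model:
        for res in chain:
            icode = res.seqid.icode.strip() or None
            r = Residue(chain.name, res.seqid.num, res.name, [], icode)
            # resolve altlocs: group by atom name, keep highest occupancy
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            for name, group in by_name.items():
                best = min(group, key=lambda a: (-a.occ, a.altloc or "~"))
                el = best.element.name or "X"
                r.atoms.append(Atom(name, el, np.array([best.pos.x, best.pos.y, best.pos.z])))
            if r.atoms:
                out.add_residue(r)
    if out.n_atoms == 0:
        raise EmptyStructureError(f"{path}: zero atoms parsed")
    return out


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    for chain_id, residues in s.chains.items():
        chain = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coord)
                ga.occ = 1.0
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure, path, format: str = "pdb") -> None:
    """Write `s` as PDB or mmCIF; the file re-reads to identical topology."""
    if s.n_atoms == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    path = Path(path)
    if format == "pdb":
        for cid in s.chain_ids:
            if len(cid) > 1:
                raise StructureIOError(
                    f"chain id {cid!r} does not fit the single-character PDB chain field"
                )
    st = _to_gemmi(s)
    try:
        if format == "pdb":
            st.write_pdb(str(path))
        elif format == "mmcif":
            st.make_mmcif_document().write_file(str(path))
        else:
            raise StructureIOError(f"unknown format {format!r}")
    except (RuntimeError, OSError) as exc:
        raise StructureIOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# selection / transforms / sequence


def select(s: Structure, chain_ids, seq_range: tuple[int, int] | None = None) -> Structure:
    """Sub-structure with the given chains and (inclusive) residue range."""
    if isinstance(chain_ids, str):
        chain_ids = [chain_ids]
    chain_ids = list(chain_ids)
    for cid in chain_ids:
        if cid not in s.chains:
            raise SelectionError(f"chain {cid!r} not in structure {s.id!r}")
    out = Structure(s.id, dict(s.metadata))
    for cid in chain_ids:
        for res in s.chains[cid]:
            if seq_range is not None and not (seq_range[0] <= res.seq_id <= seq_range[1]):
                continue
            out.add_residue(
                Residue(
                    res.chain_id,
                    res.seq_id,
                    res.res_name,
                    [Atom(a.name, a.element, a.coord.copy()) for a in res.atoms],
                    res.insertion_code,
                )
            )
    if out.n_atoms == 0:
        raise EmptySelectionError(
            f"selection chains={chain_ids} range={seq_range} matches no residues"
        )
    return out


def apply_pose(s: Structure, p: Pose) -> Structure:
    """Map every coordinate x to R·x + t; topology unchanged."""
    p.validate()
    return s.transformed(p.rotation, p.translation)


def extract_sequence(
    s: Structure, chain_id: str, map_modified: bool = False
) -> tuple[str, list[int]]:
    """One-letter sequence of a chain plus the parallel author seq_id list."""
    if chain_id not in s.chains:
        raise SelectionError(f"chain {chain_id!r} not in structure {s.id!r}")
    letters, seq_ids = [], []
    for res in s.chains[chain_id]:
        letters.append(res.one_letter(map_modified=map_modified))
        seq_ids.append(res.seq_id)
    return "".join(letters), seq_ids


def combine(*structures: Structure, id: str = "complex") -> Structure:
    """Merge structures into one (chain ids must not collide)."""
    out = Structure(id)
    for s in structures:
        for cid in s.chain_ids:
            if cid in out.chains:
                raise SelectionError(f"chain id collision on {cid!r} while combining")
        for res in s.residues():
            out.add_residue(
                Residue(
                    res.chain_id,
                    res.seq_id,
                    res.res_name,
                    [Atom(a.name, a.element, a.coord.copy()) for a in res.atoms],
                    res.insertion_code,
                )
            )
    return out
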