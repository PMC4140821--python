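import numpy as np
import pytest

from mpn_integrator import synthetic_data as syn
from mpn_integrator.structure_io import Atom, Residue, Structure


@pytest.fixture(scope="session")
def toy_assembly():
    """3-subunit ring of 25-residue helices (Cα + pseudo-Cβ)."""
    return syn.make_toy_assembly(syn.ToyAssemblySpec(n_subunits=3, residues_per_subunit=25))


@pytest.fixture(scope="session")
def single_helix():
    return syn.make_toy_assembly(syn.ToyAssemblySpec(n_subunits=1, residues_per_subunit=30))


@pytest.fixture(scope="session")
def docking_pair():
    """(receptor, ligand, native pose) for docking experiments."""
    return syn.make_docking_pair(residues_per_subunit=30)


@pytest.fixture()
def tri_residue():
    """Minimal hand-built 3-residue structure."""
    s = Structure("tri")
    for i, (name, x) in enumerate([("ALA", 0.0), ("GLY", 3.8), ("LYS", 7.6)], start=1):
        s.add_residue(
            Residue(
                "A", i, name,
                [Atom("CA", "C", [x, 0.0, 0.0]), Atom("CB", "C", [x, 1.5, 0.0])],
            )
        )
    return s


def chain_shifted(structure, chain_id, shift):
    """Copy of `structure` with one chain rigidly translated."""
    out = structure.copy()
    shift = np.asarray(shift, dtype=float)
    for res in out.chains[chain_id]:
        for a in res.atoms:
            a.coord = a.coord + shift
    return out
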