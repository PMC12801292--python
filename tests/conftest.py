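from __future__ import annotations

import math

import numpy as np
import pytest
from rdkit import Chem

from pharmscreen import chem_io, fixtures
from pharmscreen.chem_io import Atom, PoseRecord, ReceptorStructure, Residue


@pytest.fixture
def pocket():
    """Small deterministic pocket with all four fixture residue types."""
    return fixtures.generate_pocket(8, seed=11, structure_id="STR1")


@pytest.fixture
def residue_of(pocket):
    def pick(resname: str, nth: int = 0) -> Residue:
        matches = [r for r in pocket.residues if r.name == resname]
        return matches[nth]

    return pick


def make_pose(mol: Chem.Mol, compound_id: str = "c1", structure_id: str = "STR1", score: float = -8.0) -> PoseRecord:
    chem_io.set_mol_id(mol, compound_id)
    return PoseRecord(compound_id, structure_id, mol, score)


def build_fragment_pose(
    atoms: list[tuple[str, tuple[float, float, float]]],
    bonds: list[tuple[int, int]] | None = None,
    compound_id: str = "c1",
    structure_id: str = "STR1",
    score: float = -8.0,
) -> PoseRecord:
    """Geometric pose from explicit atoms/bonds (no valence model)."""
    rw = Chem.RWMol()
    for symbol, _ in atoms:
        a = Chem.Atom(symbol)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for i, j in bonds or []:
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, (_, xyz) in enumerate(atoms):
        conf.SetAtomPosition(i, xyz)
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol, chem_io.GEOMETRY_SANITIZE_FLAGS)
    return make_pose(mol, compound_id, structure_id, score)


def random_geometry_pose(pocket: ReceptorStructure, seed: int, n_atoms: int = 12) -> PoseRecord:
    """Random unstructured ligand geometry inside the cavity: C/N/O atoms
    scattered within the pocket radius, some N atoms given an explicit H.

    Exercises detector boundaries far more aggressively than planted poses.
    """
    rng = np.random.default_rng(seed)
    rw = Chem.RWMol()
    coords: list[tuple[float, float, float]] = []
    for _ in range(n_atoms):
        symbol = rng.choice(["C", "C", "N", "O"])
        a = Chem.Atom(str(symbol))
        a.SetNoImplicit(True)
        idx = rw.AddAtom(a)
        # bias toward the hemisphere shell where residues live
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        direction[2] = abs(direction[2])
        radius = rng.uniform(1.0, 9.0)
        pos = radius * direction
        coords.append(tuple(float(v) for v in pos))
        if symbol == "N" and rng.random() < 0.5:
            h = Chem.Atom(1)
            h_idx = rw.AddAtom(h)
            rw.AddBond(idx, h_idx, Chem.BondType.SINGLE)
            offset = rng.normal(size=3)
            offset /= np.linalg.norm(offset)
            h_pos = np.array(pos) + 1.01 * offset
            coords.append(tuple(float(v) for v in h_pos))
    mol = rw.GetMol()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, xyz)
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol, chem_io.GEOMETRY_SANITIZE_FLAGS)
    return make_pose(mol, f"rand{seed}", pocket.id)
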