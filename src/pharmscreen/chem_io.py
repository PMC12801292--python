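"""Molecule, receptor, pose and score-manifest I/O.

All downstream modules consume the containers defined here: RDKit ``Mol``
objects for small molecules (with the compound id stored on the ``_Name``
property), a lightweight residue/atom model for receptor binding sites read
from PDB, and :class:`PoseRecord` rows joining a docked conformer to the
engine score reported for it.

Conventions
-----------
* Coordinates are in Angstrom (PDB and SDF standard).
* Compound and structure identifiers are compared case-sensitively after
  whitespace trimming; nothing is silently merged.
* Explicit hydrogens present in an input pose are preserved and never added.
* PDB alternate locations: only altloc ' ' or 'A' atoms are kept, so each
  receptor atom has a single deterministic position.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

#: RDKit sanitization used for geometry-only poses (ring perception and
#: aromaticity, but no valence model — synthetic poses are geometric
#: scaffolds, not chemically complete molecules).
GEOMETRY_SANITIZE_FLAGS = (
    Chem.SanitizeFlags.SANITIZE_ALL
    ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
    ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
)


class ChemIOError(Exception):
    """Base class for I/O failures in this module."""


class EmptyInputError(ChemIOError):
    """An input file contained no usable records."""


class ManifestError(ChemIOError):
    """A docking-score manifest failed validation."""


# ---------------------------------------------------------------------------
# receptor model
# ---------------------------------------------------------------------------

WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


@dataclass(frozen=True)
class Atom:
    """A single receptor atom (PDB naming, Angstrom coordinates)."""

    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class Residue:
    chain: str
    number: int
    name: str
    atoms: tuple[Atom, ...]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.name)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class ReceptorStructure:
    """A protein binding-site model: residues with typed, positioned atoms."""

    id: str
    residues: tuple[Residue, ...]
    binding_site: frozenset[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for r in self.residues:
            k = (r.chain, r.number)
            if k in seen:
                raise ValueError(f"duplicate residue {k} in structure {self.id!r}")
            seen.add(k)
        if self.binding_site is not None:
            missing = set(self.binding_site) - seen
            if missing:
                raise ValueError(f"binding-site members not in residues: {sorted(missing)}")

    def residue(self, chain: str, number: int) -> Residue:
        for r in self.residues:
            if r.chain == chain and r.number == number:
                return r
        raise KeyError((chain, number))

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


# ---------------------------------------------------------------------------
# small molecules
# ---------------------------------------------------------------------------

Molecule = Chem.Mol


def mol_id(mol: Chem.Mol) -> str:
    """Identifier of a molecule (``_Name`` property, whitespace-trimmed)."""
    if mol.HasProp("_Name"):
        return mol.GetProp("_Name").strip()
    return ""


def set_mol_id(mol: Chem.Mol, ident: str) -> Chem.Mol:
    mol.SetProp("_Name", ident.strip())
    return mol


def heavy_atom_count(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def read_sdf(path: str | Path, *, sanitize: bool = True) -> list[Chem.Mol]:
    """Read an SDF (V2000) file into a list of RDKit molecules.

    Per-record parse failures are logged and skipped rather than aborting
    the read; SD tags are preserved as molecule properties. Raises
    :class:`EmptyInputError` when no record parses.
    """
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=sanitize)
    mols: list[Chem.Mol] = []
    n_failed = 0
    for i, mol in enumerate(supplier):
        if mol is None:
            n_failed += 1
            logger.warning("SDF record %d of %s failed to parse", i, path)
            continue
        if not sanitize:
            Chem.SanitizeMol(mol, GEOMETRY_SANITIZE_FLAGS)
        mols.append(mol)
    if not mols:
        raise EmptyInputError(f"no valid SDF records in {path}")
    if n_failed:
        logger.warning("%d of %d SDF records in %s failed to parse", n_failed, n_failed + len(mols), path)
    return mols


def write_sdf(mols: Iterable[Chem.Mol], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for mol in mols:
        writer.write(mol)
    writer.close()


def read_smiles(path: str | Path) -> list[Chem.Mol]:
    """Read a SMILES file (one molecule per line, optional id column)."""
    path = Path(path)
    mols: list[Chem.Mol] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        mol = Chem.MolFromSmiles(parts[0])
        if mol is None:
            logger.warning("line %d of %s: unparseable SMILES %r", lineno, path, parts[0])
            continue
        set_mol_id(mol, parts[1] if len(parts) > 1 else f"line{lineno}")
        mols.append(mol)
    if not mols:
        raise EmptyInputError(f"no valid SMILES in {path}")
    return mols


def write_smiles(mols: Iterable[Chem.Mol], path: str | Path) -> None:
    with open(path, "w") as fh:
        for mol in mols:
            fh.write(f"{Chem.MolToSmiles(mol)}\t{mol_id(mol)}\n")


# ---------------------------------------------------------------------------
# PDB receptor parsing / writing
# ---------------------------------------------------------------------------


def read_pdb_receptor(
    path: str | Path,
    *,
    structure_id: str | None = None,
    chain: str | None = None,
    keep_hetero: bool = False,
) -> ReceptorStructure:
    """Parse a PDB file into a :class:`ReceptorStructure`.

    Waters and ligand heteroatoms are stripped unless ``keep_hetero`` is
    set; residue numbering is taken verbatim from the file; only altloc
    ' '/'A' atoms are retained.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(structure_id or path.stem, str(path))
    model = next(structure.get_models())
    residues: list[Residue] = []
    for ch in model:
        if chain is not None and ch.id != chain:
            continue
        for res in ch:
            hetfield, resseq, _icode = res.id
            resname = res.get_resname().strip()
            if resname in WATER_RESNAMES or hetfield == "W":
                continue
            if hetfield.strip() and not keep_hetero:
                continue
            atoms = []
            for atom in res.get_unpacked_list():
                if atom.get_altloc() not in (" ", "A"):
                    continue
                x, y, z = (float(v) for v in atom.get_coord())
                element = (atom.element or atom.get_name()[0]).strip().capitalize()
                atoms.append(Atom(atom.get_name().strip(), element, x, y, z))
            if atoms:
                residues.append(Residue(ch.id, int(resseq), resname, tuple(atoms)))
    if not residues:
        raise EmptyInputError(f"no protein atoms in {path}")
    return ReceptorStructure(structure_id or path.stem, tuple(residues))


def write_pdb_receptor(receptor: ReceptorStructure, path: str | Path) -> None:
    """Write a receptor as minimal PDB ATOM records (fixed-width, Angstrom)."""
    lines = []
    serial = 1
    for res in receptor.residues:
        for atom in res.atoms:
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {res.name:>3s} {res.chain:1s}"
                f"{res.number:4d}    {atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                f"  1.00  0.00          {atom.element:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# poses and score manifests
# ---------------------------------------------------------------------------


@dataclass
class PoseRecord:
    """One docked conformation of one compound in one receptor structure.

    ``docking_score`` follows the engine convention that more negative is
    a better predicted binder.
    """

    compound_id: str
    structure_id: str
    mol: Chem.Mol
    docking_score: float

    def __post_init__(self) -> None:
        self.compound_id = self.compound_id.strip()
        self.structure_id = self.structure_id.strip()
        if not math.isfinite(self.docking_score):
            raise ValueError(f"non-finite docking score for {self.compound_id!r}")
        if self.mol.GetNumConformers() == 0:
            raise ValueError(f"pose for {self.compound_id!r} has no 3D coordinates")
        if heavy_atom_count(self.mol) < 1:
            raise ValueError(f"pose for {self.compound_id!r} has no heavy atoms")

    @property
    def key(self) -> tuple[str, str]:
        return (self.compound_id, self.structure_id)

    def coords(self) -> np.ndarray:
        return self.mol.GetConformer().GetPositions()


MANIFEST_COLUMNS = ("compound_id", "structure_id", "docking_score", "pose_file")


def write_manifest(records: Sequence[Mapping[str, object]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(MANIFEST_COLUMNS))
        writer.writeheader()
        for row in records:
            writer.writerow({c: row[c] for c in MANIFEST_COLUMNS})


def load_pose_set(
    manifest_path: str | Path,
    pose_dir: str | Path | None = None,
    *,
    sanitize: bool = True,
) -> list[PoseRecord]:
    """Load docked poses listed in a score manifest.

    The manifest is CSV/TSV with header ``compound_id,structure_id,
    docking_score,pose_file``; each pose file is an SDF whose record names
    match the compound id. Duplicate (compound, structure) keys raise
    immediately; missing files or compounds are accumulated and raised as a
    single error report. Row order does not affect the returned set.
    """
    manifest_path = Path(manifest_path)
    base = Path(pose_dir) if pose_dir is not None else manifest_path.parent
    import pandas as pd

    sep = "\t" if manifest_path.suffix in (".tsv", ".tab") else ","
    frame = pd.read_csv(manifest_path, sep=sep)
    missing_cols = set(MANIFEST_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise ManifestError(f"manifest missing columns: {sorted(missing_cols)}")

    seen: set[tuple[str, str]] = set()
    errors: list[str] = []
    records: list[PoseRecord] = []
    cache: dict[Path, dict[str, Chem.Mol]] = {}

    for row in frame.itertuples(index=False):
        cid = str(row.compound_id).strip()
        sid = str(row.structure_id).strip()
        key = (cid, sid)
        if key in seen:
            raise ManifestError(f"duplicate manifest key {key}")
        seen.add(key)
        pose_path = base / str(row.pose_file)
        if pose_path not in cache:
            if not pose_path.exists():
                errors.append(f"missing pose file: {pose_path}")
                cache[pose_path] = {}
            else:
                try:
                    mols = read_sdf(pose_path, sanitize=sanitize)
                except ChemIOError as exc:
                    errors.append(str(exc))
                    mols = []
                cache[pose_path] = {mol_id(m): m for m in mols}
        pool = cache[pose_path]
        if cid not in pool:
            if pose_path.exists():
                errors.append(f"compound {cid!r} not found in {pose_path}")
            continue
        records.append(PoseRecord(cid, sid, pool[cid], float(row.docking_score)))

    if errors:
        raise ManifestError("pose-set errors:\n" + "\n".join(errors))
    return records
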