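"""Protein-ligand interaction detection and typing.

Two interaction classes are detected in a docked pose: hydrogen bonds (HB)
and hydrophobic contacts (HP). Hydrophobic contacts are subtyped alkyl
(aliphatic carbon-carbon), pi (aromatic ring stacking) or mixed (a residue
contacted through both channels in the same pose). The residue-level set of
typed contacts a pose makes is its :class:`InteractionProfile` — the unit
the pharmacological model counts over.

Geometric criteria
------------------
The defaults are community-standard values, all configurable through
:class:`InteractionCriteria`:

* HB: heavy-atom donor-acceptor distance <= 3.5 A; when the donor hydrogen
  is explicit, D-H...A angle >= 120 deg (the angle test is skipped for
  implicit hydrogens).
* Alkyl: apolar carbon pair <= 4.5 A. Apolar means a non-aromatic carbon
  whose heavy neighbors are all carbon (ligand side) or a non-aromatic
  side-chain carbon (receptor side, i.e. not the backbone C/CA and not part
  of an aromatic ring system).
* Pi stacking: aromatic ring centroids <= 5.5 A with interplanar angle
  <= 30 deg (parallel) or within [60, 90] deg (T-shaped).

Donor/acceptor typing is deliberately simple and reproducible: ligand N/O
with at least one hydrogen donate; every ligand N/O can accept. On the
receptor side (usually without explicit hydrogens) nitrogens and the
Ser/Thr/Tyr hydroxyl oxygens donate, oxygens and the His ring nitrogens
accept. No charge or pKa inference is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from rdkit import Chem
from scipy.spatial import cKDTree

from .chem_io import PoseRecord, ReceptorStructure, Residue

HB = "HB"
HP = "HP"
ALKYL = "alkyl"
PI = "pi"
MIXED = "mixed"
DONOR = "donor"
ACCEPTOR = "acceptor"

ResidueKey = tuple[str, int, str]
ProfileKey = tuple  # (chain, resnum, resname, kind[, subtype])


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric thresholds for interaction detection (Angstrom, degrees)."""

    hb_distance_max: float = 3.5
    hb_angle_min: float = 120.0
    hp_distance_max: float = 4.5
    pi_centroid_max: float = 5.5
    pi_parallel_angle_max: float = 30.0
    pi_tshaped_angle_min: float = 60.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "InteractionCriteria":
        return cls(**data)


DEFAULT_CRITERIA = InteractionCriteria()


@dataclass(frozen=True, order=True)
class Interaction:
    """A typed residue contact made by one pose."""

    chain: str
    resnum: int
    resname: str
    kind: str  # HB | HP
    subtype: str  # donor/acceptor for HB; alkyl/pi/mixed for HP
    distance: float
    angle: float | None = None

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("interaction distance must be positive")
        if self.kind == HB and self.subtype not in (DONOR, ACCEPTOR):
            raise ValueError(f"bad HB subtype {self.subtype!r}")
        if self.kind == HP and self.subtype not in (ALKYL, PI, MIXED):
            raise ValueError(f"bad HP subtype {self.subtype!r}")
        if self.angle is not None and not (0.0 <= self.angle <= 180.0):
            raise ValueError("angle outside [0, 180]")

    @property
    def residue(self) -> ResidueKey:
        return (self.chain, self.resnum, self.resname)

    def key(self, include_subtype: bool = False) -> ProfileKey:
        base = (self.chain, self.resnum, self.resname, self.kind)
        return base + (self.subtype,) if include_subtype else base


@dataclass(frozen=True)
class InteractionProfile:
    """The deduplicated set of typed residue contacts one pose makes."""

    compound_id: str
    structure_id: str
    interactions: tuple[Interaction, ...]

    def keys(self, include_subtype: bool = False) -> frozenset[ProfileKey]:
        return frozenset(i.key(include_subtype) for i in self.interactions)

    def __len__(self) -> int:
        return len(self.interactions)

    def to_records(self) -> list[dict]:
        """Tidy rows for CSV export."""
        return [
            {
                "compound_id": self.compound_id,
                "structure_id": self.structure_id,
                "chain": i.chain,
                "resnum": i.resnum,
                "resname": i.resname,
                "kind": i.kind,
                "subtype": i.subtype,
                "distance": i.distance,
                "angle": i.angle,
            }
            for i in self.interactions
        ]


# ---------------------------------------------------------------------------
# ligand atom typing
# ---------------------------------------------------------------------------


def _explicit_hydrogens(atom: Chem.Atom) -> list[int]:
    return [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() == 1]


def _has_hydrogen(atom: Chem.Atom) -> bool:
    return atom.GetTotalNumHs() > 0 or bool(_explicit_hydrogens(atom))


def ligand_donors(mol: Chem.Mol) -> list[tuple[int, list[int]]]:
    """N/O atoms with >=1 hydrogen; returns (atom index, explicit H indices)."""
    out = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() in (7, 8) and _has_hydrogen(atom):
            out.append((atom.GetIdx(), _explicit_hydrogens(atom)))
    return out


def ligand_acceptors(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8)]


def ligand_apolar_carbons(mol: Chem.Mol) -> list[int]:
    """Non-aromatic carbons with only carbon/hydrogen neighbors."""
    out = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetIsAromatic():
            continue
        if all(n.GetAtomicNum() in (1, 6) for n in atom.GetNeighbors()):
            out.append(atom.GetIdx())
    return out


def ligand_aromatic_rings(mol: Chem.Mol) -> list[tuple[int, ...]]:
    rings = []
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            rings.append(tuple(ring))
    return rings


# ---------------------------------------------------------------------------
# receptor atom typing
# ---------------------------------------------------------------------------

#: PDB atom names forming the aromatic ring system(s) of standard residues.
RECEPTOR_RING_ATOMS: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),),
    "TYR": (("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ),
    "HIS": (("CG", "ND1", "CE1", "NE2", "CD2"),),
}

#: Hydroxyl oxygens of Ser/Thr/Tyr: hydrogen-bond donors even without
#: explicit hydrogens in the PDB.
HYDROXYL_OXYGEN_NAMES = frozenset({"OG", "OG1", "OH"})

BACKBONE_CARBON_NAMES = frozenset({"C", "CA"})


def _residue_ring_atom_names(resname: str) -> frozenset[str]:
    return frozenset(n for ring in RECEPTOR_RING_ATOMS.get(resname, ()) for n in ring)


def receptor_acceptors(residue: Residue) -> list[int]:
    """Indices (into residue.atoms) of hydrogen-bond acceptor atoms."""
    out = []
    for i, a in enumerate(residue.atoms):
        if a.element == "O":
            out.append(i)
        elif a.element == "N" and residue.name == "HIS" and a.name in ("ND1", "NE2"):
            out.append(i)
    return out


def receptor_donors(residue: Residue) -> list[int]:
    out = []
    for i, a in enumerate(residue.atoms):
        if a.element == "N":
            out.append(i)
        elif a.element == "O" and a.name in HYDROXYL_OXYGEN_NAMES:
            out.append(i)
    return out


def receptor_alkyl_carbons(residue: Residue) -> list[int]:
    """Non-aromatic side-chain carbons eligible for alkyl contacts."""
    ring_names = _residue_ring_atom_names(residue.name)
    return [
        i
        for i, a in enumerate(residue.atoms)
        if a.element == "C" and a.name not in BACKBONE_CARBON_NAMES and a.name not in ring_names
    ]


def receptor_rings(residue: Residue) -> list[np.ndarray]:
    """Coordinates (n x 3) of each complete aromatic ring of the residue."""
    rings = []
    for names in RECEPTOR_RING_ATOMS.get(residue.name, ()):
        atoms = [residue.atom(n) for n in names]
        if all(a is not None for a in atoms):
            rings.append(np.array([[a.x, a.y, a.z] for a in atoms]))
    return rings


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a ring given its atom coordinates."""
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[-1]


def interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two ring planes, folded into [0, 90] degrees."""
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return math.degrees(math.acos(min(1.0, c)))


def dha_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    """Donor-hydrogen-acceptor angle in degrees."""
    v1 = d - h
    v2 = a - h
    c = float(np.dot(v1, v2)) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _stacking_angle_ok(angle: float, criteria: InteractionCriteria) -> bool:
    return angle <= criteria.pi_parallel_angle_max or criteria.pi_tshaped_angle_min <= angle <= 90.0


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------


def _receptor_atom_table(
    receptor: ReceptorStructure, selector
) -> tuple[np.ndarray, list[ResidueKey]]:
    """Flatten per-residue atom selections into coords + residue labels."""
    coords: list[np.ndarray] = []
    labels: list[ResidueKey] = []
    for res in receptor.residues:
        for i in selector(res):
            coords.append(res.atoms[i].coord)
            labels.append(res.key)
    if not coords:
        return np.empty((0, 3)), []
    return np.array(coords), labels


def _require_coords(pose: PoseRecord) -> np.ndarray:
    if pose.mol.GetNumConformers() == 0:
        raise ValueError(f"pose {pose.compound_id!r} has no coordinates")
    return pose.mol.GetConformer().GetPositions()


def detect_hbonds(
    receptor: ReceptorStructure,
    pose: PoseRecord,
    criteria: InteractionCriteria = DEFAULT_CRITERIA,
) -> list[Interaction]:
    """Hydrogen bonds between a pose and the receptor.

    Every (donor, acceptor) pair within the heavy-atom distance cutoff is
    returned, one :class:`Interaction` per pair, labelled with the ligand's
    role. The D-H...A angle test applies only when the donor hydrogen is
    explicit (the best hydrogen is used); receptor donors are accepted
    without an angle test since PDB files rarely carry hydrogens.
    """
    xyz = _require_coords(pose)
    out: list[Interaction] = []

    # ligand donates
    acc_coords, acc_labels = _receptor_atom_table(receptor, receptor_acceptors)
    if len(acc_labels):
        tree = cKDTree(acc_coords)
        for d_idx, h_idxs in ligand_donors(pose.mol):
            d = xyz[d_idx]
            for j in tree.query_ball_point(d, criteria.hb_distance_max):
                dist = float(np.linalg.norm(acc_coords[j] - d))
                angle = None
                if h_idxs:
                    angle = max(dha_angle(d, xyz[h], acc_coords[j]) for h in h_idxs)
                    if angle < criteria.hb_angle_min:
                        continue
                ch, num, name = acc_labels[j]
                out.append(Interaction(ch, num, name, HB, DONOR, dist, angle))

    # ligand accepts
    don_coords, don_labels = _receptor_atom_table(receptor, receptor_donors)
    if len(don_labels):
        tree = cKDTree(don_coords)
        for a_idx in ligand_acceptors(pose.mol):
            a = xyz[a_idx]
            for j in tree.query_ball_point(a, criteria.hb_distance_max):
                dist = float(np.linalg.norm(don_coords[j] - a))
                ch, num, name = don_labels[j]
                out.append(Interaction(ch, num, name, HB, ACCEPTOR, dist, None))

    out.sort()
    return out


def detect_hydrophobic(
    receptor: ReceptorStructure,
    pose: PoseRecord,
    criteria: InteractionCriteria = DEFAULT_CRITERIA,
) -> list[Interaction]:
    """Hydrophobic contacts, one per residue, subtyped alkyl/pi/mixed.

    A residue reached both by an aliphatic carbon-carbon contact and by a
    ring-stacking contact in the same pose is reported once, as mixed.
    """
    xyz = _require_coords(pose)
    alkyl_hits: dict[ResidueKey, float] = {}
    pi_hits: dict[ResidueKey, tuple[float, float]] = {}

    carbon_coords, carbon_labels = _receptor_atom_table(receptor, receptor_alkyl_carbons)
    lig_carbons = ligand_apolar_carbons(pose.mol)
    if len(carbon_labels) and lig_carbons:
        tree = cKDTree(carbon_coords)
        for i in lig_carbons:
            c = xyz[i]
            for j in tree.query_ball_point(c, criteria.hp_distance_max):
                dist = float(np.linalg.norm(carbon_coords[j] - c))
                key = carbon_labels[j]
                if key not in alkyl_hits or dist < alkyl_hits[key]:
                    alkyl_hits[key] = dist

    lig_rings = [np.array([xyz[i] for i in ring]) for ring in ligand_aromatic_rings(pose.mol)]
    if lig_rings:
        lig_planes = [ring_plane(r) for r in lig_rings]
        for res in receptor.residues:
            for rec_ring in receptor_rings(res):
                rc, rn = ring_plane(rec_ring)
                for lc, ln in lig_planes:
                    dist = float(np.linalg.norm(rc - lc))
                    if dist > criteria.pi_centroid_max:
                        continue
                    angle = interplanar_angle(ln, rn)
                    if not _stacking_angle_ok(angle, criteria):
                        continue
                    key = res.key
                    if key not in pi_hits or dist < pi_hits[key][0]:
                        pi_hits[key] = (dist, angle)

    out: list[Interaction] = []
    for key in set(alkyl_hits) | set(pi_hits):
        ch, num, name = key
        if key in alkyl_hits and key in pi_hits:
            out.append(Interaction(ch, num, name, HP, MIXED, min(alkyl_hits[key], pi_hits[key][0])))
        elif key in alkyl_hits:
            out.append(Interaction(ch, num, name, HP, ALKYL, alkyl_hits[key]))
        else:
            dist, angle = pi_hits[key]
            out.append(Interaction(ch, num, name, HP, PI, dist, angle))
    out.sort()
    return out


def profile_pose(
    receptor: ReceptorStructure,
    pose: PoseRecord,
    criteria: InteractionCriteria = DEFAULT_CRITERIA,
) -> InteractionProfile:
    """Union of HB and HP interactions, deduplicated to residue-level keys.

    Multiple hydrogen bonds to one residue collapse to the closest; the
    ordering is deterministic by (chain, residue number, kind).
    """
    best: dict[tuple, Interaction] = {}
    for inter in detect_hbonds(receptor, pose, criteria) + detect_hydrophobic(receptor, pose, criteria):
        k = inter.key()
        if k not in best or inter.distance < best[k].distance:
            best[k] = inter
    ordered = tuple(sorted(best.values(), key=lambda i: (i.chain, i.resnum, i.kind)))
    return InteractionProfile(pose.compound_id, pose.structure_id, ordered)


def profiles_to_frame(profiles: Iterable[InteractionProfile]):
    """Concatenate profiles into a tidy DataFrame for CSV export."""
    import pandas as pd

    rows = [r for p in profiles for r in p.to_records()]
    return pd.DataFrame(
        rows,
        columns=[
            "compound_id",
            "structure_id",
            "chain",
            "resnum",
            "resname",
            "kind",
            "subtype",
            "distance",
            "angle",
        ],
    )
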