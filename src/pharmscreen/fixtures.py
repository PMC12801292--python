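"""Synthetic pockets, planted-interaction poses and benchmark generation.

Everything the pipeline needs can be generated here with no external data:

* :func:`generate_pocket` builds a geometric binding pocket — simplified
  residues (Ser-like H-bond partners, Leu/Ala-like aliphatic side chains,
  Phe-like aromatic rings) arranged on a hemisphere around an origin
  cavity, written/read as ordinary PDB.
* :func:`plant_pose` places small ligand fragments so that each requested
  interaction satisfies its geometric criterion with margin (hydrogen-bond
  distances sampled in [2.7, 3.3] A, alkyl contacts in [3.6, 4.2] A,
  ring stacks in [3.3, 3.9] A) while every non-requested residue stays
  outside all cutoffs.
* :func:`generate_benchmark` emulates an actives-vs-decoys evaluation:
  actives realise each planted interaction with probability ``p_active``,
  decoys with a lower ``p_decoy``, and docking scores are drawn from
  class-conditional Gaussians whose overlap leaves docking-only enrichment
  clearly imperfect — the headroom the pharmacological score is meant to
  exploit.

The pockets are geometric scaffolds for exercising detectors and scoring,
not physically realistic structures; poses are built with ring/aromaticity
perception but no valence model. Everything is deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem_io import (
    Atom,
    GEOMETRY_SANITIZE_FLAGS,
    PoseRecord,
    ReceptorStructure,
    Residue,
    set_mol_id,
)
from .interactions import ALKYL, HB, HP, MIXED, PI

POCKET_RADIUS = 8.0  # distance of residue anchor atoms from the cavity origin
MIN_SEPARATION_DEG = 40.0  # guaranteed angular spacing between residues

HB_DISTANCE_RANGE = (2.7, 3.3)
ALKYL_DISTANCE_RANGE = (3.6, 4.2)
PI_DISTANCE_RANGE = (3.3, 3.9)

RING_RADIUS = 1.39  # aromatic C-C ring radius, Angstrom

#: residue types and the interaction each affords
HB_RESIDUES = ("SER",)
ALKYL_RESIDUES = ("LEU", "ALA")
AROMATIC_RESIDUES = ("PHE",)
RESIDUE_CYCLE = ("SER", "LEU", "PHE", "ALA")


class PlantingError(ValueError):
    """A requested interaction cannot be realised with the pocket."""


@dataclass(frozen=True)
class PlantedInteraction:
    """A single interaction to realise in a planted pose.

    ``subtype``: 'donor' for HB (the ligand donates to the residue's
    acceptor), or 'alkyl'/'pi'/'mixed' for HP.
    """

    residue_number: int
    kind: str
    subtype: str
    chain: str = "A"


# ---------------------------------------------------------------------------
# pocket construction
# ---------------------------------------------------------------------------


def _hemisphere_directions(n: int) -> np.ndarray:
    """n well-separated unit vectors on the upper hemisphere (Fibonacci)."""
    golden = math.pi * (3.0 - math.sqrt(5.0))
    out = np.empty((n, 3))
    for i in range(n):
        z = (i + 0.5) / n
        r = math.sqrt(1.0 - z * z)
        phi = i * golden
        out[i] = (r * math.cos(phi), r * math.sin(phi), z)
    return out


def _min_separation_deg(directions: np.ndarray) -> float:
    worst = 180.0
    for i in range(len(directions)):
        for j in range(i + 1, len(directions)):
            c = float(np.clip(np.dot(directions[i], directions[j]), -1, 1))
            worst = min(worst, math.degrees(math.acos(c)))
    return worst


def _tangent_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    t1 = np.cross(u, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(u, t1)
    return t1, t2


def _residue_atoms(resname: str, u: np.ndarray) -> list[Atom]:
    """Atoms of a simplified residue whose interaction anchor sits at
    POCKET_RADIUS * u, side chain pointing at the origin cavity."""
    t1, t2 = _tangent_frame(u)
    r = POCKET_RADIUS

    def at(name: str, element: str, du: float, d1: float = 0.0, d2: float = 0.0) -> Atom:
        pos = (r + du) * u + d1 * t1 + d2 * t2
        return Atom(name, element, float(pos[0]), float(pos[1]), float(pos[2]))

    if resname == "SER":
        return [
            at("OG", "O", 0.0),
            at("CB", "C", 1.42),
            at("CA", "C", 2.5, 0.8),
            at("N", "N", 3.3, 1.6),
            at("C", "C", 3.0, -0.9),
            at("O", "O", 4.1, -1.3),
        ]
    if resname == "LEU":
        return [
            at("CD1", "C", 0.0),
            at("CD2", "C", 0.9, 0.0, 1.3),
            at("CG", "C", 0.9, 0.75),
            at("CB", "C", 2.2, 1.1),
            at("CA", "C", 3.5, 0.9),
            at("N", "N", 4.3, 1.9),
            at("C", "C", 3.9, -0.4),
            at("O", "O", 5.0, -0.8),
        ]
    if resname == "ALA":
        return [
            at("CB", "C", 0.0),
            at("CA", "C", 1.54, 0.4),
            at("N", "N", 2.3, 1.5),
            at("C", "C", 2.2, -0.9),
            at("O", "O", 3.3, -1.2),
        ]
    if resname == "PHE":
        ring = []
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        for k, name in enumerate(names):
            theta = math.radians(60.0 * k)
            ring.append(at(name, "C", 0.0, RING_RADIUS * math.cos(theta), RING_RADIUS * math.sin(theta)))
        tail = [
            at("CB", "C", 1.2, 2.0),
            at("CA", "C", 2.5, 2.2),
            at("N", "N", 3.2, 3.2),
            at("C", "C", 3.0, 1.2),
            at("O", "O", 4.0, 0.9),
        ]
        return ring + tail
    raise ValueError(f"unknown fixture residue type {resname!r}")


def generate_pocket(n_residues: int, seed: int, structure_id: str = "POCKET") -> ReceptorStructure:
    """Deterministic synthetic binding pocket with ``n_residues`` residues.

    Residue types cycle through Ser/Leu/Phe/Ala (shuffled per seed) so any
    pocket with >= 4 residues affords hydrogen-bond, alkyl and pi partners.
    Raises if the hemisphere arrangement cannot guarantee the minimum
    angular spacing that keeps planted fragments outside the cutoffs of
    non-target residues.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    directions = _hemisphere_directions(n_residues)
    if _min_separation_deg(directions) < MIN_SEPARATION_DEG:
        raise ValueError(
            f"{n_residues} residues cannot be spaced >= {MIN_SEPARATION_DEG} degrees apart"
        )
    rng = np.random.default_rng(seed)
    types = [RESIDUE_CYCLE[i % len(RESIDUE_CYCLE)] for i in range(n_residues)]
    order = rng.permutation(n_residues)
    residues = []
    for i in range(n_residues):
        resname = types[order[i]]
        residues.append(Residue("A", i + 1, resname, tuple(_residue_atoms(resname, directions[i]))))
    return ReceptorStructure(structure_id, tuple(residues))


# ---------------------------------------------------------------------------
# planted poses
# ---------------------------------------------------------------------------


def _anchor(residue: Residue) -> np.ndarray:
    """Interaction anchor point of a fixture residue."""
    if residue.name in HB_RESIDUES:
        return residue.atom("OG").coord
    if residue.name == "LEU":
        return residue.atom("CD1").coord
    if residue.name == "ALA":
        return residue.atom("CB").coord
    if residue.name in AROMATIC_RESIDUES:
        ring = [residue.atom(n) for n in ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")]
        return np.mean([a.coord for a in ring], axis=0)
    raise PlantingError(f"residue {residue.key} has no fixture anchor")


class _PoseBuilder:
    def __init__(self) -> None:
        self.mol = Chem.RWMol()
        self.coords: list[tuple[float, float, float]] = []

    def add_atom(self, symbol: str, pos: np.ndarray, aromatic: bool = False) -> int:
        atom = Chem.Atom(symbol)
        atom.SetNoImplicit(True)
        if aromatic:
            atom.SetIsAromatic(True)
        idx = self.mol.AddAtom(atom)
        self.coords.append((float(pos[0]), float(pos[1]), float(pos[2])))
        return idx

    def add_bond(self, i: int, j: int, order=Chem.BondType.SINGLE, aromatic: bool = False) -> None:
        self.mol.AddBond(i, j, order)
        if aromatic:
            self.mol.GetBondBetweenAtoms(i, j).SetIsAromatic(True)

    def finish(self, compound_id: str) -> Chem.Mol:
        mol = self.mol.GetMol()
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, xyz in enumerate(self.coords):
            conf.SetAtomPosition(i, xyz)
        mol.AddConformer(conf)
        Chem.SanitizeMol(mol, GEOMETRY_SANITIZE_FLAGS)
        set_mol_id(mol, compound_id)
        return mol


def _plant_hb(builder: _PoseBuilder, anchor: np.ndarray, rng: np.random.Generator) -> None:
    u = anchor / np.linalg.norm(anchor)
    d = rng.uniform(*HB_DISTANCE_RANGE)
    n_pos = anchor - d * u  # toward the cavity origin
    h_pos = n_pos + 1.01 * u  # on the N...acceptor axis: angle 180 deg
    i_n = builder.add_atom("N", n_pos)
    i_h = builder.add_atom("H", h_pos)
    builder.add_bond(i_n, i_h)


def _plant_alkyl(builder: _PoseBuilder, anchor: np.ndarray, rng: np.random.Generator) -> None:
    u = anchor / np.linalg.norm(anchor)
    d = rng.uniform(*ALKYL_DISTANCE_RANGE)
    builder.add_atom("C", anchor - d * u)


def _plant_ring(builder: _PoseBuilder, center: np.ndarray, normal: np.ndarray, rng: np.random.Generator) -> None:
    t1, t2 = _tangent_frame(normal)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    idxs = []
    for k in range(6):
        theta = phase + math.radians(60.0 * k)
        pos = center + RING_RADIUS * (math.cos(theta) * t1 + math.sin(theta) * t2)
        idxs.append(builder.add_atom("C", pos, aromatic=True))
    for k in range(6):
        order = Chem.BondType.DOUBLE if k % 2 == 0 else Chem.BondType.SINGLE
        builder.add_bond(idxs[k], idxs[(k + 1) % 6], order, aromatic=True)


def plant_pose(
    pocket: ReceptorStructure,
    planted: Sequence[PlantedInteraction],
    seed: int | np.random.Generator,
    *,
    compound_id: str = "PLANTED",
    docking_score: float = -8.0,
) -> PoseRecord:
    """Build a pose realising exactly the requested interactions.

    Each fragment is placed along the line from its target residue's anchor
    to the cavity origin, well inside its cutoff; hemisphere spacing keeps
    it outside every other residue's cutoffs. An empty request yields a
    single carbon parked at the origin (no residue within any cutoff).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    builder = _PoseBuilder()
    for p in planted:
        try:
            residue = pocket.residue(p.chain, p.residue_number)
        except KeyError:
            raise PlantingError(f"no residue {p.chain}:{p.residue_number} in pocket") from None
        anchor = _anchor(residue)
        if p.kind == HB:
            if residue.name not in HB_RESIDUES:
                raise PlantingError(f"residue {residue.key} cannot accept a hydrogen bond")
            _plant_hb(builder, anchor, rng)
        elif p.kind == HP and p.subtype == ALKYL:
            if residue.name not in ALKYL_RESIDUES:
                raise PlantingError(f"residue {residue.key} has no aliphatic side chain")
            _plant_alkyl(builder, anchor, rng)
        elif p.kind == HP and p.subtype == PI:
            if residue.name not in AROMATIC_RESIDUES:
                raise PlantingError(f"residue {residue.key} has no aromatic ring")
            u = anchor / np.linalg.norm(anchor)
            d = rng.uniform(*PI_DISTANCE_RANGE)
            _plant_ring(builder, anchor - d * u, u, rng)
        elif p.kind == HP and p.subtype == MIXED:
            if residue.name not in AROMATIC_RESIDUES:
                raise PlantingError(f"mixed contact needs an aromatic residue, not {residue.key}")
            u = anchor / np.linalg.norm(anchor)
            d = rng.uniform(*PI_DISTANCE_RANGE)
            _plant_ring(builder, anchor - d * u, u, rng)
            # aliphatic partner near the ring-stack centroid: approaches the
            # residue's CB from the cavity axis so no neighbouring residue
            # falls inside the alkyl cutoff
            cb = residue.atom("CB")
            d2 = rng.uniform(*ALKYL_DISTANCE_RANGE)
            toward_axis = anchor - 3.8 * u - cb.coord
            toward_axis /= np.linalg.norm(toward_axis)
            builder.add_atom("C", cb.coord + d2 * toward_axis)
        else:
            raise PlantingError(f"cannot plant kind={p.kind!r} subtype={p.subtype!r}")
    if not planted:
        builder.add_atom("C", np.zeros(3))
    mol = builder.finish(compound_id)
    return PoseRecord(compound_id, pocket.id, mol, docking_score)


# ---------------------------------------------------------------------------
# benchmark generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreModel:
    """Class-conditional Gaussian docking-score model (more negative = better).

    The default mean shift of 1.4 at sd 1.5 puts docking-only enrichment
    near AUC 0.75 — good but imperfect, leaving headroom for the
    interaction term.
    """

    active_mean: float = -8.4
    decoy_mean: float = -7.0
    sd: float = 1.5


@dataclass(frozen=True)
class BenchmarkSpec:
    """Study conditions for a planted-signal actives-vs-decoys benchmark.

    Defaults mirror a desk-scale screen: three receptor structures, 60
    model-building actives per structure (of which the top 30 by docking
    score define the pharmacological model), and an evaluation set of 30
    actives versus 90 decoys. Actives realise each planted interaction
    with probability 0.9 (a conserved contact), decoys with 0.2
    (incidental contact).
    """

    n_structures: int = 3
    n_actives: int = 30
    n_decoys: int = 90
    n_model_actives: int = 60
    n_residues: int = 8
    n_planted_hb: int = 2
    n_planted_hp: int = 3
    p_active: float = 0.9
    p_decoy: float = 0.2
    score_model: ScoreModel = ScoreModel()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_decoy <= 1.0 and 0.0 <= self.p_active <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_actives < 1 or self.n_decoys < 1:
            raise ValueError("need at least one active and one decoy")


@dataclass
class Benchmark:
    """Generated benchmark: receptors, planted keys, poses and labels."""

    spec: BenchmarkSpec
    receptors: dict[str, ReceptorStructure]
    planted: dict[str, list[PlantedInteraction]]
    model_poses: dict[str, list[PoseRecord]]
    eval_poses: dict[str, list[PoseRecord]]
    labels: dict[str, int]  # compound id -> 1 active / 0 decoy


def _choose_planted(pocket: ReceptorStructure, spec: BenchmarkSpec, rng: np.random.Generator) -> list[PlantedInteraction]:
    hb_pool = [r for r in pocket.residues if r.name in HB_RESIDUES]
    hp_pool = [r for r in pocket.residues if r.name in ALKYL_RESIDUES + AROMATIC_RESIDUES]
    if len(hb_pool) < spec.n_planted_hb or len(hp_pool) < spec.n_planted_hp:
        raise ValueError("pocket composition cannot host the requested planted interactions")
    hb_pick = rng.choice(len(hb_pool), size=spec.n_planted_hb, replace=False)
    hp_pick = rng.choice(len(hp_pool), size=spec.n_planted_hp, replace=False)
    planted = [
        PlantedInteraction(hb_pool[i].number, HB, "donor") for i in sorted(hb_pick)
    ]
    for i in sorted(hp_pick):
        res = hp_pool[i]
        subtype = PI if res.name in AROMATIC_RESIDUES else ALKYL
        planted.append(PlantedInteraction(res.number, HP, subtype))
    return planted


def _realized_pose(
    pocket: ReceptorStructure,
    planted: Sequence[PlantedInteraction],
    p_realize: float,
    score_mean: float,
    score_sd: float,
    compound_id: str,
    rng: np.random.Generator,
) -> PoseRecord:
    realized = [p for p in planted if rng.random() < p_realize]
    score = float(rng.normal(score_mean, score_sd))
    return plant_pose(pocket, realized, rng, compound_id=compound_id, docking_score=score)


def generate_benchmark(spec: BenchmarkSpec) -> Benchmark:
    """Generate all structures, poses, scores and labels for one benchmark."""
    rng = np.random.default_rng(spec.seed)
    sm = spec.score_model
    receptors: dict[str, ReceptorStructure] = {}
    planted: dict[str, list[PlantedInteraction]] = {}
    model_poses: dict[str, list[PoseRecord]] = {}
    eval_poses: dict[str, list[PoseRecord]] = {}

    model_ids = [f"ACT{i + 1:03d}" for i in range(spec.n_model_actives)]
    active_ids = [f"EVA{i + 1:03d}" for i in range(spec.n_actives)]
    decoy_ids = [f"DEC{i + 1:03d}" for i in range(spec.n_decoys)]
    labels = {**{c: 1 for c in active_ids}, **{c: 0 for c in decoy_ids}}

    for s in range(spec.n_structures):
        sid = f"STR{s + 1}"
        pocket_seed = int(rng.integers(0, 2**31 - 1))
        pocket = generate_pocket(spec.n_residues, pocket_seed, sid)
        receptors[sid] = pocket
        planted[sid] = _choose_planted(pocket, spec, rng)
        model_poses[sid] = [
            _realized_pose(pocket, planted[sid], spec.p_active, sm.active_mean, sm.sd, cid, rng)
            for cid in model_ids
        ]
        eval_poses[sid] = [
            _realized_pose(
                pocket,
                planted[sid],
                spec.p_active if labels[cid] else spec.p_decoy,
                sm.active_mean if labels[cid] else sm.decoy_mean,
                sm.sd,
                cid,
                rng,
            )
            for cid in active_ids + decoy_ids
        ]
    return Benchmark(spec, receptors, planted, model_poses, eval_poses, labels)


def write_benchmark(benchmark: Benchmark, outdir: str | Path) -> None:
    """Serialize a benchmark as plain PDB/SDF/CSV files."""
    from . import chem_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for sid, pocket in benchmark.receptors.items():
        chem_io.write_pdb_receptor(pocket, outdir / f"{sid}.pdb")
        for tag, poses in (("model", benchmark.model_poses[sid]), ("eval", benchmark.eval_poses[sid])):
            sdf = outdir / f"{sid}_{tag}.sdf"
            chem_io.write_sdf([p.mol for p in poses], sdf)
            for p in poses:
                manifest_rows.append(
                    {
                        "compound_id": p.compound_id,
                        "structure_id": sid,
                        "docking_score": p.docking_score,
                        "pose_file": sdf.name,
                    }
                )
    chem_io.write_manifest(manifest_rows, outdir / "manifest.csv")
    with open(outdir / "labels.csv", "w") as fh:
        fh.write("compound_id,label\n")
        for cid in sorted(benchmark.labels):
            fh.write(f"{cid},{benchmark.labels[cid]}\n")


# ---------------------------------------------------------------------------
# 2D libraries for filtering / similarity / screening
# ---------------------------------------------------------------------------

_CORES = ("c1ccccc1", "c1ccncc1", "c1ccc2[nH]ccc2c1", "C1CCNCC1", "c1ccsc1", "c1cnc2[nH]cnc2c1")
_LINKERS = ("C(=O)N", "CN", "OC", "C(=O)O", "S(=O)(=O)N")
_TAILS = ("C", "CC", "CCO", "C(C)C", "CCN(C)C", "c1ccccc1")
_DECOR = ("", "O", "N", "Cl", "F", "OC")


def make_smiles_library(n: int, seed: int, prefix: str = "LIB") -> list[tuple[str, str]]:
    """Deterministic combinatorial library of valid, drug-sized SMILES."""
    pool: list[str] = []
    for dec in _DECOR:
        for tail in _TAILS:
            for linker in _LINKERS:
                for core in _CORES:
                    pool.append(f"{dec}{tail}{linker}{core}")
    valid = [s for s in pool if Chem.MolFromSmiles(s) is not None]
    if n > len(valid):
        raise ValueError(f"library pool holds only {len(valid)} valid compounds")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(valid), size=n, replace=False)
    return [(f"{prefix}{i + 1:04d}", valid[j]) for i, j in enumerate(sorted(picks))]


def designed_filter_library() -> list[tuple[str, str, str | None]]:
    """Ten compounds, one designed failure per cascade stage.

    Returns (id, smiles, expected_failing_stage_or_None). Designed for the
    classical Lipinski setting (one violation tolerated): the QED-stage
    compound carries exactly one logP violation, because a molecule passing
    a zero-violation rule of five essentially cannot fall below QED 0.25.
    """
    return [
        ("ok_benzamide", "NC(=O)c1ccccc1", None),
        ("ok_aspirin", "CC(=O)Oc1ccccc1C(=O)O", None),
        ("ok_caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", None),
        ("ok_ibuprofen", "CC(C)Cc1ccc(C(C)C(=O)O)cc1", None),
        ("ok_paracetamol", "CC(=O)Nc1ccc(O)cc1", None),
        ("fail_hts_silane", "CC[Si](CC)(CC)CC", "hts"),
        ("fail_lipinski_c40", "C" * 40, "lipinski"),
        ("fail_veber_peg", "CCOCCOCCOCCOCCOCC", "veber"),
        ("fail_pains_catechol", "Oc1ccccc1O", "pains"),
        (
            "fail_qed_nitro_pentaphenyl",
            "O=[N+]([O-])c1ccc(-c2ccc(-c3ccc(-c4ccc(-c5ccccc5)cc4)cc3)cc2)cc1",
            "qed",
        ),
    ]
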