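from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem

from pharmscreen import chem_io, fixtures
from pharmscreen.chem_io import Atom, PoseRecord, ReceptorStructure, Residue
from pharmscreen.interactions import (
    ALKYL,
    DEFAULT_CRITERIA,
    DONOR,
    HB,
    HP,
    MIXED,
    PI,
    InteractionCriteria,
    detect_hbonds,
    detect_hydrophobic,
    profile_pose,
)

from conftest import build_fragment_pose, make_pose, random_geometry_pose
from oracles import brute_force_profile_keys


def _serine_pocket() -> ReceptorStructure:
    """One serine with its hydroxyl O at the origin-facing position."""
    res = Residue(
        "A",
        7,
        "SER",
        (
            Atom("OG", "O", 0.0, 0.0, 0.0),
            Atom("CB", "C", 0.0, 0.0, 1.42),
            Atom("CA", "C", 0.8, 0.0, 2.5),
            Atom("N", "N", 1.6, 0.0, 3.3),
            Atom("C", "C", -0.9, 0.0, 3.0),
            Atom("O", "O", -1.3, 0.0, 4.1),
        ),
    )
    return ReceptorStructure("STR1", (res,))


def _leucine_pocket() -> ReceptorStructure:
    res = Residue(
        "A",
        3,
        "LEU",
        (
            Atom("CD1", "C", 0.0, 0.0, 0.0),
            Atom("CG", "C", 0.75, 0.0, 0.9),
            Atom("CB", "C", 1.1, 0.0, 2.2),
            Atom("CA", "C", 0.9, 0.0, 3.5),
        ),
    )
    return ReceptorStructure("STR1", (res,))


def test_hbond_ideal_geometry_is_donor():
    pocket = _serine_pocket()
    # N 2.8 A below OG, H on the N->OG axis: textbook donor geometry
    pose = build_fragment_pose([("N", (0.0, 0.0, -2.8)), ("H", (0.0, 0.0, -1.79))], [(0, 1)])
    hbonds = detect_hbonds(pocket, pose)
    assert any(i.subtype == DONOR and i.resnum == 7 for i in hbonds)
    donor = next(i for i in hbonds if i.subtype == DONOR)
    assert donor.distance == pytest.approx(2.8)
    assert donor.angle == pytest.approx(180.0)


def test_hbond_beyond_distance_cutoff():
    pocket = _serine_pocket()
    pose = build_fragment_pose([("N", (0.0, 0.0, -4.0)), ("H", (0.0, 0.0, -2.99))], [(0, 1)])
    assert detect_hbonds(pocket, pose) == []


def test_hbond_angle_rejects_bent_donor():
    pocket = _serine_pocket()
    # H placed sideways: D-H...A angle ~90 degrees, below the 120 cutoff
    pose = build_fragment_pose([("N", (0.0, 0.0, -2.8)), ("H", (1.01, 0.0, -2.8))], [(0, 1)])
    assert all(i.subtype != DONOR for i in detect_hbonds(pocket, pose))


def test_hbond_implicit_hydrogen_skips_angle_test():
    pocket = _serine_pocket()
    rw = Chem.RWMol()
    n = Chem.Atom(7)
    n.SetNoImplicit(True)
    n.SetNumExplicitHs(1)  # hydrogen present but not in the graph
    rw.AddAtom(n)
    mol = rw.GetMol()
    conf = Chem.Conformer(1)
    conf.SetAtomPosition(0, (0.0, 0.0, -2.8))
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol, chem_io.GEOMETRY_SANITIZE_FLAGS)
    pose = make_pose(mol)
    hbonds = detect_hbonds(pocket, pose)
    assert any(i.subtype == DONOR and i.angle is None for i in hbonds)


def test_alkyl_contact_on_leucine():
    pocket = _leucine_pocket()
    pose = build_fragment_pose([("C", (0.0, 0.0, -4.0))])
    hits = detect_hydrophobic(pocket, pose)
    assert [(i.resnum, i.kind, i.subtype) for i in hits] == [(3, HP, ALKYL)]
    assert hits[0].distance == pytest.approx(4.0)


def test_alkyl_polar_carbon_excluded():
    pocket = _leucine_pocket()
    # carbon bonded to oxygen is polarised, not an apolar contact atom
    pose = build_fragment_pose([("C", (0.0, 0.0, -4.0)), ("O", (0.0, 0.0, -5.4))], [(0, 1)])
    assert detect_hydrophobic(pocket, pose) == []


def test_pi_stacking_parallel_rings(pocket, residue_of):
    phe = residue_of("PHE")
    pose = fixtures.plant_pose(
        pocket, [fixtures.PlantedInteraction(phe.number, HP, PI)], seed=5, compound_id="pi"
    )
    hits = detect_hydrophobic(pocket, pose)
    assert [(i.resnum, i.subtype) for i in hits] == [(phe.number, PI)]


def test_mixed_contact_merges_to_single_entry(pocket, residue_of):
    phe = residue_of("PHE")
    pose = fixtures.plant_pose(
        pocket, [fixtures.PlantedInteraction(phe.number, HP, MIXED)], seed=6, compound_id="mx"
    )
    profile = profile_pose(pocket, pose)
    assert [(i.resnum, i.kind, i.subtype) for i in profile.interactions] == [(phe.number, HP, MIXED)]


def test_duplicate_contacts_deduplicate():
    pocket = _leucine_pocket()
    pose = build_fragment_pose([("C", (0.0, 0.0, -4.0)), ("C", (0.5, 0.0, -3.9))])
    profile = profile_pose(pocket, pose)
    assert len(profile) == 1


def test_empty_profile_when_nothing_in_range(pocket):
    pose = fixtures.plant_pose(pocket, [], seed=1, compound_id="far")
    assert len(profile_pose(pocket, pose)) == 0


def test_pose_without_coordinates_rejected():
    mol = Chem.MolFromSmiles("CCO")
    chem_io.set_mol_id(mol, "flat")
    with pytest.raises(ValueError, match="coordinates"):
        PoseRecord("flat", "STR1", mol, -5.0)


def test_profile_invariant_to_atom_order(pocket):
    planted = [
        fixtures.PlantedInteraction(r.number, HB, "donor")
        for r in pocket.residues
        if r.name == "SER"
    ] + [
        fixtures.PlantedInteraction(r.number, HP, ALKYL)
        for r in pocket.residues
        if r.name == "LEU"
    ]
    pose = fixtures.plant_pose(pocket, planted, seed=2, compound_id="c")
    order = list(range(pose.mol.GetNumAtoms()))[::-1]
    permuted = Chem.RenumberAtoms(pose.mol, order)
    pose2 = PoseRecord("c", pocket.id, permuted, pose.docking_score)
    assert profile_pose(pocket, pose).keys(True) == profile_pose(pocket, pose2).keys(True)


def test_monotonic_in_cutoffs(pocket):
    loose = InteractionCriteria(hb_distance_max=4.5, hp_distance_max=6.0, pi_centroid_max=7.0)
    for seed in range(8):
        pose = random_geometry_pose(pocket, seed)
        tight_keys = profile_pose(pocket, pose).keys()
        loose_keys = profile_pose(pocket, pose, loose).keys()
        assert tight_keys <= loose_keys


def _rigid_transform(receptor, pose, rotation, translation):
    def move(p):
        return rotation @ p + translation

    residues = []
    for r in receptor.residues:
        atoms = tuple(
            Atom(a.name, a.element, *[float(v) for v in move(a.coord)]) for a in r.atoms
        )
        residues.append(Residue(r.chain, r.number, r.name, atoms))
    rec2 = ReceptorStructure(receptor.id, tuple(residues))
    mol2 = Chem.Mol(pose.mol)
    conf = mol2.GetConformer()
    for i in range(mol2.GetNumAtoms()):
        conf.SetAtomPosition(i, tuple(float(v) for v in move(np.array(conf.GetAtomPosition(i)))))
    return rec2, PoseRecord(pose.compound_id, pose.structure_id, mol2, pose.docking_score)


def test_rigid_transform_invariance(pocket):
    rng = np.random.default_rng(0)
    theta = 0.7
    rotation = np.array(
        [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
    )
    translation = np.array([3.0, -2.0, 5.0])
    for seed in (1, 4, 9):
        pose = random_geometry_pose(pocket, seed)
        rec2, pose2 = _rigid_transform(pocket, pose, rotation, translation)
        assert profile_pose(pocket, pose).keys(True) == profile_pose(rec2, pose2).keys(True)


@pytest.mark.parametrize("seed", range(12))
def test_detector_matches_brute_force_enumeration(pocket, seed):
    pose = random_geometry_pose(pocket, seed, n_atoms=16)
    detected = profile_pose(pocket, pose).keys()
    expected = brute_force_profile_keys(pocket, pose, DEFAULT_CRITERIA)
    assert detected == expected
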