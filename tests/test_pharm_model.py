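from __future__ import annotations

import logging

import numpy as np
import pytest
from rdkit import Chem

from pharmscreen.chem_io import PoseRecord
from pharmscreen.interactions import DONOR, HB, HP, ALKYL, Interaction, InteractionProfile
from pharmscreen.pharm_model import (
    FrequencyTable,
    PharmacologicalModel,
    count_matches,
    identify_pharmacological,
    interaction_frequencies,
    select_top_poses,
)


def _dummy_pose(cid: str, score: float, sid: str = "STR1") -> PoseRecord:
    mol = Chem.MolFromSmiles("C")
    conf = Chem.Conformer(1)
    conf.SetAtomPosition(0, (0.0, 0.0, 0.0))
    mol.AddConformer(conf)
    mol.SetProp("_Name", cid)
    return PoseRecord(cid, sid, mol, score)


def _profile(cid: str, keys: list[tuple], sid: str = "STR1") -> InteractionProfile:
    inters = tuple(
        Interaction(ch, num, name, kind, DONOR if kind == HB else ALKYL, 3.0)
        for ch, num, name, kind in keys
    )
    return InteractionProfile(cid, sid, inters)


SER_HB = ("A", 2, "SER", HB)
LEU_HP = ("A", 3, "LEU", HP)
PHE_HP = ("A", 5, "PHE", HP)


class TestSelectTopPoses:
    def test_top_30_of_60_by_most_negative_score(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(-8, 2, size=60)
        poses = [_dummy_pose(f"c{i:02d}", float(s)) for i, s in enumerate(scores)]
        top = select_top_poses(poses, 30)
        assert len(top) == 30
        cutoff = sorted(scores)[29]
        assert all(p.docking_score <= cutoff for p in top)

    def test_ties_break_lexicographically(self):
        poses = [_dummy_pose(c, -5.0) for c in ("b", "c", "a")]
        top = select_top_poses(poses, 2)
        assert [p.compound_id for p in top] == ["a", "b"]

    def test_n_equal_to_pool_is_identity(self):
        poses = [_dummy_pose(f"c{i}", -float(i)) for i in range(5)]
        assert len(select_top_poses(poses, 5)) == 5

    def test_fewer_than_n_warns_and_returns_all(self, caplog):
        poses = [_dummy_pose(f"c{i}", -float(i)) for i in range(3)]
        with caplog.at_level(logging.WARNING):
            top = select_top_poses(poses, 30)
        assert len(top) == 3
        assert any("only 3" in r.message for r in caplog.records)

    def test_best_pose_per_compound(self):
        poses = [_dummy_pose("a", -4.0), _dummy_pose("a", -9.0), _dummy_pose("b", -6.0)]
        top = select_top_poses(poses, 2)
        assert [(p.compound_id, p.docking_score) for p in top] == [("a", -9.0), ("b", -6.0)]


class TestFrequencies:
    def test_half_and_full_frequencies(self):
        profiles = [_profile(f"c{i}", [SER_HB] if i < 15 else []) for i in range(30)]
        profiles = [
            InteractionProfile(p.compound_id, p.structure_id, p.interactions + _profile("x", [LEU_HP]).interactions)
            for p in profiles
        ]
        table = interaction_frequencies(profiles)
        assert table.frequencies[SER_HB[:4]] == pytest.approx(0.50)
        assert table.frequencies[LEU_HP[:4]] == pytest.approx(1.0)

    def test_matches_counting_oracle_on_random_sets(self):
        rng = np.random.default_rng(3)
        pool = [SER_HB, LEU_HP, PHE_HP, ("A", 7, "ALA", HP), ("A", 8, "SER", HB)]
        profiles = []
        for i in range(40):
            picks = [pool[j] for j in range(len(pool)) if rng.random() < 0.5]
            profiles.append(_profile(f"c{i}", picks))
        table = interaction_frequencies(profiles)
        # oracle: recount by brute force over the profile list
        for key in pool:
            expected = sum(1 for p in profiles if key in p.keys()) / len(profiles)
            assert table.frequencies.get(key, 0.0) == pytest.approx(expected)

    def test_concatenated_sets_average(self):
        a = [_profile(f"a{i}", [SER_HB]) for i in range(10)]
        b = [_profile(f"b{i}", []) for i in range(10)]
        fa = interaction_frequencies(a).frequencies.get(SER_HB, 0.0)
        fb = interaction_frequencies(b).frequencies.get(SER_HB, 0.0)
        fab = interaction_frequencies(a + b).frequencies.get(SER_HB, 0.0)
        assert fab == pytest.approx((fa + fb) / 2)

    def test_mixed_structures_rejected(self):
        with pytest.raises(ValueError, match="structure"):
            interaction_frequencies([_profile("a", []), _profile("b", [], sid="STR2")])


class TestThresholds:
    def test_threshold_application(self):
        table = FrequencyTable(
            "STR1",
            100,
            {
                ("A", 1, "SER", HB): 63,
                ("A", 2, "LYS", HB): 30,
                ("A", 3, "LEU", HP): 85,
                ("A", 4, "TYR", HP): 70,
            },
        )
        model = identify_pharmacological(table)
        assert model.key_interactions == {("A", 1, "SER", HB), ("A", 3, "LEU", HP)}

    def test_boundaries_are_inclusive(self):
        table = FrequencyTable(
            "STR1", 100, {("A", 1, "SER", HB): 50, ("A", 3, "LEU", HP): 80}
        )
        model = identify_pharmacological(table)
        assert len(model.key_interactions) == 2

    def test_just_below_boundary_excluded(self):
        table = FrequencyTable(
            "STR1", 100, {("A", 1, "SER", HB): 49, ("A", 3, "LEU", HP): 79}
        )
        assert len(identify_pharmacological(table).key_interactions) == 0

    def test_empty_table_gives_empty_model(self):
        model = identify_pharmacological(FrequencyTable("STR1", 10, {}))
        assert model.key_interactions == frozenset()

    def test_raising_thresholds_never_adds_keys(self):
        rng = np.random.default_rng(5)
        counts = {("A", i, "SER" if i % 2 else "LEU", HB if i % 2 else HP): int(rng.integers(0, 101)) for i in range(12)}
        table = FrequencyTable("STR1", 100, counts)
        prev = identify_pharmacological(table, 0.3, 0.3).key_interactions
        for t in (0.5, 0.7, 0.9, 1.0):
            cur = identify_pharmacological(table, t, t).key_interactions
            assert cur <= prev
            prev = cur


class TestCountMatches:
    MODEL = PharmacologicalModel(
        "STR1", key_interactions=frozenset({SER_HB, LEU_HP, PHE_HP, ("A", 7, "ALA", HP), ("A", 8, "SER", HB)})
    )

    def test_full_match(self):
        profile = _profile("c", [SER_HB, LEU_HP, PHE_HP, ("A", 7, "ALA", HP), ("A", 8, "SER", HB)])
        assert count_matches(profile, self.MODEL) == 5

    def test_empty_profile(self):
        assert count_matches(_profile("c", []), self.MODEL) == 0

    def test_partial_match_ignores_non_model_contacts(self):
        profile = _profile("c", [SER_HB, LEU_HP, ("B", 1, "GLY", HB), ("B", 2, "VAL", HP), ("B", 3, "ILE", HP)])
        assert count_matches(profile, self.MODEL) == 2

    def test_structure_mismatch_raises(self):
        with pytest.raises(ValueError, match="structure"):
            count_matches(_profile("c", [], sid="STR2"), self.MODEL)

    def test_bounded_by_model_size(self):
        rng = np.random.default_rng(9)
        pool = list(self.MODEL.key_interactions) + [("B", i, "GLY", HB) for i in range(5)]
        for i in range(20):
            picks = [k for k in pool if rng.random() < 0.6]
            n = count_matches(_profile(f"c{i}", picks), self.MODEL)
            assert 0 <= n <= len(self.MODEL.key_interactions)


def test_model_json_round_trip(tmp_path):
    model = PharmacologicalModel(
        "STR1",
        key_interactions=frozenset({SER_HB, LEU_HP}),
        provenance={"n_poses": 30, "source_compounds": ["a", "b"]},
    )
    path = tmp_path / "model.json"
    model.to_json(path)
    back = PharmacologicalModel.from_json(path)
    assert back.structure_id == model.structure_id
    assert back.key_interactions == model.key_interactions
    assert back.hb_threshold == model.hb_threshold
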