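from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy import stats

from pharmscreen import chem_io, fixtures
from pharmscreen.fixtures import (
    Benchmark,
    BenchmarkSpec,
    PlantedInteraction,
    PlantingError,
    ScoreModel,
    generate_benchmark,
    generate_pocket,
    plant_pose,
)
from pharmscreen.interactions import ALKYL, HB, HP, MIXED, PI, profile_pose
from pharmscreen.pharm_model import build_model
from pharmscreen.evaluate import roc_auc


class TestPocket:
    def test_deterministic_pdb_output(self, tmp_path):
        a, b = tmp_path / "a.pdb", tmp_path / "b.pdb"
        chem_io.write_pdb_receptor(generate_pocket(8, seed=42), a)
        chem_io.write_pdb_receptor(generate_pocket(8, seed=42), b)
        assert a.read_bytes() == b.read_bytes()

    def test_residue_count(self):
        assert len(generate_pocket(5, seed=1).residues) == 5

    def test_round_trip_through_pdb(self, tmp_path):
        pocket = generate_pocket(7, seed=9, structure_id="P")
        path = tmp_path / "p.pdb"
        chem_io.write_pdb_receptor(pocket, path)
        back = chem_io.read_pdb_receptor(path, structure_id="P")
        assert [r.key for r in back.residues] == [r.key for r in pocket.residues]

    def test_too_many_residues_rejected(self):
        with pytest.raises(ValueError, match="spaced"):
            generate_pocket(30, seed=1)


class TestPlantPose:
    """The module's core contract: the detector recovers exactly the
    requested interactions, nothing more."""

    @pytest.mark.parametrize("seed", range(6))
    def test_detected_profile_equals_request(self, pocket, seed):
        rng = np.random.default_rng(seed)
        ser = [r for r in pocket.residues if r.name == "SER"]
        leu = [r for r in pocket.residues if r.name in ("LEU", "ALA")]
        phe = [r for r in pocket.residues if r.name == "PHE"]
        planted = []
        if rng.random() < 0.8:
            planted.append(PlantedInteraction(ser[int(rng.integers(len(ser)))].number, HB, "donor"))
        if rng.random() < 0.8:
            planted.append(PlantedInteraction(leu[int(rng.integers(len(leu)))].number, HP, ALKYL))
        if rng.random() < 0.8:
            planted.append(PlantedInteraction(phe[int(rng.integers(len(phe)))].number, HP, PI))
        pose = plant_pose(pocket, planted, seed=seed + 100, compound_id="p")
        detected = profile_pose(pocket, pose)
        expected = {("A", p.residue_number, pocket.residue("A", p.residue_number).name, p.kind) for p in planted}
        assert detected.keys() == expected

    def test_subtypes_match_request(self, pocket, residue_of):
        phe = residue_of("PHE")
        leu = residue_of("LEU")
        planted = [
            PlantedInteraction(phe.number, HP, MIXED),
            PlantedInteraction(leu.number, HP, ALKYL),
        ]
        pose = plant_pose(pocket, planted, seed=3, compound_id="p")
        by_res = {i.resnum: i.subtype for i in profile_pose(pocket, pose).interactions}
        assert by_res == {phe.number: MIXED, leu.number: ALKYL}

    def test_empty_request_empty_profile(self, pocket):
        pose = plant_pose(pocket, [], seed=1, compound_id="e")
        assert len(profile_pose(pocket, pose)) == 0

    def test_unrealizable_request_names_residue(self, pocket, residue_of):
        leu = residue_of("LEU")
        with pytest.raises(PlantingError, match=str(leu.number)):
            plant_pose(pocket, [PlantedInteraction(leu.number, HP, PI)], seed=1)
        with pytest.raises(PlantingError, match="99"):
            plant_pose(pocket, [PlantedInteraction(99, HB, "donor")], seed=1)


class TestBenchmark:
    def test_analytic_separation_case(self):
        # perfect realisation split + identical docking scores:
        # interaction count separates classes fully, docking not at all
        spec = BenchmarkSpec(
            n_structures=2,
            n_actives=10,
            n_decoys=20,
            n_model_actives=20,
            p_active=1.0,
            p_decoy=0.0,
            score_model=ScoreModel(active_mean=-8.0, decoy_mean=-8.0, sd=0.0),
            seed=5,
        )
        bench = generate_benchmark(spec)
        for sid, pocket in bench.receptors.items():
            model = build_model(pocket, bench.model_poses[sid], top_n=20)
            assert len(model) == spec.n_planted_hb + spec.n_planted_hp
            compounds = sorted(bench.labels)
            y = [bench.labels[c] for c in compounds]
            from pharmscreen.pharm_model import count_matches

            n_by_c = {}
            d_by_c = {}
            for pose in bench.eval_poses[sid]:
                profile = profile_pose(pocket, pose)
                n_by_c[pose.compound_id] = count_matches(profile, model)
                d_by_c[pose.compound_id] = pose.docking_score
            assert roc_auc([n_by_c[c] for c in compounds], y) == pytest.approx(1.0)
            assert roc_auc([-d_by_c[c] for c in compounds], y) == pytest.approx(0.5)

    def test_null_case_no_systematic_gap(self):
        # equal realisation probabilities and equal score means: neither
        # ranking carries signal, so neither should beat the other
        from pharmscreen.pipeline import run_benchmark

        diffs = []
        base = BenchmarkSpec(
            n_structures=2,
            n_actives=12,
            n_decoys=24,
            n_model_actives=20,
            p_active=0.5,
            p_decoy=0.5,
            score_model=ScoreModel(active_mean=-7.5, decoy_mean=-7.5, sd=1.5),
        )
        rng = np.random.default_rng(77)
        for _ in range(25):
            spec = dataclasses.replace(base, seed=int(rng.integers(0, 2**31 - 1)))
            result = run_benchmark(spec, top_n=20)
            diffs.append(result["mean_auc_pharmacological"] - result["mean_auc_docking"])
        mean = float(np.mean(diffs))
        sem = float(np.std(diffs, ddof=1) / np.sqrt(len(diffs)))
        assert abs(mean) < 3 * sem + 1e-9

    def test_planted_frequency_within_binomial_ci(self):
        spec = BenchmarkSpec(seed=13)
        bench = generate_benchmark(spec)
        sid = "STR1"
        pocket = bench.receptors[sid]
        planted_keys = {
            ("A", p.residue_number, pocket.residue("A", p.residue_number).name, p.kind)
            for p in bench.planted[sid]
        }
        counts = {k: 0 for k in planted_keys}
        poses = bench.model_poses[sid]
        for pose in poses:
            keys = profile_pose(pocket, pose).keys()
            for k in planted_keys & keys:
                counts[k] += 1
        n = len(poses)
        lo, hi = stats.binom.interval(0.99, n, spec.p_active)
        for k, c in counts.items():
            assert lo <= c <= hi, (k, c, lo, hi)

    def test_determinism_of_written_files(self, tmp_path):
        spec = BenchmarkSpec(seed=3, n_structures=1, n_actives=3, n_decoys=3, n_model_actives=4)
        for sub in ("a", "b"):
            fixtures.write_benchmark(generate_benchmark(spec), tmp_path / sub)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_labels_and_counts(self):
        spec = BenchmarkSpec(seed=1, n_structures=2, n_actives=5, n_decoys=7, n_model_actives=6)
        bench = generate_benchmark(spec)
        assert sum(bench.labels.values()) == 5
        assert len(bench.labels) == 12
        for sid in bench.receptors:
            assert len(bench.model_poses[sid]) == 6
            assert len(bench.eval_poses[sid]) == 12
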