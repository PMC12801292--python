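"""End-to-end orchestration: benchmark evaluation and the staged screen.

:func:`run_benchmark` executes the full model-building + evaluation protocol
on a planted-signal benchmark: build one pharmacological model per receptor
structure from the top-scored known actives, score an actives-vs-decoys set
with the docking score alone and with the pharmacological score, and
aggregate per-structure rankings into a consensus. It reports ROC-AUCs for
every ranker.

:func:`run_screen` mirrors a production virtual screen at configurable
scale: library generation -> drug-likeness filter cascade -> (mock) docking
-> top-K by docking score -> per-structure pharmacological scoring ->
consensus rerank -> top-K consensus -> similarity clustering ->
representative list. Every stage writes a plain-file artifact and its
counts into a run report; wall-clock timings go to a separate JSON-lines
log so the artifact set is byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from rdkit import Chem

from . import chem_io, filters, fixtures, pharm_model, scoring, similarity
from .evaluate import roc_auc
from .interactions import DEFAULT_CRITERIA, InteractionCriteria, profile_pose


# ---------------------------------------------------------------------------
# benchmark protocol
# ---------------------------------------------------------------------------


def run_benchmark(
    spec: fixtures.BenchmarkSpec,
    criteria: InteractionCriteria = DEFAULT_CRITERIA,
    *,
    top_n: int = pharm_model.DEFAULT_TOP_N,
    hb_threshold: float = pharm_model.DEFAULT_HB_THRESHOLD,
    hp_threshold: float = pharm_model.DEFAULT_HP_THRESHOLD,
) -> dict:
    """Generate a benchmark and evaluate docking, pharmacological and
    consensus rankers on it.

    Returns per-structure AUCs for the docking-only and pharmacological
    rankers, the consensus AUC over all structures, and the fitted models.
    """
    bench = fixtures.generate_benchmark(spec)
    labels = bench.labels
    compounds = sorted(labels)
    y = [labels[c] for c in compounds]

    auc_dock: dict[str, float] = {}
    auc_pharm: dict[str, float] = {}
    rankings: dict[str, pd.DataFrame] = {}
    models: dict[str, pharm_model.PharmacologicalModel] = {}

    for sid in sorted(bench.receptors):
        pocket = bench.receptors[sid]
        models[sid] = pharm_model.build_model(
            pocket,
            bench.model_poses[sid],
            criteria=criteria,
            top_n=top_n,
            hb_threshold=hb_threshold,
            hp_threshold=hp_threshold,
        )
        rows = []
        for pose in bench.eval_poses[sid]:
            profile = profile_pose(pocket, pose, criteria)
            n = pharm_model.count_matches(profile, models[sid])
            rows.append(
                {
                    "compound_id": pose.compound_id,
                    "structure_id": sid,
                    "D": pose.docking_score,
                    "N": n,
                    "S": scoring.pharmacological_score(n, pose.docking_score),
                }
            )
        table = scoring.rank_by_score(pd.DataFrame(rows))
        rankings[sid] = table
        d = dict(zip(table["compound_id"], table["D"]))
        s = dict(zip(table["compound_id"], table["S"]))
        auc_dock[sid] = roc_auc([-d[c] for c in compounds], y)
        auc_pharm[sid] = roc_auc([s[c] for c in compounds], y)

    consensus = scoring.consensus_rank(rankings)
    cons_score = dict(zip(consensus["compound_id"], consensus["consensus_score"]))
    auc_consensus = roc_auc([-cons_score[c] for c in compounds], y)

    return {
        "auc_docking": auc_dock,
        "auc_pharmacological": auc_pharm,
        "auc_consensus": auc_consensus,
        "mean_auc_docking": float(np.mean(list(auc_dock.values()))),
        "mean_auc_pharmacological": float(np.mean(list(auc_pharm.values()))),
        "models": models,
        "rankings": rankings,
        "consensus": consensus,
        "labels": labels,
    }


def benchmark_replicates(
    base_spec: fixtures.BenchmarkSpec,
    n_replicates: int,
    seed: int,
    criteria: InteractionCriteria = DEFAULT_CRITERIA,
) -> pd.DataFrame:
    """Run the benchmark protocol across seeded replicates.

    Returns one row per replicate with the mean single-structure AUCs and
    the consensus AUC.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for i in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        spec = dataclasses.replace(base_spec, seed=rep_seed)
        result = run_benchmark(spec, criteria)
        rows.append(
            {
                "replicate": i,
                "seed": rep_seed,
                "auc_docking": result["mean_auc_docking"],
                "auc_pharmacological": result["mean_auc_pharmacological"],
                "auc_consensus": result["auc_consensus"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# staged screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenConfig:
    """Configuration of the scaled synthetic screen."""

    n_library: int = 200
    n_structures: int = 3
    n_residues: int = 8
    n_model_actives: int = 60
    n_planted_hb: int = 2
    n_planted_hp: int = 3
    active_fraction: float = 0.15
    p_active: float = 0.9
    p_decoy: float = 0.2
    top_k_docking: int = 50
    top_k_consensus: int = 10
    top_n_model: int = 30
    hb_threshold: float = 0.50
    hp_threshold: float = 0.80
    cluster_threshold: float = 0.6
    k_representatives: int = 5
    qed_threshold: float = 0.25
    lipinski_max_violations: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(config: ScreenConfig) -> str:
    text = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_screen(config: ScreenConfig, outdir: str | Path) -> dict:
    """Execute the staged synthetic screen and write per-stage artifacts.

    Returns the run report (also written as ``run_report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "screen.log"
    log_fh = open(log_path, "w")
    t_start = time.monotonic()
    counts: dict[str, int] = {}

    def log_stage(stage: str, **payload) -> None:
        entry = {"stage": stage, "elapsed_s": round(time.monotonic() - t_start, 3), **payload}
        log_fh.write(json.dumps(entry, sort_keys=True) + "\n")
        log_fh.flush()

    rng = np.random.default_rng(config.seed)

    # stage 1: library
    library = fixtures.make_smiles_library(config.n_library, int(rng.integers(0, 2**31 - 1)))
    mols = []
    for cid, smi in library:
        mol = Chem.MolFromSmiles(smi)
        chem_io.set_mol_id(mol, cid)
        mols.append(mol)
    chem_io.write_smiles(mols, outdir / "library.smi")
    counts["library"] = len(mols)
    log_stage("library", count=len(mols))

    # stage 2: filter cascade
    fconfig = filters.FilterConfig(
        lipinski_max_violations=config.lipinski_max_violations,
        qed_threshold=config.qed_threshold,
    )
    survivors, report = filters.apply_filter_chain(mols, fconfig)
    report.to_json(outdir / "filter_report.json")
    chem_io.write_smiles(survivors, outdir / "survivors.smi")
    counts["filter_survivors"] = len(survivors)
    log_stage("filter", count=len(survivors))

    # stage 3: pockets, models, mock docking
    pockets: dict[str, chem_io.ReceptorStructure] = {}
    planted: dict[str, list[fixtures.PlantedInteraction]] = {}
    models: dict[str, pharm_model.PharmacologicalModel] = {}
    bench_spec = fixtures.BenchmarkSpec(
        n_structures=config.n_structures,
        n_residues=config.n_residues,
        n_model_actives=config.n_model_actives,
        n_planted_hb=config.n_planted_hb,
        n_planted_hp=config.n_planted_hp,
        p_active=config.p_active,
        p_decoy=config.p_decoy,
    )
    sm = bench_spec.score_model
    survivor_ids = [chem_io.mol_id(m) for m in survivors]
    latent = {cid: int(rng.random() < config.active_fraction) for cid in survivor_ids}
    poses: list[chem_io.PoseRecord] = []
    for s in range(config.n_structures):
        sid = f"STR{s + 1}"
        pocket = fixtures.generate_pocket(config.n_residues, int(rng.integers(0, 2**31 - 1)), sid)
        pockets[sid] = pocket
        planted[sid] = fixtures._choose_planted(pocket, bench_spec, rng)
        model_poses = [
            fixtures._realized_pose(
                pocket, planted[sid], config.p_active, sm.active_mean, sm.sd, f"ACT{i + 1:03d}", rng
            )
            for i in range(config.n_model_actives)
        ]
        models[sid] = pharm_model.build_model(
            pocket,
            model_poses,
            top_n=config.top_n_model,
            hb_threshold=config.hb_threshold,
            hp_threshold=config.hp_threshold,
        )
        models[sid].to_json(outdir / f"model_{sid}.json")
        chem_io.write_pdb_receptor(pocket, outdir / f"{sid}.pdb")
        for cid in survivor_ids:
            z = latent[cid]
            poses.append(
                fixtures._realized_pose(
                    pocket,
                    planted[sid],
                    config.p_active if z else config.p_decoy,
                    sm.active_mean if z else sm.decoy_mean,
                    sm.sd,
                    cid,
                    rng,
                )
            )
    counts["docked"] = len(poses)
    log_stage("docking", count=len(poses))

    # stage 4: top-K by docking score (best score across structures)
    best_d: dict[str, float] = {}
    for p in poses:
        if p.compound_id not in best_d or p.docking_score < best_d[p.compound_id]:
            best_d[p.compound_id] = p.docking_score
    k_dock = config.top_k_docking
    if k_dock >= len(best_d):
        log_stage("top_k_docking", warning="top_k_docking >= library size; stage is identity")
        k_dock = len(best_d)
    top_ids = set(
        cid for cid, _ in sorted(best_d.items(), key=lambda kv: (kv[1], kv[0]))[:k_dock]
    )
    top_poses = [p for p in poses if p.compound_id in top_ids]
    counts["top_docking"] = len(top_ids)
    log_stage("top_docking", count=len(top_ids))

    # stage 5: pharmacological scoring + consensus
    tables = scoring.score_compound_set(pockets, top_poses, models)
    for sid, table in tables.items():
        table.to_csv(outdir / f"scored_{sid}.csv", index=False)
    consensus = scoring.consensus_rank({sid: t[["compound_id", "rank"]] for sid, t in tables.items()})
    consensus.to_csv(outdir / "consensus.csv", index=False)
    top_consensus = consensus.head(config.top_k_consensus)
    top_consensus.to_csv(outdir / "top_consensus.csv", index=False)
    counts["top_consensus"] = len(top_consensus)
    log_stage("consensus", count=len(top_consensus))

    # stage 6: similarity clustering and representatives
    smiles_by_id = dict(library)
    ranked_ids = list(top_consensus["compound_id"])
    fps = []
    for cid in ranked_ids:
        mol = Chem.MolFromSmiles(smiles_by_id[cid])
        chem_io.set_mol_id(mol, cid)
        fps.append(similarity.ecfp(mol))
    clusters = similarity.cluster_select(fps, config.cluster_threshold, config.k_representatives)
    clusters.to_csv(outdir / "clusters.csv", index=False)
    representatives = clusters[clusters["is_representative"]]
    representatives.to_csv(outdir / "representatives.csv", index=False)
    counts["representatives"] = len(representatives)
    log_stage("representatives", count=len(representatives))

    report_payload = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "counts": counts,
    }
    (outdir / "run_report.json").write_text(json.dumps(report_payload, indent=2, sort_keys=True) + "\n")
    log_fh.close()
    return report_payload
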