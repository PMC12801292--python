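"""Pharmacological scoring, per-structure ranking and consensus reranking.

The pharmacological score of compound i on one receptor structure is

    S(i) = N(i) + (-0.01) * D(i)

where N(i) is the number of key pharmacological interactions the compound
forms and D(i) its docking score (more negative = better, so the small
negative weight converts the docking term into a positive bonus). Per
structure, compounds are ranked by S descending; across two or more
structures the ordinal ranks are summed into a consensus score and the
compounds reranked ascending by that sum.

Tie handling (the ranking must be a strict total order): equal S breaks by
the more negative docking score, then by compound id ascending. Compounds
missing from one structure's ranking (e.g. docking failures) receive rank
K+1 there, keeping the consensus defined over the union while penalising
the failure.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_io import PoseRecord, ReceptorStructure
from .interactions import InteractionCriteria, DEFAULT_CRITERIA, profile_pose
from .pharm_model import PharmacologicalModel, count_matches

SCORE_WEIGHT = -0.01  # weight of the docking-score term in S


def pharmacological_score(n: int, d: float) -> float:
    """S = N + (-0.01) * D."""
    if n < 0:
        raise ValueError("N must be non-negative")
    if not math.isfinite(d):
        raise ValueError("docking score must be finite")
    return n + SCORE_WEIGHT * d


def rank_by_score(scored: pd.DataFrame) -> pd.DataFrame:
    """Assign ranks 1..K within one structure, best pharmacological score first.

    Expects columns compound_id, structure_id, D, N, S. Ties in S break by
    more negative D, then compound_id ascending; the result has no rank gaps.
    """
    required = {"compound_id", "structure_id", "D", "N", "S"}
    missing = required - set(scored.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if scored["structure_id"].nunique() > 1:
        raise ValueError("rank_by_score expects a single structure")
    if scored["compound_id"].duplicated().any():
        dupes = scored.loc[scored["compound_id"].duplicated(), "compound_id"].tolist()
        raise ValueError(f"duplicate compound ids: {dupes}")
    out = scored.sort_values(
        ["S", "D", "compound_id"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def consensus_rank(rankings: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Sum per-structure ranks into a consensus score and rerank.

    ``rankings`` maps structure id to a frame with compound_id and rank
    columns (as produced by :func:`rank_by_score`). A compound absent from
    a structure's ranking receives rank K+1 for that structure. The output
    has one row per compound in the union, columns ``rank_<structure>``,
    ``consensus_score`` (exact integer rank sum) and ``final_rank``
    (ascending consensus score, ties by compound id).
    """
    if len(rankings) < 2:
        raise ValueError("consensus needs rankings from at least two structures")
    structures = sorted(rankings)
    all_compounds = sorted(set().union(*(set(rankings[s]["compound_id"]) for s in structures)))
    data = {"compound_id": all_compounds}
    for s in structures:
        frame = rankings[s]
        if frame["compound_id"].duplicated().any():
            raise ValueError(f"duplicate compound ids in ranking for {s!r}")
        lookup = dict(zip(frame["compound_id"], frame["rank"].astype(int)))
        worst = len(frame) + 1
        data[f"rank_{s}"] = [lookup.get(c, worst) for c in all_compounds]
    out = pd.DataFrame(data)
    rank_cols = [f"rank_{s}" for s in structures]
    out["consensus_score"] = out[rank_cols].sum(axis=1)
    out = out.sort_values(["consensus_score", "compound_id"], kind="mergesort").reset_index(drop=True)
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out


def score_compound_set(
    receptors: Mapping[str, ReceptorStructure],
    poses: Sequence[PoseRecord],
    models: Mapping[str, PharmacologicalModel],
    criteria: InteractionCriteria = DEFAULT_CRITERIA,
) -> dict[str, pd.DataFrame]:
    """Profile, score and rank every pose against its structure's model.

    Returns one ranked frame per structure with columns (compound_id,
    structure_id, D, N, S, rank). Poses whose structure has no model are
    collected into a single error report.
    """
    by_structure: dict[str, list[PoseRecord]] = {}
    orphans: list[str] = []
    for p in poses:
        if p.structure_id not in models or p.structure_id not in receptors:
            orphans.append(f"{p.compound_id}/{p.structure_id}")
            continue
        by_structure.setdefault(p.structure_id, []).append(p)
    if orphans:
        raise ValueError("poses without model or receptor: " + ", ".join(orphans))

    out: dict[str, pd.DataFrame] = {}
    for sid, plist in sorted(by_structure.items()):
        rows = []
        for p in plist:
            profile = profile_pose(receptors[sid], p, criteria)
            n = count_matches(profile, models[sid])
            rows.append(
                {
                    "compound_id": p.compound_id,
                    "structure_id": sid,
                    "D": p.docking_score,
                    "N": n,
                    "S": pharmacological_score(n, p.docking_score),
                }
            )
        out[sid] = rank_by_score(pd.DataFrame(rows))
    return out
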