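"""Validation machinery: redocking RMSD and actives-vs-decoys enrichment.

Redocking validation re-places a crystal ligand into its own receptor and
measures the in-place heavy-atom RMSD to the crystal pose (no
re-superposition: both conformations live in the receptor frame). Symmetry
correction minimises over the heavy-atom graph automorphisms, so e.g. a
benzene flipped by 60 degrees scores zero. The conventional success
criterion is RMSD strictly below 2.5 A.

Enrichment uses the Mann-Whitney / midrank convention:
AUC = P(score_active > score_decoy) + 0.5 * P(tie).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.stats import rankdata

DEFAULT_RMSD_THRESHOLD = 2.5


@dataclass(frozen=True)
class RedockResult:
    structure_id: str
    rmsd: float
    threshold: float
    passed: bool


@dataclass(frozen=True)
class EnrichmentResult:
    label: str
    n_actives: int
    n_decoys: int
    auc: float


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------


def _heavy_skeleton(mol: Chem.Mol) -> Chem.Mol:
    try:
        return Chem.RemoveHs(mol, sanitize=True)
    except Exception:
        return Chem.RemoveHs(mol, sanitize=False)


def pose_rmsd(reference: Chem.Mol, redocked: Chem.Mol, *, symmetry_aware: bool = True) -> float:
    """In-place heavy-atom RMSD between two conformations of one molecule.

    Both molecules must share the same heavy-atom graph and carry 3D
    coordinates in a common (receptor) frame; no superposition is applied.
    With ``symmetry_aware`` the minimum over all graph automorphisms is
    returned.
    """
    ref = _heavy_skeleton(reference)
    prb = _heavy_skeleton(redocked)
    if ref.GetNumAtoms() != prb.GetNumAtoms():
        raise ValueError("heavy-atom counts differ; not the same molecule")
    if ref.GetNumConformers() == 0 or prb.GetNumConformers() == 0:
        raise ValueError("both poses need 3D coordinates")
    matches = prb.GetSubstructMatches(ref, uniquify=False, useChirality=False, maxMatches=100000)
    if not matches:
        raise ValueError("heavy-atom graphs do not match")
    if not symmetry_aware:
        matches = matches[:1]
    ref_xyz = ref.GetConformer().GetPositions()
    prb_xyz = prb.GetConformer().GetPositions()
    best = np.inf
    for match in matches:
        delta = ref_xyz - prb_xyz[list(match)]
        rmsd = float(np.sqrt((delta**2).sum(axis=1).mean()))
        best = min(best, rmsd)
    return best


def redock_validate(
    pairs: Mapping[str, tuple[Chem.Mol, Chem.Mol]],
    threshold: float = DEFAULT_RMSD_THRESHOLD,
    *,
    symmetry_aware: bool = True,
) -> list[RedockResult]:
    """RMSD + pass flag per structure for (crystal, redocked) pose pairs.

    Success is RMSD strictly below the threshold.
    """
    out = []
    for sid in sorted(pairs):
        crystal, redocked = pairs[sid]
        rmsd = pose_rmsd(crystal, redocked, symmetry_aware=symmetry_aware)
        out.append(RedockResult(sid, rmsd, threshold, rmsd < threshold))
    return out


# ---------------------------------------------------------------------------
# ROC / enrichment
# ---------------------------------------------------------------------------


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Midrank (Mann-Whitney) ROC-AUC; higher score = predicted active."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one active and one decoy")
    ranks = rankdata(scores)  # midranks
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve_points(scores: Sequence[float], labels: Sequence[int]) -> pd.DataFrame:
    """(fpr, tpr) per descending score threshold, for curve export."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # keep the last point of each tied block
    keep = np.r_[np.diff(s) != 0, True]
    tpr = np.r_[0.0, tps[keep] / max(tps[-1], 1)]
    fpr = np.r_[0.0, fps[keep] / max(fps[-1], 1)]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def evaluate_rankers(
    rankers: Mapping[str, Mapping[str, float]],
    labels: Mapping[str, int],
) -> pd.DataFrame:
    """One AUC per named ranker over a shared active/decoy label set.

    Each ranker maps compound id -> score with higher = predicted active
    (negate consensus rank sums before passing them in, since a lower sum
    is better).
    """
    compounds = sorted(labels)
    y = [labels[c] for c in compounds]
    rows = []
    n_pos = sum(y)
    n_neg = len(y) - n_pos
    for name in sorted(rankers):
        scores = [rankers[name][c] for c in compounds]
        rows.append(
            {
                "model": name,
                "n_actives": n_pos,
                "n_decoys": n_neg,
                "auc": roc_auc(scores, y),
            }
        )
    return pd.DataFrame(rows, columns=["model", "n_actives", "n_decoys", "auc"])
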