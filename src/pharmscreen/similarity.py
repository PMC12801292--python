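"""Fingerprints, Tanimoto similarity and cluster-based representative picking.

Compounds are encoded as extended-connectivity (Morgan/ECFP) fingerprints,
radius 2 on 2048 bits by default (ECFP4-equivalent). Pairwise Tanimoto
coefficients |A∩B|/|A∪B| fill a symmetric similarity matrix; the top-ranked
screening compounds are grouped by leader (sphere-exclusion) clustering and
each cluster contributes its best-ranked member as a representative.

Convention: the Tanimoto coefficient of two all-zero fingerprints is 1.0
(two featureless molecules are indistinguishable); this is logged once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import mol_id

logger = logging.getLogger(__name__)

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048
DEFAULT_CLUSTER_THRESHOLD = 0.6


@dataclass(frozen=True)
class Fingerprint:
    """Circular-substructure fingerprint as a set of on-bits."""

    compound_id: str
    on_bits: frozenset[int]
    n_bits: int = DEFAULT_N_BITS
    radius: int = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if self.on_bits and max(self.on_bits) >= self.n_bits:
            raise ValueError("on-bit index outside fingerprint length")


def ecfp(mol: Chem.Mol, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS) -> Fingerprint:
    """Morgan/ECFP fingerprint; invariant to input atom ordering."""
    if mol is None:
        raise ValueError("cannot fingerprint an unparseable molecule")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(mol_id(mol), frozenset(bv.GetOnBits()), n_bits, radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A∩B| / |A∪B|; defined as 1.0 when both fingerprints are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprint lengths differ")
    union = len(a.on_bits | b.on_bits)
    if union == 0:
        logger.debug("both fingerprints empty; Tanimoto defined as 1.0")
        return 1.0
    return len(a.on_bits & b.on_bits) / union


def fingerprints(mols: Sequence[Chem.Mol], radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS) -> list[Fingerprint]:
    return [ecfp(m, radius, n_bits) for m in mols]


def similarity_matrix(
    items: Sequence[Chem.Mol] | Sequence[Fingerprint],
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> tuple[list[str], np.ndarray]:
    """Full symmetric Tanimoto matrix over molecules or fingerprints."""
    if len(items) < 2:
        raise ValueError("need at least two molecules")
    fps = [x if isinstance(x, Fingerprint) else ecfp(x, radius, n_bits) for x in items]
    n = len(fps)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = tanimoto(fps[i], fps[j])
    return [fp.compound_id for fp in fps], mat


def matrix_to_frame(ids: list[str], matrix: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(matrix, index=ids, columns=ids)


def cluster_map(ids: list[str], matrix: np.ndarray, path: str | Path) -> None:
    """Export a hierarchically clustered heat map of the similarity matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import seaborn as sns

    grid = sns.clustermap(matrix_to_frame(ids, matrix), cmap="viridis", vmin=0.0, vmax=1.0)
    grid.savefig(str(path))
    import matplotlib.pyplot as plt

    plt.close("all")


def cluster_select(
    fps: Sequence[Fingerprint],
    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
    k_representatives: int | None = None,
) -> pd.DataFrame:
    """Leader (sphere-exclusion) clustering over rank-ordered compounds.

    ``fps`` must be ordered best consensus rank first. Walking down the
    ranking, a compound joins the first existing cluster whose leader it
    resembles at Tanimoto >= threshold, otherwise it founds a new cluster;
    leaders are therefore the best-ranked member of their cluster and serve
    as representatives. The representative list is capped at
    ``k_representatives`` (first clusters by leader rank).

    Returns a frame with compound_id, cluster_id, is_representative.
    """
    leaders: list[int] = []
    assignment: list[int] = []
    for i, fp in enumerate(fps):
        placed = False
        for ci, li in enumerate(leaders):
            if tanimoto(fps[li], fp) >= threshold:
                assignment.append(ci)
                placed = True
                break
        if not placed:
            assignment.append(len(leaders))
            leaders.append(i)
    n_reps = len(leaders) if k_representatives is None else min(k_representatives, len(leaders))
    rep_indices = set(leaders[:n_reps])
    return pd.DataFrame(
        {
            "compound_id": [fp.compound_id for fp in fps],
            "cluster_id": assignment,
            "is_representative": [i in rep_indices for i in range(len(fps))],
        }
    )
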