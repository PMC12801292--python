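"""Per-structure pharmacological interaction models.

The model for one receptor structure is the set of residue contacts formed
frequently enough by top-scored known actives: hydrogen bonds present in at
least 50% of the docked actives and hydrophobic contacts present in at
least 80% (both boundaries inclusive, both configurable). A compound's
match count N against the model feeds the pharmacological score
S = N - 0.01 * D.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .chem_io import PoseRecord
from .interactions import HB, HP, InteractionProfile, ProfileKey

logger = logging.getLogger(__name__)

DEFAULT_HB_THRESHOLD = 0.50
DEFAULT_HP_THRESHOLD = 0.80
DEFAULT_TOP_N = 30


@dataclass
class FrequencyTable:
    """Fraction of aggregated profiles containing each interaction key."""

    structure_id: str
    n_poses: int
    counts: dict[ProfileKey, int]

    @property
    def frequencies(self) -> dict[ProfileKey, float]:
        return {k: c / self.n_poses for k, c in self.counts.items()}


@dataclass
class PharmacologicalModel:
    """Key interactions of one structure plus the provenance to audit them."""

    structure_id: str
    hb_threshold: float = DEFAULT_HB_THRESHOLD
    hp_threshold: float = DEFAULT_HP_THRESHOLD
    key_interactions: frozenset[ProfileKey] = frozenset()
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.key_interactions)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "structure_id": self.structure_id,
            "thresholds": {"hb": self.hb_threshold, "hp": self.hp_threshold},
            "key_interactions": [
                {
                    "chain": k[0],
                    "resnum": k[1],
                    "resname": k[2],
                    "kind": k[3],
                    **({"subtype": k[4]} if len(k) > 4 else {}),
                }
                for k in sorted(self.key_interactions)
            ],
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PharmacologicalModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        keys = set()
        for k in payload["key_interactions"]:
            base = (k["chain"], k["resnum"], k["resname"], k["kind"])
            keys.add(base + ((k["subtype"],) if "subtype" in k else ()))
        return cls(
            structure_id=payload["structure_id"],
            hb_threshold=payload["thresholds"]["hb"],
            hp_threshold=payload["thresholds"]["hp"],
            key_interactions=frozenset(keys),
            provenance=payload.get("provenance", {}),
        )


def select_top_poses(poses: Sequence[PoseRecord], n: int = DEFAULT_TOP_N) -> list[PoseRecord]:
    """The ``n`` best-scored poses for one structure, one pose per compound.

    More negative docking scores rank first; ties break by compound id
    ascending. A compound appearing with several poses contributes only its
    best-scored one. Fewer than ``n`` compounds is allowed with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    structure_ids = {p.structure_id for p in poses}
    if len(structure_ids) > 1:
        raise ValueError(f"poses span multiple structures: {sorted(structure_ids)}")
    best: dict[str, PoseRecord] = {}
    for p in poses:
        cur = best.get(p.compound_id)
        if cur is None or p.docking_score < cur.docking_score:
            best[p.compound_id] = p
    ordered = sorted(best.values(), key=lambda p: (p.docking_score, p.compound_id))
    if len(ordered) < n:
        logger.warning(
            "requested top %d poses but only %d compounds available", n, len(ordered)
        )
    return ordered[:n]


def interaction_frequencies(
    profiles: Sequence[InteractionProfile], *, include_subtype: bool = False
) -> FrequencyTable:
    """Count, per interaction key, the fraction of profiles containing it.

    By default hydrophobic subtypes aggregate at residue level (one entry
    per residue regardless of alkyl/pi/mixed), matching how frequency
    profiles are conventionally reported; set ``include_subtype`` for
    subtype-resolved keys.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    structure_ids = {p.structure_id for p in profiles}
    if len(structure_ids) != 1:
        raise ValueError(f"profiles span multiple structures: {sorted(structure_ids)}")
    counts: dict[ProfileKey, int] = {}
    for p in profiles:
        for k in p.keys(include_subtype):
            counts[k] = counts.get(k, 0) + 1
    return FrequencyTable(structure_ids.pop(), len(profiles), counts)


def identify_pharmacological(
    freq: FrequencyTable,
    hb_threshold: float = DEFAULT_HB_THRESHOLD,
    hp_threshold: float = DEFAULT_HP_THRESHOLD,
    *,
    provenance: dict | None = None,
) -> PharmacologicalModel:
    """Apply the class thresholds to a frequency table.

    Hydrogen-bond keys are kept iff their frequency is at least
    ``hb_threshold``; hydrophobic keys iff at least ``hp_threshold``
    (inclusive boundaries — "at least").
    """
    for t in (hb_threshold, hp_threshold):
        if not (0.0 < t <= 1.0):
            raise ValueError("thresholds must be in (0, 1]")
    keys = set()
    for k, f in freq.frequencies.items():
        threshold = hb_threshold if k[3] == HB else hp_threshold
        if f >= threshold:
            keys.add(k)
    prov = dict(provenance or {})
    prov.setdefault("n_poses", freq.n_poses)
    return PharmacologicalModel(
        structure_id=freq.structure_id,
        hb_threshold=hb_threshold,
        hp_threshold=hp_threshold,
        key_interactions=frozenset(keys),
        provenance=prov,
    )


def count_matches(profile: InteractionProfile, model: PharmacologicalModel) -> int:
    """N for one compound: how many model key interactions its profile forms."""
    if profile.structure_id != model.structure_id:
        raise ValueError(
            f"profile structure {profile.structure_id!r} != model structure {model.structure_id!r}"
        )
    include_subtype = any(len(k) > 4 for k in model.key_interactions)
    return len(profile.keys(include_subtype) & model.key_interactions)


def build_model(
    receptor,
    poses: Sequence[PoseRecord],
    *,
    criteria=None,
    top_n: int = DEFAULT_TOP_N,
    hb_threshold: float = DEFAULT_HB_THRESHOLD,
    hp_threshold: float = DEFAULT_HP_THRESHOLD,
) -> PharmacologicalModel:
    """Convenience composition: top poses -> profiles -> frequencies -> model."""
    from .interactions import DEFAULT_CRITERIA, profile_pose

    criteria = criteria or DEFAULT_CRITERIA
    top = select_top_poses(poses, top_n)
    profiles = [profile_pose(receptor, p, criteria) for p in top]
    freq = interaction_frequencies(profiles)
    provenance = {
        "source_compounds": [p.compound_id for p in top],
        "n_poses": len(top),
        "criteria": criteria.to_dict(),
    }
    return identify_pharmacological(freq, hb_threshold, hp_threshold, provenance=provenance)
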