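"""Screening-library preparation: the drug-likeness filter cascade.

Stages, applied in order with a per-stage audit trail:

1. HTS structural filter — reject non-organic elements and reactive
   substructures (acyl halides, epoxides, isocyanates, Michael acceptors,
   anhydrides, ...).
2. Lipinski rule of five — MW > 500, logP > 5, HBD > 5, HBA > 10 are
   violations; by default any violation excludes (``max_violations=0``),
   the classical "one violation tolerated" reading is available via config.
3. Veber — rotatable bonds <= 10 and TPSA <= 140 A^2.
4. PAINS — any match in the published SMARTS families A, B, C excludes.
5. QED — quantitative estimate of drug-likeness below the threshold
   (default 0.25, strict "below") excludes.

Descriptors come from RDKit: Crippen atom-contribution logP, topological
PSA, the Lipinski H-bond donor/acceptor counts (N/O based) and the original
QED desirability composite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, QED, rdMolDescriptors
from rdkit.Chem import FilterCatalog

from .chem_io import mol_id

#: Elements allowed by the HTS organic filter.
ALLOWED_ELEMENTS = frozenset({"H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I"})

#: Reactive substructures rejected by the HTS filter (name -> SMARTS).
REACTIVE_SMARTS: dict[str, str] = {
    "acyl_halide": "[CX3](=O)[F,Cl,Br,I]",
    "sulfonyl_halide": "[SX4](=O)(=O)[F,Cl,Br,I]",
    "acid_anhydride": "[CX3](=O)O[CX3](=O)",
    "epoxide": "[C;r3]1[O;r3][C;r3]1",
    "aziridine": "[C;r3]1[N;r3][C;r3]1",
    "isocyanate": "[NX2]=[CX2]=[OX1]",
    "isothiocyanate": "[NX2]=[CX2]=[SX1]",
    "aldehyde_michael_acceptor": "[CX3]=[CX3][CX3H1]=[OX1]",
    "diazo": "[NX2]=[NX2,NX1]",
    "azide": "[NX1]~[NX2]~[NX2,NX1]",
}

_REACTIVE_PATTERNS = {name: Chem.MolFromSmarts(s) for name, s in REACTIVE_SMARTS.items()}

LOGP_ESTIMATOR = "Crippen atom contribution (RDKit MolLogP)"

_pains_catalog: FilterCatalog.FilterCatalog | None = None


def _pains() -> FilterCatalog.FilterCatalog:
    global _pains_catalog
    if _pains_catalog is None:
        params = FilterCatalog.FilterCatalogParams()
        for fam in ("PAINS_A", "PAINS_B", "PAINS_C"):
            params.AddCatalog(getattr(FilterCatalog.FilterCatalogParams.FilterCatalogs, fam))
        _pains_catalog = FilterCatalog.FilterCatalog(params)
    return _pains_catalog


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------


def hts_filter(mol: Chem.Mol) -> tuple[bool, str | None]:
    """Organic-elements + reactive-substructure screen.

    Returns (passed, reason); the reason names the offending element or
    reactive pattern.
    """
    if mol is None:
        return False, "parse"
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ALLOWED_ELEMENTS:
            return False, f"nonorganic element {atom.GetSymbol()}"
    for name, pattern in _REACTIVE_PATTERNS.items():
        if mol.HasSubstructMatch(pattern):
            return False, f"reactive substructure {name}"
    return True, None


def lipinski_violations(mol: Chem.Mol) -> list[str]:
    """Violated rule-of-five criteria (strict '>' boundaries)."""
    out = []
    if Descriptors.MolWt(mol) > 500:
        out.append("MW>500")
    if Crippen.MolLogP(mol) > 5:
        out.append("logP>5")
    if rdMolDescriptors.CalcNumLipinskiHBD(mol) > 5:
        out.append("HBD>5")
    if rdMolDescriptors.CalcNumLipinskiHBA(mol) > 10:
        out.append("HBA>10")
    return out


def lipinski_pass(mol: Chem.Mol, max_violations: int = 0) -> tuple[bool, list[str]]:
    """Rule-of-five check; fails when violations exceed ``max_violations``."""
    violations = lipinski_violations(mol)
    return len(violations) <= max_violations, violations


def veber_pass(mol: Chem.Mol) -> tuple[bool, list[str]]:
    """Veber oral-bioavailability criteria: RotB <= 10 and TPSA <= 140."""
    out = []
    if rdMolDescriptors.CalcNumRotatableBonds(mol) > 10:
        out.append("RotB>10")
    if rdMolDescriptors.CalcTPSA(mol) > 140:
        out.append("TPSA>140")
    return not out, out


def pains_flag(mol: Chem.Mol) -> list[str]:
    """Identifiers of matched PAINS patterns (families A, B, C); empty = pass."""
    return sorted(entry.GetDescription() for entry in _pains().GetMatches(mol))


def qed_filter(mol: Chem.Mol, threshold: float = 0.25) -> tuple[bool, float]:
    """QED drug-likeness; fails when the score is strictly below threshold."""
    value = QED.qed(mol)
    return value >= threshold, value


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------


@dataclass
class StageResult:
    name: str
    n_input: int
    n_passed: int
    removed: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)


@dataclass
class FilterReport:
    stages: list[StageResult] = field(default_factory=list)

    def validate(self) -> None:
        for prev, cur in zip(self.stages, self.stages[1:]):
            if prev.n_passed != cur.n_input:
                raise ValueError(f"stage chaining broken at {cur.name}")
        for s in self.stages:
            if s.n_passed + len(s.removed) != s.n_input:
                raise ValueError(f"count mismatch in stage {s.name}")

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "input": s.n_input,
                    "passed": s.n_passed,
                    "removed": [{"compound_id": cid, "reason": r} for cid, r in s.removed],
                }
                for s in self.stages
            ]
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass(frozen=True)
class FilterConfig:
    stages: tuple[str, ...] = ("hts", "lipinski", "veber", "pains", "qed")
    lipinski_max_violations: int = 0
    qed_threshold: float = 0.25

    def to_dict(self) -> dict:
        return {
            "stages": list(self.stages),
            "lipinski_max_violations": self.lipinski_max_violations,
            "qed_threshold": self.qed_threshold,
            "logp_estimator": LOGP_ESTIMATOR,
        }


DEFAULT_FILTER_CONFIG = FilterConfig()


def _stage_check(stage: str, mol: Chem.Mol, config: FilterConfig) -> tuple[bool, str | None]:
    if stage == "hts":
        return hts_filter(mol)
    if stage == "lipinski":
        ok, violations = lipinski_pass(mol, config.lipinski_max_violations)
        return ok, ("lipinski: " + ", ".join(violations)) if not ok else None
    if stage == "veber":
        ok, reasons = veber_pass(mol)
        return ok, ("veber: " + ", ".join(reasons)) if not ok else None
    if stage == "pains":
        matches = pains_flag(mol)
        return not matches, ("pains: " + ", ".join(matches)) if matches else None
    if stage == "qed":
        ok, value = qed_filter(mol, config.qed_threshold)
        return ok, None if ok else f"qed {value:.3f} < {config.qed_threshold}"
    raise ValueError(f"unknown filter stage {stage!r}")


def apply_filter_chain(
    mols: Sequence[Chem.Mol | None],
    config: FilterConfig = DEFAULT_FILTER_CONFIG,
) -> tuple[list[Chem.Mol], FilterReport]:
    """Run the staged cascade; removals are attributed to the first failing
    stage, unparseable inputs to the first stage with reason "parse"."""
    report = FilterReport()
    survivors: list[Chem.Mol] = []
    pool: list[tuple[str, Chem.Mol | None]] = [
        (mol_id(m) if m is not None else f"record{i}", m) for i, m in enumerate(mols)
    ]
    for stage in config.stages:
        result = StageResult(stage, n_input=len(pool), n_passed=0)
        kept: list[tuple[str, Chem.Mol | None]] = []
        for cid, mol in pool:
            if mol is None:
                result.removed.append((cid, "parse"))
                continue
            ok, reason = _stage_check(stage, mol, config)
            if ok:
                kept.append((cid, mol))
            else:
                result.removed.append((cid, reason or stage))
        result.n_passed = len(kept)
        report.stages.append(result)
        pool = kept
    survivors = [m for _, m in pool if m is not None]
    report.validate()
    return survivors, report
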