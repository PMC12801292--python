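"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as literal enumeration — nested loops over all
pairs, exhaustive automorphism search — deliberately sharing no code with
the package's detectors, rankers or RMSD routine.
"""

from __future__ import annotations

import math

import numpy as np

HYDROXYL_NAMES = {"OG", "OG1", "OH"}
RING_NAMES = {
    "PHE": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "TYR": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "TRP": [
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ],
    "HIS": [("CG", "ND1", "CE1", "NE2", "CD2")],
}


def _angle(a, b, c):
    v1, v2 = np.asarray(a) - np.asarray(b), np.asarray(c) - np.asarray(b)
    cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def _plane_normal(coords):
    coords = np.asarray(coords)
    centered = coords - coords.mean(axis=0)
    # normal = eigenvector of smallest eigenvalue of the covariance
    w, v = np.linalg.eigh(centered.T @ centered)
    return v[:, 0]


def brute_force_profile_keys(receptor, pose, criteria):
    """Residue-level (chain, resnum, resname, kind) keys by literal
    all-pairs enumeration under the documented typing rules."""
    mol = pose.mol
    xyz = mol.GetConformer().GetPositions()
    keys = set()

    lig_atoms = list(mol.GetAtoms())

    def explicit_h(atom):
        return [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() == 1]

    # hydrogen bonds
    for res in receptor.residues:
        for atom in res.atoms:
            is_acceptor = atom.element == "O" or (
                res.name == "HIS" and atom.name in ("ND1", "NE2")
            )
            is_donor = atom.element == "N" or (
                atom.element == "O" and atom.name in HYDROXYL_NAMES
            )
            for la in lig_atoms:
                if la.GetAtomicNum() not in (7, 8):
                    continue
                d = float(np.linalg.norm(xyz[la.GetIdx()] - atom.coord))
                if d > criteria.hb_distance_max:
                    continue
                has_h = la.GetTotalNumHs() > 0 or bool(explicit_h(la))
                if is_acceptor and has_h:
                    hs = explicit_h(la)
                    if hs:
                        best = max(_angle(xyz[la.GetIdx()], xyz[h], atom.coord) for h in hs)
                        if best >= criteria.hb_angle_min:
                            keys.add((res.chain, res.number, res.name, "HB"))
                    else:
                        keys.add((res.chain, res.number, res.name, "HB"))
                if is_donor:
                    keys.add((res.chain, res.number, res.name, "HB"))

    # alkyl contacts
    for res in receptor.residues:
        ring_names = {n for ring in RING_NAMES.get(res.name, []) for n in ring}
        for atom in res.atoms:
            if atom.element != "C" or atom.name in ("C", "CA") or atom.name in ring_names:
                continue
            for la in lig_atoms:
                if la.GetAtomicNum() != 6 or la.GetIsAromatic():
                    continue
                if any(n.GetAtomicNum() not in (1, 6) for n in la.GetNeighbors()):
                    continue
                d = float(np.linalg.norm(xyz[la.GetIdx()] - atom.coord))
                if d <= criteria.hp_distance_max:
                    keys.add((res.chain, res.number, res.name, "HP"))

    # pi stacking
    lig_rings = [
        ring
        for ring in mol.GetRingInfo().AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    ]
    for res in receptor.residues:
        for names in RING_NAMES.get(res.name, []):
            atoms = [res.atom(n) for n in names]
            if any(a is None for a in atoms):
                continue
            rcoords = np.array([a.coord for a in atoms])
            rc, rn = rcoords.mean(axis=0), _plane_normal(rcoords)
            for ring in lig_rings:
                lcoords = np.array([xyz[i] for i in ring])
                lc, ln = lcoords.mean(axis=0), _plane_normal(lcoords)
                if np.linalg.norm(rc - lc) > criteria.pi_centroid_max:
                    continue
                cosv = abs(float(np.dot(rn, ln)))
                ang = math.degrees(math.acos(min(1.0, cosv)))
                if ang <= criteria.pi_parallel_angle_max or (
                    criteria.pi_tshaped_angle_min <= ang <= 90.0
                ):
                    keys.add((res.chain, res.number, res.name, "HP"))
    return keys


def pair_count_auc(scores, labels):
    """O(n^2) Mann-Whitney AUC: count active>decoy pairs, half for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def rank_sum_order(rankings):
    """Brute-force consensus: sum ranks (missing -> K+1), sort by (sum, id)."""
    compounds = set()
    for frame in rankings.values():
        compounds |= set(frame["compound_id"])
    sums = {}
    for c in sorted(compounds):
        total = 0
        for frame in rankings.values():
            match = frame.loc[frame["compound_id"] == c, "rank"]
            total += int(match.iloc[0]) if len(match) else len(frame) + 1
        sums[c] = total
    return sorted(compounds, key=lambda c: (sums[c], c)), sums


def automorphism_rmsd(ref_mol, prb_mol):
    """Min in-place heavy-atom RMSD over graph automorphisms (networkx)."""
    import networkx as nx
    from networkx.algorithms import isomorphism

    def graph(mol):
        g = nx.Graph()
        heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
        index = {a.GetIdx(): k for k, a in enumerate(heavy)}
        for a in heavy:
            g.add_node(index[a.GetIdx()], element=a.GetSymbol())
        for b in mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if i in index and j in index:
                g.add_edge(index[i], index[j], order=str(b.GetBondType()))
        coords = mol.GetConformer().GetPositions()
        xyz = np.array([coords[a.GetIdx()] for a in heavy])
        return g, xyz

    g_ref, xyz_ref = graph(ref_mol)
    g_prb, xyz_prb = graph(prb_mol)
    matcher = isomorphism.GraphMatcher(
        g_ref,
        g_prb,
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )
    best = np.inf
    for mapping in matcher.isomorphisms_iter():
        perm = [mapping[i] for i in range(len(xyz_ref))]
        delta = xyz_ref - xyz_prb[perm]
        best = min(best, float(np.sqrt((delta**2).sum(axis=1).mean())))
    if not np.isfinite(best):
        raise ValueError("graphs not isomorphic")
    return best
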