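# Methods

## The model

`pharmscreen` rescoring rests on one assumption: compounds that bind a
target the way its known actives do are more likely to be active than
compounds that merely score well in docking. The method operationalises
"the way its known actives bind" as a set of *pharmacological
interactions* per receptor structure: residue contacts formed by at least
50% (hydrogen bonds) or at least 80% (hydrophobic contacts) of the top
30 docked actives. Both boundaries are inclusive ("at least") and both
fractions are configurable. The different class thresholds reflect the
different base rates of the two contact types: hydrophobic contacts are
promiscuous, so only near-universal ones are informative.

A compound's pharmacological score on one structure is

    S(i) = N(i) + (−0.01) · D(i)

with `N(i)` the number of key interactions its pose forms and `D(i)` the
engine docking score (more negative = better). The weight −0.01 makes the
docking term a small positive bonus: interaction matches dominate in unit
steps, and the docking score breaks ties within an `N` stratum. Across
structures, per-structure rankings by `S` are fused by summing ordinal
ranks (the consensus score; lower is better). Ordinal ranks, not midranks,
keep the sums integer; ties in `S` break deterministically by more
negative `D`, then compound id. A compound missing from one structure's
ranking (a docking failure) receives rank `K+1` there — the consensus
stays defined over the union of compounds and the failure is penalised
rather than silently dropped.

## Interaction detection

Detection is purely geometric and deliberately criterion-transparent; all
thresholds live in one `InteractionCriteria` object:

| parameter | default | meaning |
|---|---|---|
| `hb_distance_max` | 3.5 Å | heavy-atom donor–acceptor distance |
| `hb_angle_min` | 120° | D–H···A angle, applied only when the donor H is explicit |
| `hp_distance_max` | 4.5 Å | apolar carbon–carbon contact distance |
| `pi_centroid_max` | 5.5 Å | aromatic ring centroid distance |
| `pi_parallel_angle_max` | 30° | interplanar angle band for parallel stacking |
| `pi_tshaped_angle_min` | 60° | lower edge of the T-shaped band (to 90°) |

These are community-standard values; the hydrophobic subtype letters
follow the usual A (alkyl), P (pi-stacking), M (mixed) convention, where
*mixed* means one residue is reached through both channels in the same
pose. Donor/acceptor typing is element-based and reproducible without pKa
models: ligand N/O with a hydrogen donate, all ligand N/O accept; receptor
nitrogens and Ser/Thr/Tyr hydroxyl oxygens donate, receptor oxygens and
His ring nitrogens accept. Poses with and without explicit hydrogens are
both supported — the angle test simply switches off when the hydrogen is
implicit. "Alkyl" is restricted to non-aromatic apolar carbons on both
sides (an aromatic carbon participates only through stacking); without
that restriction every stacked ring pair would also register an alkyl
contact and collapse to subtype *mixed*, making P unreachable.

Profiles are deduplicated to residue-level keys `(chain, resnum, resname,
kind)` by default because frequency profiles are conventionally reported
per residue with a single subtype letter; subtype-resolved keys are
available via a flag. Backbone and side-chain contacts are not
distinguished in the key.

## The synthetic benchmark

The fixtures module emulates the study conditions of an
actives-vs-decoys protocol at desk scale:

* **Pockets** are geometric scaffolds: simplified Ser/Leu/Ala/Phe residues
  on a hemisphere of radius 8 Å around an origin cavity, spaced at least
  40° apart so a fragment planted against one residue cannot graze
  another's cutoff. They are not force-field-valid structures, and poses
  are built with ring/aromaticity perception but no valence model.
* **Planted interactions**: per structure, 2 hydrogen bonds and
  3 hydrophobic contacts — mirroring the canonical kinase pattern of a
  hinge hydrogen bond plus a bed of conserved hydrophobic anchors.
* **Realisation probabilities**: actives realise each planted interaction
  with p = 0.9 (a conserved contact), decoys with p = 0.2 (incidental).
* **Docking scores**: class-conditional Gaussians, actives −8.4 ± 1.5,
  decoys −7.0 ± 1.5. The 1.4 shift at sd 1.5 puts docking-only enrichment
  near AUC 0.75 — a deliberately good-but-imperfect baseline that leaves
  headroom for the interaction term.
* **Sizes**: 3 structures; 60 model-building actives per structure (top 30
  by docking score used); evaluation over 30 actives vs 90 decoys, a
  desk-scale analogue of a 30-vs-990 evaluation that keeps 100-replicate
  runs under a minute on one CPU.

What passing the benchmark shows: the pipeline recovers a planted contact
signal through the full model-building → scoring → consensus path, and the
enrichment ordering (consensus ≥ single-structure pharmacological ≥
docking-only) holds across replicates. What it does not show: performance
on real docked poses, where interaction realisation is correlated with
docking score, contact geometries are not sampled with safety margins, and
actives are not exchangeable — absolute AUCs here are optimistic and only
the ordering is meaningful.

## Numerical and design choices

* **Frequency boundaries.** Exact 50%/80% frequencies are *included*; the
  fractions are exact ratios `count/M`, so no floating-point boundary
  wobble is possible at the defaults with M = 30.
* **QED threshold.** 0.25 by default (configurable). The filter-cascade
  default rejects any Lipinski violation; the classical "one violation
  tolerated" reading is a config switch. The logP estimator is the Crippen
  atom-contribution method and is named in the config output, since
  estimator choice shifts borderline compounds.
* **PAINS.** All three published SMARTS families (A, B, C).
* **Redocking.** RMSD is computed in place (no re-superposition — crystal
  and redocked poses share the receptor frame), heavy atoms only, with
  symmetry correction by minimising over graph automorphisms; the pass
  criterion is strictly below 2.5 Å.
* **ROC-AUC.** Midrank / Mann-Whitney convention, so heavy score ties are
  handled exactly; verified against O(n²) pair counting.
* **Tanimoto of two empty fingerprints** is defined as 1.0 (featureless
  molecules are indistinguishable) and logged.
* **Clustering.** The representative-picking step uses leader
  (sphere-exclusion) clustering at Tanimoto 0.6, processing compounds in
  consensus-rank order; each cluster's representative is its leader, i.e.
  its best-ranked member. Deterministic given the ranking.
* **Determinism.** All randomness flows through `numpy.random.default_rng`
  seeds; pipeline artifacts contain no timestamps (timings go to a
  separate log), so a rerun with the same seed is byte-identical.

## Known limitations

* Donor/acceptor typing ignores charge states, tautomers and water-mediated
  bridges; halogen bonds, salt bridges and cation–pi interactions are out
  of scope.
* Receptor hydrogens are not modelled, so receptor-donor hydrogen bonds are
  accepted on distance alone.
* The docking step itself is an external adapter contract (a score
  manifest plus pose files); the package never generates docked poses for
  real molecules, and the mock adapter used in the synthetic screen samples
  geometry independently of the 2D structures used for filtering and
  clustering.
* Aromatic–aliphatic ("pi–alkyl") contacts are not scored as hydrophobic;
  tools that count them will report higher hydrophobic frequencies.
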