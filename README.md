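# pharmscreen

Consensus pharmacological-interaction rescoring for structure-based virtual
screening.

Docking scores alone are noisy rankers of candidate inhibitors. When a set
of known actives is available for a target, the residue contacts those
actives reliably make — the hinge hydrogen bonds and conserved hydrophobic
anchors of a kinase ATP pocket, for example — can be distilled into a
per-structure *pharmacological interaction model* and used to rescore a
screening library. `pharmscreen` implements that protocol end to end:

1. **Interaction detection.** Hydrogen bonds and hydrophobic contacts
   (subtyped alkyl / pi-stacking / mixed) are detected in docked poses by
   configurable geometric criteria and reduced to a residue-level contact
   profile per compound.
2. **Model building.** The top-*n* actives by docking score (default
   *n* = 30) are profiled per receptor structure; contacts formed by at
   least 50% (hydrogen bonds) or 80% (hydrophobic) of them become the
   structure's key pharmacological interactions.
3. **Rescoring.** Each compound gets the pharmacological score
   `S(i) = N(i) + (−0.01)·D(i)`, where `N(i)` counts the key interactions
   its pose forms and `D(i)` is its docking score (more negative = better).
4. **Consensus.** Per-structure rankings by `S` are combined across two or
   more receptor structures by summing ordinal ranks; compounds are
   reranked by the rank sum (lower = better).
5. **Evaluation & support.** Mann-Whitney ROC-AUC against decoy sets,
   symmetry-corrected redocking RMSD validation (pass = RMSD < 2.5 Å), a
   drug-likeness filter cascade (HTS organic/reactive screen, Lipinski,
   Veber, PAINS, QED), and ECFP4/Tanimoto similarity with leader clustering
   for representative picking.

A synthetic-fixtures module generates everything needed to exercise the
pipeline with no external data: geometric binding pockets, poses with
planted interactions, and actives-vs-decoys benchmarks with a controllable
pharmacological signal.

## Worked example

```python
from pharmscreen import BenchmarkSpec, run_benchmark

result = run_benchmark(BenchmarkSpec(seed=7))
print({k: round(v, 3) for k, v in result["auc_docking"].items()})
print({k: round(v, 3) for k, v in result["auc_pharmacological"].items()})
print(round(result["auc_consensus"], 3))
```

prints

```
{'STR1': 0.738, 'STR2': 0.776, 'STR3': 0.742}
{'STR1': 0.998, 'STR2': 0.994, 'STR3': 0.998}
1.0
```

Three synthetic receptor structures are generated, each with five planted
key interactions (two hydrogen bonds, three hydrophobic contacts). Sixty
synthetic actives per structure build the pharmacological models; an
evaluation set of 30 actives and 90 decoys is then ranked. Docking scores
alone discriminate at AUC ≈ 0.75 (by construction); adding the interaction
term lifts each structure above 0.99, and the three-structure rank-sum
consensus reaches 1.0 — the qualitative ordering (consensus ≥ single
pharmacological ≥ docking-only) the method is designed to deliver.

The same protocol is available from the shell:

```bash
pharmscreen screen --out run/ --seed 1        # staged end-to-end screen
pharmscreen evaluate --replicates 20          # AUC table over replicates
pharmscreen filter --in library.smi --report report.json
pharmscreen fixtures --out bench/ --seed 1    # write a benchmark as PDB/SDF/CSV
```

`pharmscreen screen` runs library generation → filter cascade → (mock)
docking → top-K by docking score → pharmacological scoring → consensus
rerank → top-K consensus → clustering → representatives, writing every
stage's artifact plus a provenance report; reruns with the same seed are
byte-identical.

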