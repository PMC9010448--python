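# fragchal

An evaluation toolkit for blind crystallographic fragment-screening
challenges, built for challenge organizers and method developers who need to
score community submissions against experimental ground truth. It covers the
three tasks such a challenge poses:

1. **Screening** — did a method discriminate crystallographic binders from
   non-binders? Boolean submissions are scored against a per-fragment ground
   truth (hit / miss / excluded-for-no-data) using sensitivity (TPR),
   specificity (TNR) and their mean, the **balanced accuracy**
   BA = (TPR + TNR)/2, with 95% percentile-bootstrap confidence intervals
   (10,000 resamples of the paired prediction/label arrays). BA = 0.5 is the
   random line for a class-imbalanced library.
2. **Pose prediction** — how close are 1–5 ranked docked poses to the
   crystallographic pose? Predicted receptors are superposed onto the
   experimental one by a Kabsch least-squares fit of paired Cα coordinates
   (reflection-corrected, det R = +1), the fitted rigid transform carries the
   ligand into the crystallographic frame, and the deviation is the
   **symmetry-corrected heavy-atom RMSD**: the minimum over all
   automorphisms σ of the element-labeled molecular graph of
   √(mean‖x_pred,σ(k) − x_ref,k‖²), so swaps of chemically equivalent atoms
   are free. Success is RMSD ≤ 2 Å (inclusive, configurable); *top-1* and
   *best-in-all* rates are reported together with full success-vs-cutoff
   curves.
3. **Follow-up enumeration** — are suggested elaborations reasonable?
   Molecular descriptors (MW, Wildman–Crippen logP, Ertl TPSA, HBD/HBA,
   rotatable bonds, rings), Lipinski rule-of-5 compliance, Morgan-fingerprint
   Tanimoto similarity, and cohort comparisons against the fragment-hit set.

A **fragment network** supports chemical-space enumeration around hits:
molecules are recursively fragmented (substituent, ring and linker removal
at acyclic single bonds), nodes are hydrogen-capped canonical structures,
edges are parent→child relations, and queries return library molecules
within `hops` edge traversals whose heavy-atom / ring-atom counts stay
within `hac` / `rac` of the query.

Everything is testable offline: a fixtures module generates toy libraries,
perturbed poses of known RMSD, simulated submissions of known
sensitivity/specificity, and a synthetic helical receptor.

## Worked example

```sh
python examples/screening_metrics.py
```

prints

```
library 799, positives 47, negatives 712, excluded 40
hit rate: 5.88%
sensitivity 0.553  specificity 0.910  balanced accuracy 0.732
95% bootstrap CI for balanced accuracy: [0.657, 0.803]
random predictor balanced accuracy: 0.474 (0.5 = random line)
```

The ground truth mirrors a real screen's bookkeeping: 799 fragments, 47
crystallographic hits at the acetyl-lysine site, 40 fragments dropped
because no usable diffraction data existed (these never touch any metric),
leaving 712 negatives and a 5.88% hit rate. The simulated submission was
generated to find 60% of binders and reject 90% of non-binders; the
realized rates (0.553/0.910) reflect binomial noise at 47 positives, and the
bootstrap interval quantifies exactly that uncertainty. The random
predictor lands near 0.5 no matter what fraction of the library it calls
binders.

The other examples follow the same pattern: `pose_rmsd.py` (why symmetry
correction matters, and top-1 vs best-in-all bookkeeping),
`follow_up_descriptors.py` (descriptor drift of elaborated compounds), and
`fragment_network.py` (network construction and monotone neighborhood
queries).

## Command line

For batch evaluation the same machinery is exposed as a thin CLI:

```sh
fragchal stage1 --ground-truth gt.csv --submission sub.csv --out-dir out/
fragchal stage2 --reference-dir refs/ --submission-dir poses/ --out-dir out/
fragchal stage3 --followups followups.csv --hits hits.smi --out-dir out/
fragchal fragnet-build --library library.smi --out network.jsonl
fragchal fragnet-query --network network.jsonl --smiles c1ccccc1 --hops 2
fragchal fixtures --what submissions --out-dir fixtures/
```

Reports are JSON + CSV side by side and embed the configuration, seed,
toolkit version and input digests so every run can be replayed.

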