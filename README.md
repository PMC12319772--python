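# nesyqsar

A neuro-symbolic QSAR toolkit for binary bioactivity classification of enzyme
inhibitors — built around DPP-4 (dipeptidyl peptidase-4, a type-2-diabetes
drug target) but applicable to any SMILES + IC50 table.

It is aimed at computational chemists and ML researchers who want a
**Logic Tensor Network (LTN)** style classifier — a neural network trained by
maximising the satisfaction of first-order class axioms under differentiable
fuzzy (Real) logic — together with the complete data machinery around it:
multi-source bioactivity curation, molecular featurization, a plain-DNN
baseline, and reproducible end-to-end runs.

## The model

The classifier is a *grounded predicate* `P(x, l)`: an MLP whose
softmax output at index `l` is read as the fuzzy truth degree, in [0, 1], of
"compound `x` carries class label `l`". The knowledge base holds one
universally quantified axiom per class,

```
K = { ∀x_A  P(x_A, l_A),   ∀x_B  P(x_B, l_B) }
```

(every active compound should be labeled active; every inactive one
inactive). The ∀ quantifier uses the **pMeanError** semantics

```
pME(u₁,…,uₙ; p) = 1 − ( (1/n) Σᵢ (1 − uᵢ)ᵖ )^(1/p),   p ≥ 1,
```

the complement of the generalized p-mean of deviations from full truth. A
satisfaction aggregator (SatAgg, pMeanError again by default) combines the
axiom truths, and training minimises `L = 1 − SatAgg` by Adam. All gradients
are hand-derived NumPy; a finite-difference check pins their correctness.

Around the logic core:

- **Curation** (`nesyqsar.curation`): harmonise IC50 units (nM = μM × 1000),
  compute pIC50 = −log10(IC50·10⁻⁹), label active/inactive at pIC50 ≥ 6
  (IC50 ≤ 1 μM, configurable), canonicalise SMILES with RDKit, deduplicate,
  stratified 70:10:20 split, standard-scale on training statistics.
- **Featurization** (`nesyqsar.featurization`): Morgan/ECFP fingerprints at
  512/1024/2048 bits (radius 2 ≈ ECFP4), six physicochemical properties
  (MW, LogP, TPSA, HBD, HBA, rotatable bonds), an optional CDK-extended
  (PaDEL) adapter and a precomputed-embedding plugin.
- **Evaluation** (`nesyqsar.metrics`): confusion counts, accuracy, F1,
  ROC-AUC (rank statistic), Matthews correlation coefficient.
- **Synthetic data** (`nesyqsar.synthetic`): ledgered raw-table generator
  (unit mixes, equivalent-SMILES duplicates, missing fields) and separable
  Gaussian feature sets with closed-form Bayes error.

## Worked example

```python
import numpy as np
from nesyqsar import (KnowledgeBase, NetworkSpec, TrainConfig,
                      evaluate, simulate_separable_features, train_ltn)
from nesyqsar.curation import standard_scale

x, y, bayes = simulate_separable_features(n=2000, dim=32, separation=6.0, seed=42)
split = np.array(["train"]*1400 + ["val"]*200 + ["test"]*400)
xs, _ = standard_scale(x, split)

kb = KnowledgeBase.binary_classification()          # the two class axioms
net = NetworkSpec((None, 384, 192, 2), "relu", 0.25)
cfg = TrainConfig(epochs=100, batch_size=128, learning_rate=1e-4, seed=42)
pred, history = train_ltn(xs[:1400], y[:1400], kb, net, cfg)
report = evaluate(pred, xs[1600:], y[1600:])
print(f"bayes error {bayes:.4f}  accuracy {report.accuracy:.4f}  mcc {report.mcc:.4f}")
```

prints

```
bayes error 0.0013  accuracy 0.9950  mcc 0.9900
```

i.e. on two Gaussian classes separated by 6σ (Bayes error 0.13%), the
axiom-trained classifier recovers the labels of held-out compounds at 99.5%
accuracy — the satisfaction loss drives the same decision boundary as
cross-entropy (`train_dnn` reaches 99.75% on the same fixture).

The same workflow runs from the shell:

```bash
nesyqsar simulate --n 500 --seed 42 --out raw.csv --ledger ledger.json
nesyqsar curate --in raw.csv --threshold 6.0 --seed 42 --out curated.csv
nesyqsar featurize --in curated.csv --schemes morgan,physchem --morgan-bits 512 --out features.csv
nesyqsar run-all --out run_dir/          # full pipeline into a run directory
```

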