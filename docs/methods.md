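# Methods

## The classification model

`nesyqsar` casts binary bioactivity classification as knowledge-base
satisfaction in differentiable fuzzy logic (Real Logic, the semantics of
Logic Tensor Networks). The trainable object is a grounded predicate
`G_θ = P(x, l)`: a feed-forward network with softmax head whose output at
class index `l` is the truth degree of "compound x has label l". Because the
head is a softmax, the per-class truths are each in [0, 1] and sum to 1 —
the one-hot label grounding.

The knowledge base contains exactly two universally quantified axioms, one
per class: every active compound should be labeled active, and every
inactive compound inactive. No connectives, existential quantifiers or
relational predicates are needed for this task, and none are implemented.

The universal quantifier is interpreted by the pMeanError aggregator

    pME(u_1..u_n; p) = 1 − ( (1/n) Σ (1 − u_i)^p )^(1/p),  p ≥ 1,

applied to the truth degrees of an axiom's class members in the batch. A
satisfaction aggregator combines the axiom truths into one scalar; training
minimises `L = 1 − SatAgg` with Adam over stratified mini-batches.

### Design choices in the logic core

- **Aggregator order.** `p = 2` for both the quantifier and SatAgg, exposed
  as `p_forall` / `p_satagg`. `p = 1` is the arithmetic mean; growing p
  weights the worst-classified examples more strongly and approaches the
  minimum truth (the gap to the minimum scales as `log(n)/p`, so p = 200 on
  a handful of truths is within 1e-2 of `min`). p = 2 is the conventional
  default for this aggregator family and behaves well under SGD.
- **SatAgg operator.** pMeanError reused across axioms, with `min` and
  `mean` as configurable alternatives. With two well-balanced axioms the
  three behave nearly identically; pMeanError keeps the loss smooth.
- **Axioms missing from a batch** are skipped for that batch rather than
  failing the step; stratified batching makes this rare by construction, and
  a batch covering no axiom at all is an error.
- **Label map.** Active → index 0, inactive → index 1 by default,
  configurable (`label_map`), since either orientation is defensible.
- **Numerical stability.** The forward value of pME is exact: it is computed
  in max-factored form `d_max · mean((d/d_max)^p)^(1/p)` so that large p
  neither under- nor overflows, and no clipping perturbs the value. The
  singularity of the gradient (`M^(1−p)` as the mean deviation M → 0) lives
  only in the backward path, so deviations are clipped to [0, 1−1e-7] and
  the power mean floored at 1e-12 **there only**. The closed-form gradient
  matches central finite differences to ~1e-6 relative error.

### Why hand-written backpropagation

The package deliberately carries its own compact MLP (dense layers, ReLU,
inverted dropout, softmax, Adam) with explicit backward passes. The
satisfaction loss has a simple closed-form chain rule — pME gradients into a
softmax Jacobian at the label coordinate — and writing it out keeps the
dependency footprint to NumPy while making the loss's structure inspectable.
Correctness is enforced by finite-difference tests over *all* parameters of
a small predicate, for both the satisfaction loss and cross-entropy.

### Training protocol

Defaults: hidden widths (384, 192), ReLU, dropout 0.25 (training only —
evaluation is deterministic), batch size 128, 100 epochs, Adam at learning
rate 1e-4 with standard betas, seed 42, no early stopping. The input layer
is always sized to the incoming feature dimension. Mini-batches are
stratified (each class's indices are shuffled, chunked, and zipped) so both
axioms see members in every batch. The DNN baseline is the identical network
and protocol with sparse categorical cross-entropy, which isolates the
contribution of the logic loss in comparisons.

## Curation pipeline

- Units harmonised to nM (`nM = μM × 1000`); unit strings accepted
  case-insensitively (`nM`, `uM`, `μM`, `µM`). Non-positive or unit-less
  measurements are errors.
- `pIC50 = −log10(IC50 · 10⁻⁹)` with IC50 in nM, so 1000 nM ↦ 6.0 and
  1 nM ↦ 9.0 exactly.
- **Activity threshold**: pIC50 ≥ 6.0 (IC50 ≤ 1 μM) ⇒ active, the standard
  potency convention in bioactivity QSAR; the boundary counts as active.
  Configurable, with an optional (default-off) exclusion band for a pIC50
  gray zone — the default labeling is strictly binary.
- **Deduplication** is on internally recomputed RDKit canonical SMILES
  (source "canonical" columns are not trusted across databases). Records
  are stably ordered by source priority (ChEMBL, BindingDB, PubChem, GTP)
  and the first-seen record wins; duplicates are counted, not averaged.
- Records missing ID/SMILES/IC50, censored measurements (">"/"<"
  qualifiers), unparseable SMILES and unknown units are dropped with
  per-filter counts in the curation log.
- **Split**: stratified 70:10:20 via scikit-learn with integer split sizes
  (avoids float-ratio rounding drift); deterministic under the seed.
- **Scaling**: scikit-learn StandardScaler fitted on the training split
  only; validation/test are transformed with frozen training statistics;
  zero-variance columns pass through centered.

## Featurization

Morgan (ECFP-style) hashed fingerprints via RDKit's fingerprint generator at
512/1024/2048 bits, radius 2 (the ECFP4 convention); requesting several
widths concatenates independent fingerprints (512+1024+2048 = 3584 columns).
Bits, not counts. The six physicochemical properties are MW, Crippen LogP,
TPSA, H-bond donors/acceptors and rotatable bonds, in that fixed order. The
CDK-extended 1024-bit fingerprint is an adapter over the optional `padelpy`
backend (a Java descriptor engine): when absent it raises a documented
`FeatureBackendUnavailable` and the rest of the pipeline is unaffected.
Chemical-language-model embeddings are supported only as precomputed CSVs
aligned by canonical SMILES; computing them requires pretrained weights and
is out of scope. All featurizers are pure functions of the canonical SMILES.

## Synthetic data

The raw-table generator emulates a multi-source IC50 export on a bundled
pool of 630 unique, RDKit-validated drug-like molecules (the approved DPP-4
inhibitors — sitagliptin, saxagliptin, vildagliptin, alogliptin, linagliptin
— plus common drugs and a scaffold × substituent grid). Defaults: 500
records, 50% intended actives, 30% of rows reported in μM, 10% duplicates,
5% rows with a missing mandatory field, seed 42.

- Activity is tied to structure — molecules above the active-fraction
  molecular-weight quantile are the intended actives — so fingerprints carry
  a learnable signal end to end.
- IC50 values are log-normal around class centres of 50 nM (actives) and
  20 μM (inactives) with 0.7 log10 spread, which puts ~3% of each class on
  the wrong side of the pIC50 = 6 cutoff: labels are noisy but strongly
  class-correlated, exercising non-trivial classification.
- μM rows define their ground-truth nM as `value × 1000` computed in
  float64, so unit harmonisation restores them bit-exactly.
- Duplicates re-emit earlier rows under an alternative (randomly re-ordered
  but equivalent) SMILES spelling, exercising canonicalisation; missing rows
  blank one mandatory field. Sampling is without replacement, so with no
  injected pathologies every record survives curation.
- The generator emits a **ledger** — survivor count, surviving compound IDs
  and per-label counts — computed by independent bookkeeping over the
  emitted rows (the same stable source-priority/first-seen rule, applied to
  known ground truth). Tests require curation to reproduce the ledger
  exactly.

What the generator does *not* emulate: assay heterogeneity beyond log-normal
spread, activity cliffs, scaffold-split generalisation gaps, inter-database
value conflicts beyond simple duplicates. Passing tests therefore
demonstrate correctness of the machinery and learnability under clean
conditions, not predictive performance on real screening data.

The separable-feature generator draws two spherical Gaussians whose means
are `separation · σ` apart along a random direction; its Bayes error is
Φ(−separation/2). At separation 6 that is 0.00135, so ≥98% held-out accuracy
is attainable and both models reach ≥99% under the default protocol.

## Problem sizes

The reference learning fixture is n = 2000, dim = 32, separation 6σ,
split 1400/200/400, trained for the full 100-epoch protocol; the ledgered
curation fixture is 500 records; pipeline reproducibility uses a 300-record
simulated table with 512-bit fingerprints and a (64, 32) network for 30
epochs. These sizes exercise every code path at full protocol fidelity while
keeping a complete verification run to well under a minute.

## Known limitations

- Only binary classification; the axiom schema generalises to k classes but
  the curation labeling is two-class.
- The reported external-data regime (training on the published curated
  DPP-4 set with CDK-extended + Morgan features, accuracy ≈ 0.97) requires
  the authors' dataset download and the Java PaDEL backend; with both
  available, `run_pipeline` on that CSV with
  `schemes=("cdk_extended", "morgan")`, `morgan_bits=(512, 1024, 2048)` is
  the corresponding manual experiment. It is not part of the automated
  verification.
- Training is CPU NumPy; fine at these problem sizes, not meant for
  million-compound screens.
- Duplicate IC50 conflicts are resolved by source priority, not by
  averaging; censored values are dropped rather than modelled.
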