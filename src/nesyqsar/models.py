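"""Training and evaluation of the Real-Logic (LTN) classifier and the plain
DNN baseline.

Both models share the same MLP grounding, architecture and optimisation
protocol (Adam, fixed epoch budget, stratified mini-batches, dropout during
training only); they differ solely in the loss.  The LTN minimises
``1 - SatAgg`` over the knowledge base of per-class axioms; the baseline
minimises sparse categorical cross-entropy.  Gradients of both losses with
respect to the network logits are written in closed form and pushed through
:meth:`nesyqsar.nn.MLP.backward`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .metrics import EvalReport
from .nn import MLP, Adam, NetworkSpec
from .real_logic import (
    GroundedPredicate,
    KnowledgeBase,
    pmean_error,
    pmean_error_grad,
    sat_agg,
)

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "train_ltn",
    "train_dnn",
    "evaluate",
    "grid_search",
    "plot_history",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol: Adam over a fixed epoch budget, seeded."""

    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-4
    seed: int = 42
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the 'adam' optimizer is supported")


def _stratified_batches(labels: np.ndarray, batch_size: int, rng: np.random.Generator):
    """Yield batch index arrays in which every class is represented.

    Each class's indices are shuffled and cut into the same number of chunks,
    then chunks are zipped together, so per-class axioms always see members.
    """
    classes = np.unique(labels)
    n_batches = max(1, int(np.ceil(labels.size / batch_size)))
    per_class = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        per_class.append(np.array_split(idx, n_batches))
    for chunks in zip(*per_class):
        batch = np.concatenate(chunks)
        if batch.size:
            yield batch


def _ltn_logit_grad(
    kb: KnowledgeBase, probs: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Satisfaction loss on a batch and its gradient w.r.t. the logits.

    Chain: loss = 1 − SatAgg(a_1..a_K); a_k = pME(u in class k, p∀);
    u_i = softmax(logits_i)[label_i].  Axioms with no batch members are
    skipped.
    """
    labels = np.asarray(labels, dtype=np.int64)
    n, n_classes = probs.shape
    axiom_truths: list[float] = []
    axiom_members: list[np.ndarray] = []
    axiom_labels: list[int] = []
    for axiom in kb.axioms:
        idx = np.flatnonzero(labels == axiom.class_value)
        if idx.size == 0:
            continue
        u = np.clip(probs[idx, axiom.label], 0.0, 1.0)
        axiom_truths.append(pmean_error(u, kb.p_forall))
        axiom_members.append(idx)
        axiom_labels.append(axiom.label)
    if not axiom_truths:
        raise ValueError("batch contains no member of any axiom's class")

    a = np.asarray(axiom_truths)
    if kb.satagg_operator == "pmean_error":
        satagg = pmean_error(a, kb.p_satagg)
        dsat_da = pmean_error_grad(a, kb.p_satagg)
    elif kb.satagg_operator == "min":
        satagg = float(a.min())
        dsat_da = np.zeros_like(a)
        dsat_da[int(a.argmin())] = 1.0
    else:  # mean
        satagg = float(a.mean())
        dsat_da = np.full_like(a, 1.0 / a.size)

    dlogits = np.zeros_like(probs)
    for k, (idx, label) in enumerate(zip(axiom_members, axiom_labels)):
        u = np.clip(probs[idx, label], 0.0, 1.0)
        # dL/du_i = −(dSatAgg/da_k)(da_k/du_i)
        du = -dsat_da[k] * pmean_error_grad(u, kb.p_forall)
        # softmax jacobian at the label coordinate:
        # du/dlogit_j = u (δ_{j,label} − p_j)
        contrib = -du[:, None] * u[:, None] * probs[idx]
        contrib[np.arange(idx.size), label] += du * u
        dlogits[idx] += contrib
    return 1.0 - satagg, dlogits


def _xent_logit_grad(probs: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Sparse categorical cross-entropy and its logit gradient."""
    labels = np.asarray(labels, dtype=np.int64)
    n = probs.shape[0]
    picked = np.clip(probs[np.arange(n), labels], 1e-12, 1.0)
    loss = float(-np.mean(np.log(picked)))
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


def _train(
    features: np.ndarray,
    labels: np.ndarray,
    net: NetworkSpec,
    cfg: TrainConfig,
    loss_grad,
    val: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[MLP, dict[str, list[float]]]:
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if np.unique(labels).size < 2:
        raise ValueError("training labels contain a single class")
    model = MLP(net.with_input_dim(features.shape[1]), seed=cfg.seed)
    opt = Adam(model.parameters, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history: dict[str, list[float]] = {"loss": [], "train_accuracy": []}
    if val is not None:
        history["val_accuracy"] = []
    for _ in range(cfg.epochs):
        losses = []
        for batch in _stratified_batches(labels, cfg.batch_size, rng):
            probs = model.forward(features[batch], training=True)
            loss, dlogits = loss_grad(probs, labels[batch])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at step {opt.t}: loss={loss!r}; "
                    "check feature scaling and learning rate"
                )
            grads_w, grads_b = model.backward(dlogits)
            opt.step(grads_w + grads_b)
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        pred = model.predict_proba(features).argmax(axis=1)
        history["train_accuracy"].append(float(np.mean(pred == labels)))
        if val is not None:
            vpred = model.predict_proba(val[0]).argmax(axis=1)
            history["val_accuracy"].append(float(np.mean(vpred == np.asarray(val[1]))))
    return model, history


def train_ltn(
    features: np.ndarray,
    labels: np.ndarray,
    kb: KnowledgeBase,
    net: NetworkSpec = NetworkSpec(),
    cfg: TrainConfig = TrainConfig(),
    val: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[GroundedPredicate, dict[str, list[float]]]:
    """Fit the grounded predicate by maximising knowledge-base satisfaction."""
    model, history = _train(
        features, labels, net, cfg,
        loss_grad=lambda probs, y: _ltn_logit_grad(kb, probs, y),
        val=val,
    )
    return GroundedPredicate(model), history


def train_dnn(
    features: np.ndarray,
    labels: np.ndarray,
    net: NetworkSpec = NetworkSpec(),
    cfg: TrainConfig = TrainConfig(),
    val: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[MLP, dict[str, list[float]]]:
    """Identical protocol to :func:`train_ltn` but with cross-entropy loss."""
    return _train(features, labels, net, cfg, loss_grad=_xent_logit_grad, val=val)


def evaluate(
    model,
    features: np.ndarray,
    labels: np.ndarray,
    positive_label: int = 0,
    history: dict[str, list[float]] | None = None,
) -> EvalReport:
    """Confusion counts + accuracy/F1/ROC-AUC/MCC on an evaluation split.

    ``positive_label`` names the class treated as positive in the confusion
    matrix; under the default label map the active class is index 0.
    Dropout is inactive: evaluation is deterministic.
    """
    net = model.network if isinstance(model, GroundedPredicate) else model
    probs = net.predict_proba(np.asarray(features, dtype=np.float64))
    scores = probs[:, positive_label]
    preds = probs.argmax(axis=1)
    y = np.asarray(labels, dtype=np.int64)
    report = EvalReport.from_scores(
        y_true=(y == positive_label).astype(int),
        positive_scores=scores,
        history=history,
    )
    # argmax prediction, not score thresholding, defines the confusion matrix
    from .metrics import accuracy, confusion_counts, f1_score, mcc

    counts = confusion_counts((y == positive_label).astype(int), (preds == positive_label).astype(int))
    report.counts = counts
    report.accuracy = accuracy(counts)
    report.f1 = f1_score(counts)
    report.mcc = mcc(counts)
    return report


def training_sat_agg(pred: GroundedPredicate, kb: KnowledgeBase,
                     features: np.ndarray, labels: np.ndarray) -> float:
    """Knowledge-base satisfaction of a fitted predicate on a dataset."""
    return sat_agg(kb, pred, features, labels)


def grid_search(
    space: dict[str, list],
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    model: str = "ltn",
    kb: KnowledgeBase | None = None,
    net: NetworkSpec = NetworkSpec(),
    cfg: TrainConfig = TrainConfig(),
) -> pd.DataFrame:
    """Exhaustive grid search ranked by validation accuracy.

    ``space`` maps config fields to candidate lists; recognised keys are
    ``activation``, ``dropout``, ``hidden`` (tuple of hidden widths),
    ``learning_rate``, ``epochs``, ``batch_size``.  Every trial logs its full
    configuration, so the best trial is reproducible from its row.
    """
    if model == "ltn" and kb is None:
        kb = KnowledgeBase.binary_classification()
    keys = list(space)
    rows = []
    for values in itertools.product(*(space[k] for k in keys)):
        combo = dict(zip(keys, values))
        trial_net = NetworkSpec(
            layer_widths=(None, *combo.get("hidden", net.layer_widths[1:-1]), net.layer_widths[-1]),
            activation=combo.get("activation", net.activation),
            dropout=combo.get("dropout", net.dropout),
        )
        trial_cfg = replace(
            cfg,
            learning_rate=combo.get("learning_rate", cfg.learning_rate),
            epochs=combo.get("epochs", cfg.epochs),
            batch_size=combo.get("batch_size", cfg.batch_size),
        )
        if model == "ltn":
            fitted, history = train_ltn(*train, kb, trial_net, trial_cfg, val=val)
        else:
            fitted, history = train_dnn(*train, trial_net, trial_cfg, val=val)
        report = evaluate(fitted, *val)
        rows.append(
            {
                **combo,
                "val_accuracy": report.accuracy,
                "val_f1": report.f1,
                "final_loss": history["loss"][-1],
                "seed": trial_cfg.seed,
            }
        )
    trials = pd.DataFrame(rows).sort_values("val_accuracy", ascending=False, kind="stable")
    return trials.reset_index(drop=True)


def plot_history(history: dict[str, list[float]], path) -> None:
    """Save per-epoch loss/accuracy curves (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax1.plot(history["loss"])
    ax1.set_xlabel("epoch")
    ax1.set_ylabel("training loss")
    for key in ("train_accuracy", "val_accuracy"):
        if key in history:
            ax2.plot(history[key], label=key.replace("_", " "))
    ax2.set_xlabel("epoch")
    ax2.set_ylabel("accuracy")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
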