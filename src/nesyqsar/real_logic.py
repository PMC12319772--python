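"""Differentiable Real-Logic semantics for knowledge-based classification.

The classifier is a *grounded predicate*: a feed-forward network whose
softmax output ``P(x, l)`` is read as the fuzzy truth degree, in [0, 1], of
the statement "compound ``x`` carries class label ``l``".  A knowledge base
is a set of universally quantified axioms, one per class::

    K = { forall x_A : P(x_A, l_A),   forall x_B : P(x_B, l_B) }

i.e. every member of a class should receive that class's label.  The
universal quantifier is given the *pMeanError* semantics

    pME(u_1, ..., u_n; p) = 1 - ( (1/n) * sum_i (1 - u_i)^p )^(1/p),   p >= 1,

the complement of the generalized p-mean of the deviations ``1 - u_i`` from
full truth.  Axiom truths are aggregated across the knowledge base by a
satisfaction aggregator (SatAgg, pMeanError again by default) and training
minimises ``L = 1 - SatAgg``.

Everything here is pure NumPy; gradients of the aggregators are provided in
closed form so the training loop in :mod:`nesyqsar.models` can backpropagate
through the logic without an autodiff framework.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "TruthDegree",
    "DeviationOrder",
    "Axiom",
    "KnowledgeBase",
    "GroundedPredicate",
    "pmean_error",
    "pmean_error_grad",
    "quantify_forall",
    "predicate_truth",
    "sat_agg",
    "satisfaction_loss",
]

#: floor added to the power-mean before the (1/p - 1) exponent in gradients;
#: keeps the derivative finite when every deviation is ~0.
_GRAD_EPS = 1e-12
#: deviations are clipped below 1 - 1e-7 in the gradient path so d^(p-1)
#: cannot saturate the M^(1-p) factor at the u = 0 corner.
_DEV_CLIP = 1.0 - 1e-7


def _as_truths(values: Sequence[float] | np.ndarray) -> np.ndarray:
    u = np.asarray(values, dtype=np.float64)
    if u.ndim != 1 or u.size == 0:
        raise ValueError("truth degrees must form a non-empty 1-D sequence")
    if np.any(~np.isfinite(u)) or np.any(u < 0.0) or np.any(u > 1.0):
        raise ValueError("truth degrees must lie in [0, 1]")
    return u


@dataclass(frozen=True)
class TruthDegree:
    """A fuzzy truth value, constrained to [0, 1]."""

    value: float

    def __post_init__(self) -> None:
        if not (0.0 <= float(self.value) <= 1.0):
            raise ValueError(f"truth degree {self.value!r} outside [0, 1]")

    def __float__(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class DeviationOrder:
    """Exponent of the generalized mean of deviations; must satisfy p >= 1."""

    p: float = 2.0

    def __post_init__(self) -> None:
        if not (float(self.p) >= 1.0):
            raise ValueError(f"deviation order p={self.p!r} must be >= 1")

    def __float__(self) -> float:
        return float(self.p)


def pmean_error(truths: Sequence[float] | np.ndarray, p: float | DeviationOrder = 2.0) -> float:
    """1 minus the generalized p-mean of the deviations ``1 - u_i``.

    Computed in a max-factored form, ``M = d_max * mean((d/d_max)^p)^(1/p)``,
    so large ``p`` (the min-approaching regime) does not underflow.
    """
    u = _as_truths(truths)
    p = float(DeviationOrder(float(p)))
    d = 1.0 - u
    dmax = float(d.max())
    if dmax == 0.0:
        return 1.0
    m = dmax * float(np.mean((d / dmax) ** p)) ** (1.0 / p)
    return float(np.clip(1.0 - m, 0.0, 1.0))


def pmean_error_grad(truths: Sequence[float] | np.ndarray, p: float | DeviationOrder = 2.0) -> np.ndarray:
    """d pME / d u_i, elementwise.

    With ``M = (mean(d^p))^(1/p)`` and ``d_i = 1 - u_i``:
    ``d pME/d u_i = (1/n) * d_i^(p-1) * M^(1-p)`` (non-negative: raising any
    truth never lowers the aggregate).  Deviations are clipped and the mean is
    floored so the ``M -> 0`` corner stays finite.
    """
    u = _as_truths(truths)
    p = float(DeviationOrder(float(p)))
    n = u.size
    d = np.clip(1.0 - u, 0.0, _DEV_CLIP)
    s = float(np.mean(d**p)) + _GRAD_EPS
    return (d ** (p - 1.0)) * s ** (1.0 / p - 1.0) / n


def quantify_forall(
    domain_truths: Sequence[float] | np.ndarray, p: float | DeviationOrder = 2.0
) -> float:
    """Universal quantification over one axiom's class domain: pMeanError."""
    return pmean_error(domain_truths, p)


@dataclass(frozen=True)
class Axiom:
    """One universally quantified class rule: every class member gets its label.

    ``class_value`` is the value in the label column that selects this axiom's
    domain; ``label`` is the class index the grounded predicate should assert.
    """

    name: str
    class_value: int
    label: int


@dataclass
class KnowledgeBase:
    """Ordered axioms plus the aggregation orders for ∀ and SatAgg."""

    axioms: list[Axiom]
    p_forall: DeviationOrder = field(default_factory=DeviationOrder)
    p_satagg: DeviationOrder = field(default_factory=DeviationOrder)
    satagg_operator: Literal["pmean_error", "min", "mean"] = "pmean_error"

    def __post_init__(self) -> None:
        if not self.axioms:
            raise ValueError("knowledge base must contain at least one axiom")

    @classmethod
    def binary_classification(
        cls,
        p_forall: float = 2.0,
        p_satagg: float = 2.0,
        satagg_operator: Literal["pmean_error", "min", "mean"] = "pmean_error",
        label_map: dict[str, int] | None = None,
    ) -> "KnowledgeBase":
        """The two-axiom KB for active/inactive classification.

        ``label_map`` maps the class names to indices; the default follows the
        convention active -> 0, inactive -> 1.
        """
        label_map = {"active": 0, "inactive": 1} if label_map is None else label_map
        axioms = [
            Axiom(name=f"forall_{name}", class_value=idx, label=idx)
            for name, idx in sorted(label_map.items(), key=lambda kv: kv[1])
        ]
        return cls(
            axioms=axioms,
            p_forall=DeviationOrder(p_forall),
            p_satagg=DeviationOrder(p_satagg),
            satagg_operator=satagg_operator,
        )


class GroundedPredicate:
    """Neural grounding G_theta of the classification predicate P(x, l).

    Wraps a multilayer perceptron (see :class:`nesyqsar.nn.MLP`); the truth
    degree of ``P(x, l)`` is the softmax-normalised network output at index
    ``l``, so for every input the per-class truths sum to 1.
    """

    def __init__(self, network) -> None:
        self.network = network

    @property
    def in_dim(self) -> int:
        return self.network.layer_widths[0]

    @property
    def n_classes(self) -> int:
        return self.network.layer_widths[-1]

    def truths(self, x: np.ndarray, labels: np.ndarray, training: bool = False) -> np.ndarray:
        """Truth degrees P(x_i, labels_i) for a batch (vectorised)."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.in_dim:
            raise ValueError(
                f"feature dimension {x.shape[1]} != predicate input dimension {self.in_dim}"
            )
        labels = np.asarray(labels, dtype=np.int64)
        if labels.min() < 0 or labels.max() >= self.n_classes:
            raise ValueError("label index out of range")
        probs = self.network.predict_proba(x) if not training else self.network.forward(x, training=True)
        return probs[np.arange(x.shape[0]), labels]


def predicate_truth(pred: GroundedPredicate, x: np.ndarray, label: int) -> TruthDegree:
    """Truth degree of P(x, label) for a single feature vector."""
    value = float(pred.truths(np.atleast_2d(x), np.array([int(label)]))[0])
    # guard against float round just outside [0, 1]
    return TruthDegree(min(1.0, max(0.0, value)))


def _axiom_truths(
    kb: KnowledgeBase,
    pred: GroundedPredicate,
    features: np.ndarray,
    labels: np.ndarray,
    training: bool = False,
) -> tuple[list[float], list[np.ndarray]]:
    """Per-axiom quantified truths over the batch, with the member index sets.

    Axioms whose class has no member in the batch are skipped (stratified
    batching makes this rare); an entirely uncovered batch is an error.
    """
    labels = np.asarray(labels, dtype=np.int64)
    truths: list[float] = []
    members: list[np.ndarray] = []
    for axiom in kb.axioms:
        idx = np.flatnonzero(labels == axiom.class_value)
        if idx.size == 0:
            continue
        u = pred.truths(features[idx], np.full(idx.size, axiom.label), training=training)
        truths.append(pmean_error(np.clip(u, 0.0, 1.0), kb.p_forall))
        members.append(idx)
    if not truths:
        raise ValueError("batch contains no member of any axiom's class")
    return truths, members


def _aggregate(kb: KnowledgeBase, axiom_truths: Sequence[float]) -> float:
    if kb.satagg_operator == "pmean_error":
        return pmean_error(axiom_truths, kb.p_satagg)
    if kb.satagg_operator == "min":
        return float(np.min(axiom_truths))
    if kb.satagg_operator == "mean":
        return float(np.mean(axiom_truths))
    raise ValueError(f"unknown SatAgg operator {kb.satagg_operator!r}")


def sat_agg(
    kb: KnowledgeBase,
    pred: GroundedPredicate,
    features: np.ndarray,
    labels: np.ndarray,
) -> float:
    """Aggregate satisfaction of the knowledge base on a batch, in [0, 1]."""
    truths, _ = _axiom_truths(kb, pred, np.atleast_2d(features), labels)
    return _aggregate(kb, truths)


def satisfaction_loss(
    kb: KnowledgeBase,
    pred: GroundedPredicate,
    features: np.ndarray,
    labels: np.ndarray,
) -> float:
    """Training loss ``L = 1 - SatAgg`` (in [0, 1])."""
    return 1.0 - sat_agg(kb, pred, features, labels)
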