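"""The four training losses and their weighted sum.

* classification loss on labeled source rows (one-vs-all BCE on one-hot
  labels by default, softmax cross-entropy as an alternative head);
* domain adversarial loss, the symmetric average of the two binary
  cross-entropy terms ``(BCE(d_S, 1) + BCE(d_t, 0)) / 2``;
* individual adversarial loss, cross-entropy of the subject-membership
  distribution against the true subject index;
* target cluster loss, ``mean BCE(d_T, 1)`` over target rows whose
  predicted emotion confidence passes a selection rule — pulling
  confident target samples toward the source side of the domain
  discriminator's decision space.

Total: ``L_total = L_cls + L_domain + L_individual + lambda * L_cluster``.

All probabilities are clamped to ``[CLAMP_EPS, 1 - CLAMP_EPS]`` before
logs.  Every function accepts either plain arrays or autodiff tensors and
returns an autodiff tensor, so the same code path serves training and the
numeric tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor
from .exceptions import ConfigurationError

__all__ = [
    "LossBundle",
    "bce",
    "domain_loss",
    "individual_loss",
    "classification_loss",
    "select_confident_targets",
    "cluster_loss",
    "total_loss",
    "CLAMP_EPS",
]

CLAMP_EPS = 1e-7


@dataclass
class LossBundle:
    """The four loss terms, the cluster weight, and their exact sum."""

    cls: Tensor
    domain: Tensor
    individual: Tensor
    cluster: Tensor
    lambda_cluster: float
    total: Tensor
    n_selected: int

    def as_floats(self) -> dict[str, float]:
        return {
            "cls": self.cls.item(),
            "domain": self.domain.item(),
            "individual": self.individual.item(),
            "cluster": self.cluster.item(),
            "total": self.total.item(),
            "n_selected": float(self.n_selected),
        }


def _clamped(prob) -> Tensor:
    return ad.clip(as_tensor(prob), CLAMP_EPS, 1.0 - CLAMP_EPS)


def bce(y, y_hat) -> Tensor:
    """Mean binary cross-entropy over all elements.

    ``y`` may be hard labels in {0, 1} or soft targets in [0, 1]; ``y_hat``
    are predicted probabilities.
    """
    y = as_tensor(y)
    p = _clamped(y_hat)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: targets {y.shape} vs probabilities {p.shape}")
    terms = y * ad.log(p) + (1.0 - y) * ad.log(1.0 - p)
    return -terms.mean()


def domain_loss(domain_prob_source, domain_prob_target) -> Tensor:
    """Symmetric domain BCE: source rows toward 1, target rows toward 0."""
    ds = as_tensor(domain_prob_source)
    dt = as_tensor(domain_prob_target)
    if ds.data.size == 0 or dt.data.size == 0:
        raise ConfigurationError("domain loss needs rows on both sides")
    ones = np.ones(ds.shape)
    zeros = np.zeros(dt.shape)
    return 0.5 * (bce(ones, ds) + bce(zeros, dt))


def individual_loss(individual_prob, subject_labels, n_individuals: int) -> Tensor:
    """Mean cross-entropy of subject-membership probabilities."""
    p = as_tensor(individual_prob)
    labels = np.asarray(subject_labels, dtype=np.int64)
    if p.ndim != 2 or p.shape[0] != labels.shape[0]:
        raise ValueError("probability matrix and labels disagree in row count")
    if labels.size and (labels.min() < 0 or labels.max() >= n_individuals):
        raise ValueError(
            f"subject labels must lie in [0, {n_individuals}); got range "
            f"[{labels.min()}, {labels.max()}]"
        )
    picked = _clamped(p)[np.arange(labels.shape[0]), labels]
    return -ad.log(picked).mean()


def classification_loss(class_scores, labels, n_classes: int,
                        head: str = "ova_bce") -> Tensor:
    """Emotion classification loss on labeled source rows.

    ``head='ova_bce'`` treats the scores as per-class sigmoid probabilities
    and averages the binary cross-entropy of each class against the one-hot
    label (the literal multi-class BCE reading); ``head='softmax_ce'``
    treats them as a softmax distribution and applies cross-entropy.
    """
    scores = as_tensor(class_scores)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.ndim != 2 or scores.shape[1] != n_classes:
        raise ValueError(f"class scores must be (rows, {n_classes}); got {scores.shape}")
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    onehot = np.zeros((labels.shape[0], n_classes))
    onehot[np.arange(labels.shape[0]), labels] = 1.0
    if head == "ova_bce":
        return bce(onehot, scores)
    if head == "softmax_ce":
        picked = _clamped(scores)[np.arange(labels.shape[0]), labels]
        return -ad.log(picked).mean()
    raise ConfigurationError(f"unknown classification head {head!r}")


def select_confident_targets(class_scores_target, rule: str = "threshold",
                             threshold: float = 0.9,
                             fraction: float = 0.5) -> tuple[np.ndarray, int]:
    """Pick target rows whose max class probability passes the rule.

    ``rule='threshold'`` keeps rows with confidence >= ``threshold``;
    ``rule='top_fraction'`` keeps the ``fraction`` most confident rows
    (at least one when the fraction is positive).  Returns
    ``(indices, n_selected)``; the selection is detached from any gradient.
    """
    scores = class_scores_target.data if isinstance(class_scores_target, Tensor) \
        else np.asarray(class_scores_target, float)
    if scores.ndim != 2 or scores.shape[0] == 0:
        raise ValueError("need a non-empty (rows, classes) score matrix")
    confidence = scores.max(axis=1)
    if rule == "threshold":
        idx = np.flatnonzero(confidence >= threshold)
    elif rule == "top_fraction":
        k = max(1, int(round(fraction * len(confidence)))) if fraction > 0 else 0
        order = np.argsort(-confidence, kind="stable")
        idx = np.sort(order[:k])
    else:
        raise ConfigurationError(f"unknown selection rule {rule!r}")
    return idx, int(len(idx))


def cluster_loss(domain_prob_selected_targets) -> Tensor:
    """Mean ``BCE(d_T, 1)`` over the selected target rows; 0 if none."""
    d = as_tensor(domain_prob_selected_targets)
    if d.data.size == 0:
        return Tensor(0.0)
    return bce(np.ones(d.shape), d)


def total_loss(cls: Tensor, domain: Tensor, individual: Tensor,
               cluster: Tensor, lambda_cluster: float,
               n_selected: int = 0) -> LossBundle:
    """Assemble the bundle; ``total`` is the exact weighted sum."""
    cls, domain = as_tensor(cls), as_tensor(domain)
    individual, cluster = as_tensor(individual), as_tensor(cluster)
    total = cls + domain + individual + lambda_cluster * cluster
    return LossBundle(cls=cls, domain=domain, individual=individual,
                      cluster=cluster, lambda_cluster=float(lambda_cluster),
                      total=total, n_selected=int(n_selected))
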