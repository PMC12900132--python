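"""Evaluation protocols: subject-dependent trial splits and leave-one-subject-out.

Two standard experimental designs for EEG emotion decoding:

* **subject-dependent** — within one subject and session, the first block
  of trials is the labeled source domain and the remaining trials the
  unlabeled target domain (9/6 for three-class 15-trial sessions, 16/8
  for four-class 24-trial sessions);
* **LOSO** — each subject in turn is the unlabeled target domain and all
  other subjects form the source.

:func:`train` fits the adversarial estimator on one split,
:func:`evaluate` measures target-domain accuracy and confusion, and
:func:`run_protocol` loops over all splits and aggregates mean ± std.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from sklearn.metrics import confusion_matrix

from .data import FeatureSet
from .estimator import DomainAdversarialEEGClassifier
from .exceptions import ConfigurationError
from .reporting import RunSummary, summarize

__all__ = [
    "ProtocolSplit",
    "TrainConfig",
    "SPLIT_RULES",
    "make_subject_dependent_splits",
    "make_loso_splits",
    "train",
    "evaluate",
    "EvalResult",
    "run_protocol",
]

#: (source trials, target trials) per dataset variant.
SPLIT_RULES = {"seed": (9, 6), "seed_iv": (16, 8)}


@dataclass
class ProtocolSplit:
    """Source/target partition for one experimental run."""

    name: str                      # "subject_dependent" or "loso"
    source: FeatureSet
    target: FeatureSet
    target_subject: int | None = None
    split_rule: str = ""


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the reference protocol
    (RMSprop at 5e-4 with 1e-4 weight decay, batch 96, 1000 epochs,
    Chebyshev order 3, reversal ramp between 0.5 and 0.9).  Tests and the
    synthetic benchmark override ``epochs`` downward."""

    learning_rate: float = 5e-4
    l2_weight: float = 1e-4
    batch_size: int = 96
    epochs: int = 1000
    cheb_order: int = 3
    gcn_layers: int = 1
    gcn_out_dim: int = 8
    disc_hidden: int = 16
    extractor: str = "chebyshev"
    grl_hi: float = 0.9
    grl_lo: float = 0.5
    individual_grl_hi: float | None = 0.18
    individual_grl_lo: float | None = 0.1
    alpha: float = 10.0
    lambda_cluster: float = 0.1
    cluster_rule: str = "threshold"
    cluster_threshold: float = 0.9
    cluster_fraction: float = 0.5
    cls_head: str = "ova_bce"
    use_domain_discriminator: bool = True
    use_individual_discriminator: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("learning_rate", "l2_weight", "batch_size", "epochs",
                     "cheb_order", "gcn_layers", "gcn_out_dim", "alpha"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.grl_hi < self.grl_lo:
            raise ConfigurationError("grl_hi must be >= grl_lo")

    def to_estimator(self) -> DomainAdversarialEEGClassifier:
        self.validate()
        return DomainAdversarialEEGClassifier(
            cheb_order=self.cheb_order, gcn_layers=self.gcn_layers,
            gcn_out_dim=self.gcn_out_dim, disc_hidden=self.disc_hidden,
            extractor=self.extractor, grl_hi=self.grl_hi, grl_lo=self.grl_lo,
            individual_grl_hi=self.individual_grl_hi,
            individual_grl_lo=self.individual_grl_lo,
            grl_alpha=self.alpha, lambda_cluster=self.lambda_cluster,
            cluster_rule=self.cluster_rule,
            cluster_threshold=self.cluster_threshold,
            cluster_fraction=self.cluster_fraction, cls_head=self.cls_head,
            use_domain_discriminator=self.use_domain_discriminator,
            use_individual_discriminator=self.use_individual_discriminator,
            learning_rate=self.learning_rate, l2_weight=self.l2_weight,
            batch_size=self.batch_size, epochs=self.epochs,
            random_state=self.seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_yaml(path) -> "TrainConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {k: v for k, v in raw.items()
                 if k in TrainConfig.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return TrainConfig(**known)


# ---------------------------------------------------------------------
# split construction
# ---------------------------------------------------------------------

def make_subject_dependent_splits(data: FeatureSet,
                                  variant: str = "seed") -> list[ProtocolSplit]:
    """One split per (subject, session): leading trials source, rest target."""
    if variant not in SPLIT_RULES:
        raise ConfigurationError(f"unknown variant {variant!r}")
    n_src, n_tgt = SPLIT_RULES[variant]
    splits = []
    for subject in data.subjects:
        smask = data.subject_id == subject
        for session in np.unique(data.session_id[smask]):
            mask = smask & (data.session_id == session)
            trials = np.unique(data.trial_id[mask])
            if len(trials) != n_src + n_tgt:
                raise ValueError(
                    f"subject {subject} session {session} has {len(trials)} trials; "
                    f"the {variant} rule needs exactly {n_src + n_tgt}")
            src_trials = set(trials[:n_src].tolist())
            src_mask = mask & np.isin(data.trial_id, list(src_trials))
            tgt_mask = mask & ~np.isin(data.trial_id, list(src_trials))
            splits.append(ProtocolSplit(
                name="subject_dependent",
                source=data.select(src_mask),
                target=data.select(tgt_mask),
                target_subject=int(subject),
                split_rule=f"first {n_src} trials source / last {n_tgt} target",
            ))
    return splits


def make_loso_splits(data: FeatureSet) -> list[ProtocolSplit]:
    """One split per subject: that subject is the unlabeled target."""
    subjects = data.subjects
    if len(subjects) < 2:
        raise ConfigurationError("LOSO needs at least two subjects")
    splits = []
    for subject in subjects:
        tmask = data.subject_id == subject
        splits.append(ProtocolSplit(
            name="loso",
            source=data.select(~tmask),
            target=data.select(tmask),
            target_subject=int(subject),
            split_rule="leave one subject out",
        ))
    return splits


# ---------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------

def train(split: ProtocolSplit, config: TrainConfig,
          track_target_accuracy: bool = False) -> DomainAdversarialEEGClassifier:
    """Fit the adversarial classifier on one protocol split.

    Target emotion labels are used only for the optional per-epoch
    accuracy trace, never for any gradient.
    """
    est = config.to_estimator()
    trace: list[float] = []
    callback = None
    if track_target_accuracy:
        def callback(predict):
            pred = predict(split.target.features)
            trace.append(float(np.mean(pred == split.target.labels)))
    est.fit(split.source.features, split.source.labels,
            X_target=split.target.features,
            subjects=split.source.subject_id,
            target_subjects=split.target.subject_id,
            epoch_callback=callback)
    if track_target_accuracy:
        est.history_["target_accuracy"] = trace
    return est


@dataclass
class EvalResult:
    accuracy: float
    per_class_accuracy: np.ndarray
    confusion: np.ndarray              # rows true, columns predicted
    confusion_normalized: np.ndarray   # row-normalized
    n_segments: int


def evaluate(model: DomainAdversarialEEGClassifier,
             target: FeatureSet) -> EvalResult:
    """Target-domain accuracy, per-class accuracy and confusion matrices."""
    if target.n_segments == 0:
        raise ValueError("target set is empty")
    pred = model.predict(target.features)
    cm = confusion_matrix(target.labels, pred, labels=model.classes_)
    row_sums = cm.sum(axis=1, keepdims=True)
    cm_norm = np.divide(cm, row_sums, out=np.zeros(cm.shape, dtype=float),
                        where=row_sums > 0)
    return EvalResult(
        accuracy=float(np.mean(pred == target.labels)),
        per_class_accuracy=np.diag(cm_norm).copy(),
        confusion=cm,
        confusion_normalized=cm_norm,
        n_segments=target.n_segments,
    )


def run_protocol(data: FeatureSet, protocol: str, config: TrainConfig,
                 variant: str = "seed", ablation_tag: str = "full",
                 out_dir=None) -> tuple[RunSummary, list[dict]]:
    """Train and evaluate every split of a protocol; aggregate mean ± std."""
    if protocol == "subject_dependent":
        splits = make_subject_dependent_splits(data, variant)
    elif protocol == "loso":
        splits = make_loso_splits(data)
    else:
        raise ConfigurationError(f"unknown protocol {protocol!r}")

    per_split: list[dict] = []
    confusions: list[np.ndarray] = []
    for i, split in enumerate(splits):
        model = train(split, config)
        res = evaluate(model, split.target)
        confusions.append(res.confusion)
        per_split.append({
            "split_index": i,
            "target_subject": split.target_subject,
            "accuracy": res.accuracy,
            "n_segments": res.n_segments,
            "adjacency": model.adjacency_,
        })
    summary = summarize(
        [{"accuracy": r["accuracy"], "confusion": c}
         for r, c in zip(per_split, confusions)],
        protocol=protocol, ablation_tag=ablation_tag)
    if out_dir is not None:
        _persist(Path(out_dir), summary, per_split, config)
    return summary, per_split


def _persist(out_dir: Path, summary: RunSummary, per_split: list[dict],
             config: TrainConfig) -> None:
    import json

    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "config.yaml", "w") as f:
        yaml.safe_dump(config.to_dict(), f)
    with open(out_dir / "metrics.json", "w") as f:
        json.dump({
            "protocol": summary.protocol,
            "mean_accuracy": summary.mean,
            "std_accuracy": summary.std,
            "per_split": [
                {k: v for k, v in r.items() if k != "adjacency"}
                for r in per_split
            ],
        }, f, indent=2)
    for r in per_split:
        if r["adjacency"] is not None:
            np.savetxt(out_dir / f"adjacency_split{r['split_index']}.csv",
                       r["adjacency"], delimiter=",")
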