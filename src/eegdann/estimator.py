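"""Scikit-learn style estimator for domain-adversarial EEG emotion decoding.

:class:`DomainAdversarialEEGClassifier` trains a shared feature extractor
(a learnable-adjacency Chebyshev graph convolution, or a two-layer MLP for
ablation), an emotion classifier head on labeled source segments, and two
adversarial heads behind gradient-reversal layers: a binary source/target
domain discriminator and a multi-class subject ("individual")
discriminator.  Unlabeled target segments enter only through the domain
discriminator and the confidence-selected cluster loss — target emotion
labels are never consumed.

The estimator follows scikit-learn conventions (``get_params`` /
``set_params`` / ``fit`` / ``predict`` / ``predict_proba``, fitted
attributes with trailing underscores) so it composes with ``clone`` and
model-selection utilities; note that ``X`` is a 3-D array
``(segments, channels, bands)`` rather than the usual 2-D design matrix
(2-D input is accepted and reshaped when ``n_channels`` is given).
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import autodiff as ad
from .autodiff import Tensor
from .adversarial import (DomainDiscriminator, GRLSchedule,
                          IndividualDiscriminator, reverse_gradient)
from .data import FeatureSet, make_domain_batches
from .exceptions import ConfigurationError, TrainingError
from .graph import ChebGraphExtractor, MLPExtractor
from .nn import Linear, RMSprop
from .objectives import (classification_loss, cluster_loss, domain_loss,
                         individual_loss, select_confident_targets,
                         total_loss)

__all__ = ["DomainAdversarialEEGClassifier"]


class DomainAdversarialEEGClassifier(ClassifierMixin, BaseEstimator):
    """Adversarially adapted emotion classifier for channel-by-band features.

    Parameters
    ----------
    cheb_order : int
        Order K of the Chebyshev filter bank (number of polynomial terms).
    gcn_layers, gcn_out_dim : int
        Depth and per-channel width of the graph extractor; the flattened
        feature dimension is ``n_channels * gcn_out_dim``.
    leaky_slope : float
        Negative slope of every Leaky ReLU in the network.
    adjacency_init_bound : float or None
        Half-width of the uniform adjacency init; ``None`` means
        ``1 / sqrt(n_channels)``.
    extractor : {'chebyshev', 'mlp'}
        Feature extractor; ``'mlp'`` is the two-linear-layer ablation.
    grl_hi, grl_lo, grl_alpha : float
        Bounds and rate of the sigmoid reversal-strength ramp.
    individual_grl_hi, individual_grl_lo : float or None
        Independent ramp bounds for the individual branch (default a weak
        reversal at roughly one fifth of the domain ramp); ``None`` shares
        the domain branch's schedule.
    use_domain_discriminator, use_individual_discriminator : bool
        Disable either adversarial branch (the networks are still built,
        for run-to-run comparability, but contribute no loss).
    lambda_cluster : float
        Weight of the target cluster loss.
    cluster_rule : {'threshold', 'top_fraction'}
        Confident-target selection rule, with ``cluster_threshold`` /
        ``cluster_fraction`` as the corresponding knobs.
    cls_head : {'ova_bce', 'softmax_ce'}
        Classification loss: per-class sigmoid one-vs-all BCE, or softmax
        cross-entropy.
    learning_rate, l2_weight, batch_size, epochs
        RMSprop step size, weight decay applied to all parameters
        (including the adjacency), mini-batch size (split evenly between
        source and target rows), and training epochs.
    n_channels, n_bands : int or None
        Only needed when ``X`` is passed flattened 2-D.
    standardize : bool
        Z-score each (channel, band) feature over the pooled source and
        target segments before training (label-free).
    random_state : int or None
        Seeds parameter initialization and batch shuffling.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in ``y``.
    adjacency_ : ndarray or None
        Learned symmetric channel adjacency (``None`` for the MLP ablation).
    history_ : dict[str, list[float]]
        Per-epoch means of each loss term, selected-target counts and,
        optionally, target accuracy.
    n_iter_ : int
        Total optimizer steps taken.
    """

    def __init__(self, *, cheb_order: int = 3, gcn_layers: int = 1,
                 gcn_out_dim: int = 8, leaky_slope: float = 0.01,
                 adjacency_init_bound: float | None = None,
                 extractor: str = "chebyshev", mlp_hidden: int = 128,
                 disc_hidden: int = 16,
                 grl_hi: float = 0.9, grl_lo: float = 0.5,
                 grl_alpha: float = 10.0,
                 individual_grl_hi: float | None = 0.18,
                 individual_grl_lo: float | None = 0.1,
                 use_domain_discriminator: bool = True,
                 use_individual_discriminator: bool = True,
                 lambda_cluster: float = 0.1,
                 cluster_rule: str = "threshold",
                 cluster_threshold: float = 0.9,
                 cluster_fraction: float = 0.5,
                 cls_head: str = "ova_bce",
                 learning_rate: float = 5e-4, l2_weight: float = 1e-4,
                 batch_size: int = 96, epochs: int = 1000,
                 n_channels: int | None = None, n_bands: int | None = None,
                 standardize: bool = True,
                 random_state: int | None = None):
        self.cheb_order = cheb_order
        self.gcn_layers = gcn_layers
        self.gcn_out_dim = gcn_out_dim
        self.leaky_slope = leaky_slope
        self.adjacency_init_bound = adjacency_init_bound
        self.extractor = extractor
        self.mlp_hidden = mlp_hidden
        self.disc_hidden = disc_hidden
        self.grl_hi = grl_hi
        self.grl_lo = grl_lo
        self.grl_alpha = grl_alpha
        self.individual_grl_hi = individual_grl_hi
        self.individual_grl_lo = individual_grl_lo
        self.use_domain_discriminator = use_domain_discriminator
        self.use_individual_discriminator = use_individual_discriminator
        self.lambda_cluster = lambda_cluster
        self.cluster_rule = cluster_rule
        self.cluster_threshold = cluster_threshold
        self.cluster_fraction = cluster_fraction
        self.cls_head = cls_head
        self.learning_rate = learning_rate
        self.l2_weight = l2_weight
        self.batch_size = batch_size
        self.epochs = epochs
        self.n_channels = n_channels
        self.n_bands = n_bands
        self.standardize = standardize
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _coerce_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            if self.n_channels is None or self.n_bands is None:
                raise ConfigurationError(
                    "2-D input needs n_channels and n_bands to reshape; "
                    "pass X as (segments, channels, bands) instead"
                )
            X = X.reshape(X.shape[0], self.n_channels, self.n_bands)
        if X.ndim != 3:
            raise ValueError(f"X must be 2-D or 3-D; got shape {X.shape}")
        return X

    def _build_modules(self, n_ch: int, n_bd: int, n_classes: int,
                       n_individuals: int, rng: np.random.Generator):
        """Construct all networks in a fixed order from one RNG stream.

        Every module is always built — including discriminators that a
        disabled branch will never use — so two configurations that differ
        only in which losses are active share bit-identical initial
        parameters under the same seed.
        """
        if self.extractor == "chebyshev":
            ext = ChebGraphExtractor(
                n_ch, n_bd, rng, order=self.cheb_order,
                n_layers=self.gcn_layers, out_dim=self.gcn_out_dim,
                negative_slope=self.leaky_slope,
                init_bound=self.adjacency_init_bound)
        elif self.extractor == "mlp":
            ext = MLPExtractor(n_ch, n_bd, rng, hidden=self.mlp_hidden,
                               out_dim=self.gcn_out_dim,
                               negative_slope=self.leaky_slope)
        else:
            raise ConfigurationError(f"unknown extractor {self.extractor!r}")
        head = Linear(ext.feature_dim, n_classes, rng)
        dom = DomainDiscriminator(ext.feature_dim, rng, hidden=self.disc_hidden,
                                  negative_slope=self.leaky_slope)
        ind = IndividualDiscriminator(ext.feature_dim, max(n_individuals, 2),
                                      rng, hidden=self.disc_hidden,
                                      negative_slope=self.leaky_slope)
        return ext, head, dom, ind

    def _class_scores(self, features: Tensor, head: Linear) -> Tensor:
        logits = head(features)
        if self.cls_head == "ova_bce":
            return ad.sigmoid(logits)
        return ad.softmax(logits, axis=-1)

    # ------------------------------------------------------------------
    def fit(self, X, y, X_target=None, subjects=None, target_subjects=None,
            epoch_callback=None):
        """Train on labeled source segments and optional unlabeled targets.

        ``subjects`` / ``target_subjects`` give per-segment subject ids for
        the individual discriminator; omitted ids default to a single
        pseudo-subject per domain side.  ``epoch_callback``, if given, is
        called after every epoch with a ``predict(X) -> labels`` closure
        over the current parameters (used by the protocol runner to track
        target accuracy without ever feeding target labels into training).
        """
        X = self._coerce_X(X)
        y = np.asarray(y)
        if y.shape != (X.shape[0],):
            raise ValueError("y must be one label per source segment")
        if X.shape[0] == 0:
            raise ConfigurationError("source set is empty")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ConfigurationError("need at least two emotion classes")
        n_ch, n_bd = X.shape[1], X.shape[2]
        self.n_features_in_ = n_ch * n_bd

        subjects = np.zeros(X.shape[0], dtype=np.int64) if subjects is None \
            else np.asarray(subjects, dtype=np.int64)
        has_target = X_target is not None and np.size(X_target) > 0
        if has_target:
            X_target = self._coerce_X(X_target)

        # Per-(channel, band) z-scoring over the pooled unlabeled inputs —
        # standard preprocessing for band-power features; uses no labels.
        if self.standardize:
            pooled = np.concatenate([X, X_target]) if has_target else X
            self.scaler_mean_ = pooled.mean(axis=0)
            self.scaler_std_ = np.maximum(pooled.std(axis=0), 1e-12)
        else:
            self.scaler_mean_ = np.zeros((n_ch, n_bd))
            self.scaler_std_ = np.ones((n_ch, n_bd))
        X = (X - self.scaler_mean_) / self.scaler_std_
        if has_target:
            X_target = (X_target - self.scaler_mean_) / self.scaler_std_
            if target_subjects is None:
                target_subjects = np.full(X_target.shape[0],
                                          int(subjects.max()) + 1, dtype=np.int64)
            else:
                target_subjects = np.asarray(target_subjects, dtype=np.int64)
            union = np.union1d(np.unique(subjects), np.unique(target_subjects))
        else:
            union = np.unique(subjects)
        n_individuals = len(union)

        individual_active = self.use_individual_discriminator and n_individuals >= 2
        if self.use_individual_discriminator and n_individuals < 2:
            warnings.warn(
                "individual discriminator disabled: only one subject present",
                stacklevel=2)

        seed = self.random_state if self.random_state is not None else 0
        rng = np.random.default_rng(seed)
        ext, head, dom, ind = self._build_modules(
            n_ch, n_bd, n_classes, n_individuals, rng)
        params = (ext.parameters + head.parameters
                  + dom.parameters + ind.parameters)
        opt = RMSprop(params, lr=self.learning_rate,
                      weight_decay=self.l2_weight)

        # assemble FeatureSets for the batcher
        src_fs = FeatureSet(features=X, labels=y_idx, subject_id=subjects,
                            session_id=np.zeros(X.shape[0], dtype=np.int64),
                            trial_id=np.zeros(X.shape[0], dtype=np.int64))
        if has_target:
            tgt_fs = FeatureSet(features=X_target,
                                labels=np.zeros(X_target.shape[0], dtype=np.int64),
                                subject_id=target_subjects,
                                session_id=np.zeros(X_target.shape[0], dtype=np.int64),
                                trial_id=np.zeros(X_target.shape[0], dtype=np.int64))
            half = self.batch_size // 2
            steps_per_epoch = int(np.ceil(X.shape[0] / half))
        else:
            steps_per_epoch = int(np.ceil(X.shape[0] / self.batch_size))
        max_iters = max(1, self.epochs * steps_per_epoch)

        schedule = GRLSchedule(hi=self.grl_hi, lo=self.grl_lo,
                               alpha=self.grl_alpha, max_iters=max_iters)
        if self.individual_grl_hi is not None or self.individual_grl_lo is not None:
            ind_hi = self.grl_hi if self.individual_grl_hi is None else self.individual_grl_hi
            ind_lo = self.grl_lo if self.individual_grl_lo is None else self.individual_grl_lo
            ind_schedule = GRLSchedule(hi=ind_hi, lo=ind_lo,
                                       alpha=self.grl_alpha, max_iters=max_iters)
        else:
            ind_schedule = schedule

        history: dict[str, list[float]] = {
            k: [] for k in ("cls", "domain", "individual", "cluster",
                            "total", "n_selected")}

        step = 0
        for epoch in range(self.epochs):
            epoch_seed = int(rng.integers(0, 2**31 - 1))
            if has_target:
                batches = make_domain_batches(src_fs, tgt_fs, self.batch_size,
                                              seed=epoch_seed, cycle_target=True)
            else:
                batches = _source_only_batches(src_fs, self.batch_size, epoch_seed)
            sums = dict.fromkeys(history, 0.0)
            n_batches = 0
            for batch in batches:
                bundle = self._train_step(batch, ext, head, dom, ind,
                                          schedule, ind_schedule,
                                          individual_active, n_classes, opt)
                if not np.isfinite(bundle.total.item()):
                    raise TrainingError(
                        f"non-finite loss at epoch {epoch}, step {step}")
                step += 1
                if schedule is not ind_schedule:
                    ind_schedule.step()
                schedule.step()
                for k, v in bundle.as_floats().items():
                    if k in sums:
                        sums[k] += v
                n_batches += 1
            for k in ("cls", "domain", "individual", "cluster", "total",
                      "n_selected"):
                history[k].append(sums[k] / max(n_batches, 1))
            if epoch_callback is not None:
                epoch_callback(
                    lambda Xq: self.classes_[self._predict_arr(
                        (self._coerce_X(np.asarray(Xq)) - self.scaler_mean_)
                        / self.scaler_std_, ext, head)])

        self._extractor = ext
        self._head = head
        self._domain_disc = dom
        self._individual_disc = ind
        self._n_channels = n_ch
        self._n_bands = n_bd
        self.individual_active_ = individual_active
        self.adjacency_ = ext.learned_adjacency()
        self.history_ = history
        self.n_iter_ = step
        self.grl_schedule_ = schedule
        return self

    def _train_step(self, batch, ext, head, dom, ind, schedule, ind_schedule,
                    individual_active, n_classes, opt):
        b_s = batch.n_source
        xcat = Tensor(batch.all_features())
        feats = ext(xcat)
        zero = Tensor(0.0)

        if b_s > 0:
            scores_src = self._class_scores(feats[:b_s], head)
            l_cls = classification_loss(scores_src,
                                        batch.source_emotion_labels,
                                        n_classes, head=self.cls_head)
        else:
            l_cls = zero

        l_dom, l_clu, n_sel = zero, zero, 0
        use_domain = (self.use_domain_discriminator and b_s > 0
                      and batch.n_target > 0)
        if use_domain:
            rev = reverse_gradient(feats, schedule.coeff)
            dprob = dom(rev)
            l_dom = domain_loss(dprob[:b_s], dprob[b_s:])
            if self.lambda_cluster != 0.0:
                scores_tgt = self._class_scores(feats[b_s:], head).data
                sel, n_sel = select_confident_targets(
                    scores_tgt, rule=self.cluster_rule,
                    threshold=self.cluster_threshold,
                    fraction=self.cluster_fraction)
                if n_sel > 0:
                    l_clu = cluster_loss(dprob[b_s + sel])

        l_ind = zero
        if individual_active:
            rev_i = reverse_gradient(feats, ind_schedule.coeff)
            _, probs = ind(rev_i)
            l_ind = individual_loss(probs, batch.individual_labels,
                                    ind.n_individuals)

        bundle = total_loss(l_cls, l_dom, l_ind, l_clu,
                            self.lambda_cluster, n_sel)
        bundle.total.backward()
        opt.step()
        opt.zero_grad()
        return bundle

    # ------------------------------------------------------------------
    def _predict_arr(self, X: np.ndarray, ext, head) -> np.ndarray:
        scores = self._class_scores(ext(Tensor(X)), head).data
        return np.argmax(scores, axis=1)

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        X = (self._coerce_X(X) - self.scaler_mean_) / self.scaler_std_
        return self._class_scores(self._extractor(Tensor(X)), self._head).data

    def predict_proba(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        if self.cls_head == "ova_bce":
            denom = scores.sum(axis=1, keepdims=True)
            return np.where(denom > 0, scores / denom,
                            np.full_like(scores, 1.0 / scores.shape[1]))
        return scores

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def extract_features(self, X) -> np.ndarray:
        """Flattened extractor output for fitted models (for embeddings)."""
        check_is_fitted(self, "classes_")
        X = (self._coerce_X(X) - self.scaler_mean_) / self.scaler_std_
        return self._extractor(Tensor(X)).data


def _source_only_batches(src_fs: FeatureSet, batch_size: int, seed: int):
    """Plain shuffled source batches (no target side) as DomainBatch objects."""
    from .data import DomainBatch

    rng = np.random.default_rng(seed)
    perm = rng.permutation(src_fs.n_segments)
    empty = np.zeros((0, src_fs.n_channels, src_fs.n_bands))
    union = np.unique(src_fs.subject_id)
    subj_idx = np.searchsorted(union, src_fs.subject_id)
    for start in range(0, len(perm), batch_size):
        idx = perm[start:start + batch_size]
        yield DomainBatch(
            source_features=src_fs.features[idx],
            target_features=empty,
            source_emotion_labels=src_fs.labels[idx],
            domain_labels=np.ones(len(idx), dtype=np.int64),
            individual_labels=subj_idx[idx],
            n_individuals=len(union),
        )
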