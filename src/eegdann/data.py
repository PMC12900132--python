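"""Dataset containers, SEED-style MAT readers, and domain-batch assembly.

The central container is :class:`FeatureSet`: per-segment channel-by-band
differential-entropy (DE) features together with emotion labels and
subject / session / trial metadata.  :func:`load_seed_features` reads the
"ExtractedFeatures" directory layout the SEED and SEED-IV releases use
(one MAT file per subject and session holding per-trial arrays, plus a
``label.mat`` with per-trial emotion codes), accepting both the classic
MAT v7 dialect and the HDF5-backed v7.3 dialect.

:func:`make_domain_batches` assembles the mixed source/target mini-batches
adversarial training consumes: source rows first, then target rows, with
domain labels 1/0 and subject indices over the union of subjects.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np
import scipy.io

from .exceptions import ConfigurationError, FormatError

__all__ = [
    "FeatureSet",
    "DomainBatch",
    "load_seed_features",
    "make_domain_batches",
    "BAND_NAMES",
    "LABEL_CODES",
    "CLASS_NAMES",
]

#: Conventional five EEG frequency bands of the DE features.
BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")

#: Native per-trial emotion codes -> contiguous class indices.
LABEL_CODES = {
    "seed": {-1: 0, 0: 1, 1: 2},
    "seed_iv": {0: 0, 1: 1, 2: 2, 3: 3},
}

CLASS_NAMES = {
    "seed": ("negative", "neutral", "positive"),
    "seed_iv": ("neutral", "sad", "fear", "happy"),
}


@dataclass
class FeatureSet:
    """Labeled per-segment EEG feature tensors with acquisition metadata.

    ``features`` has shape ``(n_segments, n_channels, n_bands)``; the
    remaining per-segment arrays all share the first dimension.
    """

    features: np.ndarray
    labels: np.ndarray
    subject_id: np.ndarray
    session_id: np.ndarray
    trial_id: np.ndarray
    channel_names: tuple[str, ...] = ()
    band_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 3:
            raise FormatError(
                f"features must be (segments, channels, bands); got shape {self.features.shape}"
            )
        n = self.features.shape[0]
        for name in ("labels", "subject_id", "session_id", "trial_id"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.shape != (n,):
                raise FormatError(f"{name} must have length {n}; got shape {arr.shape}")
            setattr(self, name, arr)
        if not self.channel_names:
            self.channel_names = tuple(f"ch_{i + 1}" for i in range(self.n_channels))
        if not self.band_names:
            names = BAND_NAMES if self.n_bands == 5 else tuple(
                f"band_{i + 1}" for i in range(self.n_bands))
            self.band_names = tuple(names)
        if len(self.channel_names) != self.n_channels:
            raise FormatError("channel_names length does not match feature tensor")
        if len(self.band_names) != self.n_bands:
            raise FormatError("band_names length does not match feature tensor")
        if n and self.labels.min() < 0:
            raise FormatError("labels must be nonnegative class indices")

    # -- shape accessors ----------------------------------------------
    @property
    def n_segments(self) -> int:
        return self.features.shape[0]

    @property
    def n_channels(self) -> int:
        return self.features.shape[1]

    @property
    def n_bands(self) -> int:
        return self.features.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.n_segments else 0

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_id)

    def flat_features(self) -> np.ndarray:
        """Features flattened to ``(n_segments, n_channels * n_bands)``."""
        return self.features.reshape(self.n_segments, -1)

    # -- subsetting ----------------------------------------------------
    def select(self, mask: np.ndarray) -> "FeatureSet":
        return FeatureSet(
            features=self.features[mask],
            labels=self.labels[mask],
            subject_id=self.subject_id[mask],
            session_id=self.session_id[mask],
            trial_id=self.trial_id[mask],
            channel_names=self.channel_names,
            band_names=self.band_names,
        )

    @staticmethod
    def concatenate(parts: Sequence["FeatureSet"]) -> "FeatureSet":
        if not parts:
            raise ConfigurationError("cannot concatenate an empty list of feature sets")
        return FeatureSet(
            features=np.concatenate([p.features for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            subject_id=np.concatenate([p.subject_id for p in parts]),
            session_id=np.concatenate([p.session_id for p in parts]),
            trial_id=np.concatenate([p.trial_id for p in parts]),
            channel_names=parts[0].channel_names,
            band_names=parts[0].band_names,
        )

    # -- HDF5 fixture container ---------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("features", data=self.features)
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("subject_id", data=self.subject_id)
            f.create_dataset("session_id", data=self.session_id)
            f.create_dataset("trial_id", data=self.trial_id)
            f.attrs["channel_names"] = list(self.channel_names)
            f.attrs["band_names"] = list(self.band_names)

    @staticmethod
    def from_hdf5(path) -> "FeatureSet":
        with h5py.File(path, "r") as f:
            return FeatureSet(
                features=f["features"][()],
                labels=f["labels"][()],
                subject_id=f["subject_id"][()],
                session_id=f["session_id"][()],
                trial_id=f["trial_id"][()],
                channel_names=tuple(str(c) for c in f.attrs["channel_names"]),
                band_names=tuple(str(b) for b in f.attrs["band_names"]),
            )


@dataclass
class DomainBatch:
    """One adversarial mini-batch: source rows first, then target rows."""

    source_features: np.ndarray
    target_features: np.ndarray
    source_emotion_labels: np.ndarray
    domain_labels: np.ndarray
    individual_labels: np.ndarray
    n_individuals: int

    @property
    def n_source(self) -> int:
        return self.source_features.shape[0]

    @property
    def n_target(self) -> int:
        return self.target_features.shape[0]

    def all_features(self) -> np.ndarray:
        return np.concatenate([self.source_features, self.target_features])


# ---------------------------------------------------------------------
# SEED-style MAT reading
# ---------------------------------------------------------------------

def _load_mat_arrays(path: Path) -> dict[str, np.ndarray]:
    """Load a MAT file's top-level arrays, accepting v7 and v7.3 dialects."""
    try:
        raw = scipy.io.loadmat(path)
        return {k: v for k, v in raw.items() if not k.startswith("__")}
    except (NotImplementedError, ValueError, OSError):
        pass
    # MAT v7.3 is HDF5; MATLAB stores arrays with reversed axis order.
    try:
        out: dict[str, np.ndarray] = {}
        with h5py.File(path, "r") as f:
            for key, node in f.items():
                if isinstance(node, h5py.Dataset):
                    arr = node[()]
                    out[key] = np.transpose(arr, axes=range(arr.ndim)[::-1])
        return out
    except OSError as exc:
        raise FormatError(f"{path} is not a readable MAT file: {exc}") from exc


def _read_trial_labels(directory: Path) -> np.ndarray:
    label_path = directory / "label.mat"
    if not label_path.exists():
        raise FormatError(f"missing label.mat in {directory}")
    arrays = _load_mat_arrays(label_path)
    for key in ("label", "session_label", "labels"):
        if key in arrays:
            return np.asarray(arrays[key]).ravel().astype(int)
    raise FormatError(f"{label_path} has no 'label' array (keys: {sorted(arrays)})")


def load_seed_features(path, dataset_variant: str = "seed",
                       feature_prefix: str = "de_LDS") -> FeatureSet:
    """Read a directory of SEED-style per-subject-per-session MAT files.

    Each data file is named ``<subject>_<session-token>.mat`` and holds one
    array per trial under keys like ``de_LDS1`` with shape
    ``(channels, segments, bands)``.  Per-trial emotion codes come from
    ``label.mat`` and are remapped to contiguous class indices according to
    ``dataset_variant`` (``seed``: codes -1/0/1; ``seed_iv``: codes 0..3).
    Session indices are assigned per subject in sorted token order.
    """
    if dataset_variant not in LABEL_CODES:
        raise ConfigurationError(
            f"unknown dataset_variant {dataset_variant!r}; expected one of {sorted(LABEL_CODES)}"
        )
    code_map = LABEL_CODES[dataset_variant]
    directory = Path(path)
    if not directory.is_dir():
        raise FormatError(f"{directory} is not a directory")

    name_re = re.compile(r"^(\d+)_(.+)\.mat$")
    data_files: dict[int, list[tuple[str, Path]]] = {}
    for p in sorted(directory.iterdir()):
        m = name_re.match(p.name)
        if m and "label" not in p.name.lower():
            data_files.setdefault(int(m.group(1)), []).append((m.group(2), p))
    if not data_files:
        raise FormatError(f"no SEED-style feature files found in {directory}")

    trial_labels = _read_trial_labels(directory)
    key_re = re.compile(rf"^{re.escape(feature_prefix)}(\d+)$")

    feats, labels, subj, sess, trial = [], [], [], [], []
    for subject in sorted(data_files):
        for session_idx, (_, fpath) in enumerate(sorted(data_files[subject]), start=1):
            arrays = _load_mat_arrays(fpath)
            trials = sorted(
                (int(m.group(1)), k) for k, m in
                ((k, key_re.match(k)) for k in arrays) if m
            )
            if not trials:
                raise FormatError(
                    f"{fpath} holds no arrays with prefix {feature_prefix!r}"
                )
            for t, key in trials:
                arr = np.asarray(arrays[key], dtype=np.float64)
                if arr.ndim != 3:
                    raise FormatError(
                        f"{fpath} key {key!r}: expected 3-D (channels, segments, bands), got shape {arr.shape}"
                    )
                if t - 1 >= len(trial_labels):
                    raise FormatError(
                        f"{fpath} key {key!r}: trial {t} has no entry in label.mat"
                    )
                code = int(trial_labels[t - 1])
                if code not in code_map:
                    raise FormatError(
                        f"{fpath} key {key!r}: label code {code} not valid for variant {dataset_variant!r}"
                    )
                x = np.transpose(arr, (1, 0, 2))  # (segments, channels, bands)
                n = x.shape[0]
                feats.append(x)
                labels.append(np.full(n, code_map[code]))
                subj.append(np.full(n, subject))
                sess.append(np.full(n, session_idx))
                trial.append(np.full(n, t))

    return FeatureSet(
        features=np.concatenate(feats),
        labels=np.concatenate(labels),
        subject_id=np.concatenate(subj),
        session_id=np.concatenate(sess),
        trial_id=np.concatenate(trial),
    )


# ---------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------

def subject_union_index(source: FeatureSet, target: FeatureSet) -> dict[int, int]:
    """Map each subject id in either set to its index in the sorted union."""
    union = np.union1d(source.subjects, target.subjects)
    return {int(s): i for i, s in enumerate(union)}


def make_domain_batches(source: FeatureSet, target: FeatureSet,
                        batch_size: int, seed: int,
                        cycle_target: bool = False) -> Iterator[DomainBatch]:
    """Yield one epoch of balanced source/target mini-batches.

    Each batch holds ``batch_size // 2`` source rows and the same number of
    target rows, drawn without replacement from independently shuffled
    permutations; final partial batches are allowed.  With
    ``cycle_target=True`` the shorter side is reshuffled and reused so that
    every batch sees both domains (the behaviour adversarial training wants
    when source and target differ in size); the default keeps strict
    once-per-epoch semantics on both sides.
    """
    if source.n_segments == 0 or target.n_segments == 0:
        raise ConfigurationError("source and target must both be non-empty")
    if batch_size < 2 or batch_size % 2 != 0:
        raise ConfigurationError("batch_size must be a positive even integer")

    half = batch_size // 2
    rng = np.random.default_rng(seed)
    perm_s = rng.permutation(source.n_segments)
    perm_t = rng.permutation(target.n_segments)
    subj_index = subject_union_index(source, target)
    n_individuals = len(subj_index)
    src_subj = np.vectorize(subj_index.get)(source.subject_id)
    tgt_subj = np.vectorize(subj_index.get)(target.subject_id)

    n_batches = max(int(np.ceil(source.n_segments / half)),
                    int(np.ceil(target.n_segments / half)))
    t_cursor = 0
    for b in range(n_batches):
        s_idx = perm_s[b * half:(b + 1) * half]
        if cycle_target:
            t_idx = []
            need = half
            while need > 0:
                if t_cursor >= len(perm_t):
                    perm_t = rng.permutation(target.n_segments)
                    t_cursor = 0
                chunk = perm_t[t_cursor:t_cursor + need]
                t_idx.append(chunk)
                t_cursor += len(chunk)
                need -= len(chunk)
            t_idx = np.concatenate(t_idx)
        else:
            t_idx = perm_t[b * half:(b + 1) * half]
        if len(s_idx) == 0 and len(t_idx) == 0:
            break
        yield DomainBatch(
            source_features=source.features[s_idx],
            target_features=target.features[t_idx],
            source_emotion_labels=source.labels[s_idx],
            domain_labels=np.concatenate([
                np.ones(len(s_idx), dtype=np.int64),
                np.zeros(len(t_idx), dtype=np.int64),
            ]),
            individual_labels=np.concatenate([src_subj[s_idx], tgt_subj[t_idx]]),
            n_individuals=n_individuals,
        )
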