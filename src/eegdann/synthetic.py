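"""Synthetic multi-subject EEG feature generator.

Emulates the statistical structure the adversarial decoder assumes in
real band-power data, without simulating biophysics:

* **class structure** — each emotion class has a latent mean over
  (channels x bands), partly shared within channel *communities* so that
  channels in the same community carry similar band profiles;
* **graph-structured channel correlations** — segment noise mixes a
  community-level component with an independent per-channel component,
  so cross-channel correlation is higher within communities than between
  them (what a graph extractor can exploit);
* **subject-specific distribution shift** — every subject applies an
  affine perturbation (a channel-mixing gain matrix near identity plus a
  per-channel-band offset) to the latent signal, creating a genuine
  domain-adaptation problem that is nevertheless linearly correctable.

Trials cycle through the classes in order, so prefix/suffix trial splits
are class-stratified, and each trial carries a single class — mirroring
the film-clip elicitation layout of the public 62-channel datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import scipy.io
import h5py

from .data import FeatureSet, LABEL_CODES
from .exceptions import ConfigurationError

__all__ = ["SynthSpec", "SynthTruth", "generate", "write_fixture_mat"]


@dataclass
class SynthSpec:
    """Generation parameters; the defaults are the package's benchmark.

    ``class_separation`` scales class-mean differences, ``subject_shift``
    the per-subject affine perturbation, ``graph_strength`` (in [0, 1])
    the weight of the shared community structure in both means and noise,
    and ``noise_sd`` the total segment noise standard deviation.
    """

    n_subjects: int = 6
    n_sessions: int = 1
    n_trials_per_session: int = 15
    n_segments_per_trial: int = 40
    n_channels: int = 16
    n_bands: int = 5
    n_classes: int = 3
    class_separation: float = 0.8
    subject_shift: float = 1.2
    graph_strength: float = 0.7
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_subjects", "n_sessions", "n_trials_per_session",
                     "n_segments_per_trial", "n_channels", "n_bands",
                     "n_classes"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("class_separation", "subject_shift", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.graph_strength <= 1.0:
            raise ConfigurationError("graph_strength must lie in [0, 1]")


@dataclass
class SynthTruth:
    """Ground truth behind a generated set (for tests and inspection)."""

    communities: np.ndarray            # community index per channel
    class_means: np.ndarray            # (n_classes, n_channels, n_bands)
    subject_gains: np.ndarray          # (n_subjects, n_channels, n_channels)
    subject_offsets: np.ndarray        # (n_subjects, n_channels, n_bands)


def generate(spec: SynthSpec) -> tuple[FeatureSet, SynthTruth]:
    """Draw a deterministic multi-subject feature set from ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    C, B, K = spec.n_channels, spec.n_bands, spec.n_classes
    n_comm = min(4, C)
    communities = (np.arange(C) * n_comm) // C

    g = spec.graph_strength
    chan_profiles = rng.normal(size=(K, C, B))
    comm_profiles = rng.normal(size=(K, n_comm, B))
    class_means = spec.class_separation * (
        (1.0 - g) * chan_profiles + g * comm_profiles[:, communities, :])

    # Subject shift is decision-relevant: each subject's offset is a random
    # combination of the centered class-mean directions (their emotional
    # response pattern is displaced along the class axes), plus a mild
    # channel-mixing gain.  The offset is small in norm relative to the
    # segment noise — so subjects overlap heavily in feature space — yet it
    # moves samples across class boundaries, which is what breaks plain
    # source-only transfer and what marginal alignment can repair.
    centered_means = class_means - class_means.mean(axis=0, keepdims=True)
    gains = np.empty((spec.n_subjects, C, C))
    offsets = np.empty((spec.n_subjects, C, B))
    eye = np.eye(C)
    for s in range(spec.n_subjects):
        gains[s] = eye + 0.2 * spec.subject_shift * rng.normal(size=(C, C)) / np.sqrt(C)
        w = rng.normal(size=K)
        offsets[s] = spec.subject_shift * np.einsum(
            "k,kcb->cb", w, centered_means) / np.sqrt(K)

    feats, labels, subj, sess, trial = [], [], [], [], []
    n_seg = spec.n_segments_per_trial
    for s in range(spec.n_subjects):
        for session in range(1, spec.n_sessions + 1):
            for t in range(1, spec.n_trials_per_session + 1):
                cls = (t - 1) % K
                comm_noise = rng.normal(size=(n_seg, n_comm, B))
                chan_noise = rng.normal(size=(n_seg, C, B))
                noise = spec.noise_sd * (np.sqrt(g) * comm_noise[:, communities, :]
                                         + np.sqrt(1.0 - g) * chan_noise)
                latent = class_means[cls] + noise
                x = np.einsum("ij,njb->nib", gains[s], latent) + offsets[s]
                feats.append(x)
                labels.append(np.full(n_seg, cls))
                subj.append(np.full(n_seg, s + 1))
                sess.append(np.full(n_seg, session))
                trial.append(np.full(n_seg, t))

    fs = FeatureSet(
        features=np.concatenate(feats),
        labels=np.concatenate(labels),
        subject_id=np.concatenate(subj),
        session_id=np.concatenate(sess),
        trial_id=np.concatenate(trial),
    )
    truth = SynthTruth(communities=communities, class_means=class_means,
                       subject_gains=gains, subject_offsets=offsets)
    return fs, truth


# ---------------------------------------------------------------------
# fixture writing (round-trips through the SEED-style reader)
# ---------------------------------------------------------------------

def write_fixture_mat(fs: FeatureSet, path, variant: str = "seed",
                      dialect: str = "v7",
                      feature_prefix: str = "de_LDS") -> list[Path]:
    """Emit ``fs`` in the per-subject-per-session MAT layout.

    One file ``<subject>_<session>.mat`` per (subject, session) with keys
    ``de_LDS<trial>`` shaped (channels, segments, bands), plus a
    ``label.mat`` holding the native per-trial emotion codes of the chosen
    ``variant``.  ``dialect='v7'`` writes classic MAT files via scipy;
    ``dialect='v73'`` writes HDF5-backed files with MATLAB's reversed axis
    order.  Trial labels must be consistent across subjects and sessions.
    """
    if variant not in LABEL_CODES:
        raise ConfigurationError(f"unknown variant {variant!r}")
    if dialect not in ("v7", "v73"):
        raise ConfigurationError(f"unknown MAT dialect {dialect!r}")
    inverse_codes = {v: k for k, v in LABEL_CODES[variant].items()}
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)

    trial_codes: dict[int, int] = {}
    written: list[Path] = []
    for subject in np.unique(fs.subject_id):
        for session in np.unique(fs.session_id[fs.subject_id == subject]):
            mask = (fs.subject_id == subject) & (fs.session_id == session)
            arrays = {}
            for t in np.unique(fs.trial_id[mask]):
                tmask = mask & (fs.trial_id == t)
                x = fs.features[tmask]                 # (segments, C, B)
                cls_vals = np.unique(fs.labels[tmask])
                if len(cls_vals) != 1:
                    raise ConfigurationError(
                        f"trial {t} of subject {subject} mixes classes {cls_vals}")
                code = inverse_codes.get(int(cls_vals[0]))
                if code is None:
                    raise ConfigurationError(
                        f"class {cls_vals[0]} has no native code in variant {variant!r}")
                prev = trial_codes.setdefault(int(t), code)
                if prev != code:
                    raise ConfigurationError(
                        f"trial {t} has inconsistent labels across subjects")
                arrays[f"{feature_prefix}{int(t)}"] = np.transpose(x, (1, 0, 2))
            fpath = directory / f"{int(subject)}_{int(session):02d}.mat"
            if dialect == "v7":
                scipy.io.savemat(fpath, arrays)
            else:
                with h5py.File(fpath, "w") as f:
                    for key, arr in arrays.items():
                        # MATLAB v7.3 stores arrays with reversed axes
                        f.create_dataset(key, data=np.transpose(
                            arr, axes=range(arr.ndim)[::-1]))
            written.append(fpath)

    label_vec = np.array([trial_codes[t] for t in sorted(trial_codes)])
    scipy.io.savemat(directory / "label.mat", {"label": label_vec})
    written.append(directory / "label.mat")
    return written


def spec_to_dict(spec: SynthSpec) -> dict:
    return asdict(spec)
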