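"""Aggregation of run outputs: mean ± std tables, confusion matrices,
ablation tables, and 2-D feature embeddings.

Standard deviations across splits use the sample convention (``ddof=1``;
0 for a single split).  Confusion matrices are pooled over splits before
row-normalization, so one matrix summarizes an experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = ["RunSummary", "summarize", "ablation_table", "embed_features_2d",
           "plot_confusion", "plot_embedding"]


@dataclass
class RunSummary:
    """Aggregate of one protocol run over all its splits."""

    protocol: str
    accuracies: list[float]
    mean: float
    std: float
    confusion: np.ndarray
    confusion_normalized: np.ndarray
    ablation_tag: str = "full"


def summarize(runs: Sequence[Mapping], protocol: str = "",
              ablation_tag: str = "full") -> RunSummary:
    """Aggregate per-split metrics (dicts with ``accuracy`` and optional
    ``confusion``) into mean, sample std, and a pooled confusion matrix."""
    if not runs:
        raise ValueError("cannot summarize an empty run list")
    accs = [float(r["accuracy"]) for r in runs]
    confusions = [np.asarray(r["confusion"]) for r in runs if "confusion" in r]
    if confusions:
        pooled = np.sum(confusions, axis=0)
    else:
        pooled = np.zeros((0, 0), dtype=int)
    row_sums = pooled.sum(axis=1, keepdims=True) if pooled.size else pooled
    pooled_norm = (np.divide(pooled, row_sums,
                             out=np.zeros(pooled.shape, dtype=float),
                             where=row_sums > 0)
                   if pooled.size else pooled.astype(float))
    return RunSummary(
        protocol=protocol,
        accuracies=accs,
        mean=float(np.mean(accs)),
        std=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        confusion=pooled,
        confusion_normalized=pooled_norm,
        ablation_tag=ablation_tag,
    )


def ablation_table(summaries: Mapping[str, RunSummary | Mapping[str, RunSummary]],
                   percent: bool = True) -> pd.DataFrame:
    """Tabulate ablation variants as ``mean ± std`` cells.

    ``summaries`` maps a variant name (must include ``"full"``) either to a
    single :class:`RunSummary` or to a dict keyed by dataset/spec name.
    """
    if "full" not in summaries:
        raise ConfigurationError("ablation table requires the full model row")

    def cell(s: RunSummary) -> str:
        scale = 100.0 if percent else 1.0
        return f"{s.mean * scale:.2f}±{s.std * scale:.2f}"

    rows = {}
    for variant, entry in summaries.items():
        if isinstance(entry, RunSummary):
            rows[variant] = {"accuracy": cell(entry)}
        else:
            rows[variant] = {ds: cell(s) for ds, s in entry.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def embed_features_2d(features: np.ndarray, seed: int = 0,
                      perplexity: float | None = None) -> np.ndarray:
    """t-SNE embedding of feature rows into 2-D (fixed seed, deterministic)."""
    from sklearn.manifold import TSNE

    X = np.asarray(features, dtype=float)
    X = X.reshape(X.shape[0], -1)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 rows to embed")
    if perplexity is None:
        perplexity = min(30.0, (X.shape[0] - 1) / 3.0)
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                init="pca")
    return tsne.fit_transform(X)


def plot_confusion(confusion_normalized: np.ndarray, class_names, path) -> None:
    """Save a row-normalized confusion matrix as a PNG heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(confusion_normalized, cmap="Blues", vmin=0, vmax=1)
    ax.set_xticks(range(len(class_names)), class_names, rotation=45)
    ax.set_yticks(range(len(class_names)), class_names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(confusion_normalized.shape[0]):
        for j in range(confusion_normalized.shape[1]):
            ax.text(j, i, f"{confusion_normalized[i, j]:.2f}",
                    ha="center", va="center", fontsize=8)
    fig.colorbar(im, fraction=0.046)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_embedding(coords: np.ndarray, labels: np.ndarray, path) -> None:
    """Scatter a 2-D embedding colored by class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for cls in np.unique(labels):
        m = labels == cls
        ax.scatter(coords[m, 0], coords[m, 1], s=8, label=str(cls))
    ax.legend(title="class", fontsize=8)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
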