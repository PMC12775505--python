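"""Average Neighborhood Entropy (ANE) and t-SNE feature-space views.

ANE quantifies label clustering in a feature space: for each sample the
Shannon entropy (base 2) of the label proportions among its k nearest
neighbors is computed, and the per-sample entropies are averaged. With
subject labels, a low ANE signals subject clusters — the footprint of
shortcut learning — while values near the log2(min(k, L)) ceiling mean the
subjects' samples are thoroughly intermixed.

Conventions: the sample itself is excluded from its neighborhood
(including it would inject its own label and deflate the entropy);
distances are Euclidean by default; ties at the k-th distance break by
sample index; the neighbor search is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.manifold import TSNE

from .config import derive_seed


@dataclass
class ANEResult:
    k: int
    distance_name: str
    per_sample_entropy: np.ndarray  # H_k(x_i) in bits, one per sample
    ane: float                      # mean of per_sample_entropy, bits
    n_samples: int
    label_kind: str = "subject"


def _label_codes(labels: Sequence) -> np.ndarray:
    _, codes = np.unique(np.asarray(labels, dtype=object).astype(str),
                         return_inverse=True)
    return codes


def _knn_indices(features: np.ndarray, k: int, distance: str,
                 block: int = 512) -> np.ndarray:
    """Exact k-nearest-neighbor indices, self excluded, index tie-break."""
    n = features.shape[0]
    out = np.empty((n, k), dtype=int)
    for i0 in range(0, n, block):
        q = features[i0:i0 + block]
        d = cdist(q, features, metric=distance)
        d[np.arange(q.shape[0]), np.arange(i0, i0 + q.shape[0])] = np.inf
        # lexsort: primary key distance, secondary key column index (stable
        # for exact distance ties).
        idx = np.argsort(d, axis=1, kind="stable")[:, :k]
        out[i0:i0 + q.shape[0]] = idx
    return out


def _entropy_bits(counts: np.ndarray) -> np.ndarray:
    p = counts / counts.sum(axis=-1, keepdims=True)
    lg = np.log2(np.where(p > 0, p, 1.0))
    return -(p * lg).sum(axis=-1)


def neighborhood_entropy(index: int, features: np.ndarray,
                         labels: Sequence, k: int,
                         distance: str = "euclidean") -> float:
    """H_k(x_index): entropy (bits) of labels among the k nearest neighbors."""
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the sample count {n}")
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    codes = _label_codes(labels)
    d = cdist(features[index:index + 1], features, metric=distance)[0]
    d[index] = np.inf
    nn = np.argsort(d, kind="stable")[:k]
    counts = np.bincount(codes[nn], minlength=codes.max() + 1)
    return float(_entropy_bits(counts.astype(float)))


def ane(features: np.ndarray, labels: Sequence, k: int = 10,
        distance: str = "euclidean", label_kind: str = "subject"
        ) -> ANEResult:
    """Average Neighborhood Entropy over all samples.

    Deterministic given its inputs; bounded by log2(min(k, L)) for L
    distinct labels, reaching the bound only when every neighborhood is
    uniformly mixed.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the sample count {n}")
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    codes = _label_codes(labels)
    nn = _knn_indices(features, k, distance)
    neigh_codes = codes[nn]                                # (n, k)
    n_labels = codes.max() + 1
    counts = np.zeros((n, n_labels))
    for l in range(n_labels):
        counts[:, l] = (neigh_codes == l).sum(axis=1)
    per_sample = _entropy_bits(counts)
    return ANEResult(k=k, distance_name=distance,
                     per_sample_entropy=per_sample,
                     ane=float(per_sample.mean()),
                     n_samples=n, label_kind=label_kind)


def tsne_export(features: np.ndarray, movement_labels: Sequence,
                subject_labels: Sequence, seed: int = 0,
                out_prefix: Optional[str] = None,
                perplexity: float = 30.0) -> np.ndarray:
    """One 2-D t-SNE embedding, rendered by movement and by subject labels.

    Returns the (n, 2) coordinates; when ``out_prefix`` is given, writes
    ``<prefix>_movement.png``, ``<prefix>_subject.png`` and
    ``<prefix>_coords.csv``.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < 10:
        raise ValueError("t-SNE export needs at least 10 samples")
    perplexity = min(perplexity, (n - 1) / 3.0)
    coords = TSNE(n_components=2, perplexity=perplexity,
                  random_state=derive_seed(seed, "tsne") % (2**32),
                  init="pca").fit_transform(features)
    if out_prefix is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for kind, labels in (("movement", movement_labels),
                             ("subject", subject_labels)):
            fig, ax = plt.subplots(figsize=(5, 4))
            codes = _label_codes(labels)
            sc = ax.scatter(coords[:, 0], coords[:, 1], c=codes, s=6,
                            cmap="tab20")
            ax.set_title(f"t-SNE colored by {kind}")
            ax.set_xticks([])
            ax.set_yticks([])
            fig.colorbar(sc, ax=ax, label=kind)
            fig.tight_layout()
            fig.savefig(f"{out_prefix}_{kind}.png", dpi=120)
            plt.close(fig)
        header = "x,y,movement,subject"
        rows = np.column_stack([
            coords,
            np.asarray(movement_labels, dtype=object),
            np.asarray(subject_labels, dtype=object)])
        with open(f"{out_prefix}_coords.csv", "w") as fh:
            fh.write(header + "\n")
            for r in rows:
                fh.write(f"{r[0]},{r[1]},{r[2]},{r[3]}\n")
    return coords
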