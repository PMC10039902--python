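"""Unsupervised methylation class discovery.

Top-variable probe selection, agglomerative clustering over samples
(Euclidean distance; average or Ward linkage), tree cutting into k
classes, 2-D t-SNE embedding, and a bootstrap co-clustering stability
score.  "Most variable" is implemented as largest per-probe standard
deviation of beta across samples, the common convention for methylation
classifiers; ties are broken by probe id so selections are deterministic
and nested in k.

Module functions take probes x samples beta frames (the on-disk
convention); the estimator classes follow sklearn's samples x features
orientation and compose with sklearn pipelines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.manifold import TSNE

_LINKAGES = ("average", "ward")


def select_variable_probes(beta: pd.DataFrame, k: int) -> list[str]:
    """The k probes with largest standard deviation of beta across samples.

    Ties are broken by lexicographic probe id.  The returned list is
    ordered by decreasing SD, and selections are nested:
    ``set(select(k)) <= set(select(k + 1))``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(beta):
        raise ValueError(f"k={k} exceeds the number of probes ({len(beta)})")
    if beta.isna().any().any():
        raise ValueError("beta matrix contains missing values; drop incomplete probes first")
    sd = beta.std(axis=1, ddof=1)
    order = pd.DataFrame({"sd": -sd.to_numpy(), "probe_id": sd.index}).sort_values(
        ["sd", "probe_id"], kind="mergesort"
    )
    return order["probe_id"].head(k).tolist()


def hierarchical_cluster(beta_subset: pd.DataFrame, *, metric: str = "euclidean",
                         linkage: str = "average") -> np.ndarray:
    """Agglomerative tree over samples (columns) of a beta sub-matrix.

    Returns a scipy linkage matrix.  Deterministic given input order;
    equidistant merge candidates resolve to the lowest-index pair.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if metric != "euclidean":
        raise ValueError("only euclidean distance is supported")
    X = beta_subset.T.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("at least two samples are required")
    if np.isnan(X).any():
        raise ValueError("beta matrix contains missing values")
    return hierarchy.linkage(X, method=linkage, metric=metric)


def assign_classes(tree: np.ndarray, k: int) -> np.ndarray:
    """Cut a linkage tree into exactly k groups.

    Labels are integers 1..k ordered by cluster size descending, ties by
    smallest member index.
    """
    n = tree.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    raw = hierarchy.cut_tree(tree, n_clusters=k).ravel()
    order = sorted(
        np.unique(raw),
        key=lambda c: (-int((raw == c).sum()), int(np.flatnonzero(raw == c)[0])),
    )
    relabel = {c: i + 1 for i, c in enumerate(order)}
    return np.array([relabel[c] for c in raw])


def embed_tsne(beta_subset: pd.DataFrame, seed: int, perplexity: float | None = None,
               max_iter: int = 1000) -> pd.DataFrame:
    """2-D t-SNE embedding of samples (Euclidean metric, fixed seed).

    ``perplexity=None`` uses 30 capped to the largest admissible value
    for the sample count; an explicit perplexity must satisfy
    ``perplexity < (n_samples - 1) / 3``.
    """
    X = beta_subset.T.to_numpy(dtype=float)
    n = X.shape[0]
    limit = (n - 1) / 3
    if perplexity is None:
        perplexity = min(30.0, max(1.0, limit - 1e-9) if limit > 1 else limit * 0.9)
    if perplexity >= limit:
        raise ValueError(f"perplexity must be < (n_samples - 1)/3 = {limit:.2f}")
    coords = TSNE(
        n_components=2, perplexity=perplexity, metric="euclidean",
        init="random", random_state=seed, max_iter=max_iter,
    ).fit_transform(X)
    return pd.DataFrame(coords, index=beta_subset.columns, columns=["x", "y"])


def cluster_stability(beta: pd.DataFrame, k_probes: int, n_clusters: int,
                      n_boot: int, seed: int, *, linkage: str = "average") -> pd.Series:
    """Bootstrap co-clustering consistency per sample, in [0, 1].

    Probes are resampled with replacement ``n_boot`` times from the
    top-``k_probes`` variable set; a sample is consistent in a replicate
    when it co-clusters with the majority of its original cluster mates.
    Degenerate replicates where the cut returns one effective cluster
    still count (every sample trivially consistent) and are tallied in
    the returned series' ``attrs['degenerate_replicates']``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    selected = select_variable_probes(beta, k_probes)
    base = beta.loc[selected]
    labels0 = assign_classes(hierarchical_cluster(base, linkage=linkage), n_clusters)
    n_samples = base.shape[1]
    consistent = np.zeros(n_samples)
    degenerate = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(selected), size=len(selected))
        boot = base.iloc[idx]
        boot.index = [f"b{i}" for i in range(len(selected))]
        labels_b = assign_classes(hierarchical_cluster(boot, linkage=linkage), n_clusters)
        if len(np.unique(labels_b)) < 2:
            degenerate += 1
        for i in range(n_samples):
            mates = np.flatnonzero((labels0 == labels0[i]) & (np.arange(n_samples) != i))
            if len(mates) == 0:
                consistent[i] += 1.0
            else:
                consistent[i] += float((labels_b[mates] == labels_b[i]).mean() > 0.5)
    out = pd.Series(consistent / n_boot, index=beta.columns, name="stability")
    out.attrs["degenerate_replicates"] = degenerate
    return out


def tree_to_newick(tree: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage tree to Newick text with merge heights."""
    n = tree.shape[0] + 1
    node = {i: (labels[i], 0.0) for i in range(n)}
    for i, (a, b, height, _) in enumerate(tree):
        left, hl = node.pop(int(a))
        right, hr = node.pop(int(b))
        node[n + i] = (f"({left}:{height - hl:.6g},{right}:{height - hr:.6g})", height)
    (text, _), = node.values()
    return text + ";"


class VariableProbeSelector(BaseEstimator, TransformerMixin):
    """Select the k most variable probes (samples x probes orientation)."""

    def __init__(self, k: int = 8000):
        self.k = k

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        self.selected_probe_ids_ = select_variable_probes(X.T, self.k)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        if not hasattr(self, "selected_probe_ids_"):
            raise ValueError("VariableProbeSelector is not fitted")
        if isinstance(X, pd.DataFrame):
            return X[self.selected_probe_ids_]
        return np.asarray(X)[:, self.selected_probe_ids_]


class HierarchicalClassDiscovery(BaseEstimator, ClusterMixin):
    """Agglomerative class discovery with a fixed cluster count.

    Parameters follow the clustering configuration used for methylation
    class discovery: Euclidean distance, average (default) or Ward
    linkage, and the number of classes k supplied by the analyst.

    Fitted attributes: ``linkage_`` (scipy linkage matrix) and
    ``labels_`` (1..k, ordered by cluster size).
    """

    def __init__(self, n_clusters: int = 3, linkage: str = "average"):
        self.n_clusters = n_clusters
        self.linkage = linkage

    def fit(self, X, y=None):
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        self.linkage_ = hierarchical_cluster(frame.T, linkage=self.linkage)
        self.labels_ = assign_classes(self.linkage_, self.n_clusters)
        self.n_features_in_ = frame.shape[1]
        return self


class TSNEEmbedding(BaseEstimator, TransformerMixin):
    """2-D t-SNE embedding with pinned defaults (samples x probes input)."""

    def __init__(self, perplexity: float | None = None, random_state: int = 0,
                 max_iter: int = 1000):
        self.perplexity = perplexity
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y=None):
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        self.embedding_ = embed_tsne(
            frame.T, seed=self.random_state, perplexity=self.perplexity, max_iter=self.max_iter
        )
        self.n_features_in_ = frame.shape[1]
        return self

    def transform(self, X=None):
        if not hasattr(self, "embedding_"):
            raise ValueError("TSNEEmbedding is not fitted")
        return self.embedding_.to_numpy()

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_.to_numpy()
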