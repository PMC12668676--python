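"""Cell clustering, UMAP embedding, feature-module detection, and module
activation scores.

Cells are clustered with Leiden on a k-nearest-neighbor graph (Euclidean,
n_neighbors = 20 by default) and embedded with UMAP for reporting.  Features
are partitioned into modules by average-linkage hierarchical clustering on a
covariance distance matrix, the module count picked by the largest second
difference ("derivative loss") of the within-cluster loss curve, and each
module is summarized per cell by the first principal component of its feature
submatrix (the activation score), oriented to correlate positively with the
module's mean feature value.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.neighbors import NearestNeighbors

from .config import ConfigurationError, logger


@dataclass
class ClusterLabels:
    labels: pd.Series                     # cell id -> cluster label (contiguous ints)
    n_neighbors: int
    resolution: float
    seed: int


def _knn_igraph(X: np.ndarray, n_neighbors: int) -> ig.Graph:
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1, metric="euclidean").fit(X)
    _, idx = nn.kneighbors(X)
    edges = set()
    for i in range(len(X)):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = ig.Graph(n=len(X), edges=sorted(edges), directed=False)
    return g


def cluster_cells(
    matrix: pd.DataFrame,
    n_neighbors: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterLabels:
    """Leiden community detection on the Euclidean KNN graph of cells."""
    n = len(matrix)
    if n_neighbors >= n:
        raise ConfigurationError(f"n_neighbors={n_neighbors} must be < n cells ({n})")
    g = _knn_igraph(matrix.to_numpy(dtype=float), n_neighbors)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2,
    )
    raw = np.asarray(part.membership)
    # rename labels to contiguous small integers by decreasing cluster size
    order = pd.Series(raw).value_counts().index
    remap = {old: new for new, old in enumerate(order)}
    labels = pd.Series([remap[x] for x in raw], index=matrix.index, name="cluster")
    logger.info("Leiden: %d cells -> %d clusters (resolution %.3g)", n, labels.nunique(), resolution)
    return ClusterLabels(labels=labels, n_neighbors=n_neighbors, resolution=resolution, seed=seed)


def embed_umap(matrix: pd.DataFrame, n_neighbors: int = 20, seed: int = 0) -> pd.DataFrame:
    """2-D UMAP embedding for reporting; deterministic given the seed."""
    if len(matrix) == 0:
        raise ConfigurationError("cannot embed an empty matrix")
    import umap  # deferred: heavy import

    nn = min(n_neighbors, len(matrix) - 1)
    if nn < 2:
        nn = 2
    init = "random" if len(matrix) <= 10 else "spectral"  # spectral needs n >> 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = umap.UMAP(n_neighbors=nn, n_components=2, random_state=seed,
                        init=init).fit_transform(matrix.to_numpy(dtype=float))
    emb = np.nan_to_num(np.asarray(emb, dtype=float))
    return pd.DataFrame(emb, index=matrix.index, columns=["UMAP1", "UMAP2"])


# ---------------------------------------------------------------------------
# Feature modules
# ---------------------------------------------------------------------------

@dataclass
class FeatureModuleSet:
    """Partition of features into modules with oriented unit PC1 loadings."""

    modules: dict[int, list[str]]
    loadings: dict[int, pd.Series]
    names: dict[int, str] = field(default_factory=dict)
    k_selected: int = 0
    no_elbow: bool = False

    @property
    def feature_to_module(self) -> dict[str, int]:
        return {f: mid for mid, feats in self.modules.items() for f in feats}

    def to_dict(self) -> dict:
        return {
            "k_selected": self.k_selected,
            "no_elbow": self.no_elbow,
            "modules": {
                str(mid): {
                    "name": self.names.get(mid, f"module{mid}"),
                    "features": feats,
                    "pc1_loading": [float(x) for x in self.loadings[mid].to_numpy()],
                }
                for mid, feats in self.modules.items()
            },
        }


def covariance_distance(X: np.ndarray, metric: str = "covariance") -> np.ndarray:
    """Feature-feature distance: 1 - cov/max|cov| (or 1 - Pearson r)."""
    if metric == "correlation":
        c = np.corrcoef(X, rowvar=False)
        return 1.0 - c
    cov = np.cov(X, rowvar=False)
    denom = np.abs(cov).max()
    if denom == 0:
        denom = 1.0
    return 1.0 - cov / denom


def _within_loss(d2: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squared pairwise distances."""
    loss = 0.0
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            loss += sub[np.triu_indices(len(idx), k=1)].sum()
    return loss


def _pc1(sub: np.ndarray) -> np.ndarray:
    """Leading eigenvector of the covariance of a centered submatrix."""
    c = np.cov(sub, rowvar=False)
    c = np.atleast_2d(c)
    w, v = np.linalg.eigh(c)
    lead = v[:, -1]
    return lead / np.linalg.norm(lead)


def detect_feature_modules(
    matrix: pd.DataFrame,
    k_range: tuple[int, int] = (2, 40),
    metric: str = "covariance",
    k_override: int | None = None,
) -> FeatureModuleSet:
    """Partition features into modules via average-linkage clustering on a
    covariance distance matrix; pick k by the derivative-loss (largest second
    difference) rule; attach oriented PC1 loadings per module."""
    feats = list(matrix.columns)
    p = len(feats)
    if p < 3:
        raise ConfigurationError("module detection needs >= 3 features")
    X = matrix.to_numpy(dtype=float)
    D = covariance_distance(X, metric=metric)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="average")
    d2 = D ** 2

    kmin, kmax = k_range
    lo, hi = max(2, kmin), min(kmax, p - 1)
    if (lo, hi) != (kmin, kmax):
        warnings.warn(f"k_range {k_range} clipped to ({lo}, {hi}) for {p} features")
    no_elbow = False
    if k_override is not None:
        k_star = int(k_override)
    else:
        ks = np.arange(max(lo - 1, 1), hi + 2)
        losses = []
        for k in ks:
            labels = fcluster(Z, t=k, criterion="maxclust")
            losses.append(_within_loss(d2, labels))
        losses = np.asarray(losses)
        # derivative of the loss curve: gain(k) = loss(k-1) - loss(k); the
        # elbow is the k whose gain collapses right after it (max gain ratio)
        gains = losses[:-1] - losses[1:]          # gain at ks[1:]
        eps = 1e-12 * max(losses.max(), 1.0)
        cand = [(int(ks[i + 1]), gains[i] / (max(gains[i + 1:].max(), 0.0) + eps))
                for i in range(len(gains) - 1) if lo <= ks[i + 1] <= hi]
        if not cand:
            k_star = lo
        else:
            ratios = np.array([r for _, r in cand])
            best = int(np.argmax(ratios))
            if ratios[best] < 3.0:
                warnings.warn("no clear elbow in the loss curve; falling back to k_range minimum")
                k_star, no_elbow = lo, True
            else:
                k_star = int(cand[best][0])
    labels = fcluster(Z, t=k_star, criterion="maxclust")

    modules: dict[int, list[str]] = {}
    loadings: dict[int, pd.Series] = {}
    names: dict[int, str] = {}
    for mid, lab in enumerate(sorted(np.unique(labels), key=lambda l: int(np.where(labels == l)[0][0]))):
        idx = np.where(labels == lab)[0]
        members = [feats[i] for i in idx]
        sub = X[:, idx] - X[:, idx].mean(axis=0)
        if len(idx) == 1:
            lead = np.array([1.0])
        else:
            lead = _pc1(sub)
        score = sub @ lead
        rowmean = sub.mean(axis=1)
        if len(idx) > 1 and np.corrcoef(score, rowmean)[0, 1] < 0:
            lead = -lead
        modules[mid] = members
        loadings[mid] = pd.Series(lead, index=members)
        base = _auto_name(members)
        names[mid] = base if base not in names.values() else f"{base}.{mid}"
    logger.info("feature modules: %d features -> %d modules", p, k_star)
    return FeatureModuleSet(modules=modules, loadings=loadings, names=names,
                            k_selected=int(k_star), no_elbow=no_elbow)


def _auto_name(members: list[str]) -> str:
    """Name a module '{dominant statistic}.{dominant channel}' from its
    feature-name tokens (CellProfiler-style Compartment_Class_Stat_Channel)."""
    stats_, chans = [], []
    for f in members:
        toks = f.split("_")
        if len(toks) >= 2:
            stats_.append(toks[1])
        if len(toks) >= 4:
            chans.append(toks[3])
    stat = pd.Series(stats_).mode().iat[0] if stats_ else "feature"
    chan = pd.Series(chans).mode().iat[0] if chans else "all"
    return f"{stat}.{chan}"


def module_activation_scores(matrix: pd.DataFrame, modules: FeatureModuleSet) -> pd.DataFrame:
    """Cells x modules score matrix: centered module submatrix projected on
    the module's PC1 loading (single-feature modules: the centered feature),
    oriented so the score correlates positively with the module's row mean."""
    scores = {}
    for mid, members in modules.modules.items():
        missing = [f for f in members if f not in matrix.columns]
        if missing:
            raise ConfigurationError(f"module {mid} features missing from matrix: {missing[:5]}")
        sub = matrix[members].to_numpy(dtype=float)
        sub = sub - sub.mean(axis=0)
        lead = modules.loadings[mid].to_numpy()
        s = sub @ lead
        rowmean = sub.mean(axis=1)
        sd = s.std()
        if sd > 0 and rowmean.std() > 0 and np.corrcoef(s, rowmean)[0, 1] < 0:
            s = -s
        scores[modules.names.get(mid, f"module{mid}")] = s
    return pd.DataFrame(scores, index=matrix.index)
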