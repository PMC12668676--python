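"""Feature regularization toward normality, subsampling, and redundancy
feature selection on a correlation graph.

Each feature is assigned one of six distribution families and the matching
monotone transform is applied (intensity-like features get log2(x+1), etc.),
after which every feature is min-max scaled to [0, 1000].  Cells are then
stratified-subsampled per experimental population (cap 2000) toward a
50,000-60,000 cell working set.  Features correlated above r = 0.99 form a
graph whose greedy-modularity communities are each collapsed to their most
parsimonious member; spatial x-y, Zernike, and the neighbor-angle feature are
excluded outright.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigurationError, logger

FAMILY_NAMES = {
    1: "log",
    2: "log-count",
    3: "logit",
    4: "identity",
    5: "signed-log",
    6: "rank-inverse-normal",
    0: "constant",
}


# ---------------------------------------------------------------------------
# Distribution families
# ---------------------------------------------------------------------------

def classify_feature_distribution(values: np.ndarray) -> int:
    """Assign a feature to one of the six distribution families.

    Deterministic rules on summary statistics, checked in order:

    1. non-negative with skewness > 1           -> log family
    2. integer-valued counts                    -> log family (count variant)
    3. bounded in [0, 1]                        -> logit family
    4. \\|skewness\\| <= 0.5                      -> identity family
    5. excess kurtosis > 3 (signed heavy tails) -> signed-log family
    6. otherwise                                -> rank inverse-normal family

    Returns 0 (the "constant" sentinel) when all values are identical.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 20:
        raise ConfigurationError("need >= 20 finite values to classify a feature")
    if np.ptp(v) == 0:
        return 0
    skew = stats.skew(v)
    if v.min() >= 0 and skew > 1:
        return 1
    if np.allclose(v, np.rint(v)):
        return 2
    if 0 <= v.min() and v.max() <= 1:
        return 3
    if abs(skew) <= 0.5:
        return 4
    if stats.kurtosis(v) > 3:
        return 5
    return 6


def family_transform(values: np.ndarray, family: int, logit_eps: float = 1e-6) -> np.ndarray:
    """Apply the regularization transform of one family (monotone in all cases)."""
    v = np.asarray(values, dtype=float)
    if family in (1, 2):
        return np.log2(v + 1.0)
    if family == 3:
        p = np.clip(v, logit_eps, 1.0 - logit_eps)
        return np.log(p / (1.0 - p))
    if family == 4:
        return v
    if family == 5:
        return np.sign(v) * np.log2(1.0 + np.abs(v))
    if family == 6:
        r = stats.rankdata(v, method="average")
        return stats.norm.ppf((r - 0.5) / len(v))
    raise ConfigurationError(f"unknown family {family}")


def regularize_features(
    matrix: pd.DataFrame,
    families: dict[str, int] | None = None,
    scale_max: float = 1000.0,
    logit_eps: float = 1e-6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transform each feature by its family and min-max scale to [0, scale_max].

    Returns the regularized matrix and a catalog with the family, the
    transform applied, and a retained flag (constant features are dropped
    with a warning and flagged).
    """
    if families is None:
        families = {c: classify_feature_distribution(matrix[c].to_numpy()) for c in matrix.columns}
    out = {}
    rows = []
    for col in matrix.columns:
        fam = families.get(col, 4)
        v = matrix[col].to_numpy(dtype=float)
        if fam == 0 or np.ptp(v[np.isfinite(v)]) == 0:
            rows.append({"feature": col, "family": 0, "transform": "dropped-constant",
                         "retained": False})
            warnings.warn(f"feature {col!r} is constant; dropped")
            continue
        t = family_transform(v, fam, logit_eps=logit_eps)
        if not np.isfinite(t).all():
            raise ConfigurationError(f"non-finite values after transform for feature {col!r}")
        lo, hi = t.min(), t.max()
        if hi == lo:
            rows.append({"feature": col, "family": fam, "transform": "dropped-constant",
                         "retained": False})
            warnings.warn(f"feature {col!r} is constant after transform; dropped")
            continue
        out[col] = (t - lo) / (hi - lo) * scale_max
        rows.append({"feature": col, "family": fam, "transform": FAMILY_NAMES[fam],
                     "retained": True})
    catalog = pd.DataFrame(rows).set_index("feature")
    return pd.DataFrame(out, index=matrix.index), catalog


# ---------------------------------------------------------------------------
# Subsampling
# ---------------------------------------------------------------------------

def stratified_subsample(
    matrix: pd.DataFrame,
    populations: pd.Series,
    max_per_pop: int = 2000,
    target_range: tuple[int, int] = (50000, 60000),
    seed: int = 0,
) -> pd.DataFrame:
    """Sample at most ``max_per_pop`` cells per experimental population.

    If the capped total still exceeds the target range, the cap is lowered to
    the largest integer bringing the total within it; below the range no
    upsampling happens.  Deterministic given the seed.
    """
    if len(matrix) == 0:
        raise ConfigurationError("cannot subsample an empty matrix")
    pops = populations.reindex(matrix.index)
    sizes = pops.value_counts().sort_index()

    def total(cap):
        return int(np.minimum(sizes.to_numpy(), cap).sum())

    cap = max_per_pop
    if total(cap) > target_range[1]:
        lo, hi = 1, cap
        while lo < hi:  # largest cap with total <= target_range[1]
            mid = (lo + hi + 1) // 2
            if total(mid) <= target_range[1]:
                lo = mid
            else:
                hi = mid - 1
        cap = lo
        logger.info("subsample cap lowered to %d to stay within %s", cap, target_range)
    rng = np.random.default_rng(seed)
    keep = []
    for pop in sizes.index:
        ids = matrix.index[pops == pop].to_numpy()
        if len(ids) > cap:
            ids = rng.choice(ids, size=cap, replace=False)
        keep.extend(ids)
    return matrix.loc[pd.Index(keep)]


def bootstrap_subsample_correlation(
    matrix: pd.DataFrame,
    sizes: list[int],
    reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean Pearson correlation between a subsample's per-feature mean vector
    and the full matrix's, over ``reps`` random subsamples per size."""
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    n = len(matrix)
    for s in sizes:
        if s > n or s < 1:
            raise ConfigurationError(f"subsample size {s} out of range 1..{n}")
        if s == 1:
            warnings.warn("subsample size 1: correlation is defined but degenerate")
    rng = np.random.default_rng(seed)
    X = matrix.to_numpy(dtype=float)
    full_mean = X.mean(axis=0)
    rows = []
    for s in sizes:
        rs = []
        for _ in range(reps):
            idx = rng.choice(n, size=s, replace=False)
            sub_mean = X[idx].mean(axis=0)
            rs.append(np.corrcoef(sub_mean, full_mean)[0, 1])
        rows.append({"size": s, "mean_correlation": float(np.mean(rs))})
    return pd.DataFrame(rows).set_index("size")


# ---------------------------------------------------------------------------
# Greedy-modularity communities and feature selection
# ---------------------------------------------------------------------------

def greedy_modularity_communities(n_nodes: int, edges: list[tuple[int, int]]) -> list[set[int]]:
    """Agglomerative greedy modularity maximization (fast-greedy scheme).

    Starts from singletons and repeatedly merges the connected community pair
    with the largest modularity gain until no merge improves modularity.
    Ties in gain are broken by the smallest (min-node, min-node) pair for
    determinism.  Isolated nodes stay singleton communities.
    """
    comms = {i: {i} for i in range(n_nodes)}
    if not edges:
        return [comms[i] for i in sorted(comms)]
    m = len(edges)
    degree = {i: 0 for i in range(n_nodes)}
    between: dict[tuple[int, int], int] = {}
    for u, v in edges:
        degree[u] += 1
        degree[v] += 1
        key = (min(u, v), max(u, v))
        between[key] = between.get(key, 0) + 1
    comm_degree = dict(degree)

    while True:
        best = None
        for (a, b), l_ab in between.items():
            gain = l_ab / m - comm_degree[a] * comm_degree[b] / (2.0 * m * m)
            tie = tuple(sorted((min(comms[a]), min(comms[b]))))
            if best is None or gain > best[0] + 1e-12 or (abs(gain - best[0]) <= 1e-12 and tie < best[1]):
                best = (gain, tie, a, b)
        if best is None or best[0] <= 1e-12:
            break
        _, _, a, b = best
        comms[a] |= comms.pop(b)
        comm_degree[a] += comm_degree.pop(b)
        # re-route edges from b to a
        new_between: dict[tuple[int, int], int] = {}
        for (x, y), l in between.items():
            x2 = a if x == b else x
            y2 = a if y == b else y
            if x2 == y2:
                continue
            key = (min(x2, y2), max(x2, y2))
            new_between[key] = new_between.get(key, 0) + l
        between = new_between
    return [comms[c] for c in sorted(comms, key=lambda c: min(comms[c]))]


def parsimony_rank(name: str) -> tuple[int, int, str]:
    """Proxy for measurement simplicity: fewest underscore tokens, then
    shortest name, then lexicographic."""
    return (name.count("_") + 1, len(name), name)


@dataclass
class FeatureSelection:
    retained: list[str]
    community_map: dict[str, int]
    dropped_constant: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "retained": self.retained,
            "community_map": self.community_map,
            "dropped_constant": self.dropped_constant,
            "excluded": self.excluded,
        }


def select_nonredundant_features(
    matrix: pd.DataFrame,
    r_threshold: float = 0.99,
    exclusion_patterns: list[str] | None = None,
) -> FeatureSelection:
    """Collapse near-duplicate features (|r| > threshold) to one per
    greedy-modularity community, then drop excluded-pattern features."""
    if exclusion_patterns is None:
        exclusion_patterns = ["_X", "_Y", "Zernike", "AngleBtNghbors_Adjacent"]
    if matrix.shape[1] < 2:
        raise ConfigurationError("feature selection needs >= 2 features")
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = matrix.columns[np.isnan(X).any(axis=0)][0]
        raise ConfigurationError(f"NaN values in feature column {bad!r}")
    names = list(matrix.columns)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)  # constant columns correlate with nothing
    iu, ju = np.triu_indices(len(names), k=1)
    mask = np.abs(corr[iu, ju]) > r_threshold
    edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    comms = greedy_modularity_communities(len(names), edges)

    community_map: dict[str, int] = {}
    retained = []
    for cid, comm in enumerate(comms):
        members = sorted(names[i] for i in comm)
        for mname in members:
            community_map[mname] = cid
        retained.append(min(members, key=parsimony_rank))

    excluded = [f for f in retained if any(pat in f for pat in exclusion_patterns)]
    retained = [f for f in retained if f not in excluded]
    retained.sort(key=names.index)
    logger.info("feature selection: %d -> %d retained (%d excluded by pattern)",
                len(names), len(retained), len(excluded))
    return FeatureSelection(retained=retained, community_map=community_map, excluded=excluded)
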