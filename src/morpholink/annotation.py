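"""Biological annotation of morphology features and cross-dataset transfer.

Covers: lasso transfer of cell-cycle scores (S, G2M) into the imaged
modality via the predicted feature matrix; marker-score matrices per cluster
or cell type and their cross-modality correlation; the representative
feature of each module (product of normalized PC1 loading and the
|sum of coefficients| / |intercept| predictability ratio); per-feature
marker-gene sets (two-sided > 2.5 SD rule); first-neighbor label transfer
between morphology datasets (Euclidean distance < 400); a median-alignment
batch-correction stand-in; and line-cluster association statistics
(log2 odds ratios and adjusted mutual information).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso
from sklearn.metrics import adjusted_mutual_info_score, roc_auc_score
from sklearn.neighbors import NearestNeighbors

from .config import ConfigurationError, logger
from .crossmodal import CrossModalModel, GeneCoefficientMatrix
from .modules import ClusterLabels, FeatureModuleSet


# ---------------------------------------------------------------------------
# Cell-cycle transfer
# ---------------------------------------------------------------------------

@dataclass
class CellCycleModel:
    """Two independent lasso models (score ~ features), one per score."""

    features: list[str]
    s_coef: np.ndarray
    s_intercept: float
    g2m_coef: np.ndarray
    g2m_intercept: float
    alpha: float = 0.02

    def predict(self, feature_matrix: pd.DataFrame) -> pd.DataFrame:
        missing = [f for f in self.features if f not in feature_matrix.columns]
        if missing:
            raise ConfigurationError(f"feature matrix lacks model features, e.g. {missing[:5]}")
        X = feature_matrix[self.features].to_numpy(dtype=float)
        return pd.DataFrame(
            {"S": self.s_intercept + X @ self.s_coef,
             "G2M": self.g2m_intercept + X @ self.g2m_coef},
            index=feature_matrix.index,
        )


def fit_cellcycle_transfer(
    predicted_cp: pd.DataFrame,
    s_scores: pd.Series,
    g2m_scores: pd.Series,
    alpha: float = 0.02,
    max_iter: int = 10000,
) -> CellCycleModel:
    """Fit score ~ features per cell on the predicted feature matrix; the two
    scores always get separate models."""
    s = s_scores.reindex(predicted_cp.index)
    g = g2m_scores.reindex(predicted_cp.index)
    if s.isna().any() or g.isna().any():
        raise ConfigurationError("cell-cycle scores not aligned with predicted features")
    for name, v in (("S", s), ("G2M", g)):
        if float(np.std(v)) == 0:
            raise ConfigurationError(f"{name} score has zero variance")
    X = predicted_cp.to_numpy(dtype=float)
    fits = []
    for v in (s, g):
        m = Lasso(alpha=alpha, max_iter=max_iter)
        m.fit(X, v.to_numpy(dtype=float))
        fits.append((m.coef_.copy(), float(m.intercept_)))
    return CellCycleModel(
        features=list(predicted_cp.columns),
        s_coef=fits[0][0], s_intercept=fits[0][1],
        g2m_coef=fits[1][0], g2m_intercept=fits[1][1],
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Marker scores
# ---------------------------------------------------------------------------

def marker_scores(matrix: pd.DataFrame, labels: pd.Series, method: str = "smd") -> pd.DataFrame:
    """Groups x features marker-score matrix.

    ``smd``: standardized mean difference (mean_in - mean_out) / pooled SD
    (Cohen's d); ``auc``: one-vs-rest AUROC mapped to [-1, 1] as 2*AUC - 1.
    """
    lab = labels.reindex(matrix.index)
    groups = sorted(lab.dropna().unique())
    if len(groups) < 2:
        raise ConfigurationError("marker scores need >= 2 groups")
    counts = lab.value_counts()
    small = [g for g in groups if counts[g] < 2]
    if small:
        raise ConfigurationError(f"groups with < 2 cells: {small}")
    X = matrix.to_numpy(dtype=float)
    rows = {}
    for gname in groups:
        mask = (lab == gname).to_numpy()
        a, b = X[mask], X[~mask]
        if method == "auc":
            y = mask.astype(int)
            rows[gname] = np.array([2 * roc_auc_score(y, X[:, j]) - 1 for j in range(X.shape[1])])
            continue
        n1, n2 = len(a), len(b)
        va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
        pooled = np.sqrt(((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (a.mean(axis=0) - b.mean(axis=0)) / pooled
        rows[gname] = np.where(pooled > 0, d, 0.0)
    return pd.DataFrame(rows, index=matrix.columns).T


def correlate_marker_scores(ms_a: pd.DataFrame, ms_b: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every group row of ``ms_a`` against every group
    row of ``ms_b`` across their common features."""
    common = ms_a.columns.intersection(ms_b.columns)
    if len(common) < 3:
        raise ConfigurationError(f"only {len(common)} common features; need >= 3")
    A = ms_a[common].to_numpy(dtype=float)
    B = ms_b[common].to_numpy(dtype=float)
    out = np.empty((len(A), len(B)))
    for i in range(len(A)):
        for j in range(len(B)):
            out[i, j] = np.corrcoef(A[i], B[j])[0, 1]
    return pd.DataFrame(out, index=ms_a.index, columns=ms_b.index)


# ---------------------------------------------------------------------------
# Representative features and marker genes
# ---------------------------------------------------------------------------

def select_representative_features(
    modules: FeatureModuleSet,
    model: CrossModalModel,
    eps: float = 1e-8,
) -> pd.DataFrame:
    """Per module, score features by (|PC1 loading| / module max |loading|) *
    (|sum of lasso coefficients| / |intercept|) and keep the top scorer
    (ties broken lexicographically)."""
    coef = model.coef_frame()
    rows = []
    for mid, members in modules.modules.items():
        missing = [f for f in members if f not in coef.columns]
        if missing:
            raise ConfigurationError(f"features missing from model: {missing[:5]}")
        load = modules.loadings[mid].abs()
        contribution = load / load.max() if load.max() > 0 else load * 0.0
        for f in members:
            b0 = abs(float(model.intercept[f]))
            flagged = b0 < eps
            predictability = abs(float(coef[f].sum())) / max(b0, eps)
            rows.append({
                "module": mid, "module_name": modules.names.get(mid, f"module{mid}"),
                "feature": f, "contribution": float(contribution[f]),
                "predictability": predictability,
                "score": float(contribution[f]) * predictability,
                "intercept_near_zero": flagged,
            })
    table = pd.DataFrame(rows)
    table["selected"] = False
    for mid, grp in table.groupby("module"):
        ordered = grp.sort_values(["score", "feature"], ascending=[False, True], kind="stable")
        table.loc[ordered.index[0], "selected"] = True
    return table.set_index(["module", "feature"])


def feature_marker_genes(
    coeffs: GeneCoefficientMatrix,
    feature: str,
    sd_threshold: float = 2.5,
) -> pd.DataFrame:
    """Genes whose slope deviates from the feature's mean slope by more than
    ``sd_threshold`` standard deviations (two-sided), with the deviation sign."""
    if feature not in coeffs.slopes.columns:
        raise ConfigurationError(f"feature {feature!r} not in coefficient matrix")
    s = coeffs.slopes[feature]
    sd = float(s.std(ddof=1))
    if sd == 0:
        warnings.warn(f"zero coefficient SD for feature {feature!r}; empty marker set")
        return pd.DataFrame(columns=["coefficient", "sign"])
    dev = (s - s.mean()) / sd
    sel = s[dev.abs() > sd_threshold]
    out = sel.rename("coefficient").to_frame()
    out["sign"] = np.sign(dev[sel.index]).astype(int)
    return out.sort_values("coefficient", ascending=False)


# ---------------------------------------------------------------------------
# Label transfer, batch correction, and abundance association
# ---------------------------------------------------------------------------

@dataclass
class LabelTransferResult:
    assignments: pd.DataFrame             # per query cell: label (or NaN), distance
    max_dist: float = 400.0

    @property
    def n_assigned(self) -> int:
        return int(self.assignments["label"].notna().sum())


def transfer_labels_knn(
    reference: pd.DataFrame,
    reference_labels: pd.Series,
    query: pd.DataFrame,
    max_dist: float = 400.0,
) -> LabelTransferResult:
    """First-nearest-neighbor label transfer: a query cell takes its nearest
    reference cell's label iff their Euclidean distance is strictly below
    ``max_dist``; otherwise it stays unassigned."""
    if list(reference.columns) != list(query.columns):
        raise ConfigurationError("reference and query feature spaces differ")
    lab = reference_labels.reindex(reference.index)
    if lab.isna().any():
        raise ConfigurationError("reference labels not aligned with reference matrix")
    nn = NearestNeighbors(n_neighbors=1, metric="euclidean").fit(reference.to_numpy(dtype=float))
    dist, idx = nn.kneighbors(query.to_numpy(dtype=float))
    dist, idx = dist[:, 0], idx[:, 0]
    assigned = dist < max_dist
    labels = pd.Series(
        [lab.iloc[i] if ok else np.nan for i, ok in zip(idx, assigned)],
        index=query.index, dtype=object,
    )
    res = pd.DataFrame({"label": labels, "distance": dist}, index=query.index)
    logger.info("label transfer: %d/%d assigned (max_dist=%g)", assigned.sum(), len(query), max_dist)
    return LabelTransferResult(assignments=res, max_dist=max_dist)


def batch_correct(matrix: pd.DataFrame, batch_labels: pd.Series) -> pd.DataFrame:
    """Median-alignment batch-correction stand-in: per feature, shift each
    batch so its median equals the global median (the correction contract);
    a single batch passes through unchanged.  External tools can replace
    this step through the file interface."""
    lab = batch_labels.reindex(matrix.index)
    if lab.isna().any():
        raise ConfigurationError("batch labels not aligned with matrix")
    counts = lab.value_counts()
    if (counts == 0).any():
        raise ConfigurationError("batch with 0 cells")
    if len(counts) < 2:
        return matrix.copy()
    out = matrix.copy()
    global_med = matrix.median(axis=0)
    for b in counts.index:
        mask = lab == b
        shift = global_med - matrix.loc[mask].median(axis=0)
        out.loc[mask] = matrix.loc[mask] + shift
    return out


def log2_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """log2 odds ratio of a 2x2 table with Haldane 0.5 correction when any
    cell count is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return float(np.log2((a * d) / (b * c)))


def abundance_association(
    labels: ClusterLabels | pd.Series,
    line_ids: pd.Series,
    strata: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Line-cluster association: per (line, cluster) log2 odds ratio, AMI
    between the line and cluster partitions (per stratum if given), and the
    raw abundance table for external differential-abundance tools."""
    lab = labels.labels if isinstance(labels, ClusterLabels) else labels
    lines = line_ids.reindex(lab.index)
    if lines.isna().any():
        raise ConfigurationError("every cell needs a line id")
    if lab.nunique() < 2 or lines.nunique() < 2:
        raise ConfigurationError("AMI needs >= 2 clusters and >= 2 lines")
    abundance = pd.crosstab(lines, lab)
    n = abundance.to_numpy().sum()
    rows = []
    for line in abundance.index:
        for cl in abundance.columns:
            a = int(abundance.loc[line, cl])
            b = int(abundance.loc[line].sum() - a)
            c = int(abundance[cl].sum() - a)
            d = int(n - a - b - c)
            rows.append({"line": line, "cluster": cl,
                         "log2_odds_ratio": log2_odds_ratio(a, b, c, d)})
    or_table = pd.DataFrame(rows).set_index(["line", "cluster"])
    if strata is None:
        ami = {"all": float(adjusted_mutual_info_score(lines, lab))}
    else:
        st = strata.reindex(lab.index)
        ami = {
            str(s): float(adjusted_mutual_info_score(lines[st == s], lab[st == s]))
            for s in sorted(st.dropna().unique())
        }
    return or_table, ami, abundance
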