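"""Evaluation statistics for imputed chromatin-tracing data.

Covers the population-level summaries (per-entry mean and SD distance
matrices, Pearson correlation between mean matrices), a
detection-efficiency indistinguishability benchmark (can a radial-kernel
SVM tell well-detected from poorly-detected chromosomes after
imputation? for a faithful imputer it should be near chance), and a
PCA + hierarchical-clustering AMI score for cell-type separability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_mutual_info_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .normalization import DistanceMatrix


@dataclass
class SummaryMatrices:
    """Per-entry mean/SD distance matrices over a collection of traces."""

    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray


def summarize(matrices: list[DistanceMatrix]) -> SummaryMatrices:
    """Per-entry mean and sample SD over the available entries of each (i, j).

    Entries contributing fewer than 2 traces have undefined (NaN) SD;
    entries available nowhere have undefined mean.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    vals = np.stack([m.values for m in matrices])
    masks = np.stack([m.mask for m in matrices])
    n = masks.sum(axis=0)
    sums = np.where(masks, vals, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
        sq = np.where(masks, (vals - mean[None]) ** 2, 0.0).sum(axis=0)
        sd = np.where(n > 1, np.sqrt(sq / np.maximum(n - 1, 1)), np.nan)
    return SummaryMatrices(mean, sd, n)


def matrix_correlation(M1: np.ndarray, M2: np.ndarray) -> float:
    """Pearson r over upper-triangle entries finite in both matrices."""
    M1, M2 = np.asarray(M1, float), np.asarray(M2, float)
    if M1.shape != M2.shape:
        raise ValueError("matrices must have the same shape")
    iu = np.triu_indices(M1.shape[0], k=1)
    a, b = M1[iu], M2[iu]
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 shared entries")
    return float(stats.pearsonr(a[ok], b[ok]).statistic)


def upper_triangle_features(matrices: list[DistanceMatrix]) -> np.ndarray:
    """Stack each trace's upper-triangle distances into a feature matrix."""
    K = matrices[0].K
    iu = np.triu_indices(K, k=1)
    return np.stack([m.values[iu] for m in matrices])


def tertile_bins(efficiencies: np.ndarray) -> np.ndarray:
    """Bin traces into detection-efficiency tertiles (0 low, 2 high).

    Binning is by rank with stable order, so ties spanning the 33.3% /
    66.7% quantiles resolve deterministically.
    """
    eff = np.asarray(efficiencies, float)
    n = eff.size
    order = np.argsort(eff, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    return np.minimum(3 * rank // n, 2)


def efficiency_classification(
    imputed: list[DistanceMatrix],
    efficiencies: np.ndarray,
    seed: int = 0,
    n_splits: int = 5,
) -> np.ndarray:
    """5-fold CV accuracies of an RBF SVM separating low- vs high-efficiency traces.

    Traces are binned into tertiles by raw-data detection efficiency;
    each distance entry is normalized by its across-dataset average; a
    soft-margin radial-kernel SVM (C = 1, scaled kernel width) is
    trained to separate the first from the third tertile.  Accuracies
    near 0.5 mean imputed conformations are indistinguishable from
    well-observed ones.
    """
    bins = tertile_bins(efficiencies)
    feats = upper_triangle_features(imputed)
    entry_mean = feats.mean(axis=0)
    feats = feats / np.where(entry_mean != 0, entry_mean, 1.0)
    sel = bins != 1
    X, y = feats[sel], (bins[sel] == 2).astype(int)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accs = []
    for train, test in cv.split(X, y):
        clf = SVC(C=1.0, kernel="rbf", gamma="scale")
        clf.fit(X[train], y[train])
        accs.append(float(clf.score(X[test], y[test])))
    return np.array(accs)


def cluster_ami(
    features: np.ndarray,
    labels: np.ndarray,
    n_clusters: int,
    seed: int = 0,
    var_explained: float = 0.9,
    max_components: int = 20,
) -> float:
    """AMI between hierarchical clusters of PCA-embedded features and labels.

    Features are z-scored per dimension, projected onto the smallest
    number of principal components explaining ``var_explained`` of the
    variance (capped at ``max_components``), Ward-clustered into
    ``n_clusters`` groups, and scored by adjusted mutual information.
    """
    X = np.asarray(features, float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 true classes")
    sd = X.std(axis=0)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    cap = min(max_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=cap, random_state=seed)
    Z = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    ncomp = int(np.searchsorted(cum, var_explained) + 1)
    ncomp = min(ncomp, cap)
    pred = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward").fit_predict(
        Z[:, :ncomp]
    )
    return float(adjusted_mutual_info_score(labels, pred))


def masked_entry_scores(
    raw: list[DistanceMatrix],
    imputed: list[DistanceMatrix],
    truth: list[DistanceMatrix],
) -> tuple[float, float]:
    """(RMSE, Pearson r) of imputed vs true distances on originally missing entries."""
    est, ref = [], []
    for r, m, t in zip(raw, imputed, truth):
        iu = np.triu_indices(r.K, k=1)
        sel = ~r.mask[iu] & m.mask[iu] & t.mask[iu]
        est.append(m.values[iu][sel])
        ref.append(t.values[iu][sel])
    est, ref = np.concatenate(est), np.concatenate(ref)
    if est.size < 2:
        raise ValueError("no masked entries to score")
    rmse = float(np.sqrt(np.mean((est - ref) ** 2)))
    r = float(stats.pearsonr(est, ref).statistic)
    return rmse, r
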