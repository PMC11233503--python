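"""Synthetic-scale benchmark experiments for the imputation pipeline.

Each function simulates a study under the package's standard synthetic
conditions (random-walk traces with conformational clusters and MCAR
missingness), runs one or more imputers, and measures the statistics
used to validate the method: normalization calibration, gradient
correctness, twin-restoration exactness, mean-imputation conservation,
recovery fidelity against ground truth, and the detection-efficiency
indistinguishability SVM.  They are consumed by the acceptance tests
and the reproduction script; sample sizes default to the standard
conditions (200 traces, K = 60).
"""

from __future__ import annotations

import numpy as np

from .baselines import mean_impute
from .data import TraceCollection
from .evaluation import (
    cluster_ami,
    efficiency_classification,
    masked_entry_scores,
    matrix_correlation,
    summarize,
    upper_triangle_features,
)
from .imputation import impute_distances
from .normalization import (
    fit_separation_params,
    normalize,
    pairwise_distances,
)
from .pipeline import linear_impute_collection, snapfish_impute
from .recovery import RecoveryProblem, recover_coordinates, linear_initialize
from .simulate import SimulationConfig, apply_missingness, simulate_population


def standard_conditions(seed: int, **overrides) -> SimulationConfig:
    """The package's reference synthetic study: 200 traces, K=60, 2 clusters."""
    kwargs = dict(K=60, n_traces=200, n_clusters=2, cluster_strength=0.7,
                  missing_rate=0.3, seed=seed)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def _masked_population(seed: int, **overrides):
    cfg = standard_conditions(seed, **overrides)
    complete, labels = simulate_population(cfg)
    masked, truth = apply_missingness(complete, cfg.missing_rate, seed=cfg.seed + 1)
    return masked, truth, labels


def normalization_calibration(seed: int, n_traces: int = 50, K: int = 30) -> dict:
    """Max deviation of per-class pooled normalized mean from 0 and SD from 1."""
    masked, _, _ = _masked_population(seed, n_traces=n_traces, K=K)
    mats = [pairwise_distances(t) for t in masked]
    params = fit_separation_params(mats, masked.annotation)
    normed = [normalize(m, params) for m in mats]
    cls = params.class_matrix
    upper = np.triu(np.ones_like(cls, dtype=bool), k=1)
    worst_mean, worst_sd = 0.0, 0.0
    for c in np.flatnonzero(params.valid):
        if params.n_obs[c] < 10:
            continue
        sel = (cls == c) & upper
        pooled = np.concatenate([m.values[sel & m.mask] for m in normed])
        worst_mean = max(worst_mean, abs(float(pooled.mean())))
        worst_sd = max(worst_sd, abs(float(pooled.std(ddof=1)) - 1.0))
    return {"max_abs_mean": worst_mean, "max_sd_deviation": worst_sd,
            "n_classes": int(params.valid.sum())}


def gradient_check(seed: int, n_instances: int = 50, K: int = 12,
                   n_missing: int = 4) -> float:
    """Worst relative disagreement between analytic and central-difference gradients."""
    from .normalization import SeparationParams, separation_classes
    from .recovery import objective_and_gradient
    from .data import GenomicAnnotation, ChromosomeTrace

    rng = np.random.default_rng(seed)
    worst = 0.0
    starts = 1 + 25_000 * np.arange(K, dtype=np.int64)
    ann = GenomicAnnotation("g", "chr1", starts, starts + 24_999)
    cls, sep = separation_classes(ann)
    for _ in range(n_instances):
        n_cls = sep.size
        params = SeparationParams(
            cls, sep,
            rng.uniform(-1.5, 1.5, n_cls), rng.normal(0, 1, n_cls),
            rng.uniform(0.5, 2.0, n_cls), np.full(n_cls, 100), np.full(n_cls, 1e-3),
        )
        coords = np.cumsum(rng.normal(0, 100, (K, 3)), axis=0)
        miss = rng.choice(K, size=n_missing, replace=False)
        masked = coords.copy()
        masked[miss] = np.nan
        trace = ChromosomeTrace("c", "a", "g", masked)
        target = rng.normal(size=(K, K))
        target = (target + target.T) / 2
        prob = RecoveryProblem(trace, target, params, linear_initialize(trace, ann))
        x0 = prob.init_coords[prob.free].ravel() + rng.normal(0, 10, 3 * n_missing)
        _, g = objective_and_gradient(prob, x0)
        eps = 1e-4
        fd = np.empty_like(g)
        for i in range(x0.size):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += eps
            xm[i] -= eps
            fd[i] = (objective_and_gradient(prob, xp)[0]
                     - objective_and_gradient(prob, xm)[0]) / (2 * eps)
        worst = max(worst, float(np.abs(g - fd).max() / max(np.abs(fd).max(), 1e-12)))
    return worst


def twin_experiment(seed: int, n_traces: int = 40, K: int = 30,
                    mask_fraction: float = 0.3) -> dict:
    """Duplicate a complete trace, mask 30% of its loci, and impute.

    The masked twin's normalized distances must be restored exactly to
    the complete twin's values (its dissimilarity to the twin is 0, so
    the twin wins every donor argmin), and coordinate recovery against
    those targets should reach a near-zero objective.
    """
    cfg = standard_conditions(seed, n_traces=n_traces, K=K)
    complete, _ = simulate_population(cfg)
    rng = np.random.default_rng(cfg.seed + 100)
    ann = complete.annotation

    twin_src = complete.traces[0]
    masked_coords = twin_src.coords.copy()
    drop = rng.choice(K, size=int(mask_fraction * K), replace=False)
    masked_coords[drop] = np.nan
    twin = twin_src.with_coords(masked_coords)
    twin.cell_id = "twin"
    coll = TraceCollection(ann, [twin] + complete.traces)

    raw = [pairwise_distances(t) for t in coll]
    params = fit_separation_params(raw, ann)
    normed = [normalize(m, params) for m in raw]
    out = impute_distances(normed)

    src_norm = normed[1]  # the complete twin
    filled = src_norm.mask & ~normed[0].mask
    max_diff = float(np.abs(out.matrices[0].values[filled] - src_norm.values[filled]).max())

    prob = RecoveryProblem(twin, out.matrices[0].values, params,
                           linear_initialize(twin, ann))
    res = recover_coordinates(prob)
    return {"max_restore_diff": max_diff, "recovery_L_final": res.objective_final,
            "n_restored": int(filled.sum())}


def mean_conservation(seed: int, n_traces: int = 60, K: int = 30) -> float:
    """Worst relative deviation of the mean matrix under mean imputation.

    Mean imputation preserves the available-entry mean matrix exactly in
    exact arithmetic; the measured deviation is floating-point roundoff,
    reported relative to the entry magnitude (distances are nm-scale, so
    a relative measure is the meaningful one).
    """
    masked, _, _ = _masked_population(seed, n_traces=n_traces, K=K)
    mats = [pairwise_distances(t) for t in masked]
    before = summarize(mats).mean
    after = summarize(mean_impute(mats)).mean
    sel = np.isfinite(before)
    return float((np.abs(after[sel] - before[sel]) / np.abs(before[sel])).max())


def end_to_end_comparison(seed: int, **overrides) -> dict:
    """Run the full pipeline and the linear baseline on one synthetic study.

    Reports the Pearson correlation between each method's mean distance
    matrix and the ground-truth mean matrix, plus the RMSE of imputed
    distances on the masked entries.
    """
    masked, truth, labels = _masked_population(seed, **overrides)
    truth_d = [pairwise_distances(t) for t in truth]
    raw_d = [pairwise_distances(t) for t in masked]
    truth_mean = summarize(truth_d).mean

    out = snapfish_impute(masked)
    snap_d = [pairwise_distances(t) for t in out.collection]
    lin = linear_impute_collection(masked)
    lin_d = [pairwise_distances(t) for t in lin]

    rmse_snap, r_masked_snap = masked_entry_scores(raw_d, snap_d, truth_d)
    rmse_lin, r_masked_lin = masked_entry_scores(raw_d, lin_d, truth_d)
    return {
        "pearson_r_snapfish": matrix_correlation(summarize(snap_d).mean, truth_mean),
        "pearson_r_linear": matrix_correlation(summarize(lin_d).mean, truth_mean),
        "masked_rmse_snapfish": rmse_snap,
        "masked_rmse_linear": rmse_lin,
        "masked_pearson_snapfish": r_masked_snap,
        "masked_pearson_linear": r_masked_lin,
        "_state": (masked, out, labels),
    }


def svm_indistinguishability(seed: int, **overrides) -> dict:
    """Tertile-SVM accuracies for pipeline output vs mean-imputed distances."""
    masked, truth, _ = _masked_population(seed, **overrides)
    eff = masked.detection_efficiencies()
    raw_d = [pairwise_distances(t) for t in masked]
    out = snapfish_impute(masked)
    snap_d = [pairwise_distances(t) for t in out.collection]
    mean_d = mean_impute(raw_d)
    acc_snap = efficiency_classification(snap_d, eff, seed=seed)
    acc_mean = efficiency_classification(mean_d, eff, seed=seed)
    return {
        "svm_accuracy_snapfish": float(acc_snap.mean()),
        "svm_accuracy_mean_imputed": float(acc_mean.mean()),
        "svm_accuracy_snapfish_folds": acc_snap,
        "svm_accuracy_mean_folds": acc_mean,
    }


def ami_comparison(seeds, n_traces: int = 60, K: int = 24,
                   cluster_strength: float = 0.7) -> dict:
    """Paired AMI of pipeline vs linear imputation over several seeds.

    Two well-separated conformational classes are simulated per seed;
    each imputer's completed distance features are PCA-embedded and
    Ward-clustered, scored by AMI against the true class labels.
    """
    snap_scores, lin_scores = [], []
    for seed in seeds:
        masked, _, labels = _masked_population(
            seed, n_traces=n_traces, K=K, cluster_strength=cluster_strength
        )
        out = snapfish_impute(masked)
        lin = linear_impute_collection(masked)
        for coll, store in ((out.collection, snap_scores), (lin, lin_scores)):
            feats = upper_triangle_features([pairwise_distances(t) for t in coll])
            store.append(cluster_ami(feats, labels, n_clusters=2, seed=seed))
    return {
        "ami_snapfish": np.array(snap_scores),
        "ami_linear": np.array(lin_scores),
        "ami_snapfish_mean": float(np.mean(snap_scores)),
        "ami_linear_mean": float(np.mean(lin_scores)),
    }
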