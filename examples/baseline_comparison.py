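"""Compare the pipeline with linear, cubic spline, and mean imputation.

Reproduces the package's benchmark comparison at a small scale: all
four imputers on one synthetic study, scored by population fidelity
(Pearson r of mean distance matrices vs ground truth), masked-entry
RMSE, and the detection-efficiency SVM (near 0.5 means imputed
conformations are indistinguishable from well-observed ones).
"""

import numpy as np

from fishimpute import (
    SimulationConfig,
    apply_missingness,
    efficiency_classification,
    linear_impute_collection,
    masked_entry_scores,
    matrix_correlation,
    mean_impute,
    pairwise_distances,
    simulate_population,
    snapfish_impute,
    summarize,
)

cfg = SimulationConfig(seed=1)  # 200 traces, K=60, 30% missing
complete, _ = simulate_population(cfg)
masked, truth = apply_missingness(complete, cfg.missing_rate, seed=2)
eff = masked.detection_efficiencies()

raw_d = [pairwise_distances(t) for t in masked]
truth_d = [pairwise_distances(t) for t in truth]
truth_mean = summarize(truth_d).mean

methods = {
    "snapfish": [pairwise_distances(t) for t in snapfish_impute(masked).collection],
    "linear": [pairwise_distances(t) for t in linear_impute_collection(masked, "linear")],
    "cubic": [pairwise_distances(t) for t in linear_impute_collection(masked, "cubic")],
    "mean": mean_impute(raw_d),  # distances only; coordinates are not recovered
}

print(f"{'method':<10} {'r_mean':>7} {'rmse_nm':>8} {'svm_acc':>8}")
for name, mats in methods.items():
    r = matrix_correlation(summarize(mats).mean, truth_mean)
    rmse, _ = masked_entry_scores(raw_d, mats, truth_d)
    acc = efficiency_classification(mats, eff, seed=1).mean()
    print(f"{name:<10} {r:7.4f} {rmse:8.1f} {acc:8.2f}")

print("\nsnapfish keeps r highest and rmse lowest; its SVM accuracy near "
      "0.5 means the classifier cannot tell imputed from observed "
      "conformations, while mean imputation is detectable.")
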