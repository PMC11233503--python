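# fishimpute

Imputation of missing 3D loci in multiplexed DNA FISH chromatin-tracing data.

Chromatin tracing (sequential DNA FISH: MERFISH, seqFISH+ and relatives)
images an ordered set of genomic loci on individual chromosomes and
reports a 3D coordinate per detected locus. Detection is imperfect —
typically 20–70% of loci per chromosome copy go undetected — and the
resulting missing coordinates break most downstream analyses (PCA/UMAP
embeddings, loop calling, cell-type clustering). Simple fixes either
work only on distances (per-entry mean imputation, which erases
cell-to-cell variability) or only use adjacent loci (linear/spline
interpolation of coordinates, which misses global structure and creates
end-of-region outliers).

`fishimpute` implements a nonparametric imputer that borrows structure
from chromosomes with similar conformations:

1. **Normalization.** Per haploid chromosome copy *n*, pairwise
   Euclidean distances D⁽ⁿ⁾ᵢⱼ are grouped by 1D genomic separation.
   Each separation class *d* gets a Box-Cox exponent λ_d by maximum
   likelihood, and transformed distances are z-scored within the class:

       A⁽ⁿ⁾ᵢⱼ = ( (D⁽ⁿ⁾ᵢⱼ^λ − 1)/λ − μ_d ) / σ_d ,   d = class(i, j)

   After this every entry is approximately standard normal regardless
   of separation.
2. **Dissimilarity.** Normalized matrices are coarsened to a side just
   above 20 by window averaging (zero padding: 0 is the standard-normal
   mean). Between copies *n* and *m*, S_nm = s·|h(n,m)|^(−1/2) with
   s² the sum of squared differences over the shared available entries
   h(n,m); scores sharing <80% of the sparser copy's entries are left
   undefined.
3. **Distance imputation.** Iteratively, each missing normalized entry
   (i, j) of copy *n* is copied from the most similar copy that has it
   (argmin of S_nm over donors carrying (i, j)); dissimilarities are
   recomputed between rounds so filled entries become donors.
4. **Coordinate recovery.** Observed loci stay fixed; the coordinates
   of missing loci minimize
   L = Σ_{i∈m(n)} Σ_{j≠i} ( f_ij(W_ij) − H_ij )², where W_ij is the
   distance from the current coordinates, f_ij the class transform, and
   H the completed target matrix — via L-BFGS with the analytic
   gradient, from a linear-interpolation start.

The package also ships the comparison imputers (linear, cubic spline,
per-entry mean), evaluation statistics (mean/SD distance matrices,
matrix correlation, a detection-efficiency SVM benchmark, PCA +
Ward-clustering AMI), and a synthetic-trace simulator so the whole
pipeline is testable without downloads.

## Worked example

```python
from fishimpute import (SimulationConfig, simulate_population, apply_missingness,
                        snapfish_impute, pairwise_distances, summarize,
                        matrix_correlation, masked_entry_scores)

cfg = SimulationConfig(K=40, n_traces=100, missing_rate=0.3, seed=42)
complete, labels = simulate_population(cfg)
masked, truth = apply_missingness(complete, cfg.missing_rate, seed=43)
result = snapfish_impute(masked)

raw_d   = [pairwise_distances(t) for t in masked]
imp_d   = [pairwise_distances(t) for t in result.collection]
truth_d = [pairwise_distances(t) for t in truth]
print(matrix_correlation(summarize(imp_d).mean, summarize(truth_d).mean))
print(masked_entry_scores(raw_d, imp_d, truth_d))
```

prints (see `examples/simulate_and_impute.py` for the narrated version):

```
0.9987              # Pearson r between imputed and true mean distance matrices
(88.7, 0.924)       # masked-entry RMSE in nm, and Pearson r, vs ground truth
```

i.e., the population-level mean distance matrix is reproduced almost
exactly, and individual imputed distances track the hidden truth.
Running all four imputers on the standard 200-trace study
(`examples/baseline_comparison.py`) gives

```
method      r_mean  rmse_nm  svm_acc
snapfish    0.9999     90.7     0.56
linear      0.9994     99.7     0.64
cubic       0.9895    552.4     0.53
mean        0.9994    266.6     0.72
```

where `svm_acc` is the 5-fold accuracy of an RBF SVM separating
low- from high-detection-efficiency chromosomes after imputation —
near 0.5 means imputed conformations are indistinguishable from
well-observed ones.

Each script in `examples/` is a short narrative of one capability:
simulation + end-to-end imputation, the normalization, dissimilarity
and donor ranking, and the baseline comparison.

## Command line

```bash
fishimpute simulate --k 60 --n-traces 200 --missing-rate 0.3 --seed 1 --out sim/
fishimpute impute --coords sim/coordinates.csv --annot sim/annotation.csv --out imputed/
fishimpute evaluate --raw sim/coordinates.csv --imputed imputed/imputed_coordinates.csv \
    --annot sim/annotation.csv --truth sim/ground_truth.csv --out report.csv
```

Input is a CSV with one row per observed locus
(`cell_id,allele_id,region_id,chrom,start,end,x,y,z`) plus a locus
annotation CSV (`region_id,locus_index,chrom,start,end`); missing loci
are simply absent. Regions are processed independently; coordinate
recovery parallelizes over traces (`--workers`) with results
independent of the worker count.

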