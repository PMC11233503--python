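# Methods

## Model and assumptions

The imputer treats each haploid chromosome copy as an ordered chain of
K imaged loci with coordinates in nm. The statistical backbone is a
random-walk view of chromatin at the imaged scale: for locus pairs with
the same 1D genomic separation, the per-axis coordinate differences
x_i−x_j, y_i−y_j, z_i−z_j are modeled as independent centered normals
with a common variance that grows with separation, so the squared
spatial distance is approximately a scaled chi-squared(3) variable.
Real microscopes violate this (anisotropic z resolution, slice-by-slice
acquisition, localization error), which is why distances are not
normalized parametrically but pushed through a Box-Cox transform with a
maximum-likelihood exponent per separation class, then z-scored within
the class. Two further working assumptions are inherited from the data
model: allele assignment is taken as given (each detected spot is
already attributed to a chromosome copy), and a locus is either fully
observed or fully missing (rows with any non-finite coordinate are
promoted to missing).

The unit of analysis is the chromosome copy, never the cell: all
borrowing happens between copies, and the two homologs of one cell are
just two traces.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| shared-entry threshold | 0.8 | fraction | dissimilarities between copies sharing fewer than this fraction of the sparser copy's available coarse entries are undefined; the one knob with a canonical value |
| resize target side | 20 | entries | coarsening factor k is the largest with ceil(K/k) ≥ 20; K < 20 is used as-is |
| max donor rounds | 10 | rounds | iteration cap for the fill-recompute loop; synthetic studies complete in 1–2 rounds |
| fallback fill | 0.0 | normalized units | value for entries no donor ever carries: the mean of the standard-normal normalized scale (least informative); logged |
| λ search interval | [−5, 5] | — | Box-Cox exponent bounds for the bounded MLE |
| min class size | 10 | pooled values | classes with fewer positive distances borrow parameters from the nearest fitted class by bp separation (λ MLE is unstable on tiny samples) |
| W floor | 1e−8 | nm | distance floor before the λ−2 exponent in the gradient; λ−2 < 0 diverges at coincident points |
| L-BFGS | gtol 1e−6, 500 iter, history 10 | — | recovery optimizer settings |
| SVM benchmark | C=1, RBF, gamma="scale", 5-fold | — | fixed defaults keep the benchmark deterministic given a seed |
| PCA for AMI | ≥90% variance, ≤20 components, Ward linkage | — | embedding ahead of hierarchical clustering |

Separation classes are defined by the absolute difference of locus
interval midpoints in bp, rounded to multiples of the median
adjacent-locus spacing. For equally spaced designs this reduces to the
locus-index offset |i−j|; for unevenly spaced probe sets it bins by
genomic distance, which is the quantity the model cares about.

## Numerical choices

- **Box-Cox MLE.** The profile log-likelihood (scipy's `boxcox_llf`) is
  maximized by bounded scalar search, then polished by a Brent root
  find on the analytic likelihood gradient. The polish matters: the
  likelihood is flat to machine noise within ~1e−8 of the optimum, so a
  function-value search alone leaves λ̂ (and hence normalized values)
  irreproducible at the 1e−8 level under exact symmetries such as rigid
  motions of the input.
- **Zero distances.** Coincident spots produce D = 0, which Box-Cox
  cannot take; they are excluded from fitting and clamped to the
  smallest positive pooled distance of their class before transforming.
- **SD convention.** Sample SD (divisor n−1) everywhere.
- **Coarsening.** Window means run over available entries; when K is
  not divisible by k the matrix is zero-padded and padded cells count
  as available zeros — on the normalized scale 0 is the standard-normal
  mean, so padding is neutral rather than a boundary artifact. The
  structural diagonal is unavailable and simply absent from window
  means. All entry counting for s², |h| and |a| runs over the strict
  upper triangle; full-matrix counting doubles s² and |h| together and
  leaves S unchanged (asserted by a property test).
- **Donor loop determinism.** Within a round, donor availability is a
  snapshot from the round start, so fills are order-independent; filled
  entries donate from the next round on (dissimilarities are recomputed
  between rounds). Ties in S are broken by ascending trace index.
- **Recovery objective.** The loss sums over i ∈ m(n) and all j ≠ i, so
  a pair with both endpoints missing contributes once under each outer
  term; the gradient is the exact derivative of that double-counted
  objective (enforced against central finite differences to 1e−5
  relative). Target entries whose separation class has no parameters
  are skipped. Only missing loci are free variables — optimizing
  observed loci would distort measured data.
- **W in the objective** is recomputed from the current coordinates at
  every optimizer step (a static W would make the gradient
  meaningless); the linear initialization only supplies the starting
  point. λ/μ/σ are *not* refitted after initialization: the targets H
  live on the scale fitted from raw observed distances, and both sides
  of the residual must share it.
- **Cubic spline boundary.** The cubic imputer uses a not-a-knot
  interpolating spline, which reproduces cubic polynomials exactly and
  matches the common `interp1d`-style implementation; both spline
  orders extrapolate by extending the terminal polynomial piece, which
  is precisely what produces their characteristic end-of-region
  outliers.

## The synthetic generator

`simulate_population` draws per-cluster backbone random walks (per-axis
increment SD `step_sd`, default 150 nm — adjacent 25-kb loci then
average ≈ 240 nm apart, the scale of published chromatin-tracing data)
and mixes each trace's own walk with its cluster backbone via
`cluster_strength`. Defaults are the package's reference study: K = 60
loci at 25 kb, 200 traces, 2 clusters, strength 0.7, 30% missingness.
`apply_missingness` masks loci independently (MCAR), redrawing the rare
all-missing trace; a per-locus probability vector enables locus-biased
missingness for robustness tests.

What this emulates: variance growing linearly with separation (the
normalization's model), conformational subpopulations (what the
dissimilarity must find), and uniform dropout. What it does not: real
per-trace detection-efficiency heterogeneity (real efficiencies span
~0.02–1.0 per region, while MCAR at a fixed rate concentrates them
within ±10 points), structured probe-specific failure, localization
noise, and polymer physics (confinement, loop extrusion). Consequences
for interpretation: passing tests show the algorithm is correct and
that borrowing beats interpolation under its own model; they do not
certify performance on data whose missingness is informative. The
detection-efficiency SVM benchmark in particular is sensitive to the
efficiency spread: with tightly concentrated MCAR efficiencies the
low/high tertiles are genuinely harder to separate than in real data,
so mean imputation scores lower on this benchmark here than it does on
published datasets.

## Design choices that were genuinely open

- Genomic anchor of a locus: interval midpoint (symmetric; the natural
  representative for separation binning).
- Dissimilarity is computed on ~20×20 coarse matrices, but imputation
  fills the full-resolution normalized matrices — coarse matrices exist
  only to rank donors stably.
- The 0.8 shared-proportion filter stays fixed across donor rounds;
  filling raises |h| naturally, so the filter relaxes itself.
- Per-region fitting: λ/μ/σ are fitted within each imaging region;
  regions are imputed independently throughout (and in parallel, with
  results independent of worker count).
- Missing entries never donatable by anyone are filled with 0 rather
  than left to fail recovery; the count is logged and reported.

## Limitations

Runtime of recovery grows with K² per trace, so designs with thousands
of loci per chromosome will be slow and the optimization harder;
donor-based borrowing needs enough copies that similar conformations
exist (tens of copies at minimum — with very few cells the dissimilarity
filter leaves rows undefined and more entries fall back to 0); and
chirality is not resolved — recovery constrains distances only, so a
mirror-image placement of an isolated missing stretch is an equally
valid optimum.
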