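"""End-to-end imputation of one region's trace collection.

Stages: raw pairwise distances -> separation-stratified normalization ->
iterative donor imputation of missing normalized distances -> per-trace
L-BFGS coordinate recovery.  Traces are recovered independently, so the
recovery stage parallelizes over traces with results independent of the
worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .data import ChromosomeTrace, TraceCollection, filter_min_observed
from .dissimilarity import DEFAULT_SHARED_THRESHOLD
from .imputation import DEFAULT_MAX_ROUNDS, ImputedDistanceSet, impute_distances
from .normalization import (
    SeparationParams,
    fit_separation_params,
    normalize,
    pairwise_distances,
)
from .recovery import (
    DEFAULT_GTOL,
    DEFAULT_MAX_ITER,
    RecoveryProblem,
    RecoveryResult,
    linear_initialize,
    recover_coordinates,
)

logger = logging.getLogger(__name__)


@dataclass
class ImputationOutput:
    """Completed collection plus intermediates and per-trace recovery logs."""

    collection: TraceCollection
    params: SeparationParams
    distance_set: ImputedDistanceSet
    recovery: pd.DataFrame


def _recover_one(
    trace: ChromosomeTrace, target, params, annotation, tol, max_iter
) -> tuple[np.ndarray, RecoveryResult]:
    init = linear_initialize(trace, annotation)
    problem = RecoveryProblem(trace, target, params, init)
    res = recover_coordinates(problem, tol=tol, max_iter=max_iter)
    return res.coords, res


def snapfish_impute(
    collection: TraceCollection,
    threshold: float = DEFAULT_SHARED_THRESHOLD,
    max_rounds: int = DEFAULT_MAX_ROUNDS,
    tol: float = DEFAULT_GTOL,
    max_iter: int = DEFAULT_MAX_ITER,
    n_workers: int = 1,
) -> ImputationOutput:
    """Impute every missing locus of every trace in one region.

    Normalization parameters are fitted on the raw observed distances of
    the whole collection; target matrices come from donor imputation on
    the normalized scale; coordinates are recovered per trace with the
    observed loci held fixed.  Results are deterministic and independent
    of ``n_workers``.
    """
    collection = filter_min_observed(collection, 1)
    if len(collection) < 2:
        raise ValueError("imputation needs at least 2 traces with observed loci")
    ann = collection.annotation

    raw = [pairwise_distances(t) for t in collection]
    params = fit_separation_params(raw, ann)
    normalized = [normalize(d, params) for d in raw]
    dist_set = impute_distances(normalized, threshold=threshold, max_rounds=max_rounds)

    jobs = (
        delayed(_recover_one)(t, dist_set.matrices[n].values, params, ann, tol, max_iter)
        for n, t in enumerate(collection)
    )
    if n_workers == 1:
        results = [f(*a, **kw) for f, a, kw in jobs]
    else:
        results = Parallel(n_jobs=n_workers)(jobs)

    completed, rows = [], []
    for t, (coords, res) in zip(collection, results):
        completed.append(t.with_coords(coords))
        rows.append(
            (
                t.cell_id,
                t.allele_id,
                int(t.missing.sum()),
                res.objective_initial,
                res.objective_final,
                res.iterations,
                res.converged,
            )
        )
    log = pd.DataFrame(
        rows,
        columns=["cell_id", "allele_id", "n_missing", "L_init", "L_final", "iterations", "converged"],
    )
    return ImputationOutput(TraceCollection(ann, completed), params, dist_set, log)


def linear_impute_collection(collection: TraceCollection, order: str = "linear") -> TraceCollection:
    """Baseline: complete every trace by per-axis spline interpolation."""
    from .baselines import spline_impute

    out = [spline_impute(t, collection.annotation, order=order) for t in collection]
    return TraceCollection(collection.annotation, out)
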