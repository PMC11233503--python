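"""Baseline imputers: linear / cubic spline on coordinates, mean on distances.

Linear imputation evaluates a per-axis piecewise-linear function of
genomic position at missing loci — a weighted average of the two
flanking observed loci with weights proportional to genomic proximity.
Cubic spline imputation replaces the linear pieces with an interpolating
cubic spline.  Both extrapolate beyond the observed span by extending
the terminal polynomial piece, which is what produces their
characteristic end-of-region outliers.  Mean imputation acts on distance
matrices only: each missing (i, j) is replaced by the across-trace mean
of the available (i, j) entries, so coordinates are not recovered.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import interpolate

from .data import ChromosomeTrace, GenomicAnnotation
from .normalization import DistanceMatrix

logger = logging.getLogger(__name__)


def spline_impute(
    trace: ChromosomeTrace, annotation: GenomicAnnotation, order: str = "linear"
) -> ChromosomeTrace:
    """Complete a trace by per-axis spline interpolation in genomic position.

    ``order`` is "linear" or "cubic".  Cubic needs at least 4 observed
    loci and falls back to linear (logged) below that; linear needs at
    least 2.  Observed loci are untouched.
    """
    if order not in ("linear", "cubic"):
        raise ValueError(f"unknown spline order {order!r}")
    obs = np.flatnonzero(trace.observed)
    miss = np.flatnonzero(trace.missing)
    if obs.size < 2:
        raise ValueError("spline imputation needs at least 2 observed loci")
    if miss.size == 0:
        return trace.with_coords(trace.coords.copy())
    if order == "cubic" and obs.size < 4:
        logger.warning(
            "trace (%s, %s): only %d observed loci, cubic falls back to linear",
            trace.cell_id, trace.allele_id, obs.size,
        )
        order = "linear"

    t = annotation.midpoints
    coords = trace.coords.copy()
    for ax in range(3):
        if order == "linear":
            f = interpolate.interp1d(
                t[obs], trace.coords[obs, ax], kind="linear",
                fill_value="extrapolate", assume_sorted=True,
            )
        else:
            f = interpolate.CubicSpline(
                t[obs], trace.coords[obs, ax], bc_type="not-a-knot", extrapolate=True
            )
        coords[miss, ax] = f(t[miss])
    return trace.with_coords(coords)


def mean_impute(matrices: list[DistanceMatrix]) -> list[DistanceMatrix]:
    """Fill each missing distance with its across-trace available-entry mean.

    Entries available in no trace at all are left unavailable (logged).
    The available-entry mean matrix of the collection is exactly
    preserved, since inserting the mean does not move it.
    """
    if not matrices:
        return []
    vals = np.stack([m.values for m in matrices])
    masks = np.stack([m.mask for m in matrices])
    counts = masks.sum(axis=0)
    sums = np.where(masks, vals, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    never = (counts == 0) & ~np.eye(counts.shape[0], dtype=bool)
    if never.any():
        logger.warning(
            "%d entries available in no trace remain missing after mean imputation",
            int(never.sum()) // 2,
        )
    out = []
    for m in matrices:
        fill = ~m.mask & (counts > 0)
        v = np.where(fill, mean, m.values)
        out.append(DistanceMatrix(v, m.mask | fill))
    return out
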