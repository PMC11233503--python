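"""Iterative donor imputation of missing normalized pairwise distances.

Each round, coarse dissimilarities are recomputed from the current
(partially filled) matrices; every missing entry (i, j) of trace n is
then copied from the most similar trace that both has a defined
dissimilarity with n and carries entry (i, j):

    H(n)_ij <- H(k)_ij,   k = argmin over m in p(n) ∩ u(i, j) of S_nm

Filled entries participate as donors in later rounds, so the donatable
set grows and missingness shrinks monotonically.  Donor availability is
read from a snapshot at the round start, which makes each round
order-independent and the whole procedure deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dissimilarity import (
    DEFAULT_SHARED_THRESHOLD,
    DissimilarityTable,
    choose_resize_factor,
    dissimilarity_table,
    resize,
)
from .normalization import NormalizedDistanceMatrix

logger = logging.getLogger(__name__)

DEFAULT_MAX_ROUNDS = 10
FALLBACK_VALUE = 0.0  # mean of the standard-normal normalized scale


def rank_donors(n: int, table: DissimilarityTable) -> np.ndarray:
    """Donor trace indices for trace n, most similar first.

    Sorted by ascending S_nm, ties broken by ascending trace index;
    traces with undefined S (including n itself) are excluded.
    """
    row = table.S[n]
    cand = np.flatnonzero(np.isfinite(row))
    if cand.size == 0:
        return cand
    order = np.lexsort((cand, row[cand]))
    return cand[order]


@dataclass
class ImputedDistanceSet:
    """Completed normalized distance matrices plus fill provenance."""

    matrices: list[NormalizedDistanceMatrix]
    provenance: pd.DataFrame
    rounds_used: int
    n_fallback: int = 0

    def provenance_to_csv(self, path) -> None:
        self.provenance.to_csv(path, index=False)


def impute_distances(
    normalized: list[NormalizedDistanceMatrix],
    threshold: float = DEFAULT_SHARED_THRESHOLD,
    max_rounds: int = DEFAULT_MAX_ROUNDS,
) -> ImputedDistanceSet:
    """Fill every missing entry of every matrix by iterated donor copying.

    Rounds stop when nothing is missing, a round fills nothing, or
    ``max_rounds`` is reached; any entry still missing (never available
    in any reachable donor) is filled with 0, the least informative
    value on the normalized scale, and logged.
    """
    N = len(normalized)
    if N < 2:
        raise ValueError("donor imputation needs at least 2 traces")
    K = normalized[0].K
    if any(m.K != K for m in normalized):
        raise ValueError("all matrices must share K")
    if any(not m.mask.any() for m in normalized):
        raise ValueError("every trace must have at least one available entry")

    iu, ju = np.triu_indices(K, k=1)
    vals = np.stack([m.values[iu, ju] for m in normalized])  # (N, P)
    avail = np.stack([m.mask[iu, ju] for m in normalized])
    original_avail = avail.copy()

    k = choose_resize_factor(K)
    prov: list[tuple[int, int, int, int, int]] = []
    rounds = 0
    while not avail.all() and rounds < max_rounds:
        rounds += 1
        mats = [_rebuild(vals[n], avail[n], K, iu, ju) for n in range(N)]
        table = dissimilarity_table([resize(m, k) for m in mats], threshold)
        snap_avail = avail.copy()
        snap_vals = vals.copy()
        filled_any = False
        for n in range(N):
            miss = np.flatnonzero(~avail[n])
            if miss.size == 0:
                continue
            donors = rank_donors(n, table)
            if donors.size == 0:
                continue
            sub = snap_avail[donors][:, miss]  # (d, miss)
            has = sub.any(axis=0)
            if not has.any():
                continue
            first = sub.argmax(axis=0)
            donor_idx = donors[first[has]]
            cols = miss[has]
            vals[n, cols] = snap_vals[donor_idx, cols]
            avail[n, cols] = True
            prov.extend(
                (n, int(iu[c]), int(ju[c]), int(d), rounds)
                for c, d in zip(cols, donor_idx)
            )
            filled_any = True
        if not filled_any:
            break

    n_fallback = int((~avail).sum())
    if n_fallback:
        logger.warning(
            "%d entries had no reachable donor; filled with %s", n_fallback, FALLBACK_VALUE
        )
        rn, cols = np.nonzero(~avail)
        prov.extend((int(n), int(iu[c]), int(ju[c]), -1, -1) for n, c in zip(rn, cols))
        vals[~avail] = FALLBACK_VALUE
        avail[:] = True

    # originally observed entries are untouched by construction
    assert np.array_equal(avail & original_avail, original_avail)

    matrices = [_rebuild(vals[n], avail[n], K, iu, ju) for n in range(N)]
    provenance = pd.DataFrame(prov, columns=["trace", "i", "j", "donor_trace", "round"])
    return ImputedDistanceSet(matrices, provenance, rounds, n_fallback)


def _rebuild(v: np.ndarray, a: np.ndarray, K: int, iu, ju) -> NormalizedDistanceMatrix:
    full = np.full((K, K), np.nan)
    mask = np.zeros((K, K), dtype=bool)
    full[iu, ju] = np.where(a, v, np.nan)
    full[ju, iu] = full[iu, ju]
    mask[iu, ju] = a
    mask[ju, iu] = a
    return NormalizedDistanceMatrix(full, mask)
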