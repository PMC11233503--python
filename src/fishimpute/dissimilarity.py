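"""Conformation dissimilarity between chromosome copies.

Single locus-pair distances are too noisy to compare conformations, so
normalized distance matrices are first coarsened to a side length just
above 20 by window averaging (padding contributes zeros, the mean of the
standard-normal normalized scale).  The dissimilarity between two copies
is then a shared-entry root-mean-square deviation,

    S_nm = s * |h(n, m)|^(-1/2),
    s^2  = sum over shared entries (H(n)_ij - H(m)_ij)^2,

left undefined when fewer than 80% of the sparser copy's available
entries are shared (such scores would not reflect true structural
relations).  All entry counting runs over the strict upper triangle;
including the mirrored lower triangle would double s^2 and |h| alike and
leave S unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import NormalizedDistanceMatrix

DEFAULT_SHARED_THRESHOLD = 0.8
TARGET_SIDE = 20


@dataclass
class ResizedMatrix:
    """Coarse M x M window-averaged normalized distance matrix."""

    values: np.ndarray
    mask: np.ndarray
    k: int

    @property
    def M(self) -> int:
        return self.values.shape[0]


def choose_resize_factor(K: int, target_side: int = TARGET_SIDE) -> int:
    """Largest k with ceil(K / k) >= target_side (k = 1 for small regions)."""
    if K < target_side:
        return 1
    k = 1
    while -(-K // (k + 1)) >= target_side:
        k += 1
    return k


def resize(A: NormalizedDistanceMatrix, k: int) -> ResizedMatrix:
    """Coarsen a K x K normalized matrix by k x k window means.

    Each output entry is the mean of the available entries in its
    window.  If K is not divisible by k the matrix is zero-padded:
    padded cells count as available zeros (the mean of a standard
    normal), so edge windows are means over real entries plus zeros.
    A window with no available entries and no padding is unavailable.
    """
    if k < 1:
        raise ValueError("resize factor must be >= 1")
    K = A.K
    M = -(-K // k)
    P = M * k
    vals = np.zeros((P, P))
    avail = np.zeros((P, P), dtype=bool)
    vals[:K, :K] = np.where(A.mask, A.values, 0.0)
    avail[:K, :K] = A.mask
    # padded cells count as available zeros
    pad = np.ones((P, P), dtype=bool)
    pad[:K, :K] = False
    avail |= pad

    counts = avail.reshape(M, k, M, k).sum(axis=(1, 3))
    sums = vals.reshape(M, k, M, k).sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return ResizedMatrix(out, counts > 0, k)


def _upper(M: int) -> np.ndarray:
    return np.triu(np.ones((M, M), dtype=bool), k=1)


def dissimilarity(
    Hn: ResizedMatrix, Hm: ResizedMatrix, threshold: float = DEFAULT_SHARED_THRESHOLD
) -> float | None:
    """S_nm between two resized matrices, or None when undefined.

    Undefined when no entries are shared or when the shared proportion
    |h| / min(|a(n)|, |a(m)|) falls below ``threshold``.
    """
    if Hn.M != Hm.M:
        raise ValueError("resized matrices must have the same side length")
    up = _upper(Hn.M)
    an = int((Hn.mask & up).sum())
    am = int((Hm.mask & up).sum())
    shared = Hn.mask & Hm.mask & up
    h = int(shared.sum())
    if h == 0 or min(an, am) == 0 or h / min(an, am) < threshold:
        return None
    s2 = float(((Hn.values[shared] - Hm.values[shared]) ** 2).sum())
    return float(np.sqrt(s2 / h))


@dataclass
class DissimilarityTable:
    """All-pairs S_nm with NaN where undefined; diagonal undefined."""

    S: np.ndarray
    shared_count: np.ndarray
    shared_proportion: np.ndarray

    @property
    def n_traces(self) -> int:
        return self.S.shape[0]

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.S)

    def to_frame(self) -> pd.DataFrame:
        n, m = np.nonzero(np.triu(self.defined, k=1))
        return pd.DataFrame(
            {
                "trace_n": n,
                "trace_m": m,
                "S": self.S[n, m],
                "shared_count": self.shared_count[n, m],
                "shared_proportion": self.shared_proportion[n, m],
            }
        )


def dissimilarity_table(
    resized: list[ResizedMatrix], threshold: float = DEFAULT_SHARED_THRESHOLD
) -> DissimilarityTable:
    """Evaluate S_nm for every unordered trace pair (vectorized)."""
    if not resized:
        raise ValueError("need at least one resized matrix")
    M = resized[0].M
    if any(r.M != M for r in resized):
        raise ValueError("resized matrices must share a side length")
    up = np.triu_indices(M, k=1)
    V = np.stack([r.values[up] for r in resized])
    A = np.stack([r.mask[up] for r in resized]).astype(float)
    V = np.where(A > 0, V, 0.0)

    h = A @ A.T
    g1 = (A * V**2) @ A.T
    s2 = g1 + g1.T - 2.0 * (A * V) @ (A * V).T
    a = A.sum(axis=1)
    min_a = np.minimum(a[:, None], a[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(min_a > 0, h / np.maximum(min_a, 1), 0.0)
        S = np.sqrt(np.maximum(s2, 0.0) / np.maximum(h, 1))
    S[(h == 0) | (prop < threshold)] = np.nan
    np.fill_diagonal(S, np.nan)
    return DissimilarityTable(S, h.astype(int), prop)
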