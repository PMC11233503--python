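"""Pairwise distances and the two-step separation-stratified normalization.

Under a random-walk model of chromatin, the per-axis coordinate
difference between two loci is centered normal with variance
proportional to their 1D genomic separation, so the squared spatial
distance is a scaled chi-squared(3) variable.  Real imaging data deviate
from this (anisotropic z resolution, localization error), so distances
sharing a 1D separation are first made approximately normal by a
Box-Cox power transform with maximum-likelihood exponent, then z-scored
within their separation class:

    A_ij = ( (D_ij^lambda_d - 1) / lambda_d - mu_d ) / sigma_d,   d = class(i, j)

After normalization every entry is approximately standard normal and
contributes comparably to downstream dissimilarities regardless of its
genomic separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import ChromosomeTrace, GenomicAnnotation

logger = logging.getLogger(__name__)

LAMBDA_BOUNDS = (-5.0, 5.0)
MIN_CLASS_SIZE = 10  # below this, lambda MLE is unstable; borrow neighbors


class UnfittableClassError(ValueError):
    """A separation class lacks enough distinct values to fit Box-Cox."""


@dataclass
class DistanceMatrix:
    """K x K symmetric matrix with an availability mask.

    Used both for raw Euclidean distances (nm) and, after
    :func:`normalize`, for dimensionless normalized distances.  Entry
    (i, j) is available iff both loci were observed (or,
    post-imputation, filled); matrices built from traces always mark the
    structural diagonal unavailable.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape or self.values.ndim != 2:
            raise ValueError("values and mask must be equal-shape square arrays")

    @property
    def K(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "DistanceMatrix":
        return DistanceMatrix(self.values.copy(), self.mask.copy())


# normalized matrices share the container; the distinction is semantic
NormalizedDistanceMatrix = DistanceMatrix


def pairwise_distances(trace: ChromosomeTrace) -> DistanceMatrix:
    """Euclidean distance between every observed locus pair of one trace."""
    diff = trace.coords[:, None, :] - trace.coords[None, :, :]
    with np.errstate(invalid="ignore"):
        d = np.sqrt((diff**2).sum(axis=-1))
    obs = trace.observed
    mask = obs[:, None] & obs[None, :]
    np.fill_diagonal(mask, False)  # self-distances carry no information
    d = np.where(mask, d, np.nan)
    return DistanceMatrix(d, mask)


def boxcox_transform(values: np.ndarray, lam: float) -> np.ndarray:
    """Box-Cox power transform; the lambda = 0 branch is the natural log."""
    values = np.asarray(values, dtype=float)
    if abs(lam) < 1e-12:
        return np.log(values)
    return (values**lam - 1.0) / lam


def _llf_gradient(lam: float, x: np.ndarray, logx: np.ndarray) -> float:
    """d/dlambda of the Box-Cox profile log-likelihood.

    The function-value landscape is flat to machine noise within ~1e-8
    of the optimum, so the MLE is polished by solving gradient = 0,
    which resolves lambda to near machine precision.
    """
    if abs(lam) > 1e-5:
        y = (x**lam - 1.0) / lam
        dy = (lam * x**lam * logx - (x**lam - 1.0)) / lam**2
    else:  # series around lambda = 0
        y = logx + lam * logx**2 / 2.0 + lam**2 * logx**3 / 6.0
        dy = logx**2 / 2.0 + lam * logx**3 / 3.0 + lam**2 * logx**4 / 8.0
    n = x.size
    yc = y - y.mean()
    dyc = dy - dy.mean()
    s2 = (yc**2).sum() / n
    ds2 = 2.0 * (yc * dyc).sum() / n
    return float(logx.sum() - n / 2.0 * ds2 / s2)


def fit_boxcox_lambda(values: np.ndarray, bounds: tuple[float, float] = LAMBDA_BOUNDS) -> float:
    """Maximum-likelihood Box-Cox exponent over a bounded interval.

    Maximizes the profile log-likelihood of the transformed sample
    (via :func:`scipy.stats.boxcox_llf`) with bounded scalar
    minimization, then polishes the optimum with a root find on the
    analytic likelihood gradient.  Requires strictly positive values
    with at least two distinct entries.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.unique(values).size < 2:
        raise UnfittableClassError("need >= 2 distinct positive values to fit lambda")
    if np.any(values <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, values),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-8},
    )
    lam0 = float(res.x)
    if bounds[0] + 1e-6 < lam0 < bounds[1] - 1e-6:  # interior optimum: polish
        logx = np.log(values)
        for half_width in (1e-4, 1e-2, 0.5):
            lo, hi = lam0 - half_width, lam0 + half_width
            glo = _llf_gradient(lo, values, logx)
            ghi = _llf_gradient(hi, values, logx)
            if np.isfinite(glo) and np.isfinite(ghi) and glo * ghi < 0:
                return float(optimize.brentq(
                    _llf_gradient, lo, hi, args=(values, logx), xtol=1e-13
                ))
    return lam0


def class_params(values: np.ndarray, lam: float | None = None) -> tuple[float, float, float]:
    """Fit (lambda, mu, sigma) of one separation class from pooled distances.

    ``lam`` may be forced (used when borrowing or testing); otherwise it
    is the bounded MLE.  mu and sigma are the mean and the sample
    standard deviation (divisor n - 1) of the transformed values.
    """
    values = np.asarray(values, dtype=float)
    if lam is None:
        lam = fit_boxcox_lambda(values)
    t = boxcox_transform(values, lam)
    mu = float(np.mean(t))
    sigma = float(np.std(t, ddof=1))
    if not sigma > 0:
        raise UnfittableClassError("zero variance after transform")
    return float(lam), mu, sigma


def separation_classes(
    annotation: GenomicAnnotation, bin_width: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each locus pair to a 1D-separation class.

    Separation is the absolute difference of interval midpoints in bp,
    rounded to multiples of ``bin_width`` (default: the median
    adjacent-locus spacing, which reduces to the locus-index offset
    |i - j| for equally spaced designs).  Returns ``(class_matrix,
    class_sep_bp)`` where ``class_matrix`` is K x K int (diagonal -1) and
    ``class_sep_bp[c]`` is the representative bp separation of class c.
    """
    t = annotation.midpoints
    sep = np.abs(t[:, None] - t[None, :])
    if bin_width is None:
        bin_width = float(np.median(np.diff(t)))
    cls = np.rint(sep / bin_width).astype(int)
    np.fill_diagonal(cls, -1)
    n_classes = cls.max() + 1
    class_sep = np.full(n_classes, np.nan)
    for c in range(n_classes):
        sel = cls == c
        if sel.any():
            class_sep[c] = sep[sel].mean()
    return cls, class_sep


@dataclass
class SeparationParams:
    """Per-separation-class Box-Cox and z-score parameters of one region.

    Arrays are indexed by class id; classes with no data anywhere stay
    NaN and are flagged invalid.  ``class_matrix`` maps each (i, j) to
    its class.  ``clamp`` is the smallest positive pooled distance per
    class, used to floor zero distances before transforming.
    """

    class_matrix: np.ndarray
    class_sep_bp: np.ndarray
    lam: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    n_obs: np.ndarray
    clamp: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.sigma) & (self.sigma > 0)

    def pair_valid(self) -> np.ndarray:
        """K x K mask of pairs whose class has usable parameters."""
        cls = self.class_matrix
        out = np.zeros(cls.shape, dtype=bool)
        ok = cls >= 0
        out[ok] = self.valid[cls[ok]]
        return out

    def matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(lam, mu, sigma) broadcast to K x K pair matrices (NaN where invalid)."""
        cls = np.clip(self.class_matrix, 0, None)
        lam, mu, sig = self.lam[cls], self.mu[cls], self.sigma[cls]
        bad = ~self.pair_valid()
        for a in (lam, mu, sig):
            a[bad] = np.nan
        return lam, mu, sig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "separation_bp": self.class_sep_bp,
                "lambda": self.lam,
                "mu": self.mu,
                "sigma": self.sigma,
                "n_obs": self.n_obs,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def fit_separation_params(
    matrices: list[DistanceMatrix],
    annotation: GenomicAnnotation,
    bin_width: float | None = None,
    min_class_size: int = MIN_CLASS_SIZE,
) -> SeparationParams:
    """Fit lambda/mu/sigma for every separation class, pooled across traces.

    Zero (coincident-spot) distances are excluded from fitting.  Classes
    with fewer than ``min_class_size`` pooled positive values, or with
    degenerate (constant) values, borrow parameters from the nearest
    fitted class by bp separation.
    """
    cls_mat, class_sep = separation_classes(annotation, bin_width)
    n_classes = class_sep.size
    lam = np.full(n_classes, np.nan)
    mu = np.full(n_classes, np.nan)
    sigma = np.full(n_classes, np.nan)
    n_obs = np.zeros(n_classes, dtype=int)
    clamp = np.full(n_classes, np.nan)

    upper = np.triu(np.ones_like(cls_mat, dtype=bool), k=1)
    pooled: list[np.ndarray] = []
    for c in range(n_classes):
        sel = (cls_mat == c) & upper
        vals = np.concatenate(
            [m.values[sel & m.mask] for m in matrices] or [np.empty(0)]
        )
        vals = vals[np.isfinite(vals)]
        pos = vals[vals > 0]
        pooled.append(pos)
        n_obs[c] = pos.size
        if pos.size:
            clamp[c] = pos.min()

    for c in range(n_classes):
        pos = pooled[c]
        if pos.size < max(2, min_class_size):
            continue
        try:
            lam[c], mu[c], sigma[c] = class_params(pos)
        except UnfittableClassError:
            logger.warning("separation class %d (%.0f bp) unfittable", c, class_sep[c])

    fitted = np.flatnonzero(np.isfinite(sigma))
    if fitted.size == 0:
        raise UnfittableClassError("no separation class could be fitted")
    for c in range(n_classes):
        # fitted classes keep their own fit; classes with no pairs or with no
        # observed distance anywhere stay undefined (downstream skips them)
        if np.isfinite(sigma[c]) or not np.isfinite(class_sep[c]) or n_obs[c] == 0:
            continue
        donor = fitted[np.argmin(np.abs(class_sep[fitted] - class_sep[c]))]
        logger.info(
            "class %d (%.0f bp, n=%d) borrows parameters from class %d",
            c, class_sep[c], n_obs[c], donor,
        )
        lam[c], mu[c], sigma[c] = lam[donor], mu[donor], sigma[donor]
        if not np.isfinite(clamp[c]):
            clamp[c] = clamp[donor]

    return SeparationParams(cls_mat, class_sep, lam, mu, sigma, n_obs, clamp)


def normalize(matrix: DistanceMatrix, params: SeparationParams) -> NormalizedDistanceMatrix:
    """Map each available distance through its class's Box-Cox + z-score.

    Zero distances are clamped to the smallest positive pooled distance
    of their class before transforming.  Entries in classes without
    usable parameters are left unavailable.
    """
    lam, mu, sig = params.matrices()
    ok = matrix.mask & params.pair_valid()
    dropped = matrix.mask & ~ok
    if dropped.any():
        logger.warning("%d entries in unfittable classes left unavailable", dropped.sum() // 2)

    d = matrix.values.copy()
    cls = np.clip(params.class_matrix, 0, None)
    clamp = params.clamp[cls]
    zero = ok & ~(d > 0)
    d[zero] = clamp[zero]

    out = np.full_like(d, np.nan)
    sel = ok
    lam_s, d_s = lam[sel], d[sel]
    t = np.where(
        np.abs(lam_s) < 1e-12, np.log(d_s), (d_s**lam_s - 1.0) / np.where(lam_s == 0, 1, lam_s)
    )
    out[sel] = (t - mu[sel]) / sig[sel]
    return NormalizedDistanceMatrix(out, sel)


def denormalize(values: np.ndarray, params: SeparationParams) -> np.ndarray:
    """Analytic inverse of :func:`normalize` on a K x K array (NaN passthrough)."""
    lam, mu, sig = params.matrices()
    t = values * sig + mu
    with np.errstate(invalid="ignore", over="ignore"):
        out = np.where(
            np.abs(lam) < 1e-12,
            np.exp(t),
            (lam * t + 1.0) ** (1.0 / np.where(lam == 0, 1, lam)),
        )
    return out
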