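"""Recover 3D coordinates of missing loci from imputed target distances.

Observed loci stay fixed; the 3 * |m(n)| coordinates of missing loci are
free variables.  Starting from a per-axis linear interpolation in
genomic position, we minimize

    L = sum over i in m(n), sum over j != i of ( f_ij(W_ij) - H_ij )^2

where W_ij is the Euclidean distance computed from the current
coordinates, f_ij is the separation class's Box-Cox + z-score transform
(the same parameters fitted on the raw observed distances, so both sides
of the residual live on one scale), and H is the completed target
matrix.  Pairs with both endpoints missing appear once under each
endpoint's outer term and therefore contribute twice — the gradient is
the exact derivative of this objective.  Minimization uses L-BFGS-B with
the analytic gradient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, optimize

from .data import ChromosomeTrace, GenomicAnnotation
from .normalization import SeparationParams

logger = logging.getLogger(__name__)

W_FLOOR = 1e-8  # nm; lambda - 2 < 0 diverges as W -> 0
DEFAULT_GTOL = 1e-6
DEFAULT_MAX_ITER = 500
LBFGS_HISTORY = 10


def linear_initialize(trace: ChromosomeTrace, annotation: GenomicAnnotation) -> np.ndarray:
    """Initialize missing loci by per-axis linear interpolation in bp position.

    Interior gaps are linearly interpolated between flanking observed
    loci; loci outside the observed span are linearly extrapolated from
    the two nearest observed loci.  With a single observed locus every
    missing locus starts at that locus's position.
    """
    obs = np.flatnonzero(trace.observed)
    if obs.size == 0:
        raise ValueError("cannot initialize a trace with no observed locus")
    t = annotation.midpoints
    coords = trace.coords.copy()
    miss = np.flatnonzero(trace.missing)
    if miss.size == 0:
        return coords
    if obs.size == 1:
        coords[miss] = coords[obs[0]]
        return coords
    for ax in range(3):
        f = interpolate.interp1d(
            t[obs], trace.coords[obs, ax], kind="linear", fill_value="extrapolate",
            assume_sorted=True,
        )
        coords[miss, ax] = f(t[miss])
    return coords


@dataclass
class RecoveryProblem:
    """One trace's coordinate-recovery instance."""

    trace: ChromosomeTrace
    target: np.ndarray  # K x K completed normalized distances
    params: SeparationParams
    init_coords: np.ndarray

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target, dtype=float)
        K = self.trace.K
        if self.target.shape != (K, K):
            raise ValueError("target must be K x K")
        self.free = np.flatnonzero(self.trace.missing)
        lam, mu, sig = self.params.matrices()
        self._lam, self._mu, self._sig = lam, mu, sig
        # a pair enters the objective only if its class has parameters
        # and its target entry is defined
        self._pair_ok = self.params.pair_valid() & np.isfinite(self.target)

    @property
    def n_free(self) -> int:
        return self.free.size

    def full_coords(self, flat_free: np.ndarray) -> np.ndarray:
        coords = self.init_coords.copy()
        if self.n_free:
            coords[self.free] = np.asarray(flat_free, dtype=float).reshape(-1, 3)
        return coords


def objective_and_gradient(
    problem: RecoveryProblem, flat_free: np.ndarray
) -> tuple[float, np.ndarray]:
    """Evaluate L and its exact gradient w.r.t. the free coordinates."""
    flat_free = np.asarray(flat_free, dtype=float)
    if not np.isfinite(flat_free).all():
        raise ValueError("non-finite free coordinates")
    coords = problem.full_coords(flat_free)
    m = problem.free
    M = m.size
    if M == 0:
        return 0.0, np.zeros(0)
    K = problem.trace.K

    diff = coords[m, None, :] - coords[None, :, :]  # (M, K, 3)
    W = np.sqrt((diff**2).sum(axis=-1))
    W = np.maximum(W, W_FLOOR)

    lam = problem._lam[m, :]
    mu = problem._mu[m, :]
    sig = problem._sig[m, :]
    ok = problem._pair_ok[m, :].copy()
    ok[np.arange(M), m] = False  # exclude j == i

    lam_safe = np.where(np.abs(lam) < 1e-12, 1.0, lam)
    f = np.where(
        np.abs(lam) < 1e-12,
        np.log(np.where(ok, W, 1.0)),
        (np.where(ok, W, 1.0) ** lam_safe - 1.0) / lam_safe,
    )
    f = (f - mu) / sig
    r = np.where(ok, f - problem.target[m, :], 0.0)

    L = float((r**2).sum())

    with np.errstate(invalid="ignore"):
        g = np.where(ok, 2.0 / sig * W ** (lam - 2.0) * r, 0.0)  # (M, K)
    grad = (g[:, :, None] * diff).sum(axis=1)  # d/dx_i over all j
    # pairs whose j is itself free contribute to j's gradient with opposite sign
    grad -= (g[:, m, None] * diff[:, m, :]).sum(axis=0)
    return L, grad.ravel()


@dataclass
class RecoveryResult:
    coords: np.ndarray
    objective_initial: float
    objective_final: float
    iterations: int
    converged: bool


def recover_coordinates(
    problem: RecoveryProblem,
    tol: float = DEFAULT_GTOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RecoveryResult:
    """Minimize the recovery objective with L-BFGS-B from the linear init.

    Observed coordinates never move.  If the optimizer fails to improve
    on the initialization the initial coordinates are returned with
    ``converged=False``.
    """
    if problem.n_free == 0:
        return RecoveryResult(problem.init_coords.copy(), 0.0, 0.0, 0, True)
    x0 = problem.init_coords[problem.free].ravel()
    L0, _ = objective_and_gradient(problem, x0)
    res = optimize.minimize(
        lambda x: objective_and_gradient(problem, x),
        x0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": max_iter,
            "maxcor": LBFGS_HISTORY,
            "gtol": tol,
            "ftol": 1e-14,
        },
    )
    if res.fun <= L0:
        coords = problem.full_coords(res.x)
        Lf = float(res.fun)
        ok = bool(res.success)
    else:  # pathological line-search failure: keep the initialization
        coords = problem.init_coords.copy()
        Lf, ok = L0, False
    if not ok:
        logger.warning(
            "recovery for trace (%s, %s) did not converge: %s",
            problem.trace.cell_id, problem.trace.allele_id,
            getattr(res, "message", ""),
        )
    # observed loci are bit-identical by construction
    return RecoveryResult(coords, L0, Lf, int(res.nit), ok)
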