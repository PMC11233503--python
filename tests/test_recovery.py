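"""Linear initialization, the recovery objective/gradient, and L-BFGS recovery."""

import numpy as np
import pytest

from fishimpute.data import GenomicAnnotation
from fishimpute.normalization import (
    SeparationParams,
    fit_separation_params,
    normalize,
    pairwise_distances,
    separation_classes,
)
from fishimpute.recovery import (
    RecoveryProblem,
    linear_initialize,
    objective_and_gradient,
    recover_coordinates,
)

from conftest import make_annotation, make_trace


def random_params(annotation: GenomicAnnotation, rng) -> SeparationParams:
    """Arbitrary valid per-class transform parameters (no fitting needed)."""
    cls, sep = separation_classes(annotation)
    n = sep.size
    lam = rng.uniform(-1.5, 1.5, n)
    mu = rng.normal(0, 1, n)
    sigma = rng.uniform(0.5, 2.0, n)
    return SeparationParams(cls, sep, lam, mu, sigma,
                            np.full(n, 100), np.full(n, 1e-3))


class TestLinearInitialize:
    def test_interior_midpoint(self):
        ann = make_annotation(3, spacing=25_000)
        t = make_trace([[0, 0, 0], [np.nan] * 3, [2, 2, 2]])
        init = linear_initialize(t, ann)
        np.testing.assert_allclose(init[1], [1, 1, 1])

    def test_unequal_gaps_weighted(self):
        starts = np.array([1, 10_001, 50_001])
        ann = GenomicAnnotation("r1", "chr1", starts, starts + 9)
        t = make_trace([[0, 0, 0], [np.nan] * 3, [5, 5, 5]])
        init = linear_initialize(t, ann)
        np.testing.assert_allclose(init[1], [1, 1, 1])  # weight 10k / 50k

    def test_extrapolation_from_two_nearest(self):
        ann = make_annotation(4)
        t = make_trace([[np.nan] * 3, [0, 0, 0], [1, 2, 3], [np.nan] * 3])
        init = linear_initialize(t, ann)
        np.testing.assert_allclose(init[0], [-1, -2, -3])
        np.testing.assert_allclose(init[3], [2, 4, 6])

    def test_single_observed_locus_constant(self):
        ann = make_annotation(4)
        t = make_trace([[np.nan] * 3, [7, 8, 9], [np.nan] * 3, [np.nan] * 3])
        init = linear_initialize(t, ann)
        for i in (0, 2, 3):
            np.testing.assert_array_equal(init[i], [7, 8, 9])

    def test_no_observed_raises(self):
        ann = make_annotation(3)
        with pytest.raises(ValueError):
            linear_initialize(make_trace(np.full((3, 3), np.nan)), ann)


def _random_problem(rng, K=12, n_missing=4):
    ann = make_annotation(K)
    coords = np.cumsum(rng.normal(0, 100, (K, 3)), axis=0)
    miss = rng.choice(K, size=n_missing, replace=False)
    coords_masked = coords.copy()
    coords_masked[miss] = np.nan
    trace = make_trace(coords_masked)
    params = random_params(ann, rng)
    target = rng.normal(size=(K, K))
    target = (target + target.T) / 2
    init = linear_initialize(trace, ann)
    return RecoveryProblem(trace, target, params, init)


class TestObjectiveAndGradient:
    def test_perfect_fit_gives_zero(self, small_population):
        masked_coll, truth, _ = small_population
        ann = truth.annotation
        raw = [pairwise_distances(t) for t in masked_coll]
        params = fit_separation_params(raw, ann)
        full = truth.traces[0]
        normed = normalize(pairwise_distances(full), params)
        masked = full.coords.copy()
        masked[5:10] = np.nan
        prob = RecoveryProblem(
            make_trace(masked), normed.values, params, full.coords.copy()
        )
        L, g = objective_and_gradient(prob, full.coords[prob.free].ravel())
        assert L == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        prob = _random_problem(rng)
        x0 = prob.init_coords[prob.free].ravel() + rng.normal(0, 10, 3 * prob.n_free)
        _, g = objective_and_gradient(prob, x0)
        eps = 1e-4
        fd = np.empty_like(g)
        for i in range(x0.size):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += eps
            xm[i] -= eps
            fd[i] = (objective_and_gradient(prob, xp)[0]
                     - objective_and_gradient(prob, xm)[0]) / (2 * eps)
        denom = max(np.abs(fd).max(), 1e-12)
        assert np.abs(g - fd).max() / denom < 1e-5

    def test_both_missing_pairs_counted_twice(self):
        rng = np.random.default_rng(3)
        prob = _random_problem(rng, K=8, n_missing=2)
        x0 = prob.init_coords[prob.free].ravel()
        L, _ = objective_and_gradient(prob, x0)
        # direct evaluation: sum over i in m(n), j != i, so the (i, j) pair
        # with both endpoints missing appears under both outer terms
        coords = prob.full_coords(x0)
        lam, mu, sig = prob.params.matrices()
        total, pair_terms = 0.0, {}
        for i in prob.free:
            for j in range(8):
                if j == i:
                    continue
                W = max(np.linalg.norm(coords[i] - coords[j]), 1e-8)
                f = (((W ** lam[i, j]) - 1) / lam[i, j] - mu[i, j]) / sig[i, j]
                term = (f - prob.target[i, j]) ** 2
                total += term
                pair_terms[frozenset((i, j))] = pair_terms.get(frozenset((i, j)), 0.0) + term
        assert L == pytest.approx(total, rel=1e-12)
        both = frozenset(prob.free[:2])
        single_convention = total - pair_terms[both] / 2
        assert single_convention < total  # removing the duplicate halves that pair

    def test_nonfinite_coordinates_raise(self):
        rng = np.random.default_rng(0)
        prob = _random_problem(rng)
        bad = prob.init_coords[prob.free].ravel()
        bad[0] = np.nan
        with pytest.raises(ValueError):
            objective_and_gradient(prob, bad)


@pytest.fixture(scope="module")
def planted(small_population):
    masked, truth, _ = small_population
    raw = [pairwise_distances(t) for t in truth]
    params = fit_separation_params(raw, truth.annotation)
    return truth, params


class TestRecoverCoordinates:
    def test_nothing_missing_returns_unchanged(self, masked_collection):
        ann = masked_collection.annotation
        raw = [pairwise_distances(t) for t in masked_collection]
        params = fit_separation_params(raw, ann)
        t = masked_collection.traces[0]
        full = t.with_coords(np.where(np.isfinite(t.coords), t.coords, 0.0))
        prob = RecoveryProblem(full, np.zeros((ann.K, ann.K)), params, full.coords.copy())
        res = recover_coordinates(prob)
        assert res.iterations == 0 and res.converged
        np.testing.assert_array_equal(res.coords, full.coords)

    def test_planted_solution_recovered(self, planted):
        truth, params = planted
        ann = truth.annotation
        full = truth.traces[0]
        target = normalize(pairwise_distances(full), params)
        masked = full.coords.copy()
        masked[13] = np.nan  # delete one locus; its own distances are the target
        trace = full.with_coords(masked)
        prob = RecoveryProblem(trace, target.values, params, linear_initialize(trace, ann))
        res = recover_coordinates(prob)
        assert res.objective_final < 1e-6
        # distances from the recovered locus match the planted ones
        d = np.linalg.norm(res.coords - res.coords[13], axis=1)
        d_true = np.linalg.norm(full.coords - full.coords[13], axis=1)
        keep = np.arange(ann.K) != 13
        np.testing.assert_allclose(d[keep], d_true[keep], rtol=1e-3)

    def test_observed_loci_bit_identical_and_descent(self, planted):
        truth, params = planted
        ann = truth.annotation
        full = truth.traces[1]
        target = normalize(pairwise_distances(full), params)
        masked = full.coords.copy()
        masked[[2, 9, 20]] = np.nan
        trace = full.with_coords(masked)
        prob = RecoveryProblem(trace, target.values, params, linear_initialize(trace, ann))
        res = recover_coordinates(prob)
        assert res.objective_final <= res.objective_initial
        obs = trace.observed
        np.testing.assert_array_equal(res.coords[obs], full.coords[obs])

    def test_rigid_motion_gauge_on_distances(self, planted):
        from scipy.spatial.transform import Rotation

        truth, params = planted
        ann = truth.annotation
        full = truth.traces[2]
        target = normalize(pairwise_distances(full), params)
        masked = full.coords.copy()
        masked[[4, 17]] = np.nan
        trace = full.with_coords(masked)
        res1 = recover_coordinates(
            RecoveryProblem(trace, target.values, params, linear_initialize(trace, ann))
        )
        R = Rotation.from_euler("zyx", [1.0, 0.5, -0.7]).as_matrix()
        shift = np.array([50.0, -20.0, 10.0])
        moved = trace.with_coords(trace.coords @ R.T + shift)
        init2 = linear_initialize(moved, ann)
        res2 = recover_coordinates(RecoveryProblem(moved, target.values, params, init2))
        d1 = np.linalg.norm(res1.coords[:, None] - res1.coords[None], axis=-1)
        d2 = np.linalg.norm(res2.coords[:, None] - res2.coords[None], axis=-1)
        np.testing.assert_allclose(d1, d2, atol=1e-4)
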