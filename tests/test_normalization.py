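"""Box-Cox fitting and separation-stratified distance normalization."""

import numpy as np
import pytest
from scipy import stats

from fishimpute.normalization import (
    DistanceMatrix,
    UnfittableClassError,
    boxcox_transform,
    class_params,
    denormalize,
    fit_boxcox_lambda,
    fit_separation_params,
    normalize,
    pairwise_distances,
    separation_classes,
)
from fishimpute.data import TraceCollection

from conftest import make_annotation, make_trace


def grid_best_llf(values, lo=-5.0, hi=5.0, step=0.1):
    grid = np.arange(lo, hi + step / 2, step)
    return max(stats.boxcox_llf(l, values) for l in grid)


class TestPairwiseDistances:
    def test_3_4_5_triangle(self):
        t = make_trace([[0, 0, 0], [3, 4, 0], [np.nan] * 3])
        d = pairwise_distances(t)
        assert d.values[0, 1] == pytest.approx(5.0)
        assert d.values[1, 0] == pytest.approx(5.0)

    def test_missing_locus_unavailable_row_and_column(self):
        t = make_trace([[0, 0, 0], [3, 4, 0], [np.nan] * 3])
        d = pairwise_distances(t)
        assert not d.mask[2].any() and not d.mask[:, 2].any()

    def test_diagonal_excluded(self):
        t = make_trace(np.random.default_rng(0).normal(size=(5, 3)))
        assert not np.diag(pairwise_distances(t).mask).any()


class TestBoxCoxLambda:
    def test_lognormal_gives_lambda_near_zero(self):
        x = np.exp(np.random.default_rng(0).normal(0, 0.5, size=5000))
        lam = fit_boxcox_lambda(x)
        assert abs(lam) < 0.1

    def test_truncated_normal_gives_lambda_near_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 1, size=5000)
        x = x[x > 0]
        lam = fit_boxcox_lambda(x)
        assert abs(lam - 1.0) < 0.35  # profile likelihood is flat near 1 here

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_beats_dense_grid(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.gamma(3.0, 2.0, size=800)
        lam = fit_boxcox_lambda(x)
        assert stats.boxcox_llf(lam, x) >= grid_best_llf(x) - 1e-9

    def test_degenerate_values_unfittable(self):
        with pytest.raises(UnfittableClassError):
            fit_boxcox_lambda(np.array([2.0, 2.0, 2.0]))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fit_boxcox_lambda(np.array([0.0, 1.0, 2.0]))


class TestSeparationParams:
    def test_forced_identity_lambda_hand_arithmetic(self):
        lam, mu, sigma = class_params(np.array([1.0, 2.0, 3.0]), lam=1.0)
        # transform (D - 1)/1 -> {0, 1, 2}; sample SD with divisor n-1
        assert (lam, mu, sigma) == (1.0, 1.0, 1.0)

    def test_single_value_class_unfittable(self):
        with pytest.raises(UnfittableClassError):
            class_params(np.array([2.0]))

    def test_classes_equal_index_offset_for_uniform_spacing(self):
        ann = make_annotation(10)
        cls, sep = separation_classes(ann)
        i, j = np.indices((10, 10))
        off = np.abs(i - j)
        off[i == j] = -1
        assert np.array_equal(cls, off)

    def test_pooled_zscore_mean0_sd1(self, masked_collection):
        mats = [pairwise_distances(t) for t in masked_collection]
        params = fit_separation_params(mats, masked_collection.annotation)
        normed = [normalize(m, params) for m in mats]
        cls = params.class_matrix
        upper = np.triu(np.ones_like(cls, dtype=bool), k=1)
        for c in np.flatnonzero(params.valid):
            if params.n_obs[c] < 10:
                continue  # borrowed parameters are not centered for this class
            sel = (cls == c) & upper
            pooled = np.concatenate([m.values[sel & m.mask] for m in normed])
            assert abs(pooled.mean()) < 1e-9
            assert abs(pooled.std(ddof=1) - 1.0) < 1e-9

    def test_small_classes_borrow_nearest(self):
        ann = make_annotation(25)
        rng = np.random.default_rng(3)
        # only 3 traces: the largest separations have < 10 pooled values
        coll = [make_trace(np.cumsum(rng.normal(0, 50, (25, 3)), 0), cell=f"c{i}")
                for i in range(3)]
        mats = [pairwise_distances(t) for t in coll]
        params = fit_separation_params(mats, ann)
        assert params.valid[np.flatnonzero(params.n_obs > 0)].all()


@pytest.fixture(scope="module")
def fitted(masked_collection):
    mats = [pairwise_distances(t) for t in masked_collection]
    params = fit_separation_params(mats, masked_collection.annotation)
    return mats, params


class TestNormalize:
    def test_mask_unchanged(self, fitted):
        mats, params = fitted
        for m in mats[:5]:
            n = normalize(m, params)
            assert np.array_equal(n.mask, m.mask)

    def test_monotone_in_raw_distance(self, fitted):
        _, params = fitted
        c = 3
        lam, mu, sig = params.lam[c], params.mu[c], params.sigma[c]
        d = np.linspace(10, 2000, 100)
        f = (boxcox_transform(d, lam) - mu) / sig
        assert np.all(np.diff(f) > 0)

    def test_normalize_then_denormalize_recovers(self, fitted):
        mats, params = fitted
        m = mats[0]
        n = normalize(m, params)
        back = denormalize(n.values, params)
        sel = n.mask
        np.testing.assert_allclose(back[sel], m.values[sel], rtol=1e-9)

    def test_rigid_motion_invariance(self, masked_collection):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        shift = np.array([123.0, -456.0, 789.0])
        moved = TraceCollection(
            masked_collection.annotation,
            [t.with_coords(t.coords @ R.T + shift) for t in masked_collection],
        )
        mats0 = [pairwise_distances(t) for t in masked_collection]
        mats1 = [pairwise_distances(t) for t in moved]
        p0 = fit_separation_params(mats0, masked_collection.annotation)
        p1 = fit_separation_params(mats1, masked_collection.annotation)
        for a, b in zip(mats0[:10], mats1[:10]):
            na, nb = normalize(a, p0), normalize(b, p1)
            np.testing.assert_allclose(na.values[na.mask], nb.values[nb.mask], atol=1e-9)

    def test_scale_equivariance(self, masked_collection):
        scaled = TraceCollection(
            masked_collection.annotation,
            [t.with_coords(t.coords * 3.7) for t in masked_collection],
        )
        mats0 = [pairwise_distances(t) for t in masked_collection]
        mats1 = [pairwise_distances(t) for t in scaled]
        p0 = fit_separation_params(mats0, masked_collection.annotation)
        p1 = fit_separation_params(mats1, masked_collection.annotation)
        for a, b in zip(mats0[:10], mats1[:10]):
            na, nb = normalize(a, p0), normalize(b, p1)
            np.testing.assert_allclose(na.values[na.mask], nb.values[nb.mask], atol=1e-6)

    def test_zero_distance_clamped_not_dropped(self):
        ann = make_annotation(21)
        rng = np.random.default_rng(5)
        traces = [make_trace(np.cumsum(rng.normal(0, 50, (21, 3)), 0), cell=f"c{i}")
                  for i in range(20)]
        coords = traces[0].coords.copy()
        coords[1] = coords[0]  # coincident spots
        traces[0] = traces[0].with_coords(coords)
        mats = [pairwise_distances(t) for t in traces]
        params = fit_separation_params(mats, ann)
        n = normalize(mats[0], params)
        assert n.mask[0, 1] and np.isfinite(n.values[0, 1])
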