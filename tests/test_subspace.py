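"""Subspace tests: PCA recovery, projections, readouts, tuning surfaces."""

import numpy as np
import pytest

from tunespace.dstrf import DSTRFStack
from tunespace.fitting import FitConfig
from tunespace.metrics import signal_correlation
from tunespace.models import DoubleExpParams, double_exponential
from tunespace.subspace import (SubspaceProjection, TuningSubspace,
                                estimate_tuning_surface, fit_subspace_readout,
                                pca_subspace, project_stimulus)
from tunespace.synthetic import gabor_filter, quadrature_pair, subspace_recovery_error


@pytest.fixture
def rng():
    return np.random.default_rng(9)


def make_stack(filters, coefs):
    """Stack d_t = sum_j coefs[t, j] * filters[j]."""
    stacked = np.einsum("tj,jfu->tfu", coefs, filters)
    return DSTRFStack(filters=stacked, times=np.arange(len(coefs)), neuron=0,
                      max_lag=filters.shape[-1])


class TestPCASubspace:
    def test_rank1_stack_yields_single_component_aligned_with_truth(self, rng):
        g = gabor_filter(12, 8)
        coefs = rng.uniform(0.5, 2.0, (50, 1))
        sub = pca_subspace(make_stack(g[None], coefs), 0.90)
        assert sub.n_components == 1
        cos = abs(np.dot(sub.filters[0].ravel(), g.ravel()))
        assert cos >= 1.0 - 1e-10

    def test_two_orthogonal_filters_recover_their_plane(self, rng):
        gs = quadrature_pair(n_channels=12, n_lags=8)
        coefs = rng.standard_normal((200, 2))
        sub = pca_subspace(make_stack(gs, coefs), var_threshold=0.999)
        assert sub.n_components == 2
        angles = subspace_recovery_error(gs, sub)
        assert np.all(angles <= np.rad2deg(1e-6))

    def test_explained_variance_monotone_and_complete(self, rng):
        stack = DSTRFStack(filters=rng.standard_normal((40, 6, 5)),
                           times=np.arange(40), neuron=0, max_lag=5)
        sub = pca_subspace(stack, 0.90)
        ev = sub.explained_variance
        assert np.all(np.diff(ev) >= -1e-12)
        assert ev[-1] == pytest.approx(1.0, abs=1e-10)

    def test_filters_are_orthonormal(self, rng):
        stack = DSTRFStack(filters=rng.standard_normal((40, 6, 5)),
                           times=np.arange(40), neuron=0, max_lag=5)
        sub = pca_subspace(stack, 0.99)
        gram = sub.flat() @ sub.flat().T
        assert np.allclose(gram, np.eye(sub.n_components), atol=1e-8)

    def test_threshold_rule_smallest_inclusive_count(self, rng):
        # construct singular values so 1 component explains exactly 80%
        u = np.linalg.qr(rng.standard_normal((50, 2)))[0]
        filters = np.stack([gabor_filter(10, 6, f0=0.3),
                            gabor_filter(10, 6, f0=0.8, omega_f=0.2)])
        coefs = u * np.array([np.sqrt(0.8), np.sqrt(0.2)])
        sub80 = pca_subspace(make_stack(filters, coefs), var_threshold=0.80)
        assert sub80.n_components == 1
        sub81 = pca_subspace(make_stack(filters, coefs), var_threshold=0.81)
        assert sub81.n_components == 2

    def test_sign_convention_largest_coefficient_positive(self, rng):
        stack = DSTRFStack(filters=rng.standard_normal((30, 5, 4)),
                           times=np.arange(30), neuron=0, max_lag=4)
        sub = pca_subspace(stack, 0.99)
        for comp in sub.flat():
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_all_zero_stack_rejected(self):
        stack = DSTRFStack(filters=np.zeros((10, 4, 3)), times=np.arange(10),
                           neuron=0, max_lag=3)
        with pytest.raises(ValueError, match="degenerate"):
            pca_subspace(stack)


class TestProjection:
    def test_zero_stimulus_zero_projection(self):
        sub = TuningSubspace(filters=np.ones((2, 4, 3)), explained_variance=[1.0])
        proj = project_stimulus(sub, np.zeros((4, 20)))
        assert np.all(proj.x == 0.0)

    def test_additivity(self, rng):
        sub = TuningSubspace(filters=rng.standard_normal((3, 5, 4)),
                             explained_variance=[1.0])
        s1, s2 = rng.standard_normal((2, 5, 30))
        p12 = project_stimulus(sub, s1 + s2).x
        assert np.allclose(p12, project_stimulus(sub, s1).x
                           + project_stimulus(sub, s2).x, atol=1e-10)

    def test_impulse_traces_filter_over_lags(self, rng):
        g = rng.standard_normal((1, 4, 6))
        sub = TuningSubspace(filters=g, explained_variance=[1.0])
        f0, t0 = 2, 10
        s = np.zeros((4, 25))
        s[f0, t0] = 1.0
        x = project_stimulus(sub, s).x[0]
        for t in range(25):
            u = t - t0
            expected = g[0, f0, u] if 0 <= u < 6 else 0.0
            assert x[t] == pytest.approx(expected, abs=1e-12)

    def test_channel_mismatch_raises(self):
        sub = TuningSubspace(filters=np.ones((1, 4, 3)), explained_variance=[1.0])
        with pytest.raises(ValueError, match="channels"):
            project_stimulus(sub, np.zeros((6, 10)))


def _quadrature_projections(rng, T=6000):
    """Projections of a smooth stimulus onto a quadrature pair: a rotating
    phase trajectory with slowly varying envelope."""
    phase = np.cumsum(rng.uniform(0.05, 0.3, T))
    env = 1.0 + 0.8 * np.sin(np.linspace(0, 20 * np.pi, T))
    return np.stack([env * np.cos(phase), env * np.sin(phase)])


class TestReadoutFitting:
    def test_dense_readout_captures_energy_where_affine_cannot(self, rng):
        x = _quadrature_projections(rng)
        p = DoubleExpParams(b=0.05, a=1.0, s=0.0, k=1.0)
        rate = double_exponential(np.sqrt(x[0] ** 2 + x[1] ** 2), p)[None]
        n_fit = 5000
        cfg = FitConfig(n_jackknife=2, n_inits=1, max_epochs=400, seed=1,
                        l2_strength=1e-6)
        dense = fit_subspace_readout(x[:, :n_fit], rate[:, :n_fit], cfg, "dense")
        pred_d = dense.predict(x[:, n_fit:])[0]
        poly1 = fit_subspace_readout(x[:, :n_fit], rate[:, :n_fit], cfg, "poly1")
        pred_1 = poly1.predict(x[:, n_fit:])
        r_dense = signal_correlation(pred_d, rate[0, n_fit:])
        r_poly1 = signal_correlation(pred_1, rate[0, n_fit:])
        assert r_dense >= 0.85
        assert r_poly1 <= 0.4  # symmetric energy response is unreachable affinely

    def test_poly2_on_exactly_quadratic_data(self, rng):
        x = rng.standard_normal((2, 4000))
        rate = (1.5 * x[0] ** 2 + 0.5 * x[1] ** 2 - 0.4 * x[0] * x[1]
                + 0.3 * x[0] + 0.1)[None]
        cfg = FitConfig(n_jackknife=2, n_inits=1, l2_strength=1e-8)
        ro = fit_subspace_readout(x[:, :3000], rate[:, :3000], cfg, "poly2")
        pred = ro.predict(x[:, 3000:])
        assert signal_correlation(pred, rate[0, 3000:]) >= 0.99

    def test_poly1_marginal_curve_is_affine(self, rng):
        # the planar-surface property: an order-1 readout's marginal tuning
        # curve deviates from the best affine fit by ~0 of its range
        from tunespace.metrics import tuning_curve

        x = rng.standard_normal((2, 8000))
        cfg = FitConfig(n_jackknife=2, n_inits=1, l2_strength=1e-12)
        ro = fit_subspace_readout(x[:, :4000], (0.7 * x[0, :4000] + 0.2)[None],
                                  cfg, "poly1")
        pred = ro.predict(x)
        curve = tuning_curve(x[0], pred, n_bins=20)
        # binned means of an affine map are affine in the binned projection
        # means (not the bin centers, which differ in the Gaussian tails)
        xbar = tuning_curve(x[0], x[0], n_bins=20).y
        coeffs = np.polyfit(xbar, curve.y, 1)
        resid = curve.y - np.polyval(coeffs, xbar)
        assert np.max(np.abs(resid)) <= 1e-6 * np.ptp(curve.y)

    def test_empty_subspace_rejected(self):
        with pytest.raises(ValueError):
            fit_subspace_readout(np.zeros((0, 10)), np.zeros((1, 10)))


class TestTuningSurface:
    def test_surface_constant_along_irrelevant_dimension(self, rng):
        x = rng.standard_normal((2, 40000))
        rate = np.tanh(x[0])  # depends only on dim 0
        surf = estimate_tuning_surface(x, rate, dims=(0, 1), n_bins=10)
        occ = surf.occupied
        for row in range(10):  # fixed dim-0 bin: variation along dim 1 ~ noise
            vals = surf.mean_rate[row][occ[row]]
            ses = 1.0 / np.sqrt(surf.occupancy[row][occ[row]])
            if len(vals) > 1:
                assert np.ptp(vals) <= 6 * ses.max() + 0.05

    def test_radial_symmetry_for_energy_rule(self, rng):
        x = _quadrature_projections(rng, T=50000)
        rate = x[0] ** 2 + x[1] ** 2
        surf = estimate_tuning_surface(x, rate, dims=(0, 1), n_bins=15)
        cx, cy = surf.centers
        r2 = cx[:, None] ** 2 + cy[None, :] ** 2
        occ = surf.occupied
        # mean rate should track squared radius on occupied bins
        assert np.corrcoef(surf.mean_rate[occ], r2[occ])[0, 1] > 0.99

    def test_low_occupancy_bins_flagged_empty(self, rng):
        x = rng.standard_normal((1, 300))
        surf = estimate_tuning_surface(x, np.ones(300), dims=0, n_bins=25,
                                       min_occupancy=5)
        assert np.any(~surf.occupied) or np.all(surf.occupancy >= 5)
        assert surf.occupied.dtype == bool

    def test_rate_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            estimate_tuning_surface(np.zeros((1, 10)), np.zeros(5), dims=0)


class TestRecoveryAngles:
    def test_identical_spans_have_zero_angles(self):
        gs = quadrature_pair(n_channels=10, n_lags=8)
        angles = subspace_recovery_error(gs, gs)
        assert np.allclose(angles, 0.0, atol=1e-6)

    def test_orthogonal_complement_gives_ninety(self, rng):
        a = np.zeros((1, 2, 2))
        b = np.zeros((1, 2, 2))
        a[0, 0, 0] = 1.0
        b[0, 1, 1] = 1.0
        assert subspace_recovery_error(a, b)[0] == pytest.approx(90.0, abs=1e-8)

    def test_random_planes_in_high_dimension_near_ninety(self, rng):
        a = rng.standard_normal((2, 20, 20))
        b = rng.standard_normal((2, 20, 20))
        angles = subspace_recovery_error(a, b)
        # svd-based oracle
        qa = np.linalg.qr(a.reshape(2, -1).T)[0]
        qb = np.linalg.qr(b.reshape(2, -1).T)[0]
        sv = np.clip(np.linalg.svd(qa.T @ qb, compute_uv=False), -1, 1)
        oracle = np.rad2deg(np.sort(np.arccos(sv)))
        assert np.allclose(angles, oracle, atol=1e-8)
        assert np.all(angles > 60.0)
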