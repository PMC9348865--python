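import numpy as np
import pytest

import refldesign.fisher as fisher_mod
from refldesign import (
    MeasurementCondition,
    crb_uncertainties,
    fisher_matrix,
    get_sample,
    kinetic_fisher,
    kinetic_series,
    min_eigenvalue,
)
from refldesign.fisher import FisherError, expected_counts_vector, importance_scale
from refldesign.reflectivity import Parameter

from oracles import observed_information_mc


def _cond(time=60.0, **kw):
    return MeasurementCondition(angle=0.7, time=time, n_points=50, **kw)


class TestFisherMatrix:
    def test_one_bin_closed_form(self, background_model, flux):
        """λ linear in θ gives the Poisson closed form FI = Σ (∂λ/∂θ)²/λ = Σc²/(cθ)."""
        cond = _cond()
        res = fisher_matrix(background_model, [cond], flux)
        b = background_model.param("background").value
        lam = expected_counts_vector(background_model, [cond], flux)
        incident = lam / b  # λ_k = incident_k · b exactly (no structural contrast)
        expected = np.sum(incident**2 / lam)
        assert res.raw_matrix[0, 0] == pytest.approx(expected, rel=1e-9)

    def test_linear_in_counting_time(self, one_layer_model, flux):
        g1 = fisher_matrix(one_layer_model, [_cond(time=60.0)], flux).raw_matrix
        g2 = fisher_matrix(one_layer_model, [_cond(time=120.0)], flux).raw_matrix
        np.testing.assert_allclose(g2, 2.0 * g1, rtol=1e-12)

    def test_additive_over_conditions(self, one_layer_model, flux):
        ca, cb = _cond(time=60.0), MeasurementCondition(angle=1.8, time=240.0, n_points=50)
        g_joint = fisher_matrix(one_layer_model, [ca, cb], flux).raw_matrix
        g_a = fisher_matrix(one_layer_model, [ca], flux).raw_matrix
        g_b = fisher_matrix(one_layer_model, [cb], flux).raw_matrix
        np.testing.assert_allclose(g_joint, g_a + g_b, rtol=1e-12)

    def test_matches_mc_expected_hessian(self, one_layer_model, flux):
        """G equals the Monte-Carlo average of the observed information.

        The oracle evaluates −∂² log L analytically in the counts with
        λ-derivatives from its own (finer-step) finite differences,
        averaged over 5 000 Poisson datasets.
        """
        cond = _cond(time=600.0)
        res = fisher_matrix(one_layer_model, [cond], flux)
        params = one_layer_model.varying_parameters()
        lam0 = expected_counts_vector(one_layer_model, [cond], flux)

        def lam_at(dv):
            vals = [p.value for p in params]
            try:
                for p, d in zip(params, dv):
                    p.value += d
                return expected_counts_vector(one_layer_model, [cond], flux)
            finally:
                for p, v in zip(params, vals):
                    p.value = v

        steps = [2e-4 * abs(p.value) for p in params]
        n = len(params)
        grads = np.empty((n, len(lam0)))
        hess = np.empty((n, n, len(lam0)))
        for i in range(n):
            e = np.zeros(n)
            e[i] = steps[i]
            grads[i] = (lam_at(e) - lam_at(-e)) / (2 * steps[i])
            hess[i, i] = (lam_at(e) - 2 * lam0 + lam_at(-e)) / steps[i] ** 2
        e01 = np.array([steps[0], steps[1]])
        mixed = (
            lam_at(e01) - lam_at([steps[0], -steps[1]]) - lam_at([-steps[0], steps[1]]) + lam_at(-e01)
        ) / (4 * steps[0] * steps[1])
        hess[0, 1] = hess[1, 0] = mixed

        rng = np.random.default_rng(123)
        oracle = observed_information_mc(lam0, grads, hess, 5_000, rng)
        np.testing.assert_allclose(res.raw_matrix, oracle, rtol=0.02)

    def test_parameter_order_invariance(self, one_layer_model, flux):
        cond = _cond()
        e1 = fisher_matrix(one_layer_model, [cond], flux).min_eigenvalue
        one_layer_model.parameters.reverse()
        e2 = fisher_matrix(one_layer_model, [cond], flux).min_eigenvalue
        assert e1 == pytest.approx(e2, rel=1e-9)

    def test_step_halving_stability(self, flux):
        """The default finite-difference step is converged on the model zoo."""
        cond_sets = {
            "bilayer_h_tail": [_cond(contrast_sld=6.36), _cond(contrast_sld=-0.56)],
            "monolayer_hdppg": [_cond(contrast_sld=0.0)],
            "yig_pt": [_cond(spin="up"), _cond(spin="down")],
        }
        for name, conds in cond_sets.items():
            model = get_sample(name)
            g1 = fisher_matrix(model, conds, flux).raw_matrix
            old = fisher_mod.REL_STEP
            try:
                fisher_mod.REL_STEP = old / 2.0
                g2 = fisher_matrix(model, conds, flux).raw_matrix
            finally:
                fisher_mod.REL_STEP = old
            scale = np.abs(g1).max()
            assert np.abs(g2 - g1).max() / scale < 1e-3

    def test_requires_varying_parameters(self, one_layer_model, flux):
        for p in one_layer_model.parameters:
            p.varying = False
        with pytest.raises(FisherError):
            fisher_matrix(one_layer_model, [_cond()], flux)

    def test_symmetry_and_psd(self, one_layer_model, flux):
        res = fisher_matrix(one_layer_model, [_cond()], flux)
        np.testing.assert_allclose(res.matrix, res.matrix.T, atol=1e-12 * res.matrix.max())
        assert np.all(res.eigenvalues >= -1e-10)
        assert res.min_eigenvalue == res.eigenvalues[0]


class TestImportanceScaling:
    def test_unit_weights_identity(self):
        g = np.array([[4.0, 1.0], [1.0, 2.0]])
        params = [Parameter("a", 3.0, importance=1.0), Parameter("b", 5.0, importance=1.0)]
        np.testing.assert_array_equal(importance_scale(g, params), g)

    def test_doubling_one_weight(self):
        g = np.array([[4.0, 1.0], [1.0, 2.0]])
        p1 = [Parameter("a", 3.0, importance=1.0), Parameter("b", 5.0, importance=1.0)]
        p2 = [Parameter("a", 3.0, importance=1.0), Parameter("b", 5.0, importance=2.0)]
        s1, s2 = importance_scale(g, p1), importance_scale(g, p2)
        assert s2[1, 1] == pytest.approx(4.0 * s1[1, 1])
        assert s2[0, 1] == pytest.approx(2.0 * s1[0, 1])
        assert s2[0, 0] == pytest.approx(s1[0, 0])

    def test_nonpositive_weight_rejected(self):
        g = np.eye(2)
        params = [Parameter("a", 1.0, importance=-1.0), Parameter("b", 1.0)]
        with pytest.raises(FisherError):
            importance_scale(g, params)

    def test_eigenvalues_match_direct_eigensolve(self, rng):
        a = rng.normal(size=(5, 5))
        g = a @ a.T
        w = rng.uniform(0.5, 2.0, 5)
        params = [Parameter(f"p{i}", 1.0, importance=w[i]) for i in range(5)]
        scaled = importance_scale(g, params)
        direct = np.diag(w) @ g @ np.diag(w)
        np.testing.assert_allclose(np.linalg.eigvalsh(scaled), np.linalg.eigvalsh(direct), rtol=1e-10)


class TestMinEigenvalue:
    def test_known_matrices(self, one_layer_model, flux):
        res = fisher_matrix(one_layer_model, [_cond()], flux)
        res.eigenvalues = np.array([1.0, 1.0])
        assert min_eigenvalue(res) == 1.0
        res.eigenvalues = np.sort(np.linalg.eigvalsh(np.diag([9.0, 4.0])))
        assert min_eigenvalue(res) == 4.0

    def test_against_characteristic_polynomial_roots(self, rng):
        a = rng.normal(size=(5, 5))
        g = a @ a.T
        roots = np.sort(np.roots(np.poly(g)).real)
        eigs = np.sort(np.linalg.eigvalsh(g))
        np.testing.assert_allclose(eigs, roots, rtol=1e-8)


class TestCRB:
    def test_diagonal_closed_form(self, one_layer_model, flux):
        res = fisher_matrix(one_layer_model, [_cond()], flux)
        res.raw_matrix = np.diag([16.0, 25.0])
        res.matrix = np.diag([16.0, 25.0])
        res.eigenvalues = np.array([16.0, 25.0])
        crb = crb_uncertainties(res)
        np.testing.assert_allclose(crb.sigma, [0.25, 0.2])
        assert crb.worst_combination == pytest.approx(0.25)

    def test_time_scaling_law(self, one_layer_model, flux):
        """Time ×100 scales every eigenvalue ×100 and the worst σ by 1/10."""
        r1 = fisher_matrix(one_layer_model, [_cond(time=60.0)], flux)
        r2 = fisher_matrix(one_layer_model, [_cond(time=6000.0)], flux)
        np.testing.assert_allclose(r2.eigenvalues, 100.0 * r1.eigenvalues, rtol=1e-10)
        c1, c2 = crb_uncertainties(r1), crb_uncertainties(r2)
        assert c2.worst_combination == pytest.approx(c1.worst_combination / 10.0, rel=1e-10)

    def test_singular_matrix(self, one_layer_model, flux):
        res = fisher_matrix(one_layer_model, [_cond()], flux)
        res.raw_matrix = np.zeros((2, 2))
        res.matrix = np.zeros((2, 2))
        res.eigenvalues = np.zeros(2)
        crb = crb_uncertainties(res)
        assert np.all(np.isinf(crb.sigma))
        assert np.isinf(crb.worst_combination)


class TestKineticFisher:
    def test_single_snapshot_equals_matrix(self, flux):
        mono = get_sample("monolayer_hdppg")
        cond = _cond(contrast_sld=0.0)
        scalar = kinetic_fisher([mono], cond, flux, "apm")
        matrix = fisher_matrix(mono, [cond], flux).raw_matrix[0, 0]
        assert scalar == pytest.approx(matrix, rel=1e-12)

    def test_two_identical_snapshots_double(self, flux):
        mono = get_sample("monolayer_hdppg")
        cond = _cond(contrast_sld=0.0)
        one = kinetic_fisher([mono], cond, flux, "apm")
        two = kinetic_fisher([mono, mono.copy()], cond, flux, "apm")
        assert two == pytest.approx(2.0 * one, rel=1e-12)

    def test_series_matches_bin_by_bin_summation(self, flux):
        """The 20-snapshot series FI equals an independent hand summation."""
        mono = get_sample("monolayer_hdppg")
        snaps = kinetic_series(mono, 54.1, 500.0, 20)
        cond = _cond(contrast_sld=0.0, time=450.0)
        total = kinetic_fisher(snaps, cond, flux, "apm")
        hand = 0.0
        for snap in snaps:
            p = snap.param("apm")
            h = 1e-3 * p.value
            p.value += h
            hi = expected_counts_vector(snap, [cond], flux)
            p.value -= 2 * h
            lo = expected_counts_vector(snap, [cond], flux)
            p.value += h
            lam = expected_counts_vector(snap, [cond], flux)
            grad = (hi - lo) / (2 * h)
            hand += float(np.sum(grad[lam > 0] ** 2 / lam[lam > 0]))
        assert total == pytest.approx(hand, rel=1e-6)

    def test_empty_sequence_rejected(self, flux):
        with pytest.raises(FisherError):
            kinetic_fisher([], _cond(), flux, "apm")
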