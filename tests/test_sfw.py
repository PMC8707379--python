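import itertools

import numpy as np
import pytest

from offgrid.blasso import BlassoProblem, certificate, energy, sup_certificate
from offgrid.examples import gaussian_problem, hermitian_noise
from offgrid.measures import DiscreteMeasure, tv_norm, unit_torus
from offgrid.sfw import (
    SFWConfig,
    amplitude_lasso_step,
    insertion_step,
    sliding_step,
    solve_sfw,
)


class TestAmplitudeLassoStep:
    def test_zero_data_gives_zero_amplitudes(self, fourier_fixture):
        op, _ = fourier_fixture
        prob = BlassoProblem(op, np.zeros(13, dtype=complex), 1.0)
        a = amplitude_lasso_step(prob, np.array([[0.3]]))
        assert np.all(a == 0.0)

    def test_single_atom_closed_form(self, fourier_noisy):
        """One atom: a* = soft(<y, phi(x0)>_Re, lambda) / ||phi(x0)||^2."""
        prob, _ = fourier_noisy(seed=1)
        x0 = np.array([[0.41]])
        phi = prob.operator.kernel(x0)[0]
        corr = float(np.real(np.vdot(phi, prob.y)))
        norm2 = float(np.real(np.vdot(phi, phi)))
        want = np.sign(corr) * max(abs(corr) - prob.lam, 0.0) / norm2
        a = amplitude_lasso_step(prob, x0)
        assert a[0] == pytest.approx(want, abs=1e-8)

    def test_three_atoms_match_sign_pattern_qp_oracle(self, fourier_noisy):
        """Exhaustive sign-pattern QP with KKT check as independent oracle."""
        prob, _ = fourier_noisy(seed=2)
        pos = np.array([[0.12], [0.47], [0.80]])
        A = prob.operator.kernel(pos)
        G = np.real(A @ np.conj(A.T))
        b = np.real(A @ np.conj(prob.y))
        lam = prob.lam

        def obj(a):
            return 0.5 * a @ G @ a - b @ a + lam * np.sum(np.abs(a))

        best = np.zeros(3)
        # enumerate all sign patterns (including zeros) and solve each
        # smooth restriction; keep the KKT-consistent minimum
        for signs in itertools.product([-1.0, 0.0, 1.0], repeat=3):
            s = np.array(signs)
            active = s != 0
            a = np.zeros(3)
            if np.any(active):
                Ga = G[np.ix_(active, active)]
                rhs = b[active] - lam * s[active]
                try:
                    a[active] = np.linalg.solve(Ga, rhs)
                except np.linalg.LinAlgError:
                    continue
                if np.any(np.sign(a[active]) * s[active] < 0):
                    continue
            grad = G @ a - b
            if np.any(np.abs(grad[~(s != 0)]) > lam + 1e-9):
                continue
            if obj(a) < obj(best):
                best = a
        got = amplitude_lasso_step(prob, pos)
        assert obj(got) == pytest.approx(obj(best), abs=1e-6)

    def test_positivity_clips_negative_atoms(self, fourier_fixture):
        op, _ = fourier_fixture
        truth = DiscreteMeasure(np.array([-1.0]), np.array([[0.5]]), op.domain)
        prob = BlassoProblem(op, op.apply(truth), 0.1, positivity=True)
        a = amplitude_lasso_step(
            prob, np.array([[0.5]]), SFWConfig(positivity=True)
        )
        assert np.all(a >= 0.0)


class TestSlidingStep:
    def test_fixed_point_at_local_minimum(self, fourier_fixture):
        op, truth = fourier_fixture
        y = op.apply(truth)
        prob = BlassoProblem(op, y, 1.0)
        m0 = solve_sfw(prob).measure
        e0 = energy(prob, m0)
        m1 = sliding_step(prob, m0)
        assert e0 - energy(prob, m1) < 1e-10
        assert e0 - energy(prob, m1) >= -1e-12

    def test_recovers_noiseless_spike_from_perturbed_start(self, fourier_fixture):
        op, _ = fourier_fixture
        truth = DiscreteMeasure(np.array([1.0]), np.array([[0.3]]), op.domain)
        prob = BlassoProblem(op, op.apply(truth), 1e-8)
        start = DiscreteMeasure(np.array([0.9]), np.array([[0.3 + 0.025]]), op.domain)
        out = sliding_step(prob, start)
        assert abs(out.positions[0, 0] - 0.3) < 1e-6

    def test_never_increases_energy(self, fourier_fixture, rng):
        op, _ = fourier_fixture
        for _ in range(10):
            truth = DiscreteMeasure(rng.normal(size=3), rng.random((3, 1)), op.domain)
            y = op.apply(truth) + hermitian_noise(rng, 13, 0.05)
            prob = BlassoProblem(op, y, 0.5)
            start = DiscreteMeasure(
                rng.normal(size=3), rng.random((3, 1)), op.domain
            )
            assert energy(prob, sliding_step(prob, start)) <= energy(prob, start) + 1e-12


class TestInsertionStep:
    def test_stop_when_lambda_dominates(self, fourier_fixture):
        op, truth = fourier_fixture
        y = op.apply(truth)
        prob = BlassoProblem(op, y, 100.0)
        x, val = insertion_step(prob, DiscreteMeasure.empty(op.domain), SFWConfig())
        assert x is None and val <= 1.0 + 1e-4

    def test_candidate_near_true_position(self, fourier_fixture):
        op, _ = fourier_fixture
        truth = DiscreteMeasure(np.array([1.0]), np.array([[0.62]]), op.domain)
        prob = BlassoProblem(op, op.apply(truth), 1.0)
        x, _ = insertion_step(prob, DiscreteMeasure.empty(op.domain), SFWConfig())
        assert abs(x[0] - 0.62) < 1e-3

    def test_stop_is_a_fixed_point(self, fourier_noisy):
        prob, _ = fourier_noisy(seed=7)
        res = solve_sfw(prob)
        assert res.stop_reason == "optimality"
        x, _ = insertion_step(prob, res.measure, SFWConfig())
        assert x is None


class TestSolveSFW:
    def test_three_spike_fourier_count(self, fourier_noisy):
        prob, truth = fourier_noisy(seed=0)
        res = solve_sfw(prob)
        assert len(res.measure) == 3

    def test_zero_data_returns_empty_optimal(self, fourier_fixture):
        op, _ = fourier_fixture
        prob = BlassoProblem(op, np.zeros(13, dtype=complex), 1.0)
        res = solve_sfw(prob)
        assert len(res.measure) == 0 and res.stop_reason == "optimality"

    def test_energy_trace_non_increasing(self, fourier_noisy):
        prob, _ = fourier_noisy(seed=8)
        res = solve_sfw(prob)
        assert np.all(np.diff(res.energy_trace) <= 1e-12)

    def test_result_invariants(self, fourier_noisy):
        prob, _ = fourier_noisy(seed=9)
        cfg = SFWConfig()
        res = solve_sfw(prob, cfg)
        if res.stop_reason == "optimality":
            assert res.cert_sup_trace[-1] <= 1.0 + cfg.stop_tol

    def test_gaussian_three_sources_finish_at_iterate_two(self):
        prob, truth = gaussian_problem(seed=0)
        res = solve_sfw(prob)
        assert len(res.measure) == 3
        assert res.last_insertion_iter == 2  # one insertion per source

    @pytest.mark.parametrize("n_spikes", [1, 2, 3, 4])
    def test_empirical_n_step_convergence(self, fourier_fixture, n_spikes):
        """Well-separated noiseless positive instances finish in exactly N
        insertions (positive measures carry no separation condition)."""
        op, _ = fourier_fixture
        pos = (np.arange(n_spikes) / n_spikes + 0.05)[:, None]
        amps = np.array([1.0, 0.8, 0.9, 1.1][:n_spikes])
        truth = DiscreteMeasure(amps, pos, op.domain)
        prob = BlassoProblem(op, op.apply(truth), 0.5, positivity=True)
        res = solve_sfw(prob)
        assert len(res.measure) == n_spikes
        assert res.n_outer_iters == n_spikes

    def test_noise_robustness_scaling(self, fourier_fixture, rng):
        """Position error scales linearly with the noise norm (lambda ~ ||w||)."""
        op, truth = fourier_fixture
        y0 = op.apply(truth)
        w0 = hermitian_noise(rng, 13, 0.08)
        errors, norms = [], []
        for div in [1.0, 2.0, 4.0, 8.0]:
            w = w0 / div
            lam = 3.0 * float(np.linalg.norm(w))
            res = solve_sfw(BlassoProblem(op, y0 + w, lam))
            assert len(res.measure) == 3
            got = np.sort(res.measure.positions[:, 0])
            want = np.sort(truth.positions[:, 0])
            errors.append(np.max(np.abs(got - want)))
            norms.append(np.linalg.norm(w))
        slope = np.polyfit(np.log(norms), np.log(errors), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.3)

    def test_gridless_dominates_fine_grid_lasso(self, fourier_noisy):
        """BLASSO optimum <= LASSO optimum on a 256-node grid of the torus."""
        prob, _ = fourier_noisy(seed=10)
        res = solve_sfw(prob)
        grid = np.arange(256)[:, None] / 256.0
        a = amplitude_lasso_step(prob, grid, SFWConfig(fista_max_iters=5000))
        lasso_m = DiscreteMeasure(a, grid, prob.operator.domain)
        assert energy(prob, res.measure) <= energy(prob, lasso_m) + 1e-9

    def test_solver_certificate_feasible_at_stop(self, fourier_noisy):
        prob, _ = fourier_noisy(seed=11)
        cfg = SFWConfig()
        res = solve_sfw(prob, cfg)
        val, _ = sup_certificate(certificate(prob, res.measure))
        assert val <= 1.0 + 10 * cfg.stop_tol
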