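import numpy as np
import pytest
from scipy import optimize, sparse
from scipy.stats import wasserstein_distance

from offgrid.measures import DiscreteMeasure, Domain, tv_norm, unit_torus
from offgrid.metrics import MetricConfig, flat_metric, jaccard_index, wasserstein1


def primal_flat_lp(m1, m2, tau):
    """Independent oracle: transport-with-creation LP.

    Move mass from the positive part to the negative part of c = m1 - m2 at
    cost min(dist, 2 tau) per unit, destroy/create the rest at tau per unit.
    """
    pts = np.vstack([m1.positions, m2.positions])
    c = np.concatenate([m1.amplitudes, -m2.amplitudes])
    pos_i = np.flatnonzero(c > 0)
    neg_i = np.flatnonzero(c < 0)
    mass_p, mass_n = c[pos_i], -c[neg_i]
    if pos_i.size == 0 or neg_i.size == 0:
        return tau * (mass_p.sum() + mass_n.sum())
    D = m1.domain.pairwise_distances(pts[pos_i], pts[neg_i])
    cost = np.minimum(D, 2 * tau).ravel()
    n, m = D.shape
    rows, cols, vals = [], [], []
    for i in range(n):
        rows += [i] * m
        cols += list(i * m + np.arange(m))
        vals += [1.0] * m
    for j in range(m):
        rows += [n + j] * n
        cols += list(j + m * np.arange(n))
        vals += [1.0] * n
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(n + m, n * m))
    b = np.concatenate([mass_p, mass_n])
    # objective: transport cost minus the creation cost saved per moved unit
    res = optimize.linprog(
        cost - 2 * tau, A_ub=A, b_ub=b, bounds=(0, None), method="highs"
    )
    assert res.success
    return tau * (mass_p.sum() + mass_n.sum()) + res.fun


def random_measure(rng, domain, n, signed=True):
    a = rng.normal(size=n) if signed else rng.random(n) + 0.1
    return DiscreteMeasure(a, rng.random((n, domain.d)) * domain.widths, domain)


@pytest.fixture
def cfg():
    return MetricConfig(tau=0.3, radius=0.1)


class TestFlatMetric:
    def test_identical_measures_give_zero(self, line_domain, rng, cfg):
        m = random_measure(rng, line_domain, 4)
        assert flat_metric(m, m, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_single_dirac_against_zero_costs_tau_times_mass(self, line_domain, cfg):
        for a in (0.7, -1.3):
            m = DiscreteMeasure(np.array([a]), np.array([[0.4]]), line_domain)
            zero = DiscreteMeasure.empty(line_domain)
            assert flat_metric(m, zero, cfg) == pytest.approx(cfg.tau * abs(a))

    @pytest.mark.parametrize("d,tau", [(0.25, 0.05), (0.25, 0.3), (0.6, 0.2)])
    def test_two_equal_spikes_transport_vs_creation(self, line_domain, d, tau):
        """d_tau = a * min(d, 2 tau): move when cheap, destroy/create else."""
        a = 0.8
        m1 = DiscreteMeasure(np.array([a]), np.array([[0.2]]), line_domain)
        m2 = DiscreteMeasure(np.array([a]), np.array([[0.2 + d]]), line_domain)
        got = flat_metric(m1, m2, MetricConfig(tau=tau, radius=0.1))
        assert got == pytest.approx(a * min(d, 2 * tau), abs=1e-9)

    def test_dual_lp_equals_primal_transport_lp(self, rng):
        dom = Domain(bounds=((0.0, 1.0), (0.0, 1.0)))
        for _ in range(5):
            m1 = random_measure(rng, dom, rng.integers(1, 6))
            m2 = random_measure(rng, dom, rng.integers(1, 6))
            tau = float(rng.random() * 0.5 + 0.05)
            got = flat_metric(m1, m2, MetricConfig(tau=tau, radius=0.1))
            want = primal_flat_lp(m1, m2, tau)
            assert got == pytest.approx(want, abs=1e-8)

    def test_small_tau_limit_is_tau_times_tv(self, line_domain, rng):
        m1 = random_measure(rng, line_domain, 3)
        m2 = random_measure(rng, line_domain, 2)
        # below half the minimum pairwise separation, no transport happens
        tau = 1e-3
        got = flat_metric(m1, m2, MetricConfig(tau=tau, radius=0.1))
        assert got == pytest.approx(tau * tv_norm(m1 - m2), abs=1e-10)

    def test_large_tau_limit_is_wasserstein1(self, line_domain, rng):
        a = rng.random(4) + 0.1
        m1 = DiscreteMeasure(a, rng.random((4, 1)), line_domain)
        m2 = DiscreteMeasure(
            a[rng.permutation(4)], rng.random((4, 1)), line_domain
        )
        got = flat_metric(m1, m2, MetricConfig(tau=2.0, radius=0.1))  # tau > diameter
        assert got == pytest.approx(wasserstein1(m1, m2), abs=1e-8)

    def test_symmetry_and_triangle_inequality(self, line_domain, rng, cfg):
        ms = [random_measure(rng, line_domain, 3) for _ in range(3)]
        d01 = flat_metric(ms[0], ms[1], cfg)
        d10 = flat_metric(ms[1], ms[0], cfg)
        assert d01 == pytest.approx(d10, abs=1e-10)
        d02 = flat_metric(ms[0], ms[2], cfg)
        d12 = flat_metric(ms[1], ms[2], cfg)
        assert d02 <= d01 + d12 + 1e-8

    def test_box_feasibility_upper_bound(self, line_domain, rng, cfg):
        m1 = random_measure(rng, line_domain, 5)
        m2 = random_measure(rng, line_domain, 4)
        assert flat_metric(m1, m2, cfg) <= cfg.tau * tv_norm(m1 - m2) + 1e-10

    def test_torus_ground_distance_wraps(self):
        dom = unit_torus(1)
        m1 = DiscreteMeasure(np.array([1.0]), np.array([[0.02]]), dom)
        m2 = DiscreteMeasure(np.array([1.0]), np.array([[0.97]]), dom)
        got = flat_metric(m1, m2, MetricConfig(tau=0.4, radius=0.1))
        assert got == pytest.approx(0.05, abs=1e-9)


class TestWasserstein1:
    def test_identical_measures(self, line_domain, rng):
        m = random_measure(rng, line_domain, 4, signed=False)
        assert wasserstein1(m, m) == pytest.approx(0.0, abs=1e-12)

    def test_two_unit_diracs_transport_distance(self, line_domain):
        m1 = DiscreteMeasure(np.array([1.0]), np.array([[0.1]]), line_domain)
        m2 = DiscreteMeasure(np.array([1.0]), np.array([[0.8]]), line_domain)
        assert wasserstein1(m1, m2) == pytest.approx(0.7)

    def test_matches_sorted_quantile_formula_in_1d(self, line_domain, rng):
        for _ in range(5):
            x1, x2 = rng.random(5), rng.random(5)
            w1 = rng.random(5) + 0.1
            w2 = rng.random(5) + 0.1
            w2 *= w1.sum() / w2.sum()
            m1 = DiscreteMeasure(w1, x1[:, None], line_domain)
            m2 = DiscreteMeasure(w2, x2[:, None], line_domain)
            # scipy computes the distance between normalized distributions
            want = wasserstein_distance(x1, x2, w1, w2) * w1.sum()
            assert wasserstein1(m1, m2) == pytest.approx(want, abs=1e-9)

    def test_unequal_masses_rejected(self, line_domain):
        m1 = DiscreteMeasure(np.array([1.0]), np.array([[0.1]]), line_domain)
        m2 = DiscreteMeasure(np.array([2.0]), np.array([[0.8]]), line_domain)
        with pytest.raises(ValueError, match="flat_metric"):
            wasserstein1(m1, m2)

    def test_negative_amplitudes_rejected(self, line_domain):
        m1 = DiscreteMeasure(np.array([-1.0]), np.array([[0.1]]), line_domain)
        with pytest.raises(ValueError):
            wasserstein1(m1, m1)

    def test_invariant_under_spike_relabeling(self, line_domain, rng):
        w = rng.random(6) + 0.1
        x = rng.random((6, 1))
        m1 = DiscreteMeasure(w, x, line_domain)
        perm = rng.permutation(6)
        m1p = DiscreteMeasure(w[perm], x[perm], line_domain)
        m2 = random_measure(rng, line_domain, 3, signed=False)
        m2 = m2.scaled(w.sum() / tv_norm(m2))
        assert wasserstein1(m1, m2) == pytest.approx(wasserstein1(m1p, m2), abs=1e-10)


class TestJaccard:
    def test_perfect_prediction_scores_one(self, rng):
        pts = rng.random((5, 2))
        assert jaccard_index(pts, pts, radius=0.01) == 1.0

    def test_disjoint_sets_score_zero(self):
        p = np.zeros((3, 2))
        g = np.full((3, 2), 10.0)
        assert jaccard_index(p, g, radius=0.5) == 0.0

    def test_two_of_three_matchable(self):
        g = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        p = np.array([[0.05, 0.0], [1.02, 0.0], [7.0, 0.0]])
        # TP=2, FP=1, FN=1 -> 2/4
        assert jaccard_index(p, g, radius=0.1) == pytest.approx(0.5)

    def test_optimal_assignment_beats_greedy(self):
        # greedy matching of p0 to g0 would strand p1; optimal pairs both
        g = np.array([[0.0, 0.0], [1.0, 0.0]])
        p = np.array([[0.6, 0.0], [1.4, 0.0]])
        j, counts = jaccard_index(p, g, radius=1.0, return_counts=True)
        assert counts["TP"] == 2 and j == 1.0

    def test_empty_prediction(self):
        g = np.zeros((2, 2))
        assert jaccard_index(np.zeros((0, 2)), g, radius=1.0) == 0.0

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            jaccard_index(np.zeros((1, 2)), np.zeros((1, 2)), radius=0.0)
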