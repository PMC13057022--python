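import numpy as np
import pytest

from sushibelt import (
    build_rate_matrix,
    degradation_rates,
    detachment_rates,
    edge_rates,
    half_life,
    simulate,
    trafficking_demand,
)
from sushibelt.model import DAY_S, RateSet, full_generator

from conftest import make_cable, make_y_tree


# ---------------------------------------------------------------------------
# Demand mixing and rates

def test_trafficking_demand_limits_and_mixing():
    u_star = np.array([0.8, 0.2])
    assert np.allclose(trafficking_demand(u_star, 0.0), [0.5, 0.5])   # DDD
    assert np.allclose(trafficking_demand(u_star, 1.0), u_star)       # DDT
    assert np.allclose(trafficking_demand(u_star, 0.5), [0.65, 0.35])
    assert trafficking_demand(u_star, 0.3).sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        trafficking_demand(u_star, 1.2)


def test_edge_rates_match_demand_ratio():
    tree = make_cable(1)
    a, b = edge_rates(tree, np.array([0.5, 0.5]), 1.0)
    assert a[0] == pytest.approx(0.5) and b[0] == pytest.approx(0.5)
    a, b = edge_rates(tree, np.array([0.25, 0.75]), 1.0)
    assert a[0] == pytest.approx(0.75) and b[0] == pytest.approx(0.25)
    assert b[0] / a[0] == pytest.approx(1.0 / 3.0)
    with pytest.raises(ValueError):
        edge_rates(tree, np.array([0.0, 1.0]), 1.0)


def test_edge_rate_properties_on_random_demands():
    tree = make_cable(9)
    rng = np.random.default_rng(0)
    u = rng.random(10) + 0.05
    u /= u.sum()
    a, b = edge_rates(tree, u, 2.5)
    e = tree.edges()
    assert np.allclose(a + b, 2.5)
    assert np.allclose(b / a, u[e[:, 0]] / u[e[:, 1]], rtol=1e-12)


def test_f_zero_gives_uniform_traffic():
    tree = make_cable(9)
    u_star = np.random.default_rng(1).dirichlet(np.ones(10))
    a, b = edge_rates(tree, trafficking_demand(u_star, 0.0), 1e-2)
    assert np.all(a == b)  # exact: uniform ũ makes every edge symmetric


def test_detachment_limits():
    u_star = np.random.default_rng(2).dirichlet(np.ones(8))
    c1 = detachment_rates(u_star, 1.0, 4.38e-06)
    assert np.allclose(c1, 4.38e-06)       # pure DDT: uniform detachment
    c0 = detachment_rates(u_star, 0.0, 2.0)
    assert np.allclose(c0, 2.0 * 8 * u_star)
    # uniform demand: detachment is Ctau for any F
    cu = detachment_rates(np.full(8, 1 / 8), 0.8861, 4.38e-06)
    assert np.allclose(cu, 4.38e-06)


def test_detachment_zero_over_zero_is_zero_with_warning():
    with pytest.warns(UserWarning, match="zero demand"):
        c = detachment_rates(np.array([1.0, 0.0]), 1.0, 3.0)
    assert c[1] == 0.0


def test_degradation_linear_model():
    assert np.allclose(degradation_rates(2e-6, 0.0, np.ones(4)), 2e-6)
    # slope term eighteen decades below the intercept is negligible
    d = degradation_rates(1.837e-06, 1.002e-18, np.array([0.773]))
    assert d[0] == pytest.approx(1.837e-06, rel=1e-9)
    d = degradation_rates(1.63e-06, 9.57e-08, np.array([0.999]))
    assert d[0] == pytest.approx(1.7256e-06, rel=1e-4)


# ---------------------------------------------------------------------------
# Matrix assembly

def test_two_compartment_matrix_stencil():
    tree = make_cable(1)
    rates = RateSet(a=np.array([2.0]), b=np.array([1.0]),
                    c=np.zeros(2), d=np.zeros(2))
    A = build_rate_matrix(tree, rates)
    assert np.allclose(A, [[-2.0, 1.0], [2.0, -1.0]])
    assert np.allclose(A.sum(axis=0), 0.0)


def test_column_sums_equal_minus_detachment():
    tree = make_y_tree()
    rng = np.random.default_rng(3)
    rates = RateSet(a=rng.random(3), b=rng.random(3), c=rng.random(4),
                    d=np.zeros(4))
    A = build_rate_matrix(tree, rates)
    assert np.allclose(A.sum(axis=0), -rates.c)


def test_branch_point_breaks_tridiagonality():
    tree = make_y_tree()
    rates = RateSet(a=np.ones(3), b=np.ones(3), c=np.zeros(4), d=np.zeros(4))
    A = build_rate_matrix(tree, rates)
    # node 1 feeds both children 2 and 3: two off-diagonal pairs in its row
    assert A[1, 2] != 0 and A[1, 3] != 0
    assert A[3, 1] != 0  # |i-j| = 2: not tridiagonal
    with pytest.raises(ValueError):
        build_rate_matrix(tree, RateSet(a=np.ones(2), b=np.ones(2),
                                        c=np.zeros(4), d=np.zeros(4)))


def brute_force_rhs(tree, rates, u):
    """Per-compartment mass balance evaluated edge by edge."""
    du = -rates.c * u
    for k, (i, j) in enumerate(tree.edges()):
        du[j] += rates.a[k] * u[i] - rates.b[k] * u[j]
        du[i] += rates.b[k] * u[j] - rates.a[k] * u[i]
    return du


@pytest.mark.parametrize("seed", range(5))
def test_matrix_matches_brute_force_on_random_trees(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 9))
    parent = np.array([-1] + [int(rng.integers(0, i)) for i in range(1, n)])
    tip = rng.random((n, 3)) * 50
    from sushibelt import CompartmentTree

    tree = CompartmentTree(parent, np.full(n, 5.0), tip)
    rates = RateSet(a=rng.random(n - 1), b=rng.random(n - 1),
                    c=rng.random(n), d=np.zeros(n))
    A = build_rate_matrix(tree, rates)
    u = rng.random(n)
    assert np.allclose(A @ u, brute_force_rhs(tree, rates, u), atol=1e-12)


# ---------------------------------------------------------------------------
# Integration

def run_cable(n, a, b, c, d, u0, us0, t_end, method="expm", nt=5):
    tree = make_cable(n - 1)
    rates = RateSet(a=np.full(n - 1, a), b=np.full(n - 1, b),
                    c=np.full(n, c), d=np.full(n, d))
    A = build_rate_matrix(tree, rates)
    t = np.linspace(0, t_end, nt)
    return simulate(A, rates.c, rates.d, u0, us0, t, method=method)


@pytest.mark.parametrize("method", ["expm", "bdf"])
def test_cargo_conservation_without_sinks(method):
    rng = np.random.default_rng(4)
    u0 = rng.random(6)
    traj = run_cable(6, a=3e-3, b=7e-3, c=0.0, d=0.0, u0=u0,
                     us0=np.zeros(6), t_end=7 * DAY_S, method=method)
    assert np.allclose(traj.u.sum(axis=1), u0.sum(), rtol=1e-9)
    assert np.all(traj.u >= 0) and np.all(traj.u_star >= 0)


@pytest.mark.parametrize("method", ["expm", "bdf"])
def test_single_compartment_closed_form(method):
    c, t_end = 3e-6, 7 * DAY_S
    tree = make_cable(0)
    A = build_rate_matrix(tree, RateSet(a=np.zeros(0), b=np.zeros(0),
                                        c=np.array([c]), d=np.zeros(1)))
    t = np.linspace(0, t_end, 4)
    traj = simulate(A, np.array([c]), np.zeros(1), np.array([2.0]),
                    np.array([0.5]), t, method=method)
    assert np.allclose(traj.u[:, 0], 2.0 * np.exp(-c * t), rtol=1e-6)
    assert np.allclose(traj.u_star[:, 0], 0.5 + 2.0 * (1 - np.exp(-c * t)),
                       rtol=1e-6)


@pytest.mark.parametrize("method", ["expm", "bdf"])
def test_two_pool_closed_form_with_degradation(method):
    """Detachment + degradation, no transport: analytic two-pool solution."""
    c, d, u0, us0 = 4e-6, 1.5e-6, 1.3, 0.4
    t = np.linspace(0, 7 * DAY_S, 4)
    traj = run_cable(1, a=0, b=0, c=c, d=d, u0=np.array([u0]),
                     us0=np.array([us0]), t_end=t[-1], method=method, nt=4)
    expect = us0 * np.exp(-d * t) + u0 * c / (d - c) * (
        np.exp(-c * t) - np.exp(-d * t))
    assert np.allclose(traj.u_star[:, 0], expect, rtol=1e-6)


def test_expm_and_bdf_agree_on_full_model():
    rng = np.random.default_rng(5)
    u0, us0 = rng.random(5) / 10, rng.random(5) / 10
    kw = dict(a=5e-3, b=5e-3, c=4e-6, d=2e-6, u0=u0, us0=us0,
              t_end=7 * DAY_S)
    te = run_cable(5, **kw, method="expm")
    tb = run_cable(5, **kw, method="bdf")
    assert np.allclose(te.u_star[-1], tb.u_star[-1], rtol=1e-5)


def test_two_compartment_steady_state_ratio():
    """Closed two-compartment belt settles at u1/u2 = b/a."""
    a, b = 6e-3, 2e-3
    traj = run_cable(2, a=a, b=b, c=0.0, d=0.0,
                     u0=np.array([1.0, 0.0]), us0=np.zeros(2),
                     t_end=50 / a, nt=3)
    assert traj.u[-1, 0] / traj.u[-1, 1] == pytest.approx(b / a, rel=1e-6)


def test_quasi_steady_state_edge_ratios():
    """With k_traffic >> c the cargo profile matches b/a per edge within 1%."""
    n = 10
    rng = np.random.default_rng(6)
    u_tilde = rng.dirichlet(np.ones(n)) + 0.02
    u_tilde /= u_tilde.sum()
    tree = make_cable(n - 1)
    c = 4e-6
    k = 1e4 * c * 10  # k_traffic >= 1e4 * max(c)
    a, b = edge_rates(tree, u_tilde, k)
    rates = RateSet(a=a, b=b, c=np.full(n, c), d=np.zeros(n))
    A = build_rate_matrix(tree, rates)
    t = np.array([0.0, 30 * DAY_S])
    traj = simulate(A, rates.c, rates.d, np.full(n, 1.0 / n), np.zeros(n), t)
    u = traj.u[-1]
    e = tree.edges()
    ratio = u[e[:, 0]] / u[e[:, 1]]
    assert np.allclose(ratio, b / a, rtol=0.01)


def test_demand_matching_detached_distribution():
    """DDT with uniform c, d=0: detached pool converges to ũ* (TV <= 2%)."""
    n = 10
    u_star = np.linspace(1, 3, n)
    u_star /= u_star.sum()
    tree = make_cable(n - 1)
    c = 4e-6
    a, b = edge_rates(tree, trafficking_demand(u_star, 1.0), 1e-2)
    rates = RateSet(a=a, b=b, c=np.full(n, c), d=np.zeros(n))
    A = build_rate_matrix(tree, rates)
    t = np.array([0.0, 3000 / c])
    traj = simulate(A, rates.c, rates.d, np.full(n, 1.0 / n), np.zeros(n), t)
    dist = traj.u_star[-1] / traj.u_star[-1].sum()
    assert 0.5 * np.abs(dist - u_star).sum() <= 0.02


def test_simulate_rejects_bad_grid():
    tree = make_cable(1)
    A = build_rate_matrix(tree, RateSet(a=np.ones(1), b=np.ones(1),
                                        c=np.zeros(2), d=np.zeros(2)))
    with pytest.raises(ValueError):
        simulate(A, np.zeros(2), np.zeros(2), np.ones(2), np.ones(2),
                 np.array([1.0, 2.0]))


# ---------------------------------------------------------------------------
# Half-life

def test_half_life_values():
    assert half_life(np.log(2) / DAY_S) == pytest.approx(1.0)
    assert half_life(1.837e-06) == pytest.approx(4.365, rel=0.01)
    assert half_life(4.6e-06) == pytest.approx(1.74, rel=0.01)
    with pytest.raises(ValueError):
        half_life(0.0)
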