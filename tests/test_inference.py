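import numpy as np
import pytest
from dataclasses import replace

from sushibelt import (
    FitConfig,
    FreeParameter,
    ModelParameters,
    SynthSpec,
    fit,
    make_dataset,
    recovery_experiment,
    refit_degradation,
    version_config,
)
from sushibelt.inference import _ga, _nelder_mead, _pso
from sushibelt.synthetic import CA1_WINDOW_DISTANCES

from conftest import simple_table


class Sphere:
    """Quadratic bowl standing in for the model objective."""

    def __init__(self, dim, lo=-5.0, hi=5.0):
        self.z_lo = np.full(dim, lo)
        self.z_hi = np.full(dim, hi)
        self.centre = np.linspace(-1, 1, dim)
        self.n_evals = 0

    def __call__(self, z):
        self.n_evals += 1
        return float(np.sum((z - self.centre) ** 2))


def hybrid_minimize(obj, cfg):
    ss = np.random.SeedSequence(cfg.seed)
    r1, r2 = [np.random.default_rng(s) for s in ss.spawn(2)]
    seeds, costs, _ = _pso(obj, cfg, r1)
    z, f, trace = _ga(obj, cfg, r2, seeds, costs)
    z, f = _nelder_mead(obj, z, f, 300)
    return z, f, trace


def test_hybrid_schedule_finds_sphere_minimum():
    cfg = FitConfig(free=[FreeParameter("demand", (1e-7, 1.0), (f"w{i}",))
                          for i in range(5)],
                    pso_rounds=20, ga_rounds=60, nm_every=10, nm_iters=100,
                    seed=3)
    obj = Sphere(5)
    z, f, trace = hybrid_minimize(obj, cfg)
    assert f <= 1e-6
    assert np.allclose(z, obj.centre, atol=1e-3)
    # best-so-far trace is non-increasing
    assert all(b <= a + 1e-15 for a, b in zip(trace, trace[1:]))


def test_nelder_mead_never_worsens():
    obj = Sphere(3)
    z0 = np.array([4.0, 4.0, 4.0])
    f0 = obj(z0)
    z, f = _nelder_mead(obj, z0, f0, 5)   # tiny budget
    assert f <= f0


# ---------------------------------------------------------------------------
# Full fits on synthetic data (reduced budgets)

QUICK = dict(pso_rounds=6, ga_rounds=40, nm_every=10, nm_iters=60)


@pytest.fixture()
def small_spec():
    truth = ModelParameters(F=0.7, Ctau=4e-06, mProp=0.35, dvA=2e-06,
                            dvB=0.0)
    return SynthSpec(kind="cable", n_windows=8, comps_per_window=2,
                     demand="u-shaped", truth=truth, noise_sd=0.0, seed=3)


def test_single_parameter_recovery_noiseless(small_spec):
    cfg = FitConfig(free=[FreeParameter("mProp", (0.0, 1.0))], seed=5, **QUICK)
    rep = recovery_experiment(small_spec, cfg)
    assert rep["relative_error"]["mProp"] <= 0.05
    assert rep["cost"] <= 1e-8


def test_fit_is_bit_reproducible(small_spec):
    tree, table, truth = make_dataset(small_spec)
    cfg = FitConfig(free=[FreeParameter("F", (0.0, 1.0)),
                          FreeParameter("mProp", (0.0, 1.0))],
                    seed=17, **QUICK)
    r1 = fit(cfg, table, tree, truth)
    r2 = fit(cfg, table, tree, truth)
    assert r1.values == r2.values
    assert r1.trace == r2.trace
    assert r1.cost == r2.cost
    assert r1.to_json() == r2.to_json()


def test_truth_is_global_minimum_on_self_generated_data(small_spec):
    """Data equal to the model's own prediction: cost at truth ~ 0, below
    every random start."""
    tree, table, truth = make_dataset(small_spec)
    free = [FreeParameter("F", (0.0, 1.0)), FreeParameter("Ctau", (1e-8, 1e-4))]
    from sushibelt.inference import Objective

    obj = Objective(truth, free, tree, table)
    z_truth = np.array([free[0].to_z(truth.F), free[1].to_z(truth.Ctau)])
    f_truth = obj(z_truth)
    assert f_truth <= 1e-10
    rng = np.random.default_rng(0)
    for _ in range(20):
        z = obj.z_lo + rng.random(2) * (obj.z_hi - obj.z_lo)
        assert f_truth <= obj(z) + 1e-15


def test_refit_degradation_moves_only_intercept(small_spec):
    """Data regenerated with dvA tripled: degradation-only refit recovers it."""
    tree, table, truth = make_dataset(small_spec)
    cfg = FitConfig(free=[FreeParameter("mProp", (0.0, 1.0))], seed=2, **QUICK)
    base = fit(cfg, table, tree, truth)

    spec3 = replace(small_spec, truth=replace(small_spec.truth,
                                              dvA=3 * small_spec.truth.dvA))
    _, table3, truth3 = make_dataset(spec3)
    refit = refit_degradation(base, table3, tree, linear=False, seed=4,
                              budget=QUICK)
    assert refit.params.dvA == pytest.approx(truth3.dvA, rel=0.10)
    assert refit.params.F == base.params.F          # frozen
    assert refit.params.demand == base.params.demand


def test_refit_on_own_prediction_keeps_degradation(small_spec):
    tree, table, truth = make_dataset(small_spec)
    cfg = FitConfig(free=[FreeParameter("dvA", (1e-8, 1e-4))], seed=9, **QUICK)
    base = fit(cfg, table, tree, truth)
    assert base.params.dvA == pytest.approx(truth.dvA, rel=0.02)
    assert base.cost <= 1e-9


# ---------------------------------------------------------------------------
# Model versions and config validation

def ca1_style_table():
    names = list(CA1_WINDOW_DISTANCES)
    return simple_table(20).assign(name=names)


def test_version_parameter_counts():
    table = ca1_style_table()
    assert version_config(1, table).n_par == 7     # 3 demands + dv + 3 shared
    assert version_config(2, table).n_par == 9     # + per-region degradation
    assert version_config(3, table).n_par == 25    # 20 demands + dvA/dvB + 3
    with pytest.raises(ValueError):
        version_config(4, table)


def test_population_sizes_follow_rules():
    table = ca1_style_table()
    cfg = version_config(1, table)
    assert cfg.n_pso == max(15, 5 * 7) == 35
    assert cfg.n_ga == 14
    one = FitConfig(free=[FreeParameter("F", (0.0, 1.0))])
    assert one.n_pso == 15 and one.n_ga == 6


def test_free_parameter_validation():
    with pytest.raises(ValueError):
        FreeParameter("Ctau", (0.0, 1e-3))            # log of 0
    with pytest.raises(ValueError):
        FreeParameter("F", (-0.2, 0.5))               # outside [0,1]
    with pytest.raises(ValueError):
        FreeParameter("demand", (1e-9, 1.0))          # below the floor
    with pytest.raises(ValueError):
        FitConfig(free=[FreeParameter("F", (0.0, 1.0))] * 2)  # duplicate
    with pytest.raises(ValueError):
        FitConfig(free=[FreeParameter("F", (0.0, 1.0))], pso_rounds=0,
                  ga_rounds=0)
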