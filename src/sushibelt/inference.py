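"""Hybrid global/local parameter fitting for the trafficking model.

The fitting schedule is: particle-swarm optimisation (PSO) for a fast sweep
of the box, a real-coded genetic algorithm (GA) seeded with the swarm's best
solutions, and periodic Nelder-Mead polish of the incumbent every few GA
generations.  Population sizes follow N_PSO = max(15, 5·N_par) and
N_GA = 2·N_par (floored at 6 so tournament selection stays meaningful).

Rate-like parameters (Ctau, dvA, dvB, demands, k_traffic) are searched in
log10 space and the bounded ratios (F, mProp) in logit space, since the
plausible ranges span many decades.  Everything is driven by one master
seed; each phase draws from its own deterministically spawned stream, so a
fit is bit-reproducible given (config, data, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import observation
from .model import DAY_S, DEMAND_FLOOR, ModelParameters, predict_day7
from .morphology import CompartmentTree

__all__ = [
    "FreeParameter",
    "FitConfig",
    "FitResult",
    "fit",
    "refit_degradation",
    "recovery_experiment",
    "version_config",
    "region_groups",
]

_SCALAR_FIELDS = {"F", "Ctau", "mProp", "dvA", "dvB", "k_traffic"}
_LOGIT_FIELDS = {"F", "mProp"}


@dataclass
class FreeParameter:
    """One free parameter (or tied group) of a fit.

    name : scalar field name ("F", "Ctau", "mProp", "dvA", "dvB",
        "k_traffic"), "demand" or "dv" (per-region degradation).
    bounds : (lo, hi) in natural units, finite, lo < hi.
    applies_to : for "demand"/"dv", the window names the single value is
        tied across; ignored for scalar fields.
    transform : "log", "logit" or "linear"; defaults by field kind.
    """

    name: str
    bounds: tuple
    applies_to: tuple = ()
    transform: str = ""

    def __post_init__(self):
        lo, hi = self.bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"{self.name}: bounds must be finite with lo < hi")
        if not self.transform:
            self.transform = "logit" if self.name in _LOGIT_FIELDS else "log"
        if self.transform == "log" and lo <= 0:
            raise ValueError(f"{self.name}: log-transformed bounds must be > 0")
        if self.name in _LOGIT_FIELDS and not (0 <= lo and hi <= 1):
            raise ValueError(f"{self.name}: bounds must lie in [0,1]")
        if self.name == "demand" and lo < DEMAND_FLOOR:
            raise ValueError(f"demand bounds must be >= {DEMAND_FLOOR}")

    # transformed (search-space) coordinates -------------------------------

    def to_z(self, v: float) -> float:
        if self.transform == "log":
            return float(np.log10(v))
        if self.transform == "logit":
            v = min(max(v, 1e-9), 1 - 1e-9)
            return float(np.log(v / (1 - v)))
        return float(v)

    def from_z(self, z: float) -> float:
        if self.transform == "log":
            return float(10.0 ** z)
        if self.transform == "logit":
            return float(1.0 / (1.0 + np.exp(-z)))
        return float(z)

    @property
    def z_bounds(self) -> tuple:
        lo, hi = self.bounds
        if self.transform == "logit":
            lo, hi = max(lo, 1e-6), min(hi, 1 - 1e-6)
        return self.to_z(lo), self.to_z(hi)


@dataclass
class FitConfig:
    """Free parameters, optimiser budget and seed for one fit.

    The default budget (pso_rounds=50, ga_rounds=2000, Nelder-Mead polish of
    the incumbent every 10 GA generations for 100 iterations) is the full
    published schedule; the reduced profile used in tests and recovery
    experiments shrinks the round counts, not the schedule's structure.
    """

    free: list
    pso_rounds: int = 50
    ga_rounds: int = 2000
    nm_every: int = 10
    nm_iters: int = 100
    seed: int = 0
    # GA/PSO hyperparameters (canonical values; configurable)
    pso_inertia: float = 0.72
    pso_cognitive: float = 1.49
    pso_social: float = 1.49
    ga_crossover_prob: float = 0.9
    ga_mutation_prob: float = 0.2
    ga_mutation_sigma: float = 0.05  # fraction of the bound range
    ga_elite: int = 1

    def __post_init__(self):
        if min(self.pso_rounds, self.ga_rounds) < 0 or \
                self.pso_rounds + self.ga_rounds <= 0:
            raise ValueError("optimiser budget must be positive")
        names = [f.name if f.name in _SCALAR_FIELDS else
                 (f.name, tuple(f.applies_to)) for f in self.free]
        if len(set(names)) != len(names):
            raise ValueError("duplicate free parameters")

    @property
    def n_par(self) -> int:
        return len(self.free)

    @property
    def n_pso(self) -> int:
        return max(15, 5 * self.n_par)

    @property
    def n_ga(self) -> int:
        return max(6, 2 * self.n_par)


@dataclass
class FitResult:
    """Best parameters found plus provenance of the search."""

    params: ModelParameters
    values: dict               # free-parameter name -> fitted value
    cost: float
    chi2: float
    trace: list                # best-so-far cost, one entry per round
    n_evals: int
    seed: int
    config: FitConfig

    def to_json(self) -> str:
        d = {
            "values": self.values,
            "cost": self.cost,
            "chi2": self.chi2,
            "trace": self.trace,
            "n_evals": self.n_evals,
            "seed": self.seed,
            "params": _params_dict(self.params),
            "config": {
                k: v for k, v in asdict(self.config).items() if k != "free"
            },
            "free": [f.name for f in self.config.free],
        }
        return json.dumps(d, indent=1, sort_keys=True)


def _params_dict(p: ModelParameters) -> dict:
    d = asdict(p)
    d["demand"] = dict(p.demand)
    return d


def _key(fp: FreeParameter) -> str:
    if fp.name in _SCALAR_FIELDS:
        return fp.name
    tag = fp.applies_to[0] if len(fp.applies_to) == 1 else \
        _common_prefix(fp.applies_to)
    return f"{fp.name}:{tag}"


def _common_prefix(names) -> str:
    pref = names[0]
    for nm in names[1:]:
        while not nm.startswith(pref) and pref:
            pref = pref[:-1]
    return pref.rstrip("_") or "+".join(names)


def apply_values(base: ModelParameters, free: list, vector: np.ndarray
                 ) -> ModelParameters:
    """Materialise a candidate parameter set from natural-unit values."""
    params = replace(base, demand=dict(base.demand))
    dv_region = dict(params.dv_region) if params.dv_region else None
    for fp, v in zip(free, vector):
        if fp.name in _SCALAR_FIELDS:
            params = replace(params, **{fp.name: float(v)})
        elif fp.name == "demand":
            for nm in fp.applies_to:
                params.demand[nm] = float(v)
        elif fp.name == "dv":
            dv_region = dv_region or {}
            for nm in fp.applies_to:
                dv_region[nm] = float(v)
        else:
            raise ValueError(f"unknown free parameter {fp.name!r}")
    if dv_region is not None:
        params = replace(params, dv_region=dv_region)
    return params


# ---------------------------------------------------------------------------
# Objective

class Objective:
    """Fit cost of a candidate vector (search space) against a window table.

    For each candidate: rebuild rates, initial conditions and the normalised
    Day-7 target (both depend on mProp), run the forward model for
    ``delta_days`` and return the squared-difference cost.
    """

    def __init__(self, base: ModelParameters, free: list,
                 tree: CompartmentTree, table: pd.DataFrame,
                 delta_days: float = 7.0):
        self.base = base
        self.free = free
        self.tree = tree
        self.table = table
        self.t = delta_days * DAY_S
        self.n_evals = 0
        self.z_lo = np.array([f.z_bounds[0] for f in free])
        self.z_hi = np.array([f.z_bounds[1] for f in free])

    def params_of(self, z: np.ndarray) -> ModelParameters:
        z = np.clip(z, self.z_lo, self.z_hi)
        vals = np.array([f.from_z(zi) for f, zi in zip(self.free, z)])
        return apply_values(self.base, self.free, vals)

    def __call__(self, z: np.ndarray) -> float:
        self.n_evals += 1
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", observation.DataWarning)
                p = self.params_of(z)
                ic = observation.initial_conditions(self.table, self.tree,
                                                    p.mProp)
                pf7 = predict_day7(p, self.tree, self.table, ic.u0,
                                   ic.u_star0, t=self.t)
                tgt = observation.day7_target(self.table, self.tree, p.mProp)
                return observation.cost(
                    tgt.y_tilde, observation.normalize_prediction(pf7, p.mProp))
        except (ValueError, FloatingPointError):
            return np.inf


# ---------------------------------------------------------------------------
# Optimiser phases

def _pso(obj: Objective, cfg: FitConfig, rng: np.random.Generator):
    n, d = cfg.n_pso, cfg.n_par
    span = obj.z_hi - obj.z_lo
    x = obj.z_lo + rng.random((n, d)) * span
    v = (rng.random((n, d)) - 0.5) * span * 0.1
    fx = np.array([obj(xi) for xi in x])
    pbest, pcost = x.copy(), fx.copy()
    g = int(np.argmin(pcost))
    trace = [float(pcost[g])]
    for _ in range(cfg.pso_rounds):
        r1, r2 = rng.random((n, d)), rng.random((n, d))
        v = (cfg.pso_inertia * v
             + cfg.pso_cognitive * r1 * (pbest - x)
             + cfg.pso_social * r2 * (pbest[g] - x))
        np.clip(v, -span, span, out=v)
        x = np.clip(x + v, obj.z_lo, obj.z_hi)
        fx = np.array([obj(xi) for xi in x])
        better = fx < pcost
        pbest[better], pcost[better] = x[better], fx[better]
        g = int(np.argmin(pcost))
        trace.append(float(pcost[g]))
    order = np.argsort(pcost)
    return pbest[order], pcost[order], trace


def _nelder_mead(obj: Objective, z0: np.ndarray, f0: float, iters: int):
    res = minimize(obj, z0, method="Nelder-Mead",
                   options={"maxiter": iters, "xatol": 1e-12, "fatol": 1e-16})
    if res.fun < f0:
        return np.clip(res.x, obj.z_lo, obj.z_hi), float(res.fun)
    return z0, f0  # polish never returns a worse point


def _ga(obj: Objective, cfg: FitConfig, rng: np.random.Generator,
        seeds: np.ndarray, seed_costs: np.ndarray):
    n, d = cfg.n_ga, cfg.n_par
    span = obj.z_hi - obj.z_lo
    pop = obj.z_lo + rng.random((n, d)) * span
    fx = np.full(n, np.inf)
    k = min(len(seeds), n)
    pop[:k], fx[:k] = seeds[:k], seed_costs[:k]
    for i in range(k, n):
        fx[i] = obj(pop[i])
    best = int(np.argmin(fx))
    trace = [float(fx[best])]

    def tournament():
        cand = rng.integers(0, n, size=3)
        return pop[cand[np.argmin(fx[cand])]]

    for gen in range(1, cfg.ga_rounds + 1):
        new = np.empty_like(pop)
        new[0] = pop[best]          # elitism
        fnew = np.empty(n)
        fnew[0] = fx[best]
        for i in range(cfg.ga_elite, n):
            p1, p2 = tournament(), tournament()
            if rng.random() < cfg.ga_crossover_prob:
                # blend crossover (BLX-0.5)
                lo = np.minimum(p1, p2)
                hi = np.maximum(p1, p2)
                w = hi - lo
                child = lo - 0.5 * w + rng.random(d) * 2.0 * w
            else:
                child = p1.copy()
            mut = rng.random(d) < cfg.ga_mutation_prob
            child[mut] += rng.normal(0, cfg.ga_mutation_sigma, mut.sum()) \
                * span[mut]
            new[i] = np.clip(child, obj.z_lo, obj.z_hi)
            fnew[i] = obj(new[i])
        pop, fx = new, fnew
        best = int(np.argmin(fx))
        if cfg.nm_every > 0 and gen % cfg.nm_every == 0:
            pop[best], fx[best] = _nelder_mead(obj, pop[best], fx[best],
                                               cfg.nm_iters)
        trace.append(float(fx[best]))
    return pop[best], float(fx[best]), trace


# ---------------------------------------------------------------------------

def fit(config: FitConfig, table: pd.DataFrame, tree: CompartmentTree,
        base: ModelParameters, delta_days: float = 7.0) -> FitResult:
    """Run the PSO -> GA -> Nelder-Mead schedule and return the best fit.

    ``base`` supplies every parameter not listed in ``config.free``
    (including the full demand dict); the table must already be mapped onto
    ``tree``.  Deterministic given (config, table, tree, base).
    """
    if config.n_par == 0:
        raise ValueError("no free parameters")
    obj = Objective(base, config.free, tree, table, delta_days)
    ss = np.random.SeedSequence(config.seed)
    rng_pso, rng_ga = [np.random.default_rng(s) for s in ss.spawn(2)]

    trace: list = []
    if config.pso_rounds > 0:
        seeds, seed_costs, t = _pso(obj, config, rng_pso)
        trace += t
    else:
        span = obj.z_hi - obj.z_lo
        seeds = obj.z_lo + rng_pso.random((config.n_ga, config.n_par)) * span
        seed_costs = np.array([obj(z) for z in seeds])
        order = np.argsort(seed_costs)
        seeds, seed_costs = seeds[order], seed_costs[order]

    if config.ga_rounds > 0:
        z_best, f_best, t = _ga(obj, config, rng_ga, seeds, seed_costs)
        trace += t
    else:
        z_best, f_best = seeds[0], float(seed_costs[0])

    z_best, f_best = _nelder_mead(obj, z_best, f_best, max(config.nm_iters, 200))
    trace.append(f_best)

    params = obj.params_of(z_best)
    values = {
        _key(fp): fp.from_z(float(np.clip(z, *fp.z_bounds)))
        for fp, z in zip(config.free, z_best)
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", observation.DataWarning)
        ic = observation.initial_conditions(table, tree, params.mProp)
        pf7 = predict_day7(params, tree, table, ic.u0, ic.u_star0,
                           t=delta_days * DAY_S)
        tgt = observation.day7_target(table, tree, params.mProp)
        phat = observation.normalize_prediction(pf7, params.mProp)
    x2 = observation.chi2(tgt.y_tilde, phat, tgt.eps_tilde) \
        if np.any(tgt.eps_tilde > 0) else float("nan")
    return FitResult(params=params, values=values, cost=f_best, chi2=x2,
                     trace=trace, n_evals=obj.n_evals, seed=config.seed,
                     config=config)


def refit_degradation(base: FitResult, table: pd.DataFrame,
                      tree: CompartmentTree, linear: bool = True,
                      seed: int | None = None,
                      budget: dict | None = None) -> FitResult:
    """Re-fit only the degradation rates, everything else frozen.

    With ``linear=True`` the intercept dvA and slope dvB of the linear
    degradation model are free; otherwise a single global rate dvA (dvB
    pinned by the base parameters).  Used for transferring a fitted model
    across ages, where only protein turnover is allowed to change.
    """
    free = [FreeParameter("dvA", (1e-09, 1e-02))]
    if linear:
        free.append(FreeParameter("dvB", (1e-20, 1e-04)))
    cfg = replace(
        base.config, free=free,
        seed=base.config.seed if seed is None else seed,
        **(budget or {}),
    )
    return fit(cfg, table, tree, base.params)


def recovery_experiment(spec, config: FitConfig, delta_days: float = 7.0):
    """Generate synthetic data from ``spec`` and try to recover its truth.

    Returns a report dict with the fitted values, their true counterparts,
    per-parameter relative errors, and the residual cost.
    """
    from .synthetic import make_dataset

    tree, table, truth = make_dataset(spec)
    result = fit(config, table, tree, truth, delta_days=delta_days)
    true_vals, rel_err = {}, {}
    for fp in config.free:
        key = _key(fp)
        if fp.name in _SCALAR_FIELDS:
            tv = float(getattr(truth, fp.name))
        elif fp.name == "demand":
            tv = float(np.mean([truth.demand[nm] for nm in fp.applies_to]))
        else:
            tv = float(truth.dvA)
        true_vals[key] = tv
        rel_err[key] = abs(result.values[key] - tv) / abs(tv) if tv else np.inf
    return {
        "fitted": result.values,
        "truth": true_vals,
        "relative_error": rel_err,
        "cost": result.cost,
        "n_evals": result.n_evals,
        "seed": config.seed,
        "result": result,
    }


# ---------------------------------------------------------------------------
# Model-version configurations

def region_groups(names) -> dict:
    """Group window names by anatomical region (prefix before the last '_')."""
    groups: dict = {}
    for nm in names:
        key = nm.rsplit("_", 1)[0] if "_" in nm else nm
        groups.setdefault(key, []).append(nm)
    return groups


def version_config(version: int, table: pd.DataFrame, seed: int = 0,
                   **budget) -> FitConfig:
    """The three published model versions as fit configurations.

    1: one demand per region + one global degradation rate (+ Ctau, F,
       mProp) -> 7 free parameters for the 3-region CA1 layout;
    2: one demand and one degradation rate per region -> 9;
    3: one demand per window + linear degradation (dvA, dvB) -> 25 for the
       20-window layout.
    """
    names = table["name"].tolist()
    groups = region_groups(names)
    dem_b = (DEMAND_FLOOR, 1.0)
    dv_b = (1e-09, 1e-02)
    shared = [
        FreeParameter("Ctau", (1e-09, 1e-03)),
        FreeParameter("F", (0.0, 1.0)),
        FreeParameter("mProp", (0.0, 1.0)),
    ]
    if version == 1:
        free = [FreeParameter("demand", dem_b, tuple(g)) for g in groups.values()]
        free += [FreeParameter("dvA", dv_b)] + shared
    elif version == 2:
        free = [FreeParameter("demand", dem_b, tuple(g)) for g in groups.values()]
        free += [FreeParameter("dv", dv_b, tuple(g)) for g in groups.values()]
        free += shared
    elif version == 3:
        free = [FreeParameter("demand", dem_b, (nm,)) for nm in names]
        free += [FreeParameter("dvA", dv_b), FreeParameter("dvB", (1e-20, 1e-04))]
        free += shared
    else:
        raise ValueError("version must be 1, 2 or 3")
    return FitConfig(free=free, seed=seed, **budget)
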