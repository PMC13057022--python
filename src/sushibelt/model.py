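"""Reaction–transport model of cargo trafficking on a compartment tree.

Cargo concentration u_i rides the microtubule "belt" and hops between
neighbouring compartments with forward/backward rate constants a, b.  It
irreversibly detaches with rate c_i into a synaptic pool u*_i, which degrades
with rate d_i.  On a cable the cargo pool obeys

    du_i/dt = a_{i-1} u_{i-1} - (a_i + b_{i-1} + c_i) u_i + b_i u_{i+1}
    du*_i/dt = c_i u_i - d_i u*_i

and the whole system is linear, ``d[u;u*]/dt = M [u;u*]`` with a nearly
tridiagonal transport block (branch points add extra off-diagonal pairs).

Rates are chosen so that the belt's quasi-steady-state distribution matches a
prescribed trafficking demand ũ, itself a mix of the synaptic demand ũ* and
a uniform component controlled by F:

    ũ_i = F ũ*_i + (1 - F)/N            (F=1: demand-dependent traffic, DDT;
                                         F=0: demand-dependent detachment, DDD)
    b/a = ũ_parent/ũ_child  per edge,   a + b = k_traffic
    c_i = Ctau ũ*_i / ũ_i
    d_i = dvA + dvB · demand_i

Time is in seconds throughout; reattachment of synaptic protein onto the belt
is supported by the equations but fixed to zero by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .morphology import CompartmentTree

__all__ = [
    "DAY_S",
    "DEMAND_FLOOR",
    "ModelParameters",
    "RateSet",
    "Trajectory",
    "trafficking_demand",
    "edge_rates",
    "detachment_rates",
    "degradation_rates",
    "build_rate_matrix",
    "build_rates",
    "full_generator",
    "simulate",
    "predict_day7",
    "half_life",
]

DAY_S = 86400.0
#: Raw demand values below this floor are clipped before normalisation, to
#: avoid zero-rate transport bottlenecks at zero-demand compartments.
DEMAND_FLOOR = 1e-7


@dataclass
class ModelParameters:
    """Free parameters of the extended sushi-belt model.

    F : DDT/DDD mixing ratio in [0, 1] (1 = traffic follows demand,
        0 = uniform traffic, detachment follows demand).
    Ctau : detachment-rate scale, 1/s.
    mProp : fraction of labelled protein on the belt (cargo) at time 0.
    dvA, dvB : intercept and demand slope of the linear degradation model
        d_i = dvA + dvB * demand_i, 1/s.
    demand : raw per-subregion demand values (dict name -> value); clipped
        at DEMAND_FLOOR and normalised internally.
    k_traffic : absolute trafficking speed scale a+b per edge, 1/s.  The
        demand-matching condition fixes only b/a; the sum is a free scale
        chosen ≫ c so the belt stays in quasi-steady state.
    reattach : synaptic -> belt reattachment rate, 1/s (0 in all analyses).
    dv_region : optional per-subregion degradation rates (dict name -> 1/s)
        overriding the linear dvA/dvB model where given.
    """

    F: float
    Ctau: float
    mProp: float
    dvA: float = 0.0
    dvB: float = 0.0
    demand: dict = field(default_factory=dict)
    k_traffic: float = 1e-2
    reattach: float = 0.0
    dv_region: dict | None = None

    def validate(self) -> None:
        if not 0.0 <= self.F <= 1.0:
            raise ValueError(f"F must be in [0,1], got {self.F}")
        if not 0.0 <= self.mProp <= 1.0:
            raise ValueError(f"mProp must be in [0,1], got {self.mProp}")
        for name in ("Ctau", "dvA", "dvB", "reattach"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k_traffic <= 0:
            raise ValueError("k_traffic must be > 0")

    def compartment_demand(self, tree: CompartmentTree, table: pd.DataFrame) -> np.ndarray:
        """Raw demand per compartment (soma gets the floor), clipped at the floor."""
        value = dict(zip(table["name"], _demand_vector(self, table)))
        out = np.empty(tree.n)
        for i in range(tree.n):
            out[i] = value.get(tree.subregion[i], DEMAND_FLOOR)
        return np.maximum(out, DEMAND_FLOOR)


def _demand_vector(params: ModelParameters, table: pd.DataFrame) -> np.ndarray:
    try:
        return np.array([float(params.demand[name]) for name in table["name"]])
    except KeyError as exc:
        raise KeyError(f"no demand value for subregion {exc}") from None


@dataclass
class RateSet:
    """Per-edge trafficking rates and per-compartment kinetic rates (1/s).

    ``a[k]``/``b[k]`` are the forward/backward rates of edge k (parent->child
    in :meth:`CompartmentTree.edges` order); ``c`` and ``d`` are detachment
    and degradation per compartment.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray


@dataclass
class Trajectory:
    """Time course of the belt (u) and synaptic (u_star) pools."""

    times: np.ndarray          # (T,) seconds
    u: np.ndarray              # (T, N)
    u_star: np.ndarray         # (T, N)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame: time_s, compartment, u, u_star."""
        T, N = self.u.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.times, N),
                "compartment": np.tile(np.arange(N), T),
                "u": self.u.ravel(),
                "u_star": self.u_star.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# Demand -> rates

def trafficking_demand(u_star_demand: np.ndarray, F: float) -> np.ndarray:
    """Mix synaptic demand with a uniform profile: ũ = F ũ* + (1-F)/N."""
    if not 0.0 <= F <= 1.0:
        raise ValueError(f"F must be in [0,1], got {F}")
    u = np.asarray(u_star_demand, dtype=float)
    return F * u + (1.0 - F) / u.size


def edge_rates(tree: CompartmentTree, u_tilde: np.ndarray, k_traffic: float):
    """Forward/backward rates per edge matching demand at quasi-steady state.

    For edge (i -> j): a = k ũ_j/(ũ_i+ũ_j), b = k ũ_i/(ũ_i+ũ_j), so that
    b/a = ũ_i/ũ_j exactly and a + b = k_traffic.
    """
    u = np.asarray(u_tilde, dtype=float)
    if np.any(u <= 0):
        raise ValueError("trafficking demand must be strictly positive")
    e = tree.edges()
    ui, uj = u[e[:, 0]], u[e[:, 1]]
    a = k_traffic * uj / (ui + uj)
    b = k_traffic * ui / (ui + uj)
    return a, b


def detachment_rates(u_star_demand: np.ndarray, F: float, Ctau: float) -> np.ndarray:
    """Demand-dependent detachment c_i = Ctau ũ*_i / (F ũ*_i + (1-F)/N).

    At F=1 this reduces to the uniform constant Ctau (pure DDT); at F=0 it is
    Ctau·N·ũ*_i (pure DDD).  The 0/0 case (F=1 with zero demand) is defined
    as 0 with a warning.
    """
    u = np.asarray(u_star_demand, dtype=float)
    denom = trafficking_demand(u, F)
    c = np.zeros_like(u)
    ok = denom > 0
    if not ok.all():
        warnings.warn("zero demand with F=1: detachment rate set to 0", stacklevel=2)
    c[ok] = Ctau * u[ok] / denom[ok]
    return c


def degradation_rates(dvA: float, dvB: float, demand: np.ndarray) -> np.ndarray:
    """Linear degradation model d_i = dvA + dvB · demand_i (raw demand)."""
    if dvA < 0 or dvB < 0:
        raise ValueError("dvA and dvB must be >= 0")
    return dvA + dvB * np.asarray(demand, dtype=float)


def build_rates(
    params: ModelParameters, tree: CompartmentTree, table: pd.DataFrame
) -> RateSet:
    """Assemble the full RateSet for a labelled tree from model parameters."""
    params.validate()
    raw = params.compartment_demand(tree, table)
    u_star = raw / raw.sum()
    u_tilde = trafficking_demand(u_star, params.F)
    a, b = edge_rates(tree, u_tilde, params.k_traffic)
    c = detachment_rates(u_star, params.F, params.Ctau)
    d = degradation_rates(params.dvA, params.dvB, raw)
    if params.dv_region:
        for i in range(tree.n):
            if tree.subregion[i] in params.dv_region:
                d[i] = params.dv_region[tree.subregion[i]]
        if np.any(d < 0):
            raise ValueError("per-region degradation rates must be >= 0")
    return RateSet(a=a, b=b, c=c, d=d)


# ---------------------------------------------------------------------------
# System assembly and integration

def build_rate_matrix(tree: CompartmentTree, rates: RateSet) -> np.ndarray:
    """State-transition matrix A of the cargo pool: du/dt = A u.

    Nearly tridiagonal in compartment order; each branch point contributes an
    off-diagonal pair per child.  Column j sums to -c_j (cargo leaves the
    belt only by detaching).
    """
    n = tree.n
    e = tree.edges()
    if rates.a.shape != (n - 1,) or rates.b.shape != (n - 1,) or rates.c.shape != (n,):
        raise ValueError("rate arrays do not match tree dimensions")
    A = np.zeros((n, n))
    for k, (i, j) in enumerate(e):
        A[j, i] += rates.a[k]
        A[i, i] -= rates.a[k]
        A[i, j] += rates.b[k]
        A[j, j] -= rates.b[k]
    A[np.diag_indices(n)] -= rates.c
    return A


def full_generator(A: np.ndarray, c: np.ndarray, d: np.ndarray, reattach: float = 0.0):
    """Generator of the joint linear system for state [u; u*]."""
    n = A.shape[0]
    M = np.zeros((2 * n, 2 * n))
    M[:n, :n] = A
    M[n:, :n] = np.diag(c)
    M[n:, n:] = -np.diag(np.asarray(d, dtype=float) + 0.0)
    if reattach:
        M[:n, n:] += reattach * np.eye(n)
        M[n:, n:] -= reattach * np.eye(n)
    return M


def simulate(
    A: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    u0: np.ndarray,
    u_star0: np.ndarray,
    t_grid: np.ndarray,
    method: str = "expm",
    reattach: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the joint system from (u0, u*0) over ``t_grid`` (seconds).

    method="expm" propagates with the matrix exponential (exact for this
    linear time-invariant system up to machine precision); method="bdf" uses
    scipy's implicit stiff integrator with the analytic Jacobian and the
    given tolerances, as an independent numerical route.
    """
    t = np.asarray(t_grid, dtype=float)
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must increase from 0")
    u0 = np.asarray(u0, dtype=float)
    u_star0 = np.asarray(u_star0, dtype=float)
    if np.any(u0 < 0) or np.any(u_star0 < 0):
        raise ValueError("initial pools must be non-negative")
    n = A.shape[0]
    M = full_generator(A, np.asarray(c, float), np.asarray(d, float), reattach)
    y0 = np.concatenate([u0, u_star0])

    if method == "expm":
        Y = np.empty((t.size, 2 * n))
        Y[0] = y0
        # propagate step-by-step so each dt exponential is well-scaled
        y = y0
        for k in range(1, t.size):
            y = expm(M * (t[k] - t[k - 1])) @ y
            Y[k] = y
    elif method == "bdf":
        sol = solve_ivp(
            lambda _, y: M @ y,
            (t[0], t[-1]),
            y0,
            method="BDF",
            t_eval=t,
            jac=lambda _, y: M,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed: {sol.message}")
        Y = sol.y.T
    else:
        raise ValueError(f"unknown method {method!r}")

    Y = np.where(np.abs(Y) < 1e2 * atol, np.maximum(Y, 0.0), Y)
    return Trajectory(times=t, u=Y[:, :n], u_star=Y[:, n:])


def predict_day7(
    params: ModelParameters,
    tree: CompartmentTree,
    table: pd.DataFrame,
    u0: np.ndarray,
    u_star0: np.ndarray,
    t: float = 7 * DAY_S,
) -> np.ndarray:
    """Synaptic pool per compartment after ``t`` seconds (single expm solve)."""
    rates = build_rates(params, tree, table)
    A = build_rate_matrix(tree, rates)
    M = full_generator(A, rates.c, rates.d, params.reattach)
    y = expm(M * t) @ np.concatenate([u0, u_star0])
    return np.maximum(y[tree.n:], 0.0)


def half_life(rate: float) -> float:
    """Half-life in days of a first-order decay with ``rate`` in 1/s."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    return np.log(2.0) / rate / DAY_S
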