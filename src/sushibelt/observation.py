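"""Turn window tables into model initial conditions, targets and costs.

Window (subregion) tables carry one Day-0 value V_seg, one Day-7 value T_seg
and one Day-7 SD per imaging window; each window covers L_seg compartments.
Per compartment,

    x_i = V_seg / (L_seg Σ V_seg),   x̃_i = x_i / Σ x_i
    u0_i = mProp · x̃_i,              u*0_i = (1 - mProp) · x̃_i

so the belt carries a fraction mProp of the labelled protein at time 0 and
the rest sits at synapses, both distributed like the Day-0 profile.  The
Day-7 fit target is

    y_i = T_seg / (L_seg Σ V_seg),   ỹ_i = y_i / ((1 - mProp) Σ y_i)

and the model quantity compared against it is the identically normalised
synaptic pool p̂_i = p^f7_i / ((1 - mProp) Σ p^f7): with measurements
proportional to the synaptic pool, ỹ and p̂ coincide exactly at the true
parameters.  Cost is the plain sum of squared differences; χ² additionally
weights by the normalised experimental SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphology import CompartmentTree, subregion_index, validate_table

__all__ = [
    "DataWarning",
    "InitialConditions",
    "NormalizedTarget",
    "initial_conditions",
    "day7_target",
    "normalize_prediction",
    "cost",
    "chi2",
    "apparent_half_life",
]


class DataWarning(UserWarning):
    """Degenerate-but-tolerated feature of an input table."""


@dataclass
class InitialConditions:
    """Per-compartment starting pools; Σu0 = mProp, Σu0 + Σu*0 = 1."""

    u0: np.ndarray
    u_star0: np.ndarray


@dataclass
class NormalizedTarget:
    """Per-compartment Day-7 fit target.

    y: raw per-compartment Day-7 value; y_tilde: normalised target with
    Σỹ = 1/(1-mProp); eps_tilde: SD on the same scale as y (χ² weights).
    """

    y: np.ndarray
    y_tilde: np.ndarray
    eps_tilde: np.ndarray


def _per_compartment(
    tree: CompartmentTree, table: pd.DataFrame, column: str
) -> np.ndarray:
    """Spread window values over member compartments: value/(L_seg ΣV_seg).

    The soma (and any compartment outside every window) contributes zero.
    """
    if "n_compartments" not in table.columns:
        raise ValueError("table has no n_compartments column; run map_subregions")
    idx = subregion_index(tree, table)
    L = table["n_compartments"].to_numpy(dtype=float)
    V_sum = float(table["day0"].sum())
    vals = table[column].to_numpy(dtype=float)
    out = np.zeros(tree.n)
    for i in range(tree.n):
        j = idx[i]
        if j >= 0:
            if L[j] == 0:
                continue
            out[i] = vals[j] / (L[j] * V_sum)
    empty = table.loc[(L == 0) & (vals > 0), "name"].tolist()
    if empty:
        warnings.warn(f"windows with no compartments ignored: {empty}",
                      DataWarning, stacklevel=3)
    return out


def initial_conditions(
    table: pd.DataFrame, tree: CompartmentTree, mProp: float
) -> InitialConditions:
    """Split the normalised Day-0 profile into belt and synaptic pools."""
    validate_table(table)
    if not 0.0 <= mProp <= 1.0:
        raise ValueError("mProp must be in [0,1]")
    x = _per_compartment(tree, table, "day0")
    s = x.sum()
    if s <= 0:
        raise ValueError("all-zero Day-0 values")
    x_tilde = x / s
    return InitialConditions(u0=mProp * x_tilde, u_star0=(1.0 - mProp) * x_tilde)


def day7_target(
    table: pd.DataFrame, tree: CompartmentTree, mProp: float
) -> NormalizedTarget:
    """Normalised Day-7 target ỹ and SD ε̃ per compartment."""
    validate_table(table)
    y = _per_compartment(tree, table, "day7")
    s = y.sum()
    if s <= 0:
        raise ValueError("all-zero Day-7 values")
    if mProp >= 1.0:
        raise ValueError("mProp must be < 1 for the Day-7 normalisation")
    eps = _per_compartment(tree, table, "day7_sd")
    if np.all(eps == 0):
        warnings.warn("all Day-7 SDs are zero: chi-squared is undefined",
                      DataWarning, stacklevel=2)
    return NormalizedTarget(y=y, y_tilde=y / ((1.0 - mProp) * s), eps_tilde=eps)


def normalize_prediction(p_f7: np.ndarray, mProp: float) -> np.ndarray:
    """Scale the simulated synaptic pool onto the target's scale.

    p̂_i = p^f7_i / ((1-mProp) Σ p^f7); both p̂ and ỹ then sum to 1/(1-mProp).
    """
    p = np.asarray(p_f7, dtype=float)
    s = p.sum()
    if s <= 0:
        raise ValueError("predicted synaptic pool sums to zero")
    return p / ((1.0 - mProp) * s)


def cost(y_tilde: np.ndarray, p_f7: np.ndarray) -> float:
    """Sum of squared differences between target and (normalised) prediction."""
    y = np.asarray(y_tilde, dtype=float)
    p = np.asarray(p_f7, dtype=float)
    if y.shape != p.shape:
        raise ValueError("target and prediction lengths differ")
    return float(np.sum((y - p) ** 2))


def chi2(y_tilde: np.ndarray, p_f7: np.ndarray, eps_tilde: np.ndarray) -> float:
    """SD-weighted squared error, over entries with ε̃ > 0 only."""
    y = np.asarray(y_tilde, dtype=float)
    p = np.asarray(p_f7, dtype=float)
    e = np.asarray(eps_tilde, dtype=float)
    if not (y.shape == p.shape == e.shape):
        raise ValueError("vector lengths differ")
    m = e > 0
    return float(np.sum((y[m] - p[m]) ** 2 / e[m]))


def apparent_half_life(
    day0: np.ndarray, day7: np.ndarray, delta_t: float = 7.0
) -> np.ndarray:
    """Per-window half-life under a pure exponential-decay reading (days).

    aT½ = Δt·ln2 / ln(day0/day7).  Windows where the signal did not decline
    (day7 ≥ day0) contradict pure decay and are returned as NaN.
    """
    d0 = np.asarray(day0, dtype=float)
    d7 = np.asarray(day7, dtype=float)
    if np.any(d0 <= 0):
        raise ValueError("Day-0 values must be > 0")
    out = np.full(d0.shape, np.nan)
    dec = d7 < d0
    if not dec.all():
        warnings.warn(
            f"{int((~dec).sum())} window(s) grew between Day 0 and Day 7; "
            "apparent half-life undefined there",
            DataWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        out[dec] = delta_t * np.log(2.0) / np.log(d0[dec] / d7[dec])
    return out
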