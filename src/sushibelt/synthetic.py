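"""Synthetic morphologies and pulse-chase window tables.

Every stage of the pipeline is testable without downloads: this module
builds soma-rooted trees (unbranched cables, binary trees, or an
apical/basal layout with windows on both sides of the soma), lays imaging
windows along them, and produces Day-0/Day-7 tables by running the forward
transport model at known "truth" parameters and adding multiplicative
Gaussian noise.

Unit convention: the Day-0 window value is proportional to the *synaptic*
pool at time 0 (the measured puncta), i.e. to (1-mProp)·x̃, and the Day-7
value to the simulated synaptic pool p^f7 in the same arbitrary units.  In
the detachment-free pure-decay case this makes Day7/Day0 equal to
2^(-Δt/t½) in every window exactly.

The module also carries the published reference parameter estimates for CA1
pyramidal and dentate-gyrus granule neurons (3-week / 3-month / 18-month
mice), used as ground truth in recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import observation
from .model import DAY_S, ModelParameters, predict_day7
from .morphology import CompartmentTree, map_subregions, subregion_index

__all__ = [
    "SynthSpec",
    "make_morphology",
    "make_dataset",
    "demand_profile",
    "CA1_WINDOW_DISTANCES",
    "CA1_DEMAND_3M",
    "CA1_PARAMS_3M",
    "CA1_PARAMS_3W",
    "CA1_PARAMS_18M",
    "DG_DEMAND_3M",
    "DG_PARAMS_3M",
    "DG_PARAMS_3W",
    "DG_PARAMS_18M",
]

# ---------------------------------------------------------------------------
# Reference fitted parameter sets (CA1 pyramidal neuron, 20 windows:
# 5 stratum-oriens windows on the basal side, 10 stratum-radiatum and
# 5 stratum-lacunosum/moleculare windows on the apical side).

#: Signed distance of each CA1 window from the soma along the Z axis, µm
#: (negative = basal / stratum oriens side).
CA1_WINDOW_DISTANCES = {
    "CA1so_1": -165.0, "CA1so_2": -127.5, "CA1so_3": -90.0,
    "CA1so_4": -52.5, "CA1so_5": 0.0,
    "CA1sr_1": 10.0, "CA1sr_2": 52.5, "CA1sr_3": 94.286, "CA1sr_4": 136.43,
    "CA1sr_5": 178.57, "CA1sr_6": 220.71, "CA1sr_7": 262.86, "CA1sr_8": 305.0,
    "CA1sr_9": 347.14, "CA1sr_10": 389.29,
    "CA1slm_1": 431.43, "CA1slm_2": 473.57, "CA1slm_3": 515.71,
    "CA1slm_4": 557.86, "CA1slm_5": 600.0,
}

#: Fitted local demand per CA1 window, 3-month-old mice.
CA1_DEMAND_3M = {
    "CA1so_1": 0.214, "CA1so_2": 0.061, "CA1so_3": 0.047, "CA1so_4": 0.045,
    "CA1so_5": 1.0e-07,
    "CA1sr_1": 0.773, "CA1sr_2": 0.554, "CA1sr_3": 0.147, "CA1sr_4": 0.147,
    "CA1sr_5": 0.131, "CA1sr_6": 0.154, "CA1sr_7": 0.172, "CA1sr_8": 0.202,
    "CA1sr_9": 0.373, "CA1sr_10": 0.524,
    "CA1slm_1": 0.043, "CA1slm_2": 0.196, "CA1slm_3": 0.196,
    "CA1slm_4": 0.275, "CA1slm_5": 0.999,
}

CA1_PARAMS_3M = ModelParameters(
    F=0.8861, Ctau=4.38e-06, mProp=0.312,
    dvA=1.837e-06, dvB=1.002e-18, demand=dict(CA1_DEMAND_3M),
)
CA1_PARAMS_3W = replace(CA1_PARAMS_3M, dvA=5.21e-06, dvB=1e-18,
                        demand=dict(CA1_DEMAND_3M))
CA1_PARAMS_18M = replace(CA1_PARAMS_3M, dvA=1.63e-06, dvB=9.57e-08,
                         demand=dict(CA1_DEMAND_3M))

#: Fitted local demand per dentate-gyrus window (10 even-width sections).
DG_DEMAND_3M = {
    "rd1": 1.03e-07, "rd2": 0.029, "rd3": 0.012, "rd4": 0.041, "rd5": 0.067,
    "rd6": 0.089, "rd7": 0.151, "rd8": 0.610, "rd9": 0.543, "rd10": 0.281,
}

DG_PARAMS_3M = ModelParameters(
    F=0.01, Ctau=2.3e-06, mProp=0.49, dvA=4.6e-06, dvB=0.0,
    demand=dict(DG_DEMAND_3M),
)
DG_PARAMS_3W = replace(DG_PARAMS_3M, dvA=5.52e-04, demand=dict(DG_DEMAND_3M))
DG_PARAMS_18M = replace(DG_PARAMS_3M, dvA=4.53e-06, demand=dict(DG_DEMAND_3M))


# ---------------------------------------------------------------------------

@dataclass
class SynthSpec:
    """Recipe for a synthetic study: geometry, windows, demand, truth, noise.

    kind : "cable" (windows along +Z), "binary-tree" (a trunk that splits
        once, windows by path distance) or "apical-basal" (windows on the
        -Z and +Z sides of the soma, CA1-layer style).
    n_windows : number of imaging windows (n_basal of them on the basal
        side for "apical-basal").
    comps_per_window : compartments per window along each branch.
    window_length : axial extent of one window, µm.
    demand : named profile ("uniform" | "u-shaped" | "monotone") or an
        explicit sequence/dict of per-window raw demand values.
    truth : ModelParameters used to forward-simulate Day 7 (its demand dict
        is filled from the profile if empty).
    noise_sd : fractional SD of multiplicative Gaussian noise on Day-7
        window values (0 = noiseless).
    """

    kind: str = "cable"
    n_windows: int = 20
    comps_per_window: int = 3
    window_length: float = 30.0
    n_basal: int = 5
    demand: object = "u-shaped"
    truth: ModelParameters = field(
        default_factory=lambda: ModelParameters(F=0.5, Ctau=4e-06, mProp=0.3,
                                                dvA=2e-06)
    )
    noise_sd: float = 0.0
    delta_days: float = 7.0
    seed: int = 0

    def __post_init__(self):
        if self.n_windows < 2:
            raise ValueError("need at least 2 windows")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.comps_per_window < 1 or self.window_length <= 0:
            raise ValueError("impossible geometry")

    @property
    def window_names(self) -> list[str]:
        return [f"w{k + 1}" for k in range(self.n_windows)]


def demand_profile(spec: SynthSpec) -> np.ndarray:
    """Raw per-window demand values for the spec's profile."""
    n = spec.n_windows
    if isinstance(spec.demand, str):
        k = np.arange(n)
        if spec.demand == "uniform":
            return np.full(n, 0.5)
        if spec.demand == "u-shaped":
            # high near both ends, dip in the middle (CA1sr-like)
            t = k / (n - 1)
            return 0.1 + 0.7 * (2.0 * t - 1.0) ** 2
        if spec.demand == "monotone":
            # small rising gradient with a dip at the far end (DG-like)
            v = 0.03 + 0.57 * k / (n - 1)
            if n >= 3:
                v[-1] *= 0.55
            return v
        raise ValueError(f"unknown demand profile {spec.demand!r}")
    if isinstance(spec.demand, dict):
        return np.array([float(spec.demand[nm]) for nm in spec.window_names])
    v = np.asarray(list(spec.demand), dtype=float)
    if v.size != n:
        raise ValueError("explicit demand length != n_windows")
    return v


# ---------------------------------------------------------------------------
# Morphology construction

def _chain(parent, length, tip, start_idx, origin, direction, n, step):
    """Append a straight chain of n compartments of given step length."""
    prev = start_idx
    p = np.asarray(origin, dtype=float)
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    for j in range(n):
        q = p + step * u
        parent.append(prev)
        # recompute from coordinates so SWC round-trips reproduce lengths
        length.append(float(np.linalg.norm(q - p)))
        tip.append(q.copy())
        prev = len(parent) - 1
        p = q
    return prev


def make_morphology(spec: SynthSpec, swc_path=None) -> CompartmentTree:
    """Build the spec's tree (already discretized to comps_per_window pieces).

    The soma is a 1 µm root at the origin.  Deterministic given the spec;
    optionally also written to ``swc_path`` in SWC format.
    """
    step = spec.window_length / spec.comps_per_window
    parent: list[int] = [-1]
    length: list[float] = [1.0]
    tip: list[np.ndarray] = [np.zeros(3)]

    if spec.kind == "cable":
        _chain(parent, length, tip, 0, tip[0], (0, 0, 1),
               spec.n_windows * spec.comps_per_window, step)
    elif spec.kind == "apical-basal":
        nb = spec.n_basal
        if not 0 < nb < spec.n_windows:
            raise ValueError("n_basal must lie strictly between 0 and n_windows")
        _chain(parent, length, tip, 0, tip[0], (0, 0, -1),
               nb * spec.comps_per_window, step)
        _chain(parent, length, tip, 0, tip[0], (0, 0, 1),
               (spec.n_windows - nb) * spec.comps_per_window, step)
    elif spec.kind == "binary-tree":
        n_trunk = spec.n_windows // 2
        end = _chain(parent, length, tip, 0, tip[0], (0, 0, 1),
                     max(1, n_trunk) * spec.comps_per_window, step)
        rest = spec.n_windows - max(1, n_trunk)
        base = np.asarray(tip[end])
        for side in (-1, 1):
            _chain(parent, length, tip, end, base, (0.3 * side, 0, 1),
                   rest * spec.comps_per_window, step)
    else:
        raise ValueError(f"unknown morphology kind {spec.kind!r}")

    tree = CompartmentTree(np.array(parent), np.array(length), np.array(tip))
    if swc_path is not None:
        from .morphology import write_swc

        write_swc(tree, swc_path)
    return tree


def window_table(spec: SynthSpec) -> pd.DataFrame:
    """Skeleton window table (names + nominal distances, empty abundances)."""
    w = spec.window_length
    if spec.kind == "apical-basal":
        nb = spec.n_basal
        dist = np.concatenate([
            -w * (np.arange(nb)[::-1] + 0.5),
            w * (np.arange(spec.n_windows - nb) + 0.5),
        ])
    elif spec.kind == "binary-tree":
        dist = w * (np.arange(spec.n_windows) + 0.5)
    else:
        dist = w * (np.arange(spec.n_windows) + 0.5)
    return pd.DataFrame({
        "name": spec.window_names,
        "axial_distance": dist,
        "day0": 1.0, "day7": 0.0, "day7_sd": 0.0,
    })


def mapping_mode(spec: SynthSpec) -> str:
    """Distance convention used for window mapping ("axis" or "path")."""
    return "path" if spec.kind == "binary-tree" else "axis"


# ---------------------------------------------------------------------------

def make_dataset(spec: SynthSpec):
    """Generate (tree, table, truth): a labelled morphology and a Day-0/Day-7
    window table produced by the forward model at the truth parameters.

    Day-0 window values are window sums of the synaptic pool at time 0
    ((1-mProp)·x̃ with x̃ ∝ demand); Day-7 values are window sums of the
    simulated synaptic pool, multiplied by (1 + ε) with ε ~ N(0, noise_sd²)
    truncated so values stay ≥ 0; the SD column is noise_sd × the noiseless
    value.  Deterministic given ``spec.seed``.
    """
    tree = make_morphology(spec)
    table = window_table(spec)
    dem = demand_profile(spec)
    truth = spec.truth
    if not truth.demand:
        truth = replace(truth, demand=dict(zip(spec.window_names, dem)))
    truth.validate()

    tree = map_subregions(tree, table, mode=mapping_mode(spec))
    idx = subregion_index(tree, table)

    # Day 0: synaptic pool ∝ demand (x̃ ∝ raw demand per compartment)
    raw = truth.compartment_demand(tree, table)
    raw[0] = 0.0  # soma holds no labelled synaptic signal
    x_tilde = raw / raw.sum()
    day0_comp = (1.0 - truth.mProp) * x_tilde
    for j in range(len(table)):
        table.loc[j, "day0"] = day0_comp[idx == j].sum()

    ic = observation.initial_conditions(table, tree, truth.mProp)
    p_f7 = predict_day7(truth, tree, table, ic.u0, ic.u_star0,
                        t=spec.delta_days * DAY_S)
    day7 = np.array([p_f7[idx == j].sum() for j in range(len(table))])

    rng = np.random.default_rng(spec.seed)
    noisy = day7 * (1.0 + rng.normal(0.0, spec.noise_sd, size=day7.size)) \
        if spec.noise_sd > 0 else day7.copy()
    table["day7"] = np.maximum(noisy, 0.0)
    table["day7_sd"] = spec.noise_sd * day7
    return tree, table, truth
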