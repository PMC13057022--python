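from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from sushibelt import (
    CA1_DEMAND_3M,
    CA1_PARAMS_3M,
    CA1_WINDOW_DISTANCES,
    CompartmentTree,
    SynthSpec,
    make_dataset,
)


def make_cable(n: int, step: float = 10.0) -> CompartmentTree:
    """Soma root + an unbranched chain of n compartments along +Z."""
    parent = np.arange(-1, n)
    length = np.full(n + 1, step)
    length[0] = 1.0
    tip = np.zeros((n + 1, 3))
    tip[1:, 2] = step * np.arange(1, n + 1)
    return CompartmentTree(parent, length, tip)


def make_y_tree() -> CompartmentTree:
    """Root + one trunk compartment with two children (a branch point)."""
    parent = np.array([-1, 0, 1, 1])
    length = np.array([1.0, 10.0, 10.0, 10.0])
    tip = np.array([[0, 0, 0], [0, 0, 10], [5, 0, 18], [-5, 0, 18]], dtype=float)
    return CompartmentTree(parent, length, tip)


def simple_table(n_windows: int, step: float = 10.0, day0=None, day7=None,
                 sd=None) -> pd.DataFrame:
    return pd.DataFrame({
        "name": [f"w{k + 1}" for k in range(n_windows)],
        "axial_distance": step * (np.arange(n_windows) + 0.5),
        "day0": 1.0 if day0 is None else day0,
        "day7": 0.5 if day7 is None else day7,
        "day7_sd": 0.05 if sd is None else sd,
    })


@pytest.fixture()
def ca1_spec() -> SynthSpec:
    """20-window cable with the published CA1 3-month truth, noiseless."""
    demand = [CA1_DEMAND_3M[k] for k in CA1_WINDOW_DISTANCES]
    return SynthSpec(kind="cable", n_windows=20, comps_per_window=3,
                     window_length=30.0, demand=demand,
                     truth=replace(CA1_PARAMS_3M, demand={}),
                     noise_sd=0.0, seed=11)


@pytest.fixture()
def ca1_dataset(ca1_spec):
    return make_dataset(ca1_spec)
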