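"""Recover a model parameter from synthetic pulse-chase data.

Forward-simulates noiseless Day-7 data on a 20-window cable carrying the
published CA1 3-month parameter estimates, then re-fits the cargo/synaptic
split mProp as the only free parameter with the hybrid PSO + GA +
Nelder-Mead schedule (reduced budget).  A relative error near zero shows
the fitting pipeline can identify the parameter from the spatial shape of
the Day-7 distribution alone.
"""

from dataclasses import replace

from sushibelt import (
    CA1_DEMAND_3M,
    CA1_PARAMS_3M,
    CA1_WINDOW_DISTANCES,
    FitConfig,
    FreeParameter,
    SynthSpec,
    recovery_experiment,
)

demand = [CA1_DEMAND_3M[name] for name in CA1_WINDOW_DISTANCES]
spec = SynthSpec(kind="cable", n_windows=20, comps_per_window=3,
                 window_length=30.0, demand=demand,
                 truth=replace(CA1_PARAMS_3M, demand={}), noise_sd=0.0,
                 seed=1)

config = FitConfig(free=[FreeParameter("mProp", (0.0, 1.0))], seed=42,
                   pso_rounds=6, ga_rounds=40, nm_every=10, nm_iters=60)
report = recovery_experiment(spec, config)

print(f"true mProp     : {report['truth']['mProp']:.4f}")
print(f"fitted mProp   : {report['fitted']['mProp']:.4f}")
print(f"relative error : {report['relative_error']['mProp']:.2%}")
print(f"residual cost  : {report['cost']:.3e}  "
      f"({report['n_evals']} model evaluations)")
print("\nmProp is the fraction of labelled protein still belt-bound at Day 0;"
      "\nthe residual cost is the squared mismatch of the normalised Day-7"
      "\ndistributions (0 = data reproduced exactly).")
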