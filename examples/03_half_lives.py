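"""Molecular vs apparent half-life of the labelled protein.

The model's molecular half-life follows directly from the fitted
degradation rate (ln2/d).  The "apparent" half-life read off imaging data
assumes each window decays exponentially in isolation — but transport keeps
feeding distal windows, so apparent half-lives vary along the dendrite even
when molecular degradation is flat.  This script prints both on synthetic
data generated with the published CA1 parameters.
"""

from dataclasses import replace

from sushibelt import (
    CA1_DEMAND_3M,
    CA1_PARAMS_3M,
    CA1_WINDOW_DISTANCES,
    DG_PARAMS_3M,
    DG_PARAMS_3W,
    SynthSpec,
    apparent_half_life,
    half_life,
    make_dataset,
)

print("molecular half-lives from fitted degradation intercepts:")
for label, p in [("CA1 3-month", CA1_PARAMS_3M), ("DG  3-month", DG_PARAMS_3M),
                 ("DG  3-week ", DG_PARAMS_3W)]:
    print(f"  {label}: dvA = {p.dvA:.3e} 1/s -> t1/2 = {half_life(p.dvA):6.3f} d")

demand = [CA1_DEMAND_3M[name] for name in CA1_WINDOW_DISTANCES]
spec = SynthSpec(kind="cable", n_windows=20, comps_per_window=3,
                 window_length=30.0, demand=demand,
                 truth=replace(CA1_PARAMS_3M, demand={}), noise_sd=0.0)
_, table, truth = make_dataset(spec)
app = apparent_half_life(table["day0"].to_numpy(), table["day7"].to_numpy())

print(f"\napparent per-window half-lives on synthetic CA1 data "
      f"(molecular: {half_life(truth.dvA):.2f} d):")
for name, t in zip(table["name"], app):
    print(f"  {name:10s} {t:6.2f} d")
print("\nEvery window's apparent t1/2 sits well above the molecular value:"
      "\ndetachment keeps feeding synapses from the belt-bound reserve, so the"
      "\nper-window decline understates true turnover.  (NaN would mark windows"
      "\nthat grew outright.)")
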