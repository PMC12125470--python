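#!/usr/bin/env python
"""Lagrangian particle deposition versus impaction factor (mouse).

Releases 2000 unit-density particles per size from the nostril across
1.5-43 um, tallies deposition efficiency, and writes the efficiency-vs-
impaction-factor curve.
"""

from pathlib import Path

from nosegc.flow import solve_flow
from nosegc.nose import ChannelNetwork
from nosegc.particles import run_deposition_study
from nosegc.pipeline import FLOW_ML_MIN, ML_MIN_TO_M3_S

OUT = Path("results")
net = ChannelNetwork.from_json((OUT / "mouse" / "network.json").read_text())
flow = solve_flow(net, FLOW_ML_MIN["mouse"] * ML_MIN_TO_M3_S, 0.1)
curve = run_deposition_study(net, flow, [1.5, 3, 5, 8, 12, 15, 25, 43], 2000, seed=0)
curve.to_csv(OUT / "mouse" / "deposition_curve.csv", index=False)
print(curve.to_string(index=False))
high = curve[curve.impaction_factor > 100.0]
print(
    f"\nminimum efficiency for impaction factor > 100: {100 * high.efficiency.min():.1f}% "
    f"(sizes {list(high.d_p_um)}); lost particles: {int(curve.lost.sum())}"
)
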