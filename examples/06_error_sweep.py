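"""Sweep the three error axes and compare their impact on coverage.

A scaled-down version of the full 6x6x6 sweep: the photobleach half-life axis
is traversed at fixed dye failure and Edman efficiency, and vice versa. The
range of coverage along each axis measures which error dominates. Axis ranges
only separate cleanly when each axis is traversed across its full span on a
proteome large enough to damp sampling noise, hence 400 proteins and the
six-value presets here (about half a minute).
"""

import math

from fluorosim import (
    SimulationConfig,
    generate_synthetic_proteome,
    human_like_composition,
    parameter_sweep,
)

proteome = generate_synthetic_proteome(
    400, composition=human_like_composition(), seed=11
)
config = SimulationConfig(
    protease="gluc", anchor="cysteine", scheme="K+Y+W",
    cycles=30, depth=100, seed=7, min_count=10,
)

photobleach = parameter_sweep(
    proteome, config,
    dye_failure_values=[0.15],
    edman_efficiency_values=[0.94],
    half_life_cycles_values=[math.inf, 5400.0, 1800.0, 600.0, 210.0, 70.0],
)
dye = parameter_sweep(
    proteome, config,
    dye_failure_values=[0.0, 0.05, 0.10, 0.15, 0.20, 0.25],
    edman_efficiency_values=[0.94],
    half_life_cycles_values=[1800.0],
)

print("photobleach axis (u=0.15, p=0.94):")
print(photobleach[["half_life_cycles", "coverage"]].to_string(index=False))
print("\ndye-failure axis (half-life 1800, p=0.94):")
print(dye[["dye_failure", "coverage"]].to_string(index=False))

pb_range = photobleach["coverage"].max() - photobleach["coverage"].min()
dye_range = dye["coverage"].max() - dye["coverage"].min()
print(f"\ncoverage range along photobleach axis: {pb_range:.3f}")
print(f"coverage range along dye-failure axis: {dye_range:.3f}")
winner = "photobleaching" if pb_range > dye_range else "dye failure"
print(f"=> {winner} spans the wider coverage range on this grid.")
print("Photobleaching corrupts reads (drops land at wrong cycles) rather than")
print("merely shortening them as dye failure does.")
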