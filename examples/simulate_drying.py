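"""Forward-simulate the drying of a wildtype and an ost1-2 mutant plant.

Runs the calibrated genotype presets through the two-compartment water
transport model and prints the three-phase phenology: how long the plant
defends its optimal water content (phase I), when the permanent wilting
point interrupts soil uptake, and the leaf water content at that moment.
"""

import numpy as np

from stomadry import PRESETS, segment_phases, simulate_drying

for name in ("wildtype", "ost1-2"):
    preset = PRESETS[name]
    traj = simulate_drying(preset.params, horizon_h=14 * 24.0,
                           m_dry=preset.m_dry)
    phases = segment_phases(traj.to_series(genotype=name))
    wt_at_wilt = np.interp(traj.wilt_time_h, traj.times_h,
                           traj.water_wt_pct)
    print(f"{name}:")
    print(f"  initial plateau        {phases.plateau_wtpct:5.1f} wt%")
    print(f"  phase I ends           {phases.phase_i_end_h / 24:5.1f} d")
    print(f"  wilting point reached  {traj.wilt_time_h / 24:5.1f} d")
    print(f"  water content at wilt  {wt_at_wilt:5.1f} wt%")

print("\nThe mutant cannot throttle its stomata under drought, spends the "
      "soil water faster,\nand leaves phase I about three days earlier "
      "than the wildtype.")
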