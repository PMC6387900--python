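"""Reproduce the zonation design: sweep insert heights to the 15 % target.

Raises the cells in 1 mm increments from the chamber base until the mean
cell-surface oxygen first reaches 15 % O2, labels the three liver-zone
configurations (base = perivenous, 4 mm = central, stop = periportal) and
prints the per-zone design table.
"""

import zonesim as zs

sweep = zs.height_sweep(zs.build_geometry(), target_pct=15.0, step=1e-3, refinement_level=2)

print("height sweep (1 mm steps):")
for s in sweep.summaries:
    print(
        f"  h = {s.insert_height * 1e3:4.1f} mm : mean O2 "
        f"{s.mean_surface_oxygen_pct:6.2f} %, mean shear {s.mean_surface_shear:.3e} Pa"
    )
print(f"target 15 % first reached at {sweep.stop_height * 1e3:.0f} mm\n")

zones = zs.select_zones(sweep, central_height=4e-3)
table = zs.table1_report(zones)
print(table.to_string(index=False))
print()
print("Each row is one chamber of the three-chamber circuit: the oxygen the")
print("monolayer sees spans the physiological periportal-to-perivenous range")
print("while shear stays far below damaging levels at every height.")
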