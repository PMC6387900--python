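"""Solve one perfused-chamber configuration and report the cell microenvironment.

Builds the default chamber with the coverslip raised 4 mm (the central-zone
configuration), solves steady flow and oxygen transport, and prints what the
cells experience: mean/minimum oxygen at the monolayer and the mean shear
stress magnitude.
"""

import zonesim as zs

config = zs.build_geometry(insert_height=4e-3)
mesh = zs.build_mesh(config, refinement_level=2)
flow = zs.solve_flow(config, mesh)
conc = zs.solve_oxygen(config, mesh, flow)

profile = zs.surface_oxygen_profile(conc, config)
mean_c, min_c = zs.surface_stats(profile)
shear = zs.mean_surface_shear(zs.wall_shear(flow, config))

print(f"insert height        : {config.geometry.insert_height * 1e3:.0f} mm")
print(f"mesh                 : {mesh.n_elements} cells (level 2)")
print(f"inlet Reynolds number: {flow.reynolds_number:.2f}")
print(f"mean surface O2      : {mean_c:.4f} mol/m^3 = {zs.conc_to_percent(mean_c):.2f} %")
print(f"min  surface O2      : {min_c:.4f} mol/m^3 = {zs.conc_to_percent(min_c):.2f} %")
print(f"mean surface shear   : {shear:.3e} Pa")
print()
print("The mean O2 sits in the mid-lobular (central zone) window and the")
print("shear is orders of magnitude below levels that damage hepatocytes.")
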