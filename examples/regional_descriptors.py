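"""Local viscosity and mobility descriptors around CALB's alpha5 helix.

Uses the shipped reference table of regional shell dynamics (from
published microsecond MD of CALB) to compute, for each solvent around the
mobile alpha5 helix: the surface retardation factor (shell vs bulk
diffusion), the solvent mobility ratio (shell diffusion vs water's shell
diffusion around the same helix), and the local interfacial viscosity.
"""

from solvshell.reference import bulk_solvent_table, regional_dynamics_table
from solvshell.viscosity import (
    local_viscosity,
    mobility_descriptors,
    model_viscosity,
)

REGION = "alpha5"
bulk = bulk_solvent_table().set_index("solvent")
reg = regional_dynamics_table()
reg = reg[reg["region"] == REGION].set_index("solvent")
d_water_region = reg.loc["water", "D_1e5cm2s"]

print(f"Solvation-shell descriptors around {REGION}:")
print(f"{'solvent':14s} {'D_shell':>8s} {'retard':>7s} {'mobility':>9s} "
      f"{'eta_local':>10s}")
for solvent in bulk.index:
    b = bulk.loc[solvent]
    eta_model = model_viscosity(b["eta_exp_mPas"], b["D_exp_1e5cm2s"],
                                b["D_model_1e5cm2s"])
    d_local = reg.loc[solvent, "D_1e5cm2s"]
    mob, ret = mobility_descriptors(d_local, d_water_region,
                                    b["D_model_1e5cm2s"])
    eta_loc = local_viscosity(eta_model, b["D_model_1e5cm2s"], d_local)
    print(f"{solvent:14s} {d_local:8.3f} {ret:7.2f} {mob:9.2f} "
          f"{eta_loc:10.2f}")
print("\nretard = D_shell/D_bulk (1 means unhindered); mobility = "
      "D_shell/D_water,shell;\neta_local (mPa·s) is the interfacial "
      "viscosity the helix actually feels — the\nquantity Kramers-type "
      "rate models should use instead of bulk viscosity.")
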