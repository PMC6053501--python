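"""Apparent viscosity of each bulk solvent model.

Experimental shear viscosities are scaled by the ratio of experimental to
simulated self-diffusion coefficients (a Stokes–Einstein argument), giving
the viscosity the solvent *model* effectively exhibits.  That apparent
viscosity — not the experimental one — is what local-viscosity descriptors
should be built on, because the simulations move solvent at the model's
rate.
"""

from solvshell.reference import bulk_solvent_table
from solvshell.viscosity import model_viscosity, percent_error

table = bulk_solvent_table()
print(f"{'solvent':14s} {'eta_exp':>8s} {'D_exp':>6s} {'D_model':>8s} "
      f"{'%err':>6s} {'eta_model':>10s}")
for _, r in table.iterrows():
    eta = model_viscosity(r["eta_exp_mPas"], r["D_exp_1e5cm2s"],
                          r["D_model_1e5cm2s"])
    err = percent_error(r["D_model_1e5cm2s"], r["D_exp_1e5cm2s"])
    print(f"{r['solvent']:14s} {r['eta_exp_mPas']:8.2f} "
          f"{r['D_exp_1e5cm2s']:6.2f} {r['D_model_1e5cm2s']:8.2f} "
          f"{err:6.1f} {eta:10.2f}")
print("\nViscosity in mPa·s, diffusion in 1e-5 cm^2/s. The %err column is "
      "the model's\ndiffusion error vs experiment; eta_model is the "
      "apparent viscosity the model\nexhibits, used downstream for "
      "local-viscosity descriptors.")
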