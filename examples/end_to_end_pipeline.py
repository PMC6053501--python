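"""Full pipeline on a synthetic solvated system.

Builds a labelled two-region "protein" in a box of Brownian solvent with a
known diffusion coefficient, then runs the complete analysis from one
config: shell membership -> residence times and shell diffusion with
block-averaged 95% CIs -> flexibility -> output tables + manifest.
"""

import tempfile
from pathlib import Path

from solvshell import synth
from solvshell.pipeline import run_pipeline

layout = {
    "helixA": {"n_residues": 5, "class": "helix", "exposure": "Ext"},
    "loopB": {"n_residues": 5, "class": "loop", "exposure": "Ext"},
}
traj, regions, truth = synth.gen_solvated_fixture(
    layout, solvent_D=1e-3, shell_cutoff=0.5, seed=7,
    n_solvent=200, n_frames=200,
)

outdir = Path(tempfile.mkdtemp()) / "bundle"
bundle = run_pipeline({
    "runs": {"solvent": {"trajectory": traj, "cutoff_nm": 0.5}},
    "regions": {
        n: {"class": r.klass, "residues": [list(x) for x in r.resid_ranges]}
        for n, r in regions.items()
    },
    "outdir": str(outdir),
    "block_count": 4,
    "seed": 7,
})

dyn = bundle["dynamics"]
print("per-region solvent dynamics (true D = 1.0 x 1e-5 cm^2/s):")
cols = ["region", "tau_res_corr_ps", "tau_res_corr_ci",
        "D_local_1e5cm2s", "D_local_ci"]
print(dyn[cols].round(3).to_string(index=False))
print(f"\ntables written to {outdir}")
print("Residence times are 1/e survival times per 50-ps block "
      "(mean ± student-t 95% CI);\nD comes from the MSD of molecules "
      "in each region's shell at the time origin.")
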