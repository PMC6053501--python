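# solvshell

Regional solvation-shell dynamics around proteins, and what they do to
protein flexibility.

Solvent friction is local: an α-helix does not feel the bulk viscosity of
the solvent, it feels the mobility of the few solvent molecules in its own
solvation layer. `solvshell` takes an MD trajectory of a solvated protein
(the motivating system is *Candida antarctica* lipase B, a solvent-tolerant
enzyme simulated in water, acetonitrile, *n*-butanol, *tert*-butanol and
cyclohexane) plus a map of named regions, and computes, per region and
solvent:

* **shell definition** — proximal radial distribution function g(r) of
  solvent reference sites vs distance to the nearest region atom; the
  first minimum after the first maximum sets the shell cutoff;
* **residence time** — the 1/e time of the survival correlation
  C_res(t) = ⟨h(t)·h(0)⟩ of the shell-occupancy indicator h, and
  independently the mean of histogrammed first-exit times;
* **shell diffusion coefficient** — Einstein relation ⟨r²⟩ = 2αDt fit to
  the MSD of molecules in the shell at the time origin (α = 3);
* **hydrogen-bond lifetime** — 1/e time of the intermittent H-bond
  indicator autocorrelation ⟨h(0)h(t)⟩/⟨h⟩ under the 0.35 nm / 30°
  donor–acceptor criterion;
* **viscosity descriptors** — apparent model viscosity
  η_model ≈ η_exp·D_exp/D_model, local (interfacial) viscosity
  η_local ≈ η_bulk·D_bulk/D_local (or the τ₂-reorientation variant
  η_bulk·τ₂,interface/τ₂,bulk), solvent mobility ratio
  D_solvent,region/D_water,region, and surface retardation factor
  D_solvent,region/D_solvent,bulk;
* **regional flexibility** — per-residue RMSF (all-atom, side-chain or Cα)
  after rigid-body superposition, summed over a region and expressed as a
  ratio to the same region's aqueous value, then correlated (Pearson r)
  against the four mobility descriptors;
* **conformational kinetics** — a 1-D inter-region nearest-distance
  feature, discretized into microstates, reversible maximum-likelihood
  Markov state model, implied timescales t_i(τ) = −τ/ln λ_i(τ), PCCA+
  coarse-graining to three metastable states, discrete-output hidden
  Markov refinement by EM, and transition rates k_ij = T_ij(τ)/τ with
  bootstrap errors — with Kramers' high-friction law
  k ∝ (1/η_local)·e^(−H*/RT) available to interpret the rates.

Every estimator has a generator in `solvshell.synth` that produces data
with known ground truth (Brownian solvent, exponential shell exchange,
telegraph H-bond traces, 3-state jump features, harmonic per-residue
fluctuations, overdamped double-well Langevin dynamics), so the whole
stack is validated by parameter recovery.

Units: lengths nm, times ps, diffusion reported in 10⁻⁵ cm²/s, viscosity
mPa·s, conformational rates in 10⁻³ ns⁻¹.

## Worked example

Local-viscosity descriptors around the mobile α5 helix of CALB, from the
shipped reference table of regional shell dynamics
(`python examples/regional_descriptors.py`):

```
Solvation-shell descriptors around alpha5:
solvent         D_shell  retard  mobility  eta_local
water             1.384    0.56      1.00       1.48
n-butanol         0.368    0.80      0.27       3.69
tert-butanol      0.180    0.62      0.13       5.58
acetonitrile      3.010    0.65      2.17       0.52
cyclohexane       0.950    0.90      0.69       1.52
```

D_shell is the solvent's diffusion coefficient in the α5 solvation layer
(10⁻⁵ cm²/s); `retard` compares it with the solvent's own bulk mobility
(cyclohexane runs at 90% of bulk around α5); `mobility` compares it with
water's mobility around the same helix; `eta_local` is the interfacial
viscosity (mPa·s) the helix actually feels — acetonitrile's fast shell
(0.52 mPa·s) goes with high α5 flexibility, *tert*-butanol's sluggish
shell (5.6 mPa·s) with suppressed motion.

Parameter recovery for the diffusive estimators
(`python examples/diffusion_and_residence.py`):

```
Brownian solvent: true D = 1.00, MSD-fit D = 1.002 (1e-5 cm^2/s)
Shell exchange: true residence = 40.0 ps, 1/e-time = 40.1 ps, first-exit mean = 40.5 ps
```

The other examples cover the bulk-viscosity table arithmetic
(`bulk_viscosity_table.py`), MSM/HMM rate recovery with bootstrap errors
(`msm_rates.py`), the Kramers 1/γ friction law on a double well
(`kramers_scaling.py`), and the full pipeline on a synthetic solvated
system (`end_to_end_pipeline.py`).

A thin CLI mirrors the library:
`solvshell simulate|rdf|shell|dynamics|viscosity|rmsf|correlate|msm|run`;
`solvshell run config.yaml` executes the whole pipeline from one YAML
config and writes CSV/JSON tables plus a manifest.

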