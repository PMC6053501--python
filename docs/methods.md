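# Methods

This note records the models and estimators `solvshell` implements, the
numerical choices behind them, what the synthetic generators do and do not
emulate, and the package's known limitations.

## System model and units

A trajectory is frames × atoms × 3 coordinates in nm with a per-frame
orthorhombic box, a fixed frame spacing dt (ps), and an atom table that
assigns every atom to a molecule (`mol_id`) and a class (protein, solvent,
ion). Triclinic boxes are rejected explicitly: all supported analyses only
need cubic/orthorhombic minimum-image arithmetic, with displacement
components mapped into (−L/2, L/2]. Standard formats (PDB, GRO, XTC, DCD)
are read through MDAnalysis and converted to nm/ps; a plain-text fixture
format (`write_fixture`/`read_fixture`) round-trips coordinates bitwise on
their decimal representation so tests never depend on binary readers.

Report units follow the field's tables: diffusion in 10⁻⁵ cm²/s
(1 nm²/ps = 10³ on that scale), viscosity in mPa·s, residence and H-bond
times in ps, conformational rates in 10⁻³ ns⁻¹. Physical constants are
CODATA (k_B = 1.380649×10⁻²³ J/K, R = 8.314462618 J/(mol·K)); the working
temperature defaults to 300 K (301 K is used for tert-butanol systems,
just above that solvent's melting point).

## Shell definition

The proximal RDF g(r) histograms, per solvent molecule, the distance from
its reference site to the *nearest* atom of the region. Reference sites
follow spectroscopic convention: water and alcohols their oxygen, nitriles
the nitrogen, species without a rule their centre of geometry. Because the
distance field is "nearest atom of an irregular cluster", the shell
volumes are not spherical; they are estimated by Monte-Carlo insertion
(10⁵ uniform points, fixed seed 13) into the frame-0 configuration. A
second normalisation ("plateau": spherical shell volumes rescaled so the
outermost 20% of bins average 1) is provided as a cross-check; the two
agree where g(r) has plateaued.

The first-shell cutoff is the first local minimum after the first maximum
of g(r) smoothed by a centred moving average (default 3 bins, ties broken
toward smaller r), reported with the bin width as its uncertainty. When
detection is skipped, tabulated defaults per solvent are used
(acetonitrile 0.5 nm, n-butanol 0.6, tert-butanol 0.4, cyclohexane 0.7,
water 0.5; buried interior regions one layer further out: 0.7/0.8/0.6/0.9
and 0.7 for water). Water's cutoff deliberately spans two hydration layers
for comparability with reported hydration-layer residence times; organics
use the first shell only. Membership uses all region atoms by default; a
side-chain-only scope is a flag, since RDFs around side chains and
membership against all atoms are both defensible conventions and the
choice is not derivable from first principles.

## Residence time

The survival correlation C_res(t) = ⟨h(t)·h(0)⟩ averages, over all in-shell
time origins, the probability that a molecule has remained continuously in
the shell for a further time t (first-exit / absorbing convention:
monotone non-increasing, C_res(0) = 1). The residence time is the linear
interpolation of the 1/e crossing; a curve that never reaches 1/e within
the probed window is returned as a flagged lower bound, never as a number.
Independently, first-exit times are histogrammed per (molecule, entry)
episode — an exit observed between frames is assigned to the midpoint of
the frame interval, which removes the O(dt/2) discretisation bias — and
averaged. On memoryless (exponential) exchange the two estimators agree,
and the suite checks their statistical equivalence with a paired block CI.
A re-entry-tolerant mode evaluates the literal product ⟨h(t)h(0)⟩, and a
transient-exit allowance t* (default 0 ps) can bridge brief excursions
before episode extraction.

## Shell diffusion

MSD uses unwrapped coordinates (frame-to-frame minimum-image increments,
valid while no molecule moves half a box edge per frame). Shell
conditioning is applied **at the time origin only**: molecules in the
shell at t₀ are tracked for the full lag window even if they exit.
Conditioning on continuous residence would bias the sample toward slow
molecules; origin-only conditioning measures the mobility of the shell
population. D is the least-squares slope of the MSD over the fit window
(default 2–10 ps, origins every 1 ps) divided by 2α with α = 3. A negative
fitted slope is flagged rather than silently truncated; fewer than five
lag points in the window is an error.

## Hydrogen bonds and reorientation

The H-bond indicator uses the standard geometric criterion
(donor–acceptor ≤ 0.35 nm, H–donor–acceptor angle ≤ 30°), enumerated in
both directions between a region and the solvent. The reported lifetime is
the 1/e time of the intermittent autocorrelation C(t) = ⟨h(0)h(t)⟩/⟨h⟩
(Luzar–Chandler intermittent convention; the forward/backward rate
decomposition of the full kinetic model is out of scope). Apolar solvents
with no donor/acceptor pairs report "not applicable"; non-decaying bonds
report a lower bound. Reorientation uses C₂(t) = ⟨P₂(u(0)·u(t))⟩ of a
molecular axis, whose 1/e time τ₂ feeds the alternative interfacial
viscosity η_bulk·τ₂,int/τ₂,bulk; for isotropic rotational diffusion
τ₂ = 1/(6D_r), which the suite uses as a recovery oracle.

All 1/e times are linear interpolations between bracketing samples; no
functional fitting is applied anywhere, so the estimators are assumption-
free about the decay shape.

## Uncertainties

Every per-region observable is estimated per contiguous trajectory block
and reported as mean ± t_{n−1,0.975}·s/√n with the sample (ddof = 1)
standard deviation. Block length is a configuration parameter: production
MD would use tens of ns per block; the desk-scale tests and examples use
ps-scale blocks, which is a change of problem size, not of method.

## Viscosity descriptors and Kramers rates

All descriptor arithmetic (η_model = η_exp·D_exp/D_model,
η_local = η_bulk·D_bulk/D_local, mobility ratio, retardation) is performed
on unrounded inputs and rounded only for display; the shipped bulk-solvent
reference table therefore stores only inputs (experimental η and D, model
D), and derived columns are always recomputed. Stokes–Einstein utilities
(D_T = k_BT/6πηr, D_R = k_BT/8πηr³) are evaluated in SI and converted.
The Kramers high-friction rate k = A·(1/η_local)·e^(−H*/RT) is exposed as
a function of a barrier (kJ/mol), a local viscosity and a prefactor; the
1/γ half of the law is validated on overdamped double-well Langevin
dynamics, where time-rescaling makes the inverse-friction scaling exact in
law.

## RMSF and regional flexibility

Superposition is a least-squares rigid-body fit (Kabsch via SVD) of each
frame's Cα set, by default onto the trajectory's own mean structure
(first-pass fit to frame 0, one refit to the mean): RMSF measures
fluctuation about the mean, not displacement from a crystal structure.
Collinear fit atoms are rejected as degenerate. Per-residue RMSF is the
unweighted mean of per-atom RMS deviations over the variant's atom set
(all-atom, side-chain, Cα); mass weighting is available but not default.
Regional "integration" is the plain sum of per-residue RMSF over the
region's residues, and solvent effects are the ratio of that sum to its
aqueous value (so water is 1 by construction). One caveat the tests make
explicit: an unweighted rigid fit on strongly heterogeneous fluctuations
leaks the loud residues' motion into quiet ones (the fit's 6 rigid degrees
of freedom are estimated from all atoms), so recovery oracles measure the
drift-free synthetic fixtures without refitting.

## Correlation panels

For each region × RMSF variant, flexibility ratios are correlated (sample
Pearson r) against four descriptors: 1/η_bulk,model, the solvent mobility
ratio, the surface retardation factor, and 1/η_local. The water point
(x_water, 1) is included by default — the ratio definition forces y = 1 —
and can be dropped by flag. No p-values are attached at n ≤ 5 points. On
synthetic studies where flexibility is constructed as a/η_local plus
noise, the 1/η_local panel attains the highest r in nearly every seed,
which is the level at which the "local beats bulk" claim is literally
testable.

## Conformational kinetics

The feature is the per-frame minimum heavy-atom distance between two
regions (e.g. the two lids over a binding cleft, whose distance defines
closed / crystallographic / open conformations). Discretisation is uniform
1-D binning (default 60 bins; rates are insensitive to 30 vs 100 bins
within bootstrap error), with empty bins removed and estimation restricted
to the largest strongly connected set of the count graph. The microstate
transition matrix is the reversible maximum-likelihood estimate
(fixed-point iteration on the symmetric flux matrix, stopping at relative
log-likelihood gain < 10⁻¹⁰), appropriate because equilibrium MD satisfies
detailed balance. Implied timescales t_i(τ) = −τ/ln λ_i(τ) are computed
via the π-symmetrised spectrum; flatness in τ selects the working lag, and
eigenvalues at or above 1 are reported as +∞ (an upper bound).

PCCA+ membership vectors come from the inner-simplex vertex search on the
top n_meta right eigenvectors followed by projection onto the probability
simplex; rows always lie in [0,1] and sum to 1, and a missing spectral gap
at n_meta triggers a warning. Three metastable states are the default,
matching the three known conformations of the motivating enzyme.

The hidden Markov refinement fits a discrete-output HMM by EM (hmmlearn's
categorical HMM) on lag-strided microstate sequences (single phase offset,
so strided transitions are non-overlapping), initialised from the PCCA+
memberships and the projected coarse transition matrix. The EM stopping
tolerance is interpreted per observation (10⁻⁸ × n_obs on the total
log-likelihood); an absolute 10⁻⁸ on μs-scale inputs would chase machine
noise. The estimated transition matrix is projected onto detailed balance
using its stationary distribution — reversible estimation pools forward
and backward transition statistics, halving the variance of rare-rate
estimates — and hidden states are canonically ordered by mean observed
feature value so labels are reproducible. Non-convergence raises, with the
log-likelihood trace attached.

Rates are defined as k_ij = T_ij(τ)/τ at the working lag (first-order in
τ; a generator-matrix logarithm is deliberately not used). This definition
carries an O(kτ) bias, so recovery studies run at a lag where kτ ≲ 0.01;
the estimator's variance is lag-independent, so nothing is lost. Bootstrap
uncertainties resample whole trajectories with replacement (default 5
resamples) and refit the entire microstate → PCCA+ → HMM → rates pipeline.

## Synthetic generators: what they emulate, and what they do not

Each generator reproduces exactly the statistical structure one estimator
assumes, with all randomness from one explicit per-call seed (default 7):

* `gen_brownian` — free Brownian points in a periodic box; per-axis step
  variance exactly 2·D·dt. No solvent structure, no hydrodynamics.
* `gen_shell_exchange` — exponential first-exit occupancy (optionally with
  re-entry); the geometric per-step exit probability 1−e^(−λdt) is the
  exact discrete sampling of the exponential law.
* `gen_telegraph` — the exact discrete skeleton of the two-state
  continuous-time chain, so the fluctuation autocorrelation is exactly
  e^(−(k_on+k_off)t) and occupancy is k_on/(k_on+k_off). No H-bond
  geometry is emulated.
* `gen_jump_feature` — a continuous-time Markov jump process simulated
  exactly (exponential waiting times) and sampled on the frame grid, so
  the sampled chain's transition matrix is exactly exp(K·dt) (verified by
  binomial z-tests); observed feature = state centre + Gaussian noise.
* `gen_harmonic_protein` — one CA per residue on a helical arc with
  isotropic per-coordinate SD rmsf/√3; no covariance between residues.
* `gen_double_well_langevin` — Euler–Maruyama on the overdamped equation
  γdx = −U′(x)dt + √(2RTγ)dW with U = H*(x²−1)². Two stability guards
  raise with a suggested dt: the configured dt·γ < 0.1 bound, and the
  drift bound dt·max|U″|/γ ≤ 0.25, which is the one that actually binds
  when the barrier is stiff (for overdamped dynamics, larger γ is *more*
  forgiving at fixed dt).
* `gen_solvated_fixture` — labelled CA clusters (small harmonic jitter,
  default RMSF 0.05 nm, so flexibility analyses are well-posed; set 0 for
  a frozen cluster) in a box of Brownian solvent.

Passing recovery tests therefore demonstrates estimator correctness under
each estimator's own assumptions. They do not demonstrate robustness to
what real solvation data adds: non-exponential residence-time tails,
caging and subdiffusion at short times, correlated protein–solvent
motion, rugged 1-D features that are only approximately Markovian after
discretisation.

## Problem sizes

The test suite and examples run at desk scale, chosen for statistical
power of each check: diffusion recovery at 10³ particles × 2×10³ frames,
residence and telegraph recovery at 10⁴ series, RMSF at 5×10³ frames, MSM
rate recovery at 10⁶ total frames over five trajectories, Kramers scaling
at ~50 replicas × (1.5–3.75)×10⁵ steps. Production use on real
trajectories only changes these sizes and the block length, not the
estimators.

## Known limitations

Orthorhombic boxes only; no velocities or forces; no SASA decomposition;
no Grote–Hynes frequency-dependent friction; no Bayesian MSM posteriors,
TICA, or multi-dimensional featurisation; no Chapman–Kolmogorov test
beyond implied-timescale flatness; the H-bond machinery enumerates pairs
directly and is intended for region-scale selections, not whole-box
neighbour searching.
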