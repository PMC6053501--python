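"""Protein flexibility: superposition, per-residue RMSF, regional ratios.

RMSF is the per-atom root-mean-square deviation from the time-mean
position after rigid-body superposition.  The superposition reference is
the trajectory's own mean structure (first-pass fit to frame 0, then one
refit to the resulting mean), since RMSF measures fluctuation about the
mean rather than displacement from a crystal structure.  Regional
flexibility is the plain sum of per-residue RMSF over a region's residues,
and solvent effects are expressed as the ratio of that integral to its
value in water.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .io import RegionSpec, Trajectory

__all__ = [
    "FlexibilityRecord",
    "superpose",
    "rmsf",
    "rmsf_profile",
    "regional_flexibility",
    "flexibility_ratio",
    "radius_of_gyration",
    "structure_checks",
]

_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
           "P": 30.974}

VARIANTS = ("all_atom", "side_chain", "c_alpha")
_BACKBONE = {"N", "CA", "C", "O", "OXT", "H", "HA", "HN", "H1", "H2", "H3"}


@dataclass
class FlexibilityRecord:
    region: str
    variant: str
    integrated_rmsf: float      # nm (sum over region residues)
    ratio_vs_water: float

    def __post_init__(self) -> None:
        if self.integrated_rmsf < 0:
            raise ValueError("integrated RMSF must be >= 0")


def _fit_atom_indices(traj: Trajectory,
                      fit_atoms: Sequence[int] | None) -> np.ndarray:
    if fit_atoms is not None:
        ix = np.asarray(fit_atoms, dtype=int)
    else:
        ix = np.array(
            [a.index for a in traj.atoms
             if a.mol_class == "protein" and a.name == "CA"], dtype=int,
        )
        if ix.size == 0:
            ix = traj.atom_indices("protein")
    if ix.size < 3:
        raise ValueError("need at least 3 fit atoms for superposition")
    return ix


def _kabsch_apply(mobile: np.ndarray, ref: np.ndarray,
                  fit_ix: np.ndarray) -> np.ndarray:
    """Rigid-body fit of one frame onto ref over fit_ix, applied to all
    atoms of the frame."""
    mob_fit = mobile[fit_ix]
    ref_fit = ref[fit_ix]
    mc = mob_fit.mean(axis=0)
    rc = ref_fit.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_fit - rc, mob_fit - mc)
    return rot.apply(mobile - mc) + rc


def superpose(
    traj: Trajectory,
    reference: np.ndarray | None = None,
    fit_atoms: Sequence[int] | None = None,
) -> Trajectory:
    """Least-squares rigid-body superposition of every frame.

    ``reference`` is an (n_atoms, 3) structure; by default the two-pass
    mean structure of the trajectory itself.  Fitting uses the C-alpha
    set unless ``fit_atoms`` is given.  Collinear fit atoms raise.
    """
    fit_ix = _fit_atom_indices(traj, fit_atoms)
    probe = traj.coords[0, fit_ix]
    if np.linalg.matrix_rank(probe - probe.mean(axis=0), tol=1e-9) < 2:
        raise ValueError("fit atoms are collinear; superposition is degenerate")

    if reference is None:
        ref = traj.coords[0]
        for _ in range(2):                     # fit -> mean -> refit
            aligned = np.stack(
                [_kabsch_apply(traj.coords[f], ref, fit_ix)
                 for f in range(traj.n_frames)]
            )
            ref = aligned.mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
        aligned = np.stack(
            [_kabsch_apply(traj.coords[f], ref, fit_ix)
             for f in range(traj.n_frames)]
        )
    big = float(np.abs(aligned).max()) * 4 + 1.0
    return Trajectory(
        atoms=traj.atoms, coords=aligned,
        box=np.full((traj.n_frames, 3), big),   # alignment breaks PBC
        dt=traj.dt, origin_time=traj.origin_time,
    )


def rmsf(aligned: Trajectory, variant: str = "all_atom") -> pd.Series:
    """Per-residue RMSF (nm) of an aligned trajectory.

    Per atom: RMS deviation from the time-mean position.  Per residue:
    unweighted mean over the variant's atom set (``all_atom``,
    ``side_chain`` or ``c_alpha``).  Residues with no atoms in the
    variant (e.g. glycine side chains) get NaN.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown RMSF variant {variant!r}")
    if aligned.n_frames < 2:
        raise ValueError("need at least 2 frames for RMSF")
    mean = aligned.coords.mean(axis=0)
    dev = aligned.coords - mean[None]
    per_atom = np.sqrt((dev**2).sum(axis=2).mean(axis=0))

    resids = sorted({a.resid for a in aligned.atoms
                     if a.mol_class == "protein"})
    values = {}
    for r in resids:
        atoms = [a for a in aligned.atoms
                 if a.mol_class == "protein" and a.resid == r]
        if variant == "side_chain":
            atoms = [a for a in atoms if a.name not in _BACKBONE]
        elif variant == "c_alpha":
            atoms = [a for a in atoms if a.name == "CA"]
        values[r] = (
            float(np.mean([per_atom[a.index] for a in atoms]))
            if atoms else np.nan
        )
    return pd.Series(values, name=variant)


def rmsf_profile(traj: Trajectory, variant: str = "all_atom",
                 fit_atoms: Sequence[int] | None = None) -> pd.Series:
    """Convenience: superpose then compute per-residue RMSF."""
    return rmsf(superpose(traj, fit_atoms=fit_atoms), variant)


def regional_flexibility(profile: Mapping[int, float] | pd.Series,
                         region: RegionSpec) -> float:
    """Integrated regional RMSF: sum of per-residue values over the
    region's residues (rectangle rule in residue index)."""
    prof = pd.Series(profile)
    resids = [r for r in prof.index if region.contains(int(r))]
    if not resids:
        raise ValueError(
            f"region {region.name!r} residues absent from the profile"
        )
    return float(prof.loc[resids].sum())


def flexibility_ratio(value_solvent: float, value_water: float) -> float:
    """Regional flexibility relative to the aqueous run."""
    if value_water == 0:
        raise ValueError("water integrated RMSF is zero; ratio undefined")
    return value_solvent / value_water


def radius_of_gyration(traj: Trajectory) -> np.ndarray:
    """Per-frame mass-weighted radius of gyration of the protein atoms
    (all atoms if none are labelled protein), in nm."""
    prot_ix = traj.atom_indices("protein")
    if prot_ix.size == 0:
        prot_ix = np.arange(traj.n_atoms)
    masses = np.array(
        [_MASSES.get(traj.atoms[i].element, 12.011) for i in prot_ix]
    )
    xyz = traj.coords[:, prot_ix, :]
    com = (xyz * masses[None, :, None]).sum(axis=1) / masses.sum()
    d2 = ((xyz - com[:, None, :]) ** 2).sum(axis=2)
    return np.sqrt((d2 * masses[None]).sum(axis=1) / masses.sum())


def structure_checks(
    traj: Trajectory, reference: np.ndarray,
    fit_atoms: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sanity checks: per-frame C-alpha RMSD to a reference (after
    superposition) and mass-weighted radius of gyration.

    ``reference`` must cover the same atom set as the trajectory.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (traj.n_atoms, 3):
        raise ValueError(
            f"reference has shape {ref.shape}, expected {(traj.n_atoms, 3)}"
        )
    fit_ix = _fit_atom_indices(traj, fit_atoms)
    aligned = superpose(traj, reference=ref, fit_atoms=fit_ix)
    dev = aligned.coords[:, fit_ix, :] - ref[None, fit_ix, :]
    rmsd = np.sqrt((dev**2).sum(axis=2).mean(axis=1))
    return rmsd, radius_of_gyration(traj)
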