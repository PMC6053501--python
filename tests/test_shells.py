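"""Solvation-shell definition: reference sites, proximal RDF, membership."""

import numpy as np
import pytest

from solvshell.io import AtomRecord, RegionSpec
from solvshell.shells import (
    default_cutoff,
    first_shell_cutoff,
    regional_rdf,
    RDFProfile,
    shell_membership,
    solvent_reference_site,
)

from conftest import make_trajectory, water_molecule_atoms


def protein_plus_solvent(protein_xyz, solvent_xyz, box=6.0, n_frames=1,
                         jitter=None, rng=None):
    """Static protein CA atoms plus point solvent molecules."""
    protein_xyz = np.asarray(protein_xyz, dtype=float)
    solvent_xyz = np.asarray(solvent_xyz, dtype=float)
    n_p, n_s = len(protein_xyz), len(solvent_xyz)
    atoms = [
        AtomRecord(index=i, name="CA", element="C", resid=i + 1,
                   resname="ALA", mol_id=0, mol_class="protein")
        for i in range(n_p)
    ] + [
        AtomRecord(index=n_p + i, name="S", element="X", resid=n_p + i + 1,
                   resname="BRW", mol_id=1 + i, mol_class="solvent")
        for i in range(n_s)
    ]
    frames = []
    for f in range(n_frames):
        sol = solvent_xyz.copy()
        if jitter is not None:
            sol = sol + rng.normal(0, jitter, sol.shape)
        frames.append(np.concatenate([protein_xyz, sol]))
    return make_trajectory(np.stack(frames), box=box, atoms=atoms)


REGION = RegionSpec("reg", "helix", ((1, 1),))


class TestReferenceSite:
    def test_water_uses_oxygen(self):
        atoms = water_molecule_atoms()
        coords = np.array([[[1.0, 1, 1], [1.1, 1, 1], [0.9, 1, 1]]])
        traj = make_trajectory(coords, atoms=atoms)
        site = solvent_reference_site(traj, [0, 1, 2])
        assert np.allclose(site[0], [1.0, 1, 1])

    def test_acetonitrile_uses_nitrogen(self):
        atoms = [
            AtomRecord(0, "C1", "C", 1, "ACN", 0, "solvent"),
            AtomRecord(1, "C2", "C", 1, "ACN", 0, "solvent"),
            AtomRecord(2, "N", "N", 1, "ACN", 0, "solvent"),
        ]
        coords = np.array([[[1, 1, 1], [1.15, 1, 1], [1.3, 1.0, 1.0]]])
        traj = make_trajectory(coords, atoms=atoms)
        assert np.allclose(
            solvent_reference_site(traj, [0, 1, 2])[0], [1.3, 1, 1]
        )

    def test_unruled_species_falls_back_to_centroid(self):
        atoms = [
            AtomRecord(i, f"C{i}", "C", 1, "CHX", 0, "solvent")
            for i in range(3)
        ]
        coords = np.array([[[1, 1, 1], [2, 1, 1], [3, 1, 1]]])
        traj = make_trajectory(coords, box=10.0, atoms=atoms)
        assert np.allclose(
            solvent_reference_site(traj, [0, 1, 2])[0], [2, 1, 1]
        )

    def test_missing_named_atom_raises(self):
        atoms = [AtomRecord(0, "C1", "C", 1, "ACN", 0, "solvent")]
        traj = make_trajectory(np.zeros((1, 1, 3)) + 1, atoms=atoms)
        with pytest.raises(ValueError, match="N"):
            solvent_reference_site(traj, [0])


class TestRegionalRDF:
    def test_ideal_gas_is_flat(self, rng):
        base = protein_plus_solvent([[3.0, 3.0, 3.0]],
                                    rng.uniform(0, 6.0, size=(3000, 3)))
        coords = np.stack([
            np.concatenate([[[3.0, 3.0, 3.0]],
                            rng.uniform(0, 6.0, size=(3000, 3))])
            for _ in range(10)
        ])
        traj = make_trajectory(coords, box=6.0, atoms=base.atoms)
        prof = regional_rdf(traj, REGION, r_max=2.0, dr=0.1)
        inner = (prof.r_centers > 0.55) & (prof.r_centers < 1.8)
        assert np.allclose(prof.g[inner], 1.0, atol=0.25)
        assert abs(prof.g[inner].mean() - 1.0) < 0.05

    def test_constructed_shell_peak_and_minimum(self, rng):
        center = np.array([3.0, 3.0, 3.0])
        # dense shell at r0 = 0.3, void to 0.5, uniform gas beyond
        u = rng.normal(size=(400, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        shell_pts = center + 0.3 * u
        far = rng.uniform(0, 6.0, size=(4000, 3))
        far = far[np.linalg.norm(far - center, axis=1) > 0.5]
        traj = protein_plus_solvent([center], np.vstack([shell_pts, far]))
        prof = regional_rdf(traj, REGION, r_max=1.5, dr=0.05)
        peak_r = prof.r_centers[np.argmax(prof.g)]
        assert abs(peak_r - 0.3) <= 0.05
        cutoff, unc = first_shell_cutoff(prof, smoothing_window=1)
        assert 0.3 < cutoff < 0.55

    def test_normalizations_agree_at_plateau(self, rng):
        sol = rng.uniform(0, 6.0, size=(4000, 3))
        traj = protein_plus_solvent([[3.0, 3.0, 3.0]], sol)
        g_mc = regional_rdf(traj, REGION, 2.0, 0.1,
                            normalization="proximal_mc")
        g_pl = regional_rdf(traj, REGION, 2.0, 0.1, normalization="plateau")
        sel = (g_mc.r_centers > 0.5) & (g_mc.r_centers < 1.6)
        assert np.allclose(g_mc.g[sel], g_pl.g[sel], rtol=0.05, atol=0.05)

    def test_counts_conserved(self, rng):
        sol = rng.uniform(0, 4.0, size=(500, 3))
        traj = protein_plus_solvent([[2.0, 2.0, 2.0]], sol, box=4.0)
        prof = regional_rdf(traj, REGION, r_max=4.0, dr=0.1)
        assert prof.raw_counts.sum() == 500

    def test_no_solvent_rejected(self):
        traj = protein_plus_solvent([[1.0, 1, 1]], np.empty((0, 3)))
        with pytest.raises(ValueError):
            regional_rdf(traj, REGION, 1.0, 0.1)


class TestFirstShellCutoff:
    def test_constructed_curve(self):
        r = np.arange(0.05, 1.05, 0.05)
        g = np.ones_like(r)
        g[np.isclose(r, 0.30)] = 2.5
        g[np.isclose(r, 0.45)] = 0.3
        prof = RDFProfile(r, g, np.ones_like(r, dtype=int), "plateau")
        cutoff, unc = first_shell_cutoff(prof, smoothing_window=1)
        assert np.isclose(cutoff, 0.45)
        assert np.isclose(unc, 0.05)

    def test_flat_curve_is_structureless(self):
        r = np.arange(0.05, 1.05, 0.05)
        prof = RDFProfile(r, np.ones_like(r), np.ones_like(r, dtype=int),
                          "plateau")
        with pytest.raises(ValueError, match="no shell structure"):
            first_shell_cutoff(prof, smoothing_window=1)

    def test_default_cutoff_table(self):
        # exterior first-shell boundaries per solvent
        assert default_cutoff("acetonitrile") == 0.5
        assert default_cutoff("n-butanol") == 0.6
        assert default_cutoff("tert-butanol") == 0.4
        assert default_cutoff("cyclohexane") == 0.7
        assert default_cutoff("water") == 0.5
        # buried interior regions sit one layer further out
        assert default_cutoff("acetonitrile", interior=True) == 0.7
        assert default_cutoff("n-butanol", interior=True) == 0.8
        assert default_cutoff("tert-butanol", interior=True) == 0.6
        assert default_cutoff("cyclohexane", interior=True) == 0.9
        assert default_cutoff("water", interior=True) == 0.7
        with pytest.raises(KeyError):
            default_cutoff("dmso")


class TestMembership:
    def test_extreme_cutoffs(self, rng):
        sol = rng.uniform(1.5, 4.5, size=(20, 3))
        traj = protein_plus_solvent([[3.0, 3.0, 3.0]], sol)
        tiny = shell_membership(traj, REGION, 1e-6)
        assert not tiny.member.any()
        huge = shell_membership(traj, REGION, 100.0)
        assert huge.member.all()

    def test_matches_exhaustive_enumeration(self, rng):
        """Membership equals a brute-force all-pairs check over the 27
        periodic images, on a 5-frame, 10-molecule fixture."""
        box = 4.0
        prot = rng.uniform(0, box, size=(3, 3))
        frames = rng.uniform(0, box, size=(5, 10, 3))
        traj = protein_plus_solvent(prot, frames[0], box=box)
        coords = np.concatenate(
            [np.repeat(prot[None], 5, axis=0), frames], axis=1
        )
        traj = make_trajectory(coords, box=box, atoms=traj.atoms)
        region = RegionSpec("reg", "helix", ((1, 3),))
        cutoff = 1.2
        got = shell_membership(traj, region, cutoff)
        shifts = np.array([[i, j, k] for i in (-1, 0, 1)
                           for j in (-1, 0, 1) for k in (-1, 0, 1)]) * box
        for f in range(5):
            for m in range(10):
                dmin = min(
                    np.linalg.norm(frames[f, m] - p + s)
                    for p in prot for s in shifts
                )
                assert got.member[f, m] == (dmin <= cutoff)

    def test_monotone_in_cutoff(self, rng):
        sol = rng.uniform(0, 6.0, size=(50, 3))
        traj = protein_plus_solvent([[3.0, 3.0, 3.0]], sol)
        small = shell_membership(traj, REGION, 0.8).member
        large = shell_membership(traj, REGION, 1.3).member
        assert np.all(large[small])     # enlarging never removes a member

    def test_translation_invariance(self, rng):
        sol = rng.uniform(0, 6.0, size=(40, 3))
        traj = protein_plus_solvent([[3.0, 3.0, 3.0]], sol)
        shift = np.array([2.7, -1.1, 4.9])
        moved = make_trajectory(
            np.mod(traj.coords + shift, 6.0), box=6.0, atoms=traj.atoms
        )
        a = shell_membership(traj, REGION, 0.9).member
        b = shell_membership(moved, REGION, 0.9).member
        assert np.array_equal(a, b)

    def test_missing_region_atoms_rejected(self, rng):
        sol = rng.uniform(0, 6.0, size=(5, 3))
        traj = protein_plus_solvent([[3.0, 3.0, 3.0]], sol)
        ghost = RegionSpec("ghost", "helix", ((99, 105),))
        with pytest.raises(ValueError, match="ghost"):
            shell_membership(traj, ghost, 0.5)
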