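"""Residence-time, diffusion, H-bond and reorientation estimators."""

import math

import numpy as np
import pytest

from solvshell import synth
from solvshell.dynamics import (
    HBondSpec,
    block_ci,
    diffusion_coefficient,
    fluctuation_time_constant,
    hb_lifetime,
    indicator_autocorrelation,
    interp_crossing,
    p2_from_vectors,
    survival_residence,
)
from solvshell.io import AtomRecord, RegionSpec
from solvshell.shells import ShellSeries

from conftest import make_trajectory


def brute_survival(member, jmax):
    """Independent first-exit survival correlation by direct enumeration
    of every (molecule, origin) pair."""
    F, M = member.shape
    num = np.zeros(jmax + 1)
    den = np.zeros(jmax + 1)
    for j in range(jmax + 1):
        for m in range(M):
            for t0 in range(F - j):
                if member[t0, m]:
                    den[j] += 1
                    if member[t0:t0 + j + 1, m].all():
                        num[j] += 1
    return num / np.maximum(den, 1)


def brute_exit_times(member, dt):
    F, M = member.shape
    times = []
    for m in range(M):
        t = 0
        while t < F:
            if member[t, m]:
                L = 0
                while t + L < F and member[t + L, m]:
                    L += 1
                if t + L < F:               # exit observed
                    times.append((L - 0.5) * dt)
                t += L
            else:
                t += 1
    return times


class TestSurvivalResidence:
    def test_matches_brute_force_enumeration(self, rng):
        member = rng.random((12, 6)) < 0.6
        member[0] = True
        shell = ShellSeries(member=member, dt=2.0)
        curve, tau_corr, tau_hist = survival_residence(shell)
        ref = brute_survival(member, 11)
        assert np.allclose(curve.values, ref)
        assert np.isclose(tau_hist.value,
                          np.mean(brute_exit_times(member, 2.0)))

    def test_never_leaving_flags_lower_bound(self):
        shell = ShellSeries(member=np.ones((10, 3), dtype=bool), dt=1.0)
        _, tau_corr, tau_hist = survival_residence(shell)
        assert tau_corr.lower_bound and tau_hist.lower_bound
        assert tau_corr.value == 9.0

    def test_exponential_recovery_and_estimator_equivalence(self):
        """Both estimators recover 1/lambda on exponential exchange and
        are statistically equivalent (paired CI covers zero)."""
        lam = 0.025
        shell, _ = synth.gen_shell_exchange(lam, 10_000, 400, 1.0, seed=21)
        _, tau_corr, tau_hist = survival_residence(shell)
        assert np.isclose(tau_corr.value, 1 / lam, rtol=0.05)
        assert np.isclose(tau_hist.value, 1 / lam, rtol=0.05)
        diffs = []
        for b in range(10):
            sub = ShellSeries(
                member=shell.member[:, b * 1000:(b + 1) * 1000], dt=1.0
            )
            _, tc, th = survival_residence(sub)
            diffs.append(tc.value - th.value)
        mean, half = block_ci(diffs)
        assert abs(mean) <= half        # CI covers zero

    def test_first_exit_curve_monotone(self, rng):
        member = rng.random((40, 30)) < 0.8
        member[0] = True
        curve, _, _ = survival_residence(ShellSeries(member=member, dt=1.0))
        assert np.all(np.diff(curve.values) <= 1e-12)
        assert curve.values[0] == 1.0

    def test_reentry_mode_counts_returns(self):
        member = np.array([[1, 0, 1, 1, 0, 1]], dtype=bool).T
        shell = ShellSeries(member=member, dt=1.0)
        curve, _, _ = survival_residence(shell, allow_reentry=True)
        # h(0)h(2): origins 0 (1->1), 2 (1->0), 3 (1->1) -> 2/3
        assert np.isclose(curve.values[2], 2 / 3)
        crv_abs, _, _ = survival_residence(shell)
        assert crv_abs.values[2] <= curve.values[2]

    def test_transient_exit_allowance_bridges_gaps(self):
        member = np.array([[1, 1, 0, 1, 1, 1, 0, 0, 0, 0]], dtype=bool).T
        shell = ShellSeries(member=member, dt=1.0)
        _, _, tau_plain = survival_residence(shell)
        _, _, tau_forgiving = survival_residence(shell, transient_exit_ps=1.0)
        assert tau_forgiving.value > tau_plain.value

    def test_time_origin_shift_invariance(self):
        shell, _ = synth.gen_shell_exchange(0.05, 500, 120, 1.0, seed=22)
        full = survival_residence(shell, max_lag=40.0)[1].value
        shifted = ShellSeries(member=shell.member, dt=1.0)
        assert np.isclose(
            survival_residence(shifted, max_lag=40.0)[1].value, full
        )


class TestDiffusion:
    def test_frozen_trajectory_gives_zero(self):
        traj, _ = synth.gen_brownian(0.0, 10, 50, 1.0, 3.0, seed=23)
        res = diffusion_coefficient(traj, fit_window=(2, 10))
        assert res.D_report == 0.0

    def test_brownian_recovery(self):
        traj, _ = synth.gen_brownian(1e-3, 500, 800, 1.0, 4.0, seed=24)
        res = diffusion_coefficient(traj, fit_window=(2, 10))
        assert np.isclose(res.D_report, 1.0, rtol=0.05)

    def test_report_units_identity(self):
        """D_true = 2.49e-3 nm^2/ps must be reported as 2.49 x 1e-5 cm^2/s
        x 1e3 scaling."""
        traj, _ = synth.gen_brownian(2.49e-3, 800, 400, 0.5, 5.0, seed=25)
        res = diffusion_coefficient(traj, fit_window=(1, 6))
        assert np.isclose(res.D_report, 2.49, rtol=0.05)
        assert np.isclose(res.D_report, res.D_nm2_per_ps * 1e3, rtol=1e-12)

    def test_msd_linear_with_small_intercept(self):
        traj, _ = synth.gen_brownian(1e-3, 400, 600, 1.0, 4.0, seed=26)
        res = diffusion_coefficient(traj, fit_window=(2, 10))
        msd_at_tmax = res.msd.values[10]
        assert res.msd.values[0] == 0.0
        assert np.all(res.msd.values >= 0)
        assert abs(res.intercept) < 0.05 * msd_at_tmax

    def test_shell_conditioning_selects_molecules(self):
        fast, _ = synth.gen_brownian(2e-3, 50, 100, 1.0, 4.0, seed=27)
        member = np.zeros((100, 50), dtype=bool)
        member[:, :25] = True
        shell = ShellSeries(member=member, dt=1.0)
        res = diffusion_coefficient(fast, members_at_origin=shell,
                                    fit_window=(2, 10))
        assert np.isclose(res.D_report, 2.0, rtol=0.15)

    def test_narrow_window_rejected(self):
        traj, _ = synth.gen_brownian(1e-3, 10, 50, 1.0, 3.0, seed=28)
        with pytest.raises(ValueError, match="lag points"):
            diffusion_coefficient(traj, fit_window=(2, 4))

    def test_ci_shrinks_with_sqrt_n_molecules(self):
        """Doubling the number of molecules halves the block-CI width
        within 20%."""
        def ci_width(n_mol, seed):
            traj, _ = synth.gen_brownian(1e-3, n_mol, 240, 1.0, 4.0,
                                         seed=seed)
            vals = []
            for b in range(8):
                sub = make_trajectory(
                    traj.coords[:, b * n_mol // 8:(b + 1) * n_mol // 8],
                    box=4.0, dt=1.0,
                )
                vals.append(
                    diffusion_coefficient(sub, fit_window=(2, 10)).D_report
                )
            return block_ci(vals)[1]

        w1 = np.mean([ci_width(200, s) for s in (31, 32, 33, 34)])
        w2 = np.mean([ci_width(800, s) for s in (31, 32, 33, 34)])
        assert np.isclose(w1 / w2, 2.0, rtol=0.25)


class TestHBond:
    def region(self):
        return RegionSpec("reg", "helix", ((1, 1),))

    def donor_system(self, r_da):
        """Protein N-H donor pointing at a solvent O acceptor at r_da."""
        atoms = [
            AtomRecord(0, "N", "N", 1, "ALA", 0, "protein"),
            AtomRecord(1, "H", "H", 1, "ALA", 0, "protein"),
            AtomRecord(2, "OW", "O", 2, "SOL", 1, "solvent"),
        ]
        frames = []
        for r in np.atleast_1d(r_da):
            frames.append([[1.0, 1, 1], [1.1, 1, 1], [1.0 + r, 1, 1]])
        return make_trajectory(np.array(frames), box=8.0, atoms=atoms)

    def test_geometry_criterion(self):
        spec = HBondSpec(protein_donors=(("N", "H"),),
                         solvent_acceptors=("O",))
        traj = self.donor_system([0.30, 0.34, 0.40, 0.30])
        curve, _ = hb_lifetime(traj, spec, self.region())
        # indicator on, on, off, on -> mean 0.75
        assert curve is not None

    def test_permanent_bond_is_lower_bound(self):
        spec = HBondSpec(protein_donors=(("N", "H"),),
                         solvent_acceptors=("O",))
        traj = self.donor_system([0.30] * 6)
        _, est = hb_lifetime(traj, spec, self.region())
        assert est.lower_bound

    def test_apolar_solvent_not_applicable(self):
        spec = HBondSpec()          # no donors or acceptors: cyclohexane
        traj = self.donor_system([0.30, 0.30])
        _, est = hb_lifetime(traj, spec, self.region())
        assert est.not_applicable

    def test_telegraph_fluctuation_time_recovery(self):
        """Two-state indicator: fluctuation time constant
        1/(k_on + k_off) = 20 ps recovered within 10%."""
        h, _ = synth.gen_telegraph(0.025, 0.025, 400, 2000, 1.0, seed=29)
        est = fluctuation_time_constant(h, dt=1.0, max_lag=100.0)
        assert np.isclose(est.value, 20.0, rtol=0.10)

    def test_intermittent_autocorrelation_normalised(self):
        h, _ = synth.gen_telegraph(0.02, 0.04, 50, 500, 1.0, seed=30)
        curve = indicator_autocorrelation(h, dt=1.0, max_lag=50.0)
        assert curve.values[0] == 1.0


class TestP2:
    def test_frozen_orientations_flagged(self):
        u = np.tile(np.array([[0.0, 0, 1]]), (50, 5, 1))
        _, est = p2_from_vectors(u, dt=1.0)
        assert est.lower_bound
        curve, _ = p2_from_vectors(u, dt=1.0)
        assert np.isclose(curve.values[0], 1.0)

    def test_rotational_diffusion_recovery(self, rng):
        """Isotropic rotational diffusion: tau2 = 1/(6 D_r) within 10%."""
        D_r, dt = 5e-3, 1.0
        n_frames, n_mol = 1500, 400
        u = np.empty((n_frames, n_mol, 3))
        v = rng.normal(size=(n_mol, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        u[0] = v
        sd = math.sqrt(2 * D_r * dt)
        for f in range(1, n_frames):
            step = rng.normal(0, sd, size=(n_mol, 3))
            step -= (step * v).sum(axis=1, keepdims=True) * v  # tangent
            v = v + step
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            u[f] = v
        _, est = p2_from_vectors(u, dt=dt, max_lag=200.0, origins_stride=5)
        assert np.isclose(est.value, 1 / (6 * D_r), rtol=0.10)


class TestBlockCI:
    def test_identical_blocks_zero_width(self):
        mean, half = block_ci([3.3, 3.3, 3.3, 3.3])
        assert mean == 3.3 and half == 0.0

    def test_twelve_blocks_unit_sd(self):
        """t_{11,0.975} / sqrt(12) = 0.635 for sample SD 1."""
        v = np.arange(12, dtype=float)
        v /= v.std(ddof=1)
        _, half = block_ci(v)
        assert np.isclose(half, 2.200985 / math.sqrt(12), rtol=1e-4)

    def test_two_blocks_closed_form(self):
        # {0, 2}: sample SD sqrt(2), half-width t_{1,.975} * s / sqrt(2)
        mean, half = block_ci([0.0, 2.0])
        assert mean == 1.0
        assert np.isclose(half, 12.7062, rtol=1e-4)

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            block_ci([1.0])


class TestCrossing:
    def test_interpolates_linearly(self):
        lags = np.array([0.0, 1.0, 2.0])
        vals = np.array([1.0, 0.5, 0.25])
        est = interp_crossing(lags, vals, level=1 / math.e)
        # crossing between 1 and 2: 1 + (0.5 - 1/e)/(0.5 - 0.25)
        assert np.isclose(est.value, 1 + (0.5 - 1 / math.e) / 0.25)

    def test_halves_self_consistency(self):
        """Estimates from two disjoint halves of a long series have
        overlapping confidence intervals."""
        shell, _ = synth.gen_shell_exchange(0.04, 4000, 600, 1.0, seed=31)
        cis = []
        for half in (shell.member[:, :2000], shell.member[:, 2000:]):
            vals = []
            for b in range(4):
                sub = ShellSeries(member=half[:, b * 500:(b + 1) * 500],
                                  dt=1.0)
                vals.append(survival_residence(sub)[1].value)
            cis.append(block_ci(vals))
        (m1, h1), (m2, h2) = cis
        assert abs(m1 - m2) <= h1 + h2
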