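"""Microstate MSM, PCCA+ coarse graining, HMM refinement, rates."""

import numpy as np
import pytest
from scipy.linalg import expm

from solvshell import synth
from solvshell.io import AtomRecord, RegionSpec
from solvshell.msm import (
    bootstrap_rates,
    discretize,
    estimate_msm,
    fit_msm_pipeline,
    hmm_refine,
    implied_timescales,
    min_distance_feature,
    pcca_coarse,
    transition_rates,
)

from conftest import make_trajectory


def balanced_K(pi=(0.45, 0.35, 0.20), f12=0.028, f23=0.012, f13=0.004):
    """Detailed-balanced 3-state generator (rates per ns)."""
    pi = np.asarray(pi)
    F = np.array([[0, f12, f13], [f12, 0, f23], [f13, f23, 0]])
    K = F / pi[:, None]
    np.fill_diagonal(K, -K.sum(axis=1))
    return K, pi


class TestFeature:
    def two_region_traj(self, xyz_a, xyz_b, box=10.0):
        n_a, n_b = xyz_a.shape[1], xyz_b.shape[1]
        atoms = [
            AtomRecord(i, "CA", "C", i + 1, "ALA", 0, "protein")
            for i in range(n_a)
        ] + [
            AtomRecord(n_a + i, "CA", "C", n_a + i + 1, "ALA", 0, "protein")
            for i in range(n_b)
        ]
        coords = np.concatenate([xyz_a, xyz_b], axis=1)
        return (
            make_trajectory(coords, box=box, atoms=atoms),
            RegionSpec("A", "helix", ((1, n_a),)),
            RegionSpec("B", "helix", ((n_a + 1, n_a + n_b),)),
        )

    def test_single_atoms_plain_distance(self):
        traj, a, b = self.two_region_traj(
            np.array([[[1.0, 1, 1]]]), np.array([[[1.0, 1, 3.5]]])
        )
        assert np.isclose(min_distance_feature(traj, a, b)[0], 2.5)

    def test_symmetric_and_matches_brute_force(self, rng):
        xyz_a = rng.uniform(0, 5, size=(10, 3, 3))
        xyz_b = rng.uniform(0, 5, size=(10, 4, 3))
        traj, a, b = self.two_region_traj(xyz_a, xyz_b, box=5.0)
        f_ab = min_distance_feature(traj, a, b)
        f_ba = min_distance_feature(traj, b, a)
        assert np.allclose(f_ab, f_ba)
        shifts = np.array([[i, j, k] for i in (-1, 0, 1)
                           for j in (-1, 0, 1) for k in (-1, 0, 1)]) * 5.0
        for f in range(10):
            brute = min(
                np.linalg.norm(p - q + s)
                for p in xyz_a[f] for q in xyz_b[f] for s in shifts
            )
            assert np.isclose(f_ab[f], brute)

    def test_hydrogens_excluded(self):
        atoms = [
            AtomRecord(0, "CA", "C", 1, "ALA", 0, "protein"),
            AtomRecord(1, "HA", "H", 1, "ALA", 0, "protein"),
            AtomRecord(2, "CA", "C", 2, "ALA", 0, "protein"),
        ]
        coords = np.array([[[1.0, 1, 1], [1.0, 1, 2.0], [1.0, 1, 3.0]]])
        traj = make_trajectory(coords, box=10.0, atoms=atoms)
        a = RegionSpec("A", "helix", ((1, 1),))
        b = RegionSpec("B", "helix", ((2, 2),))
        assert np.isclose(min_distance_feature(traj, a, b)[0], 2.0)


class TestDiscretize:
    def test_uniform_binning_arithmetic(self):
        series = np.linspace(0.0, 1.0, 1001)[:-1]     # spans [0, 1)
        dtrajs, centers = discretize(series, n_bins=10)
        val_bin = dtrajs[0][series.searchsorted(0.55)]
        assert val_bin == 5

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            discretize(np.ones(100), 10)

    def test_remap_preserves_frame_count_and_density(self):
        series = np.concatenate([np.zeros(50), np.ones(50) * 10.0])
        dtrajs, centers = discretize(series, n_bins=20)
        assert len(dtrajs[0]) == 100
        assert set(dtrajs[0]) == {0, 1}        # empty bins removed


class TestEstimateMSM:
    def test_constant_dtraj(self):
        model = estimate_msm(np.zeros(50, dtype=int), lag=1)
        assert model.T.shape == (1, 1) and model.T[0, 0] == 1.0

    def test_alternating_two_state(self):
        d = np.array([0, 1] * 50)
        model = estimate_msm(d, lag=1, reversible=False)
        assert np.allclose(model.T, [[0, 1], [1, 0]])

    def test_matches_matrix_exponential(self):
        K, _ = balanced_K(f12=0.28, f23=0.12, f13=0.04)   # faster for stats
        dt = 0.5
        feat, gt = synth.gen_jump_feature(K, [0, 1, 2], 0.05, 400_000, dt,
                                          seed=41)
        dtrajs, _ = discretize(feat, n_bins=12)
        # map microstates onto true states through the hidden path
        model = estimate_msm(dtrajs, lag=1)
        its = implied_timescales(dtrajs, [1], k=2, dt=dt)
        vals, _ = np.linalg.eig(expm(K * dt).T)
        lam = np.sort(np.abs(vals))[::-1]
        ref = -dt / np.log(lam[1:])
        assert np.allclose(its[0], ref, rtol=0.08)

    def test_detailed_balance_invariant(self):
        K, _ = balanced_K(f12=0.3, f23=0.15, f13=0.05)
        feat, _ = synth.gen_jump_feature(K, [0, 1, 2], 0.05, 100_000, 0.5,
                                         seed=42)
        dtrajs, _ = discretize(feat, n_bins=15)
        model = estimate_msm(dtrajs, lag=1, reversible=True)
        pi = model.pi
        flux = pi[:, None] * model.T
        assert np.abs(flux - flux.T).max() < 1e-8

    def test_no_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_msm(np.array([0]), lag=1)


class TestImpliedTimescales:
    def test_closed_form_two_state(self):
        """lambda_2 = 0.8 at a 15 ns lag gives t_2 = -15/ln 0.8 = 67.2 ns."""
        rng = np.random.default_rng(43)
        T = np.array([[0.9, 0.1], [0.1, 0.9]])           # lambda_2 = 0.8
        d = np.empty(400_000, dtype=int)
        d[0] = 0
        u = rng.random(len(d))
        for t in range(1, len(d)):
            d[t] = d[t - 1] if u[t] >= 0.1 else 1 - d[t - 1]
        its = implied_timescales([d], [1], k=1, dt=15.0)
        assert np.isclose(its[0, 0], -15.0 / np.log(0.8), rtol=0.05)

    def test_flat_in_lag_for_markovian_data(self):
        K, _ = balanced_K(f12=0.28, f23=0.12, f13=0.04)
        feat, _ = synth.gen_jump_feature(K, [0, 1, 2], 0.05, 300_000, 0.5,
                                         seed=44)
        dtrajs, _ = discretize(feat, n_bins=12)
        its = implied_timescales(dtrajs, [1, 2, 4], k=1, dt=0.5)
        spread = (its[:, 0].max() - its[:, 0].min()) / its[:, 0].mean()
        assert spread < 0.15


class TestPCCA:
    def near_block_T(self, eps):
        blocks = [
            np.array([[0.7, 0.3], [0.3, 0.7]]) for _ in range(3)
        ]
        T = np.zeros((6, 6))
        for k, b in enumerate(blocks):
            T[2 * k:2 * k + 2, 2 * k:2 * k + 2] = b
        T += eps
        return T / T.sum(axis=1, keepdims=True)

    def test_nearly_decoupled_blocks_are_crisp(self):
        chi = pcca_coarse(self.near_block_T(1e-9), n_meta=3)
        assert np.allclose(chi.sum(axis=1), 1.0, atol=1e-10)
        assert np.all((chi > 0.999) | (chi < 1e-3))
        labels = chi.argmax(axis=1)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[4] == labels[5]
        assert len(set(labels)) == 3

    def test_weak_coupling_near_crisp(self):
        chi = pcca_coarse(self.near_block_T(5e-3), n_meta=3)
        assert np.abs(chi - np.round(chi)).max() < 0.05

    def test_rows_always_on_simplex(self, rng):
        A = rng.random((8, 8)) + 0.1
        T = A / A.sum(axis=1, keepdims=True)
        chi = pcca_coarse(T, n_meta=3)
        assert np.all(chi >= 0) and np.all(chi <= 1)
        assert np.allclose(chi.sum(axis=1), 1.0)


HMM_K, HMM_PI = balanced_K(f12=0.14, f23=0.06, f13=0.02)
HMM_DT = 0.2


@pytest.fixture(scope="module")
def hmm_fit():
    """One shared HMM fit on a generated three-state feature series."""
    feat, gt = synth.gen_jump_feature(HMM_K, [1.0, 1.8, 2.6], 0.08,
                                      150_000, HMM_DT, seed=45)
    dtrajs, centers = discretize(feat, n_bins=30)
    res = hmm_refine(dtrajs, n_hidden=3, lag=1, seed=7, bin_centers=centers)
    return res, gt, centers


class TestHMM:
    def test_generative_recovery(self, hmm_fit):
        res, _, _ = hmm_fit
        T_ref = expm(HMM_K * HMM_DT)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(res.T_coarse[off], T_ref[off], rtol=0.10)

    def test_monotone_likelihood(self, hmm_fit):
        # EM log-likelihood never decreases (beyond numerical noise)
        ll = hmm_fit[0].log_likelihoods
        assert np.all(np.diff(ll) > -1e-6 * np.abs(ll[:-1]))

    def test_canonical_state_order(self, hmm_fit):
        res, _, centers = hmm_fit
        means = res.observation_probs @ centers
        assert np.all(np.diff(means) > 0)      # closed < crystal < open

    def test_populations_match_dwell_fractions(self, hmm_fit):
        res, gt, _ = hmm_fit
        dwell = np.bincount(gt["states"], minlength=3) / len(gt["states"])
        assert np.abs(res.populations - dwell).max() < 0.03


class TestRates:
    def test_arithmetic(self):
        T = np.array([[0.85, 0.15], [0.15, 0.85]])
        k = transition_rates(T, lag_ns=15.0)
        assert np.isclose(k[0, 1], 10.0)       # 0.15 / 15 ns = 10e-3 ns^-1
        assert k[0, 0] == 0.0

    def test_identity_matrix_zero_rates(self):
        assert np.all(transition_rates(np.eye(3), 15.0) == 0.0)

    def test_single_trajectory_bootstrap_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap_rates([np.array([0, 1, 0, 1])], lag=1, dt_ns=1.0)

    def test_rates_stable_under_bin_count(self):
        """Coarse rates agree between 30 and 100 microstate bins within
        bootstrap uncertainty."""
        feats = [
            synth.gen_jump_feature(HMM_K, [1.0, 1.8, 2.6], 0.08, 30_000,
                                   HMM_DT, seed=48 + i)[0]
            for i in range(3)
        ]
        models = {
            n: fit_msm_pipeline(feats, dt_ns=HMM_DT, lag_ns=HMM_DT,
                                n_bins=n, n_meta=3, n_boot=3, seed=7)
            for n in (30, 100)
        }
        off = ~np.eye(3, dtype=bool)
        diff = np.abs(models[30].rates - models[100].rates)[off]
        sd = np.maximum(models[30].rate_sd, models[100].rate_sd)[off]
        assert np.all(diff <= 3 * sd + 1e-9)
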