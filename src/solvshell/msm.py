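"""Conformational kinetics from a 1-D feature via Markov state models.

The workflow mirrors standard MSM practice on a one-dimensional
inter-region distance feature (e.g. the nearest distance between two
helices that open and close over a binding cleft):

1. ``min_distance_feature`` — per-frame nearest heavy-atom distance
   between two regions;
2. ``discretize`` — uniform 1-D microstate binning;
3. ``estimate_msm`` — sliding-window counts at a lag, reversible
   maximum-likelihood transition matrix on the largest connected set;
4. ``implied_timescales`` — t_i(tau) = -tau / ln lambda_i(tau), whose
   flatness in tau diagnoses Markovianity and fixes the working lag;
5. ``pcca_coarse`` — PCCA+ fuzzy memberships onto three metastable states;
6. ``hmm_refine`` — discrete-output hidden Markov model fitted by EM on
   lag-strided microstate trajectories, initialized from PCCA;
7. ``transition_rates`` — k_ij = T_ij(tau)/tau reported in 1e-3 ns^-1,
   with bootstrap (whole-trajectory resampling) standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components

from .io import RegionSpec, Trajectory, min_image_displacement

__all__ = [
    "MSMModel",
    "min_distance_feature",
    "discretize",
    "estimate_msm",
    "stationary_distribution",
    "implied_timescales",
    "pcca_coarse",
    "hmm_refine",
    "transition_rates",
    "bootstrap_rates",
    "fit_msm_pipeline",
]


# ---------------------------------------------------------------------------
# featurization / discretization
# ---------------------------------------------------------------------------

def min_distance_feature(
    traj: Trajectory, regionA: RegionSpec, regionB: RegionSpec,
    heavy_only: bool = True,
) -> np.ndarray:
    """Per-frame minimum min-image distance between two regions (nm).

    Hydrogens are excluded by default.  Symmetric in its arguments.
    """
    def atoms_of(region):
        ix = traj.region_atom_indices(region)
        if heavy_only:
            ix = np.array(
                [i for i in ix if not traj.atoms[i].element.upper().startswith("H")],
                dtype=int,
            )
        if ix.size == 0:
            raise ValueError(f"region {region.name!r} has no atoms")
        return ix

    ia, ib = atoms_of(regionA), atoms_of(regionB)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        d = min_image_displacement(
            traj.coords[f, ia][:, None, :], traj.coords[f, ib][None, :, :],
            traj.box[f],
        )
        out[f] = np.sqrt((d * d).sum(axis=-1)).min()
    return out


def discretize(
    series: np.ndarray | Sequence[np.ndarray], n_bins: int = 60
) -> tuple[list[np.ndarray], np.ndarray]:
    """Uniform 1-D binning into microstates.

    Bins span [min, max] of the pooled series; empty bins are removed and
    indices remapped densely.  Returns ``(dtrajs, bin_centers)``.
    """
    if n_bins < 2:
        raise ValueError("need n_bins >= 2")
    many = isinstance(series, (list, tuple))
    arrs = [np.asarray(s, dtype=float) for s in (series if many else [series])]
    pooled = np.concatenate(arrs)
    lo, hi = pooled.min(), pooled.max()
    if hi <= lo:
        raise ValueError("series is constant; cannot discretize")
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    raw = [np.clip(np.digitize(a, edges[1:-1]), 0, n_bins - 1) for a in arrs]
    occupied = np.unique(np.concatenate(raw))
    if occupied.size < 2:
        raise ValueError("all frames fall in one bin after trimming")
    remap = -np.ones(n_bins, dtype=int)
    remap[occupied] = np.arange(occupied.size)
    dtrajs = [remap[r] for r in raw]
    return dtrajs, centers[occupied]


# ---------------------------------------------------------------------------
# transition-matrix estimation
# ---------------------------------------------------------------------------

def _count_matrix(dtrajs: list[np.ndarray], lag: int, n: int) -> np.ndarray:
    C = np.zeros((n, n))
    for d in dtrajs:
        if len(d) > lag:
            np.add.at(C, (d[:-lag], d[lag:]), 1.0)
    return C


def _reversible_mle(C: np.ndarray, tol: float = 1e-10,
                    max_iter: int = 10_000) -> np.ndarray:
    """Self-consistent reversible maximum-likelihood transition matrix.

    Fixed-point iteration on the symmetric flux matrix; stops when the
    relative log-likelihood gain drops below ``tol``.
    """
    c_row = C.sum(axis=1)
    X = C + C.T
    X = X / X.sum()
    Csym = C + C.T
    prev_ll = -np.inf
    for _ in range(max_iter):
        x_row = X.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = c_row[:, None] / x_row[:, None] + c_row[None, :] / x_row[None, :]
            X_new = np.where(Csym > 0, Csym / denom, 0.0)
        X = X_new / X_new.sum()
        x_row = X.sum(axis=1)
        T = X / x_row[:, None]
        with np.errstate(divide="ignore"):
            ll = float((C[C > 0] * np.log(T[C > 0])).sum())
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            break
        prev_ll = ll
    return T


@dataclass
class MicroMSM:
    """Microstate transition matrix on the largest connected set."""

    T: np.ndarray
    counts: np.ndarray
    active: np.ndarray          # original microstate indices kept
    lag: int                    # frames
    reversible: bool

    @property
    def pi(self) -> np.ndarray:
        return stationary_distribution(self.T)


def estimate_msm(
    dtrajs: Sequence[np.ndarray] | np.ndarray,
    lag: int,
    reversible: bool = True,
) -> MicroMSM:
    """Sliding-window count matrix at ``lag`` (frames) and its
    maximum-likelihood transition matrix, restricted to the largest
    strongly connected set of the count graph."""
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    n = int(max(d.max() for d in dtrajs)) + 1
    C = _count_matrix(dtrajs, lag, n)
    if C.sum() == 0:
        raise ValueError(f"no transition counts at lag {lag}")
    n_comp, labels = connected_components(C > 0, directed=True,
                                          connection="strong")
    weights = np.array([C[labels == k].sum() for k in range(n_comp)])
    keep = labels == int(np.argmax(weights))
    active = np.nonzero(keep)[0]
    if active.size < 1:
        raise ValueError("count graph is disconnected with no usable set")
    Ca = C[np.ix_(active, active)]
    if reversible:
        T = _reversible_mle(Ca)
    else:
        T = Ca / Ca.sum(axis=1, keepdims=True)
    return MicroMSM(T=T, counts=Ca, active=active, lag=lag,
                    reversible=reversible)


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _sorted_eigenvalues(T: np.ndarray, reversible: bool,
                        k: int) -> np.ndarray:
    if reversible:
        pi = stationary_distribution(T)
        s = np.sqrt(pi)
        A = (s[:, None] * T) / s[None, :]
        A = 0.5 * (A + A.T)
        vals = np.linalg.eigvalsh(A)
        vals = vals[np.argsort(-np.abs(vals))]
    else:
        vals = np.linalg.eigvals(T)
        if np.abs(vals.imag).max() > 1e-8:
            vals = vals[np.argsort(-np.abs(vals))]
        else:
            vals = np.real(vals)[np.argsort(-np.abs(np.real(vals)))]
    return vals[: k + 1]


def implied_timescales(
    dtrajs: Sequence[np.ndarray],
    lags: Sequence[int],
    k: int = 2,
    dt: float = 1.0,
    reversible: bool = True,
) -> np.ndarray:
    """Implied timescales t_i(tau) = -tau / ln(lambda_i) for the ``k``
    largest nontrivial eigenvalues, at each lag (frames).

    ``dt`` converts frames to physical time (e.g. ns per frame); returned
    array has shape (len(lags), k).  Eigenvalues at or above 1 yield
    +inf (an upper-bound flag).
    """
    out = np.empty((len(lags), k))
    for row, lag in enumerate(lags):
        model = estimate_msm(dtrajs, lag=int(lag), reversible=reversible)
        vals = _sorted_eigenvalues(model.T, model.reversible, k)
        for i in range(k):
            if i + 1 >= len(vals):
                out[row, i] = np.nan
                continue
            lam = vals[i + 1]
            if isinstance(lam, complex):
                raise ValueError("complex eigenvalue in reversible mode")
            if lam >= 1.0 - 1e-12:
                out[row, i] = np.inf
            elif lam <= 0:
                out[row, i] = np.nan
            else:
                out[row, i] = -lag * dt / np.log(lam)
    return out


# ---------------------------------------------------------------------------
# PCCA+ coarse graining
# ---------------------------------------------------------------------------

def pcca_coarse(T: np.ndarray, n_meta: int = 3) -> np.ndarray:
    """PCCA+ fuzzy memberships of microstates onto metastable states.

    Inner-simplex vertex search on the top ``n_meta`` eigenvectors
    followed by projection onto the probability simplex; rows lie in
    [0, 1] and sum to 1.  Warns when there is no spectral gap at
    ``n_meta``.
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    if n_meta > n:
        raise ValueError("n_meta exceeds the number of microstates")
    if n_meta == n:
        return np.eye(n)
    pi = stationary_distribution(T)
    s = np.sqrt(pi)
    A = (s[:, None] * T) / s[None, :]
    A = 0.5 * (A + A.T)
    vals, phis = np.linalg.eigh(A)
    order = np.argsort(-vals)
    vals = vals[order]
    if n > n_meta and abs(abs(vals[n_meta - 1]) - abs(vals[n_meta])) < 1e-6:
        warnings.warn(
            f"no spectral gap after {n_meta} eigenvalues; metastable "
            "decomposition is ill-determined", stacklevel=2,
        )
    X = phis[:, order[:n_meta]] / s[:, None]      # right eigenvectors of T
    X[:, 0] = 1.0                                 # constant eigenvector

    # inner simplex algorithm: pick the most spread-out vertex rows
    idx = np.zeros(n_meta, dtype=int)
    ortho = X.copy()
    idx[0] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    ortho -= ortho[idx[0]][None, :]
    for j in range(1, n_meta):
        norms = np.linalg.norm(ortho, axis=1)
        idx[j] = int(np.argmax(norms))
        v = ortho[idx[j]] / max(norms[idx[j]], 1e-300)
        ortho = ortho - np.outer(ortho @ v, v)
    chi = X @ np.linalg.inv(X[idx])
    chi = np.clip(chi, 0.0, 1.0)
    chi = chi / chi.sum(axis=1, keepdims=True)
    return chi


# ---------------------------------------------------------------------------
# hidden Markov refinement
# ---------------------------------------------------------------------------

@dataclass
class HMMResult:
    T_coarse: np.ndarray
    populations: np.ndarray
    observation_probs: np.ndarray     # (n_hidden, n_symbols)
    log_likelihoods: np.ndarray       # per EM iteration
    converged: bool


def _stride_sequences(dtrajs: list[np.ndarray], lag: int) -> list[np.ndarray]:
    """Lag-strided subsampled sequences (single phase offset, so strided
    counts are statistically independent rather than sliding)."""
    out = []
    for d in dtrajs:
        s = d[::lag]
        if len(s) >= 2:
            out.append(s)
    return out


def hmm_refine(
    dtrajs: Sequence[np.ndarray] | np.ndarray,
    n_hidden: int = 3,
    lag: int = 1,
    init_memberships: np.ndarray | None = None,
    init_msm: MicroMSM | None = None,
    seed: int = 7,
    tol: float = 1e-8,
    max_iter: int = 1000,
    bin_centers: np.ndarray | None = None,
    reversible: bool = True,
) -> HMMResult:
    """Discrete-output hidden Markov model by EM on lag-strided dtrajs.

    Initialization comes from PCCA+ memberships of a microstate MSM
    (estimated here if not supplied).  ``tol`` is the EM stopping
    tolerance on the log-likelihood gain *per observation* (so stopping
    does not degrade into chasing machine noise on long trajectories).
    Hidden states are canonically ordered by mean observed feature (bin
    center, or symbol index) so labels are reproducible.  Raises on
    non-convergence, reporting the log-likelihood trace.
    """
    from hmmlearn.hmm import CategoricalHMM
    from hmmlearn.base import ConvergenceMonitor

    class _HistoryMonitor(ConvergenceMonitor):
        def __init__(self, tol, n_iter, verbose=False):
            super().__init__(tol, n_iter, verbose)
            self.full_history: list[float] = []

        def report(self, log_prob):
            self.full_history.append(float(log_prob))
            super().report(log_prob)

    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    n_symbols = int(max(d.max() for d in dtrajs)) + 1

    if init_msm is None:
        init_msm = estimate_msm(dtrajs, lag=lag, reversible=True)
    if init_memberships is None:
        init_memberships = pcca_coarse(init_msm.T, n_meta=n_hidden)
    chi = np.asarray(init_memberships, dtype=float)
    pi_micro = init_msm.pi

    # map microstate quantities back to the full symbol range
    chi_full = np.full((n_symbols, n_hidden), 1.0 / n_hidden)
    pi_full = np.full(n_symbols, 1e-12)
    chi_full[init_msm.active] = chi
    pi_full[init_msm.active] = pi_micro

    weights = chi_full * pi_full[:, None]             # (symbols, hidden)
    pops0 = weights.sum(axis=0)
    pops0 = pops0 / pops0.sum()
    B0 = (weights / np.maximum(weights.sum(axis=0), 1e-300)).T
    B0 = np.maximum(B0, 1e-10)
    B0 = B0 / B0.sum(axis=1, keepdims=True)
    # coarse-grained initial transition matrix (projection estimate)
    T_full = np.eye(n_symbols)
    T_full[np.ix_(init_msm.active, init_msm.active)] = init_msm.T
    num = weights.T @ T_full @ chi_full
    T0 = num / np.maximum(num.sum(axis=1, keepdims=True), 1e-300)
    T0 = np.maximum(T0, 1e-6)
    T0 = T0 / T0.sum(axis=1, keepdims=True)

    seqs = _stride_sequences(dtrajs, lag)
    X = np.concatenate(seqs)[:, None]
    lengths = [len(s) for s in seqs]
    tol_total = tol * len(X)            # per-observation -> total log-lik

    model = CategoricalHMM(
        n_components=n_hidden, n_iter=max_iter, tol=tol_total,
        init_params="", params="ste", random_state=seed,
    )
    model.n_features = n_symbols
    model.startprob_ = pops0
    model.transmat_ = T0
    model.emissionprob_ = B0
    model.monitor_ = _HistoryMonitor(tol_total, max_iter)
    model.fit(X, lengths)
    history = np.array(model.monitor_.full_history)
    if not model.monitor_.converged:
        raise RuntimeError(
            f"HMM EM did not converge in {len(history)} iterations "
            f"(last log-likelihoods: {history[-3:]})"
        )

    T = model.transmat_
    if reversible:
        # project onto detailed balance (equilibrium kinetics satisfies
        # pi_i T_ij = pi_j T_ji); pools forward/backward statistics
        pi = stationary_distribution(T)
        X = 0.5 * (pi[:, None] * T + (pi[:, None] * T).T)
        T = X / X.sum(axis=1, keepdims=True)
    B = model.emissionprob_
    centers = (np.asarray(bin_centers, dtype=float)
               if bin_centers is not None else np.arange(n_symbols, dtype=float))
    mean_feature = B @ centers
    order = np.argsort(mean_feature)
    T = T[np.ix_(order, order)]
    B = B[order]
    pops = stationary_distribution(T)
    return HMMResult(
        T_coarse=T, populations=pops, observation_probs=B,
        log_likelihoods=history, converged=True,
    )


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

def transition_rates(T_coarse: np.ndarray, lag_ns: float) -> np.ndarray:
    """k_ij = T_ij(tau) / tau for i != j, in 1e-3 ns^-1."""
    T = np.asarray(T_coarse, dtype=float)
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("T_coarse must be row-stochastic")
    if lag_ns <= 0:
        raise ValueError("lag must be positive")
    k = T / lag_ns * 1.0e3
    np.fill_diagonal(k, 0.0)
    return k


def bootstrap_rates(
    dtrajs: Sequence[np.ndarray],
    lag: int,
    dt_ns: float,
    n_hidden: int = 3,
    n_boot: int = 5,
    seed: int = 7,
    bin_centers: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap standard deviations of the coarse transition rates.

    Whole trajectories are resampled with replacement ``n_boot`` times and
    the full microstate-MSM -> PCCA+ -> HMM -> rates pipeline is refit on
    each resample.  Returns ``(rates_mean, rates_sd)`` in 1e-3 ns^-1.
    """
    dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
    if len(dtrajs) < 2:
        raise ValueError("bootstrap needs at least 2 trajectories")
    rng = np.random.default_rng(seed)
    samples = []
    for b in range(n_boot):
        pick = rng.integers(0, len(dtrajs), size=len(dtrajs))
        boot = [dtrajs[i] for i in pick]
        res = hmm_refine(boot, n_hidden=n_hidden, lag=lag,
                         seed=seed + 1 + b, bin_centers=bin_centers)
        samples.append(transition_rates(res.T_coarse, lag * dt_ns))
    stack = np.stack(samples)
    return stack.mean(axis=0), stack.std(axis=0, ddof=1)


# ---------------------------------------------------------------------------
# assembled model
# ---------------------------------------------------------------------------

@dataclass
class MSMModel:
    """Everything the conformational-kinetics stage produces."""

    dtrajs: list[np.ndarray]
    n_micro: int
    lag_ns: float
    T_micro: np.ndarray
    its_lags_ns: np.ndarray
    its: np.ndarray
    memberships: np.ndarray
    T_coarse: np.ndarray
    rates: np.ndarray            # 1e-3 ns^-1, zero diagonal
    rate_sd: np.ndarray | None
    populations: np.ndarray

    def as_jsonable(self) -> dict:
        return {
            "n_micro": self.n_micro,
            "lag_ns": self.lag_ns,
            "T_coarse": self.T_coarse.tolist(),
            "rates_1e-3_per_ns": self.rates.tolist(),
            "rate_sd": None if self.rate_sd is None else self.rate_sd.tolist(),
            "populations": self.populations.tolist(),
            "implied_timescales_ns": self.its.tolist(),
            "its_lags_ns": self.its_lags_ns.tolist(),
        }


def fit_msm_pipeline(
    features: Sequence[np.ndarray],
    dt_ns: float,
    lag_ns: float,
    n_bins: int = 60,
    n_meta: int = 3,
    its_lags_ns: Sequence[float] | None = None,
    n_boot: int = 5,
    seed: int = 7,
) -> MSMModel:
    """Feature series -> discretize -> MSM -> PCCA+ -> HMM -> rates."""
    dtrajs, centers = discretize(list(features), n_bins=n_bins)
    lag = max(1, int(round(lag_ns / dt_ns)))
    micro = estimate_msm(dtrajs, lag=lag, reversible=True)
    chi = pcca_coarse(micro.T, n_meta=n_meta)
    hmm = hmm_refine(dtrajs, n_hidden=n_meta, lag=lag, init_msm=micro,
                     init_memberships=chi, seed=seed, bin_centers=centers)
    rates = transition_rates(hmm.T_coarse, lag * dt_ns)
    rate_sd = None
    if len(dtrajs) >= 2 and n_boot > 0:
        _, rate_sd = bootstrap_rates(
            dtrajs, lag=lag, dt_ns=dt_ns, n_hidden=n_meta,
            n_boot=n_boot, seed=seed, bin_centers=centers,
        )
    if its_lags_ns is None:
        its_lags_ns = [lag_ns / 3, lag_ns / 2, lag_ns, 2 * lag_ns]
    its_lags = [max(1, int(round(l / dt_ns))) for l in its_lags_ns]
    its = implied_timescales(dtrajs, its_lags, k=n_meta - 1, dt=dt_ns)
    return MSMModel(
        dtrajs=dtrajs, n_micro=micro.T.shape[0], lag_ns=lag * dt_ns,
        T_micro=micro.T, its_lags_ns=np.array(its_lags) * dt_ns, its=its,
        memberships=chi, T_coarse=hmm.T_coarse, rates=rates,
        rate_sd=rate_sd, populations=hmm.populations,
    )
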