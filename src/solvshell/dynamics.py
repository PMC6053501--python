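"""Regional solvent-dynamics estimators.

Three observables are computed per region and solvent, each with
block-averaged student-t 95% confidence intervals:

* residence time — survival correlation C_res(t) = <h(t) h(0)> of the
  shell-occupancy indicator, read off at its 1/e time, and independently
  the mean of histogrammed first-exit times;
* local diffusion coefficient — Einstein relation <r^2> = 2*alpha*D*t fit
  to the mean-square displacement of molecules that are in the shell at
  the time origin (tracked through unwrapped coordinates for the full
  window, so fast molecules that exit are not discarded);
* hydrogen-bond lifetime — 1/e time of the intermittent H-bond indicator
  autocorrelation C(t) = <h(0)h(t)>/<h> under the standard 0.35 nm /
  30 degree donor–acceptor geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import RegionSpec, Trajectory, min_image_displacement
from .shells import ShellSeries, solvent_site_positions
from .units import d_nm2ps_to_report

__all__ = [
    "CorrelationCurve",
    "TimeEstimate",
    "DiffusionResult",
    "DynamicsSummary",
    "survival_residence",
    "diffusion_coefficient",
    "hb_lifetime",
    "indicator_autocorrelation",
    "fluctuation_time_constant",
    "p2_reorientation",
    "p2_from_vectors",
    "block_ci",
]

INV_E = 1.0 / math.e


@dataclass
class CorrelationCurve:
    """A normalized time correlation curve, C(0) = 1."""

    lags: np.ndarray            # ps, starting at 0, strictly increasing
    values: np.ndarray
    kind: str                   # survival / hbond / p2
    n_origins: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags[0] != 0 or np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must start at 0 and increase strictly")


@dataclass(frozen=True)
class TimeEstimate:
    """A characteristic time in ps, possibly only bounded.

    ``lower_bound`` marks curves that never reach 1/e within the probed
    window (``value`` is then the window length, a lower bound on the true
    time); ``not_applicable`` marks observables that do not exist for the
    system (e.g. H-bond lifetimes in an apolar solvent).
    """

    value: float
    lower_bound: bool = False
    not_applicable: bool = False

    def __float__(self) -> float:
        return float(self.value)


def interp_crossing(
    lags: np.ndarray, values: np.ndarray, level: float = INV_E
) -> TimeEstimate:
    """Linear interpolation of the first downward crossing of ``level``."""
    below = np.nonzero(values <= level)[0]
    if below.size == 0:
        return TimeEstimate(float(lags[-1]), lower_bound=True)
    j = int(below[0])
    if j == 0:
        return TimeEstimate(0.0)
    c0, c1 = values[j - 1], values[j]
    t = lags[j - 1] + (lags[j] - lags[j - 1]) * (c0 - level) / (c0 - c1)
    return TimeEstimate(float(t))


# ---------------------------------------------------------------------------
# residence time
# ---------------------------------------------------------------------------

def _runs(col: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of maximal True runs in a 1-D boolean array."""
    padded = np.concatenate(([False], col, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts.tolist(), (ends - starts).tolist()))


def _fill_short_gaps(member: np.ndarray, max_gap: int) -> np.ndarray:
    if max_gap <= 0:
        return member
    out = member.copy()
    n = member.shape[0]
    for m in range(member.shape[1]):
        col = member[:, m]
        for start, length in _runs(~col):
            # interior gaps only: flanked by occupancy on both sides
            if length <= max_gap and start > 0 and start + length < n:
                out[start:start + length, m] = True
    return out


def survival_residence(
    shell: ShellSeries,
    max_lag: float | None = None,
    allow_reentry: bool = False,
    transient_exit_ps: float = 0.0,
) -> tuple[CorrelationCurve, TimeEstimate, TimeEstimate]:
    """Survival correlation and the two residence-time estimators.

    Returns ``(curve, tau_corr, tau_hist)``.  In the default first-exit
    (absorbing) mode a molecule's indicator stays 0 after it first leaves
    the shell, so C_res is monotone non-increasing; ``tau_corr`` is the
    linearly interpolated 1/e time and ``tau_hist`` the mean over observed
    exit episodes (exit assigned to the midpoint of the frame interval in
    which it occurred).  With ``allow_reentry`` the literal product form
    <h(t)h(0)> is used.  Brief excursions up to ``transient_exit_ps`` can
    be forgiven before episode extraction.
    """
    member = shell.member
    n, n_mol = member.shape
    if n < 2:
        raise ValueError("need at least 2 frames")
    dt = shell.dt
    jmax = n - 1 if max_lag is None else int(round(max_lag / dt))
    if jmax > n - 1:
        raise ValueError("max_lag exceeds the trajectory span")
    gap_frames = int(round(transient_exit_ps / dt))
    member = _fill_short_gaps(member, gap_frames)

    lags = dt * np.arange(jmax + 1)
    exit_times = []
    if allow_reentry:
        num = np.empty(jmax + 1)
        den = np.empty(jmax + 1)
        for j in range(jmax + 1):
            h0 = member[: n - j]
            hj = member[j:]
            den[j] = h0.sum()
            num[j] = np.logical_and(h0, hj).sum()
    else:
        num = np.zeros(jmax + 1)
        den = np.zeros(jmax + 1)
        j_arr = np.arange(jmax + 1)
        for m in range(n_mol):
            for s, L in _runs(member[:, m]):
                # origins surviving to lag j: t0 in [s, min(s+L-j, n-j))
                hi_num = np.minimum(s + L - j_arr, n - j_arr)
                num += np.maximum(0, hi_num - s)
                hi_den = np.minimum(s + L, n - j_arr)
                den += np.maximum(0, hi_den - s)
                if s + L < n:                      # exit observed
                    exit_times.append((L - 0.5) * dt)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    if den[0] == 0:
        raise ValueError("no molecule is ever inside the shell")
    curve = CorrelationCurve(lags, c, kind="survival", n_origins=den)

    tau_corr = interp_crossing(lags, c)
    if allow_reentry:
        tau_hist = tau_corr                      # histogram undefined here
    elif exit_times:
        tau_hist = TimeEstimate(float(np.mean(exit_times)))
    else:
        tau_hist = TimeEstimate(float(lags[-1]), lower_bound=True)
    return curve, tau_corr, tau_hist


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------

@dataclass
class DiffusionResult:
    D_report: float             # 1e-5 cm^2/s
    D_nm2_per_ps: float
    msd: CorrelationCurve       # values in nm^2 (not normalized)
    slope: float
    intercept: float
    negative_slope: bool = False


def _unwrap_sites(sites: np.ndarray, box: np.ndarray) -> np.ndarray:
    out = np.empty_like(sites)
    out[0] = sites[0]
    for f in range(1, sites.shape[0]):
        d = min_image_displacement(sites[f - 1], sites[f], box[f])
        out[f] = out[f - 1] + d
    return out


def diffusion_coefficient(
    traj: Trajectory,
    members_at_origin: ShellSeries | None = None,
    fit_window: tuple[float, float] = (2.0, 10.0),
    origins_stride: float = 1.0,
    site_rules: Mapping[str, str] | None = None,
    alpha: int = 3,
) -> DiffusionResult:
    """Shell-conditioned self-diffusion coefficient from the MSD.

    Molecules contribute to a time origin if they are in the shell *at the
    origin* (or all solvent when ``members_at_origin`` is None) and are
    then tracked through unwrapped coordinates for the full lag window —
    exiting molecules are not dropped, which avoids survivorship bias
    toward slow molecules.  D is the least-squares slope of the MSD over
    ``fit_window`` (ps) divided by ``2*alpha``, reported in 1e-5 cm^2/s.
    """
    sites, _ = solvent_site_positions(traj, site_rules)
    x = _unwrap_sites(sites, traj.box)
    n, n_mol = x.shape[0], x.shape[1]
    dt = traj.dt
    t_min, t_max = fit_window
    jmax = int(round(t_max / dt))
    if jmax > n - 1:
        raise ValueError("fit window exceeds the trajectory span")
    stride = max(1, int(round(origins_stride / dt)))

    sq_sum = np.zeros(jmax + 1)
    n_obs = np.zeros(jmax + 1)
    for t0 in range(0, n - 1, stride):
        mask = (
            members_at_origin.member[t0]
            if members_at_origin is not None
            else np.ones(n_mol, dtype=bool)
        )
        if mask.sum() == 0:
            continue
        last = min(jmax, n - 1 - t0)
        d = x[t0:t0 + last + 1, mask, :] - x[t0, mask, :]
        sq = (d * d).sum(axis=2)            # (last+1, n_sel)
        sq_sum[: last + 1] += sq.sum(axis=1)
        n_obs[: last + 1] += mask.sum()
    if n_obs[0] < 2:
        raise ValueError("fewer than 2 molecules contribute to the MSD")
    msd = np.where(n_obs > 0, sq_sum / np.maximum(n_obs, 1), np.nan)
    lags = dt * np.arange(jmax + 1)

    sel = (lags >= t_min) & (lags <= t_max) & np.isfinite(msd)
    if sel.sum() < 5:
        raise ValueError("fewer than 5 lag points in the fit window")
    slope, intercept = np.polyfit(lags[sel], msd[sel], 1)
    D = slope / (2.0 * alpha)
    negative = D < 0
    D = max(D, 0.0)
    curve = CorrelationCurve(lags, np.nan_to_num(msd), kind="msd",
                             n_origins=n_obs)
    return DiffusionResult(
        D_report=d_nm2ps_to_report(D), D_nm2_per_ps=D, msd=curve,
        slope=float(slope), intercept=float(intercept),
        negative_slope=bool(negative),
    )


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def indicator_autocorrelation(
    h: np.ndarray, dt: float, max_lag: float | None = None
) -> CorrelationCurve:
    """Intermittent autocorrelation C(t) = <h(0)h(t)> / <h> of a 0/1
    indicator array of shape (n_frames, n_series); C(0) = 1."""
    h = np.asarray(h, dtype=float)
    if h.ndim == 1:
        h = h[:, None]
    n = h.shape[0]
    jmax = n - 1 if max_lag is None else min(n - 1, int(round(max_lag / dt)))
    mean_h = h.mean()
    if mean_h == 0:
        raise ValueError("indicator is never on")
    c = np.empty(jmax + 1)
    n_origins = np.empty(jmax + 1)
    for j in range(jmax + 1):
        prod = h[: n - j] * h[j:]
        c[j] = prod.mean() / h[: n - j].mean()
        n_origins[j] = (n - j) * h.shape[1]
    lags = dt * np.arange(jmax + 1)
    return CorrelationCurve(lags, c, kind="hbond", n_origins=n_origins)


def fluctuation_time_constant(h: np.ndarray, dt: float,
                              max_lag: float | None = None) -> TimeEstimate:
    """1/e time of the normalized fluctuation autocorrelation
    (C(t) - <h>) / (1 - <h>) of a stationary 0/1 indicator."""
    curve = indicator_autocorrelation(h, dt, max_lag)
    p = float(np.asarray(h, dtype=float).mean())
    if p >= 1.0:
        return TimeEstimate(float(curve.lags[-1]), lower_bound=True)
    fluct = (curve.values - p) / (1.0 - p)
    return interp_crossing(curve.lags, fluct)


@dataclass(frozen=True)
class HBondSpec:
    """Atom-name prefixes defining donor/acceptor sites.

    Donors are (heavy-atom, hydrogen) name-prefix pairs; acceptors are
    heavy-atom name prefixes.  Protein and solvent sides are listed
    separately; an apolar solvent simply has empty donor and acceptor
    lists, in which case the lifetime is reported as not applicable.
    """

    protein_donors: tuple[tuple[str, str], ...] = ()
    protein_acceptors: tuple[str, ...] = ()
    solvent_donors: tuple[tuple[str, str], ...] = ()
    solvent_acceptors: tuple[str, ...] = ()


WATER_HB_SPEC = HBondSpec(
    protein_donors=(("N", "H"),),
    protein_acceptors=("O",),
    solvent_donors=(("O", "H"),),
    solvent_acceptors=("O",),
)


def _hb_indicator(
    traj: Trajectory,
    donors: list[tuple[int, int]],
    acceptors: list[int],
    r_cut: float,
    angle_cut_deg: float,
) -> np.ndarray:
    """Indicator (n_frames, n_pairs) for all donor x acceptor pairs."""
    cols = []
    cos_min = math.cos(math.radians(angle_cut_deg))
    for d_ix, h_ix in donors:
        for a_ix in acceptors:
            if a_ix == d_ix:
                continue
            da = min_image_displacement(
                traj.coords[:, d_ix], traj.coords[:, a_ix], traj.box
            )
            r = np.sqrt((da * da).sum(axis=1))
            dh = min_image_displacement(
                traj.coords[:, d_ix], traj.coords[:, h_ix], traj.box
            )
            # angle H-donor-acceptor
            num = (da * dh).sum(axis=1)
            den = r * np.sqrt((dh * dh).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = np.where(den > 0, num / den, 1.0)
            cols.append((r <= r_cut) & (cosang >= cos_min))
    if not cols:
        return np.zeros((traj.n_frames, 0), dtype=np.int8)
    return np.stack(cols, axis=1).astype(np.int8)


def hb_lifetime(
    traj: Trajectory,
    spec: HBondSpec,
    region: RegionSpec,
    r_cut: float = 0.35,
    angle_cut_deg: float = 30.0,
    max_lag: float | None = None,
) -> tuple[CorrelationCurve | None, TimeEstimate]:
    """Protein(region)–solvent hydrogen-bond lifetime.

    Enumerates donor–acceptor pairs between the region and the solvent in
    both directions, builds the geometric indicator (donor–acceptor
    distance <= ``r_cut`` nm and H–donor–acceptor angle <=
    ``angle_cut_deg``), and returns the intermittent autocorrelation with
    its 1/e time.  Systems with no donor/acceptor pairs (apolar solvent)
    return ``(None, not-applicable)``.
    """

    def named(indices, prefix):
        return [i for i in indices if traj.atoms[i].name.startswith(prefix)]

    region_ix = traj.region_atom_indices(region)
    solvent_mols = traj.molecules("solvent")
    solvent_ix = [i for ix in solvent_mols.values() for i in ix]

    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    pairs = []
    # protein donor -> solvent acceptor
    for d_pref, h_pref in spec.protein_donors:
        p_d = named(region_ix, d_pref)
        p_h = named(region_ix, h_pref)
        for d, h in zip(p_d, p_h):
            for acc_pref in spec.solvent_acceptors:
                for a in named(solvent_ix, acc_pref):
                    pairs.append(((d, h), a))
    # solvent donor -> protein acceptor
    for d_pref, h_pref in spec.solvent_donors:
        for mol_ix in solvent_mols.values():
            s_d = named(mol_ix, d_pref)
            s_h = named(mol_ix, h_pref)
            for d, h in zip(s_d, s_h):
                for acc_pref in spec.protein_acceptors:
                    for a in named(region_ix, acc_pref):
                        pairs.append(((d, h), a))
    if not pairs:
        return None, TimeEstimate(math.nan, not_applicable=True)

    donors = [p[0] for p in pairs]
    acceptors = [p[1] for p in pairs]
    cols = []
    for (d, h), a in zip(donors, acceptors):
        cols.append(_hb_indicator(traj, [(d, h)], [a], r_cut, angle_cut_deg))
    h_arr = np.concatenate(cols, axis=1)
    if h_arr.sum() == 0:
        return None, TimeEstimate(math.nan, not_applicable=True)
    curve = indicator_autocorrelation(h_arr, traj.dt, max_lag)
    return curve, interp_crossing(curve.lags, curve.values)


# ---------------------------------------------------------------------------
# reorientation
# ---------------------------------------------------------------------------

def p2_from_vectors(
    u: np.ndarray, dt: float, max_lag: float | None = None,
    origins_stride: int = 1,
) -> tuple[CorrelationCurve, TimeEstimate]:
    """C2(t) = <P2(u(0).u(t))> for unit vectors u of shape (F, M, 3)."""
    u = np.asarray(u, dtype=float)
    n = u.shape[0]
    jmax = n - 1 if max_lag is None else min(n - 1, int(round(max_lag / dt)))
    c = np.zeros(jmax + 1)
    cnt = np.zeros(jmax + 1)
    for t0 in range(0, n - 1, origins_stride):
        last = min(jmax, n - 1 - t0)
        dots = (u[t0:t0 + last + 1] * u[t0][None]).sum(axis=2)
        p2 = 0.5 * (3.0 * dots**2 - 1.0)
        c[: last + 1] += p2.mean(axis=1)
        cnt[: last + 1] += 1
    c = c / np.maximum(cnt, 1)
    lags = dt * np.arange(jmax + 1)
    curve = CorrelationCurve(lags, c, kind="p2", n_origins=cnt)
    return curve, interp_crossing(lags, c)


def p2_reorientation(
    traj: Trajectory,
    vector_spec: tuple[str, str],
    max_lag: float | None = None,
) -> tuple[CorrelationCurve, TimeEstimate]:
    """Second-rank reorientation time of a molecular axis.

    ``vector_spec`` gives two atom-name prefixes defining the axis within
    each solvent molecule; tau2 is the 1/e time of C2(t).
    """
    a_pref, b_pref = vector_spec
    mols = traj.molecules("solvent")
    vecs = []
    for ix in mols.values():
        a = [i for i in ix if traj.atoms[i].name.startswith(a_pref)]
        b = [i for i in ix if traj.atoms[i].name.startswith(b_pref)]
        if not a or not b or a[0] == b[0]:
            raise ValueError("vector atoms not defined for every molecule")
        d = min_image_displacement(
            traj.coords[:, a[0]], traj.coords[:, b[0]], traj.box
        )
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        vecs.append(d / np.maximum(norm, 1e-12))
    u = np.stack(vecs, axis=1)
    return p2_from_vectors(u, traj.dt, max_lag)


# ---------------------------------------------------------------------------
# uncertainties
# ---------------------------------------------------------------------------

def block_ci(values: Sequence[float], confidence: float = 0.95
             ) -> tuple[float, float]:
    """Block-average mean with student-t confidence half-width.

    ``mean ± t_{n-1, (1+c)/2} * s / sqrt(n)`` with the sample (ddof=1)
    standard deviation over per-block estimates.  Needs >= 2 blocks.
    """
    v = np.asarray(list(values), dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 blocks for a confidence interval")
    s = v.std(ddof=1)
    t = stats.t.ppf(0.5 + confidence / 2.0, n - 1)
    return float(v.mean()), float(t * s / math.sqrt(n))


# ---------------------------------------------------------------------------
# summary container
# ---------------------------------------------------------------------------

@dataclass
class DynamicsSummary:
    """One region x solvent row of the dynamics tables."""

    region: str
    solvent: str
    tau_res_corr: float
    tau_res_corr_ci: float
    tau_res_hist: float
    tau_res_hist_ci: float
    D_local: float              # 1e-5 cm^2/s
    D_local_ci: float
    hblt: float | None = None   # ps; None = not applicable
    hblt_ci: float | None = None
    tau2: float | None = None

    def __post_init__(self) -> None:
        for v in (self.tau_res_corr_ci, self.tau_res_hist_ci, self.D_local_ci):
            if v < 0:
                raise ValueError("CI half-widths must be >= 0")
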