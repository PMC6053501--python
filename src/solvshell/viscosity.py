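"""Viscosity descriptors and Kramers-rate utilities.

The central quantities, all simple ratios evaluated on unrounded inputs:

* model (apparent bulk) viscosity     eta_model = eta_exp * D_exp / D_model
* local (interfacial) viscosity       eta_local = eta_bulk * D_bulk / D_local
  or, from NMR-style reorientation times, eta_bulk * tau2_int / tau2_bulk
* solvent mobility ratio              D_solvent,region / D_water,region
* surface retardation factor          D_solvent,region / D_solvent,bulk
* Kramers high-friction rate          k ∝ (1/eta_local) exp(-H*/RT)

Viscosities are in mPa·s, diffusion coefficients on the 1e-5 cm^2/s report
scale (ratios make the scale cancel), barriers in kJ/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .units import K_B, R_GAS

__all__ = [
    "KramersParams",
    "stokes_einstein",
    "model_viscosity",
    "local_viscosity",
    "local_viscosity_from_tau2",
    "mobility_descriptors",
    "kramers_rate",
    "percent_error",
]


def stokes_einstein(eta_mPas: float, r_nm: float, T: float
                    ) -> tuple[float, float]:
    """Stokes–Einstein translational and rotational diffusion.

    D_T = kB*T / (6 pi eta r)   [returned in cm^2/s]
    D_R = kB*T / (8 pi eta r^3) [returned in s^-1]
    """
    if eta_mPas <= 0 or r_nm <= 0 or T <= 0:
        raise ValueError("eta, r and T must be positive")
    eta = eta_mPas * 1e-3          # Pa s
    r = r_nm * 1e-9                # m
    d_t = K_B * T / (6.0 * math.pi * eta * r)          # m^2/s
    d_r = K_B * T / (8.0 * math.pi * eta * r**3)       # s^-1
    return d_t * 1e4, d_r


def model_viscosity(eta_exp: float, D_exp: float, D_model: float) -> float:
    """Apparent viscosity of a simulated solvent model:
    eta_model = eta_exp * D_exp / D_model."""
    if eta_exp <= 0 or D_exp <= 0:
        raise ValueError("eta_exp and D_exp must be positive")
    if D_model == 0:
        raise ValueError("D_model must be nonzero")
    if D_model < 0:
        raise ValueError("D_model must be positive")
    return eta_exp * D_exp / D_model


def local_viscosity(eta_bulk: float, D_bulk: float, D_local: float) -> float:
    """Interfacial viscosity from shell diffusion:
    eta_local = eta_bulk * D_bulk / D_local."""
    if eta_bulk <= 0 or D_bulk <= 0:
        raise ValueError("eta_bulk and D_bulk must be positive")
    if D_local == 0:
        raise ValueError("D_local must be nonzero")
    if D_local < 0:
        raise ValueError("D_local must be positive")
    return eta_bulk * D_bulk / D_local


def local_viscosity_from_tau2(eta_bulk: float, tau2_interface: float,
                              tau2_bulk: float) -> float:
    """Interfacial viscosity from reorientation times:
    eta_local = eta_bulk * tau2_interface / tau2_bulk."""
    if eta_bulk <= 0 or tau2_interface <= 0:
        raise ValueError("inputs must be positive")
    if tau2_bulk == 0:
        raise ValueError("tau2_bulk must be nonzero")
    if tau2_bulk < 0:
        raise ValueError("tau2_bulk must be positive")
    return eta_bulk * tau2_interface / tau2_bulk


def mobility_descriptors(D_solvent_region: float, D_water_region: float,
                         D_solvent_bulk: float) -> tuple[float, float]:
    """(mobility_ratio, retardation) =
    (D_solvent,region / D_water,region, D_solvent,region / D_solvent,bulk).
    """
    if D_water_region <= 0 or D_solvent_bulk <= 0:
        raise ValueError("denominators must be positive")
    return (D_solvent_region / D_water_region,
            D_solvent_region / D_solvent_bulk)


def percent_error(model: float, experiment: float) -> float:
    """100 * |model - experiment| / experiment."""
    if experiment == 0:
        raise ValueError("experimental value must be nonzero")
    return 100.0 * abs(model - experiment) / abs(experiment)


@dataclass(frozen=True)
class KramersParams:
    """Inputs to the high-friction Kramers rate."""

    H_star: float               # barrier, kJ/mol
    eta_local: float            # mPa s
    T: float = 300.0
    prefactor: float = 1.0

    def __post_init__(self) -> None:
        if self.T <= 0 or self.eta_local <= 0:
            raise ValueError("T and eta_local must be positive")


def well_escape_rate(series, dt: float, threshold: float = 0.5) -> float:
    """Empirical barrier-crossing rate of a double-well series (ps^-1).

    Transitions are counted with hysteresis: a crossing is registered only
    when the coordinate passes from beyond -threshold to beyond +threshold
    (or back), which suppresses barrier-top recrossings.  The rate is
    transitions per unit time per well (so it matches the one-way escape
    rate of a symmetric well).
    """
    import numpy as np

    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n_frames, n_rep = x.shape
    total = 0
    for r in range(n_rep):
        side = np.where(x[:, r] >= threshold, 1,
                        np.where(x[:, r] <= -threshold, -1, 0))
        side = side[side != 0]
        if side.size:
            total += int(np.count_nonzero(np.diff(side)) / 1)
    span = (n_frames - 1) * dt * n_rep
    if span <= 0:
        raise ValueError("series too short")
    # each counted event empties one well; two wells share the time span
    return total / span


def kramers_rate(p: KramersParams) -> float:
    """k = prefactor * (1/eta_local) * exp(-H*/(R T)) — the high-friction
    barrier-crossing rate, with the 1/viscosity friction dependence."""
    rt_kj = R_GAS * p.T / 1000.0
    return p.prefactor / p.eta_local * math.exp(-p.H_star / rt_kj)
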