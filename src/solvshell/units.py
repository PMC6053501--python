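"""Unit conventions and physical constants.

Internally everything is carried in a single convention:

* lengths        nm
* times          ps
* diffusion      nm^2/ps internally, reported in 1e-5 cm^2/s
* viscosity      mPa*s
* rates          ps^-1 internally, reported in 1e-3 ns^-1 where tables do
* energies       kJ/mol

1 nm^2/ps = 1e-14 m^2 / 1e-12 s = 1e-2 cm^2/s = 1e3 x (1e-5 cm^2/s).
"""

from __future__ import annotations

from dataclasses import dataclass

#: CODATA Boltzmann constant, J/K.
K_B = 1.380649e-23
#: CODATA molar gas constant, J/(mol K).
R_GAS = 8.314462618

#: multiply a diffusion coefficient in nm^2/ps by this to get 1e-5 cm^2/s
NM2_PER_PS_TO_1E5_CM2_PER_S = 1.0e3
#: multiply a rate in ps^-1 by this to get 1e-3 ns^-1
PER_PS_TO_1E3_PER_NS = 1.0e6


def d_nm2ps_to_cm2s(d: float) -> float:
    """nm^2/ps -> cm^2/s (absolute, not the 1e-5 report scale)."""
    return d * 1.0e-2


def d_nm2ps_to_report(d: float) -> float:
    """nm^2/ps -> the tabulated 1e-5 cm^2/s scale."""
    return d * NM2_PER_PS_TO_1E5_CM2_PER_S


def d_report_to_nm2ps(d: float) -> float:
    """1e-5 cm^2/s report scale -> nm^2/ps."""
    return d / NM2_PER_PS_TO_1E5_CM2_PER_S


def rate_ps_to_report(k: float) -> float:
    """ps^-1 -> the tabulated 1e-3 ns^-1 scale."""
    return k * PER_PS_TO_1E3_PER_NS


def rate_report_to_ps(k: float) -> float:
    return k / PER_PS_TO_1E3_PER_NS


@dataclass(frozen=True)
class Constants:
    """Physical constants and the working temperature.

    Parameters
    ----------
    T : float
        Absolute temperature in K.  300 K default; 301 K is used for
        tert-butanol runs (just above the solvent melting point).
    """

    k_B: float = K_B
    R: float = R_GAS
    T: float = 300.0

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError(f"temperature must be positive, got {self.T}")

    @property
    def kT_kJ_per_mol(self) -> float:
        """Thermal energy R*T in kJ/mol."""
        return self.R * self.T / 1000.0
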