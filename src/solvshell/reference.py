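"""Reference data tables for worked examples.

Two small tables ship with the package:

* ``bulk_solvent_table`` — experimental shear viscosities and self-diffusion
  coefficients at 298 K (CRC Handbook values) together with the
  self-diffusion coefficients of the corresponding OPLS-AA / SPC-E
  simulation models, for the five solvents in which CALB
  (*Candida antarctica* lipase B) has been characterised.
* ``regional_dynamics_table`` — regional solvation-shell dynamics of CALB
  (protein–solvent hydrogen-bond lifetime, shell diffusion coefficient and
  shell residence time, with 95% confidence half-widths) around each of
  its ten alpha-helices, as reported from published microsecond-scale MD
  simulations.  Missing hydrogen-bond entries are lifetimes that did not
  decay within the analysis window (or do not exist, for the apolar
  cyclohexane).

These are *inputs* for descriptor arithmetic (apparent model viscosity,
local viscosity, mobility ratios); the package's estimators never produce
them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["bulk_solvent_table", "regional_dynamics_table"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("solvshell.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def bulk_solvent_table() -> pd.DataFrame:
    """Bulk solvent properties: eta_exp (mPa·s), D_exp and D_model
    (1e-5 cm^2/s), simulation temperature (K)."""
    return _load("bulk_solvents.csv")


def regional_dynamics_table() -> pd.DataFrame:
    """Regional shell dynamics of CALB per solvent and alpha-helix."""
    return _load("calb_regional_dynamics.csv")
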