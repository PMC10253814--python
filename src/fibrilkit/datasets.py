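"""Reference datasets for insulin fibrillization in EMIM-based ionic liquids.

Small published summary tables used throughout the package as worked-example
inputs and as presets for the synthetic-data generators:

- ``load_kinetics_reference``: Boltzmann-fit kinetic parameters (t_lag,
  t_half, k_agg with uncertainties) for insulin fibrillization in the
  absence of ionic liquid and in five EMIM ionic liquids at 10/25/100 mM.
- ``load_structure_reference``: amide-I secondary-structure percentages for
  insulin monomer and fibrils per condition at 25 mM.
- ``load_z90_reference``: AFM z_90% morphometry values per condition at 25 mM.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_kinetics_reference",
    "load_structure_reference",
    "load_z90_reference",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("fibrilkit.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_kinetics_reference() -> pd.DataFrame:
    """Kinetic parameters per condition: t_lag, t_half, k_agg (+ errors)."""
    return _read("insulin_il_kinetics.csv")


def load_structure_reference() -> pd.DataFrame:
    """Secondary-structure percentages per condition and state (monomer/fibril)."""
    return _read("insulin_il_structure.csv")


def load_z90_reference() -> pd.DataFrame:
    """AFM z_90% fibril-height statistics per condition (25 mM)."""
    return _read("insulin_il_z90.csv")
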