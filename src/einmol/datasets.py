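"""Published all-atom simulation results for acetylsalicylic acid (ASA).

These are literature values from GAFF/TIP3P molecular dynamics free
energy calculations on form-I ASA at 298.15 K: the Einstein-molecule
cycle components of the 64-molecule solid, the single-molecule cycle legs
behind the standard chemical potential, and the solution-series excess
chemical potentials at fifteen concentrations.  They serve as worked-
example *inputs* to the assembly routines in this package — the
simulations behind them are far outside desk scale.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "ASA_MASS_U",
    "ASA_TEMPERATURE_K",
    "ASA_SIGMA_ROT",
    "ASA_N_SOLID",
    "asa_solid_components",
    "asa_single_molecule_cycle",
    "asa_solution_table",
]

ASA_MASS_U = 180.158  # molecular mass of acetylsalicylic acid, u
ASA_TEMPERATURE_K = 298.15
ASA_SIGMA_ROT = 1  # no proper rotation maps ASA onto itself
ASA_N_SOLID = 64  # molecules in the solid-state simulation box


def asa_solid_components() -> dict:
    """Einstein-molecule cycle components of solid ASA, per molecule, in k_BT.

    MBAR values (with the state counts used): A_EM from Monte Carlo
    integration, ΔA_EM→IEM over 118 states, ΔA_IEM→solid over 600 states.
    TI companions are included for the two alchemical legs.
    """
    return {
        "A_EM": 48.0,
        "sigma_A_EM": 3.0,
        "dA_EM_to_IEM_mbar": -167.07,
        "sigma_dA_EM_to_IEM_mbar": 0.03,
        "dA_EM_to_IEM_ti": -167.316,
        "sigma_dA_EM_to_IEM_ti": 0.001,
        "dA_IEM_to_solid_mbar": -101.644,
        "sigma_dA_IEM_to_solid_mbar": 0.002,
        "dA_IEM_to_solid_ti": -101.656,
        "sigma_dA_IEM_to_solid_ti": 0.002,
        "n_states_ff": 118,
        "n_states_restraints": 600,
    }


def asa_single_molecule_cycle() -> dict:
    """Single-Einstein-molecule cycle legs for the ASA standard chemical potential (k_BT)."""
    return {
        "mu_ideal_EM": 9.3,
        "mu_FFoff": 65.7409,
        "sigma_mu_FFoff": 0.0009,
        "mu_restraining": 94.3,
        "sigma_mu_restraining": 0.2,
    }


_SOLUTION_CSV = """\
mole_fraction,volume_nm3,n_solute,n_solvent,mu_ex,sigma
2.000e-05,3035.99,2,99998,-16.80,0.05
6.666e-05,911.17,2,30002,-15.88,0.04
7.999e-05,759.33,2,25000,-15.51,0.05
9.998e-05,911.45,3,30003,-15.65,0.04
9.999e-05,607.59,2,20000,-15.47,0.05
1.3330e-04,911.72,4,30004,-15.77,0.04
1.3332e-04,455.84,2,15000,-15.61,0.04
1.666e-04,912.00,5,30005,-15.96,0.05
1.9992e-04,912.27,6,30006,-15.78,0.04
1.9996e-04,304.01,2,10000,-15.62,0.05
3.998e-04,152.25,2,5000,-15.41,0.06
1.996e-03,30.835,2,1000,-16.37,0.05
2.991e-03,31.069,3,1000,-16.40,0.06
3.984e-03,31.309,4,1000,-16.62,0.06
4.975e-03,31.547,5,1000,-17.1,0.1
"""


def asa_solution_table() -> pd.DataFrame:
    """ASA-in-water solution series: mole fraction, NPT volume, counts, μ^ex (k_BT).

    Mole fractions are expressed as fractions (not percent); volumes are
    the mean NPT volumes of the fully coupled state.
    """
    return pd.read_csv(io.StringIO(_SOLUTION_CSV))
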