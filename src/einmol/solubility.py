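"""Assemble solid and solution chemical potentials and find where they cross.

The solid's absolute free energy follows the Einstein-molecule cycle,

    A_solid = A_EM + ΔA_EM→IEM + ΔA_IEM→solid − N·ln(Σ_rot),

and its chemical potential is the molar free energy μ_solid = A_solid/N.
The solubility point is the concentration x* at which μ_solution(x)
equals μ_solid; if the solution curve stays above μ_solid over the whole
sampled range the compound is insoluble *in that range* (extrapolation
beyond the sampled concentrations is unsupported), and if it stays below
the sampled range is entirely supersaturated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import constants as _const

from .reference import symmetry_correction

__all__ = [
    "SolidFreeEnergy",
    "assemble_solid_mu",
    "pdv_correction",
    "SolubilityReport",
    "find_solubility",
    "plot_solubility",
]


@dataclass
class SolidFreeEnergy:
    """Solid-side chemical potential assembled from the Einstein-molecule cycle."""

    a_em: float
    da_em_to_iem: float
    da_iem_to_solid: float
    symmetry: float
    n_molecules: int
    mu: float  # k_BT per molecule
    sigma: float
    per_molecule_inputs: bool

    @property
    def total(self) -> float:
        """Sum of the cycle components on the input scale (before any /N)."""
        return self.a_em + self.da_em_to_iem + self.da_iem_to_solid + self.symmetry

    def to_dict(self) -> dict:
        return {
            "A_EM_kBT": self.a_em,
            "dA_EM_to_IEM_kBT": self.da_em_to_iem,
            "dA_IEM_to_solid_kBT": self.da_iem_to_solid,
            "symmetry_correction_kBT": self.symmetry,
            "N": self.n_molecules,
            "mu_solid_kBT": self.mu,
            "sigma_kBT": self.sigma,
            "per_molecule_inputs": self.per_molecule_inputs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SolidFreeEnergy":
        return cls(
            a_em=d["A_EM_kBT"],
            da_em_to_iem=d["dA_EM_to_IEM_kBT"],
            da_iem_to_solid=d["dA_IEM_to_solid_kBT"],
            symmetry=d["symmetry_correction_kBT"],
            n_molecules=int(d["N"]),
            mu=d["mu_solid_kBT"],
            sigma=d["sigma_kBT"],
            per_molecule_inputs=bool(d["per_molecule_inputs"]),
        )


def assemble_solid_mu(
    a_em: float,
    da_em_to_iem: float,
    da_iem_to_solid: float,
    N: int,
    sigma_rot: int = 1,
    per_molecule: bool = False,
    sigmas: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> SolidFreeEnergy:
    """Chemical potential of the solid from its Einstein-molecule cycle legs.

    With extensive inputs (``per_molecule=False``) the three components
    and the symmetry correction −N·ln(Σ_rot) are summed and divided by N;
    with per-molecule inputs the sum is taken directly and the symmetry
    correction enters as −ln(Σ_rot).  Component uncertainties combine in
    quadrature.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    sym_total = symmetry_correction(N, sigma_rot)
    if per_molecule:
        sym = sym_total / N
        mu = a_em + da_em_to_iem + da_iem_to_solid + sym
        sigma = float(np.sqrt(sum(s**2 for s in sigmas)))
    else:
        sym = sym_total
        mu = (a_em + da_em_to_iem + da_iem_to_solid + sym) / N
        sigma = float(np.sqrt(sum(s**2 for s in sigmas))) / N
    return SolidFreeEnergy(
        a_em=a_em,
        da_em_to_iem=da_em_to_iem,
        da_iem_to_solid=da_iem_to_solid,
        symmetry=sym,
        n_molecules=int(N),
        mu=float(mu),
        sigma=sigma,
        per_molecule_inputs=bool(per_molecule),
    )


def pdv_correction(pressure_kpa: float, delta_v_nm3: float, temperature: float) -> float:
    """P·ΔV in k_BT at the given temperature (P in kPa, ΔV in nm³).

    For molecular solids this term is orders of magnitude below typical
    simulation errors, which is what justifies ΔG ≈ ΔA; it is reported,
    never silently added.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    energy_j = pressure_kpa * 1e3 * delta_v_nm3 * 1e-27
    return float(energy_j / (_const.k * temperature))


@dataclass
class SolubilityReport:
    """Verdict of the μ_solid vs μ_solution(x) comparison over a sampled range."""

    verdict: str  # "crossing" | "insoluble-in-range" | "supersaturated-in-range"
    mu_solid: float
    sigma_solid: float
    x_range: tuple[float, float]
    x_star: float | None = None
    confident: bool = False
    series: pd.DataFrame | None = field(default=None, repr=False)
    interpolation: str = "piecewise-linear in ln x"

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "mu_solid_kBT": self.mu_solid,
            "sigma_solid_kBT": self.sigma_solid,
            "x_range": list(self.x_range),
            "x_star": self.x_star,
            "confident": self.confident,
            "interpolation": self.interpolation,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        lines = [
            "Solubility report",
            f"  mu_solid : {self.mu_solid:.4f} ± {self.sigma_solid:.4f} k_BT",
            f"  sampled x: [{self.x_range[0]:.4g}, {self.x_range[1]:.4g}]",
            f"  verdict  : {self.verdict}" + (" (confident)" if self.confident else ""),
        ]
        if self.x_star is not None:
            lines.append(f"  x*       : {self.x_star:.6g}")
        return "\n".join(lines)


def find_solubility(
    mole_fractions: np.ndarray,
    mu_solution_values: np.ndarray,
    sigma_solution: np.ndarray,
    mu_solid: float,
    sigma_solid: float = 0.0,
) -> SolubilityReport:
    """Locate the solubility point by piecewise-linear interpolation in ln x.

    Returns the smallest crossing x* where μ_solution − μ_solid changes
    sign; otherwise an ``insoluble-in-range`` (solution curve above the
    solid everywhere) or ``supersaturated-in-range`` (below everywhere)
    verdict.  A no-crossing verdict is flagged ``confident`` when the gap
    exceeds the joint 3σ everywhere.  Exact equality at a grid point
    counts as a crossing at that (smallest) x.
    """
    x = np.asarray(mole_fractions, dtype=float)
    mu = np.asarray(mu_solution_values, dtype=float)
    sig = np.asarray(sigma_solution, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two concentrations")
    if np.any(np.diff(x) <= 0):
        raise ValueError("mole fractions must be strictly increasing (no duplicates)")
    if np.any(x <= 0):
        raise ValueError("mole fractions must be positive")
    if not (np.all(np.isfinite(mu)) and np.isfinite(mu_solid)):
        raise ValueError("non-finite chemical potentials")
    gap = mu - mu_solid
    joint = np.sqrt(sig**2 + sigma_solid**2)
    x_range = (float(x[0]), float(x[-1]))

    # exact-equality tie-break: smallest such x
    zero_hits = np.where(gap == 0.0)[0]
    if zero_hits.size:
        return SolubilityReport(
            verdict="crossing", mu_solid=mu_solid, sigma_solid=sigma_solid,
            x_range=x_range, x_star=float(x[zero_hits[0]]),
            series=_series_frame(x, mu, sig),
        )
    sign_change = np.where(np.sign(gap[:-1]) != np.sign(gap[1:]))[0]
    if sign_change.size:
        i = int(sign_change[0])
        lx = np.log(x)
        t = -gap[i] / (gap[i + 1] - gap[i])
        x_star = float(np.exp(lx[i] + t * (lx[i + 1] - lx[i])))
        return SolubilityReport(
            verdict="crossing", mu_solid=mu_solid, sigma_solid=sigma_solid,
            x_range=x_range, x_star=x_star, series=_series_frame(x, mu, sig),
        )
    verdict = "insoluble-in-range" if np.all(gap > 0) else "supersaturated-in-range"
    confident = bool(np.all(np.abs(gap) > 3.0 * joint))
    return SolubilityReport(
        verdict=verdict, mu_solid=mu_solid, sigma_solid=sigma_solid,
        x_range=x_range, confident=confident, series=_series_frame(x, mu, sig),
    )


def _series_frame(x, mu, sig) -> pd.DataFrame:
    return pd.DataFrame({"mole_fraction": x, "mu_solution": mu, "sigma": sig})


def plot_solubility(report: SolubilityReport, ax=None):
    """Two-curve plot: μ_solution(x) with error bars against the μ_solid band."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 4))
    s = report.series
    if s is not None:
        ax.errorbar(
            s["mole_fraction"], s["mu_solution"], yerr=s["sigma"],
            fmt="o-", capsize=3, label=r"$\mu_{solution}(x)$",
        )
    ax.axhline(report.mu_solid, color="k", lw=1.5, label=r"$\mu_{solid}$")
    if report.sigma_solid > 0:
        ax.axhspan(
            report.mu_solid - report.sigma_solid,
            report.mu_solid + report.sigma_solid,
            color="k", alpha=0.15,
        )
    if report.x_star is not None:
        ax.axvline(report.x_star, color="r", ls="--", label=f"x* = {report.x_star:.3g}")
    ax.set_xscale("log")
    ax.set_xlabel("mole fraction x")
    ax.set_ylabel(r"$\mu$ / $k_BT$")
    ax.legend()
    ax.set_title(f"verdict: {report.verdict}")
    return ax
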