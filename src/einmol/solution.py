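"""Chemical potential of a solute in solution.

The solution-side chemical potential decomposes as

    μ_i = μ_i⁰ + (1/β)·ln(Λ³·N_i/V) + μ_i^ex,

a standard (single-molecule) part, an ideal mixing part, and an excess
part equal to the solvation (coupling) free energy of one solute
molecule.  The standard part is obtained from a single-Einstein-molecule
cycle, μ⁰ = μ_ideal − (μ_FFoff + μ_restraining), which bypasses the
unknown internal partition function.  The excess part is estimated by
alchemically decoupling one solute from a Lennard-Jones solvent along a
soft-core path, analysed with MBAR, and cross-checked against Widom test
particle insertion (and, at low density, the second-virial limit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import constants as _const
from scipy.integrate import quad

from .estimators import MultistateBAR, diagnose_path
from .model_systems import (
    CrystalSpec,
    EnergyModel,
    LennardJones,
    MoleculeTopology,
    SoftcoreLJ,
    minimum_image,
)
from .sampling import cross_evaluate, make_schedule, sample_path, state_scalings

__all__ = [
    "de_broglie_wavelength",
    "ideal_term",
    "mu_standard",
    "ChemicalPotentialComponents",
    "mu_solution",
    "LJSolution",
    "mu_excess_decoupling",
    "widom_oracle",
    "virial_mu_excess",
    "read_concentration_series",
]

NM3_TO_A3 = 1000.0  # 1 nm³ = 1000 Å³


def de_broglie_wavelength(mass_u: float, temperature: float) -> float:
    """Thermal de Broglie wavelength Λ = h/√(2π·m·k_B·T), in Å."""
    if mass_u <= 0 or temperature <= 0:
        raise ValueError("mass and temperature must be positive")
    m = mass_u * _const.u
    lam_m = _const.h / np.sqrt(2.0 * np.pi * m * _const.k * temperature)
    return lam_m * 1e10


def ideal_term(N_i: int, V: float, lam_thermal: float) -> float:
    """Ideal mixing part (1/β)·ln(Λ³·N_i/V) in k_BT; V and Λ in Å³ and Å."""
    if N_i < 1:
        raise ValueError("N_i must be >= 1")
    if V <= 0 or lam_thermal <= 0:
        raise ValueError("volume and lambda must be positive")
    return float(np.log(lam_thermal**3 * N_i / V))


def mu_standard(mu_ideal: float, mu_ffoff: float, mu_restraining: float) -> float:
    """Standard chemical potential from the single-Einstein-molecule cycle.

    μ⁰ = μ_ideal − (μ_FFoff + μ_restraining): the free energy of a single
    ideal Einstein molecule, minus the legs that turn off the molecule's
    force field and restrain its atoms to reference positions.  All
    values in k_BT.
    """
    return float(mu_ideal - (mu_ffoff + mu_restraining))


@dataclass
class ChemicalPotentialComponents:
    """μ decomposition at one concentration: standard + ideal + excess (k_BT)."""

    mole_fraction: float
    n_solute: int
    n_solvent: int
    volume: float  # Å³
    mu_standard: float
    ideal: float
    mu_excess: float
    sigma_standard: float = 0.0
    sigma_ideal: float = 0.0
    sigma_excess: float = 0.0

    def __post_init__(self) -> None:
        x = self.n_solute / (self.n_solute + self.n_solvent)
        if abs(x - self.mole_fraction) > 0.05 * max(self.mole_fraction, 1e-12):
            raise ValueError(
                f"mole fraction {self.mole_fraction} inconsistent with "
                f"N_i/(N_i+N_solv) = {x:.6g}"
            )

    @property
    def total(self) -> float:
        return self.mu_standard + self.ideal + self.mu_excess

    @property
    def sigma_total(self) -> float:
        # independent components combined in quadrature
        return float(np.sqrt(self.sigma_standard**2 + self.sigma_ideal**2 + self.sigma_excess**2))


def mu_solution(components: ChemicalPotentialComponents) -> tuple[float, float]:
    """Total solution chemical potential and its propagated uncertainty (k_BT)."""
    return components.total, components.sigma_total


# --------------------------------------------------------------------------
# toy LJ solution and decoupling
# --------------------------------------------------------------------------


@dataclass
class LJSolution:
    """One LJ solute in an LJ solvent at fixed V and T (reduced-style units).

    Solvent atoms interact through a truncated LJ potential; the solute
    couples to the solvent through the Beutler soft-core form whose λ is
    the decoupling coordinate.  ``epsilon`` values are in k_BT (so an
    ``epsilon`` of 0.5 corresponds to reduced temperature T* = 2).
    """

    n_solvent: int
    density: float  # ρσ³, dimensionless
    epsilon: float = 0.5  # k_BT
    sigma: float = 1.0  # Å (reduced length unit)
    solute_epsilon: float | None = None
    solute_sigma: float | None = None
    cutoff: float | None = None
    seed_structure: int = 0

    def __post_init__(self) -> None:
        if self.n_solvent < 2 or self.n_solvent > 4096:
            raise ValueError("n_solvent out of supported range")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.solute_epsilon is None:
            self.solute_epsilon = self.epsilon
        if self.solute_sigma is None:
            self.solute_sigma = self.sigma
        n_total = self.n_solvent + 1
        L = (n_total * self.sigma**3 / self.density) ** (1.0 / 3.0)
        if self.cutoff is None:
            self.cutoff = min(4.0 * self.sigma, 0.49 * L)
        if self.cutoff > L / 2:
            raise ValueError("cutoff exceeds half the box edge")
        self.box = np.array([L, L, L])

    def build(self) -> tuple[CrystalSpec, EnergyModel]:
        """Initial lattice configuration and the energy model (solute is atom 0)."""
        n_total = self.n_solvent + 1
        # start from a simple-cubic lattice to avoid overlaps
        m = int(np.ceil(n_total ** (1.0 / 3.0)))
        grid = np.array(
            [[i, j, k] for i in range(m) for j in range(m) for k in range(m)],
            dtype=float,
        )[:n_total]
        coords = (grid + 0.5) * (self.box[0] / m)
        top = MoleculeTopology(labels=("X",), masses=(40.0,))
        crystal = CrystalSpec(box=self.box, coords=coords, topology=top, fixed_atom=0)
        model = EnergyModel()
        mol_ids = np.arange(n_total)
        # solvent-solvent pairs only; solute (atom 0) pairs go through soft-core
        model.add(
            LennardJones(
                self.epsilon, self.sigma, self.cutoff, molecule_ids=mol_ids, exclude_atoms=(0,)
            )
        )
        model.add(
            SoftcoreLJ(
                self.solute_epsilon, self.solute_sigma, self.cutoff, solute_index=0
            )
        )
        return crystal, model


def mu_excess_decoupling(
    solution: LJSolution,
    n_states: int = 12,
    n_sweeps: int = 4000,
    seed: int = 0,
    schedule_exponent: int = 2,
    sample_every: int = 2,
):
    """Excess chemical potential of the solute by soft-core decoupling + MBAR.

    The path runs from the fully coupled solute (segment λ = 0, soft-core
    coupling 1) to the ideal, non-interacting solute (λ = 1, coupling 0);
    μ^ex is the free energy of *coupling*, i.e. minus the segment free
    energy.  Returns ``(mu_ex, stderr, info)`` with the overlap diagnosis
    and the sample set (whose λ = 1 state is pure solvent, reusable for
    Widom insertion) in ``info``.
    """
    crystal, model = solution.build()
    path = make_schedule("power", n_states, schedule_exponent, segment="decouple")
    states = state_scalings(path, {"lj_pair": "const", "softcore": "softcore_off"})
    samples = sample_path(
        crystal,
        model,
        states,
        n_sweeps=n_sweeps,
        master_seed=seed,
        lambdas=path.lambdas,
        step=0.35 * solution.sigma,
        sample_every=sample_every,
    )
    u = cross_evaluate(samples, states, crystal, model)
    result = MultistateBAR(u).fit()
    decouple_free_energy = result.delta_f(0, -1)
    mu_ex = -decouple_free_energy
    stderr = result.stderr_delta_f(0, -1)
    diag = diagnose_path(result.overlap())
    info = {
        "diagnosis": diag,
        "mbar": result,
        "samples": samples,
        "crystal": crystal,
        "model": model,
        "lambdas": path.lambdas,
    }
    return float(mu_ex), float(stderr), info


def widom_oracle(
    solvent_configs: np.ndarray,
    box: np.ndarray,
    epsilon: float,
    sigma: float,
    cutoff: float,
    n_insertions: int = 20000,
    seed: int = 0,
    solvent_indices: np.ndarray | None = None,
):
    """Widom test particle insertion: μ^ex = −ln⟨exp(−ΔU_insertion)⟩.

    Ghost solutes are inserted at uniform random positions into the given
    solvent configurations; ΔU is the plain LJ interaction with all
    solvent atoms within the cutoff.  Returns ``(mu_ex, stderr)``.

    Raises
    ------
    RuntimeError
        If every insertion Boltzmann factor underflows to zero.
    """
    configs = np.asarray(solvent_configs, dtype=float)
    if configs.ndim != 3:
        raise ValueError("solvent_configs must be (n_frames, n_atoms, 3)")
    if solvent_indices is not None:
        configs = configs[:, np.asarray(solvent_indices, dtype=int), :]
    rng = np.random.default_rng(seed)
    n_frames = configs.shape[0]
    frame_idx = rng.integers(0, n_frames, size=n_insertions)
    pos = rng.random((n_insertions, 3)) * box[None, :]
    w = np.empty(n_insertions)
    cut2 = cutoff**2
    for i in range(n_insertions):
        dr = minimum_image(configs[frame_idx[i]] - pos[i], box)
        r2 = np.sum(dr * dr, axis=1)
        r2 = r2[r2 < cut2]
        if epsilon == 0.0 or r2.size == 0:
            du = 0.0
        else:
            sr6 = (sigma**2 / r2) ** 3
            du = float(np.sum(4.0 * epsilon * (sr6 * sr6 - sr6)))
        w[i] = np.exp(-du) if du < 700 else 0.0
    mean_w = float(np.mean(w))
    if mean_w <= 0.0:
        raise RuntimeError("all insertions rejected at machine precision")
    mu_ex = -np.log(mean_w)
    sem_w = float(np.std(w, ddof=1) / np.sqrt(n_insertions))
    stderr = sem_w / mean_w
    return float(mu_ex), float(stderr)


def virial_mu_excess(epsilon: float, sigma: float, density: float, cutoff: float | None = None) -> float:
    """Low-density limit μ^ex ≈ 2·B₂·ρ from 1-D quadrature of the virial integral.

    B₂ = −(1/2)∫ (e^{−u(r)} − 1)·4πr² dr with the same truncated LJ pair
    potential used in the simulations (integral taken to the cutoff).
    Density is ρ in Å⁻³ consistent with σ in Å; result in k_BT.
    """
    rmax = cutoff if cutoff is not None else 10.0 * sigma

    def integrand(r):
        sr6 = (sigma / r) ** 6
        u = 4.0 * epsilon * (sr6 * sr6 - sr6)
        return (np.exp(-u) - 1.0) * 4.0 * np.pi * r**2

    val, _ = quad(integrand, 1e-6 * sigma, rmax, limit=200)
    b2 = -0.5 * val
    return float(2.0 * b2 * density)


# --------------------------------------------------------------------------
# concentration series I/O
# --------------------------------------------------------------------------

SERIES_COLUMNS = ["mole_fraction", "volume_nm3", "n_solute", "n_solvent", "mu_ex", "sigma"]


def read_concentration_series(path) -> pd.DataFrame:
    """Read a concentration-series table (CSV).

    Expected columns: ``mole_fraction`` (fractional, not %), ``volume_nm3``,
    ``n_solute``, ``n_solvent``, ``mu_ex`` (k_BT), ``sigma`` (k_BT).
    """
    df = pd.read_csv(path)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"concentration series missing columns: {missing}")
    if df["mole_fraction"].duplicated().any():
        raise ValueError("duplicate mole fractions in series")
    return df.sort_values("mole_fraction").reset_index(drop=True)


def solution_series(
    df: pd.DataFrame,
    mu_std: float,
    sigma_std: float,
    lam_thermal: float,
) -> pd.DataFrame:
    """Assemble μ_solution(x) for every row of a concentration series.

    Adds ``ideal``, ``mu_solution`` and ``sigma_solution`` columns; volumes
    are converted from nm³ to Å³ for the ideal term.
    """
    out = df.copy()
    ideals, totals, sigmas = [], [], []
    for _, row in out.iterrows():
        comp = ChemicalPotentialComponents(
            mole_fraction=float(row["mole_fraction"]),
            n_solute=int(row["n_solute"]),
            n_solvent=int(row["n_solvent"]),
            volume=float(row["volume_nm3"]) * NM3_TO_A3,
            mu_standard=mu_std,
            ideal=ideal_term(int(row["n_solute"]), float(row["volume_nm3"]) * NM3_TO_A3, lam_thermal),
            mu_excess=float(row["mu_ex"]),
            sigma_standard=sigma_std,
            sigma_excess=float(row["sigma"]),
        )
        ideals.append(comp.ideal)
        t, s = mu_solution(comp)
        totals.append(t)
        sigmas.append(s)
    out["ideal"] = ideals
    out["mu_solution"] = totals
    out["sigma_solution"] = sigmas
    return out
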