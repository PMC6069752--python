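"""End-to-end toy studies: estimator oracles, overlap failure/repair, solubility recovery.

These orchestrations wire the sampler, estimators, reference free energy
and assembler together on systems small enough to run on one CPU in
minutes, with closed-form Gaussian answers wherever the Hamiltonian is
purely harmonic.  They are what the acceptance script and the heavier
tests run.
"""

from __future__ import annotations

import numpy as np

from .estimators import (
    MultistateBAR,
    bar_estimate,
    chain_segments,
    diagnose_path,
    ti_estimate,
)
from .model_systems import (
    EnergyModel,
    LennardJones,
    SiteRestraint,
    build_fcc_crystal,
)
from .reference import em_free_energy_analytic
from .sampling import (
    LambdaPath,
    SampleSet,
    StateSamples,
    cross_evaluate,
    derive_seeds,
    sample_state,
    subsample_decorrelated,
)
from .solubility import assemble_solid_mu, find_solubility
from .solution import de_broglie_wavelength, ideal_term

__all__ = [
    "k_switch_states",
    "harmonic_switch_experiment",
    "restraint_removal_overlap_experiment",
    "toy_solubility_recovery",
]


def k_switch_states(k_start: float, k_end: float, K: int, exponent: int = 4):
    """λ grid and restraint coefficients for k(λ) = k_end + (k_start−k_end)·(1−λ)^p.

    The coefficients scale a restraint term built at ``k_start``; the
    power-p mixing crowds states toward the weak-restraint end, which is
    where phase-space overlap between neighbours collapses if states are
    evenly spaced.  Returns ``(path, coefficients)``.
    """
    path = LambdaPath(
        lambdas=np.arange(K) / (K - 1), mixing=("power", exponent), segment="restraints_off"
    )
    f = path.f(path.lambdas)
    coeffs = (k_end + (k_start - k_end) * f) / k_start
    return path, coeffs


def _sample_and_subsample(
    crystal,
    model,
    coeffs,
    lambdas,
    master_seed: int,
    n_sweeps: int,
    target_samples: int | None,
    step: float,
    sample_every: int = 1,
) -> SampleSet:
    """Sample every state, then thin each archive by its statistical inefficiency.

    The decorrelation series is the restraint energy (the order parameter
    the alchemical coefficient couples to).
    """
    seeds = derive_seeds(master_seed, len(coeffs))
    out = SampleSet(lambdas=np.asarray(lambdas, dtype=float))
    restr = model.terms["site_restraint"]
    for c, sd in zip(coeffs, seeds):
        st = sample_state(
            crystal,
            model,
            {name: (c if name == "site_restraint" else 1.0) for name in model.terms},
            n_sweeps=n_sweeps,
            seed=int(sd),
            step=step,
            sample_every=sample_every,
        )
        dr = st.configs - restr.reference[None, :, :]
        series = 0.5 * np.einsum("a,ma->m", restr.k, np.sum(dr * dr, axis=2))
        idx, g = subsample_decorrelated(series)
        if target_samples is not None:
            idx = idx[:target_samples]
        out.states.append(
            StateSamples(
                configs=st.configs[idx],
                scalings=st.scalings,
                seed=st.seed,
                n_sweeps=st.n_sweeps,
                acceptance=st.acceptance,
                step=st.step,
            )
        )
    return out


def harmonic_switch_experiment(
    seed: int = 1,
    n_cells: int = 2,
    lattice_constant: float = 5.0,
    k_start: float = 4000.0,
    k_end: float = 40.0,
    K: int = 24,
    exponent: int = 4,
    target_samples: int = 10_000,
    n_sweeps: int | None = None,
) -> dict:
    """Switch the restraint constant of a pure-restraint crystal and estimate ΔA.

    A 4·n³-atom harmonic crystal (one atom fixed) has the exact free
    energy change ΔA = (3(N−1)/2)·ln(k_end/k_start) when its restraint
    constant is switched, independent of path.  TI, chained BAR and MBAR
    are all run on the same subsampled Metropolis data and compared with
    that closed form.
    """
    crystal = build_fcc_crystal(n_cells, lattice_constant)
    N = crystal.n_atoms
    model = EnergyModel().add(
        SiteRestraint(k_start, crystal.coords, fixed_atom=crystal.fixed_atom)
    )
    path, coeffs = k_switch_states(k_start, k_end, K, exponent)
    if n_sweeps is None:
        # the restraint-energy inefficiency of the tuned Metropolis chain is
        # ≈ 10–12 sweeps, so this raw length yields ≈ target_samples
        # decorrelated points per state
        n_sweeps = int(target_samples * 13.5)
    samples = _sample_and_subsample(
        crystal, model, coeffs, path.lambdas, seed, n_sweeps, target_samples,
        step=3.0 / np.sqrt(k_start),
    )
    states = [{"site_restraint": float(c)} for c in coeffs]
    u = cross_evaluate(samples, states, crystal, model)

    mbar = MultistateBAR(u).fit()
    mbar_est = mbar.total_estimate()
    diag = diagnose_path(mbar.overlap())

    # chained BAR over neighbours
    bar_segs = []
    for k in range(K - 1):
        fwd, bwd = u.forward_backward(k)
        bar_segs.append(bar_estimate(fwd, bwd))
    bar_est = chain_segments(bar_segs)

    # TI: dH/dλ = c'(λ)·E_restraint(base k_start)
    p = float(exponent)
    cprime = -p * (k_start - k_end) * (1.0 - path.lambdas) ** (p - 1.0) / k_start
    means = np.empty(K)
    sems = np.empty(K)
    restr = model.terms["site_restraint"]
    for k, st in enumerate(samples.states):
        dr = st.configs - restr.reference[None, :, :]
        e_base = 0.5 * np.einsum("a,ma->m", restr.k, np.sum(dr * dr, axis=2))
        vals = cprime[k] * e_base
        means[k] = vals.mean()
        sems[k] = vals.std(ddof=1) / np.sqrt(vals.size)
    ti_est = ti_estimate(path.lambdas, means, sems)

    exact = 1.5 * (N - 1) * np.log(k_end / k_start)
    return {
        "exact": float(exact),
        "ti": ti_est,
        "bar": bar_est,
        "mbar": mbar_est,
        "diagnosis": diag,
        "n_atoms": N,
        "n_states": K,
        "n_k": samples.n_k,
    }


def restraint_removal_overlap_experiment(
    seed: int = 1,
    n_cells: int = 2,
    lattice_constant: float | None = None,
    epsilon: float = 2.0,
    sigma: float = 3.4,
    k_start: float = 4000.0,
    sparse_K: int = 18,
    dense_K: int = 150,
    dense_exponent: int = 4,
    n_samples: int = 400,
    n_sweeps: int = 1200,
) -> dict:
    """Remove the restraints of an LJ+restraint crystal on a sparse and a dense path.

    The sparse path switches the restraint coefficient linearly over
    ``sparse_K`` evenly spaced states — the protocol that loses
    phase-space overlap as the restraints approach zero and atoms become
    mobile.  The dense path uses ``dense_K`` states with quartic mixing,
    crowding states near zero restraint.  Returns both MBAR fits, their
    overlap diagnoses and the uncertainty ratio.
    """
    if lattice_constant is None:
        lattice_constant = 2.0 ** (2.0 / 3.0) * sigma  # nearest neighbours at the LJ minimum
    crystal = build_fcc_crystal(n_cells, lattice_constant)
    cutoff = 0.49 * float(min(crystal.box))
    model = (
        EnergyModel()
        .add(SiteRestraint(k_start, crystal.coords, fixed_atom=crystal.fixed_atom))
        .add(
            LennardJones(
                epsilon, sigma, cutoff, molecule_ids=crystal.molecule_ids
            )
        )
    )

    def run(K: int, exponent: int):
        path, coeffs = k_switch_states(k_start, 0.0, K, exponent)
        samples = _sample_and_subsample(
            crystal, model, coeffs, path.lambdas, seed + K, n_sweeps,
            n_samples, step=3.0 / np.sqrt(k_start), sample_every=1,
        )
        states = [
            {"site_restraint": float(c), "lj_pair": 1.0} for c in coeffs
        ]
        u = cross_evaluate(samples, states, crystal, model)
        mbar = MultistateBAR(u).fit()
        return {
            "estimate": mbar.total_estimate(),
            "diagnosis": diagnose_path(mbar.overlap()),
            "mbar": mbar,
        }

    sparse = run(sparse_K, 1)
    dense = run(dense_K, dense_exponent)
    ratio = sparse["estimate"].stderr / max(dense["estimate"].stderr, 1e-300)
    return {
        "sparse": sparse,
        "dense": dense,
        "stderr_ratio": float(ratio),
        "n_atoms": crystal.n_atoms,
    }


def toy_solubility_recovery(
    seed: int = 1,
    n_cells: int = 2,
    lattice_constant: float = 5.0,
    k_start: float = 4000.0,
    k_solid: float = 40.0,
    K: int = 24,
    target_samples: int = 3000,
    mass_u: float = 40.0,
    temperature: float = 4.0,
    mu_standard_toy: float = 10.0,
    v_solution: float = 1.0e5,
    n_solvent: int = 1000,
    solute_grid: tuple = (20, 30, 40, 50, 60, 70, 80, 100, 120),
) -> dict:
    """End-to-end parameter recovery on a fully analytic toy.

    Solid: a pure-restraint crystal whose "solid" state keeps weak
    restraints at ``k_solid``; its absolute free energy is the analytic
    ideal Einstein-molecule term at ``k_start`` plus a simulated
    restraint-switch segment (MBAR).  Solution: an ideal solute
    (μ^ex ≡ 0) with a fixed toy standard potential.  The crossing

        μ⁰ + ln(Λ³·N_i/V) = μ_solid

    has the closed-form solution N* = (V/Λ³)·exp(μ_solid − μ⁰); the
    pipeline must recover the corresponding mole fraction within its
    propagated uncertainty.
    """
    lam = de_broglie_wavelength(mass_u, temperature)
    crystal = build_fcc_crystal(n_cells, lattice_constant)
    N = crystal.n_atoms
    a_em = em_free_energy_analytic(N, k_start, lam, crystal.volume)

    switch = harmonic_switch_experiment(
        seed=seed, n_cells=n_cells, lattice_constant=lattice_constant,
        k_start=k_start, k_end=k_solid, K=K, target_samples=target_samples,
    )
    da = switch["mbar"]

    solid = assemble_solid_mu(
        a_em.value, 0.0, da.value, N=N, sigma_rot=1, per_molecule=False,
        sigmas=(a_em.stderr, 0.0, da.stderr),
    )

    x = np.array([n / (n + n_solvent) for n in solute_grid], dtype=float)
    mu_sol = np.array(
        [mu_standard_toy + ideal_term(n, v_solution, lam) for n in solute_grid]
    )
    sig = np.zeros_like(mu_sol)
    report = find_solubility(x, mu_sol, sig, solid.mu, solid.sigma)

    exact_da = 1.5 * (N - 1) * np.log(k_solid / k_start)
    mu_solid_exact = (a_em.value + exact_da) / N
    n_star = v_solution / lam**3 * np.exp(mu_solid_exact - mu_standard_toy)
    x_star_exact = n_star / (n_star + n_solvent)
    # propagated statistical error on x*: dx*/dμ_solid = x*(1−x*)
    sigma_x = x_star_exact * (1.0 - x_star_exact) * solid.sigma
    return {
        "report": report,
        "solid": solid,
        "x_star_exact": float(x_star_exact),
        "sigma_x_star": float(sigma_x),
        "mu_solid_exact": float(mu_solid_exact),
        "switch": switch,
        "lam_thermal": float(lam),
    }
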