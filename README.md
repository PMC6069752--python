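# einmol

Absolute chemical potentials of molecular solids via the Einstein
Molecule Method (EMM), solution chemical potentials via alchemical
decoupling, and solubility as the concentration where the two cross —
implemented end-to-end on toy crystal and solution systems with
closed-form oracles, for people who develop, teach or stress-test
alchemical free-energy workflows.

## The problem and the method

Solubility is a phase equilibrium: at the solubility point the chemical
potential of the solute in the solid equals its chemical potential in
solution,

```
μ_solid = μ_solution(x*).
```

Both sides require *absolute* free energies, which direct simulation
cannot give.  The EMM supplies the solid side through a reference state
whose free energy is computable — the **ideal Einstein molecule**, a
lattice of non-interacting molecules harmonically tethered to their
sites, with one single atom fixed in space:

```
A_solid = A_EM + ΔA_EM→IEM + ΔA_IEM→solid − N·ln(Σ_rot)/β,    μ_solid = A_solid/N
```

where ΔA_EM→IEM turns the interaction Hamiltonian on, ΔA_IEM→solid turns
the harmonic restraints off, and the Σ_rot term corrects for molecular
orientations that the site restraints artificially distinguish.  Both ΔA
legs are alchemical free-energy calculations over a ladder of mixed
Hamiltonians H(λ) = f(λ)·H_initial + g(λ)·H_final, estimated by TI, EXP,
BAR or MBAR from configurations sampled at every λ state.

The solution side decomposes as

```
μ_solution = μ⁰ + (1/β)·ln(Λ³·N_i/V) + μ^ex,
```

with the standard part μ⁰ obtained by transforming a *single* molecule
into a single Einstein molecule (bypassing its unknown internal
partition function), and the excess part μ^ex equal to the solvation
free energy of one solute, here computed by soft-core decoupling from a
Lennard-Jones solvent and cross-checked by Widom test-particle
insertion.

The package's central diagnostic is the **phase-space overlap matrix**:
a row-stochastic K×K matrix of probabilities that configurations from
one λ state are representative of another.  Near-zero entries between
neighbouring states mean the free-energy estimate is unreliable no
matter how smooth a TI integrand looks — the cure is a denser (e.g.
quartically spaced) λ schedule near the weak-restraint end.

## Worked example

The repository ships the published Einstein-molecule cycle components
for acetylsalicylic acid (ASA, GAFF force field in TIP3P water at
298.15 K) as input data.  Assembling them:

```python
from einmol import datasets
from einmol.solubility import assemble_solid_mu, find_solubility
from einmol.solution import de_broglie_wavelength, mu_standard, solution_series

comp = datasets.asa_solid_components()
solid = assemble_solid_mu(
    comp["A_EM"], comp["dA_EM_to_IEM_mbar"], comp["dA_IEM_to_solid_mbar"],
    N=datasets.ASA_N_SOLID, sigma_rot=datasets.ASA_SIGMA_ROT, per_molecule=True,
    sigmas=(comp["sigma_A_EM"], comp["sigma_dA_EM_to_IEM_mbar"],
            comp["sigma_dA_IEM_to_solid_mbar"]))
print(f"mu_solid = {solid.mu:.2f} +- {solid.sigma:.2f} kBT")

cyc = datasets.asa_single_molecule_cycle()
mu0 = mu_standard(cyc["mu_ideal_EM"], cyc["mu_FFoff"], cyc["mu_restraining"])
print(f"mu_standard = {mu0:.2f} kBT")

lam = de_broglie_wavelength(datasets.ASA_MASS_U, datasets.ASA_TEMPERATURE_K)
series = solution_series(datasets.asa_solution_table(), mu0,
                         cyc["sigma_mu_restraining"], lam)
report = find_solubility(
    series["mole_fraction"].to_numpy(), series["mu_solution"].to_numpy(),
    series["sigma_solution"].to_numpy(), solid.mu, solid.sigma)
print(report.summary())
```

prints

```
mu_solid = -220.71 +- 3.00 kBT
mu_standard = -150.74 kBT
Solubility report
  mu_solid : -220.7140 ± 3.0002 k_BT
  sampled x: [2e-05, 0.004975]
  verdict  : insoluble-in-range (confident)
```

Reading: the solid sits ~30 k_BT below the solution curve at every
sampled concentration (μ_solution ranges from about −190 to −184 k_BT),
so within this energy model the compound never reaches equilibrium with
its solution in the sampled range — it is insoluble there, and the gap
dwarfs the joint statistical error, hence the confident flag.

The same machinery runs live on toy systems where the exact answer is
known.  For example, `einmol.experiments.harmonic_switch_experiment`
samples a 32-atom harmonic crystal whose restraint constant is switched
4000 → 40 k_BT/Å² over a 24-state quartically-mixed path and recovers
the closed form (3(N−1)/2)·ln(k₁/k₀) = −214.14 k_BT with TI, chained BAR
and MBAR, each within its quoted uncertainty (≈ 0.07 k_BT for MBAR).

A thin CLI mirrors the two analysis entry points:

```
einmol estimate u.csv u.json --out result.json --overlap-csv overlap.csv --strict
einmol solubility solid.json series.csv --mu-standard -150.74 --mass 180.158 \
    --out report.json --plot mu_vs_x.png
```

## Layout

```
src/einmol/
  model_systems.py   toy crystals, topologies, per-term energy models
  sampling.py        λ schedules, Metropolis/Langevin samplers, cross-evaluation
  estimators.py      TI / EXP / BAR / MBAR, overlap matrix, path diagnosis
  reference.py       ideal Einstein-molecule free energy (analytic + MC)
  solution.py        Λ, ideal term, μ⁰ cycle, soft-core decoupling, Widom
  solubility.py      solid-side assembly, PΔV, crossing search, plotting
  experiments.py     end-to-end toy studies used by tests and acceptance
  datasets.py        published ASA worked-example inputs
  cli.py             `einmol estimate` / `einmol solubility`
```

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
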