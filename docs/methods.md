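# Methods

## Scope and units

`einmol` implements the Einstein Molecule Method (EMM) for absolute free
energies of molecular solids, the companion single-molecule cycle for
standard chemical potentials, alchemical decoupling for excess chemical
potentials, and the solubility condition μ_solid = μ_solution(x*) — all
exercised on toy systems small enough that closed-form or quadrature
oracles exist.  Energies are carried in units of k_BT throughout
(β ≡ 1); lengths in Å.  The absolute temperature enters only through the
de Broglie wavelength Λ = h/√(2πmk_BT) and unit conversions (e.g. the
PΔV term).  This removes an entire class of unit errors and matches how
free-energy results are usually reported.

## Model systems

Crystals are orthorhombic and periodic with minimum-image pair
interactions; pair cutoffs must not exceed half the shortest box edge
(enforced at evaluation).  Energy models are ordered sums of named
terms — isotropic harmonic site restraints, truncated (unshifted)
12-6 Lennard-Jones between atoms of different molecules, harmonic
bonds, and a Beutler soft-core Lennard-Jones for a designated solute —
each evaluable separately so that linear λ-mixing and TI derivatives
are exact by construction.  The default restraint constant is
4000 k_BT/Å², the value strong enough that a restrained atom explores
only ~0.016 Å r.m.s.

The Einstein-molecule anchor is one fixed atom (default: atom 0 of
molecule 0; the choice is arbitrary in principle).  The fixed atom
carries no restraint term and is never moved by any sampler.  Restraints
are isotropic in x, y, z with no angular restraint; the missing
orientational bookkeeping is restored analytically by the symmetry
correction −N·ln(Σ_rot)/β, where Σ_rot is the molecule's proper-rotation
symmetry number.

## Alchemical paths

A path mixes initial and final Hamiltonians as
H(λ) = f(λ)·H_initial + g(λ)·H_final with f(0)=1, g(0)=0, f(1)=0,
g(1)=1.  Two equivalent ways of crowding states near the weak-restraint
end are exposed, because published protocols rarely say which they used:
power-spaced λ values ((i/(K−1))^p) with linear mixing, or linearly
spaced λ with power mixing f = (1−λ)^p.  Restraint-removal segments
default to p = 4 (quartic), which the overlap study below shows is the
difference between a broken and a healthy path.  λ values are stored at
full floating precision; schedules are never rounded.

Soft-core coupling uses the Beutler form with α = 0.5:
U(λ) = 4ελ[(α(1−λ)² + (r/σ)⁶)⁻² − (α(1−λ)² + (r/σ)⁶)⁻¹], finite at
r → 0 for λ < 1.  The solute's internal Hamiltonian is never scaled.

## Sampling

The default engine is single-particle-move Metropolis (numba kernel).
The displacement step is tuned toward 30–50 % acceptance during the
equilibration window only — the first 10 % of sweeps, which are
discarded — because tuning during production would break detailed
balance.  A BAOAB Langevin integrator with unit masses is available as
an alternative; its configurational distributions carry the usual
O(dt²) discretization bias, so the Metropolis engine (exact for these
toys) is preferred for estimation.  One master seed derives independent
per-state streams via `numpy.random.SeedSequence`, making every study
reproducible from a single integer.

Production series are thinned by the statistical inefficiency
g = 1 + 2·Σ C(t) (autocorrelation summed to its first zero crossing,
with the finite-series taper 1 − t/n); samples are kept every ⌈g⌉
sweeps.  A constant series is defined to carry one effective sample and
triggers a warning.  For the alchemical studies the decorrelation series
is the restraint energy — the collective coordinate the λ coefficient
couples to.

## Estimators

* **TI** — trapezoidal quadrature of ⟨∂H/∂λ⟩.  Its reported error
  propagates only the per-state integrand noise through the quadrature
  weights.  It deliberately does not reflect overlap failure or the
  behaviour of the integrand between sampled λ values; the overlap study
  demonstrates how misleading that can be.
* **EXP** — ΔA = −ln⟨e^{−ΔU}⟩ with a seeded bootstrap (200 resamples)
  standard error.  Known to be biased when overlap is poor; a test
  constructs the failure explicitly.
* **BAR** — the two-state acceptance-ratio equation solved by bracketed
  root finding to 10⁻¹⁰ k_BT, with the Bennett asymptotic variance.
  Failure to bracket a root raises (catastrophic overlap), never returns
  silently.
* **MBAR** — the multistate generalization, solved with f₀ anchored to
  0 by an adaptive scheme: damped Newton on the convex MBAR objective
  (K×K Hessian, backtracking until the gradient norm decreases) with
  the self-consistent update as fallback, initialized from forward EXP
  chained over neighbours using each source state's own samples, and
  warm-started from a strided subsample when the pool exceeds 50 000
  points.  Convergence requires the self-consistency residual
  max|f_new − f| < 10⁻¹⁰.  The asymptotic covariance is computed from
  the weight-matrix SVD; the inner matrix's single structural null mode
  (the uniform shift of the f's) is projected out, and any additional
  null mode — the signature of disconnected state blocks — or
  significantly negative mode makes the covariance infinite.  An
  infinite uncertainty on a pathological path is deliberate: a silently
  truncated pseudo-inverse would report a small, wrong error instead.

Segment estimates chain by summation with variances added in quadrature
(independent segments: each state is sampled by its own seeded chain).

### Overlap diagnosis

The overlap matrix O_ij = Σ_n W_ni W_nj N_j is row-stochastic at
convergence (rows sum to 1 within 10⁻¹⁰).  A path is flagged when the
mutual overlap of any adjacent pair falls below min(0.03, 0.5/K).  The
K-dependence is deliberate: with equal sample counts a *perfectly*
overlapping K-state path has uniform entries 1/K, so a fixed cutoff of
0.03 would condemn any path longer than ~33 states, including the dense
schedules the diagnostic is supposed to endorse.  For short paths the
0.03 rule of thumb is retained.

## Ideal Einstein-molecule reference

For point particles, A_EM = ln(NΛ³/V) + (N−1)·(3/2)·ln(kΛ²/2π) in
closed form.  For rigid molecules the orientational integrals are
evaluated by seeded Monte Carlo: orientations uniform over SO(3)
(measure 8π²; 4π for linear molecules via uniform axis directions; 1
for atoms), with the rigid-displacement integral reduced analytically —
at fixed orientation the site-restraint energy is exactly quadratic in
the rigid shift, so the positional factor is a closed-form Gaussian.
This Rao-Blackwellization removes all positional variance; for atoms the
estimate collapses to the analytic value with zero Monte Carlo error,
and a separate molecular test guards that the stochastic machinery is
genuinely exercised.  Restraint integrals are taken over all space
rather than the finite box: at k = 4000 k_BT/Å² the Gaussian decays
below machine precision within a fraction of an ångström, so the
truncation error is far below every other error in the pipeline.  The
estimator refuses (raises) when the relative error of an orientational
integral exceeds 10 % at the sample budget — uniform orientation
sampling against a sharply peaked Boltzmann factor is the known
weakness of this integrator, and pretending otherwise would produce
silently wrong references.

## Solution side

μ_solution = μ⁰ + ln(Λ³N_i/V) + μ^ex.  The standard part comes from the
single-molecule cycle μ⁰ = μ_ideal − (μ_FFoff + μ_restraining);
uncertainties of the legs combine in quadrature (independent
simulations).  The excess part is the coupling free energy of one
solute, computed by MBAR over a soft-core decoupling path (default 12
states, power-2 λ spacing with linear mixing) in a Lennard-Jones
solvent at fixed V and T.  The solute is held at the fixed-atom site
during decoupling; for a homogeneous fluid μ^ex is translation
invariant, so this costs nothing and reuses the crystal sampler
unchanged.  The fully decoupled state is pure solvent and doubles as
the configuration source for the Widom cross-check
μ^ex = −ln⟨e^{−ΔU_insertion}⟩ over uniform random insertions.  At low
density both must approach the second-virial limit 2B₂ρ/β, with B₂
computed by 1-D quadrature of the same truncated pair potential.

NPT solution volumes (as in the shipped acetylsalicylic-acid series)
are *inputs*: the toy solvent is simulated at fixed volume, and
reconstructing a published solution series uses the published mean
volumes directly.

## Solubility assembly

μ_solid = [A_EM + ΔA_EM→IEM + ΔA_IEM→solid − N ln Σ_rot]/N.  ΔG ≈ ΔA is
adopted for the solid; the PΔV term is computed and reported (for the
shipped example, 101.325 kPa × 0.14 nm³ at 298.15 K ≈ 3.4×10⁻³ k_BT)
but never silently added.  μ_solution(x) is interpolated piecewise
linearly in ln x — the ideal term is logarithmic in composition, so the
interpolant is near-exact on dilute grids — and the smallest sign change
of μ_solution − μ_solid is returned as x*.  With no sign change the
verdict is insoluble-in-range or supersaturated-in-range; "in range" is
deliberate, since extrapolation beyond the sampled concentrations is
unsupported.  A no-crossing verdict is flagged *confident* when the gap
exceeds the joint 3σ everywhere.  Ties at exact equality return the
smaller x.

## Study conditions (toy-system defaults)

* **Harmonic-switch oracle**: 32-atom fcc pure-restraint crystal
  (a = 5 Å), k switched 4000 → 40 k_BT/Å² over 24 states with quartic
  mixing, ~10⁴ decorrelated samples per state (raw chains of 13.5×
  that length; the tuned chain's restraint-energy inefficiency is
  ≈ 10–12 sweeps).  Exact answer (3(N−1)/2)·ln(k₁/k₀) = −214.140 k_BT.
* **Overlap failure/repair**: 32-atom fcc LJ crystal (σ = 3.4 Å,
  ε = 2 k_BT, nearest neighbours at the LJ minimum), restraints removed
  entirely.  Sparse protocol: 18 states, linear mixing.  Dense: 150
  states, quartic mixing, ~10²–10³ samples per state.  The sparse path
  loses neighbour overlap as k → 0 (atoms become mobile), its MBAR
  covariance acquires a disconnected-block null mode, and the
  uncertainty is reported infinite; the dense path passes diagnostics
  with a sub-k_BT error.
* **Excess chemical potential**: 100 LJ solvent atoms + 1 solute at
  ρσ³ = 0.05 and ε = 0.5 k_BT (reduced temperature T* = 2), 12-state
  soft-core decoupling, 4000 sweeps per state.  At this density the
  virial estimate 2B₂ρ carries a ~2 % third-virial correction, well
  inside the 15 % comparison band.
* **End-to-end recovery**: solid = the 32-atom harmonic crystal whose
  "solid" state keeps weak restraints at k = 40 (its absolute free
  energy is analytic); solution = ideal solute (μ^ex ≡ 0) with a toy
  standard potential μ⁰ = 10 k_BT, V = 10⁵ Å³, 1000 solvent particles,
  solute counts 20–120; solute mass 40 u at 4 K puts the crossing near
  x* ≈ 0.057.  The Λ-dependent parts of μ_solid and the ideal term
  cancel exactly, so x* is independent of the solute mass — asserted in
  a test at two masses.

These problem sizes were chosen so each study completes in seconds to a
couple of minutes on a single core while leaving the statistical errors
small against their acceptance bands.

## What the toys do and do not show

The toy systems share with the real problem its entire estimation
structure: reference-state bookkeeping, λ scheduling, cross-evaluation,
estimator behaviour under good and broken overlap, and the assembly
arithmetic.  They do not contain electrostatics, molecular flexibility,
solvent structure (hydrogen bonding), NPT volume fluctuations, or
force-field error — so passing tests validate the *method and its
implementation*, not the accuracy of any particular energy model for a
real compound.  The shipped acetylsalicylic-acid numbers illustrate
exactly that distinction: the assembly is reproduced faithfully, and the
verdict it yields (insoluble in range) disagrees with the experimental
solubility because of the underlying energy model, not the arithmetic.

## Known limitations

* Uniform-orientation Monte Carlo for A_EM fails for stiff restraints on
  extended molecules (it refuses rather than degrades); an oriented
  proposal distribution would be needed for production-strength
  restraint constants on large molecules.
* The Langevin sampler is provided for completeness; its O(dt²) bias is
  visible at the package's test tolerances, so estimation defaults to
  Metropolis.
* Truncated LJ without tail corrections: absolute energies include a
  cutoff dependence, which is immaterial here because every comparison
  is against an oracle computed with the identical truncated potential.
* `find_solubility` interpolates; it does not model activity
  coefficients or extrapolate beyond the sampled concentration range.
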