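"""Alchemical λ states, Monte Carlo / Langevin sampling, cross-evaluation.

An alchemical path mixes an initial and a final Hamiltonian,

    H(λ) = f(λ)·H_initial + g(λ)·H_final,

with f(0) = 1, g(0) = 0, f(1) = 0, g(1) = 1.  Two mixing families are
provided: ``linear`` (f = 1−λ) and ``power`` (f = (1−λ)^p), the latter
concentrating near-zero coefficients at the λ→1 end — the shape needed
when harmonic restraints are switched off and states must crowd together
as the restraint constant approaches zero.  Alternatively the schedule
itself can be power-spaced (λ_i = (i/(K−1))^p) with linear mixing; both
parameterizations are exposed because published protocols rarely state
which one they used.

Sampling honours the Einstein-molecule constraint: the fixed atom is never
displaced.  The default engine is single-particle-move Metropolis with the
displacement auto-tuned to 30–50 % acceptance during equilibration only;
a BAOAB Langevin integrator is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._mc import metropolis_chain
from .model_systems import CrystalSpec, EnergyModel, minimum_image

__all__ = [
    "LambdaPath",
    "make_schedule",
    "mixed_energy",
    "StateSamples",
    "SampleSet",
    "ReducedPotentialMatrix",
    "sample_state",
    "sample_path",
    "cross_evaluate",
    "subsample_decorrelated",
    "statistical_inefficiency",
    "state_scalings",
    "derive_seeds",
]

SEGMENT_KINDS = ("ff_on", "restraints_off", "decouple", "generic")


@dataclass(frozen=True)
class LambdaPath:
    """An ordered set of λ values with a mixing rule and a segment label.

    ``mixing`` is ``("linear",)`` or ``("power", p)``; the mixing
    functions are f(λ) = (1−λ)^p and g(λ) = 1 − f(λ) with p = 1 for
    linear mixing.
    """

    lambdas: np.ndarray
    mixing: tuple = ("linear",)
    segment: str = "generic"

    def __post_init__(self) -> None:
        lams = np.asarray(self.lambdas, dtype=float)
        object.__setattr__(self, "lambdas", lams)
        if lams.ndim != 1 or lams.size < 2:
            raise ValueError("a path needs at least two lambda values")
        if np.any(np.diff(lams) <= 0):
            raise ValueError("lambda values must be strictly increasing")
        if abs(lams[0]) > 1e-12 or abs(lams[-1] - 1.0) > 1e-12:
            raise ValueError("path must include both endpoints 0 and 1")
        if self.segment not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.segment!r}")
        if self.mixing[0] not in ("linear", "power"):
            raise ValueError(f"unknown mixing {self.mixing[0]!r}")

    @property
    def K(self) -> int:
        return self.lambdas.size

    @property
    def power(self) -> float:
        return 1.0 if self.mixing[0] == "linear" else float(self.mixing[1])

    def f(self, lam: np.ndarray | float) -> np.ndarray | float:
        return (1.0 - np.asarray(lam)) ** self.power

    def g(self, lam: np.ndarray | float) -> np.ndarray | float:
        return 1.0 - self.f(lam)

    def fprime(self, lam: np.ndarray | float) -> np.ndarray | float:
        p = self.power
        return -p * (1.0 - np.asarray(lam)) ** (p - 1.0)

    def chunk(self, size: int) -> list["LambdaPath"]:
        """Split into overlapping sub-paths of at most ``size`` states.

        Consecutive chunks share one state so chained segment free
        energies telescope to the full path; the union of chunk λ values
        reproduces the original set exactly.
        """
        if size < 2:
            raise ValueError("chunk size must be >= 2")
        out = []
        i = 0
        while i < self.K - 1:
            j = min(i + size - 1, self.K - 1)
            sub = self.lambdas[i : j + 1]
            # sub-paths are plain λ collections; rescale to [0,1] is not
            # meaningful here, so keep raw values in a lightweight holder
            out.append(sub.copy())
            i = j
        return out


def make_schedule(kind: str, K: int, exponent: int = 1, segment: str = "generic") -> LambdaPath:
    """Build a λ schedule: ``linear`` equal spacing or ``power`` λ_i = (i/(K−1))^p."""
    if K < 2:
        raise ValueError("K must be >= 2")
    if exponent < 1:
        raise ValueError("exponent must be >= 1")
    x = np.arange(K) / (K - 1)
    lams = x if kind == "linear" else x ** float(exponent)
    if kind not in ("linear", "power"):
        raise ValueError(f"unknown schedule kind {kind!r}")
    return LambdaPath(lambdas=lams, segment=segment)


def mixed_energy(
    initial: EnergyModel,
    final: EnergyModel,
    lam: float,
    coords: np.ndarray,
    box: np.ndarray,
    mixing: tuple = ("linear",),
):
    """H(λ) = f(λ)·H_initial + g(λ)·H_final and its analytic λ-derivative.

    Returns ``(energy, dH_dlam)`` in k_BT.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    path = LambdaPath(lambdas=np.array([0.0, 1.0]), mixing=mixing)
    e_i, _ = initial.evaluate(coords, box)
    e_f, _ = final.evaluate(coords, box)
    f = float(path.f(lam))
    fp = float(path.fprime(lam))
    return f * e_i + (1.0 - f) * e_f, fp * e_i - fp * e_f


def state_scalings(path: LambdaPath, roles: dict) -> list[dict]:
    """Per-state term scalings from a mixing rule and term roles.

    ``roles`` maps term name → one of ``"off"`` (scaled by f, present in
    the initial state), ``"on"`` (scaled by g, grown in), ``"const"``
    (unscaled), or ``"softcore_off"`` (soft-core coupling λ_sc = f(λ):
    fully coupled at the start of the segment, off at the end).
    """
    out = []
    for lam in path.lambdas:
        f = float(path.f(lam))
        g = 1.0 - f
        sc = {}
        for name, role in roles.items():
            if role == "off":
                sc[name] = f
            elif role == "on":
                sc[name] = g
            elif role == "const":
                sc[name] = 1.0
            elif role == "softcore_off":
                sc[name] = f
            else:
                raise ValueError(f"unknown role {role!r} for term {name!r}")
        out.append(sc)
    return out


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """Independent per-state integer seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(int(master_seed))
    return (ss.generate_state(n) % np.uint32(2**31 - 1)).astype(np.int64)


@dataclass
class StateSamples:
    """Configurations sampled from one alchemical state plus sampler metadata."""

    configs: np.ndarray  # (M, n_atoms, 3)
    scalings: dict
    seed: int
    n_sweeps: int
    acceptance: float | None = None
    step: float | None = None
    mode: str = "metropolis"

    @property
    def n(self) -> int:
        return self.configs.shape[0]


@dataclass
class SampleSet:
    """Per-state configuration archives for a λ path."""

    states: list = field(default_factory=list)
    lambdas: np.ndarray | None = None

    @property
    def K(self) -> int:
        return len(self.states)

    @property
    def n_k(self) -> np.ndarray:
        return np.array([s.n for s in self.states], dtype=int)


def _kernel_args(crystal: CrystalSpec, model: EnergyModel, scalings: dict) -> dict:
    n = crystal.n_atoms
    args = dict(
        box=crystal.box.astype(float),
        mol_id=crystal.molecule_ids.astype(np.int64),
        movable=np.array([i for i in range(n) if i != crystal.fixed_atom], dtype=np.int64),
        restr_ref=np.zeros((n, 3)),
        restr_k=np.zeros(n),
        lj_eps=0.0,
        lj_sigma=1.0,
        lj_cutoff=0.0,
        sc_idx=-1,
        sc_lam=1.0,
        sc_alpha=0.5,
        sc_eps=0.0,
        sc_sigma=1.0,
        sc_cutoff=0.0,
        bond_i=np.zeros(0, dtype=np.int64),
        bond_j=np.zeros(0, dtype=np.int64),
        bond_k=np.zeros(0),
        bond_r0=np.zeros(0),
    )
    for name, term in model.terms.items():
        c = float(scalings.get(name, 1.0))
        if name == "site_restraint":
            args["restr_ref"] = term.reference.astype(float)
            args["restr_k"] = term.k * c
        elif name == "lj_pair":
            args["lj_eps"] = term.epsilon * c
            args["lj_sigma"] = term.sigma
            args["lj_cutoff"] = term.cutoff
        elif name == "harmonic_bond":
            args["bond_i"] = term.i.astype(np.int64)
            args["bond_j"] = term.j.astype(np.int64)
            args["bond_k"] = term.k * c
            args["bond_r0"] = term.r0
        elif name == "softcore":
            args["sc_idx"] = int(term.solute_index)
            args["sc_lam"] = c
            args["sc_alpha"] = term.alpha
            args["sc_eps"] = term.epsilon
            args["sc_sigma"] = term.sigma
            args["sc_cutoff"] = term.cutoff
        else:  # pragma: no cover - defensive
            raise ValueError(f"term {name!r} not supported by the MC kernel")
    return args


def sample_state(
    crystal: CrystalSpec,
    model: EnergyModel,
    scalings: dict,
    n_sweeps: int,
    seed: int,
    mode: str = "metropolis",
    step: float = 0.3,
    sample_every: int = 1,
    equil_fraction: float = 0.1,
    start: np.ndarray | None = None,
    dt: float = 0.01,
    gamma: float = 5.0,
) -> StateSamples:
    """Draw configurations from ∝ exp(−H(λ)) at one alchemical state.

    The first ``equil_fraction`` of sweeps is discarded as equilibration
    (during which the Metropolis step is tuned).  The fixed atom never
    moves.  Runs are reproducible given the seed.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    coords0 = (crystal.coords if start is None else np.asarray(start, dtype=float)).copy()
    n_equil = int(equil_fraction * n_sweeps)
    if mode == "metropolis":
        args = _kernel_args(crystal, model, scalings)
        configs, acc, step_out = metropolis_chain(
            coords0,
            args["box"],
            args["mol_id"],
            args["movable"],
            args["restr_ref"],
            args["restr_k"],
            args["lj_eps"],
            args["lj_sigma"],
            args["lj_cutoff"],
            args["sc_idx"],
            args["sc_lam"],
            args["sc_alpha"],
            args["sc_eps"],
            args["sc_sigma"],
            args["sc_cutoff"],
            args["bond_i"],
            args["bond_j"],
            args["bond_k"],
            args["bond_r0"],
            int(n_sweeps),
            n_equil,
            int(sample_every),
            float(step),
            int(seed),
        )
        if acc == 0.0 and configs.shape[0] > 0:
            warnings.warn("zero Metropolis acceptance: pathological state", stacklevel=2)
        return StateSamples(
            configs=configs, scalings=dict(scalings), seed=int(seed),
            n_sweeps=int(n_sweeps), acceptance=float(acc), step=float(step_out),
        )
    if mode == "langevin":
        configs = _baoab_chain(
            crystal, model, scalings, coords0, n_sweeps, n_equil, sample_every, dt, gamma, seed
        )
        return StateSamples(
            configs=configs, scalings=dict(scalings), seed=int(seed),
            n_sweeps=int(n_sweeps), mode="langevin",
        )
    raise ValueError(f"unknown sampler mode {mode!r}")


def _baoab_chain(crystal, model, scalings, coords0, n_steps, n_equil, sample_every, dt, gamma, seed):
    """BAOAB Langevin discretization with unit masses; fixed atom pinned."""
    rng = np.random.default_rng(seed)
    x = coords0.copy()
    v = rng.normal(size=x.shape)  # unit mass, k_BT = 1 → unit variance
    fixed = crystal.fixed_atom
    v[fixed] = 0.0
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    f = model.forces(x, crystal.box, scalings)
    out = []
    for step_i in range(n_steps):
        v += 0.5 * dt * f
        v[fixed] = 0.0
        x += 0.5 * dt * v
        x[fixed] = coords0[fixed]
        v = c1 * v + c2 * rng.normal(size=x.shape)
        v[fixed] = 0.0
        x += 0.5 * dt * v
        x[fixed] = coords0[fixed]
        f = model.forces(x, crystal.box, scalings)
        v += 0.5 * dt * f
        v[fixed] = 0.0
        if step_i >= n_equil and (step_i - n_equil) % sample_every == 0:
            out.append(x.copy())
    return np.array(out)


def sample_path(
    crystal: CrystalSpec,
    model: EnergyModel,
    states: list[dict],
    n_sweeps: int,
    master_seed: int,
    lambdas: np.ndarray | None = None,
    **kwargs,
) -> SampleSet:
    """Sample every state of a path with independent per-state seed streams."""
    seeds = derive_seeds(master_seed, len(states))
    out = SampleSet(lambdas=None if lambdas is None else np.asarray(lambdas, dtype=float))
    for sc, sd in zip(states, seeds):
        out.states.append(sample_state(crystal, model, sc, n_sweeps, int(sd), **kwargs))
    return out


# --------------------------------------------------------------------------
# cross-evaluation
# --------------------------------------------------------------------------


@dataclass
class ReducedPotentialMatrix:
    """Samples from every state re-evaluated in every state's reduced potential.

    ``u[k, l, n]`` is sample n from state k evaluated under state l's
    Hamiltonian, in k_BT.  ``n_k`` gives the per-state sample counts;
    entries beyond ``n_k[k]`` are padding (zero) and flagged invalid by
    :meth:`mask`.
    """

    u: np.ndarray  # (K, K, Nmax)
    n_k: np.ndarray  # (K,)
    lambdas: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.u.shape[0]

    def mask(self) -> np.ndarray:
        idx = np.arange(self.u.shape[2])
        return idx[None, :] < self.n_k[:, None]

    def u_kn(self) -> np.ndarray:
        """(K, Ntot) layout: all samples pooled, each row one evaluating state."""
        cols = [self.u[k, :, : self.n_k[k]] for k in range(self.K)]
        return np.concatenate(cols, axis=1)

    def forward_backward(self, k: int):
        """ΔU lists between neighbouring states k and k+1 (for EXP/BAR)."""
        fwd = self.u[k, k + 1, : self.n_k[k]] - self.u[k, k, : self.n_k[k]]
        bwd = self.u[k + 1, k, : self.n_k[k + 1]] - self.u[k + 1, k + 1, : self.n_k[k + 1]]
        return fwd, bwd

    def to_frame(self):
        import pandas as pd

        k_idx, l_idx, n_idx = np.nonzero(self.mask()[:, None, :] & np.ones((1, self.K, 1), bool))
        return pd.DataFrame(
            {"k": k_idx, "l": l_idx, "n": n_idx, "u": self.u[k_idx, l_idx, n_idx]}
        )

    def save(self, csv_path, json_path=None) -> None:
        import json as _json

        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            meta = {
                "n_k": self.n_k.tolist(),
                "lambdas": None if self.lambdas is None else self.lambdas.tolist(),
            }
            with open(json_path, "w") as fh:
                _json.dump(meta, fh)

    @classmethod
    def load(cls, csv_path, json_path) -> "ReducedPotentialMatrix":
        import json as _json

        import pandas as pd

        df = pd.read_csv(csv_path)
        with open(json_path) as fh:
            meta = _json.load(fh)
        n_k = np.asarray(meta["n_k"], dtype=int)
        K = n_k.size
        u = np.zeros((K, K, int(n_k.max())))
        u[df["k"].to_numpy(), df["l"].to_numpy(), df["n"].to_numpy()] = df["u"].to_numpy()
        lams = meta.get("lambdas")
        return cls(u=u, n_k=n_k, lambdas=None if lams is None else np.asarray(lams))


def _batch_term_energies(model: EnergyModel, box: np.ndarray, configs: np.ndarray, chunk: int = 256) -> dict:
    """Unscaled per-term energies for a batch of configurations (vectorized)."""
    out = {}
    M = configs.shape[0]
    for name, term in model.terms.items():
        if getattr(term, "nonlinear", False):
            continue
        vals = np.empty(M)
        if name == "site_restraint":
            dr = configs - term.reference[None, :, :]
            vals = 0.5 * np.einsum("a,ma->m", term.k, np.sum(dr * dr, axis=2))
        elif name == "lj_pair":
            term._check_box(box)
            i, j = term._pair_mask(configs.shape[1])
            for lo in range(0, M, chunk):
                sub = configs[lo : lo + chunk]
                dr = minimum_image(sub[:, i, :] - sub[:, j, :], box)
                r2 = np.sum(dr * dr, axis=2)
                inside = r2 < term.cutoff**2
                sr6 = np.where(inside, (term.sigma**2 / np.where(inside, r2, 1.0)) ** 3, 0.0)
                vals[lo : lo + chunk] = np.sum(4.0 * term.epsilon * (sr6 * sr6 - sr6), axis=1)
        elif name == "harmonic_bond":
            if term.i.size == 0:
                vals[:] = 0.0
            else:
                dr = minimum_image(configs[:, term.i, :] - configs[:, term.j, :], box)
                r = np.sqrt(np.sum(dr * dr, axis=2))
                vals = np.sum(0.5 * term.k * (r - term.r0) ** 2, axis=1)
        out[name] = vals
    return out


def _batch_softcore(term, box: np.ndarray, configs: np.ndarray, lam: float) -> np.ndarray:
    if lam == 0.0:
        return np.zeros(configs.shape[0])
    s = term.solute_index
    others = np.delete(np.arange(configs.shape[1]), s)
    dr = minimum_image(configs[:, others, :] - configs[:, s : s + 1, :], box)
    r2 = np.sum(dr * dr, axis=2)
    inside = r2 < term.cutoff**2
    s6 = np.where(inside, (np.where(inside, r2, 1.0) / term.sigma**2) ** 3, np.inf)
    denom = term.alpha * (1.0 - lam) ** 2 + s6
    e = 4.0 * term.epsilon * lam * (denom**-2 - denom**-1)
    return np.sum(np.where(inside, e, 0.0), axis=1)


def cross_evaluate(
    samples: SampleSet,
    states: list[dict],
    crystal: CrystalSpec,
    model: EnergyModel,
) -> ReducedPotentialMatrix:
    """Evaluate every sample from every state under every state's Hamiltonian.

    Per-term energies are computed once per sample; linear terms are then
    combined with each state's coefficients, and the soft-core term (the
    one non-linear form) is re-evaluated per distinct coupling value.
    """
    if samples.K != len(states):
        raise ValueError("sample set and state list sizes differ")
    if any(s.n < 1 for s in samples.states):
        raise ValueError("every state must contribute at least one sample")
    K = len(states)
    n_k = samples.n_k
    nmax = int(n_k.max())
    u = np.zeros((K, K, nmax))
    sc_term = model.terms.get("softcore")
    for k, st in enumerate(samples.states):
        terms = _batch_term_energies(model, crystal.box, st.configs)
        sc_cache: dict[float, np.ndarray] = {}
        for l, scal in enumerate(states):
            tot = np.zeros(st.n)
            for name, vals in terms.items():
                tot = tot + float(scal.get(name, 1.0)) * vals
            if sc_term is not None:
                lam = float(scal.get("softcore", 1.0))
                if lam not in sc_cache:
                    sc_cache[lam] = _batch_softcore(sc_term, crystal.box, st.configs, lam)
                tot = tot + sc_cache[lam]
            u[k, l, : st.n] = tot
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite reduced potentials encountered")
    return ReducedPotentialMatrix(u=u, n_k=n_k, lambdas=samples.lambdas)


# --------------------------------------------------------------------------
# decorrelation
# --------------------------------------------------------------------------


def statistical_inefficiency(series: np.ndarray) -> float:
    """Statistical inefficiency g = 1 + 2·Σ C(t) from the autocorrelation.

    The sum is truncated where the normalized autocorrelation first drops
    below zero.  A constant series has no information: g is defined as the
    series length (one effective sample) and a warning is emitted.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("series must have length >= 2")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var <= 0 or not np.isfinite(var):
        warnings.warn("constant series: one effective sample", stacklevel=2)
        return float(n)
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, m)
    acov = np.fft.irfft(fx * np.conj(fx), m)[:n].real / n
    c = acov / var
    g = 1.0
    for t in range(1, n):
        if c[t] <= 0:
            break
        g += 2.0 * c[t] * (1.0 - t / n)
    return max(g, 1.0)


def subsample_decorrelated(series: np.ndarray):
    """Indices of approximately independent samples plus the inefficiency g."""
    g = statistical_inefficiency(series)
    stride = int(np.ceil(g))
    idx = np.arange(0, np.asarray(series).size, stride)
    return idx, g
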