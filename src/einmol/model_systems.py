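"""Toy crystals, molecule topologies and per-term energy models.

Everything downstream (alchemical sampling, free-energy estimation, the
Einstein-molecule reference) works on the objects defined here:

* :class:`UnitSystem` — energies are carried in units of k_BT (β ≡ 1); the
  absolute temperature only enters through the de Broglie wavelength and
  unit conversions.
* :class:`MoleculeTopology` — atoms, masses, harmonic bonds and the proper
  rotation symmetry number Σ_rot.
* :class:`CrystalSpec` — an orthorhombic periodic lattice of molecule
  copies with per-atom reference coordinates and exactly one fixed atom,
  the anchor of the Einstein-molecule construction.
* :class:`EnergyModel` — an ordered collection of named energy terms
  (harmonic site restraints, truncated Lennard-Jones pairs, harmonic
  bonds, a soft-core coupled solute) that can be evaluated per term so
  that alchemical mixing and TI derivatives are exact.

All boxes are orthorhombic and pair interactions use the minimum-image
convention; pair cutoffs must not exceed half the shortest box edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _const

__all__ = [
    "UnitSystem",
    "MoleculeTopology",
    "CrystalSpec",
    "EnergyModel",
    "SiteRestraint",
    "LennardJones",
    "HarmonicBonds",
    "SoftcoreLJ",
    "build_fcc_crystal",
    "build_toy_molecular_crystal",
    "evaluate_energy",
    "minimum_image",
    "diatomic_topology",
    "bent_triatomic_topology",
    "argon_topology",
]

#: default harmonic restraint force constant, k_BT / Å^2
DEFAULT_RESTRAINT_K = 4000.0


@dataclass(frozen=True)
class UnitSystem:
    """Unit conventions: energies in k_BT (β ≡ 1), lengths in Å.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin.  Only used where an absolute
        scale is required (de Broglie wavelength, pressure-volume work).
    pressure : float, optional
        Pressure in kPa, when the problem supplies one.
    """

    temperature: float = 298.15
    pressure: float | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def beta(self) -> float:
        """Inverse thermal energy in internal units (identically 1)."""
        return 1.0

    @property
    def kBT_joule(self) -> float:
        """Thermal energy k_B·T in joules."""
        return _const.k * self.temperature

    def joule_to_kBT(self, energy_j: float) -> float:
        return energy_j / self.kBT_joule

    def kBT_to_joule(self, energy_kbt: float) -> float:
        return energy_kbt * self.kBT_joule

    def kBT_to_kJ_per_mol(self, energy_kbt: float) -> float:
        return energy_kbt * self.kBT_joule * _const.Avogadro / 1000.0


def minimum_image(dr: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the primary image of an orthorhombic box."""
    return dr - box * np.round(dr / box)


@dataclass(frozen=True)
class MoleculeTopology:
    """A rigid-reference toy molecule: atoms, masses, bonds, symmetry.

    ``bonds`` is a sequence of ``(i, j, k_bond, r0)`` tuples with the
    harmonic constant in k_BT/Å² and the rest length in Å.
    ``reference_geometry`` carries the internal coordinates (Å) used when
    the molecule is replicated onto a lattice; by default atoms are laid
    out as a chain along x at the bond rest lengths.
    """

    labels: tuple[str, ...]
    masses: tuple[float, ...]
    bonds: tuple[tuple[int, int, float, float], ...] = ()
    sigma_rot: int = 1
    linear: bool = False
    reference_geometry: tuple[tuple[float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n != len(self.masses):
            raise ValueError("labels and masses must have equal length")
        if any(m <= 0 for m in self.masses):
            raise ValueError("atomic masses must be positive")
        if int(self.sigma_rot) != self.sigma_rot or self.sigma_rot < 1:
            raise ValueError("sigma_rot must be an integer >= 1")
        for i, j, kb, _r0 in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"bond ({i},{j}) references invalid atoms")
            if kb < 0:
                raise ValueError("bond force constants must be non-negative")
        if self.reference_geometry is not None and len(self.reference_geometry) != n:
            raise ValueError("reference_geometry must have one row per atom")

    @property
    def n_atoms(self) -> int:
        return len(self.labels)

    @property
    def total_mass(self) -> float:
        """Molecular mass in unified atomic mass units."""
        return float(sum(self.masses))

    def geometry(self) -> np.ndarray:
        """Internal reference coordinates (n_atoms, 3) in Å."""
        if self.reference_geometry is not None:
            return np.asarray(self.reference_geometry, dtype=float)
        # default: chain along x at bond rest lengths
        coords = np.zeros((self.n_atoms, 3))
        x = 0.0
        rest: dict[tuple[int, int], float] = {}
        for i, j, _kb, r0 in self.bonds:
            rest[(min(i, j), max(i, j))] = r0
        for a in range(1, self.n_atoms):
            x += rest.get((a - 1, a), 1.0)
            coords[a, 0] = x
        return coords

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "masses": list(self.masses),
            "bonds": [list(b) for b in self.bonds],
            "sigma_rot": int(self.sigma_rot),
            "linear": bool(self.linear),
            "reference_geometry": None
            if self.reference_geometry is None
            else [list(r) for r in self.reference_geometry],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MoleculeTopology":
        return cls(
            labels=tuple(d["labels"]),
            masses=tuple(d["masses"]),
            bonds=tuple(tuple(b) for b in d.get("bonds", ())),
            sigma_rot=int(d.get("sigma_rot", 1)),
            linear=bool(d.get("linear", False)),
            reference_geometry=None
            if d.get("reference_geometry") is None
            else tuple(tuple(r) for r in d["reference_geometry"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "MoleculeTopology":
        return cls.from_dict(json.loads(s))


def argon_topology() -> MoleculeTopology:
    """A single argon atom (the simplest 'molecule')."""
    return MoleculeTopology(labels=("Ar",), masses=(39.948,), sigma_rot=1)


def diatomic_topology(
    r0: float = 1.2, k_bond: float = 500.0, mass: float = 16.0, sigma_rot: int = 2
) -> MoleculeTopology:
    """A homonuclear harmonic diatomic (Σ_rot = 2 by default)."""
    return MoleculeTopology(
        labels=("X", "X"),
        masses=(mass, mass),
        bonds=((0, 1, k_bond, r0),),
        sigma_rot=sigma_rot,
        linear=True,
        reference_geometry=((0.0, 0.0, 0.0), (r0, 0.0, 0.0)),
    )


def bent_triatomic_topology(
    r0: float = 1.0, angle_deg: float = 104.5, k_bond: float = 500.0
) -> MoleculeTopology:
    """A bent 3-site molecule (water-like shape, Σ_rot = 2)."""
    half = np.deg2rad(angle_deg) / 2.0
    geo = (
        (0.0, 0.0, 0.0),
        (r0 * np.sin(half), r0 * np.cos(half), 0.0),
        (-r0 * np.sin(half), r0 * np.cos(half), 0.0),
    )
    return MoleculeTopology(
        labels=("O", "H", "H"),
        masses=(16.0, 1.008, 1.008),
        bonds=((0, 1, k_bond, r0), (0, 2, k_bond, r0)),
        sigma_rot=2,
        linear=False,
        reference_geometry=geo,
    )


@dataclass(frozen=True)
class CrystalSpec:
    """A periodic toy crystal: box, lattice reference coordinates, one fixed atom.

    Attributes
    ----------
    box : ndarray (3,)
        Orthorhombic box edges in Å.
    coords : ndarray (n_atoms, 3)
        Per-atom lattice reference coordinates in Å (inside the box).
    topology : MoleculeTopology
        Topology of the repeating molecule.
    fixed_atom : int
        Index of the single atom held fixed in space (the EMM anchor).
    """

    box: np.ndarray
    coords: np.ndarray
    topology: MoleculeTopology
    fixed_atom: int = 0

    def __post_init__(self) -> None:
        box = np.asarray(self.box, dtype=float)
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "box", box)
        object.__setattr__(self, "coords", coords)
        if box.shape != (3,) or np.any(box <= 0):
            raise ValueError("box must be three positive edge lengths")
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if coords.shape[0] % self.topology.n_atoms != 0:
            raise ValueError("atom count is not a multiple of the topology size")
        if not (0 <= self.fixed_atom < coords.shape[0]):
            raise ValueError("fixed_atom out of range")
        if np.any(coords < -1e-9) or np.any(coords > box + 1e-9):
            raise ValueError("reference coordinates must lie inside the box")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.n_atoms // self.topology.n_atoms

    @property
    def volume(self) -> float:
        """Box volume in Å³."""
        return float(np.prod(self.box))

    @property
    def molecule_ids(self) -> np.ndarray:
        """Molecule index of each atom (LJ pairs within a molecule are excluded)."""
        return np.repeat(np.arange(self.n_molecules), self.topology.n_atoms)

    def to_dict(self) -> dict:
        return {
            "box": self.box.tolist(),
            "coords": self.coords.tolist(),
            "topology": self.topology.to_dict(),
            "fixed_atom": int(self.fixed_atom),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrystalSpec":
        return cls(
            box=np.asarray(d["box"], dtype=float),
            coords=np.asarray(d["coords"], dtype=float),
            topology=MoleculeTopology.from_dict(d["topology"]),
            fixed_atom=int(d["fixed_atom"]),
        )


# --------------------------------------------------------------------------
# energy terms
# --------------------------------------------------------------------------


class SiteRestraint:
    """Isotropic harmonic restraints tying atoms to lattice reference sites.

    U = Σ_a (k_a/2)·|r_a − r_a⁰|²  summed over non-fixed atoms.  The fixed
    atom carries no restraint (k = 0): it never moves, so a restraint on it
    would contribute exactly zero anyway, and keeping k = 0 makes the
    Einstein-molecule bookkeeping explicit.  Restraints are absolute in
    space (no minimum-image wrapping).
    """

    name = "site_restraint"

    def __init__(self, k: float | np.ndarray, reference: np.ndarray, fixed_atom: int | None = None):
        reference = np.asarray(reference, dtype=float)
        k_arr = np.broadcast_to(np.asarray(k, dtype=float), (reference.shape[0],)).copy()
        if np.any(k_arr < 0):
            raise ValueError("restraint constants must be non-negative")
        if fixed_atom is not None:
            k_arr[fixed_atom] = 0.0
        self.k = k_arr
        self.reference = reference
        self.fixed_atom = fixed_atom

    def energy(self, coords: np.ndarray, box: np.ndarray) -> float:
        dr = coords - self.reference
        return float(0.5 * np.sum(self.k * np.sum(dr * dr, axis=1)))

    def forces(self, coords: np.ndarray, box: np.ndarray) -> np.ndarray:
        return -self.k[:, None] * (coords - self.reference)


class LennardJones:
    """Truncated (unshifted) 12-6 Lennard-Jones between atoms of different molecules."""

    name = "lj_pair"

    def __init__(
        self,
        epsilon: float,
        sigma: float,
        cutoff: float,
        molecule_ids: np.ndarray | None = None,
        exclude_atoms: tuple[int, ...] = (),
    ):
        if sigma <= 0 or cutoff <= 0:
            raise ValueError("sigma and cutoff must be positive")
        self.epsilon = float(epsilon)
        self.sigma = float(sigma)
        self.cutoff = float(cutoff)
        self.molecule_ids = None if molecule_ids is None else np.asarray(molecule_ids)
        self.exclude_atoms = tuple(int(a) for a in exclude_atoms)

    def _check_box(self, box: np.ndarray) -> None:
        if self.cutoff > min(box) / 2 + 1e-9:
            raise ValueError("LJ cutoff exceeds half the shortest box edge")

    def _pair_mask(self, n: int) -> np.ndarray:
        iu = np.triu_indices(n, k=1)
        if self.molecule_ids is None:
            keep = np.ones(iu[0].shape[0], dtype=bool)
        else:
            keep = self.molecule_ids[iu[0]] != self.molecule_ids[iu[1]]
        for a in self.exclude_atoms:
            keep &= (iu[0] != a) & (iu[1] != a)
        return iu[0][keep], iu[1][keep]

    def energy(self, coords: np.ndarray, box: np.ndarray) -> float:
        self._check_box(box)
        i, j = self._pair_mask(coords.shape[0])
        dr = minimum_image(coords[i] - coords[j], box)
        r2 = np.sum(dr * dr, axis=1)
        inside = r2 < self.cutoff**2
        sr6 = (self.sigma**2 / r2[inside]) ** 3
        return float(np.sum(4.0 * self.epsilon * (sr6 * sr6 - sr6)))

    def forces(self, coords: np.ndarray, box: np.ndarray) -> np.ndarray:
        self._check_box(box)
        i, j = self._pair_mask(coords.shape[0])
        dr = minimum_image(coords[i] - coords[j], box)
        r2 = np.sum(dr * dr, axis=1)
        f = np.zeros_like(coords)
        inside = r2 < self.cutoff**2
        i, j, dr, r2 = i[inside], j[inside], dr[inside], r2[inside]
        sr6 = (self.sigma**2 / r2) ** 3
        # dU/dr² · 2 = magnitude along dr / r
        fmag = 24.0 * self.epsilon * (2.0 * sr6 * sr6 - sr6) / r2
        fv = fmag[:, None] * dr
        np.add.at(f, i, fv)
        np.add.at(f, j, -fv)
        return f


class HarmonicBonds:
    """Intramolecular harmonic bonds U = Σ_b (k_b/2)(r_b − r0_b)²."""

    name = "harmonic_bond"

    def __init__(self, bonds_i: np.ndarray, bonds_j: np.ndarray, k: np.ndarray, r0: np.ndarray):
        self.i = np.asarray(bonds_i, dtype=int)
        self.j = np.asarray(bonds_j, dtype=int)
        self.k = np.asarray(k, dtype=float)
        self.r0 = np.asarray(r0, dtype=float)

    @classmethod
    def from_crystal(cls, crystal: CrystalSpec) -> "HarmonicBonds":
        top = crystal.topology
        i, j, k, r0 = [], [], [], []
        for mol in range(crystal.n_molecules):
            off = mol * top.n_atoms
            for bi, bj, bk, br0 in top.bonds:
                i.append(off + bi)
                j.append(off + bj)
                k.append(bk)
                r0.append(br0)
        return cls(np.array(i, dtype=int), np.array(j, dtype=int), np.array(k), np.array(r0))

    def energy(self, coords: np.ndarray, box: np.ndarray) -> float:
        if self.i.size == 0:
            return 0.0
        dr = minimum_image(coords[self.i] - coords[self.j], box)
        r = np.sqrt(np.sum(dr * dr, axis=1))
        return float(np.sum(0.5 * self.k * (r - self.r0) ** 2))

    def forces(self, coords: np.ndarray, box: np.ndarray) -> np.ndarray:
        f = np.zeros_like(coords)
        if self.i.size == 0:
            return f
        dr = minimum_image(coords[self.i] - coords[self.j], box)
        r = np.sqrt(np.sum(dr * dr, axis=1))
        fmag = -self.k * (r - self.r0) / r
        fv = fmag[:, None] * dr
        np.add.at(f, self.i, fv)
        np.add.at(f, self.j, -fv)
        return f


class SoftcoreLJ:
    """Beutler-form soft-core Lennard-Jones coupling a designated solute.

    U(λ) = 4ελ·[ (α(1−λ)² + (r/σ)⁶)⁻² − (α(1−λ)² + (r/σ)⁶)⁻¹ ] with α = 0.5.

    λ = 1 recovers the plain LJ interaction; λ = 0 switches the solute off
    entirely; the energy stays finite at r → 0 for any λ < 1, which is what
    makes decoupling paths numerically tame.  The λ value is supplied as the
    term's scaling coefficient and is *not* a linear prefactor.
    """

    name = "softcore"
    nonlinear = True

    def __init__(self, epsilon: float, sigma: float, cutoff: float, solute_index: int, alpha: float = 0.5):
        if sigma <= 0 or cutoff <= 0:
            raise ValueError("sigma and cutoff must be positive")
        self.epsilon = float(epsilon)
        self.sigma = float(sigma)
        self.cutoff = float(cutoff)
        self.solute_index = int(solute_index)
        self.alpha = float(alpha)

    def pair_energy(self, r: np.ndarray | float, lam: float) -> np.ndarray | float:
        r = np.asarray(r, dtype=float)
        if np.any(r <= 0):
            raise ValueError("pair distance must be positive")
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        s6 = (r / self.sigma) ** 6
        denom = self.alpha * (1.0 - lam) ** 2 + s6
        out = 4.0 * self.epsilon * lam * (denom**-2 - denom**-1)
        return out if out.shape else float(out)

    def energy(self, coords: np.ndarray, box: np.ndarray, lam: float = 1.0) -> float:
        if self.cutoff > min(box) / 2 + 1e-9:
            raise ValueError("soft-core cutoff exceeds half the shortest box edge")
        if lam == 0.0:
            return 0.0
        s = self.solute_index
        others = np.delete(np.arange(coords.shape[0]), s)
        dr = minimum_image(coords[others] - coords[s], box)
        r = np.sqrt(np.sum(dr * dr, axis=1))
        r = r[r < self.cutoff]
        return float(np.sum(self.pair_energy(r, lam))) if r.size else 0.0


def softcore_pair_energy(epsilon: float, sigma: float, r: float, lam: float, alpha: float = 0.5) -> float:
    """Beutler soft-core pair energy for a single distance (k_BT)."""
    term = SoftcoreLJ(epsilon, sigma, cutoff=np.inf, solute_index=0, alpha=alpha)
    return float(term.pair_energy(r, lam))


@dataclass
class EnergyModel:
    """An ordered set of named energy terms with external per-term scalings.

    ``evaluate(coords, box, scalings)`` returns the coefficient-weighted
    total together with the *unscaled* per-term energies — exactly what
    linear λ-mixing and TI derivatives need.  The soft-core term is the
    one non-linear exception: its scaling coefficient is interpreted as
    the coupling λ of the Beutler potential.
    """

    terms: dict = field(default_factory=dict)

    def add(self, term) -> "EnergyModel":
        if term.name in self.terms:
            raise ValueError(f"duplicate term {term.name!r}")
        self.terms[term.name] = term
        return self

    def term_energies(self, coords: np.ndarray, box: np.ndarray, scalings: dict | None = None) -> dict:
        """Unscaled per-term energies; the soft-core term is evaluated at its λ."""
        scalings = scalings or {}
        out = {}
        for name, term in self.terms.items():
            if getattr(term, "nonlinear", False):
                out[name] = term.energy(coords, box, lam=float(scalings.get(name, 1.0)))
            else:
                out[name] = term.energy(coords, box)
        return out

    def evaluate(self, coords: np.ndarray, box: np.ndarray, scalings: dict | None = None):
        """Total scaled energy (k_BT) and the per-term breakdown.

        Returns ``(total, breakdown)`` where ``breakdown[name]`` is the
        unscaled term energy and ``total = Σ coeff·E_term`` (soft-core
        included at its λ with unit coefficient).
        """
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("configuration must be (n_atoms, 3)")
        if np.any(~np.isfinite(coords)):
            raise ValueError("configuration contains non-finite coordinates")
        scalings = scalings or {}
        for name, c in scalings.items():
            if name not in self.terms:
                raise KeyError(f"unknown term {name!r}")
            term = self.terms[name]
            if not getattr(term, "nonlinear", False) and not (0.0 <= c <= 1.0):
                raise ValueError(f"scaling for {name!r} must lie in [0, 1]")
        breakdown = self.term_energies(coords, box, scalings)
        total = 0.0
        for name, e in breakdown.items():
            if getattr(self.terms[name], "nonlinear", False):
                total += e  # λ already applied inside the soft-core form
            else:
                total += float(scalings.get(name, 1.0)) * e
        return total, breakdown

    def forces(self, coords: np.ndarray, box: np.ndarray, scalings: dict | None = None) -> np.ndarray:
        scalings = scalings or {}
        f = np.zeros_like(coords, dtype=float)
        for name, term in self.terms.items():
            if getattr(term, "nonlinear", False):
                raise NotImplementedError("analytic forces not provided for soft-core terms")
            f += float(scalings.get(name, 1.0)) * term.forces(coords, box)
        return f


def evaluate_energy(model: EnergyModel, crystal: CrystalSpec, coords: np.ndarray, scalings: dict | None = None):
    """Evaluate a model on a configuration of the given crystal.

    Returns ``(total, breakdown)`` in k_BT.  Raises on dimension mismatch
    or non-finite coordinates.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != crystal.coords.shape:
        raise ValueError(
            f"configuration shape {coords.shape} does not match crystal {crystal.coords.shape}"
        )
    return model.evaluate(coords, crystal.box, scalings)


# --------------------------------------------------------------------------
# crystal builders
# --------------------------------------------------------------------------


def build_fcc_crystal(
    n_cells_per_edge: int,
    lattice_constant: float,
    fixed_atom: int = 0,
    topology: MoleculeTopology | None = None,
) -> CrystalSpec:
    """A face-centred-cubic atomic crystal of 4·n³ sites in a cubic box.

    Parameters
    ----------
    n_cells_per_edge : int
        Number of conventional unit cells along each edge (n ≥ 1).
    lattice_constant : float
        Conventional cell edge a in Å; the box edge is n·a.
    fixed_atom : int
        Site flagged as the fixed Einstein-molecule anchor.
    """
    n = int(n_cells_per_edge)
    if n < 1:
        raise ValueError("n_cells_per_edge must be >= 1")
    a = float(lattice_constant)
    if a <= 0:
        raise ValueError("lattice_constant must be positive")
    basis = np.array(
        [[0.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]
    )
    cells = np.array([[i, j, k] for i in range(n) for j in range(n) for k in range(n)], dtype=float)
    coords = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3) * a
    box = np.array([n * a] * 3)
    top = topology if topology is not None else argon_topology()
    if top.n_atoms != 1:
        raise ValueError("fcc builder places single-atom topologies only")
    return CrystalSpec(box=box, coords=coords, topology=top, fixed_atom=fixed_atom)


def build_toy_molecular_crystal(
    topology: MoleculeTopology,
    n_cells: int | tuple[int, int, int],
    spacing: float = 5.0,
    fixed_atom: int = 0,
) -> CrystalSpec:
    """A simple-cubic crystal of rigid-reference molecule copies.

    One molecule per cell, all in the topology's reference orientation,
    anchored on a cubic lattice with the given spacing (Å).  Rejects
    packings that bring any two atoms closer than 0.5 Å.
    """
    if isinstance(n_cells, int):
        n_cells = (n_cells, n_cells, n_cells)
    nx, ny, nz = (int(v) for v in n_cells)
    if min(nx, ny, nz) < 1:
        raise ValueError("cell counts must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    geo = topology.geometry()
    # centre the molecule inside its cell so every atom stays in the box
    offset = spacing / 2.0 - geo.mean(axis=0)
    cells = np.array(
        [[i, j, k] for i in range(nx) for j in range(ny) for k in range(nz)], dtype=float
    )
    coords = (cells[:, None, :] * spacing + geo[None, :, :] + offset).reshape(-1, 3)
    box = np.array([nx, ny, nz], dtype=float) * spacing
    # overlap check (minimum image)
    iu = np.triu_indices(coords.shape[0], k=1)
    dr = minimum_image(coords[iu[0]] - coords[iu[1]], box)
    dmin = np.sqrt(np.sum(dr * dr, axis=1)).min()
    if dmin < 0.5:
        raise ValueError(f"overlapping sites: minimum pair distance {dmin:.3f} Å < 0.5 Å")
    return CrystalSpec(box=box, coords=coords, topology=topology, fixed_atom=fixed_atom)
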