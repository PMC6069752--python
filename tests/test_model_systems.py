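"""Crystal builders, topologies and per-term energy evaluation."""

import numpy as np
import pytest

import einmol as em
from einmol.io import read_pdb, read_xyz, write_pdb, write_xyz
from einmol.model_systems import minimum_image


@pytest.mark.parametrize("n,expected", [(1, 4), (2, 32), (6, 864)])
def test_fcc_site_count(n, expected):
    c = em.build_fcc_crystal(n, 5.0)
    assert c.n_atoms == expected
    assert np.allclose(c.box, n * 5.0)


def test_fcc_nearest_neighbor_geometry():
    """Minimum-image distance between any pair of sites is at least a/√2."""
    a = 4.0
    c = em.build_fcc_crystal(2, a)
    iu = np.triu_indices(c.n_atoms, k=1)
    dr = minimum_image(c.coords[iu[0]] - c.coords[iu[1]], c.box)
    dmin = np.sqrt(np.sum(dr * dr, axis=1)).min()
    assert dmin == pytest.approx(a / np.sqrt(2), rel=1e-12)


def test_fcc_rejects_bad_inputs():
    with pytest.raises(ValueError):
        em.build_fcc_crystal(0, 5.0)
    with pytest.raises(ValueError):
        em.build_fcc_crystal(2, -1.0)


def test_molecular_crystal_counts_and_fixed_atom():
    top = em.diatomic_topology()
    c = em.build_toy_molecular_crystal(top, 2, spacing=5.0)
    assert c.n_molecules == 8
    assert c.n_atoms == 16
    assert 0 <= c.fixed_atom < c.n_atoms


def test_molecular_crystal_rejects_overlaps():
    top = em.diatomic_topology(r0=1.2)
    with pytest.raises(ValueError, match="overlap"):
        em.build_toy_molecular_crystal(top, 2, spacing=1.0)


def test_topology_serialization_roundtrip():
    top = em.diatomic_topology(sigma_rot=2)
    back = em.MoleculeTopology.from_json(top.to_json())
    assert back.sigma_rot == 2
    assert back == top


def test_bond_energy_zero_at_rest_length():
    top = em.bent_triatomic_topology()
    c = em.build_toy_molecular_crystal(top, 2, spacing=6.0)
    bonds = em.HarmonicBonds.from_crystal(c)
    assert bonds.energy(c.coords, c.box) == pytest.approx(0.0, abs=1e-12)


def test_restraint_zero_at_reference(small_fcc):
    model = em.EnergyModel().add(
        em.SiteRestraint(4000.0, small_fcc.coords, fixed_atom=0)
    )
    total, _ = em.evaluate_energy(model, small_fcc, small_fcc.coords)
    assert total == 0.0


def test_restraint_matches_direct_loop(small_fcc, rng):
    k = 7.5
    term = em.SiteRestraint(k, small_fcc.coords, fixed_atom=0)
    conf = small_fcc.coords + rng.normal(scale=0.3, size=small_fcc.coords.shape)
    expected = sum(
        0.5 * k * np.sum((conf[a] - small_fcc.coords[a]) ** 2)
        for a in range(small_fcc.n_atoms)
        if a != 0
    )
    assert term.energy(conf, small_fcc.box) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "r,expected", [(1.0, 0.0), (2.0 ** (1.0 / 6.0), -1.0)]
)
def test_lj_pair_reference_points(r, expected):
    lj = em.LennardJones(1.0, 1.0, 10.0)
    coords = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
    assert lj.energy(coords, np.array([50.0] * 3)) == pytest.approx(expected, abs=1e-12)


def test_lj_cutoff_must_fit_box():
    lj = em.LennardJones(1.0, 1.0, cutoff=30.0)
    with pytest.raises(ValueError, match="cutoff"):
        lj.energy(np.zeros((2, 3)), np.array([10.0] * 3))


def test_scaling_by_zero_removes_term(small_fcc, rng):
    model = (
        em.EnergyModel()
        .add(em.SiteRestraint(10.0, small_fcc.coords, fixed_atom=0))
        .add(em.LennardJones(1.0, 1.0, 2.0, molecule_ids=small_fcc.molecule_ids))
    )
    conf = small_fcc.coords + rng.normal(scale=0.2, size=small_fcc.coords.shape)
    total_full, br = em.evaluate_energy(model, small_fcc, conf)
    total_no_lj, _ = em.evaluate_energy(model, small_fcc, conf, {"lj_pair": 0.0})
    assert total_no_lj == pytest.approx(br["site_restraint"], rel=1e-12)
    assert total_full - total_no_lj == pytest.approx(br["lj_pair"], rel=1e-12)


def test_per_term_decomposition_sums_to_total(small_fcc, rng):
    model = (
        em.EnergyModel()
        .add(em.SiteRestraint(10.0, small_fcc.coords, fixed_atom=0))
        .add(em.LennardJones(0.5, 1.2, 2.4, molecule_ids=small_fcc.molecule_ids))
    )
    conf = small_fcc.coords + rng.normal(scale=0.2, size=small_fcc.coords.shape)
    scal = {"site_restraint": 0.7, "lj_pair": 0.3}
    total, br = em.evaluate_energy(model, small_fcc, conf, scal)
    recon = 0.7 * br["site_restraint"] + 0.3 * br["lj_pair"]
    assert total == pytest.approx(recon, abs=1e-12)


def test_periodic_translation_invariance_without_restraints(small_fcc, rng):
    lj = em.EnergyModel().add(
        em.LennardJones(1.0, 1.5, 2.4, molecule_ids=small_fcc.molecule_ids)
    )
    conf = small_fcc.coords + rng.normal(scale=0.1, size=small_fcc.coords.shape)
    e0, _ = lj.evaluate(conf, small_fcc.box)
    for shift in ([1, 0, 0], [0, 2, -1], [3, 3, 3]):
        e1, _ = lj.evaluate(conf + np.asarray(shift) * small_fcc.box, small_fcc.box)
        assert e1 == pytest.approx(e0, abs=1e-9)


def test_evaluate_energy_input_validation(small_fcc):
    model = em.EnergyModel().add(em.SiteRestraint(1.0, small_fcc.coords, fixed_atom=0))
    with pytest.raises(ValueError, match="shape"):
        em.evaluate_energy(model, small_fcc, np.zeros((3, 3)))
    bad = small_fcc.coords.copy()
    bad[1, 1] = np.nan
    with pytest.raises(ValueError, match="finite"):
        em.evaluate_energy(model, small_fcc, bad)
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        em.evaluate_energy(model, small_fcc, small_fcc.coords, {"site_restraint": 1.5})


def test_fixed_atom_carries_no_restraint(small_fcc):
    term = em.SiteRestraint(4000.0, small_fcc.coords, fixed_atom=2)
    assert term.k[2] == 0.0
    conf = small_fcc.coords.copy()
    conf[2] += 5.0  # displacing the fixed atom costs nothing
    assert term.energy(conf, small_fcc.box) == 0.0


def test_unit_system_roundtrip():
    u = em.UnitSystem(temperature=298.15)
    assert u.beta == 1.0
    assert u.joule_to_kBT(u.kBT_to_joule(3.2)) == pytest.approx(3.2, rel=1e-14)
    with pytest.raises(ValueError):
        em.UnitSystem(temperature=-1.0)


def test_xyz_roundtrip(tmp_path, small_fcc, rng):
    frames = small_fcc.coords[None] + rng.normal(scale=0.05, size=(3, 4, 3))
    path = tmp_path / "frames.xyz"
    labels = ["Ar"] * 4
    write_xyz(path, frames, labels, box=small_fcc.box)
    back, labels2, box2 = read_xyz(path)
    assert labels2 == labels
    np.testing.assert_allclose(back, frames, atol=1e-7)
    np.testing.assert_allclose(box2, small_fcc.box)


def test_pdb_roundtrip(tmp_path, small_fcc):
    path = tmp_path / "cry.pdb"
    write_pdb(path, small_fcc.coords, ["AR"] * 4, small_fcc.box)
    coords, labels, box = read_pdb(path)
    np.testing.assert_allclose(coords, small_fcc.coords, atol=2e-3)
    np.testing.assert_allclose(box, small_fcc.box, atol=1e-3)
    assert len(labels) == 4


def test_crystal_spec_serialization_roundtrip(small_fcc):
    back = em.CrystalSpec.from_dict(small_fcc.to_dict())
    np.testing.assert_allclose(back.coords, small_fcc.coords)
    assert back.fixed_atom == small_fcc.fixed_atom
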