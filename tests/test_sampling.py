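"""λ schedules, Hamiltonian mixing, samplers, cross-evaluation, decorrelation."""

import numpy as np
import pytest
from scipy import stats

import einmol as em
from einmol.sampling import (
    LambdaPath,
    make_schedule,
    statistical_inefficiency,
    subsample_decorrelated,
)


class TestSchedules:
    def test_linear_three_states(self):
        path = make_schedule("linear", 3)
        np.testing.assert_allclose(path.lambdas, [0.0, 0.5, 1.0])

    def test_power_four_spacing(self):
        path = make_schedule("power", 5, 4)
        np.testing.assert_allclose(
            path.lambdas, [0.0, 1 / 256, 16 / 256, 81 / 256, 1.0], atol=1e-15
        )

    def test_rejects_too_few_states(self):
        with pytest.raises(ValueError):
            make_schedule("linear", 1)

    def test_chunking_preserves_lambda_values(self):
        """Splitting a 600-state path into chunks of 100 keeps every λ."""
        path = make_schedule("power", 600, 4)
        chunks = path.chunk(100)
        rejoined = np.concatenate([chunks[0]] + [c[1:] for c in chunks[1:]])
        np.testing.assert_array_equal(rejoined, path.lambdas)
        assert all(len(c) <= 100 for c in chunks)

    def test_mixing_endpoint_invariants(self):
        for mixing in [("linear",), ("power", 4)]:
            path = LambdaPath(np.linspace(0, 1, 7), mixing=mixing)
            assert path.f(0.0) == 1.0 and path.g(0.0) == 0.0
            assert path.f(1.0) == 0.0 and path.g(1.0) == 1.0

    def test_requires_increasing_with_endpoints(self):
        with pytest.raises(ValueError):
            LambdaPath(np.array([0.0, 0.5, 0.5, 1.0]))
        with pytest.raises(ValueError):
            LambdaPath(np.array([0.1, 0.5, 1.0]))


class TestMixedEnergy:
    @pytest.fixture()
    def pair(self, small_fcc):
        init = em.EnergyModel().add(
            em.SiteRestraint(100.0, small_fcc.coords, fixed_atom=0)
        )
        fin = em.EnergyModel().add(
            em.LennardJones(1.0, 1.5, 2.4, molecule_ids=small_fcc.molecule_ids)
        )
        return init, fin, small_fcc

    def test_endpoints_recover_pure_hamiltonians(self, pair, rng):
        init, fin, cry = pair
        conf = cry.coords + rng.normal(scale=0.2, size=cry.coords.shape)
        e0, _ = em.mixed_energy(init, fin, 0.0, conf, cry.box)
        e1, _ = em.mixed_energy(init, fin, 1.0, conf, cry.box)
        assert e0 == pytest.approx(init.evaluate(conf, cry.box)[0], rel=1e-12)
        assert e1 == pytest.approx(fin.evaluate(conf, cry.box)[0], rel=1e-12)

    def test_identical_hamiltonians_have_zero_derivative(self, pair, rng):
        init, _, cry = pair
        conf = cry.coords + rng.normal(scale=0.2, size=cry.coords.shape)
        for lam in (0.0, 0.3, 0.8, 1.0):
            _, dh = em.mixed_energy(init, init, lam, conf, cry.box)
            assert dh == pytest.approx(0.0, abs=1e-10)

    def test_rejects_lambda_outside_unit_interval(self, pair):
        init, fin, cry = pair
        with pytest.raises(ValueError):
            em.mixed_energy(init, fin, 1.5, cry.coords, cry.box)


class TestSoftcore:
    def test_lambda_one_is_plain_lj(self):
        for r in (0.8, 1.0, 2.0 ** (1 / 6), 2.5):
            sr6 = (1.0 / r) ** 6
            assert em.softcore_pair_energy(1.0, 1.0, r, 1.0) == pytest.approx(
                4.0 * (sr6**2 - sr6), rel=1e-12
            )

    def test_lambda_zero_vanishes(self):
        for r in (0.1, 1.0, 3.0):
            assert em.softcore_pair_energy(1.0, 1.0, r, 0.0) == 0.0

    def test_finite_at_contact(self):
        # closed form at r → 0: denominator → α(1−λ)², here 0.5·0.25 = 0.125
        val = em.softcore_pair_energy(1.0, 1.0, 1e-12, 0.5)
        assert val == pytest.approx(4 * 0.5 * (0.125**-2 - 0.125**-1), rel=1e-6)


class TestSampler:
    def test_harmonic_variance_matches_equipartition(self, small_fcc):
        """k = 4 k_BT/Å² → per-coordinate variance 1/(βk) = 0.25 Å²."""
        model = em.EnergyModel().add(
            em.SiteRestraint(4.0, small_fcc.coords, fixed_atom=0)
        )
        ss = em.sample_state(small_fcc, model, {}, n_sweeps=40_000, seed=11, step=1.0)
        x = ss.configs[:, 1, 0] - small_fcc.coords[1, 0]
        idx, g = subsample_decorrelated(x)
        xs = x[idx]
        var = xs.var(ddof=1)
        se = var * np.sqrt(2.0 / (xs.size - 1))
        assert abs(var - 0.25) < 3 * se

    def test_langevin_harmonic_variance(self, small_fcc):
        model = em.EnergyModel().add(
            em.SiteRestraint(4.0, small_fcc.coords, fixed_atom=0)
        )
        ss = em.sample_state(
            small_fcc, model, {}, n_sweeps=150_000, seed=12, mode="langevin",
            dt=0.05, gamma=1.0, sample_every=5,
        )
        # pool all coordinates of the three movable atoms (independent
        # harmonic dofs) to beat the long Langevin correlation time
        x = (ss.configs[:, 1:, :] - small_fcc.coords[None, 1:, :]).reshape(-1)
        var = x.var(ddof=1)
        # BAOAB has O(dt²) configurational bias; 4 % covers bias + noise
        assert var == pytest.approx(0.25, rel=0.04)

    def test_fixed_atom_never_moves(self, small_fcc):
        model = em.EnergyModel().add(
            em.SiteRestraint(4.0, small_fcc.coords, fixed_atom=0)
        )
        for mode in ("metropolis", "langevin"):
            ss = em.sample_state(small_fcc, model, {}, n_sweeps=2000, seed=5, mode=mode)
            assert np.all(ss.configs[:, 0, :] == small_fcc.coords[0])

    def test_same_seed_reproduces_trajectory(self, small_fcc):
        model = em.EnergyModel().add(
            em.SiteRestraint(10.0, small_fcc.coords, fixed_atom=0)
        )
        a = em.sample_state(small_fcc, model, {}, n_sweeps=3000, seed=42)
        b = em.sample_state(small_fcc, model, {}, n_sweeps=3000, seed=42)
        np.testing.assert_array_equal(a.configs, b.configs)
        c = em.sample_state(small_fcc, model, {}, n_sweeps=3000, seed=43)
        assert not np.array_equal(a.configs, c.configs)

    def test_acceptance_rate_lands_in_tuned_window(self, small_fcc):
        model = em.EnergyModel().add(
            em.SiteRestraint(400.0, small_fcc.coords, fixed_atom=0)
        )
        ss = em.sample_state(small_fcc, model, {}, n_sweeps=20_000, seed=3, step=2.0)
        assert 0.2 < ss.acceptance < 0.6

    def test_restrained_coordinate_is_gaussian(self, small_fcc):
        """KS test of a sampled coordinate against N(0, 1/(βk)) at α = 0.01."""
        k = 40.0
        model = em.EnergyModel().add(
            em.SiteRestraint(k, small_fcc.coords, fixed_atom=0)
        )
        ss = em.sample_state(small_fcc, model, {}, n_sweeps=180_000, seed=21, step=0.5)
        x = ss.configs[:, 3, 2] - small_fcc.coords[3, 2]
        idx, _ = subsample_decorrelated(x)
        xs = x[idx][:12_000]
        assert xs.size >= 10_000
        _, p = stats.kstest(xs, "norm", args=(0.0, 1.0 / np.sqrt(k)))
        assert p > 0.01


class TestCrossEvaluate:
    @pytest.fixture()
    def small_run(self, small_fcc):
        model = em.EnergyModel().add(
            em.SiteRestraint(100.0, small_fcc.coords, fixed_atom=0)
        )
        states = [{"site_restraint": c} for c in (1.0, 0.5, 0.25)]
        samples = em.sample_path(
            small_fcc, model, states, n_sweeps=500, master_seed=9,
            lambdas=np.array([0.0, 0.5, 1.0]),
        )
        return small_fcc, model, states, samples

    def test_diagonal_matches_sampling_energies(self, small_run):
        cry, model, states, samples = small_run
        u = em.cross_evaluate(samples, states, cry, model)
        for k, st in enumerate(samples.states):
            for n in (0, st.n // 2, st.n - 1):
                direct, _ = em.evaluate_energy(model, cry, st.configs[n], states[k])
                assert u.u[k, k, n] == pytest.approx(direct, abs=1e-10)

    def test_identical_states_are_column_independent(self, small_run):
        cry, model, _, samples = small_run
        same = [{"site_restraint": 0.5}] * 3
        u = em.cross_evaluate(samples, same, cry, model)
        for k in range(3):
            n = samples.states[k].n
            assert np.allclose(u.u[k, 0, :n], u.u[k, 1, :n])
            assert np.allclose(u.u[k, 0, :n], u.u[k, 2, :n])

    def test_shape_and_padding_contract(self, small_run):
        cry, model, states, samples = small_run
        u = em.cross_evaluate(samples, states, cry, model)
        K = len(states)
        assert u.u.shape == (K, K, int(u.n_k.max()))
        mask = u.mask()
        assert np.array_equal(mask.sum(axis=1), u.n_k)
        assert u.u_kn().shape == (K, int(u.n_k.sum()))

    def test_two_state_matrix_gives_exp_bar_inputs(self, small_run):
        cry, model, _, samples = small_run
        two = [{"site_restraint": 1.0}, {"site_restraint": 0.5}]
        sub = em.SampleSet(states=samples.states[:2])
        u = em.cross_evaluate(sub, two, cry, model)
        fwd, bwd = u.forward_backward(0)
        assert fwd.shape == (sub.states[0].n,)
        assert bwd.shape == (sub.states[1].n,)
        # forward ΔU = (c1 − c0)·E_base < 0 here since c decreases
        assert np.all(fwd < 0)

    def test_roundtrip_through_csv(self, small_run, tmp_path):
        cry, model, states, samples = small_run
        u = em.cross_evaluate(samples, states, cry, model)
        u.save(tmp_path / "u.csv", tmp_path / "u.json")
        back = em.ReducedPotentialMatrix.load(tmp_path / "u.csv", tmp_path / "u.json")
        np.testing.assert_allclose(back.u, u.u, atol=1e-9)
        np.testing.assert_array_equal(back.n_k, u.n_k)


class TestDecorrelation:
    def test_white_noise_inefficiency_near_one(self, rng):
        g = statistical_inefficiency(rng.normal(size=10_000))
        assert abs(g - 1.0) < 0.2

    def test_ar1_matches_closed_form(self, rng):
        rho = 0.8
        n = 100_000
        eps = rng.normal(size=n)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        g = statistical_inefficiency(x)
        expected = (1 + rho) / (1 - rho)
        assert abs(g - expected) / expected < 0.25

    def test_constant_series_is_one_effective_sample(self):
        series = np.full(500, 3.14)
        with pytest.warns(UserWarning, match="constant"):
            idx, g = subsample_decorrelated(series)
        assert g == 500
        assert idx.size == 1

    def test_subsample_stride_matches_inefficiency(self, rng):
        x = np.repeat(rng.normal(size=2000), 5)  # strongly correlated blocks
        idx, g = subsample_decorrelated(x)
        assert g > 3
        assert np.all(np.diff(idx) == int(np.ceil(g)))
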