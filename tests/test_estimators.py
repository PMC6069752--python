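"""TI, EXP, BAR, MBAR and the overlap diagnostic against Gaussian closed forms.

A 1-dof harmonic state with constant k has partition function √(2π/k), so
any estimator applied to exactly sampled Gaussian data must recover
Δf = ½·ln(k_final/k_initial) — the independent oracle used throughout.
"""

import numpy as np
import pytest

from einmol.estimators import (
    FreeEnergyEstimate,
    MultistateBAR,
    OverlapMatrix,
    bar_estimate,
    chain_segments,
    diagnose_path,
    exp_estimate,
    mbar_solve,
    ti_estimate,
)

from conftest import gaussian_ladder_u


class TestTI:
    def test_constant_integrand(self):
        lam = np.linspace(0, 1, 11)
        est = ti_estimate(lam, np.full(11, 2.5), np.zeros(11))
        assert est.value == pytest.approx(2.5, abs=1e-14)
        assert est.stderr == 0.0

    def test_one_dof_harmonic_switch(self, rng):
        """k switched linearly 4000 → 40: exact ΔA = ½·ln(k₁/k₀) = −2.3026."""
        k0, k1 = 4000.0, 40.0
        K, n = 101, 4000
        lam = np.linspace(0, 1, K)
        ks = k0 + (k1 - k0) * lam
        means = np.empty(K)
        sems = np.empty(K)
        for i, k in enumerate(ks):
            x = rng.normal(0, 1 / np.sqrt(k), size=n)
            dhdl = 0.5 * (k1 - k0) * x**2
            means[i] = dhdl.mean()
            sems[i] = dhdl.std(ddof=1) / np.sqrt(n)
        est = ti_estimate(lam, means, sems)
        exact = 0.5 * np.log(k1 / k0)
        # allow for the trapezoid bias of the curved 1/k(λ) integrand on
        # top of the statistical 3σ
        quad_bias = 0.02
        assert abs(est.value - exact) < 3 * est.stderr + quad_bias

    def test_sparse_vs_dense_quadrature_differ_for_curved_integrand(self):
        lam_dense = np.linspace(0, 1, 101)
        f = lambda l: 1.0 / (0.01 + l)  # strongly curved
        dense = ti_estimate(lam_dense, f(lam_dense)).value
        sparse = ti_estimate(np.array([0.0, 1.0]), f(np.array([0.0, 1.0]))).value
        assert abs(dense - sparse) > 1.0

    def test_rejects_unsorted_lambdas(self):
        with pytest.raises(ValueError):
            ti_estimate(np.array([0.0, 0.7, 0.4, 1.0]), np.zeros(4))


class TestEXP:
    def test_constant_shift_is_exact(self):
        for c in (-3.2, 0.0, 7.5):
            est = exp_estimate(np.full(100, c))
            assert est.value == pytest.approx(c, abs=1e-12)

    def test_gaussian_cumulant_identity(self, rng):
        """ΔU ~ N(2, 1) → ΔA = m − s²/2 = 1.5 k_BT."""
        est = exp_estimate(rng.normal(2.0, 1.0, size=100_000), seed=7)
        assert abs(est.value - 1.5) < 3 * est.stderr

    def test_forward_backward_bias_on_poor_overlap(self, rng):
        """With ΔU ~ N(0, 25) the two EXP directions disagree far beyond error."""
        s = 5.0
        du = rng.normal(0.0, s, size=20_000)
        fwd = exp_estimate(du, seed=1)
        bwd = exp_estimate(-du, seed=2)
        gap = abs(fwd.value - (-bwd.value))
        assert gap > 3 * np.hypot(fwd.stderr, bwd.stderr)

    def test_rejects_empty_input(self):
        with pytest.raises(ValueError):
            exp_estimate(np.array([]))


class TestBAR:
    def test_identical_states_give_zero(self):
        z = np.zeros(200)
        assert bar_estimate(z, z).value == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry_under_direction_swap(self, rng):
        fwd = rng.normal(1.0, 1.0, 3000)
        bwd = rng.normal(-1.2, 1.1, 3000)
        a = bar_estimate(fwd, bwd)
        b = bar_estimate(bwd, fwd)
        assert a.value == pytest.approx(-b.value, abs=1e-9)

    def test_harmonic_pair_closed_form(self, rng):
        """k₀ = 4 → k₁ = 8: ΔA = ½·ln 2 = +0.3466 k_BT."""
        k0, k1, n = 4.0, 8.0, 10_000
        x0 = rng.normal(0, 1 / np.sqrt(k0), n)
        x1 = rng.normal(0, 1 / np.sqrt(k1), n)
        est = bar_estimate(0.5 * (k1 - k0) * x0**2, 0.5 * (k0 - k1) * x1**2)
        assert abs(est.value - 0.5 * np.log(2.0)) < 3 * est.stderr

    def test_rejects_empty_directions(self):
        with pytest.raises(ValueError):
            bar_estimate(np.array([]), np.zeros(5))


class TestMBAR:
    def test_two_states_reduce_to_bar(self, rng):
        u, n_k = gaussian_ladder_u([4.0, 8.0], 5000, rng)
        res = mbar_solve(u, n_k)
        x0 = u[1, :5000] - u[0, :5000]
        x1 = u[0, 5000:] - u[1, 5000:]
        bar = bar_estimate(x0, x1)
        assert abs(res.delta_f() - bar.value) < 1e-8

    def test_identical_states_flat_ladder_and_uniform_overlap(self, rng):
        u, n_k = gaussian_ladder_u([3.0, 3.0, 3.0, 3.0], 500, rng)
        res = mbar_solve(u, n_k)
        np.testing.assert_allclose(res.f_k, 0.0, atol=1e-10)
        np.testing.assert_allclose(res.overlap().matrix, 0.25, atol=1e-10)

    def test_quartic_harmonic_ladder_closed_form(self, rng):
        """k_i = 4000·(i/(K−1))⁴ + 0.04, K = 24: Δf = ½·ln(k_last/k_first)."""
        K = 24
        ks = 4000.0 * (np.arange(K) / (K - 1)) ** 4 + 0.04
        u, n_k = gaussian_ladder_u(ks, 2000, rng)
        res = mbar_solve(u, n_k)
        exact = 0.5 * np.log(ks[-1] / ks[0])
        assert abs(res.delta_f() - exact) < 3 * res.stderr_delta_f()

    def test_state_reordering_invariance(self, rng):
        ks = np.array([2.0, 5.0, 11.0, 25.0])
        u, n_k = gaussian_ladder_u(ks, 1500, rng)
        res = mbar_solve(u, n_k)
        perm = np.array([2, 0, 3, 1])
        # permute evaluating states (rows) and sample blocks consistently
        blocks = [np.arange(i * 1500, (i + 1) * 1500) for i in range(4)]
        cols = np.concatenate([blocks[p] for p in perm])
        res_p = mbar_solve(u[np.ix_(perm, cols)], n_k[perm])
        for a in range(4):
            for b in range(4):
                pa, pb = np.where(perm == a)[0][0], np.where(perm == b)[0][0]
                assert res.f_k[b] - res.f_k[a] == pytest.approx(
                    res_p.f_k[pb] - res_p.f_k[pa], abs=1e-9
                )

    def test_nonconvergence_reports_residual(self, rng):
        u, n_k = gaussian_ladder_u([1.0, 5.0, 30.0], 200, rng)
        with pytest.raises(RuntimeError, match="residual"):
            mbar_solve(u, n_k, max_iter=1)

    def test_fit_results_summary_mentions_key_facts(self, rng):
        u, n_k = gaussian_ladder_u([2.0, 4.0], 500, rng)
        res = MultistateBAR(u, n_k).fit()
        text = res.summary()
        assert "states" in text and "converged" in text


class TestOverlap:
    def test_identical_equal_n_gives_one_over_k(self, rng):
        u, n_k = gaussian_ladder_u([2.0] * 5, 400, rng)
        res = mbar_solve(u, n_k)
        np.testing.assert_allclose(res.overlap().matrix, 0.2, atol=1e-10)

    def test_distant_states_give_identity(self, rng):
        """Two harmonic wells with means 100σ apart barely share density."""
        n = 2000
        x0 = rng.normal(0.0, 1.0, n)
        x1 = rng.normal(100.0, 1.0, n)
        x = np.concatenate([x0, x1])
        u = np.vstack([0.5 * x**2, 0.5 * (x - 100.0) ** 2])
        res = MultistateBAR(u, [n, n]).fit()
        O = res.overlap().matrix
        assert O[0, 0] > 1.0 - 1e-6 and O[1, 1] > 1.0 - 1e-6
        assert O[0, 1] < 1e-6 and O[1, 0] < 1e-6

    def test_rows_sum_to_one_on_any_converged_input(self, rng):
        ks = np.array([1.0, 3.0, 9.0, 27.0, 81.0])
        u, n_k = gaussian_ladder_u(ks, 700, rng)
        res = mbar_solve(u, n_k)
        np.testing.assert_allclose(res.overlap().matrix.sum(axis=1), 1.0, atol=1e-10)

    def test_rejects_invalid_matrix(self):
        with pytest.raises(ValueError):
            OverlapMatrix(np.array([[0.9, 0.0], [0.5, 0.5]]))


class TestChaining:
    def test_cancelling_segments(self):
        segs = [
            FreeEnergyEstimate(1.0, 0.1, "BAR"),
            FreeEnergyEstimate(-1.0, 0.2, "BAR"),
        ]
        total = chain_segments(segs)
        assert total.value == 0.0
        assert total.stderr == pytest.approx(np.hypot(0.1, 0.2))

    def test_single_segment_identity(self):
        seg = FreeEnergyEstimate(2.5, 0.3, "MBAR")
        total = chain_segments([seg])
        assert total.value == seg.value and total.stderr == seg.stderr

    def test_chunked_chain_equals_unsplit_chain(self, rng):
        """A long path split into chunks of 100 chains to the same total.

        BAR-chaining the full neighbour sequence and BAR-chaining each
        chunk then summing use identical per-pair estimates, so the
        totals agree to floating precision (same samples).
        """
        K, n = 301, 60
        ks = np.geomspace(1.0, 100.0, K)
        xs = [rng.normal(0, 1 / np.sqrt(k), n) for k in ks]
        segs = []
        for i in range(K - 1):
            fwd = 0.5 * (ks[i + 1] - ks[i]) * xs[i] ** 2
            bwd = 0.5 * (ks[i] - ks[i + 1]) * xs[i + 1] ** 2
            segs.append(bar_estimate(fwd, bwd))
        full = chain_segments(segs)
        chunk_totals = [
            chain_segments(segs[i : i + 100]) for i in range(0, K - 1, 100)
        ]
        rejoined = chain_segments(chunk_totals)
        assert rejoined.value == pytest.approx(full.value, abs=1e-9)


class TestDiagnosis:
    def test_healthy_chain_passes(self):
        m = np.array(
            [[0.8, 0.2, 0.0], [0.2, 0.6, 0.2], [0.0, 0.2, 0.8]]
        )
        diag = diagnose_path(OverlapMatrix(m))
        assert diag.ok and diag.broken_links == []
        assert diag.min_neighbor_overlap == pytest.approx(0.2)

    def test_broken_link_detected(self):
        m = np.array(
            [[0.999999, 1e-6, 0.0], [1e-6, 0.999999, 0.0], [0.0, 0.0, 1.0]]
        )
        diag = diagnose_path(OverlapMatrix(m))
        assert diag.status == "warn"
        assert (1, 2) in diag.broken_links

    def test_threshold_scales_with_path_length(self, rng):
        """A healthy long path (entries ~1/K < 0.03) must still pass."""
        K = 60
        u, n_k = gaussian_ladder_u([2.0] * K, 50, rng)
        res = mbar_solve(u, n_k)
        diag = diagnose_path(res.overlap())
        assert diag.ok


class TestConcordance:
    def test_estimators_agree_on_well_overlapped_path(self, rng):
        """TI, chained BAR and MBAR agree within 3 joint σ on a healthy 1-dof path."""
        K, n = 12, 4000
        lam = np.linspace(0, 1, K)
        k0, k1 = 50.0, 10.0
        ks = k0 + (k1 - k0) * lam
        xs = [rng.normal(0, 1 / np.sqrt(k), n) for k in ks]
        x_all = np.concatenate(xs)
        u = 0.5 * ks[:, None] * x_all[None, :] ** 2
        res = mbar_solve(u, np.full(K, n))
        assert np.all(res.overlap().neighbor_overlaps() >= 0.03)

        bar_segs = []
        for i in range(K - 1):
            fwd = 0.5 * (ks[i + 1] - ks[i]) * xs[i] ** 2
            bwd = 0.5 * (ks[i] - ks[i + 1]) * xs[i + 1] ** 2
            bar_segs.append(bar_estimate(fwd, bwd))
        bar_total = chain_segments(bar_segs)

        dk = (k1 - k0)
        means = np.array([np.mean(0.5 * dk * x**2) for x in xs])
        sems = np.array(
            [np.std(0.5 * dk * x**2, ddof=1) / np.sqrt(n) for x in xs]
        )
        ti_total = ti_estimate(lam, means, sems)

        exact = 0.5 * np.log(k1 / k0)
        mbar_total = res.total_estimate()
        for est in (ti_total, bar_total, mbar_total):
            assert abs(est.value - exact) < 3 * max(est.stderr, 1e-3) + 0.01
        pairs = [(ti_total, bar_total), (ti_total, mbar_total), (bar_total, mbar_total)]
        for a, b in pairs:
            assert abs(a.value - b.value) < 3 * np.hypot(a.stderr, b.stderr) + 0.01

    def test_reversed_path_negates_every_segment(self, rng):
        ks = np.array([10.0, 5.0, 2.0])
        u, n_k = gaussian_ladder_u(ks, 2000, rng)
        res = mbar_solve(u, n_k)
        blocks = [np.arange(i * 2000, (i + 1) * 2000) for i in range(3)]
        perm = np.array([2, 1, 0])
        cols = np.concatenate([blocks[p] for p in perm])
        rev = mbar_solve(u[np.ix_(perm, cols)], n_k[perm])
        fwd_segs = np.diff(res.f_k)
        rev_segs = np.diff(rev.f_k)
        np.testing.assert_allclose(rev_segs, -fwd_segs[::-1], atol=1e-9)
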