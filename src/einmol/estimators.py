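"""Free-energy estimators: TI, EXP, BAR and multistate BAR (MBAR).

All energies are reduced (k_BT, β ≡ 1).  The multistate estimator is
exposed statsmodels-style: :class:`MultistateBAR` is constructed from the
reduced-potential data and ``fit()`` returns a :class:`MBARResult`
carrying the per-state free energies, their asymptotic covariance, the
row-stochastic phase-space overlap matrix and a ``summary()`` table.

TI uncertainties propagate only the per-state integrand noise through the
trapezoid weights; they say nothing about whether the integrand actually
varies smoothly between the sampled λ values, so a smooth-looking TI
error can mask a broken path.  BAR and MBAR uncertainties grow when
phase-space overlap is poor, which is why the overlap matrix — each row
of which must sum to 1 — is the path diagnostic of choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .sampling import ReducedPotentialMatrix

__all__ = [
    "FreeEnergyEstimate",
    "OverlapMatrix",
    "PathDiagnosis",
    "ti_estimate",
    "exp_estimate",
    "bar_estimate",
    "MultistateBAR",
    "MBARResult",
    "mbar_solve",
    "overlap_matrix",
    "chain_segments",
    "diagnose_path",
]

#: adjacent-state overlap below this is flagged as a broken link
OVERLAP_WARN_THRESHOLD = 0.03


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    """Bare-bones log-sum-exp along an axis (hot path; avoids scipy overhead)."""
    m = np.max(a, axis=axis, keepdims=True)
    out = np.log(np.sum(np.exp(a - m), axis=axis)) + np.squeeze(m, axis=axis)
    return out


@dataclass
class FreeEnergyEstimate:
    """A free-energy difference in k_BT with its standard error and provenance."""

    value: float
    stderr: float
    method: str
    n_states: int = 2
    segments: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("standard error must be non-negative")

    def summary(self) -> str:
        lines = [
            f"Free energy estimate ({self.method})",
            f"  value    : {self.value:.6f} k_BT",
            f"  stderr   : {self.stderr:.6f} k_BT",
            f"  n_states : {self.n_states}",
        ]
        for key, val in self.diagnostics.items():
            lines.append(f"  {key} : {val}")
        if self.segments:
            lines.append(f"  segments : {len(self.segments)}")
            for i, seg in enumerate(self.segments):
                lines.append(f"    [{i}] {seg.value:+.6f} ± {seg.stderr:.6f}")
        return "\n".join(lines)


@dataclass
class OverlapMatrix:
    """Row-stochastic K×K matrix of phase-space overlap probabilities."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        self.matrix = m
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("overlap matrix must be square")
        if np.any(m < -1e-12):
            raise ValueError("overlap entries must be non-negative")
        rows = m.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-8):
            raise ValueError("overlap matrix rows must sum to 1")

    @property
    def K(self) -> int:
        return self.matrix.shape[0]

    def neighbor_overlaps(self) -> np.ndarray:
        """min(O[i,i+1], O[i+1,i]) for each adjacent pair along the path."""
        m = self.matrix
        i = np.arange(self.K - 1)
        return np.minimum(m[i, i + 1], m[i + 1, i])


# --------------------------------------------------------------------------
# TI
# --------------------------------------------------------------------------


def ti_estimate(
    lambdas: np.ndarray,
    dhdl_means: np.ndarray,
    dhdl_sems: np.ndarray | None = None,
) -> FreeEnergyEstimate:
    """Thermodynamic integration: trapezoidal quadrature of ⟨∂H/∂λ⟩ over λ.

    The standard error propagates only the integrand standard errors
    through the trapezoid weights; it does not reflect overlap failure
    between sampled λ values (see the module docstring).
    """
    lam = np.asarray(lambdas, dtype=float)
    means = np.asarray(dhdl_means, dtype=float)
    if lam.size < 2:
        raise ValueError("TI needs at least two states")
    if np.any(np.diff(lam) <= 0):
        raise ValueError("lambda values must be strictly increasing")
    if not np.all(np.isfinite(means)):
        raise ValueError("non-finite integrand means")
    # trapezoid weights
    w = np.zeros_like(lam)
    dl = np.diff(lam)
    w[:-1] += dl / 2.0
    w[1:] += dl / 2.0
    value = float(np.dot(w, means))
    if dhdl_sems is None:
        stderr = 0.0
    else:
        sems = np.asarray(dhdl_sems, dtype=float)
        stderr = float(np.sqrt(np.dot(w**2, sems**2)))
    return FreeEnergyEstimate(
        value=value, stderr=stderr, method="TI", n_states=lam.size,
        diagnostics={"quadrature": "trapezoid"},
    )


# --------------------------------------------------------------------------
# EXP
# --------------------------------------------------------------------------


def exp_estimate(
    delta_u: np.ndarray, n_bootstrap: int = 200, seed: int = 0
) -> FreeEnergyEstimate:
    """Exponential averaging: ΔA = −ln⟨exp(−ΔU)⟩ with a bootstrap standard error."""
    du = np.asarray(delta_u, dtype=float)
    if du.size == 0:
        raise ValueError("empty input")
    n = du.size
    value = float(-(logsumexp(-du) - np.log(n)))
    if n == 1 or n_bootstrap == 0:
        stderr = 0.0
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_bootstrap, n))
        boots = -(logsumexp(-du[idx], axis=1) - np.log(n))
        stderr = float(np.std(boots, ddof=1))
    return FreeEnergyEstimate(value=value, stderr=stderr, method="EXP", n_states=2)


# --------------------------------------------------------------------------
# BAR
# --------------------------------------------------------------------------


def _fermi(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic 1/(1 + e^{-x})."""
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bar_estimate(
    forward: np.ndarray,
    backward: np.ndarray,
    tol: float = 1e-10,
    max_expand: int = 100,
) -> FreeEnergyEstimate:
    """Bennett acceptance ratio between two states.

    ``forward`` holds ΔU = U_{n+1} − U_n over samples from state n;
    ``backward`` holds ΔU = U_n − U_{n+1} over samples from state n+1.
    The self-consistent equation is solved by bracketed root finding to
    ``tol`` k_BT; the asymptotic variance is reported as the standard
    error.  Failure to bracket a root signals catastrophic overlap
    failure and raises rather than returning silently.
    """
    fwd = np.asarray(forward, dtype=float)
    bwd = np.asarray(backward, dtype=float)
    if fwd.size == 0 or bwd.size == 0:
        raise ValueError("both directions need at least one sample")
    nf, nr = fwd.size, bwd.size
    m = np.log(nf / nr)

    def g(da: float) -> float:
        lhs = np.mean(_fermi(-(m + fwd - da)))
        rhs = np.mean(_fermi(-(-m + bwd + da)))
        return lhs - rhs

    # initial bracket from the two EXP estimates
    lo = float(-(logsumexp(-fwd) - np.log(nf)))
    hi = float(logsumexp(-bwd) - np.log(nr))
    lo, hi = min(lo, hi) - 1.0, max(lo, hi) + 1.0
    for _ in range(max_expand):
        if g(lo) * g(hi) <= 0:
            break
        span = hi - lo
        lo -= span
        hi += span
    else:
        raise RuntimeError("BAR: no root in bracket — catastrophic overlap failure")
    da = brentq(g, lo, hi, xtol=tol)
    # Bennett asymptotic variance
    ff = _fermi(-(m + fwd - da))
    fr = _fermi(-(-m + bwd + da))
    var = (np.mean(ff**2) / np.mean(ff) ** 2 - 1.0) / nf + (
        np.mean(fr**2) / np.mean(fr) ** 2 - 1.0
    ) / nr
    return FreeEnergyEstimate(
        value=float(da), stderr=float(np.sqrt(max(var, 0.0))), method="BAR", n_states=2,
        diagnostics={"n_forward": nf, "n_backward": nr},
    )


# --------------------------------------------------------------------------
# MBAR
# --------------------------------------------------------------------------


class MultistateBAR:
    """Multistate Bennett acceptance ratio estimator.

    Parameters
    ----------
    u_kn : ndarray (K, Ntot)
        Reduced potential of every pooled sample evaluated in every
        state, or a :class:`ReducedPotentialMatrix`.
    N_k : ndarray (K,)
        Number of samples contributed by each state.

    ``fit()`` solves the MBAR self-consistent equations (anchored at
    f_0 = 0) by convex minimization followed by self-consistent
    polishing, and returns an :class:`MBARResult`.
    """

    def __init__(self, u_kn, N_k=None):
        if isinstance(u_kn, ReducedPotentialMatrix):
            self.u_kn = u_kn.u_kn()
            self.N_k = u_kn.n_k.astype(float)
        else:
            self.u_kn = np.asarray(u_kn, dtype=float)
            if N_k is None:
                raise ValueError("N_k required when u_kn is a plain array")
            self.N_k = np.asarray(N_k, dtype=float)
        if self.u_kn.ndim != 2 or self.u_kn.shape[1] != int(self.N_k.sum()):
            raise ValueError("u_kn must be (K, sum N_k)")
        if np.any(self.N_k < 1):
            raise ValueError("every state needs at least one sample")
        if not np.all(np.isfinite(self.u_kn)):
            raise ValueError("non-finite reduced potentials")

    def _residual(self, f: np.ndarray) -> np.ndarray:
        logw = f[:, None] - self.u_kn + np.log(self.N_k)[:, None]
        logd = logsumexp(logw, axis=0)
        f_new = -logsumexp(-self.u_kn - logd[None, :], axis=1)
        f_new -= f_new[0]
        return f_new - f

    def fit(self, tol: float = 1e-10, max_iter: int = 500) -> "MBARResult":
        K, Ntot = self.u_kn.shape
        # shift each sample column for conditioning
        shift = self.u_kn.min(axis=0)
        u = self.u_kn - shift[None, :]
        logN = np.log(self.N_k)

        def grad_hess(f):
            logw = f[:, None] - u + logN[:, None]
            p = np.exp(logw - _lse(logw, 0)[None, :])  # (K, Ntot), Σ_k p = 1
            grad = p.sum(axis=1) - self.N_k
            hess = np.diag(p.sum(axis=1)) - p @ p.T
            return grad, hess

        def grad_only(f):
            logw = f[:, None] - u + logN[:, None]
            p = np.exp(logw - _lse(logw, 0)[None, :])
            return p.sum(axis=1) - self.N_k

        def sc_update(f):
            logw = f[:, None] - u + logN[:, None]
            logd = _lse(logw, 0)
            f_new = -_lse(-u - logd[None, :], 1)
            return f_new - f_new[0]

        # initial guess: forward EXP chained over neighbours, each segment
        # using only the source state's own samples
        f = np.zeros(K)
        offsets = np.concatenate([[0], np.cumsum(self.N_k)]).astype(int)
        for k in range(1, K):
            sl = slice(offsets[k - 1], offsets[k])
            du = u[k, sl] - u[k - 1, sl]
            f[k] = f[k - 1] + (-(logsumexp(-du) - np.log(du.size)))
        if not np.all(np.isfinite(f)):
            f = np.zeros(K)
        # warm start from a strided subsample when the pool is large: the
        # subsampled solution lands within the Newton basin of the full one
        if Ntot > 50_000 and np.all(self.N_k > 20):
            stride = max(int(Ntot // 20_000), 1)
            if stride > 1:
                keep = np.concatenate(
                    [
                        off + np.arange(0, int(nk), stride)
                        for off, nk in zip(
                            np.concatenate([[0], np.cumsum(self.N_k)[:-1]]).astype(int),
                            self.N_k,
                        )
                    ]
                )
                sub = MultistateBAR(self.u_kn[:, keep],
                                    [len(np.arange(0, int(nk), stride)) for nk in self.N_k])
                f = sub.fit(tol=max(tol, 1e-8), max_iter=max_iter).f_k.copy()
        # adaptive iteration on the convex MBAR objective (anchor f_0 = 0):
        # at each step take whichever of the Newton and self-consistent
        # updates has the smaller gradient norm (the self-consistent map is
        # globally stable; Newton is quadratically convergent near the root)
        converged = False
        n_iter = 0
        resid = np.inf
        for _it in range(max_iter):
            n_iter += 1
            grad, hess = grad_hess(f)
            g_here = float(np.linalg.norm(grad))
            f_new = None
            try:
                step = np.linalg.solve(hess[1:, 1:] + 1e-10 * np.eye(K - 1), -grad[1:])
                # backtrack until the gradient norm decreases; essential on
                # poorly overlapping paths where the Hessian is near-singular
                alpha = 1.0
                for _ls in range(12):
                    f_try = f.copy()
                    f_try[1:] += alpha * step
                    f_try -= f_try[0]
                    if np.all(np.isfinite(f_try)) and float(
                        np.linalg.norm(grad_only(f_try))
                    ) < g_here:
                        f_new = f_try
                        break
                    alpha *= 0.5
            except np.linalg.LinAlgError:
                pass
            if f_new is None:
                f_new = sc_update(f)
            resid = float(np.max(np.abs(f_new - f)))
            f = f_new
            if resid < tol:
                # confirm against the self-consistent fixed point itself
                resid = float(np.max(np.abs(sc_update(f) - f)))
                if resid < tol:
                    converged = True
                    break
        # weights for covariance/overlap (use original u; shift cancels in W)
        logw = f[:, None] - u + logN[:, None]
        logd = logsumexp(logw, axis=0)
        W = np.exp(f[None, :] - u.T - logd[:, None])  # (Ntot, K): Σ_n W_nk = 1
        theta = _asymptotic_covariance(W, self.N_k)
        return MBARResult(
            f_k=f, theta=theta, W=W, N_k=self.N_k.copy(),
            converged=converged, n_iter=n_iter, residual=resid,
        )


def _asymptotic_covariance(W: np.ndarray, N_k: np.ndarray) -> np.ndarray:
    """MBAR asymptotic covariance Θ of the reduced free energies via SVD.

    The inner matrix is inverted exactly (up to a minuscule ridge): on a
    path with vanishing phase-space overlap it is nearly singular and the
    variances blow up — which is the correct, honest signal, matching the
    divergent uncertainties such paths are known to produce.  A silently
    truncated pseudo-inverse would instead *hide* the failure.
    """
    u_svd, s, vt = np.linalg.svd(W, full_matrices=False)
    K = N_k.size
    s_mat = np.diag(s)
    inner = np.eye(K) - s_mat @ vt @ np.diag(N_k) @ vt.T @ s_mat
    evals, evecs = np.linalg.eigh(inner)
    scale = float(np.max(np.abs(evals))) or 1.0
    null = np.abs(evals) < 1e-12 * scale
    # exactly one null mode (the uniform shift of the f's) is structural
    # and is projected out; a second one means disconnected state blocks,
    # and a significantly negative one a solution that is no optimum — in
    # both cases no finite covariance exists
    if int(null.sum()) > 1 or np.any(evals < -1e-8 * scale):
        return np.full((K, K), np.inf)
    inv_evals = np.where(null, 0.0, 1.0 / np.where(null, 1.0, evals))
    pinv = (evecs * inv_evals[None, :]) @ evecs.T
    theta = vt.T @ s_mat @ pinv @ s_mat @ vt
    return theta


@dataclass
class MBARResult:
    """MBAR fit: per-state reduced free energies, covariance, overlap, diagnostics."""

    f_k: np.ndarray
    theta: np.ndarray
    W: np.ndarray  # (Ntot, K) weight matrix
    N_k: np.ndarray
    converged: bool
    n_iter: int
    residual: float

    def delta_f(self, i: int = 0, j: int = -1) -> float:
        return float(self.f_k[j] - self.f_k[i])

    def stderr_delta_f(self, i: int = 0, j: int = -1) -> float:
        """Asymptotic standard error of f_j − f_i.

        On a path with (numerically) vanishing overlap the covariance is
        dominated by a near-singular direction: its entries overflow or
        cancel catastrophically, and the honest report is an infinite
        uncertainty rather than a silently truncated small number.
        """
        t_ii, t_jj, t_ij = self.theta[i, i], self.theta[j, j], self.theta[i, j]
        if not (np.isfinite(t_ii) and np.isfinite(t_jj) and np.isfinite(t_ij)):
            return float(np.inf)
        var = t_ii + t_jj - 2.0 * t_ij
        scale = abs(t_ii) + abs(t_jj)
        if not np.isfinite(var) or scale > 1e10 or var < -1e-8 * scale:
            return float(np.inf)
        return float(np.sqrt(max(var, 0.0)))

    def overlap(self) -> OverlapMatrix:
        if not self.converged:
            # a non-converged solution still carries relative weight
            # information; row-normalize so the diagnostic stays readable
            import warnings

            warnings.warn(
                "overlap matrix from a non-converged MBAR fit (row-normalized)",
                stacklevel=2,
            )
            O = self.W.T @ (self.W * self.N_k[None, :])
            O /= O.sum(axis=1, keepdims=True)
            return OverlapMatrix(matrix=O)
        return overlap_matrix(self.W, self.N_k)

    def total_estimate(self) -> FreeEnergyEstimate:
        """The end-to-end free energy f_{K−1} − f_0 as a FreeEnergyEstimate.

        A non-converged fit reports an infinite standard error: with no
        joint solution to the self-consistent equations the asymptotic
        covariance is meaningless, and an unusable uncertainty is the
        honest signal (broken paths do exactly this).
        """
        est = FreeEnergyEstimate(
            value=self.delta_f(0, -1),
            stderr=self.stderr_delta_f(0, -1) if self.converged else np.inf,
            method="MBAR",
            n_states=self.f_k.size,
            diagnostics={"converged": self.converged, "iterations": self.n_iter,
                         "residual": self.residual},
        )
        return est

    def summary(self) -> str:
        lines = [
            "MBAR fit",
            f"  states     : {self.f_k.size}",
            f"  samples    : {int(self.N_k.sum())}",
            f"  converged  : {self.converged} ({self.n_iter} iterations, "
            f"residual {self.residual:.2e})",
            f"  Δf (0→K−1) : {self.delta_f():.6f} ± {self.stderr_delta_f():.6f} k_BT",
            "  f_k (first/last 3): "
            + np.array2string(self.f_k[:3], precision=4)
            + " ... "
            + np.array2string(self.f_k[-3:], precision=4),
        ]
        return "\n".join(lines)


def mbar_solve(u, N_k=None, tol: float = 1e-10, max_iter: int = 10000) -> MBARResult:
    """Solve the MBAR equations for a reduced-potential matrix (f_0 anchored to 0).

    Raises :class:`RuntimeError` with the residual norm on non-convergence.
    """
    result = MultistateBAR(u, N_k).fit(tol=tol, max_iter=max_iter)
    if not result.converged:
        raise RuntimeError(
            f"MBAR did not converge: residual {result.residual:.3e} after "
            f"{result.n_iter} iterations"
        )
    return result


def overlap_matrix(W: np.ndarray, N_k: np.ndarray) -> OverlapMatrix:
    """Phase-space overlap O_ij = Σ_n W_ni·W_nj·N_j from converged MBAR weights."""
    N_k = np.asarray(N_k, dtype=float)
    O = W.T @ (W * N_k[None, :])
    # O as computed is W^T W N with rows indexing i: O_ij = Σ_n W_ni W_nj N_j
    return OverlapMatrix(matrix=O)


# --------------------------------------------------------------------------
# chaining and path diagnosis
# --------------------------------------------------------------------------


def chain_segments(segments: list[FreeEnergyEstimate]) -> FreeEnergyEstimate:
    """Sum segment free energies; variances add under the independent-segment assumption."""
    if not segments:
        raise ValueError("no segments to chain")
    value = float(sum(s.value for s in segments))
    stderr = float(np.sqrt(sum(s.stderr**2 for s in segments)))
    return FreeEnergyEstimate(
        value=value,
        stderr=stderr,
        method="+".join(sorted({s.method for s in segments})) + "-chained",
        n_states=sum(s.n_states for s in segments) - (len(segments) - 1),
        segments=list(segments),
    )


@dataclass
class PathDiagnosis:
    """Overlap-based verdict on an alchemical path."""

    status: str  # "pass" | "warn"
    min_neighbor_overlap: float
    broken_links: list
    threshold: float

    @property
    def ok(self) -> bool:
        return self.status == "pass"


def diagnose_path(overlap: OverlapMatrix, threshold: float | None = None) -> PathDiagnosis:
    """Flag adjacent state pairs whose mutual overlap falls below ``threshold``.

    Broken links mean samples from neighbouring states occupy disjoint
    regions of configuration space; the cure is densifying the λ schedule
    around the flagged pairs (e.g. power-spaced states near the
    weak-restraint end).

    The default threshold is min(0.03, 0.5/K): on long paths a state's
    probability mass is shared across many mutually overlapping
    neighbours, so even a perfectly healthy K-state path has row entries
    of order 1/K and a K-independent cutoff would mislabel it.
    """
    if threshold is None:
        threshold = min(OVERLAP_WARN_THRESHOLD, 0.5 / overlap.K)
    nb = overlap.neighbor_overlaps()
    broken = [(int(i), int(i + 1)) for i in range(nb.size) if nb[i] < threshold]
    return PathDiagnosis(
        status="warn" if broken else "pass",
        min_neighbor_overlap=float(nb.min()) if nb.size else 1.0,
        broken_links=broken,
        threshold=threshold,
    )
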