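"""Semidefinite-programming solver for the 1-D Fourier BLASSO.

For Fourier measurements on the torus the dual of the BLASSO,

    max_p  Re<y, p> - (lambda/2) ||p||^2   s.t.  ||F* p||_inf <= 1,

has an exact finite recast: the sup-norm constraint on the trigonometric
polynomial F*p is equivalent (bounded real lemma / Fejer-Riesz) to the
existence of a Hermitian Q with

    [[Q, p], [p*, 1]] >= 0   and   sum_k Q_{k, k+j} = delta_{0, j}.

The recovery pipeline is then:

1. solve the SDP for the dual variable p (here by an ADMM splitting:
   closed-form prox of the quadratic objective + affine trace projection,
   alternated with a PSD eigenvalue projection — the problem is (n+1)x(n+1)
   with n = 2 fc + 1, tiny);
2. locate the support as the unit-circle roots of the degree 2n-2
   polynomial p_{2n-2}(e^{2 i pi t}) = 1 - |F* p|^2(t) via its companion
   matrix (roots on the circle are double roots of this nonnegative
   polynomial, so near-duplicates are merged);
3. recover real amplitudes by Hermitian-symmetrized least squares on the
   Vandermonde system sum_t a_t e^{2 i pi k t} = target_k.  Solving against
   the extremality-consistent target y - lambda p yields the BLASSO
   minimizer's (soft-thresholded) amplitudes; solving against raw y yields
   the unshrunk source amplitudes on noiseless data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measures import DiscreteMeasure, unit_torus
from .operators import FourierOperator1D

__all__ = [
    "SDPDualSolution",
    "solve_dual_sdp",
    "support_from_roots",
    "amplitudes_from_support",
    "solve_blasso_sdp",
]


@dataclass
class SDPDualSolution:
    p: np.ndarray              # dual variable, length n = 2 fc + 1
    Q: np.ndarray              # Hermitian n x n block certificate
    status: str
    objective: float           # Re<y,p> - lambda/2 ||p||^2
    n_iters: int
    residual: float            # final ADMM consensus residual (Frobenius)

    def block_matrix(self) -> np.ndarray:
        n = self.p.shape[0]
        M = np.zeros((n + 1, n + 1), dtype=complex)
        M[:n, :n] = self.Q
        M[:n, n] = self.p
        M[n, :n] = np.conj(self.p)
        M[n, n] = 1.0
        return M


def _project_affine(M: np.ndarray, n: int) -> np.ndarray:
    """Project the Hermitian (n+1)^2 matrix onto the trace constraints.

    Per-diagonal sums of the Q block equal delta_{0,j}; the corner entry is
    1.  Orthogonal projection shifts each diagonal by its mean deviation.
    """
    M = 0.5 * (M + M.conj().T)
    for j in range(n):
        idx = (np.arange(n - j), np.arange(j, n))
        target = 1.0 if j == 0 else 0.0
        s = np.sum(M[idx])
        shift = (target - s) / (n - j)
        M[idx] += shift
        if j > 0:
            M[idx[1], idx[0]] += np.conj(shift)
    M[n, n] = 1.0
    return M


def _project_psd(M: np.ndarray) -> np.ndarray:
    M = 0.5 * (M + M.conj().T)
    w, V = np.linalg.eigh(M)
    w = np.maximum(w, 0.0)
    return (V * w) @ V.conj().T


def solve_dual_sdp(
    y: np.ndarray,
    lam: float,
    fc: int,
    rho: float = 1.0,
    max_iters: int = 40000,
    tol: float = 1e-9,
) -> SDPDualSolution:
    """ADMM on the SDP recast of the Fourier dual problem.

    Splitting X = Z with X carrying the affine constraints and the smooth
    objective in its p column, Z the PSD cone.  Each X-update is closed
    form (quadratic prox on p, diagonal-shift projection on Q); each
    Z-update is one (n+1)x(n+1) eigendecomposition.  Residual balancing
    adapts rho.
    """
    y = np.asarray(y, dtype=complex)
    n = 2 * fc + 1
    if y.shape != (n,):
        raise ValueError(f"y must have length {n}")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    Z = np.zeros((n + 1, n + 1), dtype=complex)
    Z[n, n] = 1.0
    U = np.zeros_like(Z)
    status, it = "max-iters", max_iters
    r_norm = np.inf
    for it in range(1, max_iters + 1):
        # X-update: affine projection, then quadratic prox on the p column
        V = Z - U
        X = _project_affine(V.copy(), n)
        v = 0.5 * (X[:n, n] + np.conj(X[n, :n]))
        p = (y + 2.0 * rho * v) / (lam + 2.0 * rho)
        X[:n, n] = p
        X[n, :n] = np.conj(p)
        # Z-update: PSD projection; dual update
        Z_new = _project_psd(X + U)
        s_norm = rho * np.linalg.norm(Z_new - Z)
        Z = Z_new
        U += X - Z
        r_norm = np.linalg.norm(X - Z)
        if r_norm < tol and s_norm < tol:
            status = "optimal"
            break
        if it % 100 == 0:  # residual balancing
            if r_norm > 10 * s_norm:
                rho *= 2.0
                U /= 2.0
            elif s_norm > 10 * r_norm:
                rho /= 2.0
                U *= 2.0
    p = 0.5 * (Z[:n, n] + np.conj(Z[n, :n]))
    obj = float(np.real(np.vdot(p, y)) - 0.5 * lam * np.real(np.vdot(p, p)))
    return SDPDualSolution(
        p=p, Q=Z[:n, :n].copy(), status=status, objective=obj,
        n_iters=it, residual=float(r_norm),
    )


def _dual_polynomial_coeffs(p: np.ndarray, fc: int) -> np.ndarray:
    """Coefficients of z^{n-1} (1 - |F* p|^2(t)) with z = e^{2 i pi t}.

    F* p(t) = sum_k conj(p_{fc+k}) e^{2 i pi k t}; |F* p|^2 has Laurent
    coefficients given by the autocorrelation of u = conj(p).  Returned
    ascending in z, degree 2n - 2.
    """
    u = np.conj(np.asarray(p, dtype=complex))
    n = u.shape[0]
    d = np.correlate(u, u, mode="full")  # d_j = sum_k u_{k+j} conj(u_k), j=-(n-1)..n-1
    b = -d
    b[n - 1] += 1.0
    return b


def support_from_roots(
    p: np.ndarray, fc: int, circle_tol: float = 1e-4
) -> np.ndarray:
    """Support of the primal measure from the unit-circle roots of 1-|F*p|^2.

    Builds the degree-(2n-2) polynomial via the autocorrelation of p, finds
    all roots through the companion matrix, keeps those with ``||z|-1| <
    circle_tol`` and merges angular clusters within ``10 * circle_tol``
    (circle roots of the nonnegative polynomial have even multiplicity and
    noise splits the pairs slightly off-circle).  Returns sorted positions
    in [0, 1).
    """
    coeffs = _dual_polynomial_coeffs(p, fc)
    if np.max(np.abs(coeffs)) == 0.0:
        raise ValueError("degenerate dual solution: zero polynomial")
    roots = np.roots(coeffs[::-1])  # np.roots wants descending order
    on_circle = roots[np.abs(np.abs(roots) - 1.0) < circle_tol]
    if on_circle.size == 0:
        return np.zeros(0)
    t = np.sort(np.mod(np.angle(on_circle) / (2.0 * np.pi), 1.0))
    # angular single-linkage merge of the double-root pairs
    merge_tol = 10.0 * circle_tol
    groups = [[t[0]]]
    for ti in t[1:]:
        if ti - groups[-1][-1] <= merge_tol:
            groups[-1].append(ti)
        else:
            groups.append([ti])
    # wrap-around: first and last group may be the same root across t = 0
    if len(groups) > 1 and (groups[0][0] + 1.0 - groups[-1][-1]) <= merge_tol:
        groups[0] = [g - 1.0 for g in groups.pop()] + groups[0]
    return np.sort(np.array([np.mod(np.mean(g), 1.0) for g in groups]))


def amplitudes_from_support(
    y: np.ndarray, support: np.ndarray, fc: int
) -> tuple[np.ndarray, float]:
    """Real least-squares amplitudes for sum_t a_t e^{2 i pi k t} = y_k.

    The complex Vandermonde system over k = -fc..fc is solved for real a by
    stacking real and imaginary parts (Hermitian symmetrization).  Returns
    (amplitudes, residual norm).  Duplicate support points make the system
    rank deficient and raise.
    """
    support = np.atleast_1d(np.asarray(support, dtype=float))
    n = 2 * fc + 1
    if support.size == 0 or support.size > n:
        raise ValueError("support must be nonempty with at most n points")
    k = np.arange(-fc, fc + 1)
    E = np.exp(2j * np.pi * k[:, None] * support[None, :])  # (n, T)
    A = np.vstack([np.real(E), np.imag(E)])
    b = np.concatenate([np.real(y), np.imag(y)])
    a, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < support.size:
        raise ValueError("rank-deficient Vandermonde system (duplicate support points?)")
    res = float(np.linalg.norm(A @ a - b))
    return a, res


def solve_blasso_sdp(
    y: np.ndarray,
    lam: float,
    fc: int,
    circle_tol: float = 1e-4,
    amp_floor_rel: float = 1e-3,
    **admm_kwargs,
) -> tuple[DiscreteMeasure, SDPDualSolution]:
    """Full SDP pipeline: dual solve, root-finding, amplitude recovery.

    Amplitudes are fit against ``y - lambda p`` (the primal acquisition
    prescribed by the extremality conditions), and support points whose
    recovered amplitude magnitude falls below ``amp_floor_rel * ||y||`` are
    dropped as spurious near-circle roots.
    """
    dual = solve_dual_sdp(y, lam, fc, **admm_kwargs)
    support = support_from_roots(dual.p, fc, circle_tol=circle_tol)
    domain = unit_torus(1)
    if support.size == 0:
        return DiscreteMeasure.empty(domain), dual
    target = np.asarray(y, dtype=complex) - lam * dual.p
    a, _ = amplitudes_from_support(target, support, fc)
    floor = amp_floor_rel * float(np.linalg.norm(y))
    keep = np.abs(a) >= floor
    if np.any(keep) and not np.all(keep):
        a, _ = amplitudes_from_support(target, support[keep], fc)
        support = support[keep]
    elif not np.any(keep):
        return DiscreteMeasure.empty(domain), dual
    return DiscreteMeasure(a, support[:, None], domain), dual


def dual_polynomial_value(p: np.ndarray, fc: int, t: np.ndarray) -> np.ndarray:
    """|F* p|(t) on the torus, for feasibility checks on a dense grid."""
    op = FourierOperator1D(fc)
    pts = np.atleast_1d(t)[:, None]
    return np.abs(op.kernel(pts) @ np.conj(p))
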