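"""The BLASSO objective and its dual certificates.

The Beurling LASSO minimizes, over Radon measures m,

    T_lambda(m) = 1/2 ||y - Phi m||_H^2 + lambda |m|(X)

with |m|(X) the total-variation norm (= sum |a_i| for a spike train).  Every
solver in this package monitors optimality through the *dual certificate*

    eta_lambda(x) = (1/lambda) <y - Phi m, phi(x)>_H = (Phi* p)(x),
    p = (y - Phi m) / lambda:

at a minimizer, |eta_lambda| <= 1 everywhere with equality on the support.
The sup of |eta_lambda| over the domain is therefore both the stopping rule
and the insertion rule (the argmax is the best new spike location).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .measures import DiscreteMeasure
from .operators import ForwardOperator, real_inner

__all__ = ["BlassoProblem", "CertificateField", "energy", "certificate", "sup_certificate"]

#: absolute slack on the dual-feasibility boundary |eta| <= 1
DUAL_FEAS_TOL = 1e-6


@dataclass
class BlassoProblem:
    """Data, operator and regularization defining one BLASSO instance."""

    operator: ForwardOperator
    y: np.ndarray
    lam: float
    positivity: bool = False

    def __post_init__(self):
        self.y = np.asarray(self.y)
        if self.y.shape != (self.operator.n_measurements,):
            raise ValueError("y length does not match operator")
        if not self.lam > 0:
            raise ValueError("lam must be > 0")

    def residual(self, m: DiscreteMeasure) -> np.ndarray:
        return self.y - self.operator.apply(m)


def energy(prob: BlassoProblem, m: DiscreteMeasure) -> float:
    """T_lambda(m) = 1/2 ||y - Phi m||^2 + lambda sum |a_i|."""
    if prob.positivity and np.any(m.amplitudes < 0):
        raise ValueError("positivity-constrained problem given a signed measure")
    r = prob.residual(m)
    return 0.5 * float(np.real(np.vdot(r, r))) + prob.lam * float(
        np.sum(np.abs(m.amplitudes))
    )


@dataclass
class CertificateField:
    """eta_lambda as an evaluable scalar field with gradient."""

    problem: BlassoProblem
    p: np.ndarray  # dual variable (y - Phi m) / lambda

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.problem.operator.adjoint(self.p, x)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.problem.operator.adjoint_gradient(self.p, x)

    def on_grid(self, axes) -> np.ndarray:
        return self.problem.operator.adjoint_on_grid(self.p, axes)


def certificate(prob: BlassoProblem, m: DiscreteMeasure) -> CertificateField:
    """Certificate of m: eta(x) = (1/lambda) <y - Phi m, phi(x)>."""
    return CertificateField(problem=prob, p=prob.residual(m) / prob.lam)


def sup_certificate(
    cert: CertificateField,
    grid_n=None,
    refine: bool = True,
) -> tuple[float, np.ndarray]:
    """Maximize |eta| (or eta itself under positivity) over the domain.

    Coarse regular grid search followed by a local derivative-based ascent
    from the best node (L-BFGS-B, box-bounded for flat axes).  The returned
    value is never below the grid maximum.  Grid ties break at the lowest
    flat index for determinism.
    """
    prob = cert.problem
    op = prob.operator
    domain = op.domain
    if grid_n is None:
        grid_n = op.default_grid()
    elif np.isscalar(grid_n):
        grid_n = [int(grid_n)] * domain.d
    if any(n < 2 for n in grid_n):
        raise ValueError("need at least 2 grid nodes per axis")
    axes = domain.regular_grid(grid_n)
    field = cert.on_grid(axes)
    score = field if prob.positivity else np.abs(field)
    flat_idx = int(np.argmax(score))
    idx = np.unravel_index(flat_idx, field.shape)
    x0 = np.array([axes[ax][idx[ax]] for ax in range(domain.d)])
    best_val = float(score[idx])
    best_x = x0
    if not refine:
        return best_val, best_x
    sign = 1.0 if (prob.positivity or field[idx] >= 0) else -1.0

    def neg(x):
        pt = x[None, :]
        val = sign * cert(pt)[0]
        grad = sign * cert.gradient(pt)[0]
        return -val, -grad

    bounds = None
    if not all(domain.torus):
        bounds = [
            (None, None) if domain.torus[ax] else domain.bounds[ax]
            for ax in range(domain.d)
        ]
    res = optimize.minimize(
        neg, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 100},
    )
    if np.all(np.isfinite(res.x)):
        x_ref = domain.wrap(res.x[None, :])[0]
        val_ref = float(cert(x_ref[None, :])[0])
        val_ref = val_ref if prob.positivity else abs(val_ref)
        if val_ref > best_val:
            best_val, best_x = val_ref, x_ref
    return best_val, best_x


def dual_feasible(cert: CertificateField, grid_n=None, tol: float = DUAL_FEAS_TOL) -> bool:
    """Check sup |eta| <= 1 + tol (the empty measure's optimality test)."""
    val, _ = sup_certificate(cert, grid_n=grid_n)
    return val <= 1.0 + tol


def empty_measure_optimal(prob: BlassoProblem, grid_n=None) -> bool:
    """For lambda >= sup |<y, phi(x)>| the zero measure solves the BLASSO."""
    from .measures import DiscreteMeasure as _DM

    cert = certificate(prob, _DM.empty(prob.operator.domain))
    return dual_feasible(cert, grid_n=grid_n)


def check_real_inner_adjointness(op, m, p) -> tuple[float, float]:
    """Convenience: (<Phi m, p>, sum a_i Phi*p(x_i)) — equal by adjointness."""
    lhs = real_inner(op.apply(m), p)
    rhs = float(np.sum(m.amplitudes * op.adjoint(p, m.positions)))
    return lhs, rhs
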