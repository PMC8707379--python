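"""Measurement operators: kernel phi, forward map Phi, adjoint Phi*, gradients.

Two acquisition models are provided:

* :class:`FourierOperator1D` — low-pass Fourier coefficients on the 1-torus,
  ``phi(x) = (e^{2 i pi k x})_{|k| <= fc}``, the classical super-resolution
  toy problem with ``n = 2 fc + 1`` complex measurements.
* :class:`GaussianPixelOperator2D` — a 2-D Gaussian point-spread function
  integrated over camera pixels, the SMLM acquisition model.  Each pixel
  value is a separable product of erf differences, so kernels, adjoints and
  gradients all factor per axis.

Conventions
-----------
The measurement space is treated as a *real* Hilbert space: the inner
product is ``<u, v> = Re sum_k u_k conj(v_k)``.  The adjoint is implemented
so that the defining identity ``<Phi m, p> = sum_i a_i (Phi* p)(x_i)`` holds
to machine precision; for Hermitian-symmetric ``p`` (the case for data from
real measures) the Fourier adjoint coincides with the trigonometric
polynomial ``sum_k conj(p_k) e^{2 i pi k x}``, which is then real-valued.

Pixel grid: pixel ``(i1, i2)`` occupies ``[i1 b1, (i1+1) b1) x [i2 b2,
(i2+1) b2)`` with pixel ``(0, 0)`` at the lower-left corner; images are
arrays of shape ``(n1, n2)`` flattened row-major (``i2`` fastest).
Positions are continuous physical coordinates (nm for SMLM) measured from
that corner, not pixel indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

from .measures import DiscreteMeasure, Domain, unit_torus

__all__ = [
    "ForwardOperator",
    "FourierOperator1D",
    "GaussianPixelOperator2D",
    "apply_forward",
    "apply_adjoint",
    "kernel_gradient",
    "pixel_psf_value",
]

_SQRT2 = np.sqrt(2.0)


class ForwardOperator:
    """Abstract acquisition model; concrete classes define the kernel."""

    domain: Domain
    n_measurements: int

    def kernel(self, x: np.ndarray) -> np.ndarray:
        """phi evaluated at points x of shape (N, d) -> (N, n)."""
        raise NotImplementedError

    def kernel_gradient(self, x: np.ndarray) -> np.ndarray:
        """d phi / d x at points x: shape (N, d, n)."""
        raise NotImplementedError

    def _check_points(self, x: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(x, dtype=float))
        if pts.shape[1] != self.domain.d:
            raise ValueError(
                f"points are {pts.shape[1]}-D, operator domain is {self.domain.d}-D"
            )
        return pts

    def _check_vector(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p)
        if p.shape != (self.n_measurements,):
            raise ValueError(
                f"measurement vector has length {p.shape}, expected {self.n_measurements}"
            )
        return p

    def apply(self, m: DiscreteMeasure) -> np.ndarray:
        """Phi m = sum_i a_i phi(x_i)."""
        if m.domain != self.domain:
            raise ValueError("measure domain does not match operator domain")
        if len(m) == 0:
            return np.zeros(self.n_measurements, dtype=self.dtype)
        return m.amplitudes @ self.kernel(m.positions)

    def adjoint(self, p: np.ndarray, x: np.ndarray) -> np.ndarray:
        """(Phi* p)(x) = <p, phi(x)>_H, real-valued, at points x -> (N,)."""
        p = self._check_vector(p)
        pts = self._check_points(x)
        return np.real(self.kernel(pts) @ np.conj(p))

    def adjoint_gradient(self, p: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Spatial gradient of Phi* p at points x -> (N, d)."""
        p = self._check_vector(p)
        pts = self._check_points(x)
        grad = self.kernel_gradient(pts)  # (N, d, n)
        return np.real(grad @ np.conj(p))

    def adjoint_on_grid(self, p: np.ndarray, axes: list[np.ndarray]) -> np.ndarray:
        """Phi* p on a tensor grid (generic fallback; subclasses specialize)."""
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([g.ravel() for g in mesh], axis=-1)
        return self.adjoint(p, pts).reshape([len(ax) for ax in axes])

    @property
    def dtype(self):
        return float


@dataclass
class FourierOperator1D(ForwardOperator):
    """Fourier coefficients up to cut-off frequency fc on the 1-torus.

    Measurement k runs over -fc..fc (storage index ``k + fc``), so the
    acquisition has ``n = 2 fc + 1`` complex entries.
    """

    fc: int

    def __post_init__(self):
        if self.fc < 1:
            raise ValueError("fc must be >= 1")
        self.domain = unit_torus(1)
        self.freqs = np.arange(-self.fc, self.fc + 1)
        self.n_measurements = 2 * self.fc + 1

    @property
    def dtype(self):
        return complex

    def kernel(self, x: np.ndarray) -> np.ndarray:
        pts = self._check_points(x)
        return np.exp(2j * np.pi * pts[:, [0]] * self.freqs[None, :])

    def kernel_gradient(self, x: np.ndarray) -> np.ndarray:
        phi = self.kernel(x)
        return (2j * np.pi * self.freqs[None, :] * phi)[:, None, :]

    def default_grid(self, per_axis_factor: int = 32) -> list[int]:
        # grid-search resolution for certificate maximization
        return [per_axis_factor * self.fc]

    # --- CSV serialization of acquisitions: columns k, Re, Im ---

    def write_acquisition(self, y: np.ndarray, path) -> None:
        y = self._check_vector(y)
        pd.DataFrame(
            {"k": self.freqs, "Re": np.real(y), "Im": np.imag(y)}
        ).to_csv(path, index=False)

    def read_acquisition(self, path) -> np.ndarray:
        df = pd.read_csv(path).sort_values("k")
        if not np.array_equal(df["k"].to_numpy(), self.freqs):
            raise ValueError("frequency axis in file does not match operator")
        return df["Re"].to_numpy() + 1j * df["Im"].to_numpy()


def _erf_profile(edges: np.ndarray, x: np.ndarray, sigma: float) -> np.ndarray:
    """1-D pixel-integrated Gaussian: 0.5*(erf((hi-x)/s√2) - erf((lo-x)/s√2)).

    edges has length nbins+1; x has shape (N,); returns (N, nbins)."""
    z = (edges[None, :] - x[:, None]) / (sigma * _SQRT2)
    e = erf(z)
    return 0.5 * (e[:, 1:] - e[:, :-1])


def _erf_profile_grad(edges: np.ndarray, x: np.ndarray, sigma: float) -> np.ndarray:
    """d/dx of the profile above: (g(lo) - g(hi)) with the Gaussian density g."""
    z = (edges[None, :] - x[:, None]) / (sigma * _SQRT2)
    g = np.exp(-(z**2)) / (sigma * np.sqrt(2.0 * np.pi))
    return g[:, :-1] - g[:, 1:]


@dataclass
class GaussianPixelOperator2D(ForwardOperator):
    """2-D Gaussian PSF integrated over a rectangular camera pixel grid.

    ``[phi(x)]_i = (1 / 2 pi sigma^2) \\int_{Omega_i} exp(-|s - x|^2 / 2 sigma^2) ds``
    which factors into a product of per-axis erf differences.  Pixel values
    lie in [0, 1] and the full-plane sum equals the unit mass of the PSF.
    """

    sigma: float
    n1: int
    n2: int
    pixel_size: tuple[float, float]
    torus: bool = False

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        b1, b2 = (float(self.pixel_size[0]), float(self.pixel_size[1]))
        if b1 <= 0 or b2 <= 0:
            raise ValueError("pixel sizes must be positive")
        self.pixel_size = (b1, b2)
        self.domain = Domain(
            bounds=((0.0, self.n1 * b1), (0.0, self.n2 * b2)),
            torus=(self.torus, self.torus),
        )
        self.edges1 = b1 * np.arange(self.n1 + 1)
        self.edges2 = b2 * np.arange(self.n2 + 1)
        self.n_measurements = self.n1 * self.n2

    @property
    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        b1, b2 = self.pixel_size
        return (
            (np.arange(self.n1) + 0.5) * b1,
            (np.arange(self.n2) + 0.5) * b2,
        )

    def _profiles(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (
            _erf_profile(self.edges1, pts[:, 0], self.sigma),
            _erf_profile(self.edges2, pts[:, 1], self.sigma),
        )

    def kernel(self, x: np.ndarray) -> np.ndarray:
        pts = self._check_points(x)
        g1, g2 = self._profiles(pts)
        return np.einsum("ni,nj->nij", g1, g2).reshape(pts.shape[0], -1)

    def kernel_gradient(self, x: np.ndarray) -> np.ndarray:
        pts = self._check_points(x)
        g1, g2 = self._profiles(pts)
        d1 = _erf_profile_grad(self.edges1, pts[:, 0], self.sigma)
        d2 = _erf_profile_grad(self.edges2, pts[:, 1], self.sigma)
        gx = np.einsum("ni,nj->nij", d1, g2).reshape(pts.shape[0], -1)
        gy = np.einsum("ni,nj->nij", g1, d2).reshape(pts.shape[0], -1)
        return np.stack([gx, gy], axis=1)

    def apply_image(self, m: DiscreteMeasure) -> np.ndarray:
        """Phi m reshaped as an (n1, n2) image."""
        return self.apply(m).reshape(self.n1, self.n2)

    def adjoint(self, p: np.ndarray, x: np.ndarray) -> np.ndarray:
        p = self._check_vector(p)
        pts = self._check_points(x)
        P = np.real(p).reshape(self.n1, self.n2)
        g1, g2 = self._profiles(pts)
        return np.einsum("ni,ij,nj->n", g1, P, g2)

    def adjoint_gradient(self, p: np.ndarray, x: np.ndarray) -> np.ndarray:
        p = self._check_vector(p)
        pts = self._check_points(x)
        P = np.real(p).reshape(self.n1, self.n2)
        g1, g2 = self._profiles(pts)
        d1 = _erf_profile_grad(self.edges1, pts[:, 0], self.sigma)
        d2 = _erf_profile_grad(self.edges2, pts[:, 1], self.sigma)
        gx = np.einsum("ni,ij,nj->n", d1, P, g2)
        gy = np.einsum("ni,ij,nj->n", g1, P, d2)
        return np.stack([gx, gy], axis=1)

    def adjoint_on_grid(self, p: np.ndarray, axes: list[np.ndarray]) -> np.ndarray:
        """Separable fast path: eta(grid) = G1 @ P @ G2^T."""
        p = self._check_vector(p)
        P = np.real(p).reshape(self.n1, self.n2)
        G1 = _erf_profile(self.edges1, np.asarray(axes[0], dtype=float), self.sigma)
        G2 = _erf_profile(self.edges2, np.asarray(axes[1], dtype=float), self.sigma)
        return G1 @ P @ G2.T

    def pixel_value(self, x: np.ndarray, i: tuple[int, int]) -> float:
        """[phi(x)]_i for one pixel index i = (i1, i2)."""
        i1, i2 = i
        if not (0 <= i1 < self.n1 and 0 <= i2 < self.n2):
            raise IndexError(f"pixel index {i} out of range")
        pts = self._check_points(x)
        g1 = _erf_profile(self.edges1[i1 : i1 + 2], pts[:, 0], self.sigma)
        g2 = _erf_profile(self.edges2[i2 : i2 + 2], pts[:, 1], self.sigma)
        return float(g1[0, 0] * g2[0, 0])

    def default_grid(self, nodes_per_sigma: int = 4) -> list[int]:
        w = self.domain.widths
        return [max(8, int(np.ceil(nodes_per_sigma * wi / self.sigma))) for wi in w]


# --- functional aliases matching the operation-level API ---


def apply_forward(op: ForwardOperator, m: DiscreteMeasure) -> np.ndarray:
    return op.apply(m)


def apply_adjoint(op: ForwardOperator, p: np.ndarray, x: np.ndarray) -> np.ndarray:
    return op.adjoint(p, x)


def kernel_gradient(op: ForwardOperator, x: np.ndarray) -> np.ndarray:
    return op.kernel_gradient(x)


def pixel_psf_value(op: GaussianPixelOperator2D, x: np.ndarray, i: tuple[int, int]) -> float:
    return op.pixel_value(x, i)


def real_inner(u: np.ndarray, v: np.ndarray) -> float:
    """The real Hilbert inner product <u, v> = Re sum u conj(v)."""
    return float(np.real(np.vdot(v, u)))
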