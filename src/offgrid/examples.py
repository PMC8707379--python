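"""Reference study configurations used across tests, docs and scripts.

Two canonical deconvolution problems exercise every solver:

* a 1-D Fourier instance on the torus: three well-separated spikes of mixed
  sign (amplitudes 1.0, -1.0, 0.7 at 0.1, 0.45, 0.78 — pairwise separation
  above the 1.87/fc recovery scale for real measures at fc = 6), observed
  through 2 fc + 1 = 13 Fourier coefficients with optional Hermitian
  complex Gaussian noise;
* a 2-D Gaussian instance on [0,1]^2: three positive sources observed
  through a pixel-integrated Gaussian kernel of spread sigma = 0.1 on a
  128 x 128 grid with additive Gaussian noise of variance 0.1, solved at
  lambda = 3e-2.  Source brightnesses (180, 240, 300) put the clean
  acquisition peak at O(1) counts, where that noise level leaves the
  noise part of the dual certificate safely below the stopping threshold.
"""

from __future__ import annotations

import numpy as np

from .blasso import BlassoProblem
from .measures import DiscreteMeasure, unit_torus
from .operators import FourierOperator1D, GaussianPixelOperator2D

__all__ = [
    "fourier_three_spikes",
    "fourier_problem",
    "hermitian_noise",
    "gaussian_three_sources",
    "gaussian_problem",
]

FOURIER_FC = 6
FOURIER_AMPLITUDES = (1.0, -1.0, 0.7)
FOURIER_POSITIONS = (0.1, 0.45, 0.78)

GAUSS_SIGMA = 0.1
GAUSS_PIXELS = 128
GAUSS_AMPLITUDES = (180.0, 240.0, 300.0)
GAUSS_POSITIONS = ((0.2, 0.3), (0.5, 0.75), (0.8, 0.35))
GAUSS_NOISE_VAR = 0.1
GAUSS_LAMBDA = 3e-2


def fourier_three_spikes(fc: int = FOURIER_FC):
    """(operator, ground-truth measure) for the 1-D Fourier instance."""
    op = FourierOperator1D(fc)
    truth = DiscreteMeasure(
        np.array(FOURIER_AMPLITUDES),
        np.array(FOURIER_POSITIONS)[:, None],
        unit_torus(1),
    )
    return op, truth


def hermitian_noise(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    """Complex Gaussian noise with Hermitian symmetry (w_{-k} = conj(w_k)),
    the noise class of Fourier measurements of real-valued data."""
    w = rng.normal(scale=scale, size=n) + 1j * rng.normal(scale=scale, size=n)
    return 0.5 * (w + np.conj(w[::-1]))


def fourier_problem(
    seed: int | None = None, noise: float = 0.02, lam: float = 1.0, fc: int = FOURIER_FC
):
    """Noisy BLASSO instance of the Fourier fixture; noiseless when seed None."""
    op, truth = fourier_three_spikes(fc)
    y = op.apply(truth)
    if seed is not None and noise > 0:
        y = y + hermitian_noise(np.random.default_rng(seed), op.n_measurements, noise)
    return BlassoProblem(op, y, lam), truth


def gaussian_three_sources(n_pixels: int = GAUSS_PIXELS, sigma: float = GAUSS_SIGMA):
    """(operator, ground-truth measure) for the 2-D Gaussian instance."""
    op = GaussianPixelOperator2D(
        sigma=sigma, n1=n_pixels, n2=n_pixels,
        pixel_size=(1.0 / n_pixels, 1.0 / n_pixels),
    )
    truth = DiscreteMeasure(
        np.array(GAUSS_AMPLITUDES), np.array(GAUSS_POSITIONS), op.domain
    )
    return op, truth


def gaussian_problem(
    seed: int | None = None,
    noise_var: float = GAUSS_NOISE_VAR,
    lam: float = GAUSS_LAMBDA,
    n_pixels: int = GAUSS_PIXELS,
):
    """Noisy positive BLASSO instance of the 2-D fixture."""
    op, truth = gaussian_three_sources(n_pixels)
    y = op.apply(truth)
    if seed is not None and noise_var > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(scale=np.sqrt(noise_var), size=y.shape)
    return BlassoProblem(op, y, lam, positivity=True), truth
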