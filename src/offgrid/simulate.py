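"""Synthetic SMLM scene and stack generator.

Emulates a single-molecule localization microscopy acquisition: fluorophores
bound to filament-like structures (spline curves standing in for tubulin),
stochastic frame-by-frame activation ("blinking"), a pixel-integrated 2-D
Gaussian PSF, and the three camera noise sources — Poisson photon shot
noise, Poisson dark current, and Gaussian readout noise.

The default configuration mirrors the EPFL 2013 challenge high-density
setting: 64 x 64 pixels of 100 nm, PSF sigma = 149.39 nm (FWHM 351.8 nm).
A second preset mirrors the ISBI real stack geometry (128 x 128 pixels,
FWHM 351.8 nm).  Per-activation photon counts are exponential with a
configurable mean — a deliberately heavy-tailed brightness model, since no
particular law is canonical.

Everything is a pure function of (config, seed): stacks regenerate
byte-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy.interpolate import CubicSpline

from .operators import GaussianPixelOperator2D

__all__ = [
    "SceneConfig",
    "fwhm_to_sigma",
    "sigma_to_fwhm",
    "make_filament_scene",
    "simulate_frame",
    "simulate_stack",
    "write_stack",
    "read_stack",
    "epfl_preset",
    "isbi_preset",
]

_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian FWHM -> standard deviation: sigma = FWHM / (2 sqrt(2 ln 2))."""
    if fwhm <= 0:
        raise ValueError("FWHM must be positive")
    return fwhm / _FWHM_FACTOR


def sigma_to_fwhm(sigma: float) -> float:
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return sigma * _FWHM_FACTOR


@dataclass
class SceneConfig:
    """Acquisition geometry, scene statistics and noise levels.

    Exactly one of ``sigma`` / ``fwhm`` must be given (nm).  Rates are per
    frame; ``dark_current_rate`` is in counts/pixel/frame and
    ``readout_std`` in counts.
    """

    n1: int = 64
    n2: int = 64
    pixel_size: float = 100.0            # nm
    sigma: float | None = 149.39         # nm
    fwhm: float | None = None            # nm
    n_frames: int = 50
    n_filaments: int = 3
    fluorophores_per_filament: int = 40
    mean_active_per_frame: float = 5.0
    photons_per_emitter: float = 4000.0
    dark_current_rate: float = 5.0
    readout_std: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if (self.sigma is None) == (self.fwhm is None):
            raise ValueError("give exactly one of sigma or fwhm")
        if self.fwhm is not None:
            self.sigma = fwhm_to_sigma(self.fwhm)
        for name in (
            "pixel_size", "sigma", "mean_active_per_frame", "photons_per_emitter",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dark_current_rate < 0 or self.readout_std < 0:
            raise ValueError("noise levels must be nonnegative")

    @property
    def fov(self) -> tuple[float, float]:
        return (self.n1 * self.pixel_size, self.n2 * self.pixel_size)

    def operator(self) -> GaussianPixelOperator2D:
        return GaussianPixelOperator2D(
            sigma=self.sigma, n1=self.n1, n2=self.n2,
            pixel_size=(self.pixel_size, self.pixel_size),
        )


def epfl_preset(**overrides) -> SceneConfig:
    """64 x 64 px, 100 nm pixels, sigma = 149.39 nm."""
    return SceneConfig(**overrides)


def isbi_preset(**overrides) -> SceneConfig:
    """128 x 128 px geometry with FWHM 351.8 nm."""
    base = dict(n1=128, n2=128, sigma=None, fwhm=351.8)
    base.update(overrides)
    return SceneConfig(**base)


def _one_filament(rng: np.random.Generator, fov, n_fluor: int) -> np.ndarray:
    """A smooth random curve spanning the field of view, with fluorophores
    placed at equal arc-length spacing (spline through jittered controls)."""
    w1, w2 = fov
    n_ctrl = 5
    # endpoints near opposite borders, interior controls jittered
    t_ctrl = np.linspace(0.0, 1.0, n_ctrl)
    start = rng.uniform([0.02 * w1, 0.02 * w2], [0.98 * w1, 0.98 * w2])
    end = rng.uniform([0.02 * w1, 0.02 * w2], [0.98 * w1, 0.98 * w2])
    # resample until the filament spans a decent fraction of the FOV
    while np.linalg.norm(end - start) < 0.5 * min(w1, w2):
        end = rng.uniform([0.02 * w1, 0.02 * w2], [0.98 * w1, 0.98 * w2])
    ctrl = start[None, :] + t_ctrl[:, None] * (end - start)[None, :]
    ctrl[1:-1] += rng.normal(scale=0.08 * min(w1, w2), size=(n_ctrl - 2, 2))
    spline = CubicSpline(t_ctrl, ctrl, axis=0)
    t_dense = np.linspace(0.0, 1.0, 512)
    path = spline(t_dense)
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arclen[-1], n_fluor)
    t_fluor = np.interp(targets, arclen, t_dense)
    pts = spline(t_fluor)
    return np.clip(pts, [0.0, 0.0], [np.nextafter(w1, 0.0), np.nextafter(w2, 0.0)])


def make_filament_scene(cfg: SceneConfig, seed: int | None = None) -> dict:
    """Ground truth for one acquisition: static fluorophores + blinking.

    Returns a dict with ``fluorophores`` (DataFrame: id, x [nm], y [nm]) and
    ``activations`` (DataFrame: frame, x [nm], y [nm], photons).  Each frame
    activates each fluorophore independently with probability
    ``mean_active_per_frame / n_fluorophores``; photons per activation are
    exponential with the configured mean.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    pts = np.vstack(
        [
            _one_filament(rng, cfg.fov, cfg.fluorophores_per_filament)
            for _ in range(cfg.n_filaments)
        ]
    )
    fluor = pd.DataFrame(
        {"id": np.arange(pts.shape[0]), "x [nm]": pts[:, 0], "y [nm]": pts[:, 1]}
    )
    n_total = pts.shape[0]
    p_on = min(cfg.mean_active_per_frame / n_total, 1.0)
    rows = []
    for frame in range(cfg.n_frames):
        on = rng.random(n_total) < p_on
        idx = np.flatnonzero(on)
        photons = rng.exponential(cfg.photons_per_emitter, size=idx.size)
        for i, ph in zip(idx, photons):
            rows.append((frame, pts[i, 0], pts[i, 1], ph))
    activations = pd.DataFrame(
        rows, columns=["frame", "x [nm]", "y [nm]", "photons"]
    )
    activations["frame"] = activations["frame"].astype(int)
    return {"fluorophores": fluor, "activations": activations}


def simulate_frame(
    op: GaussianPixelOperator2D,
    emitters: np.ndarray,
    cfg: SceneConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One camera frame, in counts (float; may go negative through readout).

    ``emitters`` is (N, 3): x [nm], y [nm], photons.  counts =
    Poisson(sum_e photons_e * phi(x_e) + dark) + N(0, readout_std^2).
    """
    emitters = np.atleast_2d(np.asarray(emitters, dtype=float))
    clean = np.zeros(op.n_measurements)
    if emitters.size:
        if not op.domain.contains(emitters[:, :2]):
            raise ValueError("emitters outside the field of view")
        clean = emitters[:, 2] @ op.kernel(emitters[:, :2])
    mean = clean + cfg.dark_current_rate
    counts = rng.poisson(mean).astype(float)
    if cfg.readout_std > 0:
        counts += rng.normal(0.0, cfg.readout_std, size=counts.shape)
    return counts.reshape(op.n1, op.n2)


def simulate_stack(
    cfg: SceneConfig, seed: int | None = None
) -> tuple[np.ndarray, dict]:
    """Full synthetic acquisition: (stack float32 (n_frames, n1, n2), scene)."""
    seed = cfg.seed if seed is None else seed
    scene = make_filament_scene(cfg, seed=seed)
    rng = np.random.default_rng(seed + 1)
    op = cfg.operator()
    act = scene["activations"]
    frames = np.zeros((cfg.n_frames, cfg.n1, cfg.n2), dtype=np.float32)
    for frame in range(cfg.n_frames):
        sub = act[act["frame"] == frame]
        emitters = sub[["x [nm]", "y [nm]", "photons"]].to_numpy()
        frames[frame] = simulate_frame(op, emitters, cfg, rng)
    return frames, scene


def write_stack(frames: np.ndarray, path, dtype=None) -> None:
    """Multi-page TIFF writer; uint16 export clips negatives with a warning."""
    frames = np.asarray(frames)
    if dtype is not None and np.dtype(dtype) == np.uint16:
        if np.any(frames < 0):
            warnings.warn("negative counts clipped at 0 for uint16 export")
        frames = np.clip(frames, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    elif dtype is not None:
        frames = frames.astype(dtype)
    # photometric tag disambiguates small stacks from RGB pages
    tifffile.imwrite(path, frames, photometric="minisblack")


def read_stack(path) -> np.ndarray:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None, ...]
    return frames


def write_ground_truth(scene: dict, path) -> None:
    scene["activations"].to_csv(path, index=False)


def read_ground_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["frame", "x [nm]", "y [nm]", "photons"]
    if list(df.columns) != expected:
        raise ValueError(f"ground-truth CSV must have columns {expected}")
    return df
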