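"""Discrete Radon measures: spike trains, norms, separation, cleanup.

A spike train is the measure ``m = sum_i a_i delta_{x_i}`` with signed real
amplitudes ``a_i`` and positions ``x_i`` in a 1-D or 2-D domain.  The domain
may be a flat box or a torus (per axis), which changes every distance
computation downstream (minimum separation, merging, flat metric ground
distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Domain",
    "DiscreteMeasure",
    "tv_norm",
    "min_separation",
    "prune_and_merge",
]


@dataclass(frozen=True)
class Domain:
    """Ambient space of spike positions: a box in R^d, optionally periodic.

    Parameters
    ----------
    bounds
        Per-axis closed intervals ``((lo, hi), ...)``; finite, ``lo < hi``.
    torus
        Per-axis periodicity flags.  On a periodic axis, distances wrap
        around and positions are reduced modulo the period.
    """

    bounds: tuple[tuple[float, float], ...]
    torus: tuple[bool, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        object.__setattr__(self, "bounds", bounds)
        torus = self.torus
        if torus is None:
            torus = (False,) * len(bounds)
        elif isinstance(torus, bool):
            torus = (torus,) * len(bounds)
        object.__setattr__(self, "torus", tuple(bool(t) for t in torus))
        if len(self.torus) != len(bounds):
            raise ValueError("torus flags must match the number of axes")
        for lo, hi in bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid axis bounds ({lo}, {hi})")

    @property
    def d(self) -> int:
        return len(self.bounds)

    @property
    def lo(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def hi(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])

    @property
    def widths(self) -> np.ndarray:
        return self.hi - self.lo

    @property
    def diameter(self) -> float:
        """Largest ground distance realizable between two points."""
        w = self.widths.copy()
        w[list(self.torus)] /= 2.0
        return float(np.sqrt(np.sum(w**2)))

    def contains(self, points: np.ndarray, atol: float = 1e-9) -> bool:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != self.d:
            raise ValueError(f"points are {pts.shape[1]}-D, domain is {self.d}-D")
        return bool(
            np.all(pts >= self.lo - atol) and np.all(pts <= self.hi + atol)
        )

    def wrap(self, points: np.ndarray) -> np.ndarray:
        """Reduce periodic axes modulo the period; clamp flat axes to the box."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
        for ax in range(self.d):
            lo, hi = self.bounds[ax]
            if self.torus[ax]:
                pts[:, ax] = lo + np.mod(pts[:, ax] - lo, hi - lo)
            else:
                pts[:, ax] = np.clip(pts[:, ax], lo, hi)
        return pts

    def diff(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Componentwise displacement a - b with wrap-around on periodic axes."""
        delta = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
        for ax in range(self.d):
            if self.torus[ax]:
                period = self.bounds[ax][1] - self.bounds[ax][0]
                delta[..., ax] = (delta[..., ax] + period / 2) % period - period / 2
        return delta

    def distance(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.sqrt(np.sum(self.diff(a, b) ** 2, axis=-1))

    def pairwise_distances(self, pts: np.ndarray, other: np.ndarray | None = None) -> np.ndarray:
        pts = np.atleast_2d(pts)
        other = pts if other is None else np.atleast_2d(other)
        return self.distance(pts[:, None, :], other[None, :, :])

    def regular_grid(self, n_per_axis: Sequence[int] | int) -> list[np.ndarray]:
        """Per-axis regular grids; periodic axes omit the duplicate endpoint."""
        if np.isscalar(n_per_axis):
            n_per_axis = [int(n_per_axis)] * self.d
        axes = []
        for ax, n in enumerate(n_per_axis):
            lo, hi = self.bounds[ax]
            if self.torus[ax]:
                axes.append(lo + (hi - lo) * np.arange(n) / n)
            else:
                axes.append(np.linspace(lo, hi, n))
        return axes


def unit_torus(d: int = 1) -> Domain:
    return Domain(bounds=((0.0, 1.0),) * d, torus=(True,) * d)


def unit_box(d: int = 2) -> Domain:
    return Domain(bounds=((0.0, 1.0),) * d, torus=(False,) * d)


@dataclass
class DiscreteMeasure:
    """A signed spike train ``sum_i a_i delta_{x_i}``."""

    amplitudes: np.ndarray
    positions: np.ndarray
    domain: Domain

    def __post_init__(self):
        a = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        x = np.asarray(self.positions, dtype=float)
        if x.size == 0:
            x = np.zeros((0, self.domain.d))
        if x.ndim == 1:
            x = x[:, None] if self.domain.d == 1 else x[None, :]
        if x.shape[0] != a.shape[0]:
            raise ValueError(
                f"{a.shape[0]} amplitudes for {x.shape[0]} positions"
            )
        if x.shape[1] != self.domain.d:
            raise ValueError(f"positions are {x.shape[1]}-D, domain is {self.domain.d}-D")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(x))):
            raise ValueError("non-finite amplitude or position")
        if a.size and not self.domain.contains(x):
            raise ValueError("positions outside domain bounds")
        self.amplitudes = a
        self.positions = self.domain.wrap(x) if a.size else x

    @classmethod
    def empty(cls, domain: Domain) -> "DiscreteMeasure":
        return cls(np.zeros(0), np.zeros((0, domain.d)), domain)

    def __len__(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_spikes(self) -> int:
        return len(self)

    def scaled(self, c: float) -> "DiscreteMeasure":
        return DiscreteMeasure(c * self.amplitudes, self.positions.copy(), self.domain)

    def __add__(self, other: "DiscreteMeasure") -> "DiscreteMeasure":
        if other.domain != self.domain:
            raise ValueError("cannot add measures on different domains")
        return DiscreteMeasure(
            np.concatenate([self.amplitudes, other.amplitudes]),
            np.vstack([self.positions, other.positions]),
            self.domain,
        )

    def __sub__(self, other: "DiscreteMeasure") -> "DiscreteMeasure":
        return self + other.scaled(-1.0)

    # --- CSV serialization: columns amplitude, x1[, x2]; one row per spike ---

    def to_frame(self) -> pd.DataFrame:
        cols = {"amplitude": self.amplitudes}
        for ax in range(self.domain.d):
            cols[f"x{ax + 1}"] = self.positions[:, ax]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, domain: Domain) -> "DiscreteMeasure":
        df = pd.read_csv(path)
        pos_cols = [f"x{ax + 1}" for ax in range(domain.d)]
        return cls(df["amplitude"].to_numpy(), df[pos_cols].to_numpy(), domain)


def tv_norm(m: DiscreteMeasure) -> float:
    """Total-variation norm |m|(X) = sum_i |a_i| (the measure's mass)."""
    return float(np.sum(np.abs(m.amplitudes)))


def min_separation(m: DiscreteMeasure) -> float:
    """Minimum pairwise distance between spike positions.

    Returns +inf for empty or single-spike measures: generators use the
    value as a constraint check, so a non-raising convention is deliberate.
    """
    n = len(m)
    if n <= 1:
        return np.inf
    dist = m.domain.pairwise_distances(m.positions)
    return float(np.min(dist[np.triu_indices(n, k=1)]))


def _single_linkage_clusters(dist: np.ndarray, tol: float) -> list[list[int]]:
    """Connected components of the graph linking points at distance <= tol."""
    n = dist.shape[0]
    unseen = set(range(n))
    clusters = []
    while unseen:
        stack = [unseen.pop()]
        comp = []
        while stack:
            i = stack.pop()
            comp.append(i)
            near = [j for j in unseen if dist[i, j] <= tol]
            for j in near:
                unseen.remove(j)
            stack.extend(near)
        clusters.append(sorted(comp))
    return clusters


def _weighted_mean_position(domain: Domain, pts: np.ndarray, w: np.ndarray) -> np.ndarray:
    """|amplitude|-weighted mean, wrap-aware: displacements are taken relative
    to the first point of the cluster so tight clusters straddling a periodic
    seam average correctly."""
    if np.sum(w) <= 0:
        w = np.ones_like(w)
    ref = pts[0]
    delta = domain.diff(pts, ref[None, :])
    mean = ref + np.average(delta, axis=0, weights=w)
    return domain.wrap(mean[None, :])[0]


def prune_and_merge(
    m: DiscreteMeasure, amp_tol: float = 0.0, pos_tol: float = 0.0
) -> DiscreteMeasure:
    """Remove near-zero spikes and fuse near-duplicate ones.

    Spikes with ``|a_i| <= amp_tol`` are dropped; remaining spikes closer
    than ``pos_tol`` (single-linkage) are replaced by one spike at the
    |amplitude|-weighted mean position carrying the summed amplitude.  With
    both tolerances zero this is the identity (spikes at *exactly* equal
    positions still fuse, which leaves the measure unchanged as a measure).
    """
    if amp_tol < 0 or pos_tol < 0:
        raise ValueError("tolerances must be nonnegative")
    keep = np.abs(m.amplitudes) > amp_tol
    a, x = m.amplitudes[keep], m.positions[keep]
    if a.size == 0:
        return DiscreteMeasure.empty(m.domain)
    if pos_tol == 0.0 and len(np.unique(x, axis=0)) == len(x):
        return DiscreteMeasure(a, x, m.domain)
    dist = m.domain.pairwise_distances(x)
    clusters = _single_linkage_clusters(dist, pos_tol)
    new_a, new_x = [], []
    for comp in clusters:
        w = np.abs(a[comp])
        new_a.append(np.sum(a[comp]))
        new_x.append(_weighted_mean_position(m.domain, x[comp], w))
    return DiscreteMeasure(np.array(new_a), np.vstack(new_x), m.domain)
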