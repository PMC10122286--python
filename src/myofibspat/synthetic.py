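"""Synthetic muscle sections with known spatial structure.

Real soleus-scale sections carry roughly 1,000-2,500 fibers packed in a
quasi-hexagonal lattice with a slow majority.  The generators here emulate
that at the level the statistics see — centroid positions and type labels —
with two label mechanisms matching the two model families:

* a Gibbs sampler for the binary Markov random field (alpha controls the
  slow/fast balance, beta the like-type interaction), and
* independent labeling from a smooth probability surface p(x, y), the
  generating process of the logistic GAM.

Every generator is a pure function of its inputs and one explicit integer
seed; there is no global random state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import expit

from .geometry import NeighborNetwork
from .section_io import BinaryLabels, FiberSection

__all__ = [
    "SurfaceSpec",
    "generate_lattice_section",
    "simulate_bmrf_labels",
    "simulate_surface_section",
    "permute_labels",
    "section_with_spins",
]

logger = logging.getLogger("myofibspat")

try:  # numba accelerates the sequential Gibbs sweeps; pure-python fallback below
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class SurfaceSpec:
    """A smooth probability surface p(x, y) in [0, 1] used to label fibers."""

    kind: str
    params: dict
    func: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None

    @classmethod
    def constant(cls, p: float) -> "SurfaceSpec":
        return cls(kind="constant", params={"p": float(p)})

    @classmethod
    def linear_gradient(cls, p_min: float, p_max: float, axis: str = "x") -> "SurfaceSpec":
        """Probability linear in one coordinate from p_min to p_max."""
        return cls(kind="linear-gradient",
                   params={"p_min": float(p_min), "p_max": float(p_max), "axis": axis})

    @classmethod
    def radial(cls, p_center: float, p_edge: float) -> "SurfaceSpec":
        """Probability varying with distance from the section centroid."""
        return cls(kind="radial", params={"p_center": float(p_center), "p_edge": float(p_edge)})

    @classmethod
    def custom(cls, func: Callable[[np.ndarray, np.ndarray], np.ndarray]) -> "SurfaceSpec":
        return cls(kind="custom", params={}, func=func)

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if self.kind == "constant":
            p = np.full_like(x, self.params["p"])
        elif self.kind == "linear-gradient":
            t = x if self.params["axis"] == "x" else y
            lo, hi = t.min(), t.max()
            frac = (t - lo) / (hi - lo) if hi > lo else np.full_like(t, 0.5)
            p = self.params["p_min"] + frac * (self.params["p_max"] - self.params["p_min"])
        elif self.kind == "radial":
            cx, cy = x.mean(), y.mean()
            r = np.hypot(x - cx, y - cy)
            frac = r / r.max() if r.max() > 0 else np.zeros_like(r)
            p = self.params["p_center"] + frac * (self.params["p_edge"] - self.params["p_center"])
        elif self.kind == "custom":
            p = np.asarray(self.func(x, y), float)
        else:
            raise ValueError(f"unknown surface kind {self.kind!r}")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("surface probabilities must lie in [0, 1] over the domain")
        return p


def generate_lattice_section(
    rows: int, cols: int, jitter: float = 0.2, seed: int = 0
) -> FiberSection:
    """Jittered unit-spacing grid of centroids emulating a fiber packing.

    ``jitter`` is the maximum uniform displacement per axis as a fraction of
    the lattice spacing (0 <= jitter < 0.5 keeps points distinct).  Labels
    are the placeholder ``unlabeled``; attach labels with
    :func:`simulate_bmrf_labels` or :func:`simulate_surface_section`.
    """
    if rows * cols < 9:
        raise ValueError("need rows * cols >= 9")
    if not 0 <= jitter < 0.5:
        raise ValueError(f"jitter must be in [0, 0.5), got {jitter}")
    rng = np.random.default_rng(seed)
    gx, gy = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    x = gx.ravel()
    y = gy.ravel()
    if jitter > 0:
        x = x + rng.uniform(-jitter, jitter, x.size)
        y = y + rng.uniform(-jitter, jitter, y.size)
    labels = np.array(["unlabeled"] * (rows * cols), dtype=object)
    return FiberSection(x=x, y=y, type_label=labels, source=f"lattice({rows}x{cols})")


if _HAVE_NUMBA:

    @njit(cache=False)
    def _gibbs_sweeps(indptr, indices, z, orders, uniforms, alpha, beta):  # pragma: no cover
        n_sweeps, n = orders.shape
        for s in range(n_sweeps):
            for t in range(n):
                i = orders[s, t]
                ssum = 0.0
                for k in range(indptr[i], indptr[i + 1]):
                    ssum += z[indices[k]]
                eta = 2.0 * (alpha + beta * ssum)
                p = 1.0 / (1.0 + np.exp(-eta))
                z[i] = 1 if uniforms[s, t] < p else -1

else:  # pragma: no cover - exercised only without numba

    def _gibbs_sweeps(indptr, indices, z, orders, uniforms, alpha, beta):
        n_sweeps, n = orders.shape
        for s in range(n_sweeps):
            for t in range(n):
                i = orders[s, t]
                ssum = float(z[indices[indptr[i]: indptr[i + 1]]].sum())
                p = 1.0 / (1.0 + np.exp(-2.0 * (alpha + beta * ssum)))
                z[i] = 1 if uniforms[s, t] < p else -1


def simulate_bmrf_labels(
    network: NeighborNetwork,
    alpha: float,
    beta: float,
    n_sweeps: int = 500,
    seed: int = 0,
) -> BinaryLabels:
    """Gibbs-sample spins from the binary Markov random field on a network.

    Each sweep visits every fiber once in random order and resamples its
    spin from Pr(Z_i = +1 | rest) = sigma(2 alpha + 2 beta S_i).  The
    default 500 sweeps comfortably exceeds the mixing time for the weak
    interactions (|beta| < 0.1) typical of real sections; the final state is
    returned.
    """
    if n_sweeps < 100:
        raise ValueError(f"n_sweeps must be at least 100 (burn-in guidance), got {n_sweeps}")
    if abs(beta) > 1:
        warnings.warn(
            f"|beta|={abs(beta):.3g} > 1: near-critical/frozen regime; "
            "Gibbs mixing may be very slow", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n = network.n
    z = np.where(rng.random(n) < expit(2.0 * alpha), 1, -1).astype(np.int8)
    adj = network.adjacency()
    orders = np.argsort(rng.random((n_sweeps, n)), axis=1).astype(np.int64)
    uniforms = rng.random((n_sweeps, n))
    _gibbs_sweeps(adj.indptr.astype(np.int64), adj.indices.astype(np.int64),
                  z, orders, uniforms, float(alpha), float(beta))
    return BinaryLabels.from_spins(z)


def simulate_surface_section(
    points: FiberSection,
    spec: SurfaceSpec,
    seed: int = 0,
    fast_label: str = "fast",
    slow_label: str = "slow",
) -> FiberSection:
    """Label fibers independently: fast with probability p(x_i, y_i)."""
    rng = np.random.default_rng(seed)
    p = spec.evaluate(points.x, points.y)
    fast = rng.random(points.n) < p
    labels = np.where(fast, fast_label, slow_label).astype(object)
    return FiberSection(x=points.x, y=points.y, type_label=labels, source=points.source)


def section_with_spins(
    points: FiberSection,
    labels: BinaryLabels,
    fast_label: str = "fast",
    slow_label: str = "slow",
) -> FiberSection:
    """Attach spin labels to a point set as a labeled section."""
    names = np.where(labels.z == 1, fast_label, slow_label).astype(object)
    return FiberSection(x=points.x, y=points.y, type_label=names, source=points.source)


def permute_labels(labels: BinaryLabels, seed: int = 0) -> BinaryLabels:
    """Uniformly random permutation of the spins (type counts preserved)."""
    rng = np.random.default_rng(seed)
    return BinaryLabels(z=rng.permutation(labels.z),
                        n_slow=labels.n_slow, n_fast=labels.n_fast)
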