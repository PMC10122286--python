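"""Penalized logistic and multinomial GAMs over fiber coordinates.

The probability ``p_i`` that fiber ``i`` at coordinate ``(x_i, y_i)`` is of
a chosen type is modeled through a logistic generalized additive model

    log(p_i / (1 - p_i)) = b0 + b1 x_i + b2 y_i + sum_{k>=3} b_k B_k(x_i, y_i)

where the ``B_k`` form a low-rank thin-plate regression spline basis built
from the radial kernel eta(r) = r^2 log r on centered, RMS-scaled
coordinates.  The affine terms (intercept, x, y) span the unpenalized null
space; the wiggly coefficients carry a quadratic roughness penalty with
smoothing parameter ``lambda``, selected by a Laplace-approximate REML
criterion (default) or GCV over a log grid refined by golden-section
search.  Fitting is penalized IRLS.

The multinomial extension shares one basis across C - 1 linear predictors
against a reference type (the most frequent), each with its own lambda, and
maps to per-type probabilities through the softmax; with two types it
reduces exactly to the binary logistic GAM.

Unlike the network-based statistics, the GAM never uses the neighbor
network: smoothing alone makes nearby fibers informative about each other.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import scipy.linalg as sla
import shapely
from scipy.optimize import minimize
from scipy.special import expit
from shapely.geometry import Polygon

from .section_io import DegenerateSectionError, FiberSection, encode_binary

__all__ = [
    "BasisSet",
    "GamFit",
    "MultiGamFit",
    "ProbabilitySurface",
    "default_basis_dim",
    "build_tprs_basis",
    "fit_logistic_gam",
    "select_lambda",
    "predict_probability_grid",
    "fit_multinomial_gam",
]

logger = logging.getLogger("myofibspat")

LAMBDA_GRID = np.logspace(-4, 8, 25)
PIRLS_TOL = 1e-10
PIRLS_MAX_ITER = 200


def default_basis_dim(n: int) -> int:
    """Default basis dimension: min(30, n // 4) + 3."""
    return min(30, n // 4) + 3


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r)
    pos = r > 0
    rp = r[pos]
    out[pos] = rp * rp * np.log(rp)
    return out


def _farthest_point_knots(pts: np.ndarray, k: int) -> np.ndarray:
    """Deterministic space-filling subset of k points (farthest-point order)."""
    n = len(pts)
    center = pts.mean(axis=0)
    start = int(np.argmin(((pts - center) ** 2).sum(axis=1)))
    chosen = [start]
    d = ((pts - pts[start]) ** 2).sum(axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, ((pts - pts[nxt]) ** 2).sum(axis=1))
    return pts[np.array(chosen)]


@dataclass(frozen=True)
class BasisSet:
    """Thin-plate regression spline basis evaluated at the training fibers.

    ``design`` is n x K = [1, x~, y~, wiggly columns] on standardized
    coordinates; ``penalty`` is K x K, zero on the affine block.  The stored
    knots and null-space projector allow exact re-evaluation at new
    coordinates.
    """

    design: np.ndarray
    penalty: np.ndarray
    K: int
    center: np.ndarray
    scale: float
    knots: np.ndarray | None  # standardized knot coordinates (K knots) or None for K=3
    Z: np.ndarray | None  # (K, K-3) null-space projector of the knot polynomial

    def standardize(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords, dtype=np.float64) - self.center) / self.scale

    def evaluate(self, coords: np.ndarray) -> np.ndarray:
        """Design matrix of the basis at arbitrary coordinates."""
        sc = self.standardize(coords)
        cols = [np.ones(len(sc)), sc[:, 0], sc[:, 1]]
        if self.knots is not None:
            r = np.sqrt(((sc[:, None, :] - self.knots[None, :, :]) ** 2).sum(axis=2))
            cols.append(_tps_kernel(r) @ self.Z)
            return np.column_stack(cols[:3] + [cols[3]])
        return np.column_stack(cols)

    @property
    def penalty_rank(self) -> int:
        return self.K - 3


def build_tprs_basis(coords: np.ndarray, K: int) -> BasisSet:
    """Low-rank thin-plate spline basis of dimension K at the given points.

    K = 3 gives the pure GLM design [1, x, y] with a zero penalty.  For
    K > 3, K knots are chosen by deterministic farthest-point sampling, the
    radial kernel columns are projected onto the orthocomplement of the
    affine polynomials at the knots (so the penalty block Z' E Z is positive
    definite), and the penalty is zero on the affine terms.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = len(coords)
    if K < 3:
        raise ValueError(f"basis dimension K must be >= 3, got {K}")
    if K > n:
        raise ValueError(f"basis dimension K={K} exceeds the number of points n={n}")
    if len(np.unique(coords[:, 0] + 1j * coords[:, 1])) < n:
        warnings.warn("duplicate coordinates; consider jittering the input", stacklevel=2)
    center = coords.mean(axis=0)
    centered = coords - center
    scale = float(np.sqrt((centered**2).sum(axis=1).mean()))
    if scale <= 0:
        raise ValueError("all coordinates identical; no spatial basis exists")
    sc = centered / scale

    if K == 3:
        design = np.column_stack([np.ones(n), sc[:, 0], sc[:, 1]])
        return BasisSet(
            design=design, penalty=np.zeros((3, 3)), K=3,
            center=center, scale=scale, knots=None, Z=None,
        )

    uniq = np.unique(sc, axis=0)
    knots = _farthest_point_knots(uniq, min(K, len(uniq)))
    if len(knots) < K:
        raise ValueError("not enough distinct points for the requested basis dimension")
    Tk = np.column_stack([np.ones(K), knots[:, 0], knots[:, 1]])
    Z = sla.null_space(Tk.T)  # (K, K-3)
    rk = np.sqrt(((knots[:, None, :] - knots[None, :, :]) ** 2).sum(axis=2))
    Ekk = _tps_kernel(rk)
    S_block = Z.T @ Ekk @ Z
    S_block = (S_block + S_block.T) / 2.0
    penalty = np.zeros((K, K))
    penalty[3:, 3:] = S_block
    basis = BasisSet(
        design=np.empty(0), penalty=penalty, K=K,
        center=center, scale=scale, knots=knots, Z=Z,
    )
    object.__setattr__(basis, "design", basis.evaluate(coords))
    return basis


@dataclass(frozen=True)
class GamFit:
    """A fitted logistic GAM: coefficients, smoothing level, basis."""

    beta: np.ndarray
    lam: float
    basis: BasisSet
    edf: float
    converged: bool
    criterion: str
    criterion_value: float
    fast_labels: tuple = ()

    def linear_predictor(self, coords: np.ndarray) -> np.ndarray:
        return self.basis.evaluate(coords) @ self.beta

    def predict(self, coords: np.ndarray) -> np.ndarray:
        """Probability of the modeled (fast) type at the given coordinates."""
        return expit(self.linear_predictor(coords))

    @property
    def fitted_probabilities(self) -> np.ndarray:
        return expit(self.basis.design @ self.beta)


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _pirls(
    X: np.ndarray,
    S: np.ndarray,
    y: np.ndarray,
    lam: float,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, bool, float, np.ndarray]:
    """Penalized IRLS for the Bernoulli GAM at fixed lambda.

    Returns (beta, converged, edf, XtWX) at the optimum of
    l(beta) - lam/2 beta' S beta.
    """
    n, K = X.shape
    beta = np.zeros(K) if beta0 is None else beta0.copy()
    lamS = lam * S

    def pen_ll(b):
        return _bernoulli_loglik(y, X @ b) - 0.5 * lam * float(b @ S @ b)

    current = pen_ll(beta)
    converged = False
    for _ in range(PIRLS_MAX_ITER):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        grad = X.T @ (y - p) - lamS @ beta
        if np.linalg.norm(grad) < PIRLS_TOL * max(1.0, n * 1e-3):
            converged = True
            break
        XtWX = (X.T * w) @ X
        A = XtWX + lamS
        try:
            c, low = sla.cho_factor(A)
            step = sla.cho_solve((c, low), grad)
        except sla.LinAlgError:
            step = sla.solve(A + 1e-8 * np.eye(K) * max(np.trace(A) / K, 1.0), grad)
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            val = pen_ll(cand)
            if val >= current - 1e-12:
                break
            t /= 2.0
        beta = beta + t * step
        current = pen_ll(beta)
    p = expit(X @ beta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    XtWX = (X.T * w) @ X
    A = XtWX + lamS
    try:
        edf = float(np.trace(sla.solve(A, XtWX, assume_a="pos")))
    except sla.LinAlgError:  # pragma: no cover
        edf = float(np.trace(np.linalg.lstsq(A, XtWX, rcond=None)[0]))
    return beta, converged, edf, XtWX


def _criterion_value(
    lam: float,
    X: np.ndarray,
    S: np.ndarray,
    y: np.ndarray,
    criterion: str,
    rank_S: int,
    beta0: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    beta, _, edf, XtWX = _pirls(X, S, y, lam, beta0=beta0)
    n = len(y)
    ll = _bernoulli_loglik(y, X @ beta)
    if criterion == "GCV":
        dev = -2.0 * ll
        val = n * dev / (n - edf) ** 2
    elif criterion == "REML":
        # negative Laplace-approximate REML, constants in lambda dropped
        pen_ll = ll - 0.5 * lam * float(beta @ S @ beta)
        sign, logdet = np.linalg.slogdet(XtWX + lam * S)
        if sign <= 0:  # pragma: no cover - PD by construction
            logdet = np.inf
        val = -pen_ll - 0.5 * rank_S * np.log(lam) + 0.5 * logdet
    else:
        raise ValueError(f"unknown criterion {criterion!r} (use 'REML' or 'GCV')")
    return float(val), beta


def _select_lambda_core(
    X: np.ndarray, S: np.ndarray, y: np.ndarray, criterion: str, rank_S: int
) -> tuple[float, float]:
    """Grid search + golden-section refinement; returns (lambda, criterion value)."""
    if rank_S == 0:
        return 0.0, float("nan")  # K=3: the penalty is identically zero
    vals = []
    beta0 = None
    for lam in LAMBDA_GRID:
        v, beta0 = _criterion_value(lam, X, S, y, criterion, rank_S, beta0=beta0)
        vals.append(v)
    vals = np.asarray(vals)
    best = int(np.argmin(vals))
    if best in (0, len(LAMBDA_GRID) - 1):
        warnings.warn(
            f"{criterion} criterion is minimized at the lambda search boundary "
            f"({LAMBDA_GRID[best]:.3g}); returning the boundary value",
            stacklevel=2,
        )
        return float(LAMBDA_GRID[best]), float(vals[best])
    # golden-section search on log(lambda) between the neighbors of the best
    lo = np.log(LAMBDA_GRID[best - 1])
    hi = np.log(LAMBDA_GRID[best + 1])
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _criterion_value(np.exp(c), X, S, y, criterion, rank_S)[0]
    fd = _criterion_value(np.exp(d), X, S, y, criterion, rank_S)[0]
    for _ in range(40):
        if b - a < 1e-3:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _criterion_value(np.exp(c), X, S, y, criterion, rank_S)[0]
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _criterion_value(np.exp(d), X, S, y, criterion, rank_S)[0]
    lam = float(np.exp((a + b) / 2.0))
    return lam, _criterion_value(lam, X, S, y, criterion, rank_S)[0]


def select_lambda(
    section: FiberSection,
    basis: BasisSet,
    criterion: str = "REML",
    fast_labels: Iterable[str] | None = None,
    y: np.ndarray | None = None,
) -> float:
    """Data-driven smoothing parameter for the logistic GAM.

    Provide either ``fast_labels`` (labels mapping to the modeled type) or a
    binary response vector ``y`` directly.  Deterministic given the data.
    """
    if y is None:
        if fast_labels is None:
            raise ValueError("provide fast_labels or y")
        labels = encode_binary(section, fast_labels)
        y = (labels.z.astype(np.float64) + 1.0) / 2.0
    lam, _ = _select_lambda_core(basis.design, basis.penalty, np.asarray(y, float),
                                 criterion, basis.penalty_rank)
    return lam


def fit_logistic_gam(
    section: FiberSection,
    fast_labels: Iterable[str],
    K: int | None = None,
    lam: float | str = "auto",
    criterion: str = "REML",
) -> GamFit:
    """Fit the logistic GAM for the probability of the fast type.

    ``lam='auto'`` selects the smoothing parameter by the given criterion;
    a numeric ``lam`` fixes it (the web-app style manual mode).
    """
    labels = encode_binary(section, fast_labels)
    y = (labels.z.astype(np.float64) + 1.0) / 2.0
    n = section.n
    if K is None:
        K = default_basis_dim(n)
    if n <= K:
        raise ValueError(f"need n > K (got n={n}, K={K})")
    basis = build_tprs_basis(section.coords, K)
    crit_val = np.nan
    if lam == "auto":
        lam, crit_val = _select_lambda_core(basis.design, basis.penalty, y,
                                            criterion, basis.penalty_rank)
    elif not isinstance(lam, (int, float)):
        raise ValueError(f"lam must be 'auto' or a number, got {lam!r}")
    beta, converged, edf, _ = _pirls(basis.design, basis.penalty, y, float(lam))
    if not converged:
        logger.warning("penalized IRLS did not reach gradient tolerance (lambda=%g)", lam)
    return GamFit(
        beta=beta, lam=float(lam), basis=basis, edf=edf, converged=converged,
        criterion=criterion, criterion_value=float(crit_val),
        fast_labels=tuple(sorted(str(t) for t in fast_labels)),
    )


@dataclass(frozen=True)
class ProbabilitySurface:
    """Type probability evaluated on a regular grid, masked to the section."""

    grid_x: np.ndarray  # (res,) ascending
    grid_y: np.ndarray  # (res,) ascending
    prob: np.ndarray  # (res, res), [0,1] inside the mask, NaN outside
    mask: np.ndarray  # (res, res) bool, True inside the boundary

    def to_frame(self):
        """Long-format DataFrame (grid_x, grid_y, prob) of in-mask points."""
        import pandas as pd

        gx, gy = np.meshgrid(self.grid_x, self.grid_y, indexing="xy")
        m = self.mask
        return pd.DataFrame({"grid_x": gx[m], "grid_y": gy[m], "prob": self.prob[m]})


def _grid_and_mask(boundary: Polygon, resolution: int):
    x0, y0, x1, y1 = boundary.bounds
    gx = np.linspace(x0, x1, resolution)
    gy = np.linspace(y0, y1, resolution)
    mx, my = np.meshgrid(gx, gy, indexing="xy")
    pts = np.column_stack([mx.ravel(), my.ravel()])
    mask = shapely.covers(boundary, shapely.points(pts)).reshape(resolution, resolution)
    return gx, gy, pts, mask


def predict_probability_grid(
    fit: GamFit, boundary: Polygon, resolution: int = 100
) -> ProbabilitySurface:
    """Evaluate the fitted probability surface on a grid inside the boundary."""
    gx, gy, pts, mask = _grid_and_mask(boundary, resolution)
    prob = np.full(mask.size, np.nan)
    flat = mask.ravel()
    if flat.any():
        prob[flat] = fit.predict(pts[flat])
    return ProbabilitySurface(grid_x=gx, grid_y=gy,
                              prob=prob.reshape(mask.shape), mask=mask)


# ---------------------------------------------------------------------------
# Multinomial GAM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultiGamFit:
    """Multinomial GAM: one shared basis, C-1 predictors vs a reference type."""

    types: tuple  # all types, reference first
    basis: BasisSet
    coef: np.ndarray  # (C-1, K) coefficients of the non-reference types
    lambdas: tuple
    converged: bool

    @property
    def reference(self) -> str:
        return self.types[0]

    def predict_proba(self, coords: np.ndarray) -> np.ndarray:
        """(n_points, C) probabilities, columns ordered as ``types``."""
        X = self.basis.evaluate(coords)
        eta = np.column_stack([np.zeros(len(X))] + [X @ b for b in self.coef])
        eta -= eta.max(axis=1, keepdims=True)
        e = np.exp(eta)
        return e / e.sum(axis=1, keepdims=True)

    def probability_grids(
        self, boundary: Polygon, resolution: int = 100
    ) -> dict[str, ProbabilitySurface]:
        gx, gy, pts, mask = _grid_and_mask(boundary, resolution)
        flat = mask.ravel()
        proba = self.predict_proba(pts[flat]) if flat.any() else np.zeros((0, len(self.types)))
        out = {}
        for c, t in enumerate(self.types):
            prob = np.full(mask.size, np.nan)
            prob[flat] = proba[:, c]
            out[t] = ProbabilitySurface(grid_x=gx, grid_y=gy,
                                        prob=prob.reshape(mask.shape), mask=mask)
        return out


def fit_multinomial_gam(
    section: FiberSection,
    K: int | None = None,
    lam: float | str = "auto",
    criterion: str = "REML",
) -> MultiGamFit:
    """Multinomial GAM over all fiber types of the section.

    The reference category is the most frequent type.  Each non-reference
    type gets its own smoothing parameter, selected on its one-vs-rest
    binary fit; coefficients are then jointly estimated by maximizing the
    penalized multinomial log-likelihood.  With exactly two types this is
    the binary logistic GAM (identical coefficients and lambda).
    """
    types = section.types  # most frequent first
    if len(types) < 2:
        raise DegenerateSectionError("need at least two fiber types")
    counts = section.type_counts
    n = section.n
    if K is None:
        K = default_basis_dim(n)
    min_count = min(counts.values())
    if min_count < max(K, 4) / 2:
        newK = max(4, int(2 * min_count))
        warnings.warn(
            f"smallest type has {min_count} fibers; reducing basis dimension "
            f"K from {K} to {newK}", stacklevel=2,
        )
        K = newK
    if min_count < 10:
        warnings.warn(
            f"a type has only {min_count} fibers; its surface will be unstable",
            stacklevel=2,
        )

    if len(types) == 2:
        bfit = fit_logistic_gam(section, fast_labels={types[1]}, K=K, lam=lam,
                                criterion=criterion)
        return MultiGamFit(
            types=types, basis=bfit.basis, coef=bfit.beta[None, :],
            lambdas=(bfit.lam,), converged=bfit.converged,
        )

    basis = build_tprs_basis(section.coords, K)
    X = basis.design
    S = basis.penalty
    norm = np.array([str(t).strip().casefold() for t in section.type_label], dtype=object)
    Y = np.column_stack([(norm == str(t).strip().casefold()).astype(float) for t in types])

    lambdas = []
    inits = []
    for c, t in enumerate(types[1:], start=1):
        if lam == "auto":
            lam_c, _ = _select_lambda_core(X, S, Y[:, c], criterion, basis.penalty_rank)
        else:
            lam_c = float(lam)
        lambdas.append(lam_c)
        beta_c, _, _, _ = _pirls(X, S, Y[:, c], lam_c)
        inits.append(beta_c)

    Kdim = X.shape[1]
    C1 = len(types) - 1
    lam_arr = np.asarray(lambdas)

    def negloglik(theta):
        B = theta.reshape(C1, Kdim)
        eta = np.column_stack([np.zeros(n)] + [X @ b for b in B])
        mx = eta.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(eta - mx).sum(axis=1))
        ll = float((Y[:, 1:] * eta[:, 1:]).sum() - lse.sum())
        pen = 0.5 * float(sum(lam_arr[c] * B[c] @ S @ B[c] for c in range(C1)))
        P = np.exp(eta - lse[:, None])
        grad = np.empty((C1, Kdim))
        for c in range(C1):
            grad[c] = X.T @ (Y[:, c + 1] - P[:, c + 1]) - lam_arr[c] * (S @ B[c])
        return -(ll - pen), -grad.ravel()

    theta0 = np.vstack(inits).ravel()
    res = minimize(negloglik, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9})
    coef = res.x.reshape(C1, Kdim)
    if not res.success:
        logger.warning("multinomial GAM optimizer stopped: %s", res.message)
    return MultiGamFit(types=types, basis=basis, coef=coef,
                       lambdas=tuple(float(v) for v in lambdas), converged=bool(res.success))
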