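"""Weighted bivariate kernel niches on shared grids.

A species' habitat niche in a pair of ordination axes is a weighted
two-dimensional kernel density estimate with a bivariate normal kernel and
an unconstrained (full-matrix) plug-in bandwidth.  All densities that are
ever compared are evaluated at the same regular grid of cell centres, so
that the three niche statistics are commensurable across site-years:

* overlap  — integral of the pointwise minimum of two densities;
* breadth  — number of grid cells inside the 95% highest-density region;
* position — cell-centre coordinates of the density maximum.

The bandwidth selector is a plug-in minimiser of the asymptotic MISE
surrogate: data are sphered, fourth-order integrated density-derivative
functionals are estimated with a normal-scale pilot, and the criterion is
minimised over symmetric positive-definite matrices through a
log-Cholesky parametrisation.  Failure of the optimisation falls back to
the d=2 normal-scale matrix ``n_eff^(-1/3) * cov`` with a warning.
Weights enter through weighted moments and the effective sample size
``n_eff = (sum w)^2 / sum(w^2)``, so uniformly scaling all weights
changes nothing.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

DEFAULT_RESOLUTION = 151
DEFAULT_PADDING = 0.15
DEFAULT_HDR_LEVEL = 0.95
MIN_KDE_POINTS = 10  # five observations per dimension, two dimensions
MIN_CAPTURED_MASS = 0.9
_CUTOFF_SD = 8.6  # kernel support truncation; exp(-37) ~ 8e-17, below eps


class InsufficientObservationsError(ValueError):
    """Too few observations to estimate a bandwidth (site-year is named)."""

    def __init__(self, n: int, minimum: int, context: str = ""):
        self.n, self.minimum, self.context = n, minimum, context
        where = f" [{context}]" if context else ""
        super().__init__(
            f"need >= {minimum} observations for a 2-D KDE, got {n}{where}"
        )


class GridExtentError(ValueError):
    """The evaluation grid captures too little probability mass."""


class ComparabilityError(ValueError):
    """Two densities on different grids cannot be compared."""


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Grid2D:
    """Regular grid of cell centres shared by all compared densities."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    resolution: int

    def __post_init__(self) -> None:
        if self.resolution < 32:
            raise ValueError("grid resolution must be >= 32 cells per axis")
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("grid extent is degenerate")

    @property
    def x_centers(self) -> np.ndarray:
        return np.linspace(self.xmin, self.xmax, self.resolution)

    @property
    def y_centers(self) -> np.ndarray:
        return np.linspace(self.ymin, self.ymax, self.resolution)

    @property
    def dx(self) -> float:
        return (self.xmax - self.xmin) / (self.resolution - 1)

    @property
    def dy(self) -> float:
        return (self.ymax - self.ymin) / (self.resolution - 1)

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    @property
    def shape(self) -> tuple[int, int]:
        return (self.resolution, self.resolution)

    def hash(self) -> str:
        payload = f"{self.xmin:.12e}|{self.xmax:.12e}|{self.ymin:.12e}|{self.ymax:.12e}|{self.resolution}"
        return hashlib.md5(payload.encode()).hexdigest()


def make_common_grid(
    scores: np.ndarray,
    resolution: int = DEFAULT_RESOLUTION,
    padding_fraction: float = DEFAULT_PADDING,
) -> Grid2D:
    """Grid spanning the pooled score range of one axis pair, expanded by
    ``padding_fraction`` of the range on each side."""
    s = np.asarray(scores, dtype=float)
    if s.ndim != 2 or s.shape[1] != 2:
        raise ValueError("scores must be an (n, 2) array")
    lo = s.min(axis=0)
    hi = s.max(axis=0)
    rng = hi - lo
    if (rng <= 0).any():
        raise ValueError("degenerate (zero-range) axis; cannot build a grid")
    lo = lo - padding_fraction * rng
    hi = hi + padding_fraction * rng
    return Grid2D(
        xmin=float(lo[0]), xmax=float(hi[0]), ymin=float(lo[1]), ymax=float(hi[1]),
        resolution=int(resolution),
    )


# ---------------------------------------------------------------------------
# plug-in bandwidth
# ---------------------------------------------------------------------------


def _normalized_weights(n: int, weights) -> np.ndarray:
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights must match the number of points")
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        w = w / w.sum()
    return w


def _weighted_moments(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = w @ x
    d = x - mu
    cov = (d * w[:, None]).T @ d
    return mu, cov


def _psi4_functionals(y: np.ndarray, w: np.ndarray, g: float) -> dict[str, float]:
    """Estimates of the order-4 integrated density-derivative functionals
    psi_(a,b) on (sphered) data, Gaussian pilot ``g^2 I``, all pairs
    including the diagonal."""
    n = len(y)
    psi = {k: 0.0 for k in ("40", "31", "22", "13", "04")}
    norm = 1.0 / (2.0 * np.pi * g * g)
    g4 = g**-4
    block = max(1, int(4e6 // max(n, 1)))
    for i0 in range(0, n, block):
        i1 = min(n, i0 + block)
        du = (y[i0:i1, None, 0] - y[None, :, 0]) / g
        dv = (y[i0:i1, None, 1] - y[None, :, 1]) / g
        phi = np.exp(-0.5 * (du * du + dv * dv)) * norm
        ww = w[i0:i1, None] * w[None, :]
        wphi = ww * phi
        he2u = du * du - 1.0
        he2v = dv * dv - 1.0
        he3u = du * (du * du - 3.0)
        he3v = dv * (dv * dv - 3.0)
        he4u = du**4 - 6.0 * du * du + 3.0
        he4v = dv**4 - 6.0 * dv * dv + 3.0
        psi["40"] += float((wphi * he4u).sum())
        psi["04"] += float((wphi * he4v).sum())
        psi["31"] += float((wphi * he3u * dv).sum())
        psi["13"] += float((wphi * du * he3v).sum())
        psi["22"] += float((wphi * he2u * he2v).sum())
    return {k: v * g4 for k, v in psi.items()}


def _pi_criterion(h11, h12, h22, psi, n_eff):
    det = h11 * h22 - h12 * h12
    var_term = 1.0 / (4.0 * np.pi * n_eff * np.sqrt(det))
    bias = (
        h11 * h11 * psi["40"]
        + h22 * h22 * psi["04"]
        + (4.0 * h12 * h12 + 2.0 * h11 * h22) * psi["22"]
        + 4.0 * h11 * h12 * psi["31"]
        + 4.0 * h12 * h22 * psi["13"]
    )
    return var_term + 0.25 * bias


def normal_scale_bandwidth(points: np.ndarray, weights=None) -> np.ndarray:
    """d=2 normal-reference bandwidth ``n_eff^(-1/3) * cov``."""
    x = np.asarray(points, dtype=float)
    w = _normalized_weights(len(x), weights)
    n_eff = 1.0 / np.sum(w * w)
    _, cov = _weighted_moments(x, w)
    return n_eff ** (-1.0 / 3.0) * cov


def plugin_bandwidth(
    points: np.ndarray,
    weights=None,
    min_points: int = MIN_KDE_POINTS,
    context: str = "",
) -> np.ndarray:
    """Unconstrained plug-in bandwidth matrix for a 2-D weighted sample.

    Sphering makes the selector exactly equivariant under linear maps of
    the data (in particular, scaling the data by c scales H by c^2).
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if not np.isfinite(x).all():
        raise ValueError("points must be finite")
    n = len(x)
    if n < min_points:
        raise InsufficientObservationsError(n, min_points, context)
    w = _normalized_weights(n, weights)
    n_eff = 1.0 / np.sum(w * w)
    mu, cov = _weighted_moments(x, w)

    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        warnings.warn(
            f"singular sample covariance{' [' + context + ']' if context else ''}; "
            "using regularized normal-scale bandwidth",
            stacklevel=2,
        )
        cov = cov + 1e-12 * np.eye(2) * max(np.trace(cov), 1e-12)
        return n_eff ** (-1.0 / 3.0) * cov

    y = np.linalg.solve(chol, (x - mu).T).T  # sphered: unit covariance

    # normal-scale pilot for order-4 functionals (d=2, |r|=4)
    g = (2.0 / ((2 + 4) * n_eff)) ** (1.0 / 8.0)
    psi = _psi4_functionals(y, w, g)

    s_ns = n_eff ** (-1.0 / 6.0)  # Cholesky scale of the normal-scale H
    lo, hi = np.log(s_ns) + np.log(0.02), np.log(s_ns) + np.log(50.0)

    def objective(theta):
        t0, t1, t2 = theta
        if not (lo <= t0 <= hi and lo <= t1 <= hi) or abs(t2) > 50.0 * s_ns:
            return 1e12
        l11 = np.exp(t0)
        l22 = np.exp(t1)
        h11 = l11 * l11
        h12 = l11 * t2
        h22 = t2 * t2 + l22 * l22
        val = _pi_criterion(h11, h12, h22, psi, n_eff)
        return val if np.isfinite(val) else 1e12

    theta0 = np.array([np.log(s_ns), np.log(s_ns), 0.0])
    res = optimize.minimize(
        objective,
        theta0,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 400},
    )
    ok = res.success and np.isfinite(res.fun)
    if ok:
        t0, t1, t2 = res.x
        near_bound = (
            min(t0 - lo, hi - t0) < 1e-6 or min(t1 - lo, hi - t1) < 1e-6
        )
        ok = not near_bound
    if not ok:
        warnings.warn(
            f"plug-in bandwidth optimization failed"
            f"{' [' + context + ']' if context else ''}; "
            "falling back to the normal-scale matrix",
            stacklevel=2,
        )
        return n_eff ** (-1.0 / 3.0) * cov

    l11, l22, l21 = np.exp(res.x[0]), np.exp(res.x[1]), res.x[2]
    h_y = np.array(
        [[l11 * l11, l11 * l21], [l11 * l21, l21 * l21 + l22 * l22]]
    )
    h = chol @ h_y @ chol.T
    return 0.5 * (h + h.T)


# ---------------------------------------------------------------------------
# evaluation + HDR
# ---------------------------------------------------------------------------


@dataclass
class DensityGrid:
    """A weighted KDE (or any density) evaluated on a shared grid, with
    its 95% highest-density-region mask."""

    grid: Grid2D
    density: np.ndarray  # (ny, nx), y-major
    H: np.ndarray | None
    n_obs: int
    total_weight: float
    hdr_mask: np.ndarray = field(default=None, repr=False)
    hdr_threshold: float = np.nan
    hdr_level: float = DEFAULT_HDR_LEVEL
    axis_pair: str = ""
    key: tuple = ()

    @property
    def mass(self) -> float:
        return float(self.density.sum() * self.grid.cell_area)


def hdr_mask(
    density: np.ndarray, grid: Grid2D, level: float = DEFAULT_HDR_LEVEL
) -> tuple[np.ndarray, float]:
    """Highest-density region at the given probability level.

    Cells are sorted by density (descending) and accumulated until their
    mass reaches ``level``; the boundary cell is included and its density
    is the returned threshold.  If ``level`` exceeds the mass captured by
    the grid, every positive-density cell is masked.
    """
    if not 0 < level <= 1:
        raise ValueError("HDR level must be in (0, 1]")
    flat = density.ravel()
    order = np.argsort(-flat, kind="stable")
    masses = flat[order] * grid.cell_area
    cum = np.cumsum(masses)
    total = cum[-1]
    if level >= total:
        mask = flat > 0
        threshold = float(flat[mask].min()) if mask.any() else 0.0
    else:
        stop = int(np.searchsorted(cum, level, side="left"))
        mask = np.zeros(flat.shape, dtype=bool)
        mask[order[: stop + 1]] = True
        threshold = float(flat[order[stop]])
    return mask.reshape(density.shape), threshold


def evaluate_kde(
    points: np.ndarray,
    weights,
    H: np.ndarray,
    grid: Grid2D,
    level: float = DEFAULT_HDR_LEVEL,
    axis_pair: str = "",
    key: tuple = (),
    min_mass: float = MIN_CAPTURED_MASS,
) -> DensityGrid:
    """Weighted Gaussian-kernel density on the grid cell centres.

    ``f(x) = sum_i w_i K_H(x - x_i) / sum_i w_i``.  Kernel tails are
    truncated beyond 8.6 standard deviations, which is below double
    precision resolution, so the evaluation is numerically exact.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if not np.isfinite(x).all():
        raise ValueError("points must be finite")
    H = np.asarray(H, dtype=float)
    try:
        chol = np.linalg.cholesky(H)
    except np.linalg.LinAlgError as e:
        raise ValueError("bandwidth matrix must be symmetric positive definite") from e
    w = _normalized_weights(len(x), weights)

    linv = np.linalg.inv(chol)
    norm = 1.0 / (2.0 * np.pi * chol[0, 0] * chol[1, 1])
    xc = grid.x_centers
    yc = grid.y_centers
    ny = nx = grid.resolution
    density = np.zeros((ny, nx))

    lam_max = np.linalg.eigvalsh(H).max()
    r = _CUTOFF_SD * np.sqrt(lam_max)
    window_cells = (min(2 * r / grid.dx, nx)) * (min(2 * r / grid.dy, ny))
    if window_cells >= 0.5 * nx * ny:
        # windows cover most of the grid: blocked full evaluation
        gx = np.broadcast_to(xc[None, :], (ny, nx)).ravel()
        gy = np.broadcast_to(yc[:, None], (ny, nx)).ravel()
        flat = np.zeros(nx * ny)
        block = max(1, int(8e6 // (nx * ny)))
        for i0 in range(0, len(x), block):
            i1 = min(len(x), i0 + block)
            dx = gx[None, :] - x[i0:i1, 0][:, None]
            dy = gy[None, :] - x[i0:i1, 1][:, None]
            u1 = linv[0, 0] * dx
            u2 = linv[1, 0] * dx + linv[1, 1] * dy
            q = u1 * u1 + u2 * u2
            np.clip(q, None, 2.0 * _CUTOFF_SD**2, out=q)
            flat += w[i0:i1] @ np.exp(-0.5 * q)
        density = flat.reshape(ny, nx)
    else:
        for i in range(len(x)):
            px, py = x[i]
            ix0 = int(np.searchsorted(xc, px - r, side="left"))
            ix1 = int(np.searchsorted(xc, px + r, side="right"))
            iy0 = int(np.searchsorted(yc, py - r, side="left"))
            iy1 = int(np.searchsorted(yc, py + r, side="right"))
            if ix0 >= ix1 or iy0 >= iy1:
                continue
            dx = xc[ix0:ix1] - px
            dy = yc[iy0:iy1] - py
            u1 = linv[0, 0] * dx[None, :]
            u2 = linv[1, 0] * dx[None, :] + linv[1, 1] * dy[:, None]
            q = u1 * u1 + u2 * u2
            density[iy0:iy1, ix0:ix1] += w[i] * np.exp(-0.5 * q)
    density *= norm

    mass = density.sum() * grid.cell_area
    if mass < min_mass:
        raise GridExtentError(
            f"grid captures only {mass:.3f} of the probability mass; "
            "enlarge the grid extent or padding"
        )
    if mass < 0.98:
        warnings.warn(
            f"grid captures {mass:.3f} < 0.98 of the probability mass", stacklevel=2
        )
    mask, thr = hdr_mask(density, grid, level)
    return DensityGrid(
        grid=grid,
        density=density,
        H=H,
        n_obs=len(x),
        total_weight=float(np.asarray(weights, dtype=float).sum()) if weights is not None else float(len(x)),
        hdr_mask=mask,
        hdr_threshold=thr,
        hdr_level=level,
        axis_pair=axis_pair,
        key=key,
    )


def density_grid_from_values(
    values: np.ndarray, grid: Grid2D, level: float = DEFAULT_HDR_LEVEL, key: tuple = ()
) -> DensityGrid:
    """Wrap an externally computed density surface (e.g. an analytic
    density) so the HDR/breadth/position machinery applies to it."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("values shape must match the grid")
    mask, thr = hdr_mask(values, grid, level)
    return DensityGrid(
        grid=grid, density=values, H=None, n_obs=0, total_weight=0.0,
        hdr_mask=mask, hdr_threshold=thr, hdr_level=level, key=key,
    )


# ---------------------------------------------------------------------------
# niche statistics
# ---------------------------------------------------------------------------


def niche_breadth(dg: DensityGrid) -> int:
    """Number of grid cells inside the HDR mask."""
    return int(dg.hdr_mask.sum())


def niche_position(dg: DensityGrid) -> tuple[float, float]:
    """Cell-centre coordinates of the density maximum (ties broken by the
    lowest linearised cell index)."""
    idx = int(np.argmax(dg.density))
    iy, ix = divmod(idx, dg.grid.resolution)
    return float(dg.grid.x_centers[ix]), float(dg.grid.y_centers[iy])


def niche_overlap(a: DensityGrid, b: DensityGrid, mode: str = "full") -> float:
    """Integral of min(f_a, f_b) over the shared grid, clipped to [0, 1].

    ``mode='full'`` (default) integrates the untruncated densities so
    identical niches score 1; ``mode='hdr_union'`` restricts the integral
    to the union of the two HDR masks.
    """
    if a.grid.hash() != b.grid.hash():
        raise ComparabilityError("densities evaluated on different grids")
    v = np.minimum(a.density, b.density)
    if mode == "hdr_union":
        v = np.where(a.hdr_mask | b.hdr_mask, v, 0.0)
    elif mode != "full":
        raise ValueError("mode must be 'full' or 'hdr_union'")
    return float(np.clip(v.sum() * a.grid.cell_area, 0.0, 1.0))


def kde_diagnostics(dg: DensityGrid) -> dict:
    """Per-KDE shape diagnostics supporting manual 'odd shape' review:
    number of connected HDR fragments and the probability mass sitting in
    the outermost ring of grid cells."""
    labeled, n_fragments = ndimage.label(dg.hdr_mask)
    ring = np.zeros(dg.grid.shape, dtype=bool)
    ring[0, :] = ring[-1, :] = True
    ring[:, 0] = ring[:, -1] = True
    boundary_mass = float(dg.density[ring].sum() * dg.grid.cell_area)
    total = dg.mass
    return {
        "hdr_fragments": int(n_fragments),
        "boundary_mass_fraction": boundary_mass / total if total > 0 else np.nan,
        "captured_mass": total,
    }
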