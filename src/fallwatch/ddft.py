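"""Discrete data density functional theory (DDFT) machinery.

Data points are treated as particles in feature space.  A Gaussian
mixture model supplies the data probability density rho(r); from it two
energy density functionals are built:

    kinetic   t[rho](r) = 2 pi^2 rho(r)                (cluster significance)
    potential u[rho](r) = 1/2 sum_i rho(r_i') / |r - r_i'|,  r != r_i'
                                                       (data similarity)

with an adaptive scaling factor gamma = 1/2 <u>/<t> (global averages
over the data points) making the two commensurable.  The Hamiltonian and
Lagrangian densities

    H = gamma^2 t + gamma u,      L = gamma^2 t - gamma u

carry the cluster structure: the mean Hamiltonian as a function of the
candidate component count K flattens once K reaches the true cluster
number (the turning point), and the zero level set of L — where kinetic
and potential densities balance — traces the cluster boundaries.

Useful identities (asserted in the test suite): H + L = 2 gamma^2 t,
H - L = 2 gamma u, and over the data points used for gamma,
<H> = 3/4 <u>^2/<t> = -3 <L>.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

from .errors import ParameterError, UndefinedPotentialError

log = logging.getLogger(__name__)

TWO_PI_SQ = 2.0 * np.pi**2

#: coincident-point guard for the potential sum (normalized units)
COINCIDENT_DELTA = 1e-9

#: default GMM fitting knobs
N_INIT = 5
EM_TOL = 1e-6
COV_FLOOR = 1e-6

#: default evaluation grid: resolution per axis and fractional padding
#: beyond the data bounding box
GRID_RESOLUTION = 200
GRID_PADDING = 0.10

#: default slope-stability threshold for cluster-number selection,
#: relative to the first Hamiltonian gap
SLOPE_EPS = 0.05


@dataclass
class DensityModel:
    """Gaussian-mixture density over (normalized) feature space."""

    K: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    fit_seed: int
    log_likelihood: float

    def __post_init__(self) -> None:
        if abs(float(self.weights.sum()) - 1.0) > 1e-9:
            raise ParameterError("mixture weights must sum to 1")
        for c in self.covariances:
            if np.min(np.linalg.eigvalsh(0.5 * (c + c.T))) <= 0:
                raise ParameterError("covariances must be positive-definite")

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def pdf(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        if points.ndim == 1:
            points = points[None, :]
        out = np.zeros(points.shape[0])
        for w, m, c in zip(self.weights, self.means, self.covariances):
            out += w * multivariate_normal.pdf(points, mean=m, cov=c)
        return out

    def to_dict(self) -> dict:
        return {
            "schema_version": "1.0",
            "kind": "density_model",
            "K": int(self.K),
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "fit_seed": int(self.fit_seed),
            "log_likelihood": float(self.log_likelihood),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DensityModel":
        return cls(K=int(d["K"]),
                   weights=np.asarray(d["weights"], dtype=float),
                   means=np.asarray(d["means"], dtype=float),
                   covariances=np.asarray(d["covariances"], dtype=float),
                   fit_seed=int(d["fit_seed"]),
                   log_likelihood=float(d["log_likelihood"]))


def fit_density(points: np.ndarray, K: int, seed: int,
                n_init: int = N_INIT, tol: float = EM_TOL,
                cov_floor: float = COV_FLOOR) -> DensityModel:
    """EM-fit a K-component full-covariance GMM (best of n_init restarts)."""
    points = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(points)):
        raise ParameterError("points must be finite")
    n = points.shape[0]
    if K <= 0 or K >= n:
        raise ParameterError(f"require 0 < K < n_points, got K={K}, n={n}")
    gm = GaussianMixture(n_components=K, covariance_type="full",
                         n_init=n_init, tol=tol, reg_covar=cov_floor,
                         max_iter=500, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # EM convergence chatter on degenerate data
        gm.fit(points)
    covs = gm.covariances_.copy()
    for i, c in enumerate(covs):  # floor any numerically indefinite component
        evals, evecs = np.linalg.eigh(0.5 * (c + c.T))
        if evals.min() < cov_floor:
            log.warning("flooring degenerate covariance of component %d", i)
            evals = np.maximum(evals, cov_floor)
            covs[i] = evecs @ np.diag(evals) @ evecs.T
    return DensityModel(K=K, weights=gm.weights_, means=gm.means_,
                        covariances=covs, fit_seed=seed,
                        log_likelihood=float(gm.score(points) * n))


def kedf(rho_values: np.ndarray) -> np.ndarray:
    """Kinetic energy density functional t = 2 pi^2 rho, elementwise."""
    rho = np.asarray(rho_values, dtype=float)
    if np.any(rho < 0):
        raise ParameterError("rho values must be non-negative")
    return TWO_PI_SQ * rho


def inverse_distances(queries: np.ndarray, data_points: np.ndarray,
                      delta: float = COINCIDENT_DELTA,
                      block: int = 4096) -> np.ndarray:
    """1/distance matrix with coincident pairs (< delta) zeroed.

    Computed blockwise to bound memory on large grids.
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    data_points = np.atleast_2d(np.asarray(data_points, dtype=float))
    out = np.empty((queries.shape[0], data_points.shape[0]))
    for lo in range(0, queries.shape[0], block):
        d = cdist(queries[lo:lo + block], data_points)
        with np.errstate(divide="ignore"):
            inv = np.where(d > delta, 1.0 / np.maximum(d, delta), 0.0)
        out[lo:lo + d.shape[0]] = inv
    return out


def pedf(queries: np.ndarray, data_points: np.ndarray,
         rho_data: np.ndarray, delta: float = COINCIDENT_DELTA,
         inv_dist: np.ndarray | None = None) -> np.ndarray:
    """Potential energy density u = 1/2 sum_i rho(r_i')/|r - r_i'|.

    Terms with |r - r_i'| <= delta are excluded (self/coincident guard).
    ``inv_dist`` may supply a precomputed inverse-distance matrix (as
    from :func:`inverse_distances`) when the same geometry is reused
    across densities.
    """
    rho_data = np.asarray(rho_data, dtype=float)
    if np.any(rho_data < 0):
        raise ParameterError("rho values must be non-negative")
    if inv_dist is None:
        inv_dist = inverse_distances(queries, data_points, delta)
    if np.any((inv_dist > 0).sum(axis=1) == 0):
        raise UndefinedPotentialError(
            "a query point coincides with every data point")
    return 0.5 * inv_dist @ rho_data


def adaptive_gamma(t_values: np.ndarray, u_values: np.ndarray) -> float:
    """Adaptive scaling factor gamma = 1/2 <u>/<t> over the data points."""
    mean_t = float(np.mean(t_values))
    if mean_t <= 0:
        raise ParameterError("mean KEDF must be positive (degenerate density)")
    return 0.5 * float(np.mean(u_values)) / mean_t


@dataclass
class EnergySurfaces:
    """KEDF/PEDF/Hamiltonian/Lagrangian values on evaluation points."""

    points: np.ndarray
    rho: np.ndarray
    t: np.ndarray
    u: np.ndarray
    gamma: float
    H: np.ndarray
    L: np.ndarray


def energy_surfaces(model: DensityModel, data_points: np.ndarray,
                    eval_points: np.ndarray | None = None,
                    delta: float = COINCIDENT_DELTA,
                    inv_dist_data: np.ndarray | None = None,
                    ) -> EnergySurfaces:
    """Evaluate rho, t, u, H, L on evaluation points (default: the data).

    gamma is always computed from the data points, never from the grid.
    """
    data_points = np.asarray(data_points, dtype=float)
    rho_data = model.pdf(data_points)
    t_data = kedf(rho_data)
    u_data = pedf(data_points, data_points, rho_data, delta,
                  inv_dist=inv_dist_data)
    gamma = adaptive_gamma(t_data, u_data)

    if eval_points is None:
        pts, rho, t, u = data_points, rho_data, t_data, u_data
    else:
        pts = np.asarray(eval_points, dtype=float)
        rho = model.pdf(pts)
        t = kedf(rho)
        u = pedf(pts, data_points, rho_data, delta)
    H = gamma**2 * t + gamma * u
    L = gamma**2 * t - gamma * u
    return EnergySurfaces(points=pts, rho=rho, t=t, u=u, gamma=gamma, H=H, L=L)


@dataclass
class HamiltonianCurve:
    """Mean Hamiltonian <H> against candidate cluster count K = 1..K_max."""

    K_values: np.ndarray
    mean_H: np.ndarray
    selected_K: int
    eps: float
    stabilized: bool  # False when the slope never settled (K_max returned)
    gammas: np.ndarray = field(default=None, repr=False)


def select_cluster_number(mean_H: np.ndarray, eps: float = SLOPE_EPS,
                          ) -> tuple[int, bool]:
    """Turning point of the Hamiltonian curve via slope stability.

    Returns the smallest K such that every later gap
    |<H>(K'+1) - <H>(K')|, K' >= K, is at most eps times the first gap
    |<H>(2) - <H>(1)|.  A curve that never settles yields (K_max, False).
    """
    mean_H = np.asarray(mean_H, dtype=float)
    if mean_H.size < 3:
        raise ParameterError("need a curve with >= 3 entries")
    gaps = np.abs(np.diff(mean_H))
    threshold = eps * gaps[0] + 1e-12 * max(1.0, float(np.abs(mean_H).max()))
    for k in range(1, mean_H.size):
        if np.all(gaps[k - 1:] <= threshold):
            return k, True
    warnings.warn("Hamiltonian slope never stabilized; returning K_max",
                  stacklevel=2)
    return int(mean_H.size), False


def hamiltonian_curve(points: np.ndarray, K_max: int, seed: int,
                      eps: float = SLOPE_EPS, n_init: int = N_INIT,
                      ) -> HamiltonianCurve:
    """<H> for K = 1..K_max, with the turning-point selection applied.

    gamma is recomputed for every K, since each K defines its own
    density.  The inverse-distance geometry is shared across K.
    """
    points = np.asarray(points, dtype=float)
    if K_max < 2:
        raise ParameterError("K_max must be >= 2")
    if points.shape[0] <= K_max:
        raise ParameterError("need more points than K_max")
    inv_dist = inverse_distances(points, points)
    ks = np.arange(1, K_max + 1)
    means, gammas = np.empty(K_max), np.empty(K_max)
    for i, K in enumerate(ks):
        model = fit_density(points, int(K), seed, n_init=n_init)
        surf = energy_surfaces(model, points, inv_dist_data=inv_dist)
        means[i] = float(np.mean(surf.H))
        gammas[i] = surf.gamma
    selected, stabilized = select_cluster_number(means, eps)
    return HamiltonianCurve(K_values=ks, mean_H=means, selected_K=selected,
                            eps=eps, stabilized=stabilized, gammas=gammas)


@dataclass
class GridSpec:
    """Rectangular evaluation grid over a 2D map."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    resolution: int = GRID_RESOLUTION

    @classmethod
    def from_points(cls, points: np.ndarray, padding: float = GRID_PADDING,
                    resolution: int = GRID_RESOLUTION) -> "GridSpec":
        points = np.asarray(points, dtype=float)
        lo, hi = points.min(axis=0), points.max(axis=0)
        span = np.maximum(hi - lo, 1e-6)
        lo, hi = lo - padding * span, hi + padding * span
        return cls(float(lo[0]), float(hi[0]), float(lo[1]), float(hi[1]),
                   resolution)

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.linspace(self.x_min, self.x_max, self.resolution),
                np.linspace(self.y_min, self.y_max, self.resolution))

    def mesh(self) -> np.ndarray:
        xs, ys = self.axes()
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])

    @property
    def cell(self) -> tuple[float, float]:
        return ((self.x_max - self.x_min) / (self.resolution - 1),
                (self.y_max - self.y_min) / (self.resolution - 1))


@dataclass
class ClusterBoundary:
    """Zero level set of the Lagrangian density on a 2D grid.

    ``contours[k]`` lists the closed L = 0 contours (arrays of (x, y)
    vertices) whose centroid is nearest cluster mean k.
    """

    contours: dict[int, list[np.ndarray]]
    grid: GridSpec
    L_grid: np.ndarray = field(repr=False)


def lagrangian_boundaries(model: DensityModel, data_points: np.ndarray,
                          grid: GridSpec | None = None,
                          resolution: int = GRID_RESOLUTION,
                          ) -> ClusterBoundary:
    """Marching-squares zero contours of L on an evaluation grid.

    The grid covers the data bounding box plus padding.  For boundary
    extraction the scaling factor gamma is the global average of u and t
    over the map domain (the grid) rather than over the data points:
    averaged over the data alone, gamma^2 t never exceeds gamma u
    anywhere for Gaussian-fitted clusters (the fitted density at a
    cluster peak is at most ~2x its data average while the potential
    stays near its own), so the balance set would be empty; the domain
    average restores positive kinetic cores whose zero level sets are
    the cluster boundaries.  Contours are labeled by the nearest cluster
    mean; if the grid shows no zero crossing, an empty boundary is
    returned with a warning.
    """
    from skimage import measure

    data_points = np.asarray(data_points, dtype=float)
    if data_points.shape[1] != 2:
        raise ParameterError("boundary extraction is defined on 2D maps")
    if grid is None:
        grid = GridSpec.from_points(data_points, resolution=resolution)
    rho_data = model.pdf(data_points)

    # gamma from a fixed-resolution quadrature over the same domain, so the
    # balance set does not drift when the display grid is refined
    qgrid = GridSpec(grid.x_min, grid.x_max, grid.y_min, grid.y_max,
                     resolution=97)
    qmesh = qgrid.mesh()
    gamma = adaptive_gamma(kedf(model.pdf(qmesh)),
                           pedf(qmesh, data_points, rho_data))

    mesh = grid.mesh()
    t_grid = kedf(model.pdf(mesh))
    u_grid = pedf(mesh, data_points, rho_data)
    L = (gamma**2 * t_grid - gamma * u_grid).reshape(grid.resolution,
                                                     grid.resolution)

    raw = measure.find_contours(L, 0.0)
    dx, dy = grid.cell
    contours: dict[int, list[np.ndarray]] = {k: [] for k in range(model.K)}
    for c in raw:
        xy = np.column_stack([grid.x_min + c[:, 0] * dx,
                              grid.y_min + c[:, 1] * dy])
        # drop speckle: contours enclosing less than ~2 grid cells are
        # marching-squares noise where the level surface grazes zero
        area = 0.5 * abs(np.dot(xy[:, 0], np.roll(xy[:, 1], 1))
                         - np.dot(xy[:, 1], np.roll(xy[:, 0], 1)))
        if area < 2.0 * dx * dy:
            continue
        centroid = xy.mean(axis=0)
        k = int(np.argmin(np.linalg.norm(model.means - centroid, axis=1)))
        contours[k].append(xy)
    if not any(contours.values()):
        warnings.warn("no Lagrangian zero crossing on the grid "
                      "(grid too small or gamma degenerate)", stacklevel=2)
    return ClusterBoundary(contours=contours, grid=grid, L_grid=L)


def interpolate_grid(grid: GridSpec, values: np.ndarray,
                     points: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a grid field at arbitrary 2D points."""
    from scipy.interpolate import RegularGridInterpolator

    xs, ys = grid.axes()
    f = RegularGridInterpolator((xs, ys), values, bounds_error=False,
                                fill_value=None)
    return f(np.atleast_2d(points))
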