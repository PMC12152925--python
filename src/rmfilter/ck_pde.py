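"""Finite-difference solvers for the replicator--mutator and Zakai equations.

All solvers work on a uniform 1-D grid with zero Dirichlet boundaries and
forward-Euler (or Euler--Maruyama) time stepping.  The mutation operator

    L* rho = -(g rho)' + (Sigma/2) rho''

is discretised with upwind first differences for the transport part and
central second differences for the diffusion part.  Expectations against the
density are trapezoid quadratures.  Densities are renormalised every step
with the accumulated log-mass stored separately, so unnormalised solutions
remain representable over long horizons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .systems import FitnessParams, NonlinearSystem1D, TimeDiscretization
from .observations import ItoObservationPath, PiecewiseObservation

__all__ = [
    "SpatialGrid",
    "GridDensity",
    "DensityTrajectory",
    "CFLError",
    "BlowUpError",
    "fitness_eval",
    "ck_solve",
    "zakai_solve",
    "grid_moments",
    "density_distance",
    "auto_grid",
    "gaussian_on_grid",
]


class CFLError(ValueError):
    """Explicit-Euler stability condition violated."""


class BlowUpError(RuntimeError):
    """Density became negative or non-finite during stepping."""

    def __init__(self, t: float, message: str):
        self.t = t
        super().__init__(f"{message} at t={t:.6g}")


@dataclass(frozen=True)
class SpatialGrid:
    lower: float
    upper: float
    n: int

    def __post_init__(self):
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("grid bounds must be finite")
        if self.upper <= self.lower:
            raise ValueError("upper bound must exceed lower bound")
        if self.n < 3:
            raise ValueError("grid needs at least 3 nodes")

    @property
    def x(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.n)

    @property
    def dx(self) -> float:
        return (self.upper - self.lower) / (self.n - 1)


@dataclass
class GridDensity:
    """Density values on a grid with a stored log-mass.

    The represented (unnormalised) function is ``values * exp(log_mass)``;
    for normalised densities ``log_mass`` is 0 and the trapezoid integral of
    ``values`` is 1.
    """

    grid: SpatialGrid
    values: np.ndarray
    log_mass: float = 0.0
    normalized: bool = False

    def mass(self) -> float:
        return float(np.trapezoid(self.values, dx=self.grid.dx))

    def normalize(self) -> "GridDensity":
        m = self.mass()
        if m <= 0:
            raise ValueError("cannot normalize a zero-mass density")
        return GridDensity(self.grid, self.values / m, 0.0, True)


def auto_grid(mean, std, n: int = 801, half_width_sds: float = 10.0,
              extra: float = 0.0) -> SpatialGrid:
    """Domain covering mean +/- half_width_sds * std, widened by ``extra``.

    ``extra`` accounts for drift of the density over the horizon (e.g. the
    distance the posterior mean is expected to travel).
    """
    mean = np.atleast_1d(mean).astype(float)
    std = max(float(np.max(np.atleast_1d(std))), 1e-6)
    lo = float(np.min(mean)) - half_width_sds * std - max(extra, 0.0)
    hi = float(np.max(mean)) + half_width_sds * std + max(extra, 0.0)
    return SpatialGrid(lo, hi, n)


def gaussian_on_grid(grid: SpatialGrid, mean: float, var: float) -> GridDensity:
    x = grid.x
    vals = np.exp(-0.5 * (x - mean) ** 2 / var) / np.sqrt(2 * np.pi * var)
    d = GridDensity(grid, vals)
    return d.normalize()


def fitness_eval(fp: FitnessParams, h, ydot, x, z, xi: float = 1.0):
    """Quadratic (r, s)-fitness for scalar observations.

    f(x, z) = -(r/2) (h(x)-ydot)^2 / xi + s (h(x)-ydot)(h(z)-ydot) / xi

    With s=0 this is the local log-likelihood fitness; the x=z diagonal
    equals (s - r/2)(h(x)-ydot)^2 / xi.
    """
    if xi <= 0:
        raise ValueError("Xi must be positive (singular observation noise)")
    hx = np.asarray(h(np.asarray(x, dtype=float)), dtype=float)
    hz = np.asarray(h(np.asarray(z, dtype=float)), dtype=float)
    dx_ = hx - ydot
    dz_ = hz - ydot
    return -(fp.r / 2.0) * dx_ ** 2 / xi + fp.s * dx_ * dz_ / xi


@dataclass
class DensityTrajectory:
    """Stored snapshots plus per-step moment diagnostics."""

    grid: SpatialGrid
    times: np.ndarray             # snapshot times
    values: np.ndarray            # (k, n_x) snapshot values (renormalised)
    log_mass: np.ndarray          # (k,) accumulated log integral
    moment_times: np.ndarray      # every step
    means: np.ndarray
    variances: np.ndarray
    normalized: bool
    boundary_mass: float = 0.0    # max density seen at the boundary nodes

    def final(self) -> GridDensity:
        return GridDensity(self.grid, self.values[-1].copy(),
                           float(self.log_mass[-1]), self.normalized)

    def density_at(self, idx: int) -> GridDensity:
        return GridDensity(self.grid, self.values[idx].copy(),
                           float(self.log_mass[idx]), self.normalized)


def _check_cfl(grid: SpatialGrid, tgrid: TimeDiscretization,
               sigma: float, gmax: float) -> None:
    dx = grid.dx
    if sigma > 0 and tgrid.dt > 0.25 * dx * dx / sigma:
        raise CFLError(
            f"dt={tgrid.dt:g} violates diffusion CFL dt <= 0.25 dx^2/Sigma = "
            f"{0.25 * dx * dx / sigma:g}")
    if gmax > 0 and tgrid.dt > 0.5 * dx / gmax:
        raise CFLError(
            f"dt={tgrid.dt:g} violates transport CFL dt <= 0.5 dx/max|g| = "
            f"{0.5 * dx / gmax:g}")


def _mutation_term(vals: np.ndarray, g_vals: np.ndarray, sigma: float,
                   dx: float) -> np.ndarray:
    """Upwind/central discretisation of L* on interior nodes (Dirichlet 0)."""
    out = np.zeros_like(vals)
    if sigma > 0:
        out[1:-1] += 0.5 * sigma * (vals[2:] - 2 * vals[1:-1] + vals[:-2]) / dx**2
    if np.any(g_vals != 0.0):
        flux = g_vals * vals
        dflux = np.zeros_like(vals)
        pos = g_vals[1:-1] > 0
        # upwind: backward difference where the flow is rightward
        dflux[1:-1] = np.where(pos,
                               (flux[1:-1] - flux[:-2]),
                               (flux[2:] - flux[1:-1])) / dx
        out -= dflux
    return out


def _step_guard(vals: np.ndarray, t: float) -> None:
    if not np.all(np.isfinite(vals)):
        raise BlowUpError(t, "non-finite density values")
    mx = float(np.max(vals))
    if mx <= 0:
        raise BlowUpError(t, "density lost all mass")
    if float(np.min(vals)) < -1e-6 * mx:
        raise BlowUpError(t, "negative density exceeding tolerance")


def _run_grid_solver(sys1d: NonlinearSystem1D, grid: SpatialGrid,
                     tgrid: TimeDiscretization, p0: GridDensity,
                     reaction, store_every: int):
    """Shared Euler loop.  ``reaction(k, vals)`` returns the per-node update
    increment (already multiplied by dt for stochastic terms)."""
    x = grid.x
    dx = grid.dx
    sys1d.check_on_grid(x)
    g_vals = np.asarray(sys1d.g(x), dtype=float)
    _check_cfl(grid, tgrid, sys1d.Sigma, float(np.max(np.abs(g_vals))))

    vals = p0.values.copy()
    m0 = float(np.trapezoid(vals, dx=dx))
    if m0 <= 0:
        raise ValueError("initial density has zero mass")
    log_mass = np.log(m0) + p0.log_mass
    vals = vals / m0

    n_store = tgrid.n_steps // store_every + 1
    snap_vals = np.empty((n_store + 1, grid.n))
    snap_logm = np.empty(n_store + 1)
    snap_t = np.empty(n_store + 1)
    means = np.empty(tgrid.n_steps + 1)
    variances = np.empty(tgrid.n_steps + 1)
    boundary_mass = 0.0

    def record_moments(k, v):
        mean = float(np.trapezoid(x * v, dx=dx))
        means[k] = mean
        variances[k] = float(np.trapezoid(x * x * v, dx=dx)) - mean * mean

    record_moments(0, vals)
    snap_vals[0] = vals
    snap_logm[0] = log_mass
    snap_t[0] = 0.0
    j = 1
    dt = tgrid.dt
    for k in range(tgrid.n_steps):
        incr = dt * _mutation_term(vals, g_vals, sys1d.Sigma, dx) + reaction(k, vals)
        vals = vals + incr
        vals[0] = 0.0
        vals[-1] = 0.0
        t = (k + 1) * dt
        _step_guard(vals, t)
        m = float(np.trapezoid(vals, dx=dx))
        if m <= 0 or not np.isfinite(m):
            raise BlowUpError(t, "density mass became invalid")
        vals = vals / m
        log_mass += np.log(m)
        boundary_mass = max(boundary_mass, float(vals[1]), float(vals[-2]))
        record_moments(k + 1, vals)
        if (k + 1) % store_every == 0 or k + 1 == tgrid.n_steps:
            snap_vals[j] = vals
            snap_logm[j] = log_mass
            snap_t[j] = t
            j += 1
    return (snap_t[:j], snap_vals[:j], snap_logm[:j], means, variances,
            boundary_mass)


def ck_solve(sys1d: NonlinearSystem1D, fp: FitnessParams,
             obs: PiecewiseObservation, grid: SpatialGrid,
             tgrid: TimeDiscretization, mode: str = "normalized",
             p0: GridDensity | None = None,
             store_every: int = 0) -> DensityTrajectory:
    """Crow--Kimura replicator--mutator driven by a smoothed observation path.

    ``mode='normalized'`` integrates the probability-density form: the
    replication term is rho * (E_z[f(x, z)] - E[f]) with the non-local
    fitness; ``mode='unnormalized'`` integrates the linear form with
    reaction coefficient -(r/2) h^T Xi^{-1} h + (r-s) h^T Xi^{-1} ydot
    (renormalised each step, with the accumulated log-mass stored).
    The two agree through rho = mu / integral(mu).
    """
    if mode not in ("normalized", "unnormalized"):
        raise ValueError("mode must be 'normalized' or 'unnormalized'")
    x = grid.x
    dx = grid.dx
    h_vals = np.asarray(sys1d.h(x), dtype=float)
    xi_inv = 1.0 / sys1d.Xi
    r, s = fp.r, fp.s
    ydots = obs.derivative_at_steps(tgrid)[:, 0]
    if p0 is None:
        raise ValueError("p0 (initial density) is required")
    if store_every <= 0:
        store_every = max(1, tgrid.n_steps // 200)

    dt = tgrid.dt

    if mode == "unnormalized":
        def reaction(k, vals):
            c = (-0.5 * r * h_vals * h_vals + (r - s) * h_vals * ydots[k]) * xi_inv
            return dt * c * vals
    else:
        def reaction(k, vals):
            ydot = ydots[k]
            dev = h_vals - ydot
            h_bar = float(np.trapezoid(h_vals * vals, dx=dx))
            # mean-field fitness W(x) = E_z[f(x,z)]
            W = xi_inv * (-0.5 * r * dev * dev + s * dev * (h_bar - ydot))
            W_bar = float(np.trapezoid(W * vals, dx=dx))
            return dt * (W - W_bar) * vals

    out = _run_grid_solver(sys1d, grid, tgrid, p0, reaction, store_every)
    snap_t, snap_vals, snap_logm, means, variances, bmass = out
    return DensityTrajectory(grid=grid, times=snap_t, values=snap_vals,
                             log_mass=snap_logm, moment_times=tgrid.times,
                             means=means, variances=variances,
                             normalized=(mode == "normalized"),
                             boundary_mass=bmass)


def zakai_solve(sys1d: NonlinearSystem1D, fp: FitnessParams,
                obs: ItoObservationPath, grid: SpatialGrid,
                tgrid: TimeDiscretization, mode: str = "ito_paper",
                p0: GridDensity | None = None,
                store_every: int = 0) -> DensityTrajectory:
    """(Modified) Zakai equation driven by the rough observation path.

    All modes share the multiplicative noise term (r-s) q h^T Xi^{-1} dZ and
    differ only in the deterministic reaction coefficient:

    * ``ito_paper``:     c0 = -(s/2) h^T Xi^{-1} h
    * ``stratonovich``:  c0 = ((r-s)^2 - r)/2 * h^T Xi^{-1} h, the Ito form
      of the Stratonovich-interpreted equation (the Wong--Zakai limit of the
      smooth-observation replicator--mutator)
    * ``ito_naive``:     c0 = -(r/2) h^T Xi^{-1} h, the smooth-limit drift
      with the noise deliberately misread as Ito (no Wong--Zakai
      correction); the 'wrong limit' contender in the static-signal
      demonstration.

    At (r, s) = (1, 0) the first two coincide with the classical Zakai
    equation while ``ito_naive`` differs by the -(1/2) h^T Xi^{-1} h drift.
    """
    if mode not in ("ito_paper", "stratonovich", "ito_naive"):
        raise ValueError("mode must be 'ito_paper', 'stratonovich' or 'ito_naive'")
    x = grid.x
    h_vals = np.asarray(sys1d.h(x), dtype=float)
    xi_inv = 1.0 / sys1d.Xi
    r, s = fp.r, fp.s
    if mode == "ito_paper":
        c0 = -0.5 * s * h_vals * h_vals * xi_inv
    elif mode == "stratonovich":
        c0 = 0.5 * ((r - s) ** 2 - r) * h_vals * h_vals * xi_inv
    else:  # ito_naive
        c0 = -0.5 * r * h_vals * h_vals * xi_inv
    dZ = obs.dZ[:, 0]
    if len(dZ) < tgrid.n_steps:
        raise ValueError("observation path shorter than the time grid")
    if p0 is None:
        raise ValueError("p0 (initial density) is required")
    if store_every <= 0:
        store_every = max(1, tgrid.n_steps // 200)

    dt = tgrid.dt
    noise_coef = (r - s) * h_vals * xi_inv

    def reaction(k, vals):
        return vals * (dt * c0 + noise_coef * dZ[k])

    out = _run_grid_solver(sys1d, grid, tgrid, p0, reaction, store_every)
    snap_t, snap_vals, snap_logm, means, variances, bmass = out
    return DensityTrajectory(grid=grid, times=snap_t, values=snap_vals,
                             log_mass=snap_logm, moment_times=tgrid.times,
                             means=means, variances=variances,
                             normalized=False, boundary_mass=bmass)


def grid_moments(density: GridDensity) -> tuple[float, float]:
    """Trapezoid mean and variance of a (normalisable) grid density."""
    vals = density.values
    dx = density.grid.dx
    mass = float(np.trapezoid(vals, dx=dx))
    if mass <= 0:
        raise ValueError("zero-mass density has no moments")
    x = density.grid.x
    mean = float(np.trapezoid(x * vals, dx=dx)) / mass
    second = float(np.trapezoid(x * x * vals, dx=dx)) / mass
    return mean, second - mean * mean


def density_distance(d1: GridDensity, d2: GridDensity,
                     metric: str = "l1") -> tuple[float, float]:
    """(L1 distance, max pointwise difference) after matching normalisation."""
    if (d1.grid.lower, d1.grid.upper, d1.grid.n) != (
            d2.grid.lower, d2.grid.upper, d2.grid.n):
        raise ValueError("densities live on different grids")
    if metric != "l1":
        raise ValueError("only the L1 metric is implemented")
    a = d1.normalize().values
    b = d2.normalize().values
    diff = np.abs(a - b)
    return float(np.trapezoid(diff, dx=d1.grid.dx)), float(np.max(diff))
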