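"""Reference signals and observation paths.

Two observation drivers are produced from one underlying Brownian path:

* the rough Ito path ``Z_t`` with increments ``dZ = h(x*) dt + Xi^{1/2} dB``,
  and
* the piecewise-smooth driver whose derivative is constant on windows of
  width ``delta_d``: ``dZ^d/dt = h(x*_{t_i}) + Xi^{1/2} (B_{t_{i+1}} - B_{t_i}) / delta_d``.

Brownian increments are always generated at the simulation resolution ``dt``
and aggregated per window, so refining ``delta_d`` with the same seed reuses
one Brownian path (common-noise refinement), and the smoothed and Ito drivers
can be coupled by sharing the increment array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .systems import LinearGaussianSystem, NonlinearSystem1D, TimeDiscretization

__all__ = [
    "SignalPath",
    "PiecewiseObservation",
    "ItoObservationPath",
    "brownian_increments",
    "simulate_signal",
    "piecewise_linear_brownian",
    "observation_derivative",
    "ito_observation",
]


@dataclass(frozen=True)
class SignalPath:
    """Euler--Maruyama path of the (possibly biased) linear signal SDE."""

    times: np.ndarray            # (N+1,)
    states: np.ndarray           # (N+1, m)
    seed: int | None = None

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class PiecewiseObservation:
    """Piecewise-constant observation derivative ('smoothed' driver)."""

    window_starts: np.ndarray    # (d,)
    delta_d: float
    xi: np.ndarray               # (d, n) per-window constant derivative
    brownian_knots: np.ndarray   # (d+1, n) underlying Brownian at window edges

    @property
    def d(self) -> int:
        return self.xi.shape[0]

    def derivative_at_steps(self, tgrid: TimeDiscretization) -> np.ndarray:
        """Per-simulation-step derivative array, shape (n_steps, n)."""
        spw = int(round(self.delta_d / tgrid.dt))
        return np.repeat(self.xi, spw, axis=0)[: tgrid.n_steps]

    def interpolant(self, t: float) -> np.ndarray:
        """Value of the piecewise-linear Brownian interpolant B^d at time t."""
        i = min(int(t / self.delta_d), self.d - 1)
        frac = (t - self.window_starts[i]) / self.delta_d
        return self.brownian_knots[i] + frac * (
            self.brownian_knots[i + 1] - self.brownian_knots[i])


@dataclass(frozen=True)
class ItoObservationPath:
    """Cumulative rough observation path and its increments."""

    times: np.ndarray            # (N+1,)
    Z: np.ndarray                # (N+1, n)
    dZ: np.ndarray               # (N, n)


def brownian_increments(tgrid: TimeDiscretization, seed: int | None,
                        dim: int = 1) -> np.ndarray:
    """N(0, dt) increments at resolution dt, shape (n_steps, dim).

    The single source of observation-noise randomness: both drivers are
    deterministic functions of this array.
    """
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, np.sqrt(tgrid.dt), size=(tgrid.n_steps, dim))


def simulate_signal(sys: LinearGaussianSystem, tgrid: TimeDiscretization,
                    seed: int | None = None, with_bias: bool = True,
                    x0: float | np.ndarray | None = None) -> SignalPath:
    """Euler--Maruyama path of dX = G X dt + b dt + Sigma^{1/2} dW.

    ``x0`` fixes the initial state; otherwise X_0 ~ N(m0, P0).
    ``with_bias=False`` drops b (the assumed model).
    """
    rng = np.random.default_rng(seed)
    m = sys.m
    N = tgrid.n_steps
    w, V = np.linalg.eigh(sys.Sigma)
    sqrt_sigma = V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T
    w, V = np.linalg.eigh(sys.P0)
    sqrt_p0 = V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T

    if x0 is None:
        x = sys.m0 + sqrt_p0 @ rng.normal(size=m)
    else:
        x = np.broadcast_to(np.atleast_1d(np.asarray(x0, dtype=float)), (m,)).copy()

    b = sys.b if with_bias else np.zeros(m)
    dW = rng.normal(0.0, np.sqrt(tgrid.dt), size=(N, m))
    states = np.empty((N + 1, m))
    states[0] = x
    for k in range(N):
        x = x + (sys.G @ x + b) * tgrid.dt + sqrt_sigma @ dW[k]
        states[k + 1] = x
    return SignalPath(times=tgrid.times, states=states, seed=seed)


def _knots_from_increments(incr: np.ndarray, tgrid: TimeDiscretization) -> np.ndarray:
    """Aggregate dt-resolution increments to Brownian values at window edges."""
    spw = tgrid.steps_per_window
    d = tgrid.d
    window_incr = incr[: d * spw].reshape(d, spw, incr.shape[1]).sum(axis=1)
    knots = np.zeros((d + 1, incr.shape[1]))
    np.cumsum(window_incr, axis=0, out=knots[1:])
    return knots


def piecewise_linear_brownian(tgrid: TimeDiscretization, seed: int | None = None,
                              dim: int = 1,
                              increments: np.ndarray | None = None
                              ) -> PiecewiseObservation:
    """Piecewise-linear Brownian interpolant and its windowed derivative.

    Window derivative = (B_{t_{i+1}} - B_{t_i}) / delta_d ~ N(0, I/delta_d).
    """
    if increments is None:
        increments = brownian_increments(tgrid, seed, dim)
    knots = _knots_from_increments(increments, tgrid)
    xi = np.diff(knots, axis=0) / tgrid.delta_d
    return PiecewiseObservation(window_starts=tgrid.window_starts,
                                delta_d=tgrid.delta_d, xi=xi,
                                brownian_knots=knots)


def _h_eval(sys, x: np.ndarray) -> np.ndarray:
    """Observation map for either system type; x is (k, m) -> (k, n)."""
    if isinstance(sys, LinearGaussianSystem):
        return x @ sys.H.T
    vals = np.asarray(sys.h(x[:, 0]), dtype=float)
    return vals[:, None]


def _xi_sqrt(sys) -> np.ndarray:
    if isinstance(sys, LinearGaussianSystem):
        w, V = np.linalg.eigh(sys.Xi)
        return V @ np.diag(np.sqrt(w)) @ V.T
    return np.array([[np.sqrt(sys.Xi)]])


def observation_derivative(signal: SignalPath, sys, tgrid: TimeDiscretization,
                           seed: int | None = None,
                           increments: np.ndarray | None = None
                           ) -> PiecewiseObservation:
    """Smoothed observation driver: xi_i = h(x*_{t_i}) + Xi^{1/2} Bdot_i.

    The signal is sampled at the left endpoint of each window.
    """
    pw = piecewise_linear_brownian(tgrid, seed, dim=_xi_sqrt(sys).shape[0],
                                   increments=increments)
    spw = tgrid.steps_per_window
    left_states = signal.states[: tgrid.n_steps: spw]     # (d, m)
    h_left = _h_eval(sys, left_states)                    # (d, n)
    xi = h_left + pw.xi @ _xi_sqrt(sys).T
    return PiecewiseObservation(window_starts=pw.window_starts,
                                delta_d=pw.delta_d, xi=xi,
                                brownian_knots=pw.brownian_knots)


def ito_observation(signal: SignalPath, sys, tgrid: TimeDiscretization,
                    seed: int | None = None,
                    increments: np.ndarray | None = None) -> ItoObservationPath:
    """Rough driver: dZ_k = h(x*_{t_k}) dt + Xi^{1/2} dB_k at resolution dt.

    Passing the same ``increments`` array used for the smoothed driver couples
    the two paths through one Brownian source.
    """
    n = _xi_sqrt(sys).shape[0]
    if increments is None:
        increments = brownian_increments(tgrid, seed, n)
    h_vals = _h_eval(sys, signal.states[:-1])             # (N, n)
    dZ = h_vals * tgrid.dt + increments @ _xi_sqrt(sys).T
    Z = np.zeros((tgrid.n_steps + 1, n))
    np.cumsum(dZ, axis=0, out=Z[1:])
    return ItoObservationPath(times=tgrid.times, Z=Z, dZ=dZ)
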