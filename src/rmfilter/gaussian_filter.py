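"""The linear-Gaussian (r, s)-filter.

For linear-Gaussian systems the replicator--mutator equation stays Gaussian
and closes on its first two moments:

    dm = G m dt + (r - s) K (dZ - H m dt),        K = C H^T Xi^{-1}
    dC/dt = G C + C G^T + Sigma - r C H^T Xi^{-1} H C

(the smooth-driver version replaces dZ with the windowed derivative times
dt).  At (r, s) = (1, 0) this is the Kalman--Bucy filter.  Note that s only
enters the mean update: two parameter pairs with equal r produce identical
covariance trajectories.

The module also provides the interacting-particle (mean-field ensemble)
realisations of the same flow and the map between (r, s) and classical
multiplicative/additive covariance inflation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .systems import FitnessParams, LinearGaussianSystem, TimeDiscretization
from .observations import ItoObservationPath, PiecewiseObservation

__all__ = [
    "GaussianMomentTrajectory",
    "EnsembleTrajectory",
    "moment_filter",
    "riccati_steady_state",
    "ensemble_filter",
    "inflation_map",
    "inflation_inverse",
    "ENSEMBLE_VARIANTS",
]

ENSEMBLE_VARIANTS = ("stochastic_rough", "deterministic_rough",
                     "stochastic_smooth", "deterministic_smooth")


@dataclass
class GaussianMomentTrajectory:
    times: np.ndarray        # (N+1,)
    means: np.ndarray        # (N+1, m)
    covariances: np.ndarray  # (N+1, m, m)

    @property
    def gains(self) -> np.ndarray:
        raise AttributeError("use gains_for(sys)")

    def gains_for(self, sys: LinearGaussianSystem) -> np.ndarray:
        Xi_inv = np.linalg.inv(sys.Xi)
        return self.covariances @ sys.H.T @ Xi_inv


@dataclass
class EnsembleTrajectory:
    times: np.ndarray            # stored times (k,)
    particles: np.ndarray        # (k, N, m)
    variant: str
    seed: int | None
    emp_means: np.ndarray        # every step (N+1, m)
    emp_covs: np.ndarray         # every step (N+1, m, m)


def _driver_terms(driver, tgrid: TimeDiscretization):
    """Return per-step observation 'increment' dZ_k (rough) or ydot_k*dt
    (smooth), shape (n_steps, n), plus a flag for smooth drivers."""
    if isinstance(driver, PiecewiseObservation):
        return driver.derivative_at_steps(tgrid) * tgrid.dt, True
    if isinstance(driver, ItoObservationPath):
        if driver.dZ.shape[0] < tgrid.n_steps:
            raise ValueError("driver shorter than time grid")
        return driver.dZ[: tgrid.n_steps], False
    raise TypeError("driver must be a PiecewiseObservation or ItoObservationPath")


def _cov_rhs(C, sys, r):
    CHt = C @ sys.H.T
    return (sys.G @ C + C @ sys.G.T + sys.Sigma
            - r * CHt @ np.linalg.inv(sys.Xi) @ CHt.T)


def moment_filter(sys: LinearGaussianSystem, fp: FitnessParams, driver,
                  tgrid: TimeDiscretization,
                  m0: np.ndarray | None = None,
                  C0: np.ndarray | None = None) -> GaussianMomentTrajectory:
    """Forward-Euler integration of the (r, s) moment equations.

    ``driver`` is a :class:`PiecewiseObservation` (smooth) or an
    :class:`ItoObservationPath` (rough; Euler--Maruyama in the mean).
    The covariance is deterministic and identical for both drivers.
    """
    m = sys.m
    dt = tgrid.dt
    N = tgrid.n_steps
    incr, _ = _driver_terms(driver, tgrid)
    Xi_inv = np.linalg.inv(sys.Xi)
    r, s = fp.r, fp.s

    mean = (sys.m0 if m0 is None else np.atleast_1d(np.asarray(m0, float))).copy()
    C = (sys.C0 if C0 is None else np.atleast_2d(np.asarray(C0, float))).copy()

    means = np.empty((N + 1, m))
    covs = np.empty((N + 1, m, m))
    means[0] = mean
    covs[0] = C
    for k in range(N):
        K = C @ sys.H.T @ Xi_inv
        innov = incr[k] - (sys.H @ mean) * dt
        mean = mean + (sys.G @ mean) * dt + (r - s) * (K @ innov)
        C = C + dt * _cov_rhs(C, sys, r)
        if np.min(np.linalg.eigvalsh((C + C.T) / 2)) <= 0:
            raise RuntimeError(
                f"filter covariance lost positive-definiteness at "
                f"t={(k + 1) * dt:.6g}")
        means[k + 1] = mean
        covs[k + 1] = C
    return GaussianMomentTrajectory(times=tgrid.times, means=means,
                                    covariances=covs)


def riccati_steady_state(sys: LinearGaussianSystem, r: float,
                         tol: float = 1e-12, max_time: float = 1e4) -> np.ndarray:
    """Steady state of dC/dt = GC + CG' + Sigma - r C H' Xi^{-1} H C.

    Scalar systems use the closed form
    C_inf = (G + sqrt(G^2 + r H^2 Xi^{-1} Sigma)) / (r H^2 Xi^{-1});
    matrix systems integrate the Riccati ODE from C0 = I until the
    Frobenius norm of the derivative drops below ``tol``.
    """
    if r <= 0:
        raise ValueError("r must be > 0")
    if sys.is_scalar:
        g, snr = sys.g_, sys.snr_
        c = (g + np.sqrt(g * g + r * snr)) / (r * sys.h_**2 / sys.xi_)
        return np.array([[c]])
    C = np.eye(sys.m)
    t, dt = 0.0, 1e-3
    while t < max_time:
        dC = _cov_rhs(C, sys, r)
        nrm = float(np.linalg.norm(dC))
        if nrm < tol:
            return (C + C.T) / 2
        step = min(dt, 0.1 / max(nrm, 1e-12))
        C = C + step * dC
        C = (C + C.T) / 2
        t += step
    raise RuntimeError("Riccati integration did not converge within the guard")


def inflation_map(epsilon: float, kind: str) -> FitnessParams:
    """Map an inflation parameter to the equivalent (r, s).

    multiplicative: (r, s) = (1 + eps, 0);  additive: (r, s) = (1 - 2 eps,
    -2 eps).  eps = 0 is the uninflated Kalman--Bucy case for both.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if kind == "multiplicative":
        fp = FitnessParams(r=1.0 + epsilon, s=0.0)
    elif kind == "additive":
        if epsilon >= 0.5:
            raise ValueError("additive inflation requires epsilon < 0.5 (r > 0)")
        fp = FitnessParams(r=1.0 - 2.0 * epsilon, s=-2.0 * epsilon)
    else:
        raise ValueError("kind must be 'multiplicative' or 'additive'")
    return fp


def inflation_inverse(fp: FitnessParams) -> tuple[float, str]:
    """Recover (epsilon, kind) from (r, s) when the pattern matches.

    Returns kind='mixed' with the residual encoded as epsilon=nan when the
    pair corresponds to a genuine combination of both inflation types.
    """
    r, s = fp.r, fp.s
    if abs(s) < 1e-12 and r >= 1.0:
        return r - 1.0, "multiplicative"
    if abs((1.0 - 2.0 * (-s / 2.0)) - r) < 1e-12 and s <= 0:
        return -s / 2.0, "additive"
    return float("nan"), "mixed"


def ensemble_filter(sys: LinearGaussianSystem, fp: FitnessParams, variant: str,
                    N: int, driver, tgrid: TimeDiscretization,
                    seed: int | None = None,
                    store_every: int = 0) -> EnsembleTrajectory:
    """Mean-field ensemble realisation of the (r, s) filter.

    All four variants share the pre-drift -(s/2) K H (X - m) dt and the
    innovation weight (r - s); they differ in the innovation centre
    (particle HX for 'stochastic', the average (HX + Hm)/2 for
    'deterministic') and in whether an independent perturbation noise of
    covariance (r - s) K Xi K^T per unit time is added ('stochastic' only).
    The gain K uses the N-particle empirical covariance (1/(N-1) estimator),
    recomputed every step, so the empirical moments satisfy the (r, s)
    moment equations as N grows.
    """
    if variant not in ENSEMBLE_VARIANTS:
        raise ValueError(f"variant must be one of {ENSEMBLE_VARIANTS}")
    if N < 2:
        raise ValueError("need at least 2 particles")
    incr, smooth = _driver_terms(driver, tgrid)
    if ("smooth" in variant) != smooth:
        raise ValueError(f"variant {variant!r} needs a "
                         f"{'smooth' if 'smooth' in variant else 'rough'} driver")
    stochastic = variant.startswith("stochastic")
    m = sys.m
    dt = tgrid.dt
    r, s = fp.r, fp.s
    Xi_inv = np.linalg.inv(sys.Xi)
    w, V = np.linalg.eigh(sys.Xi)
    sqrt_xi = V @ np.diag(np.sqrt(w)) @ V.T
    w, V = np.linalg.eigh(sys.Sigma)
    sqrt_sigma = V @ np.diag(np.sqrt(np.clip(w, 0, None))) @ V.T
    w, V = np.linalg.eigh(sys.C0)
    sqrt_c0 = V @ np.diag(np.sqrt(w)) @ V.T

    rng = np.random.default_rng(seed)
    X = sys.m0 + rng.normal(size=(N, m)) @ sqrt_c0.T
    if store_every <= 0:
        store_every = max(1, tgrid.n_steps // 50)

    n_store = tgrid.n_steps // store_every + 2
    stored = np.empty((n_store, N, m))
    stored_t = np.empty(n_store)
    emp_means = np.empty((tgrid.n_steps + 1, m))
    emp_covs = np.empty((tgrid.n_steps + 1, m, m))

    def record(k):
        mu = X.mean(axis=0)
        emp_means[k] = mu
        dev = X - mu
        emp_covs[k] = dev.T @ dev / (N - 1)

    record(0)
    stored[0] = X
    stored_t[0] = 0.0
    j = 1
    sqrt_dt = np.sqrt(dt)
    for k in range(tgrid.n_steps):
        mu = X.mean(axis=0)
        dev = X - mu
        C = dev.T @ dev / (N - 1)
        if np.min(np.linalg.eigvalsh((C + C.T) / 2)) <= 0:
            raise RuntimeError(f"degenerate ensemble covariance at step {k}")
        K = C @ sys.H.T @ Xi_inv
        drift = X @ sys.G.T - (s / 2.0) * (dev @ (K @ sys.H).T)
        if stochastic:
            innov = incr[k][None, :] - (X @ sys.H.T) * dt
        else:
            innov = incr[k][None, :] - 0.5 * ((X + mu) @ sys.H.T) * dt
        update = (r - s) * (innov @ K.T)
        X = X + drift * dt + update
        if sys.Sigma.any():
            X = X + rng.normal(size=(N, m)) @ (sqrt_sigma.T * sqrt_dt)
        if stochastic:
            # independent perturbation noise, covariance (r-s) K Xi K' dt
            pert = rng.normal(size=(N, sys.n)) @ (sqrt_xi @ K.T)
            X = X + np.sqrt(max(r - s, 0.0)) * sqrt_dt * pert
        record(k + 1)
        if (k + 1) % store_every == 0 or k + 1 == tgrid.n_steps:
            stored[j] = X
            stored_t[j] = (k + 1) * dt
            j += 1
    return EnsembleTrajectory(times=stored_t[:j], particles=stored[:j],
                              variant=variant, seed=seed,
                              emp_means=emp_means, emp_covs=emp_covs)
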