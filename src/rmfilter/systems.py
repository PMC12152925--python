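"""Model objects shared across the package.

The central object is a linear-Gaussian filtering problem: a hidden signal
``dX = G X dt + b dt + Sigma^{1/2} dW`` observed through
``dZ = H X dt + Xi^{1/2} dB``.  The pair ``(r, s)`` parameterises the
quadratic fitness landscape of the replicator--mutator equation that the
filter corresponds to: ``r`` weighs the data-misfit (replication) term and
``s`` weighs the non-local conformity/diversity interaction.  ``s = 0``
recovers a local (log-likelihood) fitness; ``s < 0`` rewards diversity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "LinearGaussianSystem",
    "NonlinearSystem1D",
    "FitnessParams",
    "TimeDiscretization",
    "AdmissibilityReport",
    "Fig1Example",
    "validate_fitness",
    "builtin_fixture",
]

_SPECTRAL_TOL = 1e-10


def _as_matrix(a, name: str) -> np.ndarray:
    """Promote scalars / nested lists to a 2-D float array."""
    arr = np.atleast_2d(np.asarray(a, dtype=float))
    if arr.ndim != 2:
        raise ValueError(f"{name} must be at most 2-dimensional")
    return arr


def _as_vector(a, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(a, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"{name} must be a vector")
    return arr


def _check_symmetric_psd(a: np.ndarray, name: str, definite: bool) -> None:
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    eigs = np.linalg.eigvalsh(a)
    if definite:
        if np.min(eigs) <= 0:
            raise ValueError(f"{name} must be positive definite")
    elif np.min(eigs) < -1e-12:
        raise ValueError(f"{name} must be positive semi-definite")


@dataclass(frozen=True)
class LinearGaussianSystem:
    """Linear-Gaussian signal/observation pair with an optional constant bias.

    Parameters
    ----------
    G : (m, m) signal drift matrix [1/time].
    H : (n, m) observation matrix.
    Sigma : (m, m) signal noise covariance [state^2/time], symmetric PSD.
    Xi : (n, n) observation noise covariance, symmetric PD.
    b : (m,) constant signal bias [state/time]; the misspecification is that
        the assumed model drops this term.
    m0 : (m,) initial mean.
    C0 : (m, m) initial filter covariance, symmetric PD.
    P0 : (m, m) initial true-state covariance, symmetric PD.  Kept separate
        from ``C0`` because under misspecification the filter covariance and
        the error covariance evolve differently.
    """

    G: np.ndarray
    H: np.ndarray
    Sigma: np.ndarray
    Xi: np.ndarray
    b: np.ndarray
    m0: np.ndarray
    C0: np.ndarray
    P0: np.ndarray

    def __init__(self, G, H, Sigma, Xi, b=0.0, m0=0.0, C0=1.0, P0=1.0):
        G = _as_matrix(G, "G")
        m = G.shape[0]
        if G.shape != (m, m):
            raise ValueError("G must be square")
        H = _as_matrix(H, "H")
        if H.shape[1] != m:
            raise ValueError("H must have m columns")
        n = H.shape[0]
        Sigma = _as_matrix(Sigma, "Sigma")
        Xi = _as_matrix(Xi, "Xi")
        if Sigma.shape != (m, m) or Xi.shape != (n, n):
            raise ValueError("Sigma/Xi dimensions inconsistent with G/H")
        _check_symmetric_psd(Sigma, "Sigma", definite=False)
        _check_symmetric_psd(Xi, "Xi", definite=True)
        b = np.broadcast_to(_as_vector(b, "b"), (m,)).astype(float)
        m0 = np.broadcast_to(_as_vector(m0, "m0"), (m,)).astype(float)
        C0 = _as_matrix(C0, "C0")
        P0 = _as_matrix(P0, "P0")
        if C0.shape != (m, m) or P0.shape != (m, m):
            raise ValueError("C0/P0 must be m x m")
        _check_symmetric_psd(C0, "C0", definite=True)
        _check_symmetric_psd(P0, "P0", definite=True)
        for name, val in [("G", G), ("H", H), ("Sigma", Sigma), ("Xi", Xi),
                          ("b", b), ("m0", m0), ("C0", C0), ("P0", P0)]:
            object.__setattr__(self, name, val)

    @property
    def m(self) -> int:
        return self.G.shape[0]

    @property
    def n(self) -> int:
        return self.H.shape[0]

    @property
    def is_scalar(self) -> bool:
        return self.m == 1 and self.n == 1

    def _require_scalar(self) -> None:
        if not self.is_scalar:
            raise ValueError("operation requires a scalar (m=n=1) system")

    # scalar accessors -------------------------------------------------
    @property
    def g_(self) -> float:
        self._require_scalar()
        return float(self.G[0, 0])

    @property
    def h_(self) -> float:
        self._require_scalar()
        return float(self.H[0, 0])

    @property
    def sigma_(self) -> float:
        self._require_scalar()
        return float(self.Sigma[0, 0])

    @property
    def xi_(self) -> float:
        self._require_scalar()
        return float(self.Xi[0, 0])

    @property
    def b_(self) -> float:
        self._require_scalar()
        return float(self.b[0])

    @property
    def snr_(self) -> float:
        """The combination H^2 Xi^{-1} Sigma that controls every scalar formula."""
        return self.h_**2 * self.sigma_ / self.xi_

    def replace(self, **kwargs) -> "LinearGaussianSystem":
        fields = {k: getattr(self, k)
                  for k in ("G", "H", "Sigma", "Xi", "b", "m0", "C0", "P0")}
        fields.update(kwargs)
        return LinearGaussianSystem(**fields)

    # JSON round trip --------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {k: np.asarray(getattr(self, k)).tolist()
                   for k in ("G", "H", "Sigma", "Xi", "b", "m0", "C0", "P0")}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LinearGaussianSystem":
        if isinstance(source, (str, bytes)) and not str(source).lstrip().startswith("{"):
            with open(source) as fh:
                payload = json.load(fh)
        elif isinstance(source, (str, bytes)):
            payload = json.loads(source)
        else:
            payload = json.load(source)
        return cls(**payload)


@dataclass(frozen=True)
class NonlinearSystem1D:
    """Scalar signal/observation pair with callable drift and observation maps."""

    g: Callable[[np.ndarray], np.ndarray]
    h: Callable[[np.ndarray], np.ndarray]
    Sigma: float
    Xi: float

    def __post_init__(self):
        if self.Sigma < 0:
            raise ValueError("Sigma must be >= 0")
        if self.Xi <= 0:
            raise ValueError("Xi must be > 0")

    def check_on_grid(self, x: np.ndarray) -> None:
        for name, fn in (("g", self.g), ("h", self.h)):
            vals = np.asarray(fn(x), dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"{name} is not finite on the configured domain")


@dataclass(frozen=True)
class FitnessParams:
    """Replication weight r > 0 and conformity weight s < r.

    ``(r, s) = (1, 0)`` is the exact Bayesian (Kalman--Bucy) case.
    """

    r: float
    s: float = 0.0

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if self.s >= self.r:
            raise ValueError("s must be < r")


@dataclass(frozen=True)
class TimeDiscretization:
    """Simulation horizon T, step dt and observation window delta_d.

    The horizon is split into ``d`` windows of width ``delta_d`` on which the
    smoothed observation derivative is constant; ``delta_d`` must be an
    integer multiple of ``dt`` and divide ``T`` exactly.
    """

    T: float
    dt: float
    delta_d: float | None = None

    def __post_init__(self):
        if self.T <= 0 or self.dt <= 0:
            raise ValueError("T and dt must be positive")
        dd = self.dt if self.delta_d is None else self.delta_d
        object.__setattr__(self, "delta_d", float(dd))
        if dd <= 0:
            raise ValueError("delta_d must be positive")
        if abs(dd / self.dt - round(dd / self.dt)) > 1e-9:
            raise ValueError("delta_d must be an integer multiple of dt")
        if abs(self.T / dd - round(self.T / dd)) > 1e-9:
            raise ValueError("T must be an integer multiple of delta_d")

    @property
    def n_steps(self) -> int:
        return int(round(self.T / self.dt))

    @property
    def d(self) -> int:
        """Number of observation windows."""
        return int(round(self.T / self.delta_d))

    @property
    def steps_per_window(self) -> int:
        return int(round(self.delta_d / self.dt))

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.T, self.n_steps + 1)

    @property
    def window_starts(self) -> np.ndarray:
        return np.arange(self.d) * self.delta_d

    def window_index(self, step: int) -> int:
        """Observation window containing simulation step ``step``."""
        return min(step // self.steps_per_window, self.d - 1)


@dataclass(frozen=True)
class Fig1Example:
    """Static-signal scalar example: g=0, Sigma=0, h(x)=Hx.

    The signal is frozen at ``x0_star`` so the smoothed observation
    derivative on each window is an i.i.d. N(H x0*, Xi/delta_d) draw.
    """

    H: float = 2.0
    Xi: float = 1.0
    m0: float = 0.0
    P0: float = 0.3
    x0_star: float = 5.0
    delta_d_steps: int = 500  # delta_d = 500 * dt

    @property
    def system1d(self) -> NonlinearSystem1D:
        H = self.H
        return NonlinearSystem1D(g=lambda x: np.zeros_like(x),
                                 h=lambda x: H * np.asarray(x, dtype=float),
                                 Sigma=0.0, Xi=self.Xi)


@dataclass(frozen=True)
class AdmissibilityReport:
    """Outcome of the (r, s) admissibility checks for a given system.

    Spectral failures are recorded as flags rather than raised: a user may
    legitimately want to evaluate an inadmissible pair to see it diverge.
    """

    r: float
    s: float
    r_positive: bool
    s_below_r: bool
    s_bound: float | None          # scalar-only closed-form bound on s
    s_below_bound: bool | None
    alpha_A_inf: float
    alpha_A_inf_sym: float
    stable: bool                   # alpha(A_inf) < 0
    sym_stable: bool               # alpha(A_inf + A_inf^T) < 0
    controllable: bool
    observable: bool

    @property
    def admissible(self) -> bool:
        ok = self.r_positive and self.s_below_r and self.stable and self.sym_stable
        if self.s_below_bound is not None:
            ok = ok and self.s_below_bound
        return ok and self.controllable and self.observable


def _rank_conditions(sys: LinearGaussianSystem) -> tuple[bool, bool]:
    """Controllability of (G, Sigma^{1/2}) and observability of (G, H)."""
    m = sys.m
    w, V = np.linalg.eigh(sys.Sigma)
    sqrt_sigma = V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T
    ctrl_blocks, obs_blocks = [], []
    Gp = np.eye(m)
    for _ in range(m):
        ctrl_blocks.append(Gp @ sqrt_sigma)
        obs_blocks.append(sys.H @ Gp)
        Gp = Gp @ sys.G
    ctrl = np.hstack(ctrl_blocks)
    obs = np.vstack(obs_blocks)
    return (np.linalg.matrix_rank(ctrl) == m, np.linalg.matrix_rank(obs) == m)


def validate_fitness(fp: FitnessParams, sys: LinearGaussianSystem) -> AdmissibilityReport:
    """Check that (r, s) yields stable steady-state error dynamics.

    Computes the steady-state filter covariance C_inf for ``r``, forms
    ``A_inf = G - (r-s) C_inf H^T Xi^{-1} H`` and checks the spectral abscissa
    of ``A_inf`` and of its symmetrisation.  For scalar systems the
    closed-form admissible-``s`` bound is evaluated as well.
    """
    from .gaussian_filter import riccati_steady_state  # local: avoid cycle

    r, s = fp.r, fp.s
    if r <= 0:
        raise ValueError("r must be > 0")
    if s >= r:
        raise ValueError("s must be < r")

    C_inf = riccati_steady_state(sys, r)
    Xi_inv = np.linalg.inv(sys.Xi)
    A_inf = sys.G - (r - s) * C_inf @ sys.H.T @ Xi_inv @ sys.H
    alpha = float(np.max(np.real(np.linalg.eigvals(A_inf))))
    alpha_sym = float(np.max(np.linalg.eigvalsh(A_inf + A_inf.T)))

    s_bound = s_below = None
    if sys.is_scalar:
        y = np.sqrt(sys.g_**2 + r * sys.snr_)
        s_bound = float(min(r, r * y / (sys.g_ + y)))
        s_below = bool(s < s_bound)

    ctrl, obs = _rank_conditions(sys)
    return AdmissibilityReport(
        r=r, s=s, r_positive=True, s_below_r=True,
        s_bound=s_bound, s_below_bound=s_below,
        alpha_A_inf=alpha, alpha_A_inf_sym=alpha_sym,
        stable=bool(alpha < -_SPECTRAL_TOL),
        sym_stable=bool(alpha_sym < -_SPECTRAL_TOL),
        controllable=ctrl, observable=obs,
    )


_TABLE_SYSTEMS = {
    # name -> (G, H, Sigma, Xi, b)
    "system1": (0.5, 8.5, 0.8, 6.3, 9.9),
    "system2": (2.5, 2.9, 18.0, 26.0, 1.2),
}


def builtin_fixture(name: str):
    """Packaged experiment configurations.

    ``system1`` / ``system2`` return the two scalar misspecified systems used
    throughout the steady-state analysis (C0 and P0 default to the
    perfect-model steady-state covariance; analyses that need C0 = C_inf(r)
    set it themselves).  ``fig1`` returns the static-signal example.
    """
    if name == "fig1":
        return Fig1Example()
    if name not in _TABLE_SYSTEMS:
        raise KeyError(f"unknown fixture {name!r}; choose from "
                       f"{sorted(_TABLE_SYSTEMS) + ['fig1']}")
    G, H, Sigma, Xi, b = _TABLE_SYSTEMS[name]
    # perfect-model steady-state covariance, Riccati closed form at r=1
    snr = H * H * Sigma / Xi
    c_hat = (G + np.sqrt(G * G + snr)) / (H * H / Xi)
    return LinearGaussianSystem(G=G, H=H, Sigma=Sigma, Xi=Xi, b=b,
                                m0=0.0, C0=c_hat, P0=c_hat)
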