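"""Asymptotic error analysis for biased linear-Gaussian filtering.

The signal truly evolves as dX = G X dt + b dt + Sigma^{1/2} dW but the
filter assumes b = 0.  The tracking error eps_t = m_t - x*_t then carries a
persistent bias, and the asymptotic mean-squared error decomposes as

    E_inf = Tr(P_inf) + nu_inf,   nu_inf = ||A_inf^{-1} b||^2,

where A_inf = G - (r - s) K_inf H governs the error dynamics.  In the scalar
case everything is available in closed form, including the fitness weights
(r, s) minimising E_inf: the optimal error rate A_inf* solves a depressed
cubic, s_opt(r) follows from it, and a unique 'calibrated' pair (r*, s*)
additionally makes the reported covariance C_inf equal the achieved MSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_continuous_lyapunov

from .systems import FitnessParams, LinearGaussianSystem, TimeDiscretization
from .gaussian_filter import riccati_steady_state

__all__ = [
    "ErrorTrajectory",
    "SteadyStateReport",
    "OptimaReport",
    "a_infty",
    "error_moments_solve",
    "nu_infty",
    "e_infty",
    "e_infty_bound",
    "a_star",
    "s_opt",
    "s_bounds",
    "r_opt",
    "r0_opt",
    "joint_optimum",
    "perfect_covariance",
    "overconfidence",
    "steady_state_report",
    "optima_report",
]

_BISECT_TOL = 1e-10


# ----------------------------------------------------------------------
# steady-state quantities

def a_infty(sys: LinearGaussianSystem, fp: FitnessParams) -> np.ndarray:
    """Steady-state error-dynamics matrix A_inf = G - (r-s) C_inf H' Xi^{-1} H.

    The scalar result is cross-checked against the closed form
    (s/r) G - ((r-s)/r) sqrt(G^2 + r H^2 Xi^{-1} Sigma).
    """
    r, s = fp.r, fp.s
    C = riccati_steady_state(sys, r)
    A = sys.G - (r - s) * C @ sys.H.T @ np.linalg.inv(sys.Xi) @ sys.H
    if sys.is_scalar:
        closed = (s / r) * sys.g_ - ((r - s) / r) * np.sqrt(
            sys.g_**2 + r * sys.snr_)
        if abs(closed - A[0, 0]) > 1e-8 * max(1.0, abs(closed)):
            raise AssertionError("scalar A_inf closed form disagrees with "
                                 "the gain-based value")
    return A


def _check_stability(A: np.ndarray) -> None:
    if np.max(np.real(np.linalg.eigvals(A))) >= 0:
        raise ValueError("alpha(A_inf) >= 0: error dynamics unstable for "
                         "this (r, s); no stationary MSE exists")
    if np.max(np.linalg.eigvalsh(A + A.T)) >= 0:
        raise ValueError("alpha(A_inf + A_inf^T) >= 0: symmetrised stability "
                         "assumption violated")


def nu_infty(sys: LinearGaussianSystem, fp: FitnessParams) -> float:
    """Asymptotic squared bias ||A_inf^{-1} b||^2."""
    A = a_infty(sys, fp)
    _check_stability(A)
    v = np.linalg.solve(A, sys.b)
    return float(v @ v)


def _lyapunov_x_inf(A: np.ndarray) -> np.ndarray:
    """Unique X solving A^T X + X A + I = 0."""
    X = solve_continuous_lyapunov(A.T, -np.eye(A.shape[0]))
    return (X + X.T) / 2


def e_infty(sys: LinearGaussianSystem, fp: FitnessParams) -> float:
    """Asymptotic mean-squared error E_inf.

    Scalar systems use the closed form
    E_inf = -(Sigma + (G - A_inf)^2 Xi / H^2) / (2 A_inf) + (b / A_inf)^2;
    matrix systems evaluate the trace/Lyapunov representation
    Tr[(Sigma + (r-s)(G - A_inf) C_inf - 2 A_inf^{-1} b b^T) X_inf].
    The two coincide on 1x1 inputs.
    """
    r, s = fp.r, fp.s
    A = a_infty(sys, fp)
    _check_stability(A)
    if sys.is_scalar:
        a = float(A[0, 0])
        quad = (sys.g_ - a) ** 2 * sys.xi_ / sys.h_**2
        return float(-0.5 * (sys.sigma_ + quad) / a + (sys.b_ / a) ** 2)
    C = riccati_steady_state(sys, r)
    X = _lyapunov_x_inf(A)
    Ainv_b = np.linalg.solve(A, sys.b)
    M = (sys.Sigma + (r - s) * (sys.G - A) @ C
         - 2.0 * np.outer(Ainv_b, sys.b))
    return float(np.trace(M @ X))


def e_infty_bound(sys: LinearGaussianSystem, fp: FitnessParams) -> float:
    """Gronwall upper bound on E_inf (valid under the stability assumptions)."""
    r, s = fp.r, fp.s
    A = a_infty(sys, fp)
    _check_stability(A)
    C = riccati_steady_state(sys, r)
    alpha_sym = float(np.max(np.linalg.eigvalsh(A + A.T)))
    Ainv_b = np.linalg.solve(A, sys.b)
    HtXiH = sys.H.T @ np.linalg.inv(sys.Xi) @ sys.H
    # Tr[K Xi K'] = Tr[H'Xi^{-1}H C^2] <= alpha(H'Xi^{-1}H) ||C||_F^2
    gamma = (-2.0 * float(Ainv_b @ sys.b) + float(np.trace(sys.Sigma))
             + (r - s) ** 2 * float(np.max(np.linalg.eigvalsh(HtXiH)))
             * float(np.linalg.norm(C)) ** 2)
    return -gamma / alpha_sym


# ----------------------------------------------------------------------
# transient error moments

@dataclass
class ErrorTrajectory:
    """Bias / covariance / MSE curves for a given (r, s).

    ``P_tilde = P + bias biasT`` holds exactly at every stored time, so the
    bias--variance identity E = Tr(P) + nu is satisfied by construction.
    """

    times: np.ndarray
    bias: np.ndarray          # (N+1, m) E[eps_t]
    P: np.ndarray             # (N+1, m, m) error covariance
    P_tilde: np.ndarray       # (N+1, m, m) mean-square matrix
    nu: np.ndarray            # (N+1,) squared bias
    E: np.ndarray             # (N+1,) MSE
    E_upper: np.ndarray       # Gronwall bound curve
    covariances: np.ndarray   # (N+1, m, m) filter covariance C_t


def error_moments_solve(sys: LinearGaussianSystem, fp: FitnessParams,
                        T: float, dt: float = 1e-4,
                        C0: np.ndarray | None = None,
                        P0: np.ndarray | None = None) -> ErrorTrajectory:
    """Integrate the bias and error-covariance ODEs with the C_t gain.

    C0 defaults to the steady state C_inf(r) (the calibrated setting used
    throughout the asymptotic analysis); P0 defaults to the system's P0.
    The bias ODE is d E[eps]/dt = A_t E[eps] - b with A_t = G - (r-s) K_t H.
    """
    r, s = fp.r, fp.s
    tg = TimeDiscretization(T=T, dt=dt)
    m = sys.m
    Xi_inv = np.linalg.inv(sys.Xi)
    HtXiH = sys.H.T @ Xi_inv @ sys.H
    alpha_HtXiH = float(np.max(np.linalg.eigvalsh(HtXiH)))

    C = (riccati_steady_state(sys, r) if C0 is None
         else np.atleast_2d(np.asarray(C0, float))).copy()
    P = (sys.P0 if P0 is None else np.atleast_2d(np.asarray(P0, float))).copy()
    e = np.zeros(m)

    N = tg.n_steps
    bias = np.empty((N + 1, m))
    Ps = np.empty((N + 1, m, m))
    Pts = np.empty((N + 1, m, m))
    covs = np.empty((N + 1, m, m))
    E_upper = np.empty(N + 1)
    E_bound = float(np.trace(P))  # E0 with zero initial bias

    for k in range(N + 1):
        bias[k] = e
        Ps[k] = P
        Pts[k] = P + np.outer(e, e)
        covs[k] = C
        E_upper[k] = E_bound
        if k == N:
            break
        K = C @ sys.H.T @ Xi_inv
        A = sys.G - (r - s) * K @ sys.H
        noise = sys.Sigma + (r - s) ** 2 * K @ sys.Xi @ K.T
        alpha_sym = float(np.max(np.linalg.eigvalsh(A + A.T)))
        dE_bound = (alpha_sym * E_bound - 2.0 * float(e @ sys.b)
                    + float(np.trace(sys.Sigma))
                    + (r - s) ** 2 * alpha_HtXiH * float(np.linalg.norm(C)) ** 2)
        e = e + dt * (A @ e - sys.b)
        P = P + dt * (A @ P + P @ A.T + noise)
        CHt = C @ sys.H.T
        C = C + dt * (sys.G @ C + C @ sys.G.T + sys.Sigma
                      - r * CHt @ Xi_inv @ CHt.T)
        E_bound = E_bound + dt * dE_bound

    nu = np.einsum("ki,ki->k", bias, bias)
    E = np.trace(Pts, axis1=1, axis2=2)
    return ErrorTrajectory(times=tg.times, bias=bias, P=Ps, P_tilde=Pts,
                           nu=nu, E=E, E_upper=E_upper, covariances=covs)


# ----------------------------------------------------------------------
# scalar optimal-(r, s) design

def _require_scalar(sys: LinearGaussianSystem):
    if not sys.is_scalar:
        raise ValueError("the optimal-(r, s) formulas are scalar-only")


def _cubic_coeffs(sys: LinearGaussianSystem) -> tuple[float, float, float]:
    """(p, q, tau) of the depressed cubic A^3 + p A + q = 0 for A_inf*."""
    p = -(sys.snr_ + sys.g_**2)
    q = 4.0 * sys.b_**2 * sys.h_**2 / sys.xi_
    tau = q * q / 4.0 + p**3 / 27.0
    return p, q, tau


def _cubic_value(A: float, p: float, q: float) -> float:
    return A**3 + p * A + q


def _a_star_bisect(p: float, q: float) -> float:
    """The unique negative real root of A^3 + p A + q (p < 0, q >= 0), found
    by bracketed bisection; independent oracle for the branch formulas."""
    hi = 0.0
    lo = -max(1.0, 2.0 * np.sqrt(-p), abs(q))
    while _cubic_value(lo, p, q) >= 0:
        lo *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _cubic_value(mid, p, q) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < _BISECT_TOL * max(1.0, abs(lo)):
            break
    return 0.5 * (lo + hi)


def a_star(sys: LinearGaussianSystem) -> tuple[float, float, float, float]:
    """MSE-optimal error rate A_inf* and its cubic data (A_inf*, p, q, tau).

    tau > 0: single real root via Cardano; tau < 0: three real roots, the
    negative one given by the k=2 trigonometric branch.  The printed-branch
    value is asserted against a bracketed-bisection root to 1e-8.
    """
    _require_scalar(sys)
    p, q, tau = _cubic_coeffs(sys)
    if tau > 0:
        root = (np.cbrt(-q / 2.0 + np.sqrt(tau))
                + np.cbrt(-q / 2.0 - np.sqrt(tau)))
    else:
        arg = (3.0 * q / (2.0 * p)) * np.sqrt(-3.0 / p)
        root = 2.0 * np.sqrt(-p / 3.0) * np.cos(
            np.arccos(np.clip(arg, -1.0, 1.0)) / 3.0 - 4.0 * np.pi / 3.0)
    oracle = _a_star_bisect(p, q)
    if abs(root - oracle) > 1e-8 * max(1.0, abs(oracle)):
        raise AssertionError(
            f"cubic branch root {root} disagrees with bisection {oracle}")
    if abs(_cubic_value(root, p, q)) > 1e-9 * max(1.0, abs(root) ** 3):
        raise AssertionError("cubic residual too large")
    return float(root), p, q, tau


def s_opt(sys: LinearGaussianSystem, r: float) -> float:
    """MSE-minimising s for fixed r:  s = r (A_inf* + y) / (G + y),
    y = sqrt(G^2 + r H^2 Xi^{-1} Sigma)."""
    _require_scalar(sys)
    if r <= 0:
        raise ValueError("r must be > 0")
    A_st = a_star(sys)[0]
    y = np.sqrt(sys.g_**2 + r * sys.snr_)
    return float(r * (A_st + y) / (sys.g_ + y))


def s_bounds(sys: LinearGaussianSystem) -> tuple[float, float]:
    """(s_l, s_u): the range of s values that can be MSE-optimal.

    s_l = -(G + A_inf*)^2 / (4 H^2 Xi^{-1} Sigma) is the minimum of
    s_opt over y; s_u is s_opt evaluated at the boundary y = |G| (zero
    exactly when G > 0).
    """
    _require_scalar(sys)
    A_st = a_star(sys)[0]
    snr = sys.snr_
    s_l = -(sys.g_ + A_st) ** 2 / (4.0 * snr)
    g_abs = abs(sys.g_)
    s_u = (g_abs - sys.g_) * (A_st + g_abs) / snr
    return float(s_l), float(s_u)


def r_opt(sys: LinearGaussianSystem, s: float) -> tuple[float, ...]:
    """MSE-minimising r value(s) for fixed s.

    Solves the quadratic y^2 + (A_inf* - G) y - G A_inf* - s H^2 Xi^{-1}
    Sigma = 0 and maps admissible roots (y > |G|) to r = (y^2 - G^2) /
    (H^2 Xi^{-1} Sigma).  Returns one or two roots, largest last.
    """
    _require_scalar(sys)
    A_st = a_star(sys)[0]
    snr = sys.snr_
    disc = (sys.g_ - A_st) ** 2 + 4.0 * (sys.g_ * A_st + s * snr)
    if disc < -1e-12 * max(1.0, (sys.g_ - A_st) ** 2):
        raise ValueError("s below s_l: no real optimal r exists")
    disc = max(disc, 0.0)
    sq = np.sqrt(disc)
    ys = [((sys.g_ - A_st) - sq) / 2.0, ((sys.g_ - A_st) + sq) / 2.0]
    roots = []
    for y in ys:
        if y > abs(sys.g_) + 1e-12:
            roots.append(float((y * y - sys.g_**2) / snr))
    if not roots:
        raise ValueError("no admissible root with y > |G| for this s")
    return tuple(sorted(set(np.round(roots, 14))))


def r0_opt(sys: LinearGaussianSystem) -> float:
    """MSE-minimising r for s = 0 (pure multiplicative inflation):
    r = ((A_inf*)^2 - G^2) / (H^2 Xi^{-1} Sigma)."""
    _require_scalar(sys)
    A_st = a_star(sys)[0]
    return float((A_st**2 - sys.g_**2) / sys.snr_)


def _rs_gap_target(sys: LinearGaussianSystem) -> float:
    """Right-hand side of the calibration identity for r - s at the joint
    optimum: (A*)^2 (G - A*) / (-A*/2 (H^2 Xi^{-1} Sigma + (G - A*)^2)
    + b^2 H^2 Xi^{-1})."""
    A_st = a_star(sys)[0]
    num = A_st**2 * (sys.g_ - A_st)
    den = (-0.5 * A_st * (sys.snr_ + (sys.g_ - A_st) ** 2)
           + sys.b_**2 * sys.h_**2 / sys.xi_)
    return num / den


def joint_optimum(sys: LinearGaussianSystem,
                  verify_tol: float = 1e-6) -> tuple[float, float]:
    """The unique (r*, s*) that minimises E_inf AND calibrates C_inf = E_inf.

    Solves r - s_opt(r) = target by bisection on r in (0, r0_opt + 1], then
    verifies the calibration |C_inf(r*) - E_inf(r*, s*)| / E_inf < tol.
    """
    _require_scalar(sys)
    target = _rs_gap_target(sys)

    def gap(r):
        return r - s_opt(sys, r) - target

    lo, hi = 1e-9, r0_opt(sys) + 1.0
    flo, fhi = gap(lo), gap(hi)
    while flo * fhi > 0 and hi < 1e6:
        hi *= 2.0
        fhi = gap(hi)
    if flo * fhi > 0:
        raise RuntimeError("no sign change bracketing the joint optimum")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if gap(mid) * flo <= 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < _BISECT_TOL:
            break
    r_star = 0.5 * (lo + hi)
    s_star = s_opt(sys, r_star)
    fp = FitnessParams(r=r_star, s=s_star)
    C = float(riccati_steady_state(sys, r_star)[0, 0])
    E = e_infty(sys, fp)
    if abs(C - E) / E > verify_tol:
        raise AssertionError(
            f"calibration failed: C_inf={C:.8g} vs E_inf={E:.8g}")
    return float(r_star), float(s_star)


def perfect_covariance(sys: LinearGaussianSystem) -> float:
    """Perfect-model Kalman--Bucy steady-state covariance
    (G + sqrt(G^2 + H^2 Xi^{-1} Sigma)) / (H^2 Xi^{-1})."""
    _require_scalar(sys)
    return float((sys.g_ + np.sqrt(sys.g_**2 + sys.snr_))
                 / (sys.h_**2 / sys.xi_))


def overconfidence(sys: LinearGaussianSystem) -> tuple[float, bool]:
    """Ratio C_inf(r0_opt) / C_hat_inf and whether it certifies overconfidence.

    For tau > 0 and G > 0 the ratio is provably < 1: pure multiplicative
    inflation tuned for MSE reports less uncertainty than even the
    perfect-model filter.
    """
    _require_scalar(sys)
    r0 = r0_opt(sys)
    ratio = float(riccati_steady_state(sys, r0)[0, 0]) / perfect_covariance(sys)
    tau = _cubic_coeffs(sys)[2]
    flag = bool(tau > 0 and sys.g_ > 0)
    if flag and not ratio < 1.0:
        raise AssertionError("overconfidence bound violated (tau>0, G>0)")
    return ratio, flag


# ----------------------------------------------------------------------
# reports

@dataclass
class SteadyStateReport:
    r: float
    s: float
    A_inf: float
    C_inf: float
    K_inf: float
    nu_inf: float
    E_inf: float
    E_upper: float
    X_inf: float
    p: float
    q: float
    tau: float
    A_star: float


@dataclass
class OptimaReport:
    s_l: float
    s_u: float
    r0_opt: float
    r_star: float
    s_star: float
    A_star: float
    tau: float
    C_hat_inf: float
    C_inf_r0: float
    overconfidence_ratio: float
    E_inf_opt: float


def steady_state_report(sys: LinearGaussianSystem,
                        fp: FitnessParams) -> SteadyStateReport:
    _require_scalar(sys)
    A = float(a_infty(sys, fp)[0, 0])
    C = float(riccati_steady_state(sys, fp.r)[0, 0])
    A_st, p, q, tau = a_star(sys)
    X = float(_lyapunov_x_inf(np.array([[A]]))[0, 0])
    return SteadyStateReport(
        r=fp.r, s=fp.s, A_inf=A, C_inf=C,
        K_inf=C * sys.h_ / sys.xi_,
        nu_inf=nu_infty(sys, fp), E_inf=e_infty(sys, fp),
        E_upper=e_infty_bound(sys, fp), X_inf=X,
        p=p, q=q, tau=tau, A_star=A_st)


def optima_report(sys: LinearGaussianSystem) -> OptimaReport:
    _require_scalar(sys)
    A_st, _, _, tau = a_star(sys)
    s_l, s_u = s_bounds(sys)
    r0 = r0_opt(sys)
    r_star, s_star = joint_optimum(sys)
    c_hat = perfect_covariance(sys)
    c_r0 = float(riccati_steady_state(sys, r0)[0, 0])
    return OptimaReport(
        s_l=s_l, s_u=s_u, r0_opt=r0, r_star=r_star, s_star=s_star,
        A_star=A_st, tau=tau, C_hat_inf=c_hat, C_inf_r0=c_r0,
        overconfidence_ratio=c_r0 / c_hat,
        E_inf_opt=e_infty(sys, FitnessParams(r=r_star, s=s_star)))
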