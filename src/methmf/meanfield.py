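"""Mean-field models of the nearest-neighbour collaborative system.

Three approximations of increasing fidelity are solved for their
steady-state statistics:

* **one-site**: every site sees only the mean u/h/m occupancies; the
  steady state solves a pair of implicit equations for (mu_u, mu_h).
* **DPMF** (distinct-pairs): the lattice is tiled by non-overlapping pairs;
  a pair interacts internally and with the *mean* state of pairs.
* **OPMF** (overlapping-pairs): every site belongs to two pairs; flanking
  influence enters through conditional probabilities given the shared site.

Each pair model is a six-state continuous-time chain over the unordered
pair states (mm, uu, hh, um, hm, uh) whose twelve effective rates depend on
the pair proportions themselves; the steady state is the self-consistent
fixed point found by damped iteration (stationary distribution of the
generator built at the current proportions, mixed back with damping 0.5).
All steady-state statistics are independent of the rate scale ``a``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .reaction_model import Params, ReactionRates, rates_from_params
from .sumstats import SummaryStats

__all__ = [
    "PAIR_STATE_NAMES",
    "OneSiteSolution",
    "PairSolution",
    "SensitivityResult",
    "SolverError",
    "onesite_steady_state",
    "onesite_statistics",
    "onesite_moment_ode_rhs",
    "integrate_onesite_second_moments",
    "dpmf_rates",
    "opmf_rates",
    "pair_steady_state",
    "pair_statistics",
    "model_statistics",
    "model_moments",
    "relative_sensitivity",
]

# unordered pair states, in the fixed order used for mu_1..mu_6
PAIR_STATE_NAMES = ("mm", "uu", "hh", "um", "hm", "uh")

# transitions of the effective six-state pair chain: (from, to) for rates 1..12
_PAIR_FROM = np.array([0, 1, 2, 2, 3, 3, 4, 4, 4, 5, 5, 5], dtype=np.int64)
_PAIR_TO = np.array([4, 5, 5, 4, 4, 5, 3, 0, 2, 2, 1, 3], dtype=np.int64)

# mean z of each pair state ((z_left + z_right) / 2) and z_left * z_right
_PAIR_ZBAR = np.array([3.0, 1.0, 2.0, 2.0, 2.5, 1.5])
_PAIR_VW = np.array([9.0, 1.0, 4.0, 3.0, 6.0, 2.0])


class SolverError(RuntimeError):
    """No physical self-consistent fixed point was found."""


# --------------------------------------------------------------------------
# one-site model
# --------------------------------------------------------------------------

@dataclass
class OneSiteSolution:
    mu_u: float
    mu_h: float
    mu_m: float
    a1s: float
    a2s: float
    a3s: float
    a4s: float
    residual: float


@njit(cache=True)
def _onesite_fp_nb(k, tol, max_iter):
    """Damped one-site self-consistency iteration on (mu_u, mu_h)."""
    mu_u = 1.0 / 3.0
    mu_h = 1.0 / 3.0
    res = 1.0e300
    for _ in range(max_iter):
        mu_m = 1.0 - mu_u - mu_h
        a1 = k[2] + 2 * k[8] * mu_h + 2 * k[9] * mu_u
        a2 = k[1] + 4 * k[6] * mu_h + 2 * k[7] * mu_m
        a3 = k[0] + 2 * k[4] * mu_h + 2 * k[5] * mu_m
        a4 = k[3] + 4 * k[10] * mu_h + 2 * k[11] * mu_u
        den = a1 * a3 + a2 * a3 + a1 * a4
        if den <= 0.0:
            nu, nh = 1.0, 0.0
        else:
            nu = a1 * a4 / den
            nh = a1 * a3 / den
        res = max(abs(nu - mu_u), abs(nh - mu_h))
        mu_u = 0.5 * mu_u + 0.5 * nu
        mu_h = 0.5 * mu_h + 0.5 * nh
        if res < tol:
            break
    return mu_u, mu_h, res


def _onesite_effective_rates(k: ReactionRates, mu_u: float, mu_h: float):
    """Effective first-order rates a1..a4 at mean occupancies (mu_u, mu_h).

    The k7/k11 terms carry an extra factor of two because their reactions
    involve two h reactants, either of which can change state.
    """
    mu_m = 1.0 - mu_u - mu_h
    a1 = k.k3 + 2 * k.k9 * mu_h + 2 * k.k10 * mu_u   # m -> h
    a2 = k.k2 + 4 * k.k7 * mu_h + 2 * k.k8 * mu_m    # h -> m
    a3 = k.k1 + 2 * k.k5 * mu_h + 2 * k.k6 * mu_m    # u -> h
    a4 = k.k4 + 4 * k.k11 * mu_h + 2 * k.k12 * mu_u  # h -> u
    return a1, a2, a3, a4


def _onesite_map(k: ReactionRates, mu_u: float, mu_h: float):
    """One application of the self-consistency map (mu_u, mu_h) -> (mu_u', mu_h')."""
    a1, a2, a3, a4 = _onesite_effective_rates(k, mu_u, mu_h)
    den = a1 * a3 + a2 * a3 + a1 * a4
    if den <= 0:
        # all rates into/out of h vanish together only if every k_i is 0,
        # which Params forbids; guard anyway
        return 1.0, 0.0
    return a1 * a4 / den, a1 * a3 / den


def onesite_steady_state(
    x: float,
    y: float,
    a: float = 1.0,
    tol: float = 1e-14,
    max_iter: int = 100_000,
) -> OneSiteSolution:
    """Self-consistent steady state of the one-site mean-field model.

    Independent of ``a``; the argument only scales the reported effective
    rates.  At x = 0 the solution has the closed form
    ``(1, y, y^2) / (1 + y + y^2)``.
    """
    k = rates_from_params(Params(a=a, x=x, y=y))
    mu_u, mu_h, res = _onesite_fp_nb(k.as_array(), tol, max_iter)
    if not res < 1e-10:
        # multi-start fallback via a root finder on the residual map
        def f(v):
            nu, nh = _onesite_map(k, v[0], v[1])
            return [nu - v[0], nh - v[1]]

        rng = np.random.default_rng(0)
        starts = [np.array([1 / 3, 1 / 3])] + [
            rng.dirichlet(np.ones(3))[:2] for _ in range(10)
        ]
        for s in starts:
            sol = root(f, s, method="hybr", tol=1e-14)
            v = sol.x
            if sol.success and v[0] >= -1e-12 and v[1] >= -1e-12 and v.sum() <= 1 + 1e-12:
                mu_u, mu_h = float(np.clip(v[0], 0, 1)), float(np.clip(v[1], 0, 1))
                nu, nh = _onesite_map(k, mu_u, mu_h)
                res = max(abs(nu - mu_u), abs(nh - mu_h))
                break
        else:
            raise SolverError(f"one-site fixed point not found at x={x}, y={y}")
    a1, a2, a3, a4 = _onesite_effective_rates(k, mu_u, mu_h)
    return OneSiteSolution(
        mu_u=mu_u, mu_h=mu_h, mu_m=1.0 - mu_u - mu_h,
        a1s=a1, a2s=a2, a3s=a3, a4s=a4, residual=res,
    )


def onesite_statistics(sol: OneSiteSolution) -> SummaryStats:
    """Site statistics implied by the one-site solution.

    Uses the indicator moment collapse <L_i L_i> = mu_i, <L_i L_j> = 0, so
    variances are mu - mu^2 and covariances -mu mu'.  The model carries no
    spatial information: neighbour covariance/correlation are unavailable
    (``None``).
    """
    mu_u, mu_h, mu_m = sol.mu_u, sol.mu_h, sol.mu_m
    var_u = mu_u - mu_u**2
    var_h = mu_h - mu_h**2
    var_m = var_u + var_h + 2 * (-mu_u * mu_h)
    cov_uh = -mu_u * mu_h
    cov_um = -var_u - cov_uh
    cov_hm = -cov_uh - var_h
    mu_z = mu_u + 2 * mu_h + 3 * mu_m
    var_z = var_u + 4 * var_h + 9 * var_m + 2 * (2 * cov_uh + 3 * cov_um + 6 * cov_hm)
    return SummaryStats(
        mu_u=mu_u, mu_h=mu_h, mu_m=mu_m,
        mu_z=mu_z, var_z=var_z, covar_z=None, rho_z=None,
    )


def onesite_moment_ode_rhs(t, m, a1, a2, a3, a4, mu_u, mu_h):
    """RHS of the one-site second-moment equations at fixed effective rates.

    ``m = (<LuLu>, <LuLh>, <LhLh>)``.  With the effective rates and means
    held at their steady-state values, the stationary point of this linear
    system reproduces the indicator collapse <LuLu> = mu_u, <LuLh> = 0,
    <LhLh> = mu_h.
    """
    muu, muh, mhh = m
    d_uu = -2 * a3 * muu + 2 * a4 * muh + a4 * mu_h + a3 * mu_u
    d_uh = (
        -a1 * (muu + muh)
        - a2 * muh
        + a3 * (muu - muh)
        - a4 * (muh - mhh)
        + a1 * mu_u
        - a3 * mu_u
        - a4 * mu_h
    )
    d_hh = (
        -2 * a1 * (muh + mhh)
        - 2 * a2 * mhh
        + 2 * a3 * muh
        - 2 * a4 * mhh
        + a1 * (1 - mu_u + mu_h)
        + a2 * mu_h
        + a3 * mu_u
        + a4 * mu_h
    )
    return [d_uu, d_uh, d_hh]


def integrate_onesite_second_moments(
    sol: OneSiteSolution, m0=(0.0, 0.0, 0.0), t_max: float = 500.0
) -> tuple[float, float, float]:
    """Integrate the second-moment ODEs to stationarity.

    Returns the final ``(<LuLu>, <LuLh>, <LhLh>)``; independent of the
    initial condition for any physical steady state.
    """
    args = (sol.a1s, sol.a2s, sol.a3s, sol.a4s, sol.mu_u, sol.mu_h)
    res = solve_ivp(
        onesite_moment_ode_rhs, (0.0, t_max), list(m0), args=args,
        rtol=1e-12, atol=1e-12, method="LSODA",
    )
    return tuple(float(v) for v in res.y[:, -1])


# --------------------------------------------------------------------------
# pair models: effective rates (numba kernels with thin validated wrappers)
# --------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _cond(num, den):
    """Conditional-probability ratio, defined as 0 on an empty condition."""
    return num / den if den > 0.0 else 0.0


@njit(cache=True)
def _dpmf_rates_nb(m, k):
    a = np.empty(12)
    a[0] = 2 * k[2] + k[8] * (2 * m[2] + m[4] + m[5]) + k[9] * (2 * m[1] + m[3] + m[5])
    a[1] = 2 * k[0] + k[4] * (2 * m[2] + m[4] + m[5]) + k[5] * (2 * m[0] + m[3] + m[4])
    a[2] = (
        2 * k[3] + 2 * k[10]
        + k[10] * (4 * m[2] + m[4] + m[5])
        + k[11] * (2 * m[1] + m[3] + m[5])
    )
    a[3] = (
        2 * k[1] + 2 * k[6]
        + k[6] * (4 * m[2] + m[4] + m[5])
        + k[7] * (2 * m[0] + m[3] + m[4])
    )
    a[4] = (
        k[0] + k[5]
        + k[4] * (m[2] + m[4] / 2 + m[5] / 2)
        + k[5] * (m[0] + m[3] / 2 + m[4] / 2)
    )
    a[5] = (
        k[2] + k[9]
        + k[8] * (m[2] + m[4] / 2 + m[5] / 2)
        + k[9] * (m[1] + m[3] / 2 + m[5] / 2)
    )
    a[6] = (
        k[3]
        + k[10] * (m[2] + m[4] + m[5] / 2)
        + k[11] * (m[1] + m[3] / 2 + m[5] / 2)
    )
    a[7] = (
        k[1] + k[7]
        + k[6] * (m[2] + m[4] + m[5] / 2)
        + k[7] * (m[0] + m[3] / 2 + m[4] / 2)
    )
    a[8] = (
        k[2] + k[8]
        + k[8] * (m[2] + m[4] / 2 + m[5] / 2)
        + k[9] * (m[1] + m[3] / 2 + m[5] / 2)
    )
    a[9] = (
        k[0] + k[4]
        + k[4] * (m[2] + m[4] / 2 + m[5] / 2)
        + k[5] * (m[0] + m[3] / 2 + m[4] / 2)
    )
    a[10] = (
        k[3] + k[11]
        + k[10] * (m[2] + m[4] / 2 + m[5])
        + k[11] * (m[1] + m[3] / 2 + m[5] / 2)
    )
    a[11] = (
        k[1]
        + k[6] * (m[2] + m[4] / 2 + m[5])
        + k[7] * (m[0] + m[3] / 2 + m[4] / 2)
    )
    return a


@njit(cache=True)
def _opmf_rates_nb(m, k):
    # conditional denominators: pair-level m, u, h occupancies
    dm = m[0] + m[3] / 2 + m[4] / 2
    du = m[1] + m[3] / 2 + m[5] / 2
    dh = m[2] + m[4] / 2 + m[5] / 2
    qm_h = _cond(m[4] / 2, dm)  # P(flank h | shared m)
    qm_u = _cond(m[3] / 2, dm)  # P(flank u | shared m)
    qu_h = _cond(m[5] / 2, du)  # P(flank h | shared u)
    qu_m = _cond(m[3] / 2, du)  # P(flank m | shared u)
    qh_h = _cond(m[2], dh)      # P(flank h | shared h)
    qh_u = _cond(m[5] / 2, dh)  # P(flank u | shared h)
    qh_m = _cond(m[4] / 2, dh)  # P(flank m | shared h)
    a = np.empty(12)
    a[0] = 2 * k[2] + 2 * k[8] * qm_h + 2 * k[9] * qm_u
    a[1] = 2 * k[0] + 2 * k[4] * qu_h + 2 * k[5] * qu_m
    a[2] = 2 * k[3] + 2 * k[10] + 2 * k[10] * qh_h + 2 * k[11] * qh_u
    a[3] = 2 * k[1] + 2 * k[6] + 2 * k[6] * qh_h + 2 * k[7] * qh_m
    a[4] = k[0] + k[5] + k[4] * qu_h + k[5] * qu_m
    a[5] = k[2] + k[9] + k[8] * qm_h + k[9] * qm_u
    a[6] = k[3] + k[10] * qh_h + k[11] * qh_u
    a[7] = k[1] + k[7] + k[6] * qh_h + k[7] * qh_m
    a[8] = k[2] + k[8] + k[8] * qm_h + k[9] * qm_u
    a[9] = k[0] + k[4] + k[4] * qu_h + k[5] * qu_m
    a[10] = k[3] + k[11] + k[10] * qh_h + k[11] * qh_u
    a[11] = k[1] + k[6] * qh_h + k[7] * qh_m
    return a


@njit(cache=True)
def _pair_stationary_nb(rates):
    """Stationary distribution of the six-state chain with the given rates.

    Solves pi Q = 0 with the normalization row replacing one (redundant)
    balance equation.
    """
    A = np.zeros((6, 6))
    for idx in range(12):
        f = _PAIR_FROM[idx]
        t = _PAIR_TO[idx]
        r = rates[idx]
        A[t, f] += r
        A[f, f] -= r
    for j in range(6):
        A[5, j] = 1.0
    b = np.zeros(6)
    b[5] = 1.0
    return np.linalg.solve(A, b)


@njit(cache=True)
def _pair_fixed_point_nb(kind, k, mu0, damping, tol, max_iter):
    """Damped self-consistent iteration; kind 0 = DPMF, 1 = OPMF.

    Returns (mu, residual, iterations).
    """
    mu = mu0.copy()
    res = 1.0e300
    it = 0
    for it in range(max_iter):
        if kind == 0:
            rates = _dpmf_rates_nb(mu, k)
        else:
            rates = _opmf_rates_nb(mu, k)
        pi = _pair_stationary_nb(rates)
        res = 0.0
        for j in range(6):
            d = abs(pi[j] - mu[j])
            if d > res:
                res = d
        for j in range(6):
            mu[j] = (1.0 - damping) * mu[j] + damping * pi[j]
        if res < tol:
            break
    return mu, res, it + 1


def _validate_simplex(mu, tol: float = 1e-9) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (6,):
        raise ValueError("pair proportions must have 6 components")
    if np.any(mu < -tol) or abs(mu.sum() - 1.0) > max(tol, 1e-6):
        raise ValueError(f"pair proportions outside the simplex: {mu}")
    return np.clip(mu, 0.0, None)


def _k_array(k) -> np.ndarray:
    return k.as_array() if isinstance(k, ReactionRates) else np.asarray(k, float)


def dpmf_rates(mu, k) -> np.ndarray:
    """Twelve DPMF effective rates at pair proportions ``mu`` (mm,uu,hh,um,hm,uh)."""
    return _dpmf_rates_nb(_validate_simplex(mu), _k_array(k))


def opmf_rates(mu, k) -> np.ndarray:
    """Twelve OPMF effective rates; conditional terms are 0 on empty conditions."""
    return _opmf_rates_nb(_validate_simplex(mu), _k_array(k))


# --------------------------------------------------------------------------
# pair steady state
# --------------------------------------------------------------------------

@dataclass
class PairSolution:
    """Self-consistent pair-state proportions of the DPMF/OPMF model."""

    model_kind: str
    mu: np.ndarray       # (mm, uu, hh, um, hm, uh)
    rates: np.ndarray    # effective rates at the fixed point
    residual: float
    branches: Optional[list] = None  # all distinct fixed points, if > 1


_KIND_CODE = {"dpmf": 0, "opmf": 1}


def _product_measure(x: float, y: float) -> np.ndarray:
    """Independent-sites pair proportions built from the one-site solution."""
    k = rates_from_params(Params(a=1.0, x=x, y=y)).as_array()
    pu, ph, res = _onesite_fp_nb(k, 1e-14, 100_000)
    if not res < 1e-10:
        s = onesite_steady_state(x, y)
        pu, ph = s.mu_u, s.mu_h
    pm = 1.0 - pu - ph
    return np.array(
        [pm * pm, pu * pu, ph * ph, 2 * pu * pm, 2 * ph * pm, 2 * pu * ph]
    )


def _solve_pair_once(kind: int, k: np.ndarray, start: np.ndarray, tol: float,
                     max_iter: int) -> Optional[tuple[np.ndarray, float]]:
    try:
        mu, res, _ = _pair_fixed_point_nb(kind, k, start, 0.5, tol, max_iter)
    except Exception:
        return None
    if not np.isfinite(mu).all():
        return None
    if np.any(mu < -1e-8) or abs(mu.sum() - 1.0) > 1e-6:
        return None
    if res > 1e-9:
        return None
    return np.clip(mu, 0.0, None), res


def _root_fallback(kind: int, k: np.ndarray, starts) -> Optional[tuple[np.ndarray, float]]:
    rates_fn = _dpmf_rates_nb if kind == 0 else _opmf_rates_nb

    def f(v5):
        mu = np.empty(6)
        mu[:5] = v5
        mu[5] = 1.0 - v5.sum()
        mu = np.clip(mu, 0.0, 1.0)
        mu /= mu.sum()
        try:
            pi = _pair_stationary_nb(rates_fn(mu, k))
        except Exception:
            return np.full(5, 1e6)
        return (pi - mu)[:5]

    for s in starts:
        sol = root(f, s[:5], method="hybr", tol=1e-13)
        if not sol.success:
            continue
        mu = np.empty(6)
        mu[:5] = sol.x
        mu[5] = 1.0 - sol.x.sum()
        if np.any(mu < -1e-8) or np.any(mu > 1 + 1e-8):
            continue
        mu = np.clip(mu, 0.0, None)
        mu /= mu.sum()
        res = float(np.max(np.abs(f(mu[:5]))))
        if res < 1e-9:
            return mu, res
    return None


def pair_steady_state(
    model_kind: str,
    x: float,
    y: float,
    a: float = 1.0,
    tol: float = 1e-12,
    max_iter: int = 100_000,
    probe_multiplicity: bool = True,
) -> PairSolution:
    """Self-consistent steady state of the DPMF or OPMF model.

    Starts the damped iteration from the independent-sites product measure.
    A handful of seeded random simplex starts probe for additional physical
    fixed points; if distinct ones are found, the principal branch is
    selected by continuation in y from the unique y = 0.1 regime and all
    branches are reported.
    """
    kind = _KIND_CODE.get(model_kind)
    if kind is None:
        raise ValueError(f"model_kind must be 'dpmf' or 'opmf', got {model_kind!r}")
    k = rates_from_params(Params(a=a, x=x, y=y)).as_array()
    start = _product_measure(x, y)
    principal = _solve_pair_once(kind, k, start, tol, max_iter)

    solutions: list[np.ndarray] = []
    if principal is not None:
        solutions.append(principal[0])
    if probe_multiplicity or principal is None:
        rng = np.random.default_rng(12345)
        extra = [np.full(6, 1.0 / 6.0)] + [rng.dirichlet(np.ones(6)) for _ in range(4)]
        for s in extra:
            got = _solve_pair_once(kind, k, s, tol, max_iter)
            if got is None:
                continue
            if not any(np.max(np.abs(got[0] - u)) < 1e-6 for u in solutions):
                solutions.append(got[0])

    if not solutions:
        rng = np.random.default_rng(6789)
        starts = [start, np.full(6, 1.0 / 6.0)] + [
            rng.dirichlet(np.ones(6)) for _ in range(10)
        ]
        got = _root_fallback(kind, k, starts)
        if got is None:
            raise SolverError(
                f"no physical fixed point for {model_kind} at x={x}, y={y}"
            )
        solutions.append(got[0])

    if len(solutions) > 1:
        mu = _continuation_select(kind, k, x, y, tol, max_iter, solutions)
    else:
        mu = solutions[0]

    rates_fn = _dpmf_rates_nb if kind == 0 else _opmf_rates_nb
    rates = rates_fn(mu, k)
    res = float(np.max(np.abs(_pair_stationary_nb(rates) - mu)))
    return PairSolution(
        model_kind=model_kind,
        mu=mu,
        rates=rates,
        residual=res,
        branches=solutions if len(solutions) > 1 else None,
    )


def _continuation_select(kind, k_target, x, y, tol, max_iter, solutions):
    """Principal branch by stepping y up from the unique y = 0.1 regime."""
    y0 = min(0.1, y)
    ys = np.linspace(y0, y, max(2, int(abs(y - y0) / 0.05) + 2))
    mu = _product_measure(x, y0)
    for yi in ys:
        ki = rates_from_params(Params(a=1.0, x=x, y=float(yi))).as_array()
        got = _solve_pair_once(kind, ki, mu, tol, max_iter)
        if got is None:
            break
        mu = got[0]
    # snap to the nearest of the candidate fixed points at the target
    dists = [np.max(np.abs(mu - s)) for s in solutions]
    return solutions[int(np.argmin(dists))]


def pair_statistics(sol: PairSolution) -> SummaryStats:
    """Site-level statistics implied by a pair-model solution.

    Means come from splitting mixed pairs evenly; <vw> weights each pair
    state by the product of its two z codes; the site-to-site variance
    follows from the pair-level variance of (v + w)/2 via
    ``var_z = 2 var(z_pair) - covar_z``.
    """
    mu = np.asarray(sol.mu, dtype=float)
    mu_u = mu[1] + mu[3] / 2 + mu[5] / 2
    mu_h = mu[2] + mu[4] / 2 + mu[5] / 2
    mu_m = mu[0] + mu[3] / 2 + mu[4] / 2
    mu_z = float(_PAIR_ZBAR @ mu)
    var_hat = float((_PAIR_ZBAR**2) @ mu - mu_z**2)  # pair-to-pair variance
    vw = float(_PAIR_VW @ mu)
    covar_z = vw - mu_z**2
    var_z = 2 * var_hat - covar_z
    rho_z = covar_z / var_z if var_z > 1e-300 else None
    return SummaryStats(
        mu_u=float(mu_u), mu_h=float(mu_h), mu_m=float(mu_m),
        mu_z=mu_z, var_z=float(var_z), covar_z=float(covar_z), rho_z=rho_z,
    )


# --------------------------------------------------------------------------
# unified front end + sensitivities
# --------------------------------------------------------------------------

def model_statistics(model_kind: str, x: float, y: float) -> SummaryStats:
    """Steady-state statistics of any of the three mean-field models."""
    if model_kind == "onesite":
        return onesite_statistics(onesite_steady_state(x, y))
    return pair_statistics(pair_steady_state(model_kind, x, y))


def model_moments(
    model_kind: str, x: float, y: float, fast: bool = True
) -> tuple[float, float]:
    """(mu_z, var_z) for a mean-field model.

    ``fast=True`` runs the jitted damped iteration from the product-measure
    start only (the principal branch in all regimes probed); used inside
    ABC where millions of forward evaluations matter.
    """
    if model_kind == "onesite":
        s = onesite_statistics(onesite_steady_state(x, y))
        return s.mu_z, s.var_z
    kind = _KIND_CODE[model_kind]
    if fast:
        k = rates_from_params(Params(a=1.0, x=x, y=y)).as_array()
        got = _solve_pair_once(kind, k, _product_measure(x, y), 1e-12, 100_000)
        if got is not None:
            sol = PairSolution(model_kind, got[0], np.empty(12), got[1])
            s = pair_statistics(sol)
            return s.mu_z, s.var_z
    s = pair_statistics(pair_steady_state(model_kind, x, y))
    return s.mu_z, s.var_z


@dataclass
class SensitivityResult:
    """Relative sensitivities S_p(Q) = (p/Q) dQ/dp of mu_z and var_z."""

    model_kind: str
    x: float
    y: float
    s_x: dict
    s_y: dict
    ratio: float  # ||(S_x(mu_z), S_x(var_z))|| / ||(S_y(mu_z), S_y(var_z))||


def relative_sensitivity(
    model_kind: str, x: float, y: float, rel_step: float = 0.01
) -> SensitivityResult:
    """Relative parameter sensitivities by central finite differences.

    The sensitivity of statistic Q to parameter p is (p/Q) dQ/dp with step
    ``rel_step * p``.  The scalar x/y ratio aggregates over the two
    statistics the inference consumes (mu_z and var_z) by Euclidean norm.
    """
    if x <= 0 or y <= 0:
        raise ValueError("sensitivities require x > 0 and y > 0")
    q0 = np.array(model_moments(model_kind, x, y))
    if np.any(q0 == 0):
        raise ValueError("target statistics must be nonzero")
    hx, hy = rel_step * x, rel_step * y
    qx = (
        np.array(model_moments(model_kind, x + hx, y))
        - np.array(model_moments(model_kind, x - hx, y))
    ) / (2 * hx)
    qy = (
        np.array(model_moments(model_kind, x, y + hy))
        - np.array(model_moments(model_kind, x, y - hy))
    ) / (2 * hy)
    s_x = {"mu_z": float(x / q0[0] * qx[0]), "var_z": float(x / q0[1] * qx[1])}
    s_y = {"mu_z": float(y / q0[0] * qy[0]), "var_z": float(y / q0[1] * qy[1])}
    num = np.hypot(s_x["mu_z"], s_x["var_z"])
    den = np.hypot(s_y["mu_z"], s_y["var_z"])
    return SensitivityResult(
        model_kind=model_kind, x=x, y=y, s_x=s_x, s_y=s_y,
        ratio=float(num / den),
    )
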