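"""Exact stationary distribution of the full lattice CME for small N.

For N up to 8 the 3^N global configurations are enumerated, the generator
is assembled from the same per-site propensities the simulator uses, and
the stationary distribution is the normalized null vector of its transpose
(dense solve with the normalization row appended).  This is ground truth
for testing the stochastic simulator and the mean-field approximations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reaction_model import Params, rates_from_params, site_propensities
from .sumstats import SummaryStats, encode_z

__all__ = ["StationaryDistribution", "exact_stationary", "oracle_statistics"]

_MAX_N = 8


@dataclass
class StationaryDistribution:
    """Probability per global configuration in {u,h,m}^N.

    ``configs[c]`` is the length-N state-code row for configuration index c
    (base-3 enumeration, site 0 most significant); ``prob[c]`` its
    stationary probability.
    """

    prob: np.ndarray
    configs: np.ndarray
    N: int
    params: Params


def _enumerate_configs(n: int) -> np.ndarray:
    idx = np.arange(3**n)
    out = np.empty((3**n, n), dtype=np.int8)
    for site in range(n - 1, -1, -1):
        out[:, site] = idx % 3
        idx //= 3
    return out


def exact_stationary(N: int, p: Params) -> StationaryDistribution:
    """Stationary distribution of the N-site circular system (2 <= N <= 8).

    For reducible chains (y = 0, where the all-u configuration absorbs) the
    returned vector is the absorbing distribution.
    """
    if not (2 <= N <= _MAX_N):
        raise ValueError(f"N must be in [2, {_MAX_N}], got {N}")
    r = rates_from_params(p)
    configs = _enumerate_configs(N)
    nc = configs.shape[0]
    powers = 3 ** np.arange(N - 1, -1, -1)
    # generator transpose: A[c2, c1] = rate(c1 -> c2)
    A = np.zeros((nc, nc))
    for c in range(nc):
        pattern = configs[c]
        base = int(pattern @ powers)
        for i in range(N):
            for new_state, prop in site_propensities(pattern, i, r):
                if prop == 0.0:
                    continue
                c2 = base + (new_state - int(pattern[i])) * int(powers[i])
                A[c2, c] += prop
                A[c, c] -= prop
    A[-1, :] = 1.0
    b = np.zeros(nc)
    b[-1] = 1.0
    try:
        prob = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        prob, *_ = np.linalg.lstsq(A, b, rcond=None)
    prob = np.clip(prob, 0.0, None)
    prob /= prob.sum()
    return StationaryDistribution(prob=prob, configs=configs, N=N, params=p)


def oracle_statistics(d: StationaryDistribution) -> SummaryStats:
    """Exact expectations of the pattern statistics under ``d``.

    Each per-snapshot estimator (level means; z mean; z variance with
    denominator N-1; neighbour covariance with denominator N) is evaluated
    per configuration and averaged under the stationary law, matching the
    simulator-side conventions exactly.  rho is E[covar]/E[var], undefined
    when the variance vanishes.
    """
    w = d.prob
    configs = d.configs
    n = d.N
    mu_u = float(w @ np.mean(configs == 0, axis=1))
    mu_h = float(w @ np.mean(configs == 1, axis=1))
    mu_m = float(w @ np.mean(configs == 2, axis=1))
    z = encode_z(configs).astype(float)
    mu_t = z.mean(axis=1)
    zc = z - mu_t[:, None]
    var_rows = np.sum(zc**2, axis=1) / (n - 1)
    cov_rows = np.sum(zc * np.roll(zc, -1, axis=1), axis=1) / n
    mu_z = float(w @ mu_t)
    var_z = float(w @ var_rows)
    covar_z = float(w @ cov_rows)
    rho_z = covar_z / var_z if var_z > 0 else None
    return SummaryStats(
        mu_u=mu_u, mu_h=mu_h, mu_m=mu_m,
        mu_z=mu_z, var_z=var_z, covar_z=covar_z, rho_z=rho_z,
    )
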