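"""Exact stochastic simulation of the circular N-CpG system.

The simulator runs Gillespie's direct method on the periodic lattice,
detects steady state by monitoring u/h/m proportions over fixed event
windows, then records ``T`` snapshots at constant time intervals.  It also
emulates hairpin-bisulfite sequencing by sparse, per-CpG-independent
sampling of a steady-state snapshot pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .reaction_model import Params, ParameterError, rates_from_params

__all__ = [
    "SimConfig",
    "SampleMatrix",
    "ReadDataset",
    "ConvergenceError",
    "gillespie_run",
    "detect_burn_in",
    "emulate_hairpin_reads",
]


class ConvergenceError(RuntimeError):
    """Steady state was not reached within the configured event budget."""


@dataclass
class SimConfig:
    """Simulation settings.

    Parameters
    ----------
    N : int
        Number of CpG sites on the circle (>= 2).
    T : int
        Number of steady-state snapshots to record.
    seed : int
        RNG seed; identical (Params, SimConfig) give bit-identical output.
    sample_interval : float, optional
        Time between snapshots.  Default: ``N / phi_hat`` where ``phi_hat``
        is the mean total propensity over the last burn-in window, i.e.
        about one reaction per site per interval.
    initial_state : str
        One of ``uniform`` (random per site), ``all-u``, ``all-m``.
    burn_window_events : int, optional
        Events per monitoring window; default ``max(50 * N, 10_000)`` (the
        floor keeps window-averaged proportions quiet enough for the
        stabilization tolerance on very small lattices).
    burn_tol : float
        Max-norm tolerance on consecutive window-mean proportion vectors.
    burn_successes : int
        Number of consecutive sub-tolerance comparisons required.
    fixed_burn_in_events : int, optional
        Skip detection and burn in for exactly this many events.
    max_events : int
        Event budget before declaring non-convergence.
    """

    N: int
    T: int
    seed: int
    sample_interval: Optional[float] = None
    initial_state: str = "uniform"
    burn_window_events: Optional[int] = None
    burn_tol: float = 0.01
    burn_successes: int = 2
    fixed_burn_in_events: Optional[int] = None
    max_events: int = 1_000_000_000

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ParameterError(f"N must be >= 2, got {self.N}")
        if self.T < 1:
            raise ParameterError(f"T must be >= 1, got {self.T}")
        if self.sample_interval is not None and not (self.sample_interval > 0):
            raise ParameterError("sample_interval must be positive")
        if self.initial_state not in ("uniform", "all-u", "all-m"):
            raise ParameterError(f"unknown initial_state {self.initial_state!r}")


@dataclass
class SampleMatrix:
    """T x N archive of steady-state snapshots (int codes 0/1/2 = u/h/m)."""

    data: np.ndarray
    params: Params
    config: SimConfig
    burn_in_time: float
    burn_in_events: int
    dt: float


@dataclass
class ReadDataset:
    """Flat hairpin-bisulfite-like observations.

    ``states[j]`` is the methylation state observed for CpG
    ``cpg_index[j]``; every CpG contributes exactly ``coverage`` reads drawn
    at independent random timepoints.
    """

    cpg_index: np.ndarray
    states: np.ndarray
    N: int
    coverage: int
    params: Optional[Params] = None
    seed: Optional[int] = None


def _burn_in_index(props: np.ndarray, tol: float, successes: int) -> Optional[int]:
    """Index of the window completing the required run of sub-tol diffs."""
    run = 0
    for w in range(1, props.shape[0]):
        if np.max(np.abs(props[w] - props[w - 1])) < tol:
            run += 1
            if run >= successes:
                return w
        else:
            run = 0
    return None


def detect_burn_in(
    trajectory: np.ndarray, tol: float = 0.01, successes: int = 2
) -> float:
    """Burn-in time from a trajectory of window-mean u/h/m proportions.

    ``trajectory`` has rows ``(time_at_window_end, p_u, p_h, p_m)``.  Steady
    state is declared at the end of the window that completes ``successes``
    consecutive window-to-window proportion changes below ``tol`` in max
    norm.

    Raises
    ------
    ConvergenceError
        If the criterion is never met within the trajectory.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 4:
        raise ValueError("trajectory must have rows (time, p_u, p_h, p_m)")
    idx = _burn_in_index(traj[:, 1:], tol, successes)
    if idx is None:
        raise ConvergenceError(
            f"proportions never stabilized to {tol} over {traj.shape[0]} windows"
        )
    return float(traj[idx, 0])


def _initial_pattern(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.initial_state == "all-u":
        return np.zeros(cfg.N, dtype=np.int8)
    if cfg.initial_state == "all-m":
        return np.full(cfg.N, 2, dtype=np.int8)
    return rng.integers(0, 3, size=cfg.N, dtype=np.int8)


def gillespie_run(p: Params, cfg: SimConfig) -> SampleMatrix:
    """Simulate to steady state and record ``cfg.T`` snapshots.

    The chain is advanced in windows of ``burn_window_events`` events while
    time-averaged u/h/m proportions are monitored; once they stabilize
    (or the chain is absorbed, e.g. the all-u state at y = 0), snapshots are
    taken every ``sample_interval`` time units.
    """
    k = rates_from_params(p).as_array()
    ss = np.random.SeedSequence(cfg.seed)
    init_seed, kernel_seed = (int(s) % 2**31 for s in ss.generate_state(2))
    rng = np.random.default_rng(init_seed)
    state = _initial_pattern(cfg, rng)
    _kernels.seed_kernel(kernel_seed)

    n = cfg.N
    nblk = (n + _kernels.BLOCK - 1) // _kernels.BLOCK
    lam = np.zeros(n, dtype=np.float64)
    blk = np.zeros(nblk, dtype=np.float64)
    counts = np.array(
        [np.sum(state == 0), np.sum(state == 1), np.sum(state == 2)], dtype=np.int64
    )
    phi = _kernels.init_propensities(state, k, lam, blk)

    window = (
        cfg.burn_window_events
        if cfg.burn_window_events is not None
        else max(50 * n, 10_000)
    )
    t = 0.0
    events = 0
    phi_hat = phi
    if cfg.fixed_burn_in_events is not None:
        remaining = cfg.fixed_burn_in_events
        while remaining > 0:
            chunk = min(remaining, window)
            dt_w, phi, done, _, _, _, mphi = _kernels.run_events(
                state, lam, blk, counts, k, phi, chunk
            )
            t += dt_w
            events += done
            phi_hat = mphi
            remaining -= chunk
            if done < chunk:  # absorbed
                break
    else:
        props = []
        while True:
            dt_w, phi, done, pu, ph, pm, mphi = _kernels.run_events(
                state, lam, blk, counts, k, phi, window
            )
            t += dt_w
            events += done
            phi_hat = mphi
            props.append((pu, ph, pm))
            if done < window:  # absorbed: trivially stationary
                break
            if _burn_in_index(np.asarray(props), cfg.burn_tol, cfg.burn_successes) is not None:
                break
            if events >= cfg.max_events:
                raise ConvergenceError(
                    f"burn-in not reached within {cfg.max_events} events "
                    f"(a={p.a}, x={p.x}, y={p.y}, N={n})"
                )

    if cfg.sample_interval is not None:
        dt = cfg.sample_interval
    elif phi_hat > 0:
        dt = n / phi_hat
    else:
        dt = 1.0  # absorbed chain: spacing is immaterial

    out = np.empty((cfg.T, n), dtype=np.int8)
    phi, _ = _kernels.sample_snapshots(state, lam, blk, counts, k, phi, dt, out)
    return SampleMatrix(
        data=out,
        params=p,
        config=cfg,
        burn_in_time=t,
        burn_in_events=events,
        dt=dt,
    )


def emulate_hairpin_reads(
    p: Params,
    N: int = 1000,
    pool: int = 10_000,
    coverage: int = 30,
    seed: int = 0,
    sim_config: Optional[SimConfig] = None,
) -> ReadDataset:
    """Emulate hairpin-bisulfite sequencing from a steady-state simulation.

    A pool of ``pool`` steady-state snapshots of an ``N``-CpG system is
    generated; for each CpG, ``coverage`` snapshot indices are drawn
    uniformly without replacement, independently of every other CpG, and the
    selected states are concatenated into one flat dataset.  This mimics
    short reads in which each observed molecule covers a single CpG and
    molecules for different CpGs are unrelated.
    """
    if coverage < 1:
        raise ParameterError(f"coverage must be >= 1, got {coverage}")
    if coverage > pool:
        raise ParameterError(f"coverage {coverage} exceeds snapshot pool {pool}")
    ss = np.random.SeedSequence(seed)
    sim_seed, pick_seed = (int(s) % 2**31 for s in ss.generate_state(2))
    cfg = sim_config or SimConfig(N=N, T=pool, seed=sim_seed)
    if cfg.T != pool or cfg.N != N:
        raise ParameterError("sim_config must match N and pool")
    sample = gillespie_run(p, cfg)
    rng = np.random.default_rng(pick_seed)
    cpg_index = np.repeat(np.arange(N, dtype=np.int64), coverage)
    states = np.empty(N * coverage, dtype=np.int8)
    for i in range(N):
        rows = rng.choice(pool, size=coverage, replace=False)
        states[i * coverage : (i + 1) * coverage] = sample.data[rows, i]
    return ReadDataset(
        cpg_index=cpg_index, states=states, N=N, coverage=coverage, params=p, seed=seed
    )
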