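"""Numba kernels for the Gillespie (direct-method) lattice simulation.

State codes are 0/1/2 for u/h/m.  ``k`` is the length-12 rate array with
``k[i-1] == k_i``.  Site selection uses a two-level (block) linear scan over
per-site exit propensities; after each event only the target site and its two
neighbours are updated, so the cost per event is O(block size), not O(N).

All randomness comes from numba's internal RNG, seeded once per run via
:func:`seed_kernel`, which makes runs bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BLOCK = 32
_EPS = 1e-300  # total propensity below this means the chain is absorbed


@njit(cache=True)
def seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _site_rates(state, i, n, k):
    """Exit rates of site i: (rate0, new0, rate1, new1); new1 = -1 if absent."""
    left = state[i - 1] if i > 0 else state[n - 1]
    right = state[i + 1] if i < n - 1 else state[0]
    n_u = (left == 0) + (right == 0)
    n_h = (left == 1) + (right == 1)
    n_m = (left == 2) + (right == 2)
    s = state[i]
    if s == 0:  # u -> h
        return k[0] + k[4] * n_h + k[5] * n_m, 1, 0.0, -1
    elif s == 1:  # h -> m | h -> u
        return (
            k[1] + k[6] * n_h + k[7] * n_m,
            2,
            k[3] + k[10] * n_h + k[11] * n_u,
            0,
        )
    else:  # m -> h
        return k[2] + k[8] * n_h + k[9] * n_u, 1, 0.0, -1


@njit(cache=True)
def init_propensities(state, k, lam, blk):
    """Fill per-site totals ``lam`` and block sums ``blk``; return Phi."""
    n = state.shape[0]
    for i in range(n):
        r0, _, r1, b1 = _site_rates(state, i, n, k)
        lam[i] = r0 + r1 if b1 >= 0 else r0
    blk[:] = 0.0
    for i in range(n):
        blk[i // BLOCK] += lam[i]
    phi = 0.0
    for b in range(blk.shape[0]):
        phi += blk[b]
    return phi


@njit(cache=True, inline="always")
def _select_site(lam, blk, r):
    """Find the site whose cumulative propensity interval contains r.

    Returns (site, r_offset) where r_offset = r minus the cumulative
    propensity of all earlier sites (used for branch selection).
    """
    n = lam.shape[0]
    nblk = blk.shape[0]
    acc = 0.0
    b = nblk - 1
    for j in range(nblk):
        if acc + blk[j] > r:
            b = j
            break
        acc += blk[j]
    i0 = b * BLOCK
    i1 = min(i0 + BLOCK, n)
    i = i1 - 1
    # fall back to the last positive-rate site on float round-off
    for j in range(i0, i1):
        if acc + lam[j] > r:
            i = j
            break
        acc += lam[j]
    return i, r - acc


@njit(cache=True, inline="always")
def _apply_event(state, lam, blk, counts, k, i, u):
    """Fire the event at site i (branch chosen by u in [0, lam_i)).

    Returns the change in total propensity.
    """
    n = state.shape[0]
    r0, b0, r1, b1 = _site_rates(state, i, n, k)
    new = b0
    if b1 >= 0 and u >= r0:
        new = b1
    counts[state[i]] -= 1
    counts[new] += 1
    state[i] = new
    dphi = 0.0
    jl = i - 1 if i > 0 else n - 1
    jr = i + 1 if i < n - 1 else 0
    # update left, self, and (unless N == 2 makes it the same site) right
    n_upd = 2 if jr == jl else 3
    for idx in range(n_upd):
        j = jl if idx == 0 else (i if idx == 1 else jr)
        q0, _, q1, c1 = _site_rates(state, j, n, k)
        new_lam = q0 + q1 if c1 >= 0 else q0
        d = new_lam - lam[j]
        lam[j] = new_lam
        blk[j // BLOCK] += d
        dphi += d
    return dphi


@njit(cache=True)
def run_events(state, lam, blk, counts, k, phi, n_events):
    """Advance exactly n_events reaction events (or until absorption).

    Returns (elapsed_time, phi, events_done, mean_u, mean_h, mean_m,
    mean_phi) where the means are time-weighted averages over the window.
    Absorption (phi ~ 0) ends the window early.
    """
    t = 0.0
    tu = 0.0
    th = 0.0
    tm = 0.0
    tphi = 0.0
    done = 0
    n = float(state.shape[0])
    for _ in range(n_events):
        if phi <= _EPS:
            break
        tau = -np.log(np.random.random()) / phi
        t += tau
        tu += counts[0] * tau
        th += counts[1] * tau
        tm += counts[2] * tau
        tphi += phi * tau
        r = np.random.random() * phi
        i, u = _select_site(lam, blk, r)
        phi += _apply_event(state, lam, blk, counts, k, i, u)
        done += 1
        if done % 65536 == 0:
            # resum to control floating-point drift
            phi = 0.0
            for b in range(blk.shape[0]):
                blk[b] = 0.0
            for j in range(state.shape[0]):
                blk[j // BLOCK] += lam[j]
            for b in range(blk.shape[0]):
                phi += blk[b]
    if t > 0.0:
        return t, phi, done, tu / (t * n), th / (t * n), tm / (t * n), tphi / t
    return 0.0, phi, done, counts[0] / n, counts[1] / n, counts[2] / n, phi


@njit(cache=True)
def sample_snapshots(state, lam, blk, counts, k, phi, dt, out):
    """Record out.shape[0] snapshots at constant time spacing dt.

    Uses the memorylessness of exponential waiting times: an event time
    drawn beyond the snapshot boundary is discarded and redrawn in the next
    interval, which leaves the process law unchanged.  Returns (phi, events).
    """
    nsnap = out.shape[0]
    n = state.shape[0]
    events = 0
    for t_idx in range(nsnap):
        rem = dt
        while phi > _EPS:
            tau = -np.log(np.random.random()) / phi
            if tau > rem:
                break
            rem -= tau
            r = np.random.random() * phi
            i, u = _select_site(lam, blk, r)
            phi += _apply_event(state, lam, blk, counts, k, i, u)
            events += 1
            if events % 65536 == 0:
                phi = 0.0
                for b in range(blk.shape[0]):
                    blk[b] = 0.0
                for j in range(n):
                    blk[j // BLOCK] += lam[j]
                for b in range(blk.shape[0]):
                    phi += blk[b]
        for j in range(n):
            out[t_idx, j] = state[j]
    return phi, events
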