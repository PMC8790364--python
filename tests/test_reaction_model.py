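"""Rate parameterization and per-site propensities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methmf.oracle import exact_stationary
from methmf.reaction_model import (
    H,
    M,
    U,
    ParameterError,
    Params,
    rates_from_params,
    site_propensities,
)


@pytest.mark.parametrize(
    "a, x, y, expected",
    [
        # x = y = 1 collapses every product to a
        (0.2, 1.0, 1.0, {f"k{i}": 0.2 for i in range(1, 13)}),
        (
            1.0, 0.5, 2.0,
            {"k1": 2, "k2": 2, "k3": 1, "k4": 1,
             "k5": 1, "k6": 1, "k7": 1, "k8": 1,
             "k9": 0.5, "k10": 0.5, "k11": 0.5, "k12": 0.5},
        ),
        # x = 0 annihilates every collaborative channel
        (
            1.0, 0.0, 0.7,
            {"k1": 0.7, "k2": 0.7, "k3": 1, "k4": 1,
             **{f"k{i}": 0.0 for i in range(5, 13)}},
        ),
    ],
)
def test_rates_from_params(a, x, y, expected):
    r = rates_from_params(Params(a=a, x=x, y=y))
    for name, val in expected.items():
        assert getattr(r, name) == pytest.approx(val)


@pytest.mark.parametrize(
    "a, x, y", [(0.0, 1, 1), (-1, 1, 1), (1, -0.1, 1), (1, 1, -2)]
)
def test_invalid_params_rejected(a, x, y):
    with pytest.raises(ParameterError):
        Params(a=a, x=x, y=y)


def test_rate_degeneracies():
    r = rates_from_params(Params(a=0.7, x=3.0, y=0.4))
    assert r.k3 == r.k4
    assert r.k1 == r.k2
    assert r.k9 == r.k10 == r.k11 == r.k12
    assert r.k5 == r.k6 == r.k7 == r.k8


class TestSitePropensities:
    r = rates_from_params(Params(a=1.0, x=2.0, y=0.5))

    def test_u_site_with_h_and_m_neighbours(self):
        pattern = np.array([H, U, M], dtype=np.int8)
        chans = site_propensities(pattern, 1, self.r)
        assert chans == [(H, pytest.approx(self.r.k1 + self.r.k5 + self.r.k6))]

    def test_h_site_between_two_h(self):
        pattern = np.array([H, H, H], dtype=np.int8)
        chans = dict(
            (new, prop) for new, prop in site_propensities(pattern, 1, self.r)
        )
        assert chans[M] == pytest.approx(self.r.k2 + 2 * self.r.k7)
        assert chans[U] == pytest.approx(self.r.k4 + 2 * self.r.k11)

    def test_m_site_between_two_m_has_no_mediators(self):
        pattern = np.array([M, M, M], dtype=np.int8)
        chans = site_propensities(pattern, 1, self.r)
        assert chans == [(H, pytest.approx(self.r.k3))]

    def test_two_site_lattice_counts_single_neighbour_twice(self):
        # for N = 2 the one other site fills both neighbour slots
        pattern = np.array([U, H], dtype=np.int8)
        chans = site_propensities(pattern, 0, self.r)
        assert chans == [(H, pytest.approx(self.r.k1 + 2 * self.r.k5))]

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            site_propensities(np.array([U, U], dtype=np.int8), 2, self.r)


@settings(max_examples=60, deadline=None)
@given(
    pattern=st.lists(st.integers(0, 2), min_size=2, max_size=8),
    x=st.floats(0, 10),
    y=st.floats(0, 3),
    i=st.integers(0, 7),
)
def test_propensity_properties(pattern, x, y, i):
    """No direct u<->m channel; propensities non-negative; states valid."""
    i %= len(pattern)
    pattern = np.array(pattern, dtype=np.int8)
    r = rates_from_params(Params(a=0.5, x=x, y=y))
    chans = site_propensities(pattern, i, r)
    s = pattern[i]
    for new, prop in chans:
        assert prop >= 0
        assert new in (U, H, M)
        assert abs(new - s) == 1  # never u <-> m directly


def test_two_site_propensities_match_oracle_generator():
    """The oracle's stationary law at N=2 balances site-level fluxes.

    Detailed check that both modules build the same chain: for every
    2-site configuration, total probability flux out (from
    site_propensities) equals total flux in under the exact stationary
    distribution.
    """
    p = Params(a=0.3, x=4.0, y=1.5)
    r = rates_from_params(p)
    d = exact_stationary(2, p)
    idx = {tuple(c): k for k, c in enumerate(map(tuple, d.configs))}
    net = np.zeros(len(d.prob))
    for c_i, conf in enumerate(d.configs):
        for site in range(2):
            for new, prop in site_propensities(conf, site, r):
                target = list(conf)
                target[site] = new
                t_i = idx[tuple(target)]
                net[c_i] -= prop * d.prob[c_i]
                net[t_i] += prop * d.prob[c_i]
    assert np.max(np.abs(net)) < 1e-12
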