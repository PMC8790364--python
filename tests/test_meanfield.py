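"""One-site, DPMF and OPMF mean-field models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methmf.meanfield import (
    dpmf_rates,
    integrate_onesite_second_moments,
    model_statistics,
    onesite_statistics,
    onesite_steady_state,
    opmf_rates,
    pair_statistics,
    pair_steady_state,
    relative_sensitivity,
)
from methmf.reaction_model import Params, rates_from_params


def product_pair_measure(y):
    p = np.array([1, y, y**2]) / (1 + y + y**2)
    pu, ph, pm = p
    return np.array([pm**2, pu**2, ph**2, 2 * pu * pm, 2 * ph * pm, 2 * pu * ph])


class TestOneSite:
    @pytest.mark.parametrize(
        "y, expected",
        [(1.0, (1 / 3, 1 / 3, 1 / 3)), (2.0, (1 / 7, 2 / 7, 4 / 7))],
    )
    def test_closed_form_at_x0(self, y, expected):
        s = onesite_steady_state(0.0, y)
        assert (s.mu_u, s.mu_h, s.mu_m) == pytest.approx(expected, abs=1e-10)

    def test_all_u_at_y0(self):
        s = onesite_steady_state(3.0, 0.0)
        assert (s.mu_u, s.mu_h, s.mu_m) == pytest.approx((1, 0, 0), abs=1e-10)

    def test_statistics_at_uniform_point(self):
        st_ = onesite_statistics(onesite_steady_state(0.0, 1.0))
        assert st_.mu_z == pytest.approx(2.0, abs=1e-10)
        assert st_.var_z == pytest.approx(2 / 3, abs=1e-10)  # uniform on {1,2,3}
        assert st_.covar_z is None and st_.rho_z is None

    def test_degenerate_variance_at_y0(self):
        st_ = onesite_statistics(onesite_steady_state(2.0, 0.0))
        assert st_.var_z == pytest.approx(0.0, abs=1e-10)

    def test_independent_of_rate_scale(self):
        sols = [onesite_steady_state(3.0, 1.4, a=a) for a in (0.2, 2.0, 20.0)]
        for s in sols[1:]:
            assert s.mu_u == pytest.approx(sols[0].mu_u, abs=1e-10)
            assert s.mu_h == pytest.approx(sols[0].mu_h, abs=1e-10)


class TestPairRates:
    k = rates_from_params(Params(a=1.0, x=0.0, y=0.8))
    kx = rates_from_params(Params(a=1.0, x=2.0, y=0.8))

    def test_dpmf_collaborative_terms_vanish_at_x0(self):
        a = dpmf_rates(np.full(6, 1 / 6), self.k)
        assert a[0] == pytest.approx(2 * self.k.k3)
        assert a[11] == pytest.approx(self.k.k2)
        assert a[4] == pytest.approx(self.k.k1)

    def test_dpmf_uniform_proportions(self):
        a = dpmf_rates(np.full(6, 1 / 6), self.kx)
        # 2*mu3 + mu5 + mu6 = 2*mu2 + mu4 + mu6 = 2/3
        assert a[0] == pytest.approx(
            2 * self.kx.k3 + (2 / 3) * (self.kx.k9 + self.kx.k10)
        )

    def test_opmf_degenerate_denominator_rule(self):
        mu = np.array([0.0, 0.5, 0.3, 0.0, 0.0, 0.2])  # no mm/um/hm pairs
        a = opmf_rates(mu, self.kx)
        assert a[0] == pytest.approx(2 * self.kx.k3)  # conditional terms zeroed

    def test_opmf_collaborative_terms_vanish_at_x0(self):
        a = opmf_rates(np.full(6, 1 / 6), self.k)
        assert a[0] == pytest.approx(2 * self.k.k3)
        assert a[11] == pytest.approx(self.k.k2)

    def test_opmf_product_measure_conditionals(self):
        # on a product measure, P(flank h | shared h) = p_h and
        # P(flank u | shared h) = p_u, so the hh -> uh rate reduces to
        # 2k4 + 2k11 + 2k11 p_h + 2k12 p_u
        y = 0.8
        p = np.array([1, y, y**2]) / (1 + y + y**2)
        a = opmf_rates(product_pair_measure(y), self.kx)
        expected = (
            2 * self.kx.k4 + 2 * self.kx.k11
            + 2 * self.kx.k11 * p[1] + 2 * self.kx.k12 * p[0]
        )
        assert a[2] == pytest.approx(expected)

    @settings(max_examples=30, deadline=None)
    @given(
        alpha=st.lists(st.floats(0.1, 5), min_size=6, max_size=6),
        x=st.floats(0, 20),
        y=st.floats(0, 2),
    )
    def test_effective_rates_nonnegative(self, alpha, x, y):
        mu = np.array(alpha)
        mu /= mu.sum()
        k = rates_from_params(Params(a=1.0, x=x, y=y))
        assert (dpmf_rates(mu, k) >= 0).all()
        assert (opmf_rates(mu, k) >= 0).all()

    def test_simplex_validation(self):
        with pytest.raises(ValueError):
            dpmf_rates(np.array([0.5, 0.5, 0.5, 0, 0, 0]), self.k)


class TestPairSteadyState:
    @pytest.mark.parametrize("kind", ["dpmf", "opmf"])
    @pytest.mark.parametrize("y", [0.5, 2.0])
    def test_product_measure_at_x0(self, kind, y):
        sol = pair_steady_state(kind, 0.0, y)
        assert np.allclose(sol.mu, product_pair_measure(y), atol=1e-8)
        st_ = pair_statistics(sol)
        assert st_.covar_z == pytest.approx(0.0, abs=1e-8)
        assert st_.rho_z == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("kind", ["dpmf", "opmf"])
    @pytest.mark.parametrize("x", [1.0, 5.0, 50.0])
    def test_u_m_symmetry_at_y1(self, kind, x):
        sol = pair_steady_state(kind, x, 1.0)
        assert sol.mu[0] == pytest.approx(sol.mu[1], abs=1e-9)  # mm = uu
        assert sol.mu[4] == pytest.approx(sol.mu[5], abs=1e-9)  # hm = uh
        assert sol.mu.sum() == pytest.approx(1.0, abs=1e-9)
        assert ((sol.mu >= 0) & (sol.mu <= 1)).all()

    @pytest.mark.parametrize("kind", ["dpmf", "opmf"])
    def test_independent_of_rate_scale(self, kind):
        mus = [pair_steady_state(kind, 5.0, 1.3, a=a).mu for a in (0.2, 2.0, 20.0)]
        assert np.allclose(mus[0], mus[1], atol=1e-9)
        assert np.allclose(mus[0], mus[2], atol=1e-9)

    @pytest.mark.parametrize("model", ["onesite", "dpmf", "opmf"])
    def test_u_m_relabelling_maps_y_to_inverse(self, model):
        s = model_statistics(model, 2.0, 1.6)
        t = model_statistics(model, 2.0, 1 / 1.6)
        assert s.mu_u == pytest.approx(t.mu_m, abs=1e-8)
        assert s.mu_h == pytest.approx(t.mu_h, abs=1e-8)

    @pytest.mark.parametrize("y", [0.5, 1.0])
    def test_models_coincide_at_x0(self, y):
        stats = [model_statistics(m, 0.0, y) for m in ("onesite", "dpmf", "opmf")]
        for s in stats[1:]:
            assert s.mu_u == pytest.approx(stats[0].mu_u, abs=1e-8)
            assert s.var_z == pytest.approx(stats[0].var_z, abs=1e-8)


def test_pair_statistics_worked_example():
    from methmf.meanfield import PairSolution

    sol = PairSolution(
        model_kind="opmf",
        mu=np.array([0.3, 0.3, 0.1, 0.1, 0.1, 0.1]),
        rates=np.zeros(12),
        residual=0.0,
    )
    s = pair_statistics(sol)
    assert (s.mu_u, s.mu_h, s.mu_m) == pytest.approx((0.4, 0.2, 0.4))
    assert s.mu_z == pytest.approx(2.0)
    assert s.covar_z == pytest.approx(0.5)  # <vw> = 4.5, minus mu_z^2 = 4


def test_second_moments_collapse_to_indicator_identities():
    """Integrating the second-moment ODEs reproduces <L_i L_j> = delta_ij mu_i."""
    for x, y in [(0.0, 1.0), (2.0, 0.7), (5.0, 1.2)]:
        sol = onesite_steady_state(x, y)
        muu, muh, mhh = integrate_onesite_second_moments(sol)
        assert muu == pytest.approx(sol.mu_u, abs=1e-8)
        assert muh == pytest.approx(0.0, abs=1e-8)
        assert mhh == pytest.approx(sol.mu_h, abs=1e-8)


class TestSensitivity:
    def test_onesite_y_sensitivity_near_x0(self):
        # closed form mu_z = (1+2y+3y^2)/(1+y+y^2): S_y at y=1 is 1/3
        r = relative_sensitivity("onesite", 1e-8, 1.0)
        assert r.s_y["mu_z"] == pytest.approx(1 / 3, rel=1e-4)

    def test_central_difference_step_consistency(self):
        r1 = relative_sensitivity("opmf", 2.0, 0.8, rel_step=0.01)
        r2 = relative_sensitivity("opmf", 2.0, 0.8, rel_step=0.005)
        for key in ("mu_z", "var_z"):
            assert r2.s_x[key] == pytest.approx(r1.s_x[key], rel=1e-2)
            assert r2.s_y[key] == pytest.approx(r1.s_y[key], rel=1e-2)

    def test_opmf_less_sensitive_to_x_than_y_spotchecks(self):
        for x, y in [(0.1, 0.7), (5.0, 1.3)]:
            assert relative_sensitivity("opmf", x, y).ratio < 1.0
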