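"""Gillespie simulator: determinism, steady state, read emulation."""

import numpy as np
import pytest

from methmf.reaction_model import ParameterError, Params
from methmf.simulator import (
    ConvergenceError,
    SimConfig,
    detect_burn_in,
    emulate_hairpin_reads,
    gillespie_run,
)
from methmf.sumstats import level_means


def test_seed_determinism():
    p = Params(a=0.2, x=2.0, y=0.8)
    cfg = SimConfig(N=25, T=200, seed=77)
    a = gillespie_run(p, cfg)
    b = gillespie_run(p, cfg)
    assert np.array_equal(a.data, b.data)
    assert a.burn_in_time == b.burn_in_time
    c = gillespie_run(p, SimConfig(N=25, T=200, seed=78))
    assert not np.array_equal(a.data, c.data)


def test_snapshot_shape_follows_config():
    cfg = SimConfig(N=50, T=10**6 // 50 // 100, seed=1)  # scaled-down T rule
    sm = gillespie_run(Params(a=0.2, x=0.5, y=1.2), cfg)
    assert sm.data.shape == (cfg.T, 50)
    assert set(np.unique(sm.data)) <= {0, 1, 2}


def test_independent_sites_occupancy():
    """At x=0, y=1 every site is independently uniform over u/h/m."""
    sm = gillespie_run(Params(a=1.0, x=0.0, y=1.0), SimConfig(N=60, T=3000, seed=5))
    # batch-mean standard error over 20 contiguous batches
    batches = np.array_split(sm.data, 20)
    props = np.array([level_means(b) for b in batches])
    mean = props.mean(axis=0)
    se = props.std(axis=0, ddof=1) / np.sqrt(len(batches))
    for got, s in zip(mean, se):
        assert abs(got - 1 / 3) < 3 * max(s, 1e-3)


def test_no_methylation_absorbs_to_all_u():
    sm = gillespie_run(Params(a=1.0, x=3.0, y=0.0), SimConfig(N=15, T=8, seed=3))
    assert (sm.data[-1] == 0).all()


class TestDetectBurnIn:
    def _traj(self, props):
        t = np.arange(1.0, len(props) + 1)
        return np.column_stack([t, np.asarray(props)])

    def test_constant_trajectory_declares_at_first_opportunity(self):
        traj = self._traj([[0.2, 0.3, 0.5]] * 6)
        # two consecutive sub-tolerance comparisons need three windows
        assert detect_burn_in(traj) == 3.0

    def test_monotone_relaxation_crossing(self):
        # u-proportion decays towards 0.5; window diffs are
        # 0.2, 0.08, 0.03, 0.008, 0.003, ... -> first two sub-0.01
        # comparisons complete at the 6th window
        u = 0.5 + np.array([0.321, 0.121, 0.041, 0.011, 0.003, 0.0, 0.0])
        props = np.column_stack([u, 1 - u, np.zeros_like(u)])
        assert detect_burn_in(self._traj(props)) == 6.0

    def test_oscillation_never_settles(self):
        props = [[0.3, 0.3, 0.4], [0.4, 0.3, 0.3]] * 10
        with pytest.raises(ConvergenceError):
            detect_burn_in(self._traj(props))


def test_event_budget_error_names_budget():
    p = Params(a=0.2, x=5.0, y=1.0)
    cfg = SimConfig(N=40, T=5, seed=9, max_events=5000, burn_window_events=2000,
                    burn_tol=1e-9)
    with pytest.raises(ConvergenceError, match="5000"):
        gillespie_run(p, cfg)


class TestHairpinReads:
    def test_dataset_shape(self):
        ds = emulate_hairpin_reads(
            Params(a=0.5, x=1.0, y=1.0), N=40, pool=200, coverage=7, seed=2
        )
        assert ds.states.size == 40 * 7
        assert ds.cpg_index.size == 40 * 7
        assert (np.bincount(ds.cpg_index, minlength=40) == 7).all()

    def test_full_coverage_recovers_columns(self):
        """Sampling without replacement at coverage = pool exhausts the pool."""
        p = Params(a=0.5, x=0.5, y=0.9)
        ds = emulate_hairpin_reads(p, N=10, pool=50, coverage=50, seed=4)
        sim_seed = int(np.random.SeedSequence(4).generate_state(2)[0]) % 2**31
        sample = gillespie_run(p, SimConfig(N=10, T=50, seed=sim_seed))
        for i in range(10):
            col = np.sort(sample.data[:, i])
            got = np.sort(ds.states[ds.cpg_index == i])
            assert np.array_equal(col, got)

    def test_absorbed_system_reads_all_u(self):
        ds = emulate_hairpin_reads(
            Params(a=1.0, x=1.0, y=0.0), N=12, pool=60, coverage=5, seed=6
        )
        assert (ds.states == 0).all()

    def test_coverage_exceeding_pool_rejected(self):
        with pytest.raises(ParameterError):
            emulate_hairpin_reads(
                Params(a=1.0, x=1.0, y=1.0), N=5, pool=10, coverage=11, seed=1
            )

    def test_per_cpg_draws_are_independent(self):
        ds = emulate_hairpin_reads(
            Params(a=0.5, x=1.0, y=1.0), N=30, pool=100, coverage=3, seed=8
        )
        ds2 = emulate_hairpin_reads(
            Params(a=0.5, x=1.0, y=1.0), N=30, pool=100, coverage=3, seed=8
        )
        assert np.array_equal(ds.states, ds2.states)  # seeded
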