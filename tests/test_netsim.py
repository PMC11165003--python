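import numpy as np
import pytest
from scipy.integrate import solve_ivp

from syncpath import (
    HeterogeneitySpec,
    SimConfig,
    cluster_error,
    empirical_thresholds,
    rossler,
    simulate_network,
    sweep_errors,
)
from syncpath.netsim import NetworkTrajectory, SyncErrorCurves


def make_traj(states, dt=0.1, coupled=(1,)):
    states = np.asarray(states, dtype=float)
    times = np.arange(states.shape[0]) * dt
    labels = [str(i + 1) for i in range(states.shape[1])]
    return NetworkTrajectory(times, states, labels, 0.0, tuple(coupled))


class TestClusterError:
    def test_identical_trajectories_give_zero(self):
        node = np.random.default_rng(0).standard_normal((50, 1, 3))
        traj = make_traj(np.repeat(node, 4, axis=1))
        assert cluster_error(traj, {"1", "2", "3", "4"}, 2.0) == 0.0

    def test_two_constant_states_give_half_separation(self):
        c = 0.7
        states = np.zeros((30, 2, 3))
        states[:, 1, 1] = 2 * c  # deviation only on the tracked component
        traj = make_traj(states)
        assert cluster_error(traj, {"1", "2"}, 1.0) == pytest.approx(c)

    def test_full_state_and_coupled_modes_agree_on_synchrony(self):
        node = np.random.default_rng(1).standard_normal((40, 1, 3))
        traj = make_traj(np.repeat(node, 3, axis=1))
        assert cluster_error(traj, {"1", "2"}, 1.0, variables=(0, 1, 2)) == 0.0
        assert cluster_error(traj, {"1", "2"}, 1.0) == 0.0

    def test_contract_violations(self):
        traj = make_traj(np.zeros((10, 3, 3)))
        with pytest.raises(ValueError, match="at least 2"):
            cluster_error(traj, {"1"}, 0.5)
        with pytest.raises(ValueError, match="empty variable"):
            cluster_error(traj, {"1", "2"}, 0.5, variables=())
        with pytest.raises(ValueError, match="window"):
            cluster_error(traj, {"1", "2"}, 100.0)


class TestSimulateNetwork:
    def test_identical_initial_conditions_stay_synchronized(self, f4):
        cfg = SimConfig(coupling=0.05, total_time=30.0, error_window=10.0,
                        ic_amplitude=0.0, seed=1)
        traj = simulate_network(f4, rossler(), cfg)
        assert cluster_error(traj, set(f4.node_labels), 10.0) < 1e-8

    def test_uncoupled_nodes_follow_isolated_flow(self, f4):
        sys = rossler()
        cfg = SimConfig(coupling=0.0, total_time=5.0, error_window=1.0, seed=7)
        traj = simulate_network(f4, sys, cfg)
        for i in range(2):
            ref = solve_ivp(
                lambda t, x: sys.f(x), (0.0, 5.0), traj.states[0, i],
                method="DOP853", rtol=1e-10, atol=1e-10, t_eval=traj.times,
            )
            np.testing.assert_allclose(traj.states[:, i], ref.y.T, atol=1e-4)

    def test_heterogeneous_parameters_drawn_in_band(self, f4):
        het = HeterogeneitySpec("b", 0.01)
        cfg = SimConfig(coupling=0.2, total_time=30.0, error_window=10.0, seed=4)
        traj = simulate_network(f4, rossler(), cfg, het)
        b = traj.heterogeneity_draws["b"]
        assert b.shape == (4,)
        assert np.all((b >= 0.09) & (b <= 0.11))
        assert len(np.unique(b)) == 4

    def test_unknown_heterogeneity_parameter_rejected(self, f4):
        cfg = SimConfig(coupling=0.1, total_time=20.0, error_window=5.0)
        with pytest.raises(ValueError, match="no parameter"):
            simulate_network(f4, rossler(), cfg, HeterogeneitySpec("q", 0.01))


class TestSweep:
    def test_single_ensemble_fixed_seed_reproducible(self, f4):
        cfg = SimConfig(total_time=40.0, error_window=10.0, seed=9)
        kwargs = dict(clusters={"C1": {"3", "4"}}, n_ensembles=1, cfg=cfg)
        a = sweep_errors(f4, rossler(), [0.02, 0.1], **kwargs)
        b = sweep_errors(f4, rossler(), [0.02, 0.1], **kwargs)
        np.testing.assert_array_equal(a.raw, b.raw)
        assert a.cluster_ids == ["C1", "EN"]

    def test_normalization_peaks_at_one(self, f4):
        cfg = SimConfig(total_time=40.0, error_window=10.0, seed=9)
        curves = sweep_errors(f4, rossler(), [0.02, 0.1], {"C1": {"3", "4"}},
                              n_ensembles=1, cfg=cfg)
        for row in curves.normalized:
            assert row.max() == pytest.approx(1.0)
            assert np.all(row >= 0)

    def test_tidy_export_schema(self, f4):
        cfg = SimConfig(total_time=40.0, error_window=10.0, seed=9)
        curves = sweep_errors(f4, rossler(), [0.05], {"C1": {"3", "4"}},
                              n_ensembles=1, cfg=cfg)
        df = curves.to_dataframe()
        assert list(df.columns) == [
            "cluster_id", "d", "raw_error", "normalized_error", "n_ensembles"
        ]
        assert len(df) == 2  # C1 and EN at one coupling


class TestConvergenceAndHeterogeneity:
    def test_doubling_total_time_stable_plateau_error(self, f4):
        # uncoupled nodes give a stationary error plateau; a converged window
        # average should not move by more than 10% when the run is doubled
        errs = []
        for total in (300.0, 600.0):
            cfg = SimConfig(coupling=0.0, total_time=total, error_window=100.0,
                            seed=2)
            traj = simulate_network(f4, rossler(), cfg)
            errs.append(cluster_error(traj, set(f4.node_labels), 100.0))
        assert abs(errs[1] - errs[0]) < 0.10 * errs[0]

    def test_heterogeneous_units_keep_event_ordering(self, f4):
        # with slightly non-identical units the exact synchronous state no
        # longer exists (errors stay positive), but the cluster {3,4} still
        # locks before the entire network does
        het = HeterogeneitySpec("b", 0.01)
        cfg = SimConfig(total_time=300.0, error_window=100.0, seed=6)
        curves = sweep_errors(f4, rossler(), [0.03, 0.06, 0.12],
                              {"C1": {"3", "4"}}, n_ensembles=3, cfg=cfg,
                              het=het)
        assert np.all(curves.raw > 0)
        c1 = curves.normalized[curves.cluster_ids.index("C1")]
        en = curves.normalized[curves.cluster_ids.index("EN")]
        assert c1[1] < 0.1 < en[1]  # cluster locked at 0.06, network not yet
        assert en[2] < 0.1  # network nearly locked well above its threshold


class TestEmpiricalThresholds:
    def _curves(self, grid, rows, ids=None):
        rows = np.asarray(rows, dtype=float)
        ids = ids or [f"C{i+1}" for i in range(rows.shape[0])]
        return SyncErrorCurves(
            d_grid=np.asarray(grid, dtype=float), cluster_ids=ids,
            cluster_nodes={}, raw=rows, normalized=rows, n_ensembles=1,
        )

    def test_step_curve(self):
        curves = self._curves([0.01, 0.02, 0.03, 0.04], [[1, 1, 0.004, 0.002]])
        assert empirical_thresholds(curves, 0.01) == {"C1": 0.03}

    def test_never_synchronized_reported_as_none(self):
        curves = self._curves([0.01, 0.02], [[1.0, 1.0]])
        assert empirical_thresholds(curves, 0.01) == {"C1": None}

    def test_transient_dip_does_not_count(self):
        curves = self._curves(
            [0.01, 0.02, 0.03, 0.04], [[1, 0.005, 0.5, 0.001]]
        )
        assert empirical_thresholds(curves, 0.01) == {"C1": 0.04}

    def test_eps_bounds_enforced(self):
        curves = self._curves([0.01], [[1.0]])
        with pytest.raises(ValueError):
            empirical_thresholds(curves, 0.0)


class TestConfigValidation:
    def test_window_must_fit_in_total(self):
        with pytest.raises(ValueError):
            SimConfig(total_time=50.0, error_window=100.0)

    def test_negative_coupling_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(coupling=-0.1)

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            HeterogeneitySpec("b", -0.01)
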