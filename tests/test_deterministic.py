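import numpy as np
import pytest

from p53combo.deterministic import (
    Trajectory,
    find_ir_crit,
    oscillation_period,
    resting_state,
    simulate,
)
from p53combo.network import CAS_COMMIT, NORMAL, PTEN_CANCER
from p53combo.protocols import EventSchedule, make_protocol


@pytest.fixture(scope="module")
def normal_net(network):
    return network.apply_phenotype(NORMAL)


class TestRestingState:
    def test_untreated_trajectory_stays_at_fixed_point(self, normal_net):
        rest = resting_state(normal_net)
        traj = simulate(normal_net, make_protocol(24, 2, 0.0))
        assert traj.apoptosis_time_h is None
        # every species stays within 1% (or a few molecules) of the rest state
        drift = np.abs(traj.states - rest).max(axis=0)
        tol = np.maximum(0.01 * np.abs(rest), 5.0)
        assert np.all(drift <= tol)

    def test_no_caspase_at_rest(self, normal_net):
        rest = resting_state(normal_net)
        cas = rest[normal_net.index["Caspase"]]
        assert cas < 0.01 * CAS_COMMIT


class TestIntegration:
    def test_step_refinement_below_tenth_percent(self, normal_net):
        """Halving the integrator step changes no species by more than 0.1%
        in sup-norm (relative to the species' own scale)."""
        prot = make_protocol(24, 2, 1.0, (6.0, 18.0), 10.0, "oral")
        a = simulate(normal_net, prot, dt_s=30.0)
        b = simulate(normal_net, prot, dt_s=15.0)
        scale = np.maximum(np.abs(b.states).max(axis=0), 1.0)
        rel = np.abs(a.states - b.states).max(axis=0) / scale
        assert rel.max() < 1e-3

    def test_events_applied_before_sample(self, normal_net):
        traj = simulate(normal_net, make_protocol(24, 1, 2.0),
                        sample_every_h=0.5)
        dsb0 = traj.species("DSB")[0]
        # the t=0 sample already contains the first irradiation's lesions
        assert dsb0 == pytest.approx(
            2.0 * normal_net.params["dsb_per_gy"], rel=0.05)

    def test_horizon_shorter_than_protocol_rejected(self, normal_net):
        with pytest.raises(ValueError):
            simulate(normal_net, make_protocol(24, 6, 1.0), horizon_h=24.0)

    def test_trajectory_nonnegative(self, normal_net):
        traj = simulate(normal_net, make_protocol(12, 4, 3.0))
        assert traj.states.min() >= 0.0

    def test_committed_flag_is_absorbing(self, normal_net):
        traj = simulate(normal_net, make_protocol(24, 3, 1.3))
        assert traj.apoptosis_time_h is not None
        flags = traj.committed
        # once set, never reverts
        first = np.argmax(flags)
        assert flags[first:].all()
        assert not flags[:first].any()


class TestFindIrCrit:
    def test_bracket_and_tolerance(self, normal_net):
        res = find_ir_crit(normal_net, make_protocol(24, 3, None),
                           tolerance=0.05)
        assert np.isfinite(res.ir_crit)
        lo, hi = res.bracket
        assert lo < res.ir_crit <= hi
        assert hi - lo <= 0.05 + 1e-12

    def test_dose_above_crit_is_apoptotic_and_no_later(self, normal_net):
        """Monotone treatment response near the bisection bracket: a higher
        dose commits no later than a lower (both supercritical) dose."""
        res = find_ir_crit(normal_net, make_protocol(24, 6, None),
                           tolerance=0.05)
        d1 = res.ir_crit + 0.1
        d2 = res.ir_crit + 0.3
        t1 = simulate(normal_net, make_protocol(24, 6, d1)).apoptosis_time_h
        t2 = simulate(normal_net, make_protocol(24, 6, d2)).apoptosis_time_h
        assert t1 is not None and t2 is not None
        assert t2 <= t1 + 1e-6

    def test_resistant_cells_reported_unbounded(self, network):
        res = find_ir_crit(network.apply_phenotype(PTEN_CANCER),
                           make_protocol(24, 3, None), tolerance=0.1)
        assert res.resistant
        assert res.ir_crit == np.inf

    def test_warm_bracket_matches_cold(self, normal_net):
        prot = make_protocol(24, 3, None)
        cold = find_ir_crit(normal_net, prot, tolerance=0.05)
        warm = find_ir_crit(normal_net, prot, tolerance=0.05,
                            warm_bracket=(cold.ir_crit - 0.3,
                                          cold.ir_crit + 0.3))
        assert warm.ir_crit == pytest.approx(cold.ir_crit, abs=0.05)


class TestOscillationPeriod:
    def _traj(self, t_h, x):
        states = np.zeros((len(t_h), 1))
        states[:, 0] = x
        return Trajectory(np.asarray(t_h), states, ("s",),
                          EventSchedule(()), None)

    def test_synthetic_sine(self):
        t = np.linspace(0, 72, 2000)
        traj = self._traj(t, 100 + 50 * np.sin(2 * np.pi * t / 7.0))
        assert oscillation_period(traj, "s") == pytest.approx(7.0, abs=0.1)

    def test_constant_signal_is_none(self):
        t = np.linspace(0, 72, 500)
        assert oscillation_period(self._traj(t, np.full_like(t, 5.0)), "s") is None

    def test_fewer_than_three_peaks_is_none(self):
        t = np.linspace(0, 10, 500)
        traj = self._traj(t, 100 + 50 * np.sin(2 * np.pi * t / 7.0))
        assert oscillation_period(traj, "s") is None

    def test_window_restriction(self):
        t = np.linspace(0, 100, 4000)
        x = np.where(t < 50, 100 + 50 * np.sin(2 * np.pi * t / 5.0), 100.0)
        traj = self._traj(t, x)
        assert oscillation_period(traj, "s", window_h=(0, 50)) == pytest.approx(
            5.0, abs=0.1)
        assert oscillation_period(traj, "s", window_h=(50, 100)) is None
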