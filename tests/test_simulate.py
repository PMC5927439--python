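"""Integration, spike detection, frequency measurement and entry tallies."""

import numpy as np
import pytest

from electrocyte import (SolverOptions, SpikeTrain, Trajectory, detect_spikes,
                         epm_default, integrate, measure_frequency,
                         pulsatile_regime, resting_state, steady_regime,
                         tally_entry)
from electrocyte.params import IONS_PER_NA_MS


@pytest.fixture(scope="module")
def p():
    return epm_default()


@pytest.fixture(scope="module")
def traj_200(p):
    """Standard 200 Hz pulsatile train, 30 periods."""
    return integrate(p, pulsatile_regime(1.0, 200.0), 150.0)


class TestIntegrate:
    def test_zero_drive_holds_rest(self, p, rest):
        traj = integrate(p, None, 100.0)
        assert np.all(np.abs(traj.v - rest.v) < 0.01)

    def test_gating_variables_stay_in_unit_interval(self, traj_200):
        for x in (traj_200.m, traj_200.h, traj_200.n):
            assert x.min() >= 0.0 and x.max() <= 1.0

    def test_one_spike_per_stimulus_period(self, traj_200):
        train = detect_spikes(traj_200)
        assert len(train) == 30

    def test_sampling_resolution(self, traj_200):
        assert np.diff(traj_200.t).max() <= 0.01 + 1e-12

    def test_reproducible_bit_for_bit(self, p):
        a = integrate(p, pulsatile_regime(1.0, 200.0), 20.0)
        b = integrate(p, pulsatile_regime(1.0, 200.0), 20.0)
        assert np.array_equal(a.v, b.v) and np.array_equal(a.h, b.h)

    def test_solver_convergence_on_peak_potential(self, p):
        """Halving the step changes the steady-state V_peak by < 0.01 mV."""
        peaks = []
        for dt in (5e-4, 2.5e-4):
            traj = integrate(p, pulsatile_regime(1.0, 200.0), 150.0,
                             SolverOptions(dt=dt, sample_dt=2e-3))
            train = detect_spikes(traj)
            peaks.append(train.peaks[-10:].mean())
        assert abs(peaks[1] - peaks[0]) < 0.01

    def test_bad_duration_rejected(self, p):
        with pytest.raises(ValueError):
            integrate(p, None, 0.0)


class TestDetectSpikes:
    def test_subthreshold_drive_gives_empty_train(self, p):
        traj = integrate(p, steady_regime(0.005), 100.0)
        assert len(detect_spikes(traj)) == 0

    def test_standard_train_peaks_near_13_mv(self, traj_200):
        train = detect_spikes(traj_200)
        assert train.peaks[5:].mean() == pytest.approx(12.86, abs=0.2)

    def test_depolarization_crosses_apparent_threshold_region(self, traj_200):
        """The upstroke accelerates near -45 mV (apparent threshold)."""
        assert traj_200.v.min() < -45.0 < traj_200.v.max()

    def test_synthetic_sine_counts_crossings(self, p):
        t = np.linspace(0.0, 50.0, 20001)
        k = 7
        v = -25.0 + 20.0 * np.sin(2 * np.pi * k * t / 50.0)
        traj = Trajectory(t, v, np.zeros_like(v), np.zeros_like(v),
                          np.zeros_like(v), None, p, SolverOptions())
        train = detect_spikes(traj)
        assert len(train) == k
        assert np.all(np.abs(train.peaks - (-5.0)) < 1e-3)


class TestMeasureFrequency:
    def test_exact_intervals(self):
        train = SpikeTrain(times=np.arange(20) * 5.0, peaks=np.full(20, 10.0))
        assert measure_frequency(train, (0.0, 100.0)) == pytest.approx(200.0)

    def test_too_few_spikes_reports_nonfiring(self):
        train = SpikeTrain(times=np.array([1.0, 2.0]), peaks=np.zeros(2))
        assert measure_frequency(train, (0.0, 100.0)) == 0.0


class TestTallyEntry:
    def test_charge_to_ion_constant(self):
        assert IONS_PER_NA_MS == pytest.approx(6.2415e6, rel=1e-4)

    def test_pathway_additivity_is_exact(self, p):
        traj = integrate(p, pulsatile_regime(1.0, 200.0), 200.0)
        tally = tally_entry(traj, detect_spikes(traj))
        assert tally.na_total == tally.na_transient + tally.na_persistent \
            + tally.na_achr
        assert tally.na_nav == tally.na_transient + tally.na_persistent
        for field in ("na_transient", "na_persistent", "na_achr"):
            assert getattr(tally, field) >= 0.0

    def test_window_doubling_leaves_per_ap_entry_stable(self, p):
        """Per-AP values are stationary: doubling the train changes < 0.5%."""
        short = integrate(p, pulsatile_regime(1.0, 200.0), 150.0)
        long = integrate(p, pulsatile_regime(1.0, 200.0), 275.0)
        t_short = tally_entry(short, detect_spikes(short))
        t_long = tally_entry(long, detect_spikes(long))
        assert t_long.na_total == pytest.approx(t_short.na_total, rel=5e-3)
        assert t_long.na_achr == pytest.approx(t_short.na_achr, rel=5e-3)

    def test_steady_drive_uses_spike_midpoint_windows(self, p):
        traj = integrate(p, steady_regime(0.05), 200.0)
        train = detect_spikes(traj)
        tally = tally_entry(traj, train)
        assert tally.n_spikes >= 20
        assert tally.na_total > 0

    def test_insufficient_spikes_rejected(self, p):
        traj = integrate(p, pulsatile_regime(1.0, 200.0), 50.0)
        with pytest.raises(ValueError, match="need >= 20"):
            tally_entry(traj, detect_spikes(traj))

    def test_trajectory_csv_roundtrip(self, p, tmp_path):
        import pandas as pd

        traj = integrate(p, pulsatile_regime(1.0, 200.0), 5.0)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "t_ms", "V_mV", "m", "h", "n", "I_NaT_nA", "I_NaP_nA", "I_K_nA",
            "I_L_nA", "I_AChR_Na_nA", "I_AChR_K_nA", "I_clamp_nA"]
        np.testing.assert_allclose(df["V_mV"], traj.v, rtol=1e-9)
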