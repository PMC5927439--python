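"""Synaptic and current-clamp stimulus waveforms."""

import math

import numpy as np
import pytest

from electrocyte import (BackgroundSynDrive, CurrentClampDrive,
                         PulsatileSynDrive, StimulusRegime, clamp_current,
                         pulse_shape, syn_level)


class TestPulseShape:
    @pytest.mark.parametrize("t, expect", [
        (0.025, 0.5),                       # halfway up the linear rise
        (0.25, 1.0),                        # plateau end
        (0.35, math.exp(-1.0)),             # one decay constant into the tail
        (0.0, 0.0),
    ])
    def test_piecewise_values(self, t, expect):
        assert pulse_shape(t) == pytest.approx(expect)

    def test_unit_area(self):
        """Triangle + plateau + exponential tail integrate to 0.325 ms."""
        from scipy.integrate import quad

        area, _ = quad(pulse_shape, 0.0, 5.0, points=[0.05, 0.25], limit=200)
        assert area == pytest.approx(0.325, rel=1e-6)


class TestSynLevel:
    def test_background_only_is_constant(self):
        regime = StimulusRegime(background=BackgroundSynDrive(0.00736))
        t = np.linspace(0.0, 30.0, 1000)
        assert np.all(syn_level(t, regime) == 0.00736)

    def test_pulses_ride_additively_on_background(self):
        regime = StimulusRegime(
            pulsatile=PulsatileSynDrive(amplitude=0.4, frequency=200.0),
            background=BackgroundSynDrive(0.00736))
        # on the plateau of the second pulse
        assert syn_level(5.0 + 0.1, regime) == pytest.approx(0.40736)

    def test_zero_amplitude_reduces_to_background(self):
        regime = StimulusRegime(
            pulsatile=PulsatileSynDrive(amplitude=0.0, frequency=200.0),
            background=BackgroundSynDrive(0.02))
        t = np.linspace(0.0, 10.0, 500)
        assert np.all(syn_level(t, regime) == 0.02)

    def test_periodicity(self):
        regime = StimulusRegime(
            pulsatile=PulsatileSynDrive(amplitude=1.0, frequency=200.0))
        t = np.linspace(0.0, 5.0, 777, endpoint=False)
        np.testing.assert_allclose(syn_level(t, regime),
                                   syn_level(t + 5.0, regime), atol=1e-12)

    def test_peak_reached_on_plateau_once_per_period(self):
        regime = StimulusRegime(
            pulsatile=PulsatileSynDrive(amplitude=0.7, frequency=400.0),
            background=BackgroundSynDrive(0.1))
        t = np.linspace(0.0, 2.5, 100000, endpoint=False)
        levels = syn_level(t, regime)
        assert levels.max() == pytest.approx(0.8)
        assert levels.min() >= 0.1

    def test_regime_without_synaptic_part_rejected(self):
        clamp = CurrentClampDrive(kind="step", amplitude=100.0, duration=40.0)
        with pytest.raises(ValueError):
            syn_level(1.0, StimulusRegime(clamp=clamp))


class TestClampCurrent:
    def test_step_window(self):
        drive = CurrentClampDrive(kind="step", amplitude=1500.0, duration=40.0)
        assert clamp_current(20.0, drive) == 1500.0
        assert clamp_current(40.0, drive) == 0.0
        assert clamp_current(45.0, drive) == 0.0

    def test_ramp_is_linear_to_peak(self):
        drive = CurrentClampDrive(kind="ramp", amplitude=2400.0, duration=40.0)
        assert clamp_current(20.0, drive) == pytest.approx(1200.0)
        assert clamp_current(39.999, drive) == pytest.approx(2400.0, rel=1e-3)
        assert clamp_current(41.0, drive) == 0.0

    def test_pulse_train_duty_cycle(self):
        drive = CurrentClampDrive(kind="pulse-train", amplitude=1000.0,
                                  duration=100.0, pulse_width=0.2,
                                  frequency=200.0)
        t = np.linspace(0.0, 100.0, 200001, endpoint=False)
        duty = np.mean(clamp_current(t, drive) > 0)
        assert duty == pytest.approx(0.2 * 200.0 / 1000.0, rel=0.01)

    def test_invalid_drives_rejected(self):
        with pytest.raises(ValueError):
            CurrentClampDrive(kind="sine", amplitude=1.0, duration=10.0)
        with pytest.raises(ValueError):
            PulsatileSynDrive(amplitude=-0.1, frequency=200.0)
        with pytest.raises(ValueError):
            PulsatileSynDrive(amplitude=1.0, frequency=5000.0)  # period < pulse
        with pytest.raises(ValueError):
            StimulusRegime()

    def test_combined_synaptic_and_clamp_warns(self):
        with pytest.warns(UserWarning, match="not a standard protocol"):
            StimulusRegime(
                background=BackgroundSynDrive(0.01),
                clamp=CurrentClampDrive(kind="step", amplitude=10.0,
                                        duration=10.0))
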