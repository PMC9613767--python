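import math

import numpy as np
import pytest

from stemwave.treatment import (GLIOMA, HazardParams, TreatmentSchedule,
                                build_schedule, hazard_continuous,
                                hazard_fractionated)


class TestDecayingSourceHazard:
    def test_value_at_source_placement(self):
        # alpha_r*R0 + 2 beta_r R0^2/lam (e^{lam*omega} - 1) at t=0
        p = HazardParams()  # prostate defaults, R0 = 5.71
        expected = 0.15 * 5.71 + 2 * 0.048 * 5.71 ** 2 / 0.0408 * (
            math.exp(0.0408 / 90) - 1.0
        )
        assert hazard_continuous(0.0, p) == pytest.approx(expected, rel=1e-12)
        assert hazard_continuous(0.0, p) == pytest.approx(0.89, abs=0.01)

    def test_monotone_decay_to_zero(self):
        p = HazardParams(R0=50.0)
        t = np.linspace(0.0, 400.0, 500)
        T = hazard_continuous(t, p)
        assert np.all(np.diff(T) < 0.0)
        assert T[-1] < 1e-4 * T[0]

    def test_pure_linear_kill_without_quadratic_term(self):
        p = HazardParams(beta_r=0.0)
        t = np.array([0.0, 10.0, 30.0])
        assert np.allclose(
            hazard_continuous(t, p), 0.15 * 5.71 * np.exp(-0.0408 * t)
        )

    def test_zero_decay_rate_rejected(self):
        with pytest.raises(ValueError, match="lam"):
            hazard_continuous(1.0, HazardParams(lam=0.0))
        with pytest.raises(ValueError, match=">= 0"):
            hazard_continuous(-1.0, HazardParams())


class TestFractionatedHazard:
    @pytest.mark.parametrize(
        "dose,expected", [(2.0, 0.296), (1.5, 0.20775), (0.0, 0.0)]
    )
    def test_daily_fraction_values(self, dose, expected):
        p = HazardParams(mode="fractionated", alpha_r=GLIOMA["alpha_r"],
                         beta_r=GLIOMA["beta_r"], dose_per_fraction=dose)
        assert hazard_fractionated(p) == pytest.approx(expected, abs=1e-12)

    def test_burst_delivers_same_integrated_kill(self):
        # 2 Gy in 10 minutes: T is larger but T * width matches the daily case
        width = 10.0 / 1440.0
        p = HazardParams(mode="fractionated", alpha_r=GLIOMA["alpha_r"],
                         beta_r=GLIOMA["beta_r"], dose_per_fraction=2.0,
                         fraction_duration=width)
        assert hazard_fractionated(p) * width == pytest.approx(0.296)


class TestSchedule:
    def test_hat_rates_piecewise_definition(self):
        sched = build_schedule("continuous", start=20.0, delta=0.3,
                               baseline_alpha=0.012)
        assert sched.alpha_hat(10.0) == 0.012
        assert sched.b_hat(10.0) == 0.0
        T0 = sched.T(20.0)
        assert T0 > 0
        assert sched.alpha_hat(20.0) == pytest.approx(0.012 + T0)
        assert sched.b_hat(20.0) == pytest.approx(0.3 * T0)
        # clock measures time since the source was placed
        assert sched.T(50.0) == pytest.approx(
            hazard_continuous(30.0, sched.hazard)
        )

    def test_alpha_hat_never_below_baseline(self):
        sched = build_schedule("frac-2-2")
        t = np.linspace(0.0, 200.0, 4001)
        ah = np.array([sched.alpha_hat(tk) for tk in t])
        assert np.all(ah >= sched.baseline_alpha)

    def test_breakpoints_at_window_edges(self):
        sched = build_schedule("frac-20-20")
        assert sched.windows == ((20.0, 40.0), (60.0, 80.0))
        assert sched.breakpoints(100.0) == [0.0, 20.0, 40.0, 60.0, 80.0, 100.0]

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TreatmentSchedule(windows=((0.0, 5.0), (4.0, 8.0)))
        with pytest.raises(ValueError, match="non-positive length"):
            TreatmentSchedule(windows=((3.0, 3.0),))


class TestProtocols:
    def test_two_on_two_off_reaches_total_dose(self):
        sched = build_schedule("frac-2-2")
        # 30 on-days at 2 Gy/day in 15 two-day blocks
        assert len(sched.windows) == 15
        assert sched.cumulative_dose() == pytest.approx(60.0)
        assert sched.windows[0] == (20.0, 22.0)
        assert sched.windows[1] == (24.0, 26.0)

    def test_twenty_twenty_reaches_total_dose(self):
        sched = build_schedule("frac-20-20")
        assert sched.cumulative_dose() == pytest.approx(60.0)

    def test_daily_bursts_weekdays_only(self):
        sched = build_schedule("frac-daily-bursts")
        assert len(sched.windows) == 30  # 30 x 2 Gy = 60 Gy
        assert sched.cumulative_dose() == pytest.approx(60.0)
        width = 10.0 / 1440.0
        starts = [w[0] for w in sched.windows]
        for (a, b) in sched.windows:
            assert b - a == pytest.approx(width)
        # weekend gaps: days 5 and 6 of each week are skipped
        offsets = sorted(int(round(s - 20.0)) % 7 for s in starts)
        assert set(offsets) <= {0, 1, 2, 3, 4}

    def test_intermittent_block_pattern(self):
        sched = build_schedule("intermittent")
        # 36 weeks on / 36 off from week 4, horizon 250 weeks -> 4 blocks
        assert len(sched.windows) == 4
        assert sched.windows[0] == (28.0, 280.0)
        assert sched.windows[1] == (532.0, 784.0)

    def test_empty_protocol_is_no_treatment(self):
        sched = build_schedule("none")
        for t in (0.0, 15.0, 400.0):
            assert sched.T(t) == 0.0
            assert sched.alpha_hat(t) == sched.baseline_alpha

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError, match="unknown treatment protocol"):
            build_schedule("frac-7-7")
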