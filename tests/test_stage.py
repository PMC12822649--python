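"""Stage calibration, move planning and closed-loop positioning."""

import numpy as np
import pytest

from foveloc.errors import (CalibrationError, DataError, ParameterError,
                            TravelRangeError)
from foveloc.scene import SimulatedStage, StageModel, simulate_observation
from foveloc.stage import (Calibration, calibrate, plan_move, position_target,
                           report_localization_error)

from oracles import mean_sd_of_magnitudes


def _sim(spm=(80.0, 80.0), noise=0.0, seed=0, fovea=(0.0, 0.0)):
    return SimulatedStage(StageModel(true_steps_per_mm=spm,
                                     obs_noise_sd_mm=noise, seed=seed), fovea)


class TestCalibrate:
    @pytest.mark.parametrize("true_spm", [40.0, 80.0, 160.0])
    def test_noiseless_recovery_is_exact(self, true_spm):
        cal = calibrate(_sim(spm=(true_spm, true_spm)), (400, 400), 3)
        assert cal.steps_per_mm == pytest.approx((true_spm, true_spm))
        assert cal.residual_sd_mm == pytest.approx(0.0)

    @pytest.mark.parametrize("true_spm", [40.0, 80.0, 160.0])
    @pytest.mark.parametrize("noise", [0.005, 0.01])
    def test_noisy_recovery_within_two_percent(self, true_spm, noise):
        stage = _sim(spm=(true_spm, true_spm), noise=noise, seed=5)
        cal = calibrate(stage, (400, 400), n_repeats=25)
        for est in cal.steps_per_mm:
            assert abs(est - true_spm) / true_spm <= 0.02
        assert cal.residual_sd_mm > 0

    def test_zero_probe_rejected(self):
        with pytest.raises(ParameterError):
            calibrate(_sim(), (0, 400), 3)

    def test_vanishing_displacement_is_a_calibration_error(self):
        class FrozenStage:
            def observe_fovea(self, n_average=1):
                return np.zeros(2)

            def move_steps(self, steps):
                pass

        with pytest.raises(CalibrationError):
            calibrate(FrozenStage(), (400, 400), 3)


class TestPlanMove:
    cal = Calibration(steps_per_mm=(80.0, 80.0), n_repeats=3,
                      residual_sd_mm=0.0)

    def test_cancelling_command_arithmetic(self):
        # +x step moves the observed fovea toward -x, so cancelling a
        # positive offset takes a positive step count
        assert plan_move((2.0, -1.5), self.cal).steps == (160, -120)

    def test_origin_needs_no_move(self):
        assert plan_move((0.0, 0.0), self.cal).steps == (0, 0)

    def test_rounding_half_away_from_zero(self):
        cal = Calibration(steps_per_mm=(10.0, 10.0), n_repeats=1,
                          residual_sd_mm=0.0)
        assert plan_move((0.05, -0.05), cal).steps == (1, -1)

    def test_travel_limits_enforced(self):
        with pytest.raises(TravelRangeError):
            plan_move((30.0, 0.0), self.cal, travel_limit_steps=(2000, 2000))


class TestClosedLoop:
    def test_noiseless_positioning_within_one_step(self):
        for fovea in [(2.013, -1.492), (0.4, 0.77), (-3.2, 2.9)]:
            stage = _sim(fovea=fovea)
            cal = calibrate(stage, (400, 400), 3)
            final = position_target(stage, cal)
            assert np.all(np.abs(final) < 1.0 / 80.0)

    def test_noisy_positioning_contracts_to_one_step(self):
        stage = _sim(noise=0.005, seed=9, fovea=(2.0, -1.5))
        cal = calibrate(stage, (400, 400), n_repeats=25)
        position_target(stage, cal, n_average=5)
        true_offset = (stage.fovea_mm
                       - stage.model.position_steps
                       / np.asarray(stage.model.true_steps_per_mm))
        assert np.all(np.abs(true_offset) <= 1.0 / 80.0)

    def test_positive_step_moves_observation_negative(self):
        model = StageModel(true_steps_per_mm=(80.0, 80.0))
        before = simulate_observation(model, (0.0, 0.0))
        model.move_steps(np.array([8, 0]))
        after = simulate_observation(model, (0.0, 0.0))
        assert after[0] < before[0]
        assert after[1] == before[1]


class TestLocalizationSummary:
    def test_constant_offsets(self):
        s = report_localization_error([(0.1, 0.0)] * 5)
        assert (s.mean_mm, s.sd_mm) == pytest.approx((0.1, 0.0))
        assert s.sd_defined

    def test_single_offset_flags_undefined_sd(self):
        s = report_localization_error([(0.3, 0.4)])
        assert s.mean_mm == pytest.approx(0.5)
        assert s.sd_mm == 0.0
        assert not s.sd_defined

    def test_random_fixture_matches_hand_computation(self):
        rng = np.random.default_rng(24)
        offsets = [tuple(v) for v in rng.normal(0, 0.1, size=(24, 2))]
        s = report_localization_error(offsets)
        mean, sd = mean_sd_of_magnitudes(offsets)
        assert s.mean_mm == pytest.approx(mean)
        assert s.sd_mm == pytest.approx(sd)
        assert s.n == 24

    def test_empty_list_rejected(self):
        with pytest.raises(DataError):
            report_localization_error([])
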