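"""Stepper-stage calibration and fovea targeting.

The stage carries the eyecup under a fixed punch axis.  Its steps-per-mm
constants are never trusted from the datasheet: they are estimated by
commanding a known step count per axis and measuring the fovea's
apparent displacement in the imagery, repeated a few times to average
observation noise ("moving the stage a set distance" calibration).
Targeting then converts the measured fovea offset into an integer step
command that cancels it.

Sign convention, used consistently everywhere: a positive commanded step
on an axis moves the *observed* fovea in the negative direction of that
axis, so cancelling an offset ``o`` requires ``round(o * steps_per_mm)``
steps.

Any object with ``move_steps(steps)`` and ``observe_fovea(n_average)``
works as the stage interface; tests use the simulator from
:mod:`foveloc.scene`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, DataError, ParameterError, TravelRangeError


@dataclass(frozen=True)
class Calibration:
    """Estimated steps-per-mm per axis with repeat scatter."""

    steps_per_mm: tuple[float, float]
    n_repeats: int
    residual_sd_mm: float

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.steps_per_mm):
            raise ParameterError("steps_per_mm: must be > 0 per axis")
        if self.residual_sd_mm < 0:
            raise ParameterError("residual_sd_mm: must be >= 0")


@dataclass(frozen=True)
class MoveCommand:
    """Integer step command for the two stage axes."""

    steps: tuple[int, int]


def calibrate(stage, probe_steps: tuple[int, int], n_repeats: int = 5,
              n_average: int = 1) -> Calibration:
    """Estimate steps-per-mm by commanded probe moves.

    Per axis and repeat: observe the fovea, move by ``probe_steps`` on
    that axis, observe again, move back.  The axis constant is
    ``|probe| / mean(|observed displacement|)``; ``residual_sd_mm`` is
    the pooled sample SD of the displacement magnitudes.

    Raises :class:`CalibrationError` when the mean displacement is
    indistinguishable from zero.
    """
    probe = np.asarray(probe_steps, dtype=np.int64)
    if probe.shape != (2,) or np.any(probe == 0):
        raise ParameterError("probe_steps: both axes need a nonzero step count")
    if n_repeats < 1:
        raise ParameterError("n_repeats: must be >= 1")

    spm = np.zeros(2)
    scatter = []
    for axis in range(2):
        move = np.zeros(2, dtype=np.int64)
        move[axis] = probe[axis]
        disps = []
        for _ in range(n_repeats):
            before = stage.observe_fovea(n_average)
            stage.move_steps(move)
            after = stage.observe_fovea(n_average)
            stage.move_steps(-move)
            disps.append(abs(after[axis] - before[axis]))
        disps = np.asarray(disps)
        mean_disp = disps.mean()
        if mean_disp < 1e-12:
            raise CalibrationError(
                f"axis {axis}: mean displacement below resolution")
        spm[axis] = abs(int(probe[axis])) / mean_disp
        scatter.append(disps.std(ddof=1) if n_repeats > 1 else 0.0)

    return Calibration(steps_per_mm=(float(spm[0]), float(spm[1])),
                       n_repeats=int(n_repeats),
                       residual_sd_mm=float(np.sqrt(np.mean(np.square(scatter)))))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


def plan_move(fovea_mm, cal: Calibration,
              travel_limit_steps: tuple[int, int] | None = None) -> MoveCommand:
    """Step command that places the fovea under the punch axis.

    ``fovea_mm`` is the observed fovea offset from the punch axis; under
    the package-wide sign convention the cancelling command is
    ``round(fovea_mm * steps_per_mm)`` per axis (half away from zero).
    """
    fovea_mm = np.asarray(fovea_mm, dtype=float)
    if fovea_mm.shape != (2,) or not np.all(np.isfinite(fovea_mm)):
        raise ParameterError("fovea_mm: two finite components required")
    steps = _round_half_away(fovea_mm * np.asarray(cal.steps_per_mm))
    if travel_limit_steps is not None:
        limit = np.asarray(travel_limit_steps)
        if np.any(np.abs(steps) > limit):
            raise TravelRangeError(
                f"command {tuple(steps)} exceeds travel limits {tuple(limit)}")
    return MoveCommand(steps=(int(steps[0]), int(steps[1])))


def position_target(stage, cal: Calibration, max_iterations: int = 8,
                    n_average: int = 3,
                    travel_limit_steps: tuple[int, int] | None = None,
                    ) -> np.ndarray:
    """Closed-loop observe/plan/move until the command rounds to zero.

    Returns the final observed offset (mm).  On a noiseless stage this
    converges in one move to within one-step quantization; with noise it
    contracts to the observation-noise floor.
    """
    observed = stage.observe_fovea(n_average)
    for _ in range(max_iterations):
        cmd = plan_move(observed, cal, travel_limit_steps)
        if cmd.steps == (0, 0):
            break
        stage.move_steps(np.asarray(cmd.steps))
        observed = stage.observe_fovea(n_average)
    return observed


@dataclass(frozen=True)
class LocalizationSummary:
    """Mean and sample SD of residual offset magnitudes."""

    mean_mm: float
    sd_mm: float
    n: int
    sd_defined: bool  # False for n=1, where sd is reported as 0


def report_localization_error(offsets_mm) -> LocalizationSummary:
    """Summarize residual offsets as mean +/- sample SD of magnitudes."""
    offsets = np.atleast_2d(np.asarray(offsets_mm, dtype=float))
    if offsets.size == 0:
        raise DataError("offsets_mm: must be non-empty")
    mags = np.linalg.norm(offsets, axis=1)
    n = mags.size
    sd = float(mags.std(ddof=1)) if n > 1 else 0.0
    return LocalizationSummary(mean_mm=float(mags.mean()), sd_mm=sd,
                               n=int(n), sd_defined=n > 1)
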