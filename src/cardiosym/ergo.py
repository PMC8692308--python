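"""Ergometry utilities: maximal workload extrapolation and caffeine dosing."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ErgometryInput", "wmax", "caffeine_dose"]


@dataclass(frozen=True)
class ErgometryInput:
    """Graded-exercise-test endpoint for the Wmax extrapolation.

    ``output_w`` is the workload of the last completed stage (W) and
    ``t_s`` the time spent in the final, uncompleted stage (s).  The
    protocol increments the load by ``stage_increment_w`` per stage.
    ``stage_duration_divisor`` is the denominator of the partial-stage
    fraction: 113 as the source protocol prints it, with the
    conventional 120 s stage duration selectable.
    """

    output_w: float
    t_s: float
    stage_increment_w: float = 45.0
    stage_duration_divisor: float = 113.0

    def __post_init__(self) -> None:
        if self.output_w <= 0:
            raise ValueError("output_w must be positive")
        if self.t_s < 0:
            raise ValueError("t_s must be non-negative")
        if self.t_s > self.stage_duration_divisor:
            raise ValueError("t_s cannot exceed the stage duration")
        if self.stage_increment_w <= 0 or self.stage_duration_divisor <= 0:
            raise ValueError("increment and divisor must be positive")


def wmax(inp: ErgometryInput) -> float:
    """Maximal workload: completed load plus the pro-rated partial stage.

    Wmax = output + (t / divisor) · increment.
    """
    return inp.output_w + (inp.t_s / inp.stage_duration_divisor) * inp.stage_increment_w


def caffeine_dose(body_mass_kg: float, dose_per_kg: float = 6.0) -> float:
    """Absolute caffeine dose in mg at a per-kg prescription (default 6 mg/kg)."""
    if body_mass_kg <= 0:
        raise ValueError("body mass must be positive")
    if dose_per_kg < 0:
        raise ValueError("dose_per_kg must be non-negative")
    return round(body_mass_kg * dose_per_kg, 2)
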