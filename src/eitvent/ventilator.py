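"""Ventilator pressure programs and ideal airway-pressure waveforms.

Four modes cover the study design of a recruitment-maneuver experiment:

``volume_control_proxy``
    Baseline ventilation. The simulator is pressure-driven, so volume
    control is proxied by a linear inspiratory ramp from PEEP to a plateau
    chosen to deliver the configured driving pressure, with a short
    end-inspiratory hold so a no-flow pressure exists to read off.
``CPAP``
    Sustained inflation (SI): continuous positive airway pressure held
    constant, e.g. 40 cmH2O for 40 s.
``incremental_PEEP``
    PEEP titration (IP): a staircase from baseline PEEP up to a maximum in
    fixed increments and back down, square inspiratory cycles riding on
    each step, inspiratory pressure capped at the maneuver maximum.
``PCV``
    Pressure-controlled ventilation: square wave between PEEP and peak
    pressure with the inspiratory fraction set by the I:E ratio.

All pressures are cmH2O, rates are breaths/min, durations are seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import ConfigError, PressureTrace

MODES = ("volume_control_proxy", "CPAP", "incremental_PEEP", "PCV")


@dataclass(frozen=True)
class VentilatorProgram:
    """One ventilator setting block.

    ``i_to_e`` is the inspiratory:expiratory time ratio expressed as I/E
    (1:2 -> 0.5). ``peak_or_plateau`` is the CPAP level, PCV peak, ramp
    plateau, or the staircase maximum depending on mode. ``step_size`` /
    ``step_duration`` apply to ``incremental_PEEP`` only;
    ``riding_driving_pressure`` is the amplitude of the square cycles
    riding on each PEEP step.
    """

    mode: str
    respiratory_rate: float = 30.0
    i_to_e: float = 0.5
    peep: float = 5.0
    peak_or_plateau: float = 20.0
    duration: float = 60.0
    step_size: float = 5.0
    step_duration: float = 30.0
    riding_driving_pressure: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"unknown ventilator mode {self.mode!r}; expected one of {MODES}")
        if not self.peak_or_plateau >= self.peep >= 0:
            raise ConfigError(
                f"need peak_or_plateau >= peep >= 0, got {self.peak_or_plateau}, {self.peep}"
            )
        if not self.duration > 0:
            raise ConfigError(f"duration must be > 0, got {self.duration}")
        if not self.respiratory_rate > 0:
            raise ConfigError(f"respiratory_rate must be > 0, got {self.respiratory_rate}")
        if not self.i_to_e > 0:
            raise ConfigError(f"i_to_e must be > 0, got {self.i_to_e}")
        if self.mode == "incremental_PEEP":
            if not self.step_size > 0 or not self.step_duration > 0:
                raise ConfigError("incremental_PEEP needs step_size > 0 and step_duration > 0")

    @property
    def cycle_length(self) -> float:
        """Breath cycle length in seconds."""
        return 60.0 / self.respiratory_rate

    @property
    def inspiratory_time(self) -> float:
        """Inspiratory time per cycle: I/(I+E) of the cycle."""
        return self.cycle_length * self.i_to_e / (1.0 + self.i_to_e)

    def peep_steps(self) -> list[float]:
        """Staircase PEEP levels, ascending then descending (max not repeated)."""
        if self.mode != "incremental_PEEP":
            raise ConfigError("peep_steps only applies to incremental_PEEP")
        n_up = int(round((self.peak_or_plateau - self.peep) / self.step_size))
        up = [self.peep + k * self.step_size for k in range(n_up + 1)]
        return up + up[-2::-1]


def baseline_program(
    peep: float = 5.0,
    driving_pressure: float = 15.0,
    respiratory_rate: float = 30.0,
    duration: float = 180.0,
) -> VentilatorProgram:
    """Baseline ventilation proxy: Vt ~6 mL/kg at RR 30, I:E 1:2, PEEP 5.

    The plateau sits ``driving_pressure`` above PEEP; that pressure
    difference plays the role of the no-flow driving pressure a volume
    mode would produce.
    """
    return VentilatorProgram(
        mode="volume_control_proxy",
        respiratory_rate=respiratory_rate,
        peep=peep,
        peak_or_plateau=peep + driving_pressure,
        duration=duration,
    )


def sustained_inflation_program(pressure: float = 40.0, duration: float = 40.0) -> VentilatorProgram:
    """SI maneuver: CPAP held at 40 cmH2O for 40 s."""
    return VentilatorProgram(mode="CPAP", peep=pressure, peak_or_plateau=pressure, duration=duration)


def incremental_peep_program(
    low: float = 5.0,
    high: float = 40.0,
    step_size: float = 5.0,
    step_duration: float = 30.0,
    respiratory_rate: float = 30.0,
) -> VentilatorProgram:
    """IP maneuver: PEEP 5 -> 40 -> 5 in 5 cmH2O steps, 30 s per step."""
    n_steps = 2 * int(round((high - low) / step_size)) + 1
    return VentilatorProgram(
        mode="incremental_PEEP",
        respiratory_rate=respiratory_rate,
        peep=low,
        peak_or_plateau=high,
        duration=n_steps * step_duration,
        step_size=step_size,
        step_duration=step_duration,
    )


def pcv_program(
    peak: float = 40.0,
    peep: float = 20.0,
    duration: float = 120.0,
    respiratory_rate: float = 30.0,
    i_to_e: float = 0.5,
) -> VentilatorProgram:
    """PCV maneuver: 40/20 cmH2O, I:E 1:2, RR 30, for 2 min."""
    return VentilatorProgram(
        mode="PCV",
        respiratory_rate=respiratory_rate,
        i_to_e=i_to_e,
        peep=peep,
        peak_or_plateau=peak,
        duration=duration,
    )


def with_duration(program: VentilatorProgram, duration: float) -> VentilatorProgram:
    """Copy of ``program`` running for a different length of time."""
    return replace(program, duration=duration)


# fraction of the inspiratory time spent ramping in volume_control_proxy;
# the remainder is an end-inspiratory hold at the plateau (no-flow window)
_RAMP_FRACTION = 0.8


def pressure_waveform(program: VentilatorProgram, sample_rate: float) -> PressureTrace:
    """Render a ventilator program as an ideal airway-pressure trace.

    The trace has ``floor(duration * sample_rate)`` samples. Square
    transitions are instantaneous; no airway resistance or compliance
    shaping is applied (the lung model adds its own first-order lag).
    """
    if not sample_rate > 0:
        raise ConfigError(f"sample_rate must be > 0, got {sample_rate}")
    n = int(program.duration * sample_rate)
    t = np.arange(n) / sample_rate

    if program.mode == "CPAP":
        p = np.full(n, float(program.peak_or_plateau))
    elif program.mode == "PCV":
        phase = t % program.cycle_length
        p = np.where(phase < program.inspiratory_time, program.peak_or_plateau, program.peep)
    elif program.mode == "volume_control_proxy":
        phase = t % program.cycle_length
        ti = program.inspiratory_time
        ramp = np.clip(phase / (_RAMP_FRACTION * ti), 0.0, 1.0)
        p = np.where(
            phase < ti,
            program.peep + (program.peak_or_plateau - program.peep) * ramp,
            program.peep,
        )
    elif program.mode == "incremental_PEEP":
        steps = np.asarray(program.peep_steps())
        idx = np.minimum((t / program.step_duration).astype(int), len(steps) - 1)
        base = steps[idx]
        insp_level = np.minimum(
            base + program.riding_driving_pressure, program.peak_or_plateau
        )
        phase = t % program.cycle_length
        p = np.where(phase < program.inspiratory_time, insp_level, base)
    else:  # pragma: no cover - guarded in __post_init__
        raise ConfigError(f"unknown ventilator mode {program.mode!r}")

    return PressureTrace(samples=p, sample_rate=sample_rate)


def time_at_or_above(trace: PressureTrace, threshold: float) -> float:
    """Cumulative seconds the trace spends at pressure >= threshold."""
    return float(np.count_nonzero(trace.samples >= threshold)) / trace.sample_rate
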