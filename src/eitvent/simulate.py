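"""Time-domain simulation of EIT recordings from a lung phantom.

Per frame, every *open* lung pixel is driven toward a target impedance
``compliance * (P(t) - pressure_ref)`` through a first-order lag (time
constant ``lag_tau``); *closed* pixels are driven toward a small residual
fraction of that target (collapsed tissue is not impedance-silent).
Open/closed states evolve stochastically against the instantaneous airway
pressure with the hazards of the phantom configuration. Gaussian sensor
noise is added to every pixel and an optional sinusoidal cardiac artifact
to a small para-cardiac patch.

Outside the recording windows of a study (stabilization, inter-maneuver
washout) only the open/closed states need to be evolved, which
:func:`evolve_states` does at a coarser time step without rendering
frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .core import ConfigError, FrameSequence, PressureTrace
from .phantom import PhantomConfig, PhantomTruth, ards_preset, make_phantom
from .regional import partition_rois
from .ventilator import (
    VentilatorProgram,
    baseline_program,
    incremental_peep_program,
    pcv_program,
    pressure_waveform,
    sustained_inflation_program,
    with_duration,
)

MANEUVERS = ("SI", "IP", "PCV")


def maneuver_program(name: str) -> VentilatorProgram:
    """The published protocol settings for one maneuver."""
    if name == "SI":
        return sustained_inflation_program()
    if name == "IP":
        return incremental_peep_program()
    if name == "PCV":
        return pcv_program()
    raise ConfigError(f"unknown maneuver {name!r}; expected one of {MANEUVERS}")


def _step_open_states(
    open_flat: np.ndarray,
    p: float,
    p_open: np.ndarray,
    p_close: np.ndarray,
    p_open_hazard: float,
    p_close_hazard: float,
    rng: np.random.Generator,
) -> None:
    """One hazard step, in place. Hazard probabilities are per-step."""
    closed = ~open_flat
    can_open = closed & (p > p_open)
    if can_open.any() and p_open_hazard > 0:
        u = rng.random(can_open.sum())
        idx = np.where(can_open)[0]
        open_flat[idx[u < p_open_hazard]] = True
    can_close = open_flat & (p < p_close)
    if can_close.any() and p_close_hazard > 0:
        u = rng.random(can_close.sum())
        idx = np.where(can_close)[0]
        open_flat[idx[u < p_close_hazard]] = False


def evolve_states(
    truth: PhantomTruth,
    trace: PressureTrace,
    rng: np.random.Generator,
) -> None:
    """Evolve open/closed states (and the lagged impedance) without frames.

    Used for the long unrecorded stretches of a protocol; the pressure
    trace may be sampled far below frame rate since only hazards and the
    slow lag matter.
    """
    cfg = truth.config
    dt = 1.0 / trace.sample_rate
    po = 1.0 - np.exp(-cfg.opening_rate * dt)
    pc = 1.0 - np.exp(-cfg.closing_rate * dt)
    lung = truth.lung
    p_open = truth.opening_pressure[lung]
    p_close = truth.closing_pressure[lung]
    open_flat = truth.open[lung]
    comp = truth.compliance[lung]
    z = truth.impedance[lung]
    alpha = 1.0 - np.exp(-dt / cfg.lag_tau)
    res = cfg.residual_fraction
    for p in trace.samples:
        _step_open_states(open_flat, p, p_open, p_close, po, pc, rng)
        target = comp * (p - cfg.pressure_ref) * np.where(open_flat, 1.0, res)
        z += alpha * (target - z)
    truth.open[lung] = open_flat
    truth.impedance[lung] = z


def _cardiac_patch(config: PhantomConfig) -> tuple[slice, slice]:
    """4x4 para-cardiac patch, mid-ventral and left of the midline."""
    r0 = int(round(config.grid_rows * 0.31))
    c0 = int(round(config.grid_cols * 0.38))
    return slice(r0, r0 + 4), slice(c0, c0 + 4)


def simulate_sequence(
    truth: PhantomTruth,
    trace: PressureTrace,
    config: PhantomConfig | None = None,
    rng: np.random.Generator | None = None,
    subject_id: str = "",
    recording_label: str = "",
    record_states: bool = False,
) -> FrameSequence:
    """Render an EIT frame sequence while evolving the phantom state.

    Frames are produced at the pressure trace's sample rate. The truth
    object is updated in place: final open states and lagged impedance,
    ``roi_open_fraction`` (per-frame open fraction in each ventral->dorsal
    quarter), and, if ``record_states``, the full binary state history.
    Deterministic given the generator's state.
    """
    config = config or truth.config
    if trace.n_samples == 0:
        raise ConfigError("pressure trace is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    rows, cols = truth.lung.shape
    n = trace.n_samples
    dt = 1.0 / trace.sample_rate
    lung = truth.lung
    lung_idx = np.where(lung.ravel())[0]
    comp = truth.compliance[lung]
    p_open = truth.opening_pressure[lung]
    p_close = truth.closing_pressure[lung]
    open_flat = truth.open[lung].copy()
    z = truth.impedance[lung].copy()

    part = partition_rois(rows, cols)
    roi_of_pixel = np.empty(lung_idx.size, dtype=int)
    lung_rows = lung_idx // cols
    for i, band in enumerate(part.row_slices):
        roi_of_pixel[(lung_rows >= band.start) & (lung_rows < band.stop)] = i
    roi_counts = np.bincount(roi_of_pixel, minlength=4).astype(float)
    roi_counts[roi_counts == 0] = np.nan

    alpha = 1.0 - np.exp(-dt / config.lag_tau)
    res = config.residual_fraction
    p_eff = trace.samples - config.pressure_ref

    signals = np.empty((n, lung_idx.size))
    roi_open = np.empty((n, 4))
    states = np.empty((n, lung_idx.size), dtype=bool) if record_states else None

    frozen = config.opening_rate == 0 and config.closing_rate == 0
    if frozen:
        # no state transitions: the lag is a linear filter, apply it in one go
        cvec = comp * np.where(open_flat, 1.0, res)
        target = p_eff[:, None] * cvec[None, :]
        zi = (1.0 - alpha) * z[None, :]
        signals, zf = lfilter([alpha], [1.0, -(1.0 - alpha)], target, axis=0, zi=zi)
        z = zf[0]
        frac = np.bincount(roi_of_pixel, weights=open_flat, minlength=4) / roi_counts
        roi_open[:] = frac[None, :]
        if record_states:
            states[:] = open_flat[None, :]
    else:
        po = 1.0 - np.exp(-config.opening_rate * dt)
        pc = 1.0 - np.exp(-config.closing_rate * dt)
        for t in range(n):
            _step_open_states(open_flat, trace.samples[t], p_open, p_close, po, pc, rng)
            target = comp * p_eff[t] * np.where(open_flat, 1.0, res)
            z += alpha * (target - z)
            signals[t] = z
            roi_open[t] = np.bincount(roi_of_pixel, weights=open_flat, minlength=4) / roi_counts
            if record_states:
                states[t] = open_flat

    frames = np.zeros((n, rows * cols))
    frames[:, lung_idx] = signals
    frames = frames.reshape(n, rows, cols)
    if config.psf_sigma_px > 0:
        # reconstruction point-spread: EIT images are spatially blurred,
        # so pixels straddling an open/closed boundary report
        # intermediate tidal amplitudes
        from scipy.ndimage import gaussian_filter

        frames = gaussian_filter(frames, (0.0, config.psf_sigma_px, config.psf_sigma_px))
    if config.noise_sd > 0:
        frames += rng.normal(0.0, config.noise_sd, size=frames.shape)
    if config.cardiac_amplitude > 0:
        rs, cs = _cardiac_patch(config)
        t_s = np.arange(n) * dt
        beat = config.cardiac_amplitude * np.sin(2 * np.pi * config.cardiac_rate / 60.0 * t_s)
        frames[:, rs, cs] += beat[:, None, None]

    truth.open[lung] = open_flat
    truth.impedance[lung] = z
    truth.roi_open_fraction = roi_open
    if record_states:
        truth.open_states = states

    return FrameSequence(
        frames=frames,
        frame_rate=trace.sample_rate,
        subject_id=subject_id,
        recording_label=recording_label,
    )


@dataclass
class Recording:
    """One labelled EIT recording of a simulated study, with its truth."""

    subject_id: str
    maneuver: str
    phase: str  # "pre" or "post"
    sequence: FrameSequence
    trace: PressureTrace
    driving_pressure_setting: float
    roi_open_fraction: np.ndarray
    open_fraction_start: float
    open_fraction_end: float


def maneuver_order(rng: np.random.Generator) -> list[str]:
    """Random maneuver order for one subject (random-number-table draw)."""
    return [MANEUVERS[i] for i in rng.permutation(3)]


def simulate_cohort(
    n_subjects: int = 10,
    seed: int = 0,
    config: PhantomConfig | None = None,
    protocol_order: list[str] | None = None,
    frame_rate: float = 40.0,
    recording_duration: float = 180.0,
    equilibration_duration: float = 1800.0,
    washout_duration: float = 1800.0,
    state_rate: float = 10.0,
    baseline_driving_pressure: float = 15.0,
    baseline_peep: float = 5.0,
):
    """Simulate a recruitment-maneuver study; yields :class:`Recording`.

    Each subject receives its own phantom draw, is stabilized under the
    baseline program, then undergoes the three maneuvers in a seeded
    random order (or a fixed ``protocol_order``), with an EIT recording
    before and after each maneuver and a derecruiting washout at PEEP 5
    in between. ``n_subjects`` subjects yield ``6 * n_subjects``
    recordings, in time order per subject. Deterministic given ``seed``.
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    if protocol_order is not None and sorted(protocol_order) != sorted(MANEUVERS):
        raise ConfigError(f"protocol_order must be a permutation of {MANEUVERS}")
    config = config or ards_preset()
    children = np.random.SeedSequence(seed).spawn(n_subjects)

    base = baseline_program(
        peep=baseline_peep,
        driving_pressure=baseline_driving_pressure,
        duration=recording_duration,
    )

    for s in range(n_subjects):
        rng = np.random.default_rng(children[s])
        subject_id = f"pig{s + 1:02d}"
        truth = make_phantom(config, rng)
        order = list(protocol_order) if protocol_order else maneuver_order(rng)

        # stabilization before the first pre-maneuver recording
        evolve_states(
            truth,
            pressure_waveform(with_duration(base, equilibration_duration), state_rate),
            rng,
        )

        for m_i, name in enumerate(order):
            for phase in ("pre", "post"):
                if phase == "post":
                    evolve_states(
                        truth, pressure_waveform(maneuver_program(name), state_rate), rng
                    )
                trace = pressure_waveform(base, frame_rate)
                f0 = truth.open_fraction()
                seq = simulate_sequence(
                    truth,
                    trace,
                    config,
                    rng,
                    subject_id=subject_id,
                    recording_label=f"{name}_{phase}",
                )
                yield Recording(
                    subject_id=subject_id,
                    maneuver=name,
                    phase=phase,
                    sequence=seq,
                    trace=trace,
                    driving_pressure_setting=baseline_driving_pressure,
                    roi_open_fraction=truth.roi_open_fraction,
                    open_fraction_start=f0,
                    open_fraction_end=truth.open_fraction(),
                )
            if m_i < len(order) - 1:
                evolve_states(
                    truth,
                    pressure_waveform(with_duration(base, washout_duration), state_rate),
                    rng,
                )
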