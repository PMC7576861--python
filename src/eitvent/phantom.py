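"""Synthetic supine-pig lung phantom with gravity-graded collapse.

The phantom is a 32x32 pixel grid (the image size of 16-electrode EIT
systems) holding two elliptical lung fields. Each lung pixel is a lung
unit with

* a baseline compliance (au/cmH2O), log-normally distributed across
  pixels — ventilation is spatially heterogeneous even in a healthy lung;
* an opening pressure drawn around a ventral->dorsal *collapse gradient*,
  modelling the gravitationally dependent exudative collapse of lavage
  ARDS (dependent units need higher pressure to reopen);
* a closing pressure a fixed offset below its opening pressure, giving
  the opening/closing hysteresis that recruitment maneuvers exploit.

Units open and close stochastically: while airway pressure exceeds a
closed unit's opening pressure it opens with a constant hazard, and while
pressure is below an open unit's closing pressure it closes with a
(much smaller) hazard. Collapse is therefore a question of *pressure
exposure time*, which is what distinguishes a 40 s sustained inflation
from a 450 s PEEP staircase reaching the same maximum pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .core import ConfigError

#: (row_center, col_center, row_radius, col_radius) in pixel units
Ellipse = tuple[float, float, float, float]

GradientSpec = "tuple[float, float] | Callable[[np.ndarray], np.ndarray]"


def default_lung_geometry(rows: int = 32, cols: int = 32) -> list[Ellipse]:
    """Two elliptical lung fields scaled to the grid."""
    rc = (rows - 1) / 2.0
    return [
        (rc, cols * 0.30, rows * 0.33, cols * 0.17),
        (rc, cols * 0.70, rows * 0.33, cols * 0.17),
    ]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic thorax.

    ``collapse_gradient`` maps normalized dorsal depth d in [0, 1]
    (0 = ventral-most lung row, 1 = dorsal-most) to the *mean* opening
    pressure in cmH2O; it is given either as a ``(ventral, dorsal)`` pair
    interpolated linearly or as a vectorized callable. Individual pixels
    scatter around that mean with SD ``opening_pressure_sd``.

    ``baseline_compliance_median`` / ``compliance_sigma_log`` set the
    log-normal pixel compliance distribution (au/cmH2O). ``ml_per_au``
    converts summed impedance change to millilitres; the default makes a
    fully open phantom deliver ~6 mL/kg for a 50 kg pig at the baseline
    driving pressure of 15 cmH2O.
    """

    grid_rows: int = 32
    grid_cols: int = 32
    lung_geometry: Sequence[Ellipse] | None = None
    collapse_gradient: "tuple[float, float] | Callable" = (-10.0, -10.0)
    opening_pressure_sd: float = 0.0
    closing_offset: float = 10.0
    opening_rate: float = 0.04
    closing_rate: float = 0.002
    baseline_compliance_median: float = 0.07
    compliance_sigma_log: float = 0.55
    compliance_clip: float = 4.0
    compliance_corr_px: float = 0.0
    psf_sigma_px: float = 0.0
    residual_fraction: float = 0.02
    lag_tau: float = 0.08
    pressure_ref: float = 0.0
    noise_sd: float = 0.05
    cardiac_amplitude: float = 0.0
    cardiac_rate: float = 90.0
    ml_per_au: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ConfigError(
                f"grid must be at least 8x8, got {self.grid_rows}x{self.grid_cols}"
            )
        for name in (
            "opening_pressure_sd",
            "closing_offset",
            "opening_rate",
            "closing_rate",
            "residual_fraction",
            "noise_sd",
            "cardiac_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not self.closing_offset > 0:
            raise ConfigError("closing_offset must be > 0 so opening > closing pressure")
        if not self.baseline_compliance_median > 0:
            raise ConfigError("baseline_compliance_median must be > 0")
        if not self.compliance_clip > 1:
            raise ConfigError("compliance_clip must exceed 1 (it multiplies the median)")
        if self.compliance_corr_px < 0 or self.psf_sigma_px < 0:
            raise ConfigError("compliance_corr_px and psf_sigma_px must be >= 0")
        if not self.lag_tau > 0:
            raise ConfigError("lag_tau must be > 0")

    def geometry(self) -> list[Ellipse]:
        if self.lung_geometry is None:
            return default_lung_geometry(self.grid_rows, self.grid_cols)
        return list(self.lung_geometry)

    def gradient_fn(self) -> Callable[[np.ndarray], np.ndarray]:
        g = self.collapse_gradient
        if callable(g):
            return lambda d: np.asarray(g(d), dtype=float)
        ventral, dorsal = g
        return lambda d: ventral + (dorsal - ventral) * np.asarray(d, dtype=float)


def ards_preset(**overrides) -> PhantomConfig:
    """Lavage-ARDS phantom: dorsal collapse gradient 10 -> 35 cmH2O, SD 5.

    Calibrated so that under baseline ventilation (PEEP 5, driving
    pressure 15) the dorsal half is largely derecruited, pre-maneuver GI
    exceeds 0.45, all three maneuvers recruit dependent lung, and the
    slow opening hazard leaves the 40 s sustained inflation measurably
    less complete than the 450 s PEEP staircase reaching the same
    maximum pressure (the exposure-time mechanism separating the
    maneuvers' effect on homogeneity).
    """
    base = dict(
        collapse_gradient=(10.0, 35.0),
        opening_pressure_sd=5.0,
        closing_offset=10.0,
        opening_rate=0.025,
        closing_rate=0.0015,
        compliance_sigma_log=0.7,
        compliance_corr_px=2.0,
        psf_sigma_px=2.5,
    )
    base.update(overrides)
    return PhantomConfig(**base)


def healthy_preset(**overrides) -> PhantomConfig:
    """Healthy lung: opening pressures far below any ventilation pressure."""
    base = dict(
        collapse_gradient=(-10.0, -10.0),
        opening_pressure_sd=0.0,
        compliance_sigma_log=0.7,
        compliance_corr_px=2.0,
        psf_sigma_px=2.5,
    )
    base.update(overrides)
    return PhantomConfig(**base)


@dataclass
class PhantomTruth:
    """Simulator ground truth.

    Static per-pixel maps (compliance, opening/closing pressure, lung
    membership) plus the mutable open/closed state the simulation engine
    evolves. ``roi_open_fraction`` holds the open fraction per
    ventral->dorsal quarter sampled at frame rate for the most recent
    simulated segment; ``open_states`` optionally holds the full binary
    state history of that segment.
    """

    config: PhantomConfig
    lung: np.ndarray
    compliance: np.ndarray
    opening_pressure: np.ndarray
    closing_pressure: np.ndarray
    open: np.ndarray
    impedance: np.ndarray = field(default=None)  # per-pixel lagged state, au
    roi_open_fraction: np.ndarray | None = None
    open_states: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.impedance is None:
            self.impedance = np.zeros_like(self.compliance)

    @property
    def n_lung_pixels(self) -> int:
        return int(self.lung.sum())

    def open_fraction(self, rows: slice | None = None) -> float:
        """Fraction of lung pixels currently open, optionally row-restricted."""
        lung = self.lung if rows is None else self.lung[rows]
        opn = self.open if rows is None else self.open[rows]
        n = lung.sum()
        return float(opn[lung].sum() / n) if n else float("nan")

    def copy(self) -> "PhantomTruth":
        return PhantomTruth(
            config=self.config,
            lung=self.lung.copy(),
            compliance=self.compliance.copy(),
            opening_pressure=self.opening_pressure.copy(),
            closing_pressure=self.closing_pressure.copy(),
            open=self.open.copy(),
            impedance=self.impedance.copy(),
        )


def make_phantom(config: PhantomConfig, rng: np.random.Generator | None = None) -> PhantomTruth:
    """Draw a phantom from its configuration.

    Deterministic given ``config.seed`` (or an explicit generator). All
    lung pixels start open; callers equilibrate the state under the
    pre-maneuver ventilator program before recording, mirroring the
    stabilization period of an animal protocol.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    rows, cols = config.grid_rows, config.grid_cols
    rr, cc = np.mgrid[0:rows, 0:cols]
    lung = np.zeros((rows, cols), dtype=bool)
    for r0, c0, rrad, crad in config.geometry():
        lung |= ((rr - r0) / rrad) ** 2 + ((cc - c0) / crad) ** 2 <= 1.0
    if not lung.any():
        raise ConfigError("lung geometry covers no pixels")

    compliance = np.zeros((rows, cols))
    n = int(lung.sum())
    # log-normal spread with a physical ceiling: no lung unit is more
    # than compliance_clip times as compliant as the typical one. A
    # positive correlation length makes the log-field spatially smooth
    # (regional ventilation varies on a scale of a few pixels, not
    # pixel-by-pixel salt and pepper).
    log_field = rng.standard_normal((rows, cols))
    if config.compliance_corr_px > 0:
        from scipy.ndimage import gaussian_filter

        log_field = gaussian_filter(log_field, config.compliance_corr_px, mode="nearest")
        sd = log_field[lung].std()
        if sd > 0:
            log_field = (log_field - log_field[lung].mean()) / sd
    compliance[lung] = np.minimum(
        config.baseline_compliance_median
        * np.exp(config.compliance_sigma_log * log_field[lung]),
        config.compliance_clip * config.baseline_compliance_median,
    )

    # normalized dorsal depth of each lung row, 0 at the ventral-most
    # lung pixel, 1 at the dorsal-most (row 0 is ventral)
    lung_rows = np.where(lung.any(axis=1))[0]
    top, bottom = lung_rows.min(), lung_rows.max()
    depth = np.clip((rr - top) / max(bottom - top, 1), 0.0, 1.0)

    opening = np.full((rows, cols), -np.inf)
    opening[lung] = config.gradient_fn()(depth[lung]) + config.opening_pressure_sd * (
        rng.standard_normal(n)
    )
    closing = opening - config.closing_offset

    return PhantomTruth(
        config=config,
        lung=lung,
        compliance=compliance,
        opening_pressure=opening,
        closing_pressure=closing,
        open=lung.copy(),
    )
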