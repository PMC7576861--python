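"""Core containers shared across the pipeline.

All images follow one fixed convention: row 0 is ventral (non-dependent),
the last row is dorsal (gravity-dependent, in a supine subject), pixels are
stored row-major with 0-based indices. Every consumer in this package
assumes that orientation; flipping it silently is the single worst bug an
EIT pipeline can have, so it is carried as explicit metadata and checked
at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: the only orientation this package produces or accepts
ROW0_VENTRAL = "row0_ventral"


class EitError(Exception):
    """Base class for errors raised by this package."""


class ConfigError(EitError):
    """Invalid configuration (simulator or analysis parameters)."""


class ValidationError(EitError):
    """Data that violates a container invariant or a bundle schema."""


class UndefinedComplianceError(EitError):
    """Compliance requested with a non-positive driving pressure."""


@dataclass
class FrameSequence:
    """Time-ordered stack of 2-D relative-impedance images.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)``; relative impedance in
        arbitrary units (au).
    frame_rate
        Acquisition rate in Hz.
    orientation
        Must be :data:`ROW0_VENTRAL`.
    subject_id, recording_label
        Free-text provenance carried through to results tables.
    """

    frames: np.ndarray
    frame_rate: float
    orientation: str = ROW0_VENTRAL
    subject_id: str = ""
    recording_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValidationError(
                f"frames must be 3-D (n_frames, rows, cols), got ndim={self.frames.ndim}"
            )
        if self.frames.shape[0] == 0:
            raise ValidationError("frame sequence is empty")
        if not np.isfinite(self.frames).all():
            raise ValidationError("frames contain non-finite values")
        if not self.frame_rate > 0:
            raise ValidationError(f"frame_rate must be > 0, got {self.frame_rate}")
        if self.orientation != ROW0_VENTRAL:
            raise ValidationError(
                f"unsupported orientation {self.orientation!r}; expected {ROW0_VENTRAL!r}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of a single image."""
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames / self.frame_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class PressureTrace:
    """Airway pressure samples time-aligned to an EIT frame sequence.

    ``alignment`` is the sample index that coincides with frame 0; frames
    and pressure may run at different rates.
    """

    samples: np.ndarray
    sample_rate: float
    alignment: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not self.sample_rate > 0:
            raise ValidationError(f"sample_rate must be > 0, got {self.sample_rate}")
        if not np.isfinite(self.samples).all():
            raise ValidationError("pressure trace contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        return (np.arange(self.n_samples) - self.alignment) / self.sample_rate

    def sample_index_for_frame(self, frame_index: int, frame_rate: float) -> int:
        """Pressure sample coinciding with a given frame."""
        return self.alignment + int(round(frame_index * self.sample_rate / frame_rate))


@dataclass
class BreathCycle:
    """One complete breath: end-expiration, end-inspiration, next end-expiration."""

    end_expiration_index: int
    end_inspiration_index: int
    next_end_expiration_index: int

    def __post_init__(self) -> None:
        if not (
            self.end_expiration_index
            < self.end_inspiration_index
            < self.next_end_expiration_index
        ):
            raise ValidationError(
                "breath indices must satisfy end_exp < end_insp < next_end_exp, got "
                f"({self.end_expiration_index}, {self.end_inspiration_index}, "
                f"{self.next_end_expiration_index})"
            )


@dataclass
class TidalImage:
    """Per-breath map of end-inspiratory minus end-expiratory impedance (DI_xy)."""

    di: np.ndarray
    breath: BreathCycle | None = None
    lung_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.di = np.asarray(self.di, dtype=float)
        if self.di.ndim != 2:
            raise ValidationError("tidal image must be 2-D")
        if self.lung_mask is not None:
            self.lung_mask = np.asarray(self.lung_mask, dtype=bool)
            if self.lung_mask.shape != self.di.shape:
                raise ValidationError("lung mask shape differs from tidal image shape")
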