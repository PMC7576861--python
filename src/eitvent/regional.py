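"""EIT-derived ventilation quantities.

Everything a recruitment-maneuver analysis reports per recording:

* ``delta_z_roi`` — summed tidal impedance change per ROI, where the
  image is divided into four equal ventral->dorsal row bands (ROI1-2
  non-dependent, ROI3-4 gravity-dependent in a supine subject);
* ``regional_compliance`` — ΔZ_ROI divided by the no-flow driving
  pressure, in au/cmH2O;
* ``gi_index`` — the global inhomogeneity index: the sum of absolute
  deviations of tidal-image pixels from their median, normalized by the
  pixel sum. 0 means perfectly homogeneous tidal ventilation; ~0.4 is
  typical for healthy anesthetized lungs and values rise with collapse;
* ``delta_gi`` — GI before minus GI after a maneuver (positive =
  improved homogeneity);
* ``eeli`` — end-expiratory lung impedance, the pixel sum at
  end-expiration, tracking end-expiratory lung volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    BreathCycle,
    FrameSequence,
    PressureTrace,
    TidalImage,
    UndefinedComplianceError,
    ValidationError,
)

ROI_NAMES = ("ROI1", "ROI2", "ROI3", "ROI4")


@dataclass(frozen=True)
class RoiPartition:
    """Four contiguous, disjoint row bands covering the image, ordered
    ventral (ROI1) to dorsal (ROI4)."""

    row_slices: tuple[slice, slice, slice, slice]

    @property
    def heights(self) -> tuple[int, ...]:
        return tuple(s.stop - s.start for s in self.row_slices)

    def band_of_row(self, row: int) -> int:
        for i, s in enumerate(self.row_slices):
            if s.start <= row < s.stop:
                return i
        raise ValidationError(f"row {row} outside partition")


def partition_rois(rows: int, cols: int) -> RoiPartition:
    """Split ``rows`` image rows into four equal ventral->dorsal bands.

    When ``rows`` is not divisible by 4 the remainder rows go to the
    ventral-most bands first, e.g. 10 rows -> heights (3, 3, 2, 2).
    """
    if rows < 4:
        raise ValidationError(f"need at least 4 rows to build 4 ROIs, got {rows}")
    if cols < 1:
        raise ValidationError("need at least 1 column")
    base, rem = divmod(rows, 4)
    heights = [base + (1 if i < rem else 0) for i in range(4)]
    edges = np.cumsum([0] + heights)
    return RoiPartition(
        row_slices=tuple(slice(int(edges[i]), int(edges[i + 1])) for i in range(4))
    )


def delta_z_roi(ti: TidalImage, part: RoiPartition) -> np.ndarray:
    """Summed tidal impedance change per ROI (ΔZ_ROI), in au.

    Sums over the full row band — the ROIs are fixed image quarters, not
    mask-restricted regions — so the four values always add up to the
    global tidal impedance change.
    """
    di = ti.di
    if part.row_slices[-1].stop != di.shape[0]:
        raise ValidationError(
            f"partition covers {part.row_slices[-1].stop} rows but image has {di.shape[0]}"
        )
    return np.array([di[s].sum() for s in part.row_slices])


def driving_pressure(
    trace: PressureTrace,
    breath: BreathCycle,
    frame_rate: float,
    window_s: float = 0.05,
) -> float:
    """No-flow driving pressure of one breath, in cmH2O.

    Airway pressure at end-inspiration minus at end-expiration, each
    taken as the median over a +/-``window_s`` window around the
    corresponding frame's time (robust to the release transient right
    after an end-inspiratory hold).
    """
    half = int(round(window_s * trace.sample_rate))

    def median_at(frame_index: int) -> float:
        center = trace.sample_index_for_frame(frame_index, frame_rate)
        lo, hi = center - half, center + half + 1
        if lo < 0 or hi > trace.n_samples:
            raise ValidationError(
                f"pressure window [{lo}, {hi}) outside trace of {trace.n_samples} samples"
            )
        return float(np.median(trace.samples[lo:hi]))

    return median_at(breath.end_inspiration_index) - median_at(breath.end_expiration_index)


def regional_compliance(delta_z: float | np.ndarray, dp: float):
    """EIT-estimated compliance ΔZ_ROI / driving pressure, au/cmH2O."""
    if not dp > 0:
        raise UndefinedComplianceError(
            f"compliance undefined for driving pressure {dp} cmH2O (must be > 0)"
        )
    return np.asarray(delta_z, dtype=float) / dp


def gi_index(ti: TidalImage, pixels: str = "mask") -> float:
    """Global inhomogeneity index of one tidal image.

    GI = sum(|DI_xy - median(DI)|) / sum(DI_xy), both taken over the
    evaluation pixel set. ``pixels="mask"`` (default) evaluates over the
    tidal image's functional lung mask, the convention of the GI method
    this index comes from; ``pixels="all"`` uses every image pixel for
    sensitivity analysis. The median of an even-sized set is the mean of
    the two middle values.
    """
    if pixels == "mask":
        if ti.lung_mask is None or not ti.lung_mask.any():
            raise ValidationError("gi_index needs a nonempty lung mask (or pixels='all')")
        values = ti.di[ti.lung_mask]
    elif pixels == "all":
        values = ti.di.ravel()
    else:
        raise ValidationError(f"pixels must be 'mask' or 'all', got {pixels!r}")
    total = values.sum()
    if not total > 0:
        raise ValidationError(
            f"GI normalizer (pixel sum) must be positive, got {total}"
        )
    med = np.median(values)
    return float(np.abs(values - med).sum() / total)


def gi_summary(gis) -> float:
    """One GI per recording: arithmetic mean over its accepted breaths."""
    gis = np.asarray(gis, dtype=float)
    if gis.size == 0:
        raise ValidationError("gi_summary needs at least one per-breath GI")
    return float(gis.mean())


def delta_gi(pre: float, post: float) -> float:
    """GI before minus GI after a maneuver; positive = more homogeneous."""
    if not (np.isfinite(pre) and np.isfinite(post)):
        raise ValidationError("delta_gi needs finite GI values")
    return float(pre - post)


@dataclass(frozen=True)
class EeliResult:
    """End-expiratory lung impedance of one recording, in au.

    ``global_mean`` / ``roi_mean`` are means over breaths of the
    end-expiration frame's pixel sum; ``global_change`` / ``roi_change``
    are the same expressed relative to the recording's first
    end-expiration frame (the within-recording drift).
    """

    global_mean: float
    roi_mean: np.ndarray
    global_change: float
    roi_change: np.ndarray


def eeli(seq: FrameSequence, breaths: list[BreathCycle], part: RoiPartition) -> EeliResult:
    """End-expiratory lung impedance, global and per ROI."""
    if not breaths:
        raise ValidationError("eeli needs at least one breath")
    idx = [b.end_expiration_index for b in breaths]
    flats = seq.frames[idx]  # (n_breaths, rows, cols)
    roi_sums = np.stack([flats[:, s, :].sum(axis=(1, 2)) for s in part.row_slices], axis=1)
    roi_mean = roi_sums.mean(axis=0)
    roi_first = roi_sums[0]
    return EeliResult(
        global_mean=float(roi_mean.sum()),
        roi_mean=roi_mean,
        global_change=float(roi_mean.sum() - roi_first.sum()),
        roi_change=roi_mean - roi_first,
    )
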