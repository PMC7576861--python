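"""End-to-end analysis: recordings -> per-recording results -> study stats.

`analyze_recording` turns one EIT recording plus its pressure trace into
the quantities a recruitment-maneuver study reports (GI, ΔZ_ROI,
regional compliances, driving pressure, EELI). `run_study` simulates a
whole cohort and analyzes every recording on the fly, so frame stacks
never accumulate in memory; `study_statistics` applies the paired
before/after machinery to the resulting table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import breaths as br
from . import regional as rg
from . import stats as st
from .core import FrameSequence, PressureTrace, ValidationError
from .phantom import PhantomConfig, ards_preset
from .simulate import MANEUVERS, Recording, simulate_cohort


@dataclass
class RecordingResult:
    """Per-recording EIT quantities (one row of the study table)."""

    subject_id: str
    recording_label: str
    maneuver: str = ""
    phase: str = ""
    n_breaths: int = 0
    gi_per_breath: np.ndarray = field(default_factory=lambda: np.empty(0))
    gi_mean: float = float("nan")
    delta_z_roi: np.ndarray = field(default_factory=lambda: np.full(4, np.nan))
    regional_compliance: np.ndarray = field(default_factory=lambda: np.full(4, np.nan))
    driving_pressure: float = float("nan")
    global_compliance_ml: float = float("nan")
    eeli_global: float = float("nan")
    eeli_roi: np.ndarray = field(default_factory=lambda: np.full(4, np.nan))
    eeli_drift: float = float("nan")
    mask_area: int = 0
    open_fraction_end: float = float("nan")

    @property
    def dependent_compliance(self) -> float:
        """Summed compliance of the gravity-dependent half (ROI3 + ROI4)."""
        return float(self.regional_compliance[2] + self.regional_compliance[3])

    @property
    def nondependent_compliance(self) -> float:
        return float(self.regional_compliance[0] + self.regional_compliance[1])

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "recording_label": self.recording_label,
            "maneuver": self.maneuver,
            "phase": self.phase,
            "n_breaths": self.n_breaths,
            "gi_mean": self.gi_mean,
            "driving_pressure": self.driving_pressure,
            "global_compliance_ml": self.global_compliance_ml,
            "eeli_global": self.eeli_global,
            "eeli_drift": self.eeli_drift,
            "mask_area": self.mask_area,
            "open_fraction_end": self.open_fraction_end,
        }
        for i, name in enumerate(rg.ROI_NAMES):
            row[f"delta_z_{name}"] = float(self.delta_z_roi[i])
            row[f"compliance_{name}"] = float(self.regional_compliance[i])
            row[f"eeli_{name}"] = float(self.eeli_roi[i])
        return row


def analyze_recording(
    seq: FrameSequence,
    trace: PressureTrace,
    mask_threshold: float = 0.10,
    gi_pixels: str = "mask",
    ml_per_au: float | None = None,
    min_breath_s: float = 1.0,
) -> RecordingResult:
    """Compute every per-recording quantity from frames + pressure.

    The lung mask is built once from the recording's mean tidal image and
    reused for every breath. ΔZ_ROI and the driving pressure are averaged
    over breaths; regional compliance is their ratio. When ``ml_per_au``
    is given (the simulator's calibration scale), the global respiratory
    system compliance is reported in mL/cmH2O as
    ``ml_per_au * ΣΔZ / driving pressure``.
    """
    signal = br.global_signal(seq)
    cycles = br.detect_breaths(signal, seq.frame_rate, min_breath_s=min_breath_s)
    if not cycles:
        raise ValidationError(
            f"no breaths detected in recording {seq.recording_label!r}; cannot analyze"
        )
    mean_tidal = br.mean_tidal_image(seq, cycles)
    mask = br.lung_mask(mean_tidal, mask_threshold)
    part = rg.partition_rois(*seq.shape)

    gis, dzs, dps = [], [], []
    for cycle in cycles:
        ti = br.tidal_image(seq, cycle)
        ti.lung_mask = mask
        gis.append(rg.gi_index(ti, pixels=gi_pixels))
        dzs.append(rg.delta_z_roi(ti, part))
        dps.append(rg.driving_pressure(trace, cycle, seq.frame_rate))

    gis = np.asarray(gis)
    dz_mean = np.mean(dzs, axis=0)
    dp = float(np.median(dps))
    comp = rg.regional_compliance(dz_mean, dp)
    eeli_res = rg.eeli(seq, cycles, part)

    return RecordingResult(
        subject_id=seq.subject_id,
        recording_label=seq.recording_label,
        n_breaths=len(cycles),
        gi_per_breath=gis,
        gi_mean=rg.gi_summary(gis),
        delta_z_roi=dz_mean,
        regional_compliance=comp,
        driving_pressure=dp,
        global_compliance_ml=(
            float(ml_per_au * dz_mean.sum() / dp) if ml_per_au is not None else float("nan")
        ),
        eeli_global=eeli_res.global_mean,
        eeli_roi=eeli_res.roi_mean,
        eeli_drift=eeli_res.global_change,
        mask_area=int(mask.sum()),
    )


def analyze_cohort_recording(rec: Recording, config: PhantomConfig, **kwargs) -> RecordingResult:
    res = analyze_recording(
        rec.sequence, rec.trace, ml_per_au=config.ml_per_au, **kwargs
    )
    res.maneuver = rec.maneuver
    res.phase = rec.phase
    res.open_fraction_end = rec.open_fraction_end
    return res


@dataclass
class StudyResult:
    """All per-recording results of one simulated study."""

    results: list[RecordingResult]
    config: PhantomConfig
    seed: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.results])

    def paired(self, column: str, maneuver: str) -> st.PairedSample:
        """Pre/post values of one quantity for one maneuver, by subject."""
        t = self.table()
        t = t[t.maneuver == maneuver].pivot(
            index="subject_id", columns="phase", values=column
        )
        return st.PairedSample(
            subject_ids=tuple(t.index), before=t["pre"].to_numpy(), after=t["post"].to_numpy()
        )

    def delta_gi_table(self) -> pd.DataFrame:
        """Subject x maneuver ΔGI = GI(pre) - GI(post)."""
        t = self.table()
        out = {}
        for m in MANEUVERS:
            p = t[t.maneuver == m].pivot(index="subject_id", columns="phase", values="gi_mean")
            out[m] = p["pre"] - p["post"]
        return pd.DataFrame(out)


def run_study(
    n_subjects: int = 10,
    seed: int = 0,
    config: PhantomConfig | None = None,
    mask_threshold: float = 0.10,
    gi_pixels: str = "mask",
    **cohort_kwargs,
) -> StudyResult:
    """Simulate and analyze a full recruitment-maneuver study."""
    config = config or ards_preset()
    results = [
        analyze_cohort_recording(
            rec, config, mask_threshold=mask_threshold, gi_pixels=gi_pixels
        )
        for rec in simulate_cohort(n_subjects=n_subjects, seed=seed, config=config, **cohort_kwargs)
    ]
    return StudyResult(results=results, config=config, seed=seed)


def study_statistics(study: "StudyResult | pd.DataFrame") -> dict:
    """The paired before/after comparisons of a study.

    Accepts a :class:`StudyResult` or its bare results table (columns
    ``subject_id, maneuver, phase, gi_mean, compliance_ROI1..4,
    eeli_global``). Returns per-maneuver pre/post comparisons of GI,
    dependent- and non-dependent-half compliance, and global EELI
    (Bonferroni m = 3 across maneuvers per quantity), plus the pairwise
    ΔGI contrasts.
    """
    t = study.table() if isinstance(study, StudyResult) else study.copy()
    # compliance of the dependent (ROI3+4) and non-dependent (ROI1+2) halves
    t = t.assign(
        dependent_compliance=t.compliance_ROI3 + t.compliance_ROI4,
        nondependent_compliance=t.compliance_ROI1 + t.compliance_ROI2,
    )

    def paired(column: str, maneuver: str) -> st.PairedSample:
        p = t[t.maneuver == maneuver].pivot(
            index="subject_id", columns="phase", values=column
        )
        return st.PairedSample(
            subject_ids=tuple(p.index),
            before=p["pre"].to_numpy(),
            after=p["post"].to_numpy(),
        )

    out: dict = {"pre_post": {}, "delta_gi": None}
    for column in (
        "gi_mean",
        "eeli_global",
        "dependent_compliance",
        "nondependent_compliance",
    ):
        comps = {}
        for m in MANEUVERS:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                comps[m] = st.paired_compare(paired(column, m))
        for r, p_adj in zip(comps.values(), st.bonferroni([c.p_raw for c in comps.values()], 3)):
            r.p_adjusted = float(p_adj)
        out["pre_post"][column] = comps

    dgi = {}
    for m in MANEUVERS:
        p = t[t.maneuver == m].pivot(index="subject_id", columns="phase", values="gi_mean")
        dgi[m] = p["pre"] - p["post"]
    out["delta_gi"] = st.compare_maneuver_deltas(pd.DataFrame(dgi))
    return out


def study_report(table: pd.DataFrame) -> pd.DataFrame:
    """Flat Before/After/p report table for a study results table.

    One row per (quantity, maneuver) with the two arm summaries, the test
    used, raw and Bonferroni-adjusted p-values; plus one row per pairwise
    ΔGI contrast.
    """
    stats = study_statistics(table)
    rows = []
    for column, comps in stats["pre_post"].items():
        for m, r in comps.items():
            rows.append(
                {
                    "quantity": column,
                    "comparison": f"{m} pre vs post",
                    "before": r.summary_before,
                    "after": r.summary_after,
                    "method": r.method,
                    "n": r.n,
                    "p_raw": r.p_raw,
                    "p_adjusted": r.p_adjusted,
                }
            )
    for name, r in stats["delta_gi"].items():
        rows.append(
            {
                "quantity": "delta_gi",
                "comparison": name.replace("_vs_", " vs "),
                "before": r.summary_before,
                "after": r.summary_after,
                "method": r.method,
                "n": r.n,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
            }
        )
    return pd.DataFrame(rows)


def null_rejection_rate(
    n_replicates: int = 1000,
    n_subjects: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
    grid: int = 16,
    recording_duration: float = 10.0,
    frame_rate: float = 25.0,
) -> float:
    """Type-I error calibration of the pre/post GI comparison.

    Recruitment dynamics are frozen (zero opening and closing hazards) so
    that pre- and post-"maneuver" recordings differ only by sensor noise;
    the fraction of replicates in which the paired comparison rejects at
    ``alpha`` estimates the test's size and should sit near ``alpha``.
    Runs on a reduced phantom so a thousand replicates stay cheap.
    """
    from .simulate import simulate_sequence
    from .ventilator import baseline_program, pressure_waveform
    from .phantom import make_phantom

    config = ards_preset(
        grid_rows=grid, grid_cols=grid, opening_rate=0.0, closing_rate=0.0
    )
    program = baseline_program(duration=recording_duration)
    trace = pressure_waveform(program, frame_rate)
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    rejections = 0
    for child in children:
        rng = np.random.default_rng(child)
        pre_gi, post_gi, ids = [], [], []
        for s in range(n_subjects):
            truth = make_phantom(config, rng)
            gi_vals = []
            for _ in range(2):
                seq = simulate_sequence(truth, trace, config, rng)
                res = analyze_recording(seq, trace)
                gi_vals.append(res.gi_mean)
            pre_gi.append(gi_vals[0])
            post_gi.append(gi_vals[1])
            ids.append(s)
        sample = st.PairedSample(tuple(ids), np.asarray(pre_gi), np.asarray(post_gi))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = st.paired_compare(sample)
        if res.p_raw < alpha:
            rejections += 1
    return rejections / n_replicates
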