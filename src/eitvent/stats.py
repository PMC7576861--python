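"""Paired before/after comparisons with a normality gate.

The analysis of a small crossover study (n = 10 subjects): paired
differences are tested for normality (Shapiro-Wilk at alpha = 0.05);
normal data go to a paired t test and are summarized as mean +/- SD,
non-normal data go to an exact Wilcoxon signed-rank test and are
summarized as median [IQR]. Families of comparisons are Bonferroni
corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ValidationError

PAIRED_T = "paired_t"
WILCOXON = "wilcoxon_signed_rank"

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class PairedSample:
    """Before/after values aligned by subject."""

    subject_ids: tuple
    before: np.ndarray
    after: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "before", np.asarray(self.before, dtype=float))
        object.__setattr__(self, "after", np.asarray(self.after, dtype=float))
        if len(self.subject_ids) != self.before.size or self.before.size != self.after.size:
            raise ValidationError("subject_ids, before and after must have equal length")
        if self.before.size < 3:
            raise ValidationError(f"need n >= 3 paired observations, got {self.before.size}")

    @property
    def n(self) -> int:
        return self.before.size

    @property
    def differences(self) -> np.ndarray:
        return self.before - self.after


@dataclass
class ComparisonResult:
    method: str
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    n: int = 0
    effect: float = 0.0  # mean (t) or median (Wilcoxon) of before - after
    summary_before: str = ""
    summary_after: str = ""
    degenerate: bool = False
    extra: dict = field(default_factory=dict)


def choose_test(differences) -> str:
    """Normality gate on the paired differences.

    Shapiro-Wilk at alpha = 0.05: normal -> paired t, non-normal ->
    Wilcoxon signed-rank. Identical differences cannot be assessed for
    normality and fall through to the Wilcoxon path with a warning.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise ValidationError(f"need n >= 3 differences, got {d.size}")
    if np.ptp(d) == 0:
        warnings.warn(
            "all paired differences are identical; normality undefined, using Wilcoxon",
            stacklevel=2,
        )
        return WILCOXON
    _, p = sps.shapiro(d)
    return PAIRED_T if p >= SHAPIRO_ALPHA else WILCOXON


def _summaries(sample: PairedSample, method: str) -> tuple[str, str]:
    def mean_sd(x):
        return f"{x.mean():.3g} ± {x.std(ddof=1):.3g}"

    def med_iqr(x):
        q1, q2, q3 = np.percentile(x, [25, 50, 75])
        return f"{q2:.3g} [{q1:.3g}-{q3:.3g}]"

    f = mean_sd if method == PAIRED_T else med_iqr
    return f(sample.before), f(sample.after)


def paired_compare(sample: PairedSample, method: str | None = None) -> ComparisonResult:
    """Two-sided paired comparison of before vs after.

    ``method=None`` applies the normality gate. An all-zero difference
    vector is a degenerate null result (effect 0, p = 1); a *constant
    nonzero* difference under the paired t test is an error, since the t
    statistic's denominator is zero.
    """
    d = sample.differences
    if method is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            method = choose_test(d)
    if method not in (PAIRED_T, WILCOXON):
        raise ValidationError(f"unknown method {method!r}")

    before_s, after_s = _summaries(sample, method)
    if np.all(d == 0):
        warnings.warn("before and after are identical; degenerate comparison", stacklevel=2)
        return ComparisonResult(
            method=WILCOXON,
            statistic=float("nan"),
            p_raw=1.0,
            n=sample.n,
            effect=0.0,
            summary_before=before_s,
            summary_after=after_s,
            degenerate=True,
        )

    if method == PAIRED_T:
        if np.ptp(d) == 0:
            raise ValidationError(
                "paired t test undefined: differences have zero variance "
                f"(constant shift {d[0]:g})"
            )
        stat, p = sps.ttest_rel(sample.before, sample.after)
        effect = float(d.mean())
    else:
        # Pratt zero handling keeps tied before==after pairs in the ranking;
        # exact null distribution for the small n this design produces,
        # normal approximation above n = 25 or in the presence of zeros
        # (scipy's exact method does not admit them)
        how = "exact" if (sample.n <= 25 and not np.any(d == 0)) else "approx"
        stat, p = sps.wilcoxon(
            sample.before, sample.after, zero_method="pratt", method=how
        )
        effect = float(np.median(d))

    return ComparisonResult(
        method=method,
        statistic=float(stat),
        p_raw=float(p),
        n=sample.n,
        effect=effect,
        summary_before=before_s,
        summary_after=after_s,
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValidationError(f"m = {m} is smaller than the number of p-values ({p.size})")
    return np.minimum(1.0, p * m)


def compare_maneuver_deltas(dgi: pd.DataFrame, maneuvers=("SI", "IP", "PCV")) -> dict:
    """Pairwise paired comparisons of per-subject ΔGI between maneuvers.

    ``dgi`` is a subject x maneuver table. Returns the three contrasts
    (IP-vs-SI, IP-vs-PCV, SI-vs-PCV) Bonferroni-corrected with m = 3.
    """
    missing = dgi[list(maneuvers)].isna()
    if missing.any().any():
        bad = dgi.index[missing.any(axis=1)].tolist()
        raise ValidationError(f"ΔGI table has missing cells for subjects: {bad}")
    pairs = [("IP", "SI"), ("IP", "PCV"), ("SI", "PCV")]
    results = {}
    for a, b in pairs:
        sample = PairedSample(
            subject_ids=tuple(dgi.index),
            before=dgi[a].to_numpy(),
            after=dgi[b].to_numpy(),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results[f"{a}_vs_{b}"] = paired_compare(sample)
    adj = bonferroni([r.p_raw for r in results.values()], m=3)
    for r, p_adj in zip(results.values(), adj):
        r.p_adjusted = float(p_adj)
    return results
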