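# Methods

## The analysis pipeline

**Breath segmentation.** The global impedance curve (pixel sum per
frame) is low-passed at 2 Hz (4th-order zero-phase Butterworth) to
suppress the cardiac band (~1.5–2.5 Hz in pigs) before extremum
detection. Candidate maxima/minima at least 0.5 s apart are gated by
amplitude: a cycle counts only if its peak-to-trough excursion reaches
25 % of the median excursion (both defaults configurable). Because
smoothing skews extremum positions on asymmetric waveforms (slow
inspiratory ramp, sharp release), each accepted index is refined to the
raw-signal extremum within ±0.25 s. Only complete
end-expiration → end-inspiration → end-expiration triplets are
returned; an apneic or flat signal yields an empty list with a warning,
not an exception. On noiseless simulated ventilation the count equals
duration × RR/60 within ±2 (edge cycles).

**Tidal image and functional mask.** The tidal image of a breath is the
pixel-wise difference between its end-inspiratory and end-expiratory
frames. The lung mask — pixels whose *mean* tidal amplitude over the
recording reaches 10 % of the maximum pixel amplitude — is computed once
per recording and reused for every breath, so per-breath GI values are
comparable. The 10 % rule is the standard functional-lung-region
convention in the EIT literature; the threshold is exposed as a
parameter.

**GI index.** GI = Σ|DI − median(DI)| / ΣDI over the evaluation pixel
set. The median of an even-sized set is the midpoint of the two middle
values. By default both the median and the normalizer are taken over
the lung mask; `pixels="all"` switches to every image pixel for
sensitivity analysis, since published descriptions of the index are
ambiguous on this point. The implementation is checked against a
brute-force per-pixel loop oracle to 1e-12. The per-recording GI is the
arithmetic mean over accepted breaths.

**ROIs, compliance, EELI.** Four equal ventral→dorsal row bands cover
the image (remainder rows, when rows % 4 ≠ 0, go to the ventral-most
bands — deterministic and irrelevant at the default 32). ΔZ_ROI sums
the tidal image over the *full* band, not the mask, so the four values
conserve the global sum exactly; mask restriction is available as a
sensitivity option in principle but the fixed-quarter definition is the
default. Driving pressure is the airway pressure at end-inspiration
minus end-expiration, each a median over ±50 ms around the breath
landmark (robust to the release transient after an end-inspiratory
hold); regional compliance is mean ΔZ_ROI over breaths divided by the
median driving pressure, in au/cmH₂O. No au→mL conversion is applied to
regional values; the global respiratory-system compliance in mL/cmH₂O
uses the simulator's known volume scale (`ml_per_au`, default 0.7,
chosen so a fully open phantom delivers ≈ 6 mL/kg for a 50 kg pig at
the baseline driving pressure). EELI is the end-expiratory frame's
pixel sum, averaged over breaths, reported globally and per ROI, both
absolutely and relative to the recording's first end-expiration.

**Statistics.** Normality of the *paired differences* (not the raw
arms) is assessed with Shapiro–Wilk at α = 0.05: normal → paired t
(mean ± SD summaries), otherwise Wilcoxon signed-rank
(median [IQR]). The Wilcoxon uses Pratt zero handling (tied pairs stay
in the ranking) and the exact null distribution for n ≤ 25 without
zeros, the normal approximation otherwise — at n = 10 exactness
matters. Families of three maneuvers are Bonferroni corrected with
m = 3. Identical arms are a degenerate null result (effect 0, p = 1,
warning); a constant nonzero difference under the paired t is an error
because the statistic's denominator vanishes.

## The simulator

**Lung phantom.** Two elliptical lung fields on a 32×32 grid (the image
size of 16-electrode systems), row 0 ventral. Each lung pixel is a unit
with:

| parameter | default (ARDS preset) | meaning |
|---|---|---|
| compliance | log-normal, median 0.07 au/cmH₂O, σ(log) 0.7, capped at 4× median, spatially correlated (2 px) | regional ventilation heterogeneity |
| opening pressure | linear ventral→dorsal gradient 10→35 cmH₂O + N(0, 5²) | gravity-graded collapse of lavage ARDS |
| closing pressure | opening − 10 cmH₂O | opening/closing hysteresis |
| opening hazard | 0.025 s⁻¹ while P > opening pressure | recruitment is exposure-time dependent |
| closing hazard | 0.0015 s⁻¹ while P < closing pressure | slow derecruitment at low PEEP |
| residual signal | 2 % of the open signal | collapsed tissue is not impedance-silent |
| lag | first-order, τ = 0.08 s | regional filling dynamics |
| PSF blur | Gaussian, σ = 2.5 px | reconstruction point-spread of EIT images |
| noise | N(0, 0.05²) au per pixel per frame | sensor noise |
| cardiac artifact | off by default; sinusoid on a 4×4 para-cardiac patch | named confounder, testable without contaminating defaults |

The healthy preset differs only in its opening pressures (far below any
ventilation pressure, so nothing ever closes).

**Ventilator programs.** Pressures are ideal set-point waveforms:
baseline ventilation is a volume-control *proxy* (inspiratory ramp to
PEEP + 15 cmH₂O with a short end-inspiratory hold, I:E 1:2, RR 30 — the
simulator is pressure-driven, true flow control is out of scope); SI is
constant CPAP; IP is the up-down staircase with square inspiratory
cycles riding on each step, capped at the maneuver maximum; PCV is a
square wave with inspiratory fraction I/(I+E).

**Why the hazards are slow.** The opening hazard sets how much of the
openable lung each maneuver recruits: at 0.025 s⁻¹ the 40 s sustained
inflation opens ≈ 63 % of units whose opening pressure it exceeds,
while the 450 s staircase — which spends about seven times longer at
≥ 20 cmH₂O — approaches complete recruitment. This exposure-time
mechanism is what makes ΔGI(IP) exceed ΔGI(SI) on average, with PCV in
between. A much faster hazard would saturate all three maneuvers into
identical outcomes; a much faster closing hazard would erase IP's gains
during its mandated descending limb. The closing hazard (0.0015 s⁻¹)
derecruits ≈ 93 % of fragile units over a 30 min washout at PEEP 5
while losing only ~15 % of recruited lung during a 3 min post-maneuver
recording window.

**Why the PSF matters.** With binary open/closed units and a hard 10 %
mask threshold, fully collapsed pixels simply vanish from the
functional region, and GI would barely register collapse. Real EIT
images are heavily blurred by the reconstruction; after the Gaussian
PSF, pixels straddling the open/closed boundary report intermediate
tidal amplitudes, stay inside the mask, and raise GI — the actual
mechanism by which dependent collapse inflates the index in measured
images. The compliance field is spatially correlated for the same
reason: ventilation varies on a scale of a few pixels, not
pixel-by-pixel.

Preset values were calibrated, once, against three declared targets:
pre-maneuver GI > 0.45 under baseline ventilation of the ARDS phantom
(healthy reference ≈ 0.45), recruitment of dorsal lung by all three
maneuvers, and a mean ΔGI(IP) > ΔGI(SI). They are modelling choices,
not measurements.

**Study protocol.** `simulate_cohort` gives each subject a fresh
phantom, stabilizes it under baseline ventilation, then applies the
three maneuvers in a seeded random order with pre/post EIT recordings
and an inter-maneuver washout at PEEP 5. Outside recording windows only
the open/closed states (and the slow lag state) are evolved, at 10 Hz
instead of frame rate — no images are rendered — which makes it cheap
to simulate the full 30 min stabilization and washout periods rather
than compressing them. Everything is deterministic given the cohort
seed (per-subject generators are spawned from it).

**What the simulator does not model.** Gas exchange, hemodynamics and
blood chemistry; electrode-level forward/inverse reconstruction (frames
are synthesized in image space); airway resistance and true
flow-controlled ventilation; pendelluft or interdependence between
units; overdistention (open units remain linear at any pressure). Tests
passing on this generator therefore demonstrate that the *analysis*
recovers what the model encodes (recruitment direction, compliance
ratios, exposure-time effects), not that the model reproduces any
particular animal's physiology.

## Numerical and design choices

- One fixed orientation (row 0 = ventral) carried as metadata and
  enforced at the I/O boundary; bundles with any other orientation are
  rejected rather than flipped.
- Bundles are plain CSV/JSON; values written with 12 significant
  digits, round-tripping far below the 1e-9 tolerance the tests assert.
- The frozen-dynamics simulation path (both hazards zero) is a single
  vectorized linear filter; it matches the stepwise engine to 1e-9 and
  makes the 1000-replicate null calibration cheap.
- Degenerate inputs fail loudly: empty masks, non-positive GI
  normalizers, zero driving pressure (compliance undefined), breath
  indices outside the trace.
- Problem sizes in the test suite and acceptance script are scaled for
  a desk run: the cohort uses 60 s recording windows (30 breaths) with
  full-length maneuvers and state-only 30 min stabilization/washout;
  the null calibration uses a 16×16 phantom at 25 Hz. The GI, ROI and
  statistics layers are size-independent and tested exactly.

## Known limitations

- GI is computed globally only; per-ROI GI would be a trivial
  extension but is deliberately not reported.
- The ΔGI separation between maneuvers is a small effect (~0.01–0.02
  units at the default calibration) against per-subject simulation
  noise; single-study contrasts of ΔGI between maneuvers are therefore
  directional rather than reliably significant at n = 10.
- The mask threshold interacts with the compliance distribution's upper
  tail; the cap at 4× median keeps the 10 %-of-max rule meaningful.
- Pressure waveforms are ideal set-points; no circuit or airway
  resistance shaping beyond the pixel-level first-order lag.
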