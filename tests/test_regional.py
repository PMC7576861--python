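"""ROI partitioning, GI index, compliance and EELI.

The GI implementation is checked against an independent brute-force
oracle that walks pixels one by one and computes the median by explicit
sorting with the midpoint rule.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as hst

import eitvent as ev
from eitvent.core import (
    BreathCycle,
    TidalImage,
    UndefinedComplianceError,
    ValidationError,
)


def gi_loop_oracle(di, mask):
    """Naive per-pixel GI: |x - median| summed, over the pixel sum."""
    values = []
    for r in range(di.shape[0]):
        for c in range(di.shape[1]):
            if mask[r, c]:
                values.append(di[r, c])
    values.sort()
    n = len(values)
    if n % 2 == 1:
        med = values[n // 2]
    else:
        med = 0.5 * (values[n // 2 - 1] + values[n // 2])
    num = sum(abs(v - med) for v in values)
    den = sum(values)
    return num / den


def _ti(di, mask=None):
    di = np.asarray(di, dtype=float)
    if mask is None:
        mask = np.ones_like(di, dtype=bool)
    return TidalImage(di=di, lung_mask=np.asarray(mask, dtype=bool))


class TestPartition:
    def test_32_rows_split_8_8_8_8(self):
        assert ev.partition_rois(32, 32).heights == (8, 8, 8, 8)

    def test_4_rows_one_each(self):
        assert ev.partition_rois(4, 4).heights == (1, 1, 1, 1)

    def test_remainder_rows_go_ventral_first(self):
        assert ev.partition_rois(10, 10).heights == (3, 3, 2, 2)
        assert ev.partition_rois(9, 10).heights == (3, 2, 2, 2)

    def test_bands_are_contiguous_and_cover_all_rows(self):
        part = ev.partition_rois(13, 5)
        rows = [r for s in part.row_slices for r in range(s.start, s.stop)]
        assert rows == list(range(13))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError):
            ev.partition_rois(3, 10)


class TestDeltaZ:
    def test_uniform_image_splits_equally(self):
        part = ev.partition_rois(32, 32)
        dz = ev.delta_z_roi(_ti(np.ones((32, 32))), part)
        np.testing.assert_array_equal(dz, [256.0, 256.0, 256.0, 256.0])

    def test_signal_in_top_row_stays_in_roi1(self):
        di = np.zeros((32, 32))
        di[0] = 3.0
        dz = ev.delta_z_roi(_ti(di), ev.partition_rois(32, 32))
        np.testing.assert_array_equal(dz, [96.0, 0.0, 0.0, 0.0])

    def test_partition_conserves_global_sum(self, rng):
        part = ev.partition_rois(32, 32)
        for _ in range(100):
            di = rng.normal(size=(32, 32))
            dz = ev.delta_z_roi(_ti(di), part)
            assert dz.sum() == pytest.approx(di.sum(), abs=1e-9)


class TestDrivingPressure:
    def test_pcv_square_wave_gives_peak_minus_peep(self):
        trace = ev.pressure_waveform(ev.pcv_program(duration=10.0), 40.0)
        # end-insp frame mid-plateau (t=0.4 s), end-exp mid-expiration
        dp = ev.driving_pressure(trace, BreathCycle(60, 96, 140), 40.0)
        assert dp == pytest.approx(20.0, abs=1e-9)

    def test_constant_pressure_gives_zero_and_undefined_compliance(self):
        trace = ev.PressureTrace(samples=np.full(200, 12.0), sample_rate=40.0)
        dp = ev.driving_pressure(trace, BreathCycle(20, 60, 100), 40.0)
        assert dp == 0.0
        with pytest.raises(UndefinedComplianceError):
            ev.regional_compliance(5.0, dp)

    def test_recovers_configured_baseline_driving_pressure(self, quiet_short_recording):
        cfg, truth, trace, seq = quiet_short_recording
        cycles = ev.detect_breaths(ev.global_signal(seq), seq.frame_rate)
        dps = [ev.driving_pressure(trace, c, seq.frame_rate) for c in cycles]
        assert np.median(dps) == pytest.approx(15.0, abs=0.1)

    def test_window_outside_trace_rejected(self):
        trace = ev.PressureTrace(samples=np.ones(50), sample_rate=40.0)
        with pytest.raises(ValidationError, match="outside"):
            ev.driving_pressure(trace, BreathCycle(0, 49, 50), 40.0)


class TestRegionalCompliance:
    def test_ratio(self):
        assert ev.regional_compliance(10.0, 10.0) == pytest.approx(1.0)
        assert ev.regional_compliance(0.0, 8.0) == 0.0

    def test_negative_dp_rejected(self):
        with pytest.raises(UndefinedComplianceError):
            ev.regional_compliance(1.0, -3.0)


class TestGiIndex:
    def test_uniform_mask_is_perfectly_homogeneous(self):
        assert ev.gi_index(_ti(np.full((6, 6), 3.3))) == 0.0

    def test_worked_example_1_1_1_5(self):
        """{1,1,1,5}: median 1, sum of deviations 4, total 8 -> GI 0.5."""
        di = np.array([[1.0, 1.0], [1.0, 5.0]])
        ti = _ti(di)
        assert ev.gi_index(ti) == pytest.approx(0.5)
        assert gi_loop_oracle(di, ti.lung_mask) == pytest.approx(0.5)

    @given(hst.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, c):
        di = np.abs(np.random.default_rng(3).normal(size=(8, 8))) + 0.1
        assert ev.gi_index(_ti(c * di)) == pytest.approx(ev.gi_index(_ti(di)), rel=1e-9)

    def test_matches_loop_oracle_on_random_masked_images(self, rng):
        for _ in range(100):
            di = rng.gamma(2.0, 1.0, size=(16, 16))
            mask = rng.random((16, 16)) < 0.6
            if mask.sum() < 2:
                continue
            assert ev.gi_index(_ti(di, mask)) == pytest.approx(
                gi_loop_oracle(di, mask), abs=1e-12
            )

    def test_gi_rises_with_collapsed_fraction(self):
        """Replacing a growing fraction of a uniform lung with the 2%
        residual level makes GI strictly increase."""
        n = 200
        last = -1.0
        for f in (0.1, 0.2, 0.3, 0.4, 0.5):
            values = np.ones(n)
            values[: int(f * n)] = 0.02
            gi = ev.gi_index(_ti(values.reshape(10, 20)))
            assert gi > last
            last = gi

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError, match="mask"):
            ev.gi_index(TidalImage(di=np.ones((4, 4)), lung_mask=np.zeros((4, 4), bool)))

    def test_nonpositive_normalizer_rejected(self):
        with pytest.raises(ValidationError, match="normalizer"):
            ev.gi_index(_ti(np.full((4, 4), -1.0)))

    def test_all_pixel_variant(self):
        di = np.abs(np.random.default_rng(8).normal(size=(8, 8))) + 0.1
        mask = np.zeros((8, 8), bool)
        mask[:4] = True
        ti = _ti(di, mask)
        assert ev.gi_index(ti, pixels="all") == pytest.approx(
            gi_loop_oracle(di, np.ones((8, 8), bool)), abs=1e-12
        )


class TestGiSummaryAndDelta:
    def test_summary_is_mean(self):
        assert ev.gi_summary([0.4, 0.6]) == pytest.approx(0.5)
        assert ev.gi_summary([0.37, 0.37, 0.37]) == pytest.approx(0.37)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ev.gi_summary([])

    def test_delta_gi_is_pre_minus_post(self):
        assert ev.delta_gi(0.62, 0.42) == pytest.approx(0.20)
        assert ev.delta_gi(0.55, 0.42) == pytest.approx(0.13)
        assert ev.delta_gi(0.5, 0.5) == 0.0

    def test_per_breath_gi_stable_on_steady_recording(self, quiet_short_recording):
        cfg, truth, trace, seq = quiet_short_recording
        res = ev.analyze_recording(seq, trace)
        assert np.std(res.gi_per_breath) < 0.05


class TestEeli:
    def _steady_seq(self):
        rng = np.random.default_rng(4)
        base = rng.random((8, 8))
        frames = np.stack([base + (0.5 if i % 4 == 2 else 0.0) for i in range(16)])
        return ev.FrameSequence(frames=frames, frame_rate=4.0)

    def test_steady_recording_has_no_drift(self):
        seq = self._steady_seq()
        cycles = [BreathCycle(0, 2, 4), BreathCycle(4, 6, 8), BreathCycle(8, 10, 12)]
        res = ev.eeli(seq, cycles, ev.partition_rois(8, 8))
        assert res.global_change == pytest.approx(0.0, abs=1e-9)

    def test_roi_values_sum_to_global(self, rng):
        part = ev.partition_rois(16, 16)
        for _ in range(100):
            frames = rng.normal(size=(6, 16, 16))
            seq = ev.FrameSequence(frames=frames, frame_rate=4.0)
            cycles = [BreathCycle(0, 1, 2), BreathCycle(2, 3, 4)]
            res = ev.eeli(seq, cycles, part)
            assert res.roi_mean.sum() == res.global_mean
            assert res.roi_change.sum() == pytest.approx(res.global_change, abs=1e-9)

    def test_recruitment_raises_eeli(self):
        """Persistent opening between two recordings raises the
        end-expiratory impedance of the later one."""
        cfg = ev.ards_preset(seed=15, noise_sd=0.0)
        rng = np.random.default_rng(15)
        truth = ev.make_phantom(cfg, rng)
        ev.evolve_states(
            truth, ev.pressure_waveform(ev.baseline_program(duration=1200.0), 10.0), rng
        )
        trace = ev.pressure_waveform(ev.baseline_program(duration=20.0), 40.0)
        part = ev.partition_rois(32, 32)

        def eeli_now():
            seq = ev.simulate_sequence(truth, trace, cfg, rng)
            cycles = ev.detect_breaths(ev.global_signal(seq), 40.0)
            return ev.eeli(seq, cycles, part).global_mean

        before = eeli_now()
        ev.evolve_states(truth, ev.pressure_waveform(ev.maneuver_program("IP"), 10.0), rng)
        after = eeli_now()
        assert after > before
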