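"""Volume tracker: window mapping, segmentation, dV, QC and classification."""

import numpy as np
import pytest

from hnart import (
    ImageVolume,
    PhantomSpec,
    RegistrationRecord,
    SliceWindow,
    VolumeTrace,
    classify_reduction,
    compute_delta_v,
    compute_volume,
    generate_phantom_series,
    locate_slice_window,
    min3_summary,
    qc_successive_jump,
    segment_body,
    track_series,
)
from hnart.tracking import EmptyMaskError, WindowOutOfRangeError


def _blank_image(n_slices=40, ny=64, nx=64):
    return ImageVolume(intensities=np.zeros((n_slices, ny, nx)), slice_mm=3.0)


class TestLocateSliceWindow:
    def test_identity_shift(self):
        win = SliceWindow(c1_mm=30.0, c5_mm=90.0)
        rec = RegistrationRecord(fraction=1, shift_mm=(0.0, 0.0, 0.0))
        assert locate_slice_window(win, rec, _blank_image()) == (30.0, 90.0)

    def test_fractional_axial_shift_quantized(self):
        win = SliceWindow(c1_mm=30.0, c5_mm=90.0)
        rec = RegistrationRecord(fraction=2, shift_mm=(1.0, -2.0, 2.5))
        c1, c5 = locate_slice_window(win, rec, _blank_image())
        assert (c1, c5) == (32.5, 92.5)
        # 0.01-mm quantization, window length preserved exactly
        rec2 = RegistrationRecord(fraction=3, shift_mm=(0.0, 0.0, 0.123456))
        c1b, c5b = locate_slice_window(win, rec2, _blank_image())
        assert c1b == pytest.approx(30.12, abs=1e-9)
        assert c5b - c1b == pytest.approx(60.0, abs=1e-9)

    def test_window_beyond_scan_raises(self):
        win = SliceWindow(c1_mm=30.0, c5_mm=125.0)
        rec = RegistrationRecord(fraction=1, shift_mm=(0.0, 0.0, 0.0))
        with pytest.raises(WindowOutOfRangeError):
            locate_slice_window(win, rec, _blank_image())  # extent 120 mm

    def test_orientation_invariant_rejected(self):
        with pytest.raises(ValueError):
            SliceWindow(c1_mm=90.0, c5_mm=30.0)


class TestSegmentBody:
    def test_cavity_filled_matches_solid_phantom(self):
        base = dict(n_fractions=1, noise_sd=0.0, seed=9)
        holey = PhantomSpec(cavity=True, **base)
        solid = PhantomSpec(cavity=False, **base)
        vols = {}
        for name, spec in [("holey", holey), ("solid", solid)]:
            images, records, window, _ = generate_phantom_series(spec)
            win = locate_slice_window(window, records[0], images[0])
            mask = segment_body(images[0], win, spec.crop_box)
            vols[name] = mask.sum()
        assert vols["holey"] == vols["solid"]

    def test_couch_excluded_by_crop(self):
        spec = PhantomSpec(n_fractions=1, couch=True, seed=4)
        images, records, window, _ = generate_phantom_series(spec)
        win = locate_slice_window(window, records[0], images[0])
        mask = segment_body(images[0], win, spec.crop_box)
        assert not mask[:, spec.couch_start_row:, :].any()

    def test_all_background_raises(self):
        img = ImageVolume(intensities=np.zeros((10, 32, 32)), slice_mm=3.0)
        with pytest.raises(EmptyMaskError):
            segment_body(img, (0.0, 30.0), (0, 32, 0, 32), threshold=100.0)

    def test_crop_box_validated(self):
        img = ImageVolume(intensities=np.ones((10, 32, 32)), slice_mm=3.0)
        with pytest.raises(ValueError):
            segment_body(img, (0.0, 30.0), (0, 64, 0, 32))


class TestVolumeAndDeltaV:
    def test_volume_is_count_times_voxel(self):
        mask = np.zeros((5, 10, 10), dtype=bool)
        mask[2, :10, :10] = True  # 100 voxels
        assert compute_volume(mask, 1.0, 3.0) == pytest.approx(300.0)

    def test_monotone_under_superset(self, rng):
        mask = rng.random((6, 12, 12)) > 0.5
        bigger = mask.copy()
        bigger[0, 0, 0] = True
        assert compute_volume(bigger, 1.0, 3.0) >= compute_volume(mask, 1.0, 3.0)

    def test_empty_mask_errors(self):
        with pytest.raises(EmptyMaskError):
            compute_volume(np.zeros((2, 2, 2), dtype=bool), 1.0, 3.0)

    def test_delta_v_signed(self):
        assert compute_delta_v(900.0, 1000.0) == pytest.approx(-10.0)
        assert compute_delta_v(1000.0, 1000.0) == 0.0
        with pytest.raises(ValueError):
            compute_delta_v(900.0, 0.0)


class TestQCSuccessiveJump:
    @pytest.mark.parametrize("volumes, expected", [
        ([1000, 1000, 940], [3]),         # step 0 -> -6
        ([1000, 1000, 1000], []),          # constant
        ([1000, 960, 930], []),            # steps -4, -3
    ])
    def test_flags(self, volumes, expected):
        trace = VolumeTrace(patient_id="t", volumes_mm3=np.array(volumes, float))
        assert qc_successive_jump(trace) == expected

    def test_single_fraction_errors(self):
        trace = VolumeTrace(patient_id="t", volumes_mm3=np.array([1000.0]))
        with pytest.raises(ValueError):
            qc_successive_jump(trace)


def _trace_from_dv(dv):
    dv = np.asarray(dv, float)
    return VolumeTrace(patient_id="t", volumes_mm3=1000.0 * (1 + dv / 100),
                       delta_v_pct=dv)


class TestClassifyReduction:
    def test_fraction_counting_example(self):
        """A first qualifying window over fractions 24-26 reports fraction 25."""
        dv = np.zeros(33)
        dv[23:26] = -11.0
        label = classify_reduction(_trace_from_dv(dv))
        assert label.group == "reduction"
        assert label.trigger_fraction == 25

    def test_never_crossing_threshold(self):
        label = classify_reduction(_trace_from_dv(np.full(20, -9.9)))
        assert label.group == "non_reduction"
        assert label.trigger_fraction is None

    def test_first_of_two_qualifying_runs_wins(self):
        dv = np.zeros(25)
        dv[9:12] = -12.0   # fractions 10-12
        dv[19:22] = -15.0  # fractions 20-22
        assert classify_reduction(_trace_from_dv(dv)).trigger_fraction == 11

    def test_mean_rule_vs_all_rule(self):
        # window mean -10.33 but one member above threshold
        dv = np.zeros(10)
        dv[4:7] = [-9.0, -10.0, -12.0]
        assert classify_reduction(_trace_from_dv(dv), rule="mean").group == "reduction"
        assert classify_reduction(_trace_from_dv(dv), rule="all").group == "non_reduction"

    def test_matches_bruteforce_on_random_traces(self, rng):
        """Sliding-window rule equals exhaustive window enumeration, 1000 traces."""
        for _ in range(1000):
            n = int(rng.integers(3, 36))
            dv = np.round(rng.uniform(-20, 5, size=n), 2)
            dv[0] = 0.0
            label = classify_reduction(_trace_from_dv(dv))
            hits = [s for s in range(n - 2) if np.mean(dv[s:s + 3]) <= -10.0]
            if hits:
                assert label.group == "reduction"
                assert label.trigger_fraction == hits[0] + 2
            else:
                assert label.group == "non_reduction"

    def test_short_trace_errors(self):
        with pytest.raises(ValueError):
            classify_reduction(_trace_from_dv([0.0, -1.0]))


class TestMin3Summary:
    def test_mean_of_three_most_negative(self):
        label = classify_reduction(_trace_from_dv([0, -1, -2, -3, -4]))
        assert label.min3_mean == pytest.approx(-3.0)

    def test_all_zero(self):
        label = classify_reduction(_trace_from_dv([0.0, 0.0, 0.0]))
        assert label.min3_mean == 0.0

    def test_groupwise_summary(self):
        traces = [_trace_from_dv([0, -11, -12, -13, -1]),
                  _trace_from_dv([0, -1, -2, -3, -4])]
        out = min3_summary(traces)
        assert out["all"]["n"] == 2
        assert out["reduction"]["median"] == pytest.approx(-12.0)
        assert out["non_reduction"]["median"] == pytest.approx(-3.0)

    def test_short_trace_errors(self):
        with pytest.raises(ValueError):
            min3_summary([VolumeTrace(patient_id="x",
                                      volumes_mm3=np.array([1.0, 2.0]))])


class TestEndToEnd:
    def test_phantom_volume_recovery(self):
        """Tracked volume within 2% of truth; terminal dV within 1.5 pp of decay."""
        spec = PhantomSpec(n_fractions=15, seed=21)
        images, records, window, truth = generate_phantom_series(spec)
        trace = track_series(images, records, window, spec.crop_box)
        rel_err = np.abs(trace.volumes_mm3 - np.array(truth)) / np.array(truth)
        assert rel_err.max() < 0.02
        closed = (0.995**14 - 1) * 100
        assert trace.delta_v_pct[-1] == pytest.approx(closed, abs=1.5)

    def test_rethreshold_repair_restores_accuracy(self):
        """An inflating threshold triggers a QC flag and repair restores <=2% error."""
        spec = PhantomSpec(n_fractions=6, seed=33)
        images, records, window, truth = generate_phantom_series(spec)
        log = []
        trace = track_series(images, records, window, spec.crop_box,
                             threshold_overrides={4: 20.0}, log=log)
        assert 4 in trace.qc_flags or 5 in trace.qc_flags
        assert any(e["event"] == "re_threshold" for e in log)
        rel_err = np.abs(trace.volumes_mm3 - np.array(truth)) / np.array(truth)
        assert rel_err.max() < 0.02

    def test_empty_threshold_recovers_without_flag(self):
        """A threshold above every body voxel is repaired in the first pass."""
        spec = PhantomSpec(n_fractions=3, seed=33)
        images, records, window, truth = generate_phantom_series(spec)
        log = []
        trace = track_series(images, records, window, spec.crop_box,
                             threshold_overrides={2: 1500.0}, log=log)
        assert any(e["event"] == "re_threshold" and e["fraction"] == 2
                   for e in log)
        rel_err = np.abs(trace.volumes_mm3 - np.array(truth)) / np.array(truth)
        assert rel_err.max() < 0.02

    def test_record_count_mismatch(self, small_phantom):
        spec, images, records, window, _ = small_phantom
        with pytest.raises(ValueError):
            track_series(images, records[:-1], window, spec.crop_box)
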