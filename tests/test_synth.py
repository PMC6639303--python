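"""Generator contracts: analytic shapes, ground-truth consistency, determinism."""

import numpy as np
import pytest
from scipy.optimize import bisect

import pmrkit as pk


class TestInfluxGenerator:
    def test_no_dynamics_gives_identical_frames(self):
        model = pk.InfluxModel(influx_rate=0.0, noise_sd=0.0, photon_scale=0.0)
        stack, truth, _ = pk.generate_influx_stack(model, seed=0)
        for frame in stack.pixels:
            assert np.array_equal(frame, stack.pixels[0])
        assert np.all(truth.values == model.baseline_intensity)

    def test_repairing_trace_constant_after_repair(self):
        model = pk.InfluxModel(
            noise_sd=0.0, photon_scale=0.0, repair_time=30.0, frame_interval=2.0
        )
        stack, _, roi = pk.generate_influx_stack(model, seed=0)
        trace = pk.extract_mean_trace(stack, roi, subtract_background=False)
        plateau_start = model.injury_frame + 15  # 30 s / 2 s per frame
        in_mask_means = trace.values[plateau_start:]
        assert np.allclose(in_mask_means, in_mask_means[0])
        # and strictly rising before that, after injury
        rising = trace.values[model.injury_frame: plateau_start + 1]
        assert np.all(np.diff(rising) > 0)

    def test_nonrepairing_trace_never_plateaus(self):
        model = pk.InfluxModel(repair_time=None, noise_sd=0.0)
        _, truth = pk.generate_influx_trace(model, seed=0)
        post = truth.values[model.injury_frame:]
        assert np.all(np.diff(post) > 0)

    def test_same_seed_bit_identical(self):
        model = pk.InfluxModel(noise_sd=4.0, photon_scale=0.5)
        s1, _, _ = pk.generate_influx_stack(model, seed=42)
        s2, _, _ = pk.generate_influx_stack(model, seed=42)
        assert np.array_equal(s1.pixels, s2.pixels)
        s3, _, _ = pk.generate_influx_stack(model, seed=43)
        assert not np.array_equal(s1.pixels, s3.pixels)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            pk.InfluxModel(frame_interval=0.0)
        with pytest.raises(ValueError):
            pk.InfluxModel(repair_time=-5.0)
        with pytest.raises(ValueError):
            pk.InfluxModel(n_frames=5, injury_frame=4)
        with pytest.raises(ValueError):
            pk.EllipseSpec(semi_axes=(1.0, 30.0))


class TestTransientGenerator:
    def test_zero_amplitude_is_flat_baseline(self):
        model = pk.TransientModel(peak_amplitude=0.0, noise_sd=0.0)
        trace = pk.generate_transient_trace(model)
        assert np.allclose(trace.values, model.baseline)

    def test_instant_rise_limit_is_pure_exponential(self):
        model = pk.TransientModel(
            rise_tau=0.0, decay_tau=20.0, noise_sd=0.0, baseline=100.0,
            peak_amplitude=50.0, injury_time=10.0,
        )
        trace = pk.generate_transient_trace(model, frame_interval=0.2, n_frames=900)
        post = trace.times >= 0
        expected = 100.0 + 50.0 * np.exp(-trace.times[post] / 20.0)
        assert np.allclose(trace.values[post], expected)

    def test_quarter_peak_time_matches_bisection_oracle(self):
        """The 25 %-of-peak crossing of the sampled trace matches the root of
        the closed-form difference-of-exponentials found by bisection."""
        rise, decay, amp = 2.0, 20.0, 50.0
        model = pk.TransientModel(
            rise_tau=rise, decay_tau=decay, peak_amplitude=amp,
            injury_time=10.0, noise_sd=0.0,
        )
        dt = 0.05
        trace = pk.generate_transient_trace(model, frame_interval=dt, n_frames=4000)

        # independent closed form, peak-normalised
        t_peak = np.log(decay / rise) * rise * decay / (decay - rise)
        peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)

        def excess(t):
            return (np.exp(-t / decay) - np.exp(-t / rise)) / peak - 0.25

        t_quarter = bisect(excess, t_peak, 60 * decay, xtol=1e-10)

        post = trace.times >= 0
        values = (trace.values[post] - model.baseline) / amp
        times = trace.times[post]
        after_peak = times > t_peak
        crossing_idx = np.flatnonzero((values <= 0.25) & after_peak)[0]
        assert abs(times[crossing_idx] - t_quarter) <= dt

    def test_short_span_warns_but_produces_trace(self):
        model = pk.TransientModel(decay_tau=100.0)
        with pytest.warns(UserWarning, match="truncated"):
            trace = pk.generate_transient_trace(model, frame_interval=0.2, n_frames=100)
        assert len(trace) == 100

    def test_peak_amplitude_respected_after_normalisation(self):
        model = pk.TransientModel(rise_tau=3.0, decay_tau=30.0, peak_amplitude=80.0,
                                  noise_sd=0.0)
        trace = pk.generate_transient_trace(model, frame_interval=0.05, n_frames=4000)
        assert abs((trace.values.max() - model.baseline) - 80.0) <= 0.01 * 80.0


class TestERGenerator:
    @pytest.mark.parametrize("frac,expect_any", [(0.0, False), (1.0, True)])
    def test_pure_fields_label_extremes(self, frac, expect_any):
        model = pk.ERFieldModel(fragmentation_fraction=frac)
        stack, truth = pk.generate_er_stack(model, n_frames=2, onset_frame=0, seed=0)
        assert truth.label_mask.any() == expect_any
        if expect_any:
            # all in-mask pixels labelled when fraction is 1
            assert np.array_equal(truth.label_mask, truth.cell_mask)

    def test_half_fraction_label_extends_half_axis(self):
        """Generator's own label mask covers half the injury axis ±1 px."""
        model = pk.ERFieldModel(fragmentation_fraction=0.5)
        stack, truth = pk.generate_er_stack(model, n_frames=1, onset_frame=0, seed=0)
        axis = truth.result.axis_coordinates
        labelled = truth.label_mask[axis[:, 0], axis[:, 1]]
        # axis pixels are ordered from injury point; labelled run length
        run = int(np.argmin(labelled)) if not labelled.all() else len(labelled)
        assert abs(run - 0.5 * len(axis)) <= 2.0  # ±1 px on a diagonal step

    def test_pre_onset_frames_fully_tubular(self):
        model = pk.ERFieldModel(fragmentation_fraction=0.7)
        stack, truth = pk.generate_er_stack(model, n_frames=4, onset_frame=2, seed=0)
        assert np.array_equal(stack.pixels[0, 0], stack.pixels[1, 0])
        assert not np.array_equal(stack.pixels[1, 0], stack.pixels[2, 0])
        assert np.array_equal(stack.pixels[2, 0], stack.pixels[3, 0])

    def test_indistinguishable_textures_rejected(self):
        with pytest.raises(ValueError, match="indistinguishable"):
            pk.ERFieldModel(tubule_spacing=2.0, puncta_radius=1.5)

    def test_onset_after_last_frame_rejected(self):
        model = pk.ERFieldModel()
        with pytest.raises(ValueError):
            pk.generate_er_stack(model, n_frames=3, onset_frame=3, seed=0)


class TestBeadGenerator:
    def test_no_injured_means_blank_channels(self):
        spec = pk.BeadFieldSpec(n_cells=10, n_injured=0, n_failed=0,
                                image_size=(128, 128))
        image, table = pk.generate_bead_field(spec)
        assert np.all(image == 0)
        assert table["injured"].sum() == 0

    def test_truth_counts_match_spec(self):
        spec = pk.BeadFieldSpec(n_cells=60, n_injured=40, n_failed=12,
                                image_size=(384, 384), seed=3)
        _, table = pk.generate_bead_field(spec)
        assert table["injured"].sum() == 40
        assert table["failed"].sum() == 12
        assert (table["failed"] & ~table["injured"]).sum() == 0

    def test_cells_do_not_overlap(self):
        spec = pk.BeadFieldSpec(n_cells=50, n_injured=50, n_failed=10,
                                image_size=(384, 384), seed=1)
        _, table = pk.generate_bead_field(spec)
        pos = table[["row", "col"]].to_numpy()
        rad = table["radius"].to_numpy()
        d = np.hypot(*(pos[:, None, :] - pos[None, :, :]).transpose(2, 0, 1))
        sep = rad[:, None] + rad[None, :]
        off_diag = ~np.eye(len(pos), dtype=bool)
        assert np.all(d[off_diag] > sep[off_diag])

    def test_same_seed_identical_labels(self):
        spec = pk.BeadFieldSpec(n_cells=30, n_injured=20, n_failed=5,
                                image_size=(256, 256), seed=9)
        img1, t1 = pk.generate_bead_field(spec)
        img2, t2 = pk.generate_bead_field(spec)
        assert np.array_equal(img1, img2)
        assert t1.equals(t2)

    def test_infeasible_packing_raises(self):
        spec = pk.BeadFieldSpec(n_cells=200, n_injured=0, n_failed=0,
                                image_size=(64, 64))
        with pytest.raises(RuntimeError, match="non-overlapping"):
            pk.generate_bead_field(spec)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            pk.BeadFieldSpec(n_cells=10, n_injured=5, n_failed=6)


class TestFrapGenerator:
    def test_immobile_stays_at_bleached_level(self):
        trace = pk.generate_frap_trace(0.0, 15.0, bleach_depth=0.8, noise_sd=0.0)
        post = trace.values[10:]
        assert np.allclose(post, 0.2)

    def test_half_recovery_at_tau_ln2(self):
        tau = 12.0
        trace = pk.generate_frap_trace(
            1.0, tau, bleach_depth=0.8, frame_interval=tau * np.log(2) / 8,
            n_frames=200, noise_sd=0.0,
        )
        # t = tau·ln2 lands exactly on frame 10 + 8
        idx = 10 + 8
        assert np.isclose(trace.values[idx], 1.0 - 0.8 + 0.8 * 0.5)

    def test_matches_closed_form_everywhere(self):
        mf, tau, depth = 0.7, 15.0, 0.8
        trace = pk.generate_frap_trace(mf, tau, bleach_depth=depth,
                                       frame_interval=1.0, n_frames=100,
                                       noise_sd=0.0)
        t = np.maximum(trace.times, 0.0)
        expected = np.where(
            trace.times < 0,
            1.0,
            1.0 - depth + depth * mf * (1.0 - np.exp(-t / tau)),
        )
        assert np.allclose(trace.values, expected, atol=1e-12)

    def test_mobile_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pk.generate_frap_trace(1.2, 15.0)
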