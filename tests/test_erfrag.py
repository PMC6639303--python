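"""Injury-axis geometry and tubular/punctate texture scoring."""

import numpy as np
import pytest

import pmrkit as pk


def circle_polygon(center, radius, n=256):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )


class TestInjuryAxis:
    def test_circle_axis_is_the_diameter(self):
        poly = circle_polygon((100.0, 100.0), 40.0)
        axis = pk.injury_axis(poly, (60.0, 100.0))
        length = np.linalg.norm(axis[-1] - axis[0])
        assert abs(length - 80.0) <= 1.0

    def test_square_corner_axis_is_the_diagonal(self):
        side = 50.0
        poly = np.array([[0, 0], [0, side], [side, side], [side, 0]], dtype=float)
        axis = pk.injury_axis(poly, (0.0, 0.0))
        assert np.allclose(axis[-1], [side, side], atol=1.0)
        length = np.linalg.norm(axis[-1] - axis[0])
        assert abs(length - side * np.sqrt(2)) <= 1.5

    def test_axis_endpoint_matches_generator_far_point(self):
        model = pk.ERFieldModel()
        _, truth = pk.generate_er_stack(model, n_frames=1, onset_frame=0, seed=0)
        axis = pk.injury_axis(truth.roi.cell_polygon, truth.roi.injury_point)
        far = np.asarray(truth.result.meta["far_point"])
        assert np.linalg.norm(axis[-1] - far) <= 1.5

    def test_injury_point_outside_polygon_rejected(self):
        poly = circle_polygon((50.0, 50.0), 20.0)
        with pytest.raises(ValueError, match="outside"):
            pk.injury_axis(poly, (5.0, 5.0))


class TestScoreFragmentation:
    @pytest.mark.parametrize("frac", [0.0, 1.0])
    def test_pure_fields_recover_extremes(self, frac, er_threshold):
        model = pk.ERFieldModel(fragmentation_fraction=frac)
        stack, truth = pk.generate_er_stack(model, n_frames=2, onset_frame=0, seed=1)
        res = pk.score_fragmentation(
            stack, "ER", truth.result.axis_coordinates, 1,
            threshold=er_threshold, cell_mask=truth.cell_mask,
        )
        assert abs(res.fragmented_fraction - frac) <= 0.02

    @pytest.mark.parametrize("frac", [0.25, 0.5, 0.75])
    def test_noise_free_recovery_within_5_percent(self, frac, er_threshold):
        model = pk.ERFieldModel(fragmentation_fraction=frac)
        stack, truth = pk.generate_er_stack(model, n_frames=1, onset_frame=0, seed=2)
        res = pk.score_fragmentation(
            stack, "ER", truth.result.axis_coordinates, 0,
            threshold=er_threshold, cell_mask=truth.cell_mask,
        )
        assert abs(res.fragmented_fraction - frac) <= 0.05

    def test_invariant_to_global_intensity_scaling(self, er_threshold):
        model = pk.ERFieldModel(fragmentation_fraction=0.5)
        stack, truth = pk.generate_er_stack(model, n_frames=1, onset_frame=0, seed=3)
        res1 = pk.score_fragmentation(
            stack, "ER", truth.result.axis_coordinates, 0,
            threshold=er_threshold, cell_mask=truth.cell_mask,
        )
        scaled = pk.TimeLapseStack(
            stack.pixels * 7.0, stack.frame_interval,
            channel_names=stack.channel_names, injury_frame=stack.injury_frame,
        )
        res2 = pk.score_fragmentation(
            scaled, "ER", truth.result.axis_coordinates, 0,
            threshold=er_threshold, cell_mask=truth.cell_mask,
        )
        assert np.isclose(res1.fragmented_fraction, res2.fragmented_fraction,
                          atol=1e-6)

    def test_rotated_field_recovers_same_fraction(self, er_threshold):
        base = pk.ERFieldModel(fragmentation_fraction=0.5)
        rot = pk.ERFieldModel(
            fragmentation_fraction=0.5,
            cell=pk.EllipseSpec(center=(96.0, 96.0), semi_axes=(80.0, 48.0),
                                rotation_deg=90.0),
        )
        results = []
        for model in (base, rot):
            stack, truth = pk.generate_er_stack(model, n_frames=1, onset_frame=0,
                                                seed=4)
            res = pk.score_fragmentation(
                stack, "ER", truth.result.axis_coordinates, 0,
                threshold=er_threshold, cell_mask=truth.cell_mask,
            )
            results.append(res.fragmented_fraction)
        assert abs(results[0] - results[1]) <= 0.05

    def test_monotone_in_true_fraction(self, er_threshold):
        recovered = []
        for frac in (0.1, 0.3, 0.5, 0.7, 0.9):
            model = pk.ERFieldModel(fragmentation_fraction=frac, noise_sd=5.0)
            stack, truth = pk.generate_er_stack(model, n_frames=1, onset_frame=0,
                                                seed=5)
            thr = pk.calibrate_threshold(noise_sd=5.0)
            res = pk.score_fragmentation(
                stack, "ER", truth.result.axis_coordinates, 0,
                threshold=thr, cell_mask=truth.cell_mask,
            )
            recovered.append(res.fragmented_fraction)
        diffs = np.diff(recovered)
        assert np.all(diffs > -0.05)


class TestTimecourse:
    def test_onset_frame_splits_the_series(self, er_threshold):
        model = pk.ERFieldModel(fragmentation_fraction=0.6)
        stack, truth = pk.generate_er_stack(model, n_frames=5, onset_frame=2, seed=6)
        series = pk.fragmentation_timecourse(
            stack, "ER", truth.result.axis_coordinates,
            threshold=er_threshold, cell_mask=truth.cell_mask,
        )
        fractions = [r.fragmented_fraction for r in series]
        assert max(fractions[:2]) <= 0.05
        assert all(abs(f - 0.6) <= 0.05 for f in fractions[2:])

    def test_constant_tubular_stack_scores_zero_everywhere(self, er_threshold):
        model = pk.ERFieldModel(fragmentation_fraction=0.0)
        stack, truth = pk.generate_er_stack(model, n_frames=3, onset_frame=0, seed=7)
        series = pk.fragmentation_timecourse(
            stack, "ER", truth.result.axis_coordinates,
            threshold=er_threshold, cell_mask=truth.cell_mask,
        )
        assert all(r.fragmented_fraction <= 0.02 for r in series)

    def test_frame_independence_under_reversal(self, er_threshold):
        model = pk.ERFieldModel(fragmentation_fraction=0.5)
        stack, truth = pk.generate_er_stack(model, n_frames=4, onset_frame=2, seed=8)
        series = pk.fragmentation_timecourse(
            stack, "ER", truth.result.axis_coordinates,
            threshold=er_threshold, cell_mask=truth.cell_mask,
        )
        reversed_stack = pk.TimeLapseStack(
            stack.pixels[::-1].copy(), stack.frame_interval,
            channel_names=stack.channel_names,
        )
        rev_series = pk.fragmentation_timecourse(
            reversed_stack, "ER", truth.result.axis_coordinates,
            threshold=er_threshold, cell_mask=truth.cell_mask,
        )
        fwd = [r.fragmented_fraction for r in series]
        rev = [r.fragmented_fraction for r in rev_series]
        assert fwd == rev[::-1]
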