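"""Calcium clearance metrics: analytic decays, AUC arithmetic, equivariances."""

import numpy as np
import pytest

import pmrkit as pk
from pmrkit.calcium import NO_TRANSIENT, RIGHT_CENSORED
from pmrkit.traces import KineticTrace


def dff(values, dt=0.2, injury_frame=50):
    times = (np.arange(len(values)) - injury_frame) * dt
    return KineticTrace(times, np.asarray(values, dtype=float), kind="dff")


class TestComputeMetrics:
    @pytest.mark.parametrize("tau", [5.0, 10.0, 20.0, 40.0])
    def test_pure_exponential_clearance_is_tau_ln4(self, tau):
        model = pk.TransientModel(rise_tau=0.0, decay_tau=tau, noise_sd=0.0)
        trace = pk.generate_transient_trace(model, frame_interval=0.2,
                                            n_frames=1400)
        metrics = pk.compute_calcium_metrics(pk.to_delta_f_over_f(trace))
        assert abs(metrics.clearance75_time - tau * np.log(4)) <= 0.2

    def test_rectangular_pulse_auc_is_width_times_height(self):
        dt = 0.5
        values = np.zeros(120)
        values[50: 50 + 20] = 1.0  # 20 samples at height 1 flanked by zeros
        trace = dff(values, dt=dt, injury_frame=40)
        metrics = pk.compute_calcium_metrics(trace, smoothing_sigma=0.0)
        assert np.isclose(metrics.auc, 20 * dt * 1.0)

    def test_all_zero_trace_flagged_no_transient(self):
        metrics = pk.compute_calcium_metrics(dff(np.zeros(400)))
        assert NO_TRANSIENT in metrics.flags
        assert metrics.peak_value is None and metrics.auc is None

    def test_monotone_rise_is_right_censored(self):
        values = np.linspace(0, 1, 400)
        metrics = pk.compute_calcium_metrics(dff(values))
        assert RIGHT_CENSORED in metrics.flags
        assert metrics.clearance75_time is None

    def test_auc_clips_negative_excursions_by_default(self):
        values = np.zeros(400)
        values[60:160] = 1.0
        values[200:300] = -0.5
        trace = dff(values)
        clipped = pk.compute_calcium_metrics(trace, smoothing_sigma=0.0)
        unclipped = pk.compute_calcium_metrics(trace, smoothing_sigma=0.0,
                                               clip_negative_auc=False)
        assert clipped.auc > unclipped.auc

    def test_scale_equivariance(self):
        """c·trace has c·peak and c·AUC but the same clearance time."""
        model = pk.TransientModel(rise_tau=1.0, decay_tau=15.0, noise_sd=0.0)
        trace = pk.to_delta_f_over_f(
            pk.generate_transient_trace(model, frame_interval=0.2, n_frames=600)
        )
        m1 = pk.compute_calcium_metrics(trace)
        scaled = KineticTrace(trace.times, trace.values * 3.0, kind="dff")
        m3 = pk.compute_calcium_metrics(scaled)
        assert np.isclose(m3.peak_value, 3.0 * m1.peak_value)
        assert np.isclose(m3.auc, 3.0 * m1.auc, rtol=1e-6)
        assert np.isclose(m3.clearance75_time, m1.clearance75_time, atol=1e-9)

    def test_time_rescaling_scales_clearance_and_auc(self):
        model = pk.TransientModel(rise_tau=0.0, decay_tau=10.0, noise_sd=0.0)
        t1 = pk.to_delta_f_over_f(
            pk.generate_transient_trace(model, frame_interval=0.2, n_frames=900)
        )
        # stretch time by k: same samples, k·dt spacing, k·window
        k = 2.0
        t2 = KineticTrace(t1.times * k, t1.values, kind="dff")
        m1 = pk.compute_calcium_metrics(t1, window=120.0)
        m2 = pk.compute_calcium_metrics(t2, window=120.0 * k)
        assert np.isclose(m2.clearance75_time, k * m1.clearance75_time, rtol=0.02)
        assert np.isclose(m2.auc, k * m1.auc, rtol=1e-6)


class TestCohortSummary:
    def _metrics_for(self, decay_tau, n, seed0=0, noise_sd=1.0):
        out = []
        for i in range(n):
            model = pk.TransientModel(rise_tau=1.0, decay_tau=decay_tau,
                                      noise_sd=noise_sd)
            trace = pk.generate_transient_trace(model, frame_interval=0.2,
                                                n_frames=1400, seed=seed0 + i)
            out.append(pk.compute_calcium_metrics(pk.to_delta_f_over_f(trace)))
        return out

    def test_identical_cells_zero_sem(self):
        metrics = self._metrics_for(10.0, 1, noise_sd=0.0) * 2
        summary = pk.cohort_calcium_summary(metrics, ["g", "g"])
        assert summary.iloc[0]["clearance75_sem"] == 0.0

    def test_healthy_vs_patient_clearance_ratio_near_four(self):
        """decay_tau 10 s vs 40 s cohorts: mean clearance-75 ratio ≈ 4
        (clearance of a near-exponential transient scales with tau)."""
        healthy = self._metrics_for(10.0, 20, seed0=100)
        patient = self._metrics_for(40.0, 20, seed0=200)
        summary = pk.cohort_calcium_summary(
            healthy + patient, ["healthy"] * 20 + ["patient"] * 20
        )
        by_group = summary.set_index("group")["clearance75_mean"]
        ratio = by_group["patient"] / by_group["healthy"]
        assert 3.5 < ratio < 4.5

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            pk.cohort_calcium_summary([], [])

    def test_all_censored_group_reports_missing_mean(self):
        values = np.linspace(0, 1, 400)
        censored = pk.compute_calcium_metrics(dff(values))
        summary = pk.cohort_calcium_summary([censored, censored], ["g", "g"])
        row = summary.iloc[0]
        assert row["n_censored"] == 2
        assert np.isnan(row["clearance75_mean"])
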