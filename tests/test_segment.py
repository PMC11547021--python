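"""Epoch state machine and the 0.25-SD secondary-decline rule."""

import numpy as np
import pytest

from conftest import make_step_series
from perimob.epochs import Epoch
from perimob.preprocess import normalize_to_baseline, smooth
from perimob.segment import (
    EpochSegmentation,
    SegmentationConfig,
    detect_secondary_decline,
    epoch_durations,
    segment_epochs,
)
from perimob.simulate import TrajectoryParams, simulate_trajectory

FULL_GRID = np.arange(-730, 730)


def crafted_decline_series(depth_sd, baseline_sd=3000.0, baseline_mean=5000.0,
                           onset=400, plateau=1.0):
    """Flat recovered trajectory with an instant drop of depth_sd at onset."""
    values = np.ones(len(FULL_GRID)) * plateau
    values[FULL_GRID < -250] = 1.0
    pre = (FULL_GRID >= -250) & (FULL_GRID < 0)
    values[pre] = 1.0 - 0.5 * (FULL_GRID[pre] + 250) / 250
    post = (FULL_GRID >= 0) & (FULL_GRID < 150)
    values[post] = 0.5 + (plateau - 0.5) * FULL_GRID[post] / 150
    drop = depth_sd * baseline_sd / baseline_mean
    values[FULL_GRID >= onset] = plateau - drop
    series = make_step_series(FULL_GRID, values, baseline_mean, baseline_sd,
                              smoothing_window=None)
    return smooth(series, 14)


def test_constant_trajectory_yields_baseline_then_recovered():
    series = make_step_series(FULL_GRID, np.ones(len(FULL_GRID)))
    seg = segment_epochs(series)
    durations = epoch_durations(seg)
    assert durations[int(Epoch.BASELINE)] == 365
    assert durations[int(Epoch.FULLY_RECOVERED)] == 1460 - 365
    assert durations[int(Epoch.SECONDARY_DECLINE)] == 0
    assert "never_left_baseline" in seg.flags
    call = detect_secondary_decline(series, seg)
    assert call.declined is False and call.depth_sd == 0.0


def test_trajectory_never_reaching_recovery_has_no_epoch5():
    values = np.ones(len(FULL_GRID))
    values[FULL_GRID >= -250] = 0.7  # drops and stays below 1 - epsilon
    series = make_step_series(FULL_GRID, values)
    seg = segment_epochs(series)
    assert "not_fully_recovered" in seg.flags
    assert not seg.intervals_for(Epoch.FULLY_RECOVERED)
    assert detect_secondary_decline(series, seg).declined is False


def test_segmentation_is_deterministic():
    params = TrajectoryParams()
    s, _ = simulate_trajectory(params, seed=13)
    nas = smooth(normalize_to_baseline(s))
    a = segment_epochs(nas)
    b = segment_epochs(nas)
    assert a.intervals == b.intervals


def test_durations_partition_the_observed_window():
    for seed in range(5):
        s, _ = simulate_trajectory(TrajectoryParams(), seed=seed)
        nas = smooth(normalize_to_baseline(s))
        seg = segment_epochs(nas)
        total = sum(epoch_durations(seg).values())
        span = nas.day_index[-1] - nas.day_index[0] + 1
        assert total == span


def test_epoch_duration_additivity_over_split_intervals():
    seg = EpochSegmentation(
        patient_id="x",
        intervals=[
            (-100, -71, Epoch.PRE_OP_DECLINE),
            (-70, -41, Epoch.SPONTANEOUS_RECOVERY),
            (-40, -31, Epoch.PRE_OP_DECLINE),
            (-30, -1, Epoch.SPONTANEOUS_RECOVERY),
            (0, 10, Epoch.POST_OP_RECOVERY),
        ],
        flags=frozenset(),
        config=SegmentationConfig(),
    )
    durations = epoch_durations(seg)
    assert durations[int(Epoch.SPONTANEOUS_RECOVERY)] == 30 + 30
    assert durations[int(Epoch.PRE_OP_DECLINE)] == 40


def test_noise_free_boundaries_recovered(noise_free_cohort):
    """Detected boundaries stay within the smoothing+dwell tolerance of truth."""
    tol = 7 + SegmentationConfig().dwell_days
    for p, a in zip(noise_free_cohort.patients, noise_free_cohort.analyses):
        truth_starts = {}
        for s, e, lab in p.truth.intervals:
            truth_starts.setdefault(int(lab), []).append(s)
        det_starts = {}
        for s, e, lab in a.segmentation.intervals:
            det_starts.setdefault(int(lab), []).append(s)
        assert set(det_starts) == set(truth_starts)
        for lab, starts in truth_starts.items():
            assert len(det_starts[lab]) == len(starts)
            for t, d in zip(starts, det_starts[lab]):
                assert abs(t - d) <= tol, (p.series.patient_id, lab, t, d)


def test_decline_rule_boundary_is_inclusive():
    """A drop of exactly 0.25 SD declines; 0.249 SD does not."""
    seg_at = segment_epochs(crafted_decline_series(0.25))
    call_at = detect_secondary_decline(crafted_decline_series(0.25), seg_at)
    assert call_at.declined is True
    assert call_at.depth_sd == pytest.approx(0.25, abs=1e-9)
    assert call_at.onset_day is not None

    series_below = crafted_decline_series(0.249)
    call_below = detect_secondary_decline(series_below, segment_epochs(series_below))
    assert call_below.declined is False
    assert call_below.depth_sd == pytest.approx(0.249, abs=1e-9)


def test_threshold_monotonicity():
    """Raising the threshold never turns a non-decliner into a decliner."""
    series = crafted_decline_series(0.30)
    seg = segment_epochs(series)
    grid = [0.10, 0.20, 0.25, 0.30, 0.45]
    calls = [detect_secondary_decline(series, seg, threshold_sd=t).declined for t in grid]
    assert calls == sorted(calls, reverse=True)  # True ... then False
    assert calls[0] is True and calls[-1] is False


def test_no_epoch5_means_no_decline_regardless_of_shape():
    values = np.ones(len(FULL_GRID))
    values[FULL_GRID >= -250] = 0.6
    values[FULL_GRID >= 400] = 0.2  # deep late drop, but never recovered
    series = make_step_series(FULL_GRID, values)
    seg = segment_epochs(series)
    call = detect_secondary_decline(series, seg)
    assert call.declined is False and call.onset_day is None


def _brute_force_breakpoints(day_index, values):
    """Independent oracle: exhaustive single-change-point scans minimizing
    the SSE of a two-piece linear fit, run separately on each side of surgery."""

    def sse(x, y):
        if len(x) < 2:
            return 0.0
        coef = np.polyfit(x, y, 1)
        resid = y - np.polyval(coef, x)
        return float(resid @ resid)

    def best_break(x, y):
        best_b, best = None, np.inf
        for i in range(2, len(x) - 2):
            total = sse(x[: i + 1], y[: i + 1]) + sse(x[i + 1 :], y[i + 1 :])
            if total < best:
                best_b, best = x[i + 1], total
        return best_b

    pre = day_index < 0
    post = ~pre
    b_pre = best_break(day_index[pre].astype(float), values[pre])
    b_post = best_break(day_index[post].astype(float), values[post])
    return int(b_pre), int(b_post)


def test_state_machine_matches_bruteforce_changepoint_oracle():
    """On a noise-free two-kink trajectory both routes find the same days."""
    params = TrajectoryParams(
        noise_dispersion=0.0, missing_rate=0.0,
        decline_onset_day=-300, recovery_length_days=200, plateau_fraction=1.0,
    )
    s, _ = simulate_trajectory(params, seed=0)
    nas = smooth(normalize_to_baseline(s))
    seg = segment_epochs(nas)
    onset_machine = seg.intervals_for(Epoch.PRE_OP_DECLINE)[0][0]
    recovery_machine = seg.intervals_for(Epoch.FULLY_RECOVERED)[0][0]
    b_pre, b_post = _brute_force_breakpoints(nas.day_index, nas.values)
    tol = 7 + SegmentationConfig().dwell_days
    assert abs(onset_machine - b_pre) <= tol
    assert abs(recovery_machine - b_post) <= tol
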