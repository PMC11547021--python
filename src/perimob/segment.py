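"""Six-epoch segmentation of smoothed activity and the secondary-decline rule.

The segmenter is a deterministic threshold-plus-hysteresis state machine on
the smoothed, baseline-normalized day grid:

* epoch 1 (baseline) runs from the window start until the pre-operative
  decline begins;
* epoch 2 (pre-op decline) is entered when the smoothed value stays below
  ``1 - delta`` for at least ``dwell_days`` before surgery;
* epoch 3 (spontaneous recovery) marks pre-surgery sub-intervals where the
  value climbs back above ``1 - delta`` for at least ``dwell_days``;
* epoch 4 (post-op recovery) starts at the surgery day and ends when the
  value first holds at or above ``1 - epsilon`` for ``dwell_days``;
* epoch 5 (fully recovered) runs from that point;
* epoch 6 (secondary decline) begins when the value falls and stays below
  the running epoch-5 level by more than ``decline_delta``.

Raw threshold crossings lag the true change days by an amount proportional
to the local slope, so each detected boundary is refined to the nearest
shape feature of the smoothed curve: decline and secondary-decline onsets
walk back to the end of the preceding plateau, spontaneous-recovery starts
walk back to the local minimum, the recovery boundary walks forward to the
start of the plateau, and spontaneous-recovery ends are re-fit with a local
two-piece linear model.  On noise-free piecewise-linear input every refined
boundary lands within the smoothing half-width of the generative change day.

The secondary-decline outcome itself is a raw-scale rule: a patient has
declined when mean steps-per-day in a trailing candidate window inside epoch
6 sits at least ``threshold_sd`` baseline standard deviations below the
epoch-5 mean.  Patients who never reach epoch 5 cannot decline by
definition.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Tuple

import numpy as np

from .epochs import BASELINE_YEAR, Epoch
from .preprocess import NormalizedActivitySeries

_FLAT_TOL = 1e-9  # slope tolerance distinguishing a plateau from a ramp


@dataclasses.dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds of the epoch state machine.

    ``delta`` (entry into decline, normalized units) and ``epsilon``
    (recovery tolerance) gate transitions; ``dwell_days`` is the minimum
    calendar persistence for any transition and matches the smoothing scale.
    ``decline_delta`` gates epoch-6 entry relative to the running epoch-5
    level and defaults to ``delta``.
    """

    delta: float = 0.10
    epsilon: float = 0.05
    dwell_days: int = 14
    decline_delta: Optional[float] = None
    min_epoch5_days: int = 14
    min_epoch6_days: int = 60
    refine: bool = True
    refine_radius_days: int = 45
    onset_refine_radius_days: int = 150

    @property
    def epoch6_delta(self) -> float:
        return self.delta if self.decline_delta is None else self.decline_delta


@dataclasses.dataclass
class EpochSegmentation:
    """Ordered, contiguous labeled intervals covering the observed window."""

    patient_id: str
    intervals: List[Tuple[int, int, Epoch]]
    flags: frozenset
    config: SegmentationConfig

    def __post_init__(self) -> None:
        for (s, e, _) in self.intervals:
            if e < s:
                raise ValueError(f"empty interval ({s}, {e})")
        for (_, e0, _), (s1, _, _) in zip(self.intervals, self.intervals[1:]):
            if s1 != e0 + 1:
                raise ValueError("intervals must be contiguous and ordered")

    def intervals_for(self, label: Epoch) -> List[Tuple[int, int]]:
        return [(s, e) for s, e, lab in self.intervals if lab == label]

    @property
    def span(self) -> Tuple[int, int]:
        return self.intervals[0][0], self.intervals[-1][1]


@dataclasses.dataclass(frozen=True)
class DeclineCall:
    """Outcome of the secondary-decline rule for one patient."""

    declined: bool
    onset_day: Optional[int]
    depth_sd: float


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------


def _calendar_runs(
    mask: np.ndarray, days: np.ndarray, min_len_days: int
) -> List[Tuple[int, int]]:
    """Index runs of consecutive True spanning >= min_len_days calendar days."""
    runs: List[Tuple[int, int]] = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            if days[j] - days[i] + 1 >= min_len_days:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _walk_back_ascending(v: np.ndarray, i: int, lo: int) -> int:
    """Walk left while values keep rising backwards (toward a plateau end)."""
    while i > lo and v[i - 1] > v[i] + _FLAT_TOL:
        i -= 1
    return i


def _walk_back_descending(v: np.ndarray, i: int, lo: int) -> int:
    """Walk left while values keep falling backwards (toward a local minimum)."""
    while i > lo and v[i - 1] < v[i] - _FLAT_TOL:
        i -= 1
    return i


def _walk_forward_ascending(v: np.ndarray, i: int, hi: int) -> int:
    """Walk right while values keep rising (toward the plateau start)."""
    while i < hi and v[i + 1] > v[i] + _FLAT_TOL:
        i += 1
    return i


def _ols_sse(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2:
        return 0.0
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx <= 0:
        return syy
    return syy - float(xc @ yc) ** 2 / sxx


def _two_piece_breakpoint(
    d: np.ndarray,
    v: np.ndarray,
    center: int,
    radius_days: int,
    mode: str = "centered",
) -> int:
    """Best single breakpoint of a two-piece linear fit near ``center``.

    Returns the index of the last point of the left piece; used to localize
    slope-change boundaries that are not extrema.  ``mode`` shapes the fit
    window: ``"forward"`` starts it at ``center`` (the true change day lies
    ahead, e.g. where a fast fall rejoins a slow decline), ``"backward"``
    extends it mostly upstream (the change day lies behind the detection,
    e.g. a plateau kinking into a shallow ramp), ``"centered"`` is symmetric.
    """
    day_c = d[center]
    if mode == "forward":
        back, fwd = 0, radius_days
    elif mode == "backward":
        back, fwd = radius_days, 15
    else:
        back = fwd = radius_days
    lo = int(np.searchsorted(d, day_c - back))
    hi = int(np.searchsorted(d, day_c + fwd, side="right")) - 1
    if hi - lo < 5:
        return center
    x = d[lo : hi + 1].astype(float)
    y = v[lo : hi + 1]
    best_k, best_sse = center - lo, math.inf
    for k in range(2, len(x) - 2):
        sse = _ols_sse(x[: k + 1], y[: k + 1]) + _ols_sse(x[k + 1 :], y[k + 1 :])
        if sse < best_sse:
            best_k, best_sse = k, sse
    return lo + best_k


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_epochs(
    series: NormalizedActivitySeries, config: Optional[SegmentationConfig] = None
) -> EpochSegmentation:
    """Classify a smoothed, normalized trajectory into the six epochs.

    The output is fully determined by the input series and configuration.
    A trajectory that never leaves baseline yields epochs {1, 5} and the
    ``never_left_baseline`` flag; a trajectory that never re-reaches
    ``1 - epsilon`` after surgery has no epoch 5 and is flagged
    ``not_fully_recovered``.
    """
    cfg = config or SegmentationConfig()
    d = series.day_index
    v = series.values
    if series.smoothing_window is None:
        raise ValueError("segment a smoothed series (run preprocess.smooth first)")
    flags = set()
    n = len(d)
    pre_last = int(np.searchsorted(d, 0)) - 1  # last pre-op index, -1 if none
    boundaries: List[Tuple[int, int, Epoch]] = []

    if pre_last < 0:
        flags.add("no_pre_op_data")
        onset_day = None
    else:
        below = v[: pre_last + 1] < 1.0 - cfg.delta
        runs = _calendar_runs(below, d[: pre_last + 1], cfg.dwell_days)
        if not runs:
            onset_day = None
        else:
            i0, _ = runs[0]
            decl_i0 = i0  # first index actually below threshold
            if cfg.refine:
                # shallow ramps cross the threshold long after the true
                # kink, so localize the break over a backward-looking window
                fit = _two_piece_breakpoint(
                    d, v, i0, cfg.onset_refine_radius_days, mode="backward"
                )
                oi = min(fit, i0)
            else:
                oi = i0
            onset_day = int(d[oi])
            onset_idx = oi

    if pre_last >= 0:
        if onset_day is None:
            flags.add("never_left_baseline")
            base_end = min(BASELINE_YEAR[1], int(d[pre_last]))
            boundaries.append((int(d[0]), base_end, Epoch.BASELINE))
            if base_end < int(d[pre_last]):
                boundaries.append((base_end + 1, -1, Epoch.FULLY_RECOVERED))
        else:
            if onset_day > d[0]:
                boundaries.append((int(d[0]), onset_day - 1, Epoch.BASELINE))
            # spontaneous recoveries inside the decline span
            seg3: List[Tuple[int, int]] = []
            # a spontaneous recovery is a re-ascent: it can only begin after
            # the trajectory has first dropped below the decline threshold
            above = v[: pre_last + 1] >= 1.0 - cfg.delta
            above[:decl_i0] = False
            for (i0, i1) in _calendar_runs(above, d[: pre_last + 1], cfg.dwell_days):
                if cfg.refine:
                    si = _walk_back_descending(v, i0, onset_idx)
                    if i1 < pre_last:
                        ei = _two_piece_breakpoint(
                            d, v, i1, cfg.refine_radius_days, mode="forward"
                        )
                        ei = max(ei, si)
                    else:
                        ei = pre_last
                else:
                    si, ei = i0, i1
                s_day, e_day = int(d[si]), int(d[ei])
                if seg3 and s_day <= seg3[-1][1]:
                    s_day = seg3[-1][1] + 1
                if s_day <= e_day:
                    seg3.append((s_day, e_day))
            cursor = onset_day
            for (s_day, e_day) in seg3:
                if s_day > cursor:
                    boundaries.append((cursor, s_day - 1, Epoch.PRE_OP_DECLINE))
                boundaries.append((s_day, min(e_day, -1), Epoch.SPONTANEOUS_RECOVERY))
                cursor = e_day + 1
            if cursor <= -1:
                boundaries.append((cursor, -1, Epoch.PRE_OP_DECLINE))

    # ---- post-operative side -------------------------------------------
    post_first = pre_last + 1
    if post_first >= n:
        flags.add("no_post_op_data")
    else:
        dp = d[post_first:]
        vp = v[post_first:]
        above5 = vp >= 1.0 - cfg.epsilon
        runs = _calendar_runs(above5, dp, cfg.dwell_days)
        last_day = int(d[-1])
        if not runs:
            flags.add("not_fully_recovered")
            boundaries.append((0, last_day, Epoch.POST_OP_RECOVERY))
        else:
            i0, i1 = runs[0]
            ri = post_first + i0
            if cfg.refine:
                ri = _walk_forward_ascending(v, ri, post_first + i1)
            r_day = int(d[ri])
            if r_day > 0:
                boundaries.append((0, r_day - 1, Epoch.POST_OP_RECOVERY))
            # secondary decline: sustained drop below the running plateau level
            t_day = None
            tail = slice(ri, n)
            vt, dt = v[tail], d[tail]
            if len(vt) > 1:
                csum = np.cumsum(vt)
                # expanding mean of epoch-5 values strictly before each day
                em = np.empty_like(vt)
                em[0] = vt[0]
                em[1:] = csum[:-1] / np.arange(1, len(vt))
                cond = vt < em - cfg.epoch6_delta
                cond &= dt >= r_day + cfg.min_epoch5_days
                for (j0, _) in _calendar_runs(cond, dt, cfg.dwell_days):
                    # a secondary decline is sustained, not a transient dip:
                    # it needs a minimum stretch of trailing evidence, and
                    # the average activity from onset onward must also sit
                    # below the pre-onset plateau level
                    if dt[-1] - dt[j0] + 1 < cfg.min_epoch6_days:
                        continue
                    if float(vt[j0:].mean()) >= em[j0] - cfg.epoch6_delta:
                        continue
                    ti = ri + j0
                    if cfg.refine:
                        ti = _walk_back_ascending(v, ti, ri + 1)
                    t_day = max(int(d[ti]), r_day + 1)
                    break
            if t_day is None:
                boundaries.append((r_day, last_day, Epoch.FULLY_RECOVERED))
            else:
                boundaries.append((r_day, t_day - 1, Epoch.FULLY_RECOVERED))
                boundaries.append((t_day, last_day, Epoch.SECONDARY_DECLINE))

    merged: List[Tuple[int, int, Epoch]] = []
    for iv in boundaries:
        if merged and merged[-1][2] == iv[2] and iv[0] == merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], iv[1], iv[2])
        else:
            merged.append(iv)
    return EpochSegmentation(
        patient_id=series.patient_id,
        intervals=merged,
        flags=frozenset(flags),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# the 0.25-SD secondary-decline rule
# ---------------------------------------------------------------------------


def detect_secondary_decline(
    series: NormalizedActivitySeries,
    segmentation: EpochSegmentation,
    threshold_sd: float = 0.25,
    candidate_window_days: int = 60,
) -> DeclineCall:
    """Apply the secondary-decline outcome rule.

    ``depth_sd`` is the drop of mean raw-scale steps-per-day from the
    epoch-5 reference to the lowest trailing candidate window inside epoch 6,
    in units of the baseline-year daily standard deviation.  The comparison
    is inclusive: a drop of exactly ``threshold_sd`` counts as a decline.
    Without a fully-recovered epoch the patient is not declined by
    definition, whatever the trajectory does.
    """
    ep5 = segmentation.intervals_for(Epoch.FULLY_RECOVERED)
    ep6 = segmentation.intervals_for(Epoch.SECONDARY_DECLINE)
    if not ep5 or not ep6:
        return DeclineCall(declined=False, onset_day=None, depth_sd=0.0)

    d, v = series.day_index, series.values

    def mean_norm(intervals: List[Tuple[int, int]]) -> float:
        mask = np.zeros(len(d), dtype=bool)
        for (s, e) in intervals:
            mask |= (d >= s) & (d <= e)
        if not mask.any():
            return math.nan
        return float(v[mask].mean())

    ref = mean_norm(ep5)
    t0, t1 = ep6[0][0], ep6[-1][1]
    in6 = (d >= t0) & (d <= t1)
    d6, v6 = d[in6], v[in6]
    if len(d6) == 0 or math.isnan(ref):
        return DeclineCall(declined=False, onset_day=None, depth_sd=0.0)

    W = candidate_window_days
    if t1 - t0 + 1 <= W:
        lowest = float(v6.mean())
    else:
        lowest = math.inf
        for s_day in d6:
            if s_day + W - 1 > t1:
                break
            sel = (d6 >= s_day) & (d6 <= s_day + W - 1)
            if sel.any():
                lowest = min(lowest, float(v6[sel].mean()))
        if not math.isfinite(lowest):
            lowest = float(v6.mean())

    drop_raw = (ref - lowest) * series.baseline_mean
    if series.baseline_sd > 0:
        depth = drop_raw / series.baseline_sd
    else:
        depth = math.inf if drop_raw > 0 else 0.0
    depth = max(depth, 0.0)
    declined = depth >= threshold_sd
    return DeclineCall(
        declined=declined,
        onset_day=int(t0) if declined else None,
        depth_sd=depth,
    )


def epoch_durations(segmentation: EpochSegmentation) -> Dict[int, int]:
    """Cumulative calendar days spent in each epoch (absent epochs map to 0)."""
    out: Dict[int, int] = {int(label): 0 for label in Epoch}
    for (s, e, label) in segmentation.intervals:
        out[int(label)] += e - s + 1
    return out
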