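"""Synthetic peri-operative step-count cohorts with known ground truth.

The generator inverts the epoch structure the analysis assumes: each
patient's expected daily activity is a piecewise-linear curve over the
four-year window around surgery — a flat baseline, a linear pre-operative
decline to a nadir at the surgery day (optionally interrupted by a transient
spontaneous-recovery bump), a linear post-operative recovery to a plateau
near baseline, and optionally a late secondary decline whose depth is
expressed in units of the baseline daily standard deviation.  Daily counts
are drawn from a negative-binomial distribution around that curve (real step
data are strongly overdispersed), and days are dropped completely at random
to emulate non-wear gaps.

Every trajectory carries a :class:`GroundTruth` recording the generative
epoch boundaries and decline label, so downstream segmentation and
classification can be scored against truth.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .epochs import Epoch, WINDOW_POST_DAYS, WINDOW_PRE_DAYS
from .preprocess import DailyStepSeries

#: Day grid of the simulated window: day 0 is the surgery day (post-op side).
DAY_GRID = np.arange(-WINDOW_PRE_DAYS, WINDOW_POST_DAYS)

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


# ---------------------------------------------------------------------------
# Trajectory parameters and ground truth
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SpontaneousRecovery:
    """A transient pre-operative recovery back toward baseline.

    The expected curve rises linearly from the decline line at ``start_day``
    to ``peak_fraction`` of baseline, holds that level for a stretch
    (spontaneous remissions last weeks, they are not spikes), then falls
    back and rejoins the decline line after ``length_days``.  ``rise`` and
    ``top`` fractions split the bump; the remainder is the fall.
    """

    start_day: int
    peak_fraction: float
    length_days: int = 80
    rise_fraction: float = 0.4
    top_fraction: float = 0.3


@dataclasses.dataclass(frozen=True)
class SecondaryDecline:
    """A late drop below the recovered plateau, ramping over ``ramp_days``.

    ``depth_sd`` is the asymptotic drop of expected steps-per-day in units of
    the baseline daily standard deviation — the same scale the outcome rule
    uses.
    """

    onset_day: int
    depth_sd: float
    ramp_days: int = 30


@dataclasses.dataclass(frozen=True)
class TrajectoryParams:
    """Generative parameters for one patient trajectory."""

    baseline_mean: float = 5000.0
    noise_dispersion: float = 0.09
    missing_rate: float = 0.10
    decline_onset_day: int = -250
    pre_op_nadir_fraction: float = 0.5
    spontaneous_recovery: Optional[SpontaneousRecovery] = None
    recovery_length_days: int = 180
    plateau_fraction: float = 1.02
    secondary_decline: Optional[SecondaryDecline] = None
    weekly_amplitude: float = 0.0
    #: normalized activity level that counts as "fully recovered" when the
    #: ground truth is laid down; a plateau below it means the patient never
    #: regains baseline mobility and therefore cannot secondarily decline
    recovery_threshold: float = 0.95

    def validate(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not -WINDOW_PRE_DAYS < self.decline_onset_day < 0:
            raise ValueError(
                "ordering violated: decline_onset_day must fall strictly "
                "between the window start and the surgery day"
            )
        if not 0 < self.pre_op_nadir_fraction <= 1:
            raise ValueError("pre_op_nadir_fraction must lie in (0, 1]")
        if not 0 < self.recovery_length_days < WINDOW_POST_DAYS:
            raise ValueError("recovery_length_days must lie in (0, window)")
        if self.plateau_fraction <= 0:
            raise ValueError("plateau_fraction must be > 0")
        if not 0 <= self.weekly_amplitude < 1:
            raise ValueError("weekly_amplitude must lie in [0, 1)")
        sr = self.spontaneous_recovery
        if sr is not None:
            if sr.start_day <= self.decline_onset_day:
                raise ValueError(
                    "ordering violated: spontaneous recovery must start after "
                    "the pre-operative decline onset"
                )
            if sr.start_day + sr.length_days > -1:
                raise ValueError(
                    "ordering violated: spontaneous recovery must end before "
                    "the surgery day"
                )
            if not 0 < sr.peak_fraction <= 1.5 or sr.length_days < 2:
                raise ValueError("spontaneous recovery shape is invalid")
        sd = self.secondary_decline
        if sd is not None:
            if self.plateau_fraction < self.recovery_threshold:
                raise ValueError(
                    "ordering violated: a secondary decline requires a prior "
                    "complete recovery (plateau below the recovery threshold)"
                )
            if sd.onset_day <= self.recovery_length_days:
                raise ValueError(
                    "ordering violated: secondary decline must begin after the "
                    "post-operative recovery completes"
                )
            if sd.onset_day >= WINDOW_POST_DAYS:
                raise ValueError("secondary decline onset is outside the window")
            if sd.depth_sd < 0:
                raise ValueError("secondary decline depth_sd must be >= 0")

    @property
    def daily_cv(self) -> float:
        """Analytic coefficient of variation of baseline daily counts.

        For negative-binomial counts with mean mu and variance
        ``mu * (1 + alpha * mu)`` the CV is ``sqrt(1/mu + alpha)``; the
        noise-free limit (``alpha = 0``) degenerates to the Poisson CV.
        """
        return math.sqrt(1.0 / self.baseline_mean + self.noise_dispersion)

    @property
    def baseline_daily_sd(self) -> float:
        """Analytic SD of baseline daily counts, in steps/day."""
        return self.baseline_mean * self.daily_cv


@dataclasses.dataclass
class GroundTruth:
    """Generative truth for one trajectory: epoch intervals and the label."""

    intervals: List[Tuple[int, int, Epoch]]
    decline_label: bool
    decline_depth_sd: float

    @property
    def epoch_boundaries(self) -> np.ndarray:
        """Ordered interior boundary days (start day of each epoch after the first)."""
        return np.array([start for start, _, _ in self.intervals[1:]], dtype=int)

    def interval_for(self, label: Epoch) -> List[Tuple[int, int]]:
        return [(s, e) for s, e, lab in self.intervals if lab == label]


# ---------------------------------------------------------------------------
# Expected activity curve
# ---------------------------------------------------------------------------


def mean_curve(params: TrajectoryParams) -> np.ndarray:
    """Expected activity on ``DAY_GRID`` in units of the baseline mean."""
    params.validate()
    d = DAY_GRID.astype(float)
    m = np.ones_like(d)

    onset = params.decline_onset_day
    nadir = params.pre_op_nadir_fraction
    pre = (DAY_GRID >= onset) & (DAY_GRID < 0)
    # linear decline reaching the nadir on the surgery day
    m[pre] = 1.0 + (nadir - 1.0) * (d[pre] - onset) / (0.0 - onset)

    sr = params.spontaneous_recovery
    if sr is not None:
        s = sr.start_day
        e = s + sr.length_days
        rise_end = s + max(1, int(round(sr.rise_fraction * sr.length_days)))
        top_end = rise_end + max(
            1, int(round(sr.top_fraction * sr.length_days))
        )
        top_end = min(top_end, e - 1)
        line = 1.0 + (nadir - 1.0) * (d - onset) / (0.0 - onset)
        l_s = float(line[DAY_GRID == s][0])
        l_e = float(line[DAY_GRID == e][0])
        bump = np.full_like(d, -np.inf)
        up = (DAY_GRID >= s) & (DAY_GRID <= rise_end)
        bump[up] = l_s + (sr.peak_fraction - l_s) * (d[up] - s) / (rise_end - s)
        flat = (DAY_GRID > rise_end) & (DAY_GRID <= top_end)
        bump[flat] = sr.peak_fraction
        down = (DAY_GRID > top_end) & (DAY_GRID <= e)
        bump[down] = sr.peak_fraction + (l_e - sr.peak_fraction) * (
            d[down] - top_end
        ) / (e - top_end)
        in_bump = (DAY_GRID >= s) & (DAY_GRID <= e) & pre
        m[in_bump] = np.maximum(m[in_bump], bump[in_bump])

    R = params.recovery_length_days
    plateau = params.plateau_fraction
    post_ramp = (DAY_GRID >= 0) & (DAY_GRID < R)
    m[post_ramp] = nadir + (plateau - nadir) * d[post_ramp] / R
    m[DAY_GRID >= R] = plateau

    sd = params.secondary_decline
    if sd is not None:
        depth_norm = sd.depth_sd * params.daily_cv
        after = DAY_GRID >= sd.onset_day
        frac = np.clip((d[after] - sd.onset_day) / max(sd.ramp_days, 1), 0.0, 1.0)
        m[after] = plateau - depth_norm * frac

    return np.clip(m, 0.0, None)


def _truth_intervals(params: TrajectoryParams) -> List[Tuple[int, int, Epoch]]:
    onset = params.decline_onset_day
    end = WINDOW_POST_DAYS - 1
    R = params.recovery_length_days
    intervals: List[Tuple[int, int, Epoch]] = [
        (-WINDOW_PRE_DAYS, onset - 1, Epoch.BASELINE)
    ]
    sr = params.spontaneous_recovery
    if sr is None:
        intervals.append((onset, -1, Epoch.PRE_OP_DECLINE))
    else:
        s, e = sr.start_day, sr.start_day + sr.length_days - 1
        if s > onset:
            intervals.append((onset, s - 1, Epoch.PRE_OP_DECLINE))
        intervals.append((s, e, Epoch.SPONTANEOUS_RECOVERY))
        if e + 1 <= -1:
            intervals.append((e + 1, -1, Epoch.PRE_OP_DECLINE))
    if params.plateau_fraction < params.recovery_threshold:
        # the patient never regains baseline mobility: the post-operative
        # side is one long (incomplete) recovery and no decline can follow
        intervals.append((0, end, Epoch.POST_OP_RECOVERY))
        return intervals
    intervals.append((0, R - 1, Epoch.POST_OP_RECOVERY))
    sd = params.secondary_decline
    if sd is None:
        intervals.append((R, end, Epoch.FULLY_RECOVERED))
    else:
        intervals.append((R, sd.onset_day - 1, Epoch.FULLY_RECOVERED))
        intervals.append((sd.onset_day, end, Epoch.SECONDARY_DECLINE))
    return intervals


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------


def simulate_trajectory(
    params: TrajectoryParams,
    seed: SeedLike,
    patient_id: str = "P000",
    surgery_date: datetime.date = datetime.date(2018, 1, 3),
    outcome_threshold_sd: float = 0.25,
) -> Tuple[DailyStepSeries, GroundTruth]:
    """Simulate one patient's daily step counts and the generative truth.

    Counts are negative-binomial around the piecewise expected curve with
    variance ``mu * (1 + alpha * mu)``; ``noise_dispersion == 0`` yields the
    deterministic (rounded) curve itself.  Days are then dropped
    independently at ``missing_rate``.  Identical ``(params, seed)``
    reproduce the series exactly.
    """
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = mean_curve(params)

    dates = pd.Timestamp(surgery_date) + pd.to_timedelta(DAY_GRID, unit="D")
    if params.weekly_amplitude > 0:
        a = params.weekly_amplitude
        weekend = dates.weekday >= 5
        mod = np.where(weekend, 1.0 + a, 1.0 - 2.0 * a / 5.0)
    else:
        mod = 1.0
    mean_steps = np.clip(params.baseline_mean * m * mod, 0.0, None)

    alpha = params.noise_dispersion
    if alpha > 0:
        size = 1.0 / alpha
        p = size / (size + mean_steps)
        counts = rng.negative_binomial(size, p)
    else:
        counts = np.rint(mean_steps).astype(np.int64)

    keep = rng.random(len(DAY_GRID)) >= params.missing_rate
    series = DailyStepSeries(
        patient_id=patient_id,
        surgery_date=surgery_date,
        data=pd.Series(counts[keep].astype(np.int64), index=dates[keep]),
    )
    sd = params.secondary_decline
    depth = sd.depth_sd if sd is not None else 0.0
    truth = GroundTruth(
        intervals=_truth_intervals(params),
        decline_label=sd is not None and sd.depth_sd >= outcome_threshold_sd,
        decline_depth_sd=depth,
    )
    return series, truth


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Covariates:
    """Clinical covariates attached to each synthetic patient."""

    age_years: int
    bmi: float
    sex: str
    surgery_type: str
    operated_levels: int


@dataclasses.dataclass(frozen=True)
class CovariateConfig:
    """Binned marginal distributions for covariates.

    Defaults emulate a lumbar-surgery cohort: ages concentrated in the
    seventh decade (mean near 61), BMI centred near 28-29, a mix of fusion,
    decompression and other procedures, and mostly one- to three-level
    surgeries.  Each ``*_bins`` entry is ``((low, high), probability)`` with
    probabilities summing to 1 per variable.
    """

    age_bins: Tuple[Tuple[Tuple[int, int], float], ...] = (
        ((28, 50), 13 / 69),
        ((51, 60), 14 / 69),
        ((61, 70), 24 / 69),
        ((71, 80), 16 / 69),
        ((81, 90), 2 / 69),
    )
    bmi_bins: Tuple[Tuple[Tuple[float, float], float], ...] = (
        ((16.0, 20.0), 2 / 68),
        ((20.0, 25.0), 21 / 68),
        ((25.0, 30.0), 20 / 68),
        ((30.0, 35.0), 17 / 68),
        ((35.0, 40.0), 4 / 68),
        ((40.0, 46.0), 4 / 68),
    )
    sex_probs: Tuple[Tuple[str, float], ...] = (("male", 0.42), ("female", 0.58))
    surgery_type_probs: Tuple[Tuple[str, float], ...] = (
        ("lumbar_fusion", 34 / 75),
        ("lumbar_decompression", 28 / 75),
        ("other", 13 / 75),
    )
    levels_probs: Tuple[Tuple[int, float], ...] = (
        (1, 36 / 66),
        (2, 12 / 66),
        (3, 16 / 66),
        (4, 2 / 66),
    )

    def validate(self) -> None:
        for name, probs in (
            ("age_bins", [p for _, p in self.age_bins]),
            ("bmi_bins", [p for _, p in self.bmi_bins]),
            ("sex_probs", [p for _, p in self.sex_probs]),
            ("surgery_type_probs", [p for _, p in self.surgery_type_probs]),
            ("levels_probs", [p for _, p in self.levels_probs]),
        ):
            total = float(sum(probs))
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")


def sample_covariates(config: CovariateConfig, seed: SeedLike) -> Covariates:
    """Draw one covariate vector respecting the configured bin frequencies."""
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def pick(bins):
        probs = np.array([p for _, p in bins])
        idx = rng.choice(len(bins), p=probs / probs.sum())
        return bins[idx][0]

    age_lo, age_hi = pick(config.age_bins)
    age = int(rng.integers(age_lo, age_hi + 1))
    bmi_lo, bmi_hi = pick(config.bmi_bins)
    bmi = float(rng.uniform(bmi_lo, bmi_hi))
    sex_labels, sex_p = zip(*config.sex_probs)
    sex = str(sex_labels[rng.choice(len(sex_labels), p=np.array(sex_p) / sum(sex_p))])
    st_labels, st_p = zip(*config.surgery_type_probs)
    surgery = str(st_labels[rng.choice(len(st_labels), p=np.array(st_p) / sum(st_p))])
    lv_labels, lv_p = zip(*config.levels_probs)
    levels = int(lv_labels[rng.choice(len(lv_labels), p=np.array(lv_p) / sum(lv_p))])
    return Covariates(age, bmi, sex, surgery, levels)


# ---------------------------------------------------------------------------
# Cohort-level simulation
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Distributions over trajectory parameters and covariates for a cohort.

    The defaults target the epoch-duration and prevalence scales of a
    lumbar-surgery mobility cohort: roughly a third of patients suffer a
    secondary decline, pre-operative deterioration averages about 250 days,
    and decliners tend to have recovered faster than non-decliners
    (``recovery_gap_days`` plants that dependence, the signal the classifiers
    are meant to learn).
    """

    prevalence: float = 0.347
    baseline_mean_range: Tuple[float, float] = (3000.0, 9000.0)
    noise_dispersion: float = 0.09
    missing_rate_range: Tuple[float, float] = (0.05, 0.20)
    decline_onset_range: Tuple[int, int] = (-420, -140)
    nadir_range: Tuple[float, float] = (0.35, 0.65)
    spontaneous_prob: float = 0.4
    spontaneous_length_range: Tuple[int, int] = (60, 110)
    spontaneous_peak_range: Tuple[float, float] = (0.97, 1.05)
    spontaneous_max_level: float = 0.85
    recovery_mean_days: float = 240.0
    recovery_sd_days: float = 50.0
    recovery_gap_days: float = 120.0
    recovery_sd_decliner_days: float = 40.0
    recovery_bounds: Tuple[int, int] = (30, 400)
    plateau_mean: float = 1.00
    plateau_sd: float = 0.053
    plateau_bounds: Tuple[float, float] = (0.85, 1.15)
    decliner_plateau_min: float = 0.96
    secondary_delay_range: Tuple[int, int] = (120, 360)
    secondary_onset_max: int = 560
    depth_sd_range: Tuple[float, float] = (0.5, 1.5)
    weekly_amplitude: float = 0.0
    outcome_threshold_sd: float = 0.25
    covariates: CovariateConfig = dataclasses.field(default_factory=CovariateConfig)

    @classmethod
    def low_noise(cls) -> "CohortConfig":
        """Favourable recovery conditions: mild overdispersion, few gaps,
        deep declines — used for parameter-recovery experiments."""
        return cls(
            noise_dispersion=0.05,
            missing_rate_range=(0.03, 0.07),
            depth_sd_range=(1.0, 2.0),
        )

    @classmethod
    def noise_free(cls) -> "CohortConfig":
        """Deterministic trajectories (expected curve only, no gaps).

        With no count noise the baseline SD degenerates toward the Poisson
        scale, so decline depths are given in larger nominal SD units to keep
        the injected drops visible (about 0.2-0.4 of baseline).
        """
        return cls(
            noise_dispersion=0.0,
            missing_rate_range=(0.0, 0.0),
            depth_sd_range=(18.0, 28.0),
        )


@dataclasses.dataclass
class CohortPatient:
    """One simulated patient: the series, its truth, and covariates."""

    series: DailyStepSeries
    truth: GroundTruth
    covariates: Covariates
    params: TrajectoryParams


def _draw_params(config: CohortConfig, rng: np.random.Generator) -> TrajectoryParams:
    declines = bool(rng.random() < config.prevalence)
    onset = int(rng.integers(config.decline_onset_range[0], config.decline_onset_range[1] + 1))
    nadir = float(rng.uniform(*config.nadir_range))

    spont = None
    if rng.random() < config.spontaneous_prob:
        length = int(rng.integers(*config.spontaneous_length_range))
        # place the bump only after the decline line has dropped below
        # spontaneous_max_level, so recoveries follow meaningful declines
        frac = (1.0 - config.spontaneous_max_level) / (1.0 - nadir)
        s_min = onset + int(math.ceil(frac * (-onset)))
        s_max = -15 - length
        if s_min < s_max:
            start = int(rng.integers(s_min, s_max + 1))
            peak = float(rng.uniform(*config.spontaneous_peak_range))
            spont = SpontaneousRecovery(start, peak, length)

    if declines:
        mean_r = config.recovery_mean_days - config.recovery_gap_days
        sd_r = config.recovery_sd_decliner_days
    else:
        mean_r = config.recovery_mean_days
        sd_r = config.recovery_sd_days
    recovery = int(np.clip(round(rng.normal(mean_r, sd_r)), *config.recovery_bounds))

    plateau = float(
        np.clip(rng.normal(config.plateau_mean, config.plateau_sd), *config.plateau_bounds)
    )
    secondary = None
    if declines:
        plateau = max(plateau, config.decliner_plateau_min)
        delay = int(rng.integers(*config.secondary_delay_range))
        onset6 = min(recovery + delay, config.secondary_onset_max)
        depth = float(rng.uniform(*config.depth_sd_range))
        secondary = SecondaryDecline(onset6, depth)

    return TrajectoryParams(
        baseline_mean=float(rng.uniform(*config.baseline_mean_range)),
        noise_dispersion=config.noise_dispersion,
        missing_rate=float(rng.uniform(*config.missing_rate_range)),
        decline_onset_day=onset,
        pre_op_nadir_fraction=nadir,
        spontaneous_recovery=spont,
        recovery_length_days=recovery,
        plateau_fraction=plateau,
        secondary_decline=secondary,
        weekly_amplitude=config.weekly_amplitude,
    )


def simulate_cohort(
    n: int, config: Optional[CohortConfig] = None, seed: SeedLike = 0
) -> List[CohortPatient]:
    """Simulate ``n`` independent patients.

    Per-patient randomness comes from children of a single master
    ``SeedSequence`` (one spawn per patient, split again into parameter,
    covariate and trajectory streams), so cohorts are reproducible
    patient-by-patient and adding patients never perturbs earlier ones.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or CohortConfig()
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    patients: List[CohortPatient] = []
    for i, child in enumerate(root.spawn(n)):
        ss_params, ss_cov, ss_traj = child.spawn(3)
        rng_params = np.random.default_rng(ss_params)
        params = _draw_params(config, rng_params)
        rng_cov = np.random.default_rng(ss_cov)
        covariates = sample_covariates(config.covariates, rng_cov)
        surgery = datetime.date(2015, 1, 1) + datetime.timedelta(
            days=int(rng_cov.integers(0, 5 * 365))
        )
        series, truth = simulate_trajectory(
            params,
            ss_traj,
            patient_id=f"P{i:04d}",
            surgery_date=surgery,
            outcome_threshold_sd=config.outcome_threshold_sd,
        )
        patients.append(CohortPatient(series, truth, covariates, params))
    return patients


def write_cohort(patients: Sequence[CohortPatient], outdir) -> None:
    """Write per-patient step CSVs plus manifest and ground-truth tables."""
    from pathlib import Path

    from .preprocess import write_steps_csv

    outdir = Path(outdir)
    (outdir / "steps").mkdir(parents=True, exist_ok=True)
    manifest, truth_rows = [], []
    for p in patients:
        write_steps_csv(p.series, outdir / "steps" / f"{p.series.patient_id}.csv")
        manifest.append(
            {
                "patient_id": p.series.patient_id,
                "surgery_date": p.series.surgery_date.isoformat(),
                "age": p.covariates.age_years,
                "bmi": round(p.covariates.bmi, 2),
                "sex": p.covariates.sex,
                "surgery_type": p.covariates.surgery_type,
                "levels": p.covariates.operated_levels,
            }
        )
        truth_rows.append(
            {
                "patient_id": p.series.patient_id,
                "decline_label": int(p.truth.decline_label),
                "decline_depth_sd": p.truth.decline_depth_sd,
                "boundaries": ";".join(str(b) for b in p.truth.epoch_boundaries),
            }
        )
    pd.DataFrame(manifest).to_csv(outdir / "manifest.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.csv", index=False)
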