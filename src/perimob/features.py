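"""Per-patient modeling features: epoch durations, derivatives, covariates.

For each epoch the feature set carries its cumulative duration, the
least-squares slope of the smoothed activity against day (the 1st
derivative of the trajectory), the least-squares slope of the
first-differenced activity (the 2nd derivative), and a presence indicator
so that missing epochs stay encoded as zeros in a rectangular table.

Epoch-6 quantities are never predictors: the outcome label is defined on
that epoch.  The default ``pre_recovery`` policy goes further and also
excludes epoch 5, since the label is a statement about activity after full
recovery; the ``with_recovery`` policy includes epoch 5 for users who
accept that circularity in exchange for the full activity-parameter set.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .epochs import Epoch
from .preprocess import NormalizedActivitySeries
from .segment import EpochSegmentation
from .simulate import Covariates

#: epochs admitted as predictors under each leakage policy
POLICY_EPOCHS: Dict[str, Tuple[int, ...]] = {
    "pre_recovery": (1, 2, 3, 4),
    "with_recovery": (1, 2, 3, 4, 5),
}


@dataclasses.dataclass(frozen=True)
class EpochDerivatives:
    """1st/2nd-derivative summaries of one epoch's smoothed activity."""

    slope: float  # normalized activity units per day
    curvature: float  # units per day^2
    present: bool


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom <= 0:
        return 0.0
    return float(xc @ (y - y.mean())) / denom


def derivative_features(
    series: NormalizedActivitySeries, segmentation: EpochSegmentation
) -> Dict[int, EpochDerivatives]:
    """Slope and curvature of the smoothed activity within each epoch.

    The slope is the OLS regression slope of value on day over the epoch's
    merged intervals (robust to missing days); the curvature is the OLS
    slope of the day-to-day finite differences against their midpoints,
    which on a noise-free quadratic ``a * t**2`` recovers ``2a`` exactly.
    Epochs with fewer than 3 recorded days yield zeros with
    ``present=False``.
    """
    d = series.day_index
    v = series.values
    out: Dict[int, EpochDerivatives] = {}
    for label in Epoch:
        mask = np.zeros(len(d), dtype=bool)
        for (s, e) in segmentation.intervals_for(label):
            mask |= (d >= s) & (d <= e)
        dd, vv = d[mask].astype(float), v[mask]
        if len(dd) < 3:
            out[int(label)] = EpochDerivatives(0.0, 0.0, False)
            continue
        slope = _ols_slope(dd, vv)
        diffs = np.diff(vv) / np.diff(dd)
        mids = (dd[:-1] + dd[1:]) / 2.0
        curvature = _ols_slope(mids, diffs) if len(diffs) >= 2 else 0.0
        out[int(label)] = EpochDerivatives(slope, curvature, True)
    return out


@dataclasses.dataclass
class PatientFeatureVector:
    """One row of the modeling table plus its label."""

    patient_id: str
    features: Dict[str, float]
    label: bool


def feature_names(policy: str = "pre_recovery") -> List[str]:
    """Canonical ordered feature names for a leakage policy."""
    if policy not in POLICY_EPOCHS:
        raise ValueError(f"unknown leakage policy {policy!r}")
    names: List[str] = []
    for k in POLICY_EPOCHS[policy]:
        names += [
            f"duration_epoch_{k}",
            f"slope_epoch_{k}",
            f"curvature_epoch_{k}",
            f"present_epoch_{k}",
        ]
    names += ["age_years", "bmi"]
    return names


def build_feature_vector(
    durations: Dict[int, int],
    derivatives: Dict[int, EpochDerivatives],
    covariates: Covariates,
    label: bool,
    policy: str = "pre_recovery",
    patient_id: str = "patient",
) -> PatientFeatureVector:
    """Assemble one patient's features under a leakage policy.

    Raises if age or BMI is missing; epoch-6 fields are refused under every
    policy.
    """
    if covariates.age_years is None or covariates.bmi is None:
        raise ValueError("covariates must include age and BMI")
    feats: Dict[str, float] = {}
    for k in POLICY_EPOCHS[policy]:
        der = derivatives.get(k, EpochDerivatives(0.0, 0.0, False))
        feats[f"duration_epoch_{k}"] = float(durations.get(k, 0))
        feats[f"slope_epoch_{k}"] = der.slope if der.present else 0.0
        feats[f"curvature_epoch_{k}"] = der.curvature if der.present else 0.0
        feats[f"present_epoch_{k}"] = float(der.present)
    feats["age_years"] = float(covariates.age_years)
    feats["bmi"] = float(covariates.bmi)
    assert not any("epoch_6" in name for name in feats), "epoch 6 must not leak"
    return PatientFeatureVector(patient_id=patient_id, features=feats, label=bool(label))


def assemble_design_matrix(
    vectors: Sequence[PatientFeatureVector],
    policy: Optional[str] = None,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Stack feature vectors into an aligned (X, y) pair.

    Rows are keyed and sorted by patient id, so the table is invariant to
    input order; the column order is the canonical policy order.  Training
    is undefined on a single-class cohort, which raises.
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 patients to build a design matrix")
    policy = policy or _infer_policy(vectors[0])
    cols = feature_names(policy)
    rows = {vec.patient_id: [vec.features[c] for c in cols] for vec in vectors}
    X = pd.DataFrame.from_dict(rows, orient="index", columns=cols).sort_index()
    y = pd.Series(
        {vec.patient_id: vec.label for vec in vectors}, name="secondary_decline"
    ).sort_index()
    if y.nunique() < 2:
        raise ValueError(
            "cohort contains a single outcome class; classification is "
            "undefined — simulate or collect a mixed cohort"
        )
    return X, y.astype(int)


def _infer_policy(vec: PatientFeatureVector) -> str:
    for policy in POLICY_EPOCHS:
        if set(feature_names(policy)) == set(vec.features):
            return policy
    raise ValueError("feature vector does not match a known leakage policy")
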