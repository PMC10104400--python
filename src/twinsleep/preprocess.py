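"""Night/subject filtering, aggregation, standardisation and residualisation.

Implements the quality-control and covariate-adjustment chain applied before
any twin modelling: nights with missing device data or gross (> 6 h)
diary/device disparities are dropped, subjects must retain at least seven of
the fourteen study nights, nightly records are averaged to subject level
(overall and separately for school and nonschool nights), phenotypes are
z-scored with outliers winsorised at |z| > 3.29 and removed at |z| > 4.00,
and age and sex are regressed out so the genetic models see residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "FilterParams",
    "OutlierParams",
    "filter_nights",
    "aggregate_subject",
    "standardize_winsorize",
    "residualize",
]

PHENOTYPES = ("onset", "wake", "midpoint", "duration", "restorative")


@dataclass(frozen=True)
class FilterParams:
    """Night- and subject-level exclusion thresholds."""

    max_disparity_hours: float = 6.0
    min_nights: int = 7
    study_nights: int = 14

    def __post_init__(self):
        if self.min_nights > self.study_nights:
            raise ValueError("min_nights cannot exceed study_nights")


@dataclass(frozen=True)
class OutlierParams:
    """z-score thresholds: winsorise moderate outliers, remove extreme ones."""

    winsorize_z: float = 3.29
    remove_z: float = 4.00

    def __post_init__(self):
        if not self.winsorize_z < self.remove_z:
            raise ValueError("winsorize_z must be below remove_z")


def filter_nights(
    nights: pd.DataFrame, params: FilterParams = FilterParams()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop unusable nights, then subjects with too few retained nights.

    A night is dropped when its device data are missing or when the device
    onset and diary bedtime disagree by more than ``max_disparity_hours``
    (a disparity of exactly the threshold is retained).  Subjects with fewer
    than ``min_nights`` surviving nights are then removed entirely.  Returns
    the retained nights and an exclusion log with one reason-coded row per
    dropped night or subject.
    """
    df = nights.copy()
    log_rows = []

    missing = df["device_onset"].isna() | df["device_wake"].isna()
    disparity = (
        (df["device_onset"] - df["diary_bed"]).abs()
        > params.max_disparity_hours * 60.0
    ) & ~missing
    for mask, reason in ((missing, "missing_device"), (disparity, "extreme_disparity")):
        for _, row in df[mask].iterrows():
            log_rows.append((row["subject_id"], row["night_index"], reason))
    df = df[~(missing | disparity)]

    counts = df.groupby("subject_id")["night_index"].size()
    too_few = counts[counts < params.min_nights].index
    for sid in too_few:
        log_rows.append((sid, np.nan, "too_few_nights"))
    df = df[~df["subject_id"].isin(too_few)]

    log = pd.DataFrame(log_rows, columns=["subject_id", "night_index", "reason"])
    return df.reset_index(drop=True), log


def aggregate_subject(
    nights: pd.DataFrame, night_type: str = "all"
) -> pd.DataFrame:
    """Subject-level phenotype means for the requested night scope.

    ``night_type`` is ``all``, ``school`` or ``nonschool``.  Timing
    phenotypes are arithmetic means on the continuous minutes axis;
    restorative sleep becomes the percentage of nights coded refreshed.
    Subjects with no nights of the requested type get missing values (and
    are absent from the output).
    """
    if night_type not in ("all", "school", "nonschool"):
        raise ValueError(f"unknown night_type {night_type!r}")
    df = nights if night_type == "all" else nights[nights["night_type"] == night_type]
    if "midpoint" not in df.columns:
        df = df.assign(midpoint=(df["device_onset"] + df["device_wake"]) / 2.0)
    agg = df.groupby("subject_id").agg(
        family_id=("family_id", "first"),
        zygosity=("zygosity", "first"),
        twin_order=("twin_order", "first"),
        age=("age", "first"),
        sex=("sex", "first"),
        n_nights=("night_index", "size"),
        onset=("device_onset", "mean"),
        wake=("device_wake", "mean"),
        midpoint=("midpoint", "mean"),
        duration=("duration", "mean"),
        restorative=("restorative", "mean"),
    )
    agg["restorative"] = 100.0 * agg["restorative"]
    return agg.reset_index()


def standardize_winsorize(
    values: pd.Series | np.ndarray,
    params: OutlierParams = OutlierParams(),
) -> pd.Series:
    """z-score a phenotype, removing then winsorising outliers.

    z-scores use the mean and SD over available (non-missing) subjects.
    Values beyond ``remove_z`` in absolute value are set missing; surviving
    values beyond ``winsorize_z`` are pulled in to the threshold.  The
    z-scores are not recomputed after removal, so the transform is a single
    deterministic pass (and idempotent up to the removed entries).
    """
    s = pd.Series(np.asarray(values, dtype=float)) if not isinstance(values, pd.Series) else values.astype(float)
    obs = s.dropna()
    if len(obs) < 3:
        raise ValueError("need at least 3 non-missing values to standardise")
    sd = obs.std(ddof=1)
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("zero variance: cannot z-score")
    z = (s - obs.mean()) / sd
    z = z.mask(z.abs() > params.remove_z)
    return z.clip(-params.winsorize_z, params.winsorize_z)


def residualize(
    data: pd.DataFrame,
    phenotype: str,
    age_col: str = "age",
    sex_col: str = "sex",
) -> tuple[pd.Series, dict]:
    """OLS residuals of a phenotype after age and sex.

    Fits ``phenotype ~ age + male`` by ordinary least squares over subjects
    with complete covariates, ignoring family clustering (a fixed-effect
    screen; the familial covariance is modelled downstream).  Returns the
    residuals (aligned to the input index, missing where the phenotype is)
    and a coefficient report with the per-year age slope and the male-female
    contrast in the phenotype's units.
    """
    y = data[phenotype].astype(float)
    male = (data[sex_col] == "M").astype(float)
    X = pd.DataFrame({"age": data[age_col].astype(float), "male": male})
    if X.isna().any().any():
        raise ValueError("covariates must be complete for included subjects")
    keep = y.notna()
    X_obs = sm.add_constant(X[keep])
    if np.linalg.matrix_rank(X_obs.to_numpy()) < X_obs.shape[1]:
        raise ValueError("rank-deficient design (constant age or sex)")
    fit = sm.OLS(y[keep], X_obs).fit()
    resid = pd.Series(np.nan, index=data.index)
    resid[keep] = fit.resid
    report = {
        "age_slope": float(fit.params["age"]),
        "age_slope_se": float(fit.bse["age"]),
        "sex_contrast": float(fit.params["male"]),
        "sex_contrast_se": float(fit.bse["male"]),
        "n": int(keep.sum()),
    }
    return resid, report
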