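"""Synthetic twin cohorts, night-level sleep records, and raw arm-angle traces.

The generators in this module produce data with the statistical structure the
downstream analysis assumes, so the whole pipeline is testable without access
to raw twin data:

* ``simulate_ace_pairs`` draws pair-level phenotypes under the classical twin
  (ACE) model, in which additive-genetic influences correlate 1.0 within
  monozygotic (MZ) and 0.5 within dizygotic (DZ) pairs, shared-environment
  influences correlate 1.0 in both, and unique-environment influences are
  uncorrelated.
* ``simulate_bivariate_cholesky`` draws two phenotypes per person whose
  within- and cross-twin covariance follows triangular A/C/E path matrices.
* ``simulate_night_records`` layers a night-level observation model on top:
  subject latents from the ACE generator, fixed age/sex effects, a
  school-vs-nonschool shift, nightly noise, missing nights and occasional
  gross diary/device disparities.
* ``simulate_angle_series`` emits a 5-second-epoch arm-angle trace for one
  night, stable (sub-threshold epoch-to-epoch change) during true sleep, with
  ground truth stored alongside so detector accuracy can be measured.

All clock quantities are minutes on the continuous minutes-from-noon axis
(see ``twinsleep._clock``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._clock import from_clock

__all__ = [
    "ConfigurationError",
    "NightModel",
    "BivariatePaths",
    "SimConfig",
    "AngleSimParams",
    "AngleSeries",
    "make_cohort",
    "draw_ace_latents",
    "simulate_ace_pairs",
    "simulate_bivariate_cholesky",
    "simulate_night_records",
    "simulate_angle_series",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20211022

EPOCH_SECONDS = 5.0
EPOCH_MINUTES = EPOCH_SECONDS / 60.0


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class NightModel:
    """Observation model for one nightly phenotype.

    Timing phenotypes are in minutes from noon; ``restorative`` uses
    probability units for ``mean``/``school_shift``/``age_slope``/``sex_effect``
    and a logit-scale latent.

    Parameters
    ----------
    mean
        Population mean at the reference age (midpoint of the cohort range).
    sd
        Between-subject SD of the familial (ACE) latent.
    school_shift
        Added on nonschool nights (nonschool minus school contrast).
    age_slope
        Fixed effect per year of age.
    sex_effect
        Fixed effect for males relative to females.
    night_sd
        SD of independent night-to-night noise around the subject mean.
    """

    mean: float
    sd: float
    school_shift: float = 0.0
    age_slope: float = 0.0
    sex_effect: float = 0.0
    night_sd: float = 0.0

    def __post_init__(self):
        if self.sd <= 0:
            raise ConfigurationError("NightModel sd must be > 0")
        if self.night_sd < 0:
            raise ConfigurationError("NightModel night_sd must be >= 0")


def _default_night_model() -> dict[str, NightModel]:
    # Anchored at a 9-17-year cohort: onset ~21:51 +/- 1:00, wake ~06:46
    # +/- 0:42, nonschool delays of 25 and 15 min, age delays of 14 and
    # 6 min/yr, duration ~15 min shorter for males (carried on wake), and
    # restorative sleep on ~44% of nights.
    return {
        "onset": NightModel(
            mean=from_clock("21:51"), sd=50.0, school_shift=25.0,
            age_slope=14.0, sex_effect=0.0, night_sd=45.0,
        ),
        "wake": NightModel(
            mean=from_clock("06:46"), sd=36.0, school_shift=15.0,
            age_slope=6.0, sex_effect=-15.0, night_sd=40.0,
        ),
        "restorative": NightModel(
            mean=0.44, sd=1.0, school_shift=0.06, age_slope=-0.02,
            sex_effect=0.0, night_sd=0.0,
        ),
    }


@dataclass(frozen=True)
class BivariatePaths:
    """Lower-triangular 2x2 A/C/E path matrices for a two-trait generator."""

    a: np.ndarray
    c: np.ndarray
    e: np.ndarray

    def __post_init__(self):
        for name in ("a", "c", "e"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (2, 2) or abs(m[0, 1]) > 1e-12:
                raise ConfigurationError(
                    f"{name} paths must be 2x2 lower triangular"
                )
            object.__setattr__(self, name, m)

    def source_cov(self, source: str) -> np.ndarray:
        """Implied 2x2 covariance contributed by one source (L @ L.T)."""
        m = getattr(self, source)
        return m @ m.T

    def trait_variances(self) -> np.ndarray:
        return sum(np.diag(self.source_cov(s)) for s in ("a", "c", "e"))

    def implied_pair_cov(self, zygosity: str) -> np.ndarray:
        """4x4 covariance of (x1, y1, x2, y2) for one zygosity group.

        The cross-twin block weights the genetic covariance by the kinship
        coefficient (1 for MZ, 0.5 for DZ), the shared-environment covariance
        by 1, and the unique-environment covariance by 0.
        """
        w = {"MZ": 1.0, "DZ": 0.5}[zygosity]
        within = sum(self.source_cov(s) for s in ("a", "c", "e"))
        cross = w * self.source_cov("a") + self.source_cov("c")
        return np.block([[within, cross], [cross, within]])

    @classmethod
    def from_ip_shares(
        cls,
        common: dict[str, tuple[float, float]],
        specific: dict[str, tuple[float, float]],
    ) -> "BivariatePaths":
        """Build paths from independent-pathway variance shares.

        ``common[s]`` gives the fraction of each trait's total variance due
        to the shared factor of source ``s`` (loadings take the positive
        root, so shared sources induce positive cross-trait covariance);
        ``specific[s]`` the trait-specific fractions.  Shares must sum to 1
        per trait.
        """
        mats = {}
        totals = np.zeros(2)
        for s in ("a", "c", "e"):
            lam = np.sqrt(np.asarray(common.get(s, (0.0, 0.0)), dtype=float))
            u2 = np.asarray(specific.get(s, (0.0, 0.0)), dtype=float)
            cov = np.outer(lam, lam) + np.diag(u2)
            totals += np.diag(cov)
            mats[s] = _chol_psd(cov)
        if not np.allclose(totals, 1.0, atol=1e-8):
            raise ConfigurationError(
                f"variance shares must sum to 1 per trait, got {totals}"
            )
        return cls(**mats)


def _chol_psd(m: np.ndarray) -> np.ndarray:
    """Cholesky factor tolerant of semi-definite source matrices."""
    try:
        return np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(m)
        if w.min() < -1e-10:
            raise ConfigurationError("implied source covariance is not PSD")
        w = np.clip(w, 0.0, None)
        # rebuild a lower-triangular factor via QR of the square root
        root = v * np.sqrt(w)
        q, r = np.linalg.qr(root.T)
        lower = r.T * np.sign(np.diag(r))
        return lower


@dataclass(frozen=True)
class SimConfig:
    """Configuration for the synthetic twin cohort and its night records."""

    n_mz_pairs: int = 93
    n_dz_pairs: int = 117
    n_singletons: int = 75
    age_range: tuple[float, float] = (9.0, 17.0)
    prop_female: float = 0.55
    seed: int = DEFAULT_SEED
    a2: float = 0.62
    c2: float = 0.08
    e2: float = 0.30
    bivariate_paths: BivariatePaths | None = None
    night_model: dict[str, NightModel] = field(default_factory=_default_night_model)
    n_nights: int = 14
    p_missing_night: float = 0.05
    diary_noise_sd: float = 10.0
    p_extreme_disparity: float = 0.01
    start_weekday: int = 0  # 0 = Monday evening for night index 0
    holiday_nights: tuple[int, ...] = ()

    def __post_init__(self):
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-12:
            raise ConfigurationError("a2 + c2 + e2 must equal 1")
        for name in ("a2", "c2", "e2", "prop_female", "p_missing_night",
                     "p_extreme_disparity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must be in [0, 1]")
        if self.n_nights < 1:
            raise ConfigurationError("n_nights must be >= 1")
        if self.age_range[0] > self.age_range[1]:
            raise ConfigurationError("age_range must be (min, max)")
        if min(self.n_mz_pairs, self.n_dz_pairs, self.n_singletons) < 0:
            raise ConfigurationError("cohort counts must be non-negative")

    def with_ace(self, a2: float, c2: float, e2: float) -> "SimConfig":
        return replace(self, a2=a2, c2=c2, e2=e2)


# ---------------------------------------------------------------------------
# cohort construction
# ---------------------------------------------------------------------------

def make_cohort(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the cohort roster: paired MZ/DZ twins plus unmatched twins.

    Paired twins share family id and age; MZ co-twins share sex.  Singletons
    are unmatched members of (unobserved) twin pairs and carry a zygosity
    label of their own.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.age_range
    rows = []
    fid = 0
    for zyg, n_pairs in (("MZ", config.n_mz_pairs), ("DZ", config.n_dz_pairs)):
        for _ in range(n_pairs):
            fid += 1
            age = rng.uniform(lo, hi)
            if zyg == "MZ":
                sexes = ["F" if rng.random() < config.prop_female else "M"] * 2
            else:
                sexes = ["F" if rng.random() < config.prop_female else "M"
                         for _ in range(2)]
            for order, sex in zip((1, 2), sexes):
                rows.append((f"F{fid:04d}_{order}", f"F{fid:04d}", zyg,
                             order, age, sex))
    for _ in range(config.n_singletons):
        fid += 1
        zyg = "MZ" if rng.random() < 0.5 else "DZ"
        age = rng.uniform(lo, hi)
        sex = "F" if rng.random() < config.prop_female else "M"
        rows.append((f"F{fid:04d}_1", f"F{fid:04d}", zyg, 0, age, sex))
    return pd.DataFrame(
        rows, columns=["subject_id", "family_id", "zygosity", "twin_order",
                       "age", "sex"],
    )


def draw_ace_latents(
    cohort: pd.DataFrame,
    a2: float,
    c2: float,
    e2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Standardised ACE latent per cohort row, respecting family structure.

    A is drawn once per MZ family and as sqrt(.5)*common + sqrt(.5)*segregating
    for DZ co-twins, which makes the kinship correlations (1.0 / 0.5) exact by
    construction; C is drawn once per family; E per individual.
    """
    if abs(a2 + c2 + e2 - 1.0) > 1e-12:
        raise ConfigurationError("a2 + c2 + e2 must equal 1")
    fam_codes, fam_index = pd.factorize(cohort["family_id"])
    n_fam = len(fam_index)
    n = len(cohort)
    a_common = rng.normal(size=n_fam)[fam_codes]
    a_seg = rng.normal(size=n)
    is_dz = (cohort["zygosity"] == "DZ").to_numpy()
    a = np.where(is_dz, np.sqrt(0.5) * a_common + np.sqrt(0.5) * a_seg, a_common)
    c = rng.normal(size=n_fam)[fam_codes]
    e = rng.normal(size=n)
    return np.sqrt(a2) * a + np.sqrt(c2) * c + np.sqrt(e2) * e


def _pair_table(cohort: pd.DataFrame, values: np.ndarray, columns) -> pd.DataFrame:
    """Pivot per-subject values into one row per family (y2 NaN for singletons)."""
    df = cohort[["family_id", "zygosity", "twin_order"]].copy()
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == len(cohort):
        values = values.T
    for i, col in enumerate(columns):
        df[col] = values[i]
    first = df[df["twin_order"] != 2]
    second = df[df["twin_order"] == 2]
    out = first.merge(
        second[["family_id", *columns]], on="family_id", how="left",
        suffixes=("_1", "_2"),
    )
    cols = ["family_id", "zygosity"]
    cols += [f"{c}_{k}" for c in columns for k in (1, 2)]
    return out[cols].reset_index(drop=True)


def simulate_ace_pairs(config: SimConfig) -> pd.DataFrame:
    """Pair-level standardized phenotypes under the univariate ACE model.

    Returns one row per family with columns ``y_1``/``y_2`` (``y_2`` missing
    for unmatched twins).  Phenotypes are zero-mean, unit-variance; the
    within-pair covariance is a2 + c2 for MZ and 0.5*a2 + c2 for DZ pairs.
    """
    rng = np.random.default_rng(config.seed)
    cohort = make_cohort(config, rng)
    y = draw_ace_latents(cohort, config.a2, config.c2, config.e2, rng)
    return _pair_table(cohort, y, ["y"])


def simulate_bivariate_cholesky(config: SimConfig) -> pd.DataFrame:
    """Two-trait pair-level table under triangular A/C/E path matrices.

    Returns one row per family with columns ``x_1, x_2, y_1, y_2`` (trait x
    and y for twins 1 and 2).  Trait variances must be standardized to 1 by
    the configured paths.
    """
    if config.bivariate_paths is None:
        raise ConfigurationError("bivariate_paths must be set")
    paths = config.bivariate_paths
    if not np.allclose(paths.trait_variances(), 1.0, atol=1e-6):
        raise ConfigurationError(
            f"paths imply trait variances {paths.trait_variances()}, "
            "expected 1 (standardized)"
        )
    rng = np.random.default_rng(config.seed)
    cohort = make_cohort(config, rng)
    chol = {}
    for zyg in ("MZ", "DZ"):
        sigma = paths.implied_pair_cov(zyg)
        try:
            chol[zyg] = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            raise ConfigurationError(
                f"implied {zyg} pair covariance is not positive definite"
            ) from None
    within_chol = _chol_psd(sum(paths.source_cov(s) for s in ("a", "c", "e")))

    values = np.full((len(cohort), 2), np.nan)
    idx = cohort.reset_index(drop=True)
    paired = idx[idx["twin_order"] > 0]
    for zyg in ("MZ", "DZ"):
        fam = paired[paired["zygosity"] == zyg]
        fam1 = fam[fam["twin_order"] == 1].sort_values("family_id")
        fam2 = fam[fam["twin_order"] == 2].sort_values("family_id")
        n = len(fam1)
        draws = rng.standard_normal((n, 4)) @ chol[zyg].T
        values[fam1.index.to_numpy(), :] = draws[:, :2]
        values[fam2.index.to_numpy(), :] = draws[:, 2:]
    singles = idx[idx["twin_order"] == 0]
    draws = rng.standard_normal((len(singles), 2)) @ within_chol.T
    values[singles.index.to_numpy(), :] = draws
    return _pair_table(cohort, values, ["x", "y"])


# ---------------------------------------------------------------------------
# night-level records
# ---------------------------------------------------------------------------

def night_types(config: SimConfig) -> np.ndarray:
    """Label each study night school/nonschool from the repeating calendar.

    Night index 0 falls on the evening of ``start_weekday`` (0 = Monday).
    Nights whose following morning is Saturday or Sunday, and nights listed
    in ``holiday_nights``, are nonschool.
    """
    labels = []
    for i in range(config.n_nights):
        evening = (config.start_weekday + i) % 7
        nonschool = evening in (4, 5) or i in config.holiday_nights
        labels.append("nonschool" if nonschool else "school")
    return np.array(labels)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def simulate_night_records(
    config: SimConfig, cohort: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Night-level diary + device records for every cohort member.

    Each subject gets ``n_nights`` rows.  Device onset and wake carry the
    familial (ACE) latent, fixed age/sex effects, the nonschool shift and
    nightly noise; duration is wake minus onset.  Diary bed/wake times are
    noisy versions of the device times, a fraction of nights lose device data
    entirely, and a small fraction get gross (>6 h) diary/device disparities
    so the downstream filters have something to catch.
    """
    rng = np.random.default_rng(config.seed)
    if cohort is None:
        cohort = make_cohort(config, rng)
    n = len(cohort)
    age_ref = 0.5 * (config.age_range[0] + config.age_range[1])
    age_c = cohort["age"].to_numpy() - age_ref
    male = (cohort["sex"] == "M").to_numpy().astype(float)
    types = night_types(config)
    nonschool = (types == "nonschool").astype(float)

    subj_mean = {}
    for name in ("onset", "wake"):
        m = config.night_model[name]
        z = draw_ace_latents(cohort, config.a2, config.c2, config.e2, rng)
        subj_mean[name] = (
            m.mean + m.sd * z + m.age_slope * age_c + m.sex_effect * male
        )
    rest = config.night_model["restorative"]
    z_rest = draw_ace_latents(cohort, config.a2, config.c2, config.e2, rng)
    p_base = np.clip(
        rest.mean + rest.age_slope * age_c + rest.sex_effect * male,
        0.02, 0.98,
    )

    frames = []
    for i, ntype in enumerate(types):
        onset_m = config.night_model["onset"]
        wake_m = config.night_model["wake"]
        onset = (
            subj_mean["onset"] + onset_m.school_shift * nonschool[i]
            + rng.normal(0.0, onset_m.night_sd, size=n)
        )
        wake = (
            subj_mean["wake"] + wake_m.school_shift * nonschool[i]
            + rng.normal(0.0, wake_m.night_sd, size=n)
        )
        wake = np.maximum(wake, onset + 30.0)  # a night never inverts
        p_night = 1.0 / (1.0 + np.exp(-(
            _logit(np.clip(p_base + rest.school_shift * nonschool[i], 0.02, 0.98))
            + rest.sd * z_rest
        )))
        restorative = (rng.random(n) < p_night).astype(float)

        diary_bed = onset - np.abs(rng.normal(15.0, config.diary_noise_sd, size=n))
        diary_wake = wake + rng.normal(5.0, config.diary_noise_sd, size=n)
        extreme = rng.random(n) < config.p_extreme_disparity
        if extreme.any():
            gap = rng.uniform(390.0, 600.0, size=int(extreme.sum()))
            diary_bed = diary_bed.copy()
            diary_bed[extreme] = onset[extreme] - gap
        missing = rng.random(n) < config.p_missing_night
        onset = np.where(missing, np.nan, onset)
        wake = np.where(missing, np.nan, wake)

        frames.append(pd.DataFrame({
            "subject_id": cohort["subject_id"].to_numpy(),
            "family_id": cohort["family_id"].to_numpy(),
            "zygosity": cohort["zygosity"].to_numpy(),
            "twin_order": cohort["twin_order"].to_numpy(),
            "age": cohort["age"].to_numpy(),
            "sex": cohort["sex"].to_numpy(),
            "night_index": i,
            "night_type": ntype,
            "diary_bed": diary_bed,
            "diary_wake": diary_wake,
            "device_onset": onset,
            "device_wake": wake,
            "duration": wake - onset,
            "restorative": restorative,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["subject_id", "night_index"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# raw arm-angle traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AngleSimParams:
    """Noise model for one night's 5-second-epoch arm-angle trace.

    ``sleep_jitter`` is the half-width (degrees) of the uniform epoch-to-epoch
    angle change during sleep — kept under the 5-degree detection threshold by
    valid configurations.  ``wake_activity_rate`` is the per-epoch probability
    of a super-threshold posture change while awake; ``arousal_rate_per_hour``
    and ``arousal_duration_min`` inject brief movement bouts inside sleep.
    """

    sleep_jitter: float = 2.0
    wake_activity_rate: float = 0.3
    arousal_rate_per_hour: float = 0.0
    arousal_duration_min: float = 1.0
    diary_noise_sd: float = 10.0
    span: tuple[float, float] = (0.0, 1440.0)

    def __post_init__(self):
        if not 0.0 <= self.wake_activity_rate <= 1.0:
            raise ConfigurationError("wake_activity_rate must be in [0, 1]")
        if self.sleep_jitter < 0 or self.diary_noise_sd < 0:
            raise ConfigurationError("noise parameters must be non-negative")


@dataclass(frozen=True)
class AngleSeries:
    """5-second-epoch arm-angle trace (degrees vs the horizontal plane)."""

    times: np.ndarray  # minutes from noon, strictly increasing, 5 s spacing
    angles: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.angles, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and angles must be matching 1-d arrays")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "angles", a)


def simulate_angle_series(
    true_onset: float,
    true_wake: float,
    diary_window: tuple[float, float] | None = None,
    params: AngleSimParams | None = None,
    seed: int = DEFAULT_SEED,
) -> tuple[AngleSeries, dict]:
    """One night's arm-angle trace plus its diary record and ground truth.

    During true sleep the epoch-to-epoch change stays below the detection
    threshold (uniform within ``±sleep_jitter``); awake epochs additionally
    receive super-threshold changes at ``wake_activity_rate``, and optional
    brief arousals interrupt sleep.  If ``diary_window`` is not given, the
    diary times are truth plus noise.
    """
    params = params or AngleSimParams()
    lo, hi = params.span
    if not (lo <= true_onset < true_wake <= hi):
        raise ValueError("true sleep window must lie within the recording span")
    if diary_window is not None and not (
        lo <= diary_window[0] < diary_window[1] <= hi
    ):
        raise ValueError("diary window must lie within the recording span")
    rng = np.random.default_rng(seed)
    n = int(round((hi - lo) / EPOCH_MINUTES))
    times = lo + EPOCH_MINUTES * np.arange(n)

    asleep = (times >= true_onset) & (times < true_wake)
    if params.arousal_rate_per_hour > 0:
        hours = (true_wake - true_onset) / 60.0
        n_arousals = rng.poisson(params.arousal_rate_per_hour * hours)
        dur_ep = max(1, int(round(params.arousal_duration_min / EPOCH_MINUTES)))
        sleep_idx = np.flatnonzero(asleep)
        for _ in range(n_arousals):
            start = rng.integers(sleep_idx[0], max(sleep_idx[0] + 1, sleep_idx[-1] - dur_ep))
            asleep[start:start + dur_ep] = False

    deltas = rng.uniform(-params.sleep_jitter, params.sleep_jitter, size=n)
    awake = ~asleep
    # arousal/wake movement: super-threshold posture changes
    active = awake & (rng.random(n) < params.wake_activity_rate)
    active |= awake & (times >= true_onset) & (times < true_wake)  # arousals always move
    n_active = int(active.sum())
    if n_active:
        magnitude = rng.uniform(6.0, 40.0, size=n_active)
        deltas[active] = magnitude * rng.choice([-1.0, 1.0], size=n_active)
    # posture shifts at falling asleep and waking anchor the detector to truth
    transitions = np.flatnonzero(np.diff(asleep.astype(int)) != 0) + 1
    if len(transitions):
        deltas[transitions] = (rng.uniform(10.0, 40.0, size=len(transitions))
                               * rng.choice([-1.0, 1.0], size=len(transitions)))
    deltas[0] = 0.0
    angles = float(rng.uniform(-30.0, 30.0)) + np.cumsum(deltas)

    if diary_window is None:
        bed = true_onset - abs(rng.normal(0.0, params.diary_noise_sd))
        rise = true_wake + abs(rng.normal(0.0, params.diary_noise_sd))
        diary_window = (max(lo, bed), min(hi, rise))
    diary = {
        "diary_bed": diary_window[0],
        "diary_wake": diary_window[1],
        "true_onset": true_onset,
        "true_wake": true_wake,
    }
    return AngleSeries(times=times, angles=angles), diary
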