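"""End-to-end orchestration: pipeline driver, output tables, config handling.

Runs simulate (or ingest) -> preprocess -> univariate -> bivariate and emits
machine-readable analogues of the study's reporting surfaces: a descriptive
table (phenotype means ± SD [range; N] by stratum and night scope with Welch
contrasts), a twin-correlation table, a model-fit table (ACE family with
AIC), and bivariate decompositions (duration vs midpoint, and school vs
nonschool per phenotype).  Every output row carries the seed and a hash of
the configuration so reruns are attributable and byte-stable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from ._clock import to_clock
from . import preprocess, simulate, univariate, bivariate

__all__ = [
    "AnalysisConfig",
    "run_pipeline",
    "descriptive_table",
    "sim_config_from_yaml",
    "plot_decomposition_shares",
]

logger = logging.getLogger("twinsleep")

PHENOTYPES = ("onset", "wake", "midpoint", "duration", "restorative")
CLOCK_PHENOTYPES = ("onset", "wake", "midpoint")
DEFAULT_STRATA = {
    "full": None,
    "younger": (8.5, 15.0),
    "older": (15.0, 18.5),
}
ALPHA = 0.05 / 5  # descriptive contrasts: Bonferroni over the 5 phenotypes


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to run the pipeline end-to-end."""

    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    nights_path: str | None = None  # load night records instead of simulating
    strata: dict = field(default_factory=lambda: dict(DEFAULT_STRATA))
    phenotypes: tuple[str, ...] = PHENOTYPES
    models: tuple[str, ...] = ("ACE", "AE", "CE", "E")
    seed: int = simulate.DEFAULT_SEED
    out_dir: str | None = None

    def __post_init__(self):
        bounds = [b for b in self.strata.values() if b is not None]
        for i, b1 in enumerate(bounds):
            for b2 in bounds[i + 1:]:
                if max(b1[0], b2[0]) < min(b1[1], b2[1]):
                    raise ValueError("stratum age bounds overlap")

    def config_hash(self) -> str:
        # identifies the analysis, not the destination directory
        canonical = dataclasses.replace(self, out_dir=None)
        return hashlib.sha1(repr(canonical).encode()).hexdigest()[:12]


def sim_config_from_yaml(path: str | Path) -> simulate.SimConfig:
    """Read a SimConfig from a plain YAML key-value file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "night_model" in raw:
        raw["night_model"] = {
            k: simulate.NightModel(**v) for k, v in raw["night_model"].items()
        }
    if "age_range" in raw:
        raw["age_range"] = tuple(raw["age_range"])
    if "holiday_nights" in raw:
        raw["holiday_nights"] = tuple(raw["holiday_nights"])
    return simulate.SimConfig(**raw)


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _stratum_subjects(subjects: pd.DataFrame, name: str, bounds) -> pd.DataFrame:
    if bounds is None:
        return subjects
    lo, hi = bounds
    out = subjects[(subjects["age"] >= lo) & (subjects["age"] < hi)]
    if out.empty:
        raise ValueError(
            f"stratum {name!r} (ages [{lo}, {hi})) contains no subjects"
        )
    return out


def _clean_residuals(subjects: pd.DataFrame, phenotype: str) -> tuple[pd.Series, dict]:
    """Winsorised z-scores residualised on age and sex, within this sample."""
    z = preprocess.standardize_winsorize(subjects[phenotype])
    z.index = subjects.index
    tmp = subjects.assign(_z=z)
    resid, rep = preprocess.residualize(tmp, "_z")
    return resid, rep


def _welch(a: pd.Series, b: pd.Series) -> tuple[float, float]:
    a, b = a.dropna(), b.dropna()
    if len(a) < 2 or len(b) < 2:
        return float("nan"), float("nan")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def descriptive_table(
    subject_tables: dict[tuple[str, str], pd.DataFrame],
) -> pd.DataFrame:
    """Phenotype means ± SD [range; N] by stratum and night scope.

    Also reports the school-vs-nonschool contrast (full sample) and the
    younger-vs-older contrast (all nights) as Welch two-sample tests,
    flagged at the Bonferroni-corrected threshold .05/5.  Clock phenotypes
    get both "hh:mm" strings and minutes-from-noon numerics.
    """
    rows = []
    for (stratum, scope), df in sorted(subject_tables.items()):
        for ph in PHENOTYPES:
            if ph not in df.columns:
                continue
            vals = df[ph].dropna()
            row = {
                "stratum": stratum, "scope": scope, "phenotype": ph,
                "mean": vals.mean(), "sd": vals.std(ddof=1),
                "min": vals.min(), "max": vals.max(), "n": len(vals),
            }
            if ph in CLOCK_PHENOTYPES:
                row["mean_clock"] = to_clock(vals.mean())
                row["range_clock"] = f"{to_clock(vals.min())}-{to_clock(vals.max())}"
            rows.append(row)
    table = pd.DataFrame(rows)

    contrasts = []
    key_s, key_n = ("full", "school"), ("full", "nonschool")
    if key_s in subject_tables and key_n in subject_tables:
        for ph in PHENOTYPES:
            t, p = _welch(subject_tables[key_s][ph], subject_tables[key_n][ph])
            diff = (subject_tables[key_n][ph].mean()
                    - subject_tables[key_s][ph].mean())
            contrasts.append({
                "contrast": "nonschool_minus_school", "phenotype": ph,
                "difference": float(diff), "t": t, "p": p,
                "significant": bool(p < ALPHA) if np.isfinite(p) else False,
            })
    key_y, key_o = ("younger", "all"), ("older", "all")
    if key_y in subject_tables and key_o in subject_tables:
        for ph in PHENOTYPES:
            t, p = _welch(subject_tables[key_o][ph], subject_tables[key_y][ph])
            diff = (subject_tables[key_o][ph].mean()
                    - subject_tables[key_y][ph].mean())
            contrasts.append({
                "contrast": "older_minus_younger", "phenotype": ph,
                "difference": float(diff), "t": t, "p": p,
                "significant": bool(p < ALPHA) if np.isfinite(p) else False,
            })
    return table, pd.DataFrame(contrasts)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the full analysis and return (and optionally write) tables.

    Stages: simulate or load night records; filter nights and subjects;
    aggregate to subject level per stratum and night scope; z-score,
    winsorise and residualise each phenotype within its analysis sample;
    fit saturated + ACE-family univariate models; fit the duration-midpoint
    and school-vs-nonschool bivariate models.  Returns a dict of DataFrames
    (descriptives, contrasts, correlations, model_fits, bivariate) plus the
    exclusion log.
    """
    cfg_hash = config.config_hash()

    def tag(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        df["seed"] = config.seed
        df["config_hash"] = cfg_hash
        return df

    try:
        if config.nights_path:
            nights = pd.read_csv(config.nights_path)
        else:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            nights = simulate.simulate_night_records(sim)
        logger.info("stage=ingest nights=%d subjects=%d",
                    len(nights), nights["subject_id"].nunique())

        nights, exclusions = preprocess.filter_nights(nights)
        logger.info("stage=filter retained=%d excluded=%d",
                    len(nights), len(exclusions))

        # subject-level tables per (stratum, scope)
        base = {}
        scopes_by_stratum = {
            name: ("all", "school", "nonschool") if bounds is None else ("all",)
            for name, bounds in config.strata.items()
        }
        all_subjects = preprocess.aggregate_subject(nights, "all")
        for name, bounds in config.strata.items():
            for scope in scopes_by_stratum[name]:
                agg = preprocess.aggregate_subject(nights, scope)
                base[(name, scope)] = _stratum_subjects(agg, name, bounds)
        logger.info("stage=aggregate tables=%d", len(base))

        desc, contrasts = descriptive_table(base)

        corr_rows, fit_rows = [], []
        residuals = {}
        for (stratum, scope), subjects in base.items():
            for ph in config.phenotypes:
                resid, rep = _clean_residuals(subjects, ph)
                residuals[(stratum, scope, ph)] = (subjects, resid)
                pairs = univariate.pairs_from_subjects(
                    subjects.assign(y=resid), "y")
                sat = univariate.fit_saturated(
                    pairs, univariate.EquateFlags(order_means=True,
                                                  order_vars=True))
                corr_rows.append({
                    "stratum": stratum, "scope": scope, "phenotype": ph,
                    "rMZ": sat.correlations["MZ"],
                    "rDZ": sat.correlations["DZ"],
                    "age_slope": rep["age_slope"],
                    "sex_contrast": rep["sex_contrast"],
                })
                fits = [univariate.fit_ace_family(pairs, m)
                        for m in config.models]
                table, best = univariate.compare_models(fits)
                for f in fits:
                    fit_rows.append({
                        "stratum": stratum, "scope": scope, "phenotype": ph,
                        "model": f.model, "minus2LL": f.fit.minus2LL,
                        "n_params": f.fit.n_params, "AIC": f.fit.aic,
                        "a2": f.components.a2, "c2": f.components.c2,
                        "e2": f.components.e2,
                        "best": f.model == best,
                        "converged": f.fit.converged,
                    })
        logger.info("stage=univariate fits=%d", len(fit_rows))

        bivar_rows = []
        # duration vs midpoint, full sample, all nights
        key = ("full", "all")
        if key in base and {"duration", "midpoint"} <= set(config.phenotypes):
            subjects = base[key]
            dur = residuals[("full", "all", "duration")][1]
            mid = residuals[("full", "all", "midpoint")][1]
            pairs2 = bivariate.pairs2_from_subjects(
                subjects.assign(x=dur, y=mid), "x", "y")
            both = dur.notna() & mid.notna()
            rp = float(np.corrcoef(dur[both], mid[both])[0, 1])
            fitted2 = pairs2 if rp >= 0 else bivariate.flip_trait(pairs2, "y")
            for label, fit in (
                ("cholesky_12", bivariate.fit_cholesky(pairs2, (1, 2))),
                ("cholesky_21", bivariate.fit_cholesky(pairs2, (2, 1))),
                ("independent_pathway",
                 bivariate.fit_independent_pathway(fitted2)),
            ):
                bivar_rows.append(_bivar_row(
                    "duration_vs_midpoint", label, fit,
                    sign_flipped=(label == "independent_pathway" and rp < 0)))
        # school vs nonschool per phenotype
        for ph in config.phenotypes:
            ks, kn = ("full", "school"), ("full", "nonschool")
            if ks not in base or kn not in base:
                continue
            school = residuals[("full", "school", ph)]
            non = residuals[("full", "nonschool", ph)]
            merged = all_subjects[["subject_id", "family_id", "zygosity",
                                   "twin_order"]].copy()
            merged = merged.merge(
                school[0].assign(x=school[1])[["subject_id", "x"]],
                on="subject_id", how="left",
            ).merge(
                non[0].assign(y=non[1])[["subject_id", "y"]],
                on="subject_id", how="left",
            )
            pairs2 = bivariate.pairs2_from_subjects(merged, "x", "y")
            fit = bivariate.fit_independent_pathway(pairs2)
            bivar_rows.append(_bivar_row(f"{ph}_school_vs_nonschool",
                                         "independent_pathway", fit))
        logger.info("stage=bivariate fits=%d", len(bivar_rows))

        results = {
            "descriptives": tag(desc),
            "contrasts": tag(contrasts),
            "correlations": tag(pd.DataFrame(corr_rows)),
            "model_fits": tag(pd.DataFrame(fit_rows)),
            "bivariate": tag(pd.DataFrame(bivar_rows)),
            "exclusions": tag(exclusions),
        }
    except Exception as err:
        raise RuntimeError(f"pipeline failed: {err}") from err

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "config.json").write_text(json.dumps(
            {"seed": config.seed, "config_hash": cfg_hash,
             "config": repr(config)}, indent=2))
        logger.info("stage=write out_dir=%s files=%d", out, len(results) + 1)
    return results


def plot_decomposition_shares(decomp, trait_names=("trait x", "trait y"),
                              ax=None):
    """Stacked-bar plot of common/specific A/C/E shares per trait."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    labels = ["Ac", "Cc", "Ec", "As", "Cs", "Es"]
    colors = ["#1b6ca8", "#52b788", "#bcbcbc", "#8ecae6", "#b7e4c7", "#e0e0e0"]
    x = np.arange(2)
    bottom = np.zeros(2)
    for label, color in zip(labels, colors):
        source, kind = label[0].lower(), label[1]
        shares = (decomp.common if kind == "c" else decomp.specific)[source]
        vals = np.asarray(shares, dtype=float)
        ax.bar(x, vals, bottom=bottom, label=label, color=color,
               edgecolor="white")
        bottom += vals
    ax.set_xticks(x, trait_names)
    ax.set_ylabel("share of total variance")
    ax.set_ylim(0, 1)
    ax.legend(ncols=3, fontsize=8)
    return ax


def _bivar_row(analysis: str, model: str, fit: bivariate.BivariateFit,
               sign_flipped: bool = False) -> dict:
    d = fit.decomposition
    row = {
        "analysis": analysis, "model": model,
        "minus2LL": fit.fit.minus2LL, "AIC": fit.fit.aic,
        "converged": fit.fit.converged, "sign_flipped": sign_flipped,
        "rP": d.rP, "rG": d.rG, "rC": d.rC, "rE": d.rE,
        "h2_x": d.h2[0], "h2_y": d.h2[1],
    }
    for s in ("a", "c", "e"):
        for i, trait in enumerate(("x", "y")):
            row[f"{s.upper()}c_{trait}"] = d.common[s][i]
            row[f"{s.upper()}s_{trait}"] = d.specific[s][i]
    return row
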