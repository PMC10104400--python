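"""Univariate twin modelling: ML twin correlations, ACE-family fits, model
comparison, and profile-likelihood confidence intervals.

The classical twin design decomposes phenotypic variance into additive
genetic (A), shared/common environmental (C) and non-shared/unique
environmental (E) sources by exploiting the fixed kinship correlations of
the latent factors: additive-genetic influences correlate 1.0 within MZ and
0.5 within DZ pairs, shared environment correlates 1.0 in both, unique
environment 0.  Under the model the within-pair phenotype covariance is
a^2 + c^2 for MZ and 0.5 a^2 + c^2 for DZ pairs.

Fits maximise the bivariate-normal likelihood over pairs, with unmatched
twins contributing the marginal likelihood of their single observation
(missing-at-random).  Paths are parameterised as coefficients and squared
for reporting, so variance components are nonnegative by construction.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._likelihood import BIG_PENALTY, lrt_pvalue, minimize_restarts

__all__ = [
    "VarianceComponents",
    "ModelFit",
    "AceFit",
    "SaturatedFit",
    "EquateFlags",
    "pairs_from_subjects",
    "fit_saturated",
    "fit_ace_family",
    "compare_models",
    "profile_ci",
    "profile_deviance",
    "falconer",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_MODELS = ("ACE", "AE", "CE", "E")
_CHI2_95_1DF = float(chi2.ppf(0.95, 1))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceComponents:
    """Standardised variance proportions with optional 95% CIs."""

    a2: float
    c2: float
    e2: float
    ci95: dict | None = None

    def __post_init__(self):
        total = self.a2 + self.c2 + self.e2
        if min(self.a2, self.c2, self.e2) < -1e-10 or abs(total - 1.0) > 1e-8:
            raise ValueError("components must be nonnegative and sum to 1")

    @property
    def h2(self) -> float:
        """Heritability: the additive-genetic proportion of variance."""
        return self.a2


@dataclass(frozen=True)
class ModelFit:
    """Fit statistics for one model on one dataset."""

    model: str
    minus2LL: float
    n_params: int
    converged: bool
    data_hash: str = ""

    @property
    def aic(self) -> float:
        return self.minus2LL + 2.0 * self.n_params


@dataclass(frozen=True)
class AceFit:
    """A converged ACE-family fit, retaining the data for profiling."""

    fit: ModelFit
    components: VarianceComponents
    paths: dict  # a, c, e coefficients and mu
    total_variance: float
    _data: tuple = field(repr=False, default=())

    @property
    def model(self) -> str:
        return self.fit.model


@dataclass(frozen=True)
class SaturatedFit:
    """Saturated-model fit: free means/variances/correlations per zygosity."""

    fit: ModelFit
    correlations: dict  # zygosity -> ML within-pair correlation
    means: dict
    variances: dict
    constraint_tests: dict | None = None


@dataclass(frozen=True)
class EquateFlags:
    """Equality constraints for the saturated model."""

    order_means: bool = False
    order_vars: bool = False
    zyg_means: bool = False
    zyg_vars: bool = False


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def pairs_from_subjects(
    subjects: pd.DataFrame, columns: list[str] | str
) -> pd.DataFrame:
    """Pivot a subject-level table into one row per family.

    ``subjects`` needs family_id, zygosity, twin_order and the value
    column(s).  Twin 1 fills the ``_1`` slots (singletons count as twin 1),
    twin 2 the ``_2`` slots, left missing for unmatched twins.
    """
    if isinstance(columns, str):
        columns = [columns]
    df = subjects[["family_id", "zygosity", "twin_order", *columns]].copy()
    first = df[df["twin_order"] != 2]
    second = df[df["twin_order"] == 2]
    out = first.merge(
        second[["family_id", *columns]], on="family_id", how="outer",
        suffixes=("_1", "_2"),
    )
    # families where only twin 2 was observed: shift into slot 1
    only2 = second[~second["family_id"].isin(first["family_id"])]
    for _, row in only2.iterrows():
        sel = out["family_id"] == row["family_id"]
        out.loc[sel, "zygosity"] = row["zygosity"]
        for c in columns:
            out.loc[sel, f"{c}_1"] = row[c]
            out.loc[sel, f"{c}_2"] = np.nan
    keep = ["family_id", "zygosity"] + [f"{c}_{k}" for c in columns for k in (1, 2)]
    return out[keep].reset_index(drop=True)


def _split_groups(pairs: pd.DataFrame, col: str = "y"):
    """Per zygosity: complete-pair (n,2) array plus per-slot singleton arrays."""
    groups = {}
    for zyg in ("MZ", "DZ"):
        sub = pairs[pairs["zygosity"] == zyg]
        y1 = sub[f"{col}_1"].to_numpy(dtype=float)
        y2 = sub[f"{col}_2"].to_numpy(dtype=float)
        both = ~np.isnan(y1) & ~np.isnan(y2)
        groups[zyg] = (
            np.column_stack([y1[both], y2[both]]),
            y1[~np.isnan(y1) & np.isnan(y2)],
            y2[np.isnan(y1) & ~np.isnan(y2)],
        )
    n_complete = sum(g[0].shape[0] for g in groups.values())
    if n_complete < 2:
        raise ValueError("need at least 2 complete pairs to fit twin models")
    return groups


def _hash_groups(groups) -> str:
    h = hashlib.sha1()
    for zyg in ("MZ", "DZ"):
        for arr in groups[zyg]:
            h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def _pair_neg2ll(data, mu1, mu2, v1, v2, cv) -> float:
    """-2 log L of complete pairs under a 2-d normal (closed form)."""
    n = data.shape[0]
    if n == 0:
        return 0.0
    det = v1 * v2 - cv * cv
    if det <= 0 or v1 <= 0 or v2 <= 0:
        return BIG_PENALTY
    d1 = data[:, 0] - mu1
    d2 = data[:, 1] - mu2
    quad = (v2 * d1 @ d1 - 2.0 * cv * d1 @ d2 + v1 * d2 @ d2) / det
    return n * (2.0 * _LOG_2PI + np.log(det)) + quad


def _single_neg2ll(x, mu, v) -> float:
    if len(x) == 0:
        return 0.0
    if v <= 0:
        return BIG_PENALTY
    d = x - mu
    return len(x) * (_LOG_2PI + np.log(v)) + (d @ d) / v


# ---------------------------------------------------------------------------
# saturated model
# ---------------------------------------------------------------------------

def _saturated_names(equate: EquateFlags):
    if equate.order_means and equate.zyg_means:
        means = {("MZ", 1): "mu", ("MZ", 2): "mu", ("DZ", 1): "mu", ("DZ", 2): "mu"}
    elif equate.order_means:
        means = {(z, k): f"mu_{z}" for z in ("MZ", "DZ") for k in (1, 2)}
    elif equate.zyg_means:
        means = {(z, k): f"mu{k}" for z in ("MZ", "DZ") for k in (1, 2)}
    else:
        means = {(z, k): f"mu{k}_{z}" for z in ("MZ", "DZ") for k in (1, 2)}
    if equate.order_vars and equate.zyg_vars:
        vars_ = {("MZ", 1): "v", ("MZ", 2): "v", ("DZ", 1): "v", ("DZ", 2): "v"}
    elif equate.order_vars:
        vars_ = {(z, k): f"v_{z}" for z in ("MZ", "DZ") for k in (1, 2)}
    elif equate.zyg_vars:
        vars_ = {(z, k): f"v{k}" for z in ("MZ", "DZ") for k in (1, 2)}
    else:
        vars_ = {(z, k): f"v{k}_{z}" for z in ("MZ", "DZ") for k in (1, 2)}
    corr = {"MZ": "r_MZ", "DZ": "r_DZ"}
    names = list(dict.fromkeys(
        list(means.values()) + list(vars_.values()) + list(corr.values())
    ))
    return names, means, vars_, corr


def fit_saturated(
    pairs: pd.DataFrame,
    equate: EquateFlags = EquateFlags(),
    col: str = "y",
    test_constraints: bool = False,
    seed: int = 0,
) -> SaturatedFit:
    """ML means, variances and within-pair correlations per zygosity.

    All parameters are free unless equated via ``equate`` (across twin order
    and/or zygosity).  Unmatched twins contribute marginal likelihoods.  With
    ``test_constraints`` each equality constraint is tested against the fully
    saturated baseline by likelihood ratio.
    """
    groups = _split_groups(pairs, col)
    names, means, vars_, corr = _saturated_names(equate)
    obs = np.concatenate([np.concatenate([g[0].ravel(), g[1], g[2]])
                          for g in groups.values()])
    m0, v0 = float(np.mean(obs)), float(np.var(obs))

    def unpack(x):
        return dict(zip(names, x))

    def neg2ll(x):
        p = unpack(x)
        total = 0.0
        for zyg, (both, s1, s2) in groups.items():
            mu1, mu2 = p[means[(zyg, 1)]], p[means[(zyg, 2)]]
            v1, v2 = p[vars_[(zyg, 1)]], p[vars_[(zyg, 2)]]
            cv = p[corr[zyg]] * np.sqrt(v1 * v2)
            total += _pair_neg2ll(both, mu1, mu2, v1, v2, cv)
            total += _single_neg2ll(s1, mu1, v1) + _single_neg2ll(s2, mu2, v2)
        return total

    x0, bounds = [], []
    for name in names:
        if name.startswith("mu"):
            x0.append(m0)
            bounds.append((None, None))
        elif name.startswith("v"):
            x0.append(max(v0, 1e-4))
            bounds.append((1e-8, None))
        else:
            x0.append(0.4)
            bounds.append((-0.999, 0.999))
    rng = np.random.default_rng(seed)
    res = minimize_restarts(neg2ll, np.array(x0), bounds, rng, n_restarts=3)
    p = unpack(res.x)
    fit = ModelFit(
        model="saturated", minus2LL=float(res.fun), n_params=len(names),
        converged=bool(res.success), data_hash=_hash_groups(groups),
    )
    tests = None
    if test_constraints:
        base = fit_saturated(pairs, EquateFlags(), col=col, seed=seed) \
            if equate != EquateFlags() else None
        base_ll = base.fit.minus2LL if base else fit.minus2LL
        base_np = base.fit.n_params if base else fit.n_params
        tests = {}
        for flag in ("order_means", "order_vars", "zyg_means", "zyg_vars"):
            alt = fit_saturated(pairs, EquateFlags(**{flag: True}), col=col, seed=seed)
            df = base_np - alt.fit.n_params
            tests[flag] = {
                "minus2LL": alt.fit.minus2LL,
                "df": df,
                "p": lrt_pvalue(alt.fit.minus2LL, base_ll, df),
            }
    return SaturatedFit(
        fit=fit,
        correlations={z: float(p[corr[z]]) for z in ("MZ", "DZ")},
        means={k: float(p[v]) for k, v in means.items()},
        variances={k: float(p[v]) for k, v in vars_.items()},
        constraint_tests=tests,
    )


# ---------------------------------------------------------------------------
# ACE family
# ---------------------------------------------------------------------------

def _ace_neg2ll_factory(groups, free: str):
    """Return neg2ll(x) where x holds the free paths (in ``free`` order) + mu."""

    def neg2ll(x):
        coef = dict.fromkeys("ace", 0.0)
        for i, name in enumerate(free):
            coef[name] = x[i]
        mu = x[-1]
        a2, c2, e2 = coef["a"] ** 2, coef["c"] ** 2, coef["e"] ** 2
        v = a2 + c2 + e2
        total = 0.0
        for zyg, (both, s1, s2) in groups.items():
            cv = (1.0 if zyg == "MZ" else 0.5) * a2 + c2
            total += _pair_neg2ll(both, mu, mu, v, v, cv)
            total += _single_neg2ll(s1, mu, v) + _single_neg2ll(s2, mu, v)
        return total

    return neg2ll


def fit_ace_family(
    pairs: pd.DataFrame,
    model: str = "ACE",
    col: str = "y",
    seed: int = 0,
    n_restarts: int = 5,
) -> AceFit:
    """ML variance decomposition under an ACE-family model.

    ``model`` is ACE, AE, CE or E.  The likelihood is the structured
    bivariate normal with within-pair covariance a^2 + c^2 (MZ) or
    0.5 a^2 + c^2 (DZ); a single grand mean is estimated (phenotypes enter
    as residuals with mean near zero).  Standardised proportions and the
    path coefficients are returned; the E-only model is closed form.
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}")
    groups = _split_groups(pairs, col)
    data_hash = _hash_groups(groups)
    obs = np.concatenate([np.concatenate([g[0].ravel(), g[1], g[2]])
                          for g in groups.values()])
    m0, v0 = float(np.mean(obs)), max(float(np.var(obs)), 1e-8)

    if model == "E":
        e = np.sqrt(v0)
        neg2ll = _ace_neg2ll_factory(groups, "e")
        fun = neg2ll(np.array([e, m0]))
        return AceFit(
            fit=ModelFit("E", float(fun), 2, True, data_hash),
            components=VarianceComponents(0.0, 0.0, 1.0),
            paths={"a": 0.0, "c": 0.0, "e": float(e), "mu": m0},
            total_variance=v0,
            _data=(groups,),
        )

    free = {"ACE": "ace", "AE": "ae", "CE": "ce"}[model]
    neg2ll = _ace_neg2ll_factory(groups, free)
    # moment-based start via the correlation algebra
    start = {"a": 0.5, "c": 0.3, "e": 0.5}
    r_emp = {}
    for zyg, (both, _, _) in groups.items():
        if both.shape[0] >= 3:
            r_emp[zyg] = float(np.corrcoef(both[:, 0], both[:, 1])[0, 1])
    if len(r_emp) == 2:
        a2, c2, e2 = falconer(
            min(max(r_emp["MZ"], -0.99), 0.99),
            min(max(r_emp["DZ"], -0.99), 0.99),
            warn=False,
        )
        start = {k: np.sqrt(max(s, 0.01)) for k, s in zip("ace", (a2, c2, e2))}
    x0 = np.array([start[n] * np.sqrt(v0) for n in free] + [m0])
    bounds = [(0.0, 10.0 * np.sqrt(v0))] * len(free) + [(None, None)]
    rng = np.random.default_rng(seed)
    res = minimize_restarts(neg2ll, x0, bounds, rng, n_restarts=n_restarts,
                            jitter=0.3 * np.sqrt(v0))
    coef = dict.fromkeys("ace", 0.0)
    for i, name in enumerate(free):
        coef[name] = float(abs(res.x[i]))
    mu = float(res.x[-1])
    v = coef["a"] ** 2 + coef["c"] ** 2 + coef["e"] ** 2
    comps = VarianceComponents(
        a2=coef["a"] ** 2 / v, c2=coef["c"] ** 2 / v, e2=coef["e"] ** 2 / v
    )
    return AceFit(
        fit=ModelFit(model, float(res.fun), len(free) + 1,
                     bool(res.success), data_hash),
        components=comps,
        paths={**coef, "mu": mu},
        total_variance=float(v),
        _data=(groups,),
    )


def compare_models(fits: list[AceFit]) -> tuple[pd.DataFrame, str]:
    """Rank ACE-family fits on one dataset by AIC (ties: fewer parameters).

    Returns the comparison table (model, -2lnL, parameters, AIC, delta AIC,
    and the likelihood-ratio p-value of each sub-model against ACE when an
    ACE fit is supplied) and the name of the best model.
    """
    if not fits:
        raise ValueError("no fits to compare")
    hashes = {f.fit.data_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError("fits come from different datasets")
    ace = next((f for f in fits if f.model == "ACE"), None)
    rows = []
    for f in fits:
        p = np.nan
        if ace is not None and f.model != "ACE":
            p = lrt_pvalue(f.fit.minus2LL, ace.fit.minus2LL,
                           ace.fit.n_params - f.fit.n_params)
        rows.append((f.model, f.fit.minus2LL, f.fit.n_params, f.fit.aic, p))
    table = pd.DataFrame(
        rows, columns=["model", "minus2LL", "n_params", "AIC", "lrt_p_vs_ACE"]
    ).sort_values(["AIC", "n_params"], kind="stable").reset_index(drop=True)
    table["delta_AIC"] = table["AIC"] - table["AIC"].min()
    return table, str(table.loc[0, "model"])


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals
# ---------------------------------------------------------------------------

def _constrained_neg2ll(fit: AceFit, component: str, p: float):
    """Minimised -2lnL with one standardised component fixed at ``p``."""
    from scipy import optimize

    groups = fit._data[0]
    model = fit.model
    present = {"ACE": ("a2", "c2", "e2"), "AE": ("a2", "e2"),
               "CE": ("c2", "e2"), "E": ("e2",)}[model]
    if component not in present:
        raise ValueError(f"{component} is not free in the {model} model")
    free_paths = {"ACE": "ace", "AE": "ae", "CE": "ce", "E": "e"}[model]
    neg2ll = _ace_neg2ll_factory(groups, free_paths)
    v_hat, mu_hat = fit.total_variance, fit.paths["mu"]
    others = [c for c in present if c != component]

    def paths_from(v, t):
        rest = (1.0 - p) * v
        shares = {component: p * v}
        if len(others) == 1:
            shares[others[0]] = rest
        else:
            shares[others[0]] = rest * t
            shares[others[1]] = rest * (1.0 - t)
        full = {"a2": 0.0, "c2": 0.0, "e2": 0.0, **shares}
        return [np.sqrt(max(full[f"{n}2"], 0.0)) for n in free_paths]

    if model == "E":
        # e2 is identically 1: the profile is degenerate
        return fit.fit.minus2LL if abs(p - 1.0) < 1e-9 else float("inf")

    def obj(x):
        v, t, mu = x
        return neg2ll(np.array(paths_from(v, t) + [mu]))

    if len(others) == 1:
        t0 = 0.5
    else:
        rest = max(1.0 - getattr(fit.components, component), 1e-9)
        t0 = getattr(fit.components, others[0]) / rest
    best = None
    for t_start in {min(max(t0, 0.01), 0.99), 0.5}:
        res = optimize.minimize(
            obj, np.array([v_hat, t_start, mu_hat]),
            method="L-BFGS-B",
            bounds=[(1e-8, None), (0.0, 1.0), (None, None)],
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best:
            best = float(res.fun)
    return best


def profile_deviance(fit: AceFit, component: str, value: float) -> float:
    """Profile -2lnL rise for one standardised component fixed at ``value``.

    The 95% likelihood interval contains ``value`` exactly when this rise is
    at most the chi-square(1) critical value 3.841.
    """
    if not 0.0 <= value <= 1.0:
        raise ValueError("component value must be in [0, 1]")
    return max(0.0, _constrained_neg2ll(fit, component, value) - fit.fit.minus2LL)


def profile_ci(
    fit: AceFit, component: str, level: float = 0.95
) -> tuple[float, float]:
    """Profile-likelihood CI for a standardised variance component.

    The interval is the set of component values whose profile -2lnL rises by
    at most the chi-square(1) critical value above the minimum, bounded
    below at 0 and above at 1 (an open-ended profile reports the bound at
    the parameter limit).
    """
    from scipy.optimize import brentq

    if not fit.fit.converged:
        raise ValueError("profile CI requires a converged fit")
    crit = float(chi2.ppf(level, 1))
    p_hat = getattr(fit.components, component)

    def g(p):
        return profile_deviance(fit, component, p) - crit

    lo = 0.0 if g(0.0) <= 0 else float(brentq(g, 0.0, max(p_hat, 1e-9), xtol=1e-6))
    hi = 1.0 if g(1.0) <= 0 else float(brentq(g, min(p_hat, 1.0 - 1e-9), 1.0, xtol=1e-6))
    return lo, hi


# ---------------------------------------------------------------------------
# closed-form oracle
# ---------------------------------------------------------------------------

def falconer(rmz: float, rdz: float, warn: bool = True) -> tuple[float, float, float]:
    """Closed-form ACE decomposition implied by a twin-correlation pair.

    a2 = 2 (rMZ - rDZ), c2 = 2 rDZ - rMZ, e2 = 1 - rMZ.  Exact when the ACE
    model is just-identified to the two correlations.  Negative components
    are clamped to 0 with a warning (no refit), so the output may sum to
    less than 1 in that case.
    """
    for name, r in (("rmz", rmz), ("rdz", rdz)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name}={r} outside [-1, 1]")
    a2 = 2.0 * (rmz - rdz)
    c2 = 2.0 * rdz - rmz
    e2 = 1.0 - rmz
    clamped = [n for n, v in (("a2", a2), ("c2", c2), ("e2", e2)) if v < 0]
    if clamped and warn:
        warnings.warn(
            f"negative component(s) {clamped} clamped to 0", stacklevel=2
        )
    return max(a2, 0.0), max(c2, 0.0), max(e2, 0.0)
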