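"""Bivariate twin modelling: Cholesky and constrained independent-pathway fits.

Decomposes the covariance between two phenotypes (for example sleep duration
vs sleep midpoint, or the school- and nonschool-night versions of one
phenotype) into additive-genetic (A), shared-environment (C) and
unique-environment (E) sources that are common to both traits or specific to
one.  Families contribute a 4-variate normal likelihood over
(trait x twin 1, trait y twin 1, trait x twin 2, trait y twin 2); the
cross-twin block weights the genetic covariance by the kinship coefficient
(1 MZ, 0.5 DZ), the shared-environment covariance by 1 and the
unique-environment covariance by 0.  Incomplete families (unmatched twins,
subjects missing one trait, e.g. no school nights) contribute marginal
likelihoods.

The Cholesky decomposition parameterises each source as a lower-triangular
2x2 path matrix; its -2lnL is invariant to variable order, but the
common/specific reading of the second trait depends on the order, so it is
conventionally run twice with the order reversed.  The independent-pathway
model instead posits one common factor per source loading on both traits
(equal loadings under the default constraint) plus trait-specific factors.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._likelihood import BIG_PENALTY, minimize_restarts
from .univariate import ModelFit

__all__ = [
    "CholeskyPaths",
    "BivariateDecomposition",
    "CorrelationDecomposition",
    "BivariateFit",
    "pairs2_from_subjects",
    "flip_trait",
    "fit_cholesky",
    "fit_independent_pathway",
    "fit_saturated_bivariate",
    "correlation_decomposition",
    "shared_proportion",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_SOURCES = ("a", "c", "e")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CholeskyPaths:
    """Lower-triangular 2x2 path matrices per source (diagonals >= 0)."""

    a: np.ndarray
    c: np.ndarray
    e: np.ndarray

    def source_cov(self, source: str) -> np.ndarray:
        m = getattr(self, source)
        return m @ m.T

    def source_covs(self) -> dict[str, np.ndarray]:
        return {s: self.source_cov(s) for s in _SOURCES}


@dataclass(frozen=True)
class CorrelationDecomposition:
    """Phenotypic correlation and its source-level anatomy.

    rG (rC, rE) is the correlation between the A (C, E) influences on the
    two traits; ``contributions`` gives each source's additive share of rP,
    summing to rP.
    """

    rP: float
    rG: float
    rC: float
    rE: float
    contributions: dict[str, float]


@dataclass(frozen=True)
class BivariateDecomposition:
    """Common and specific variance shares per trait, plus correlations.

    ``common[s]`` and ``specific[s]`` hold each trait's fraction of total
    variance attributed to the shared vs trait-specific factor of source
    ``s``; per trait the six shares sum to 1.
    """

    common: dict[str, tuple[float, float]]
    specific: dict[str, tuple[float, float]]
    h2: tuple[float, float]
    rP: float
    rG: float
    rC: float
    rE: float

    def __post_init__(self):
        for i in range(2):
            total = sum(self.common[s][i] + self.specific[s][i] for s in _SOURCES)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"trait {i} shares sum to {total}, expected 1")


@dataclass(frozen=True)
class BivariateFit:
    """A fitted bivariate model with its implied source covariances."""

    fit: ModelFit
    source_covs: dict[str, np.ndarray]
    means: tuple[float, float]
    decomposition: BivariateDecomposition
    paths: CholeskyPaths | None = None
    order: tuple[int, int] = (1, 2)
    loadings: dict | None = None
    _data: tuple = field(repr=False, default=())


# ---------------------------------------------------------------------------
# data preparation and FIML likelihood
# ---------------------------------------------------------------------------

def pairs2_from_subjects(
    subjects: pd.DataFrame, trait_x: str, trait_y: str
) -> pd.DataFrame:
    """One row per family with columns x_1, y_1, x_2, y_2 for two traits."""
    from .univariate import pairs_from_subjects

    df = subjects.rename(columns={trait_x: "x", trait_y: "y"})
    return pairs_from_subjects(df, ["x", "y"])


def flip_trait(pairs2: pd.DataFrame, trait: str = "y") -> pd.DataFrame:
    """Negate one trait (both twins) — a sign flag for direction conventions."""
    out = pairs2.copy()
    for k in (1, 2):
        out[f"{trait}_{k}"] = -out[f"{trait}_{k}"]
    return out


def _prepare(pairs2: pd.DataFrame):
    """Split families by zygosity and missingness pattern for fast FIML."""
    prepared = {}
    h = hashlib.sha1()
    for zyg in ("MZ", "DZ"):
        sub = pairs2[pairs2["zygosity"] == zyg]
        data = sub[["x_1", "y_1", "x_2", "y_2"]].to_numpy(dtype=float)
        miss = np.isnan(data)
        keep = ~miss.all(axis=1)
        data, miss = data[keep], miss[keep]
        patterns, inverse = np.unique(miss, axis=0, return_inverse=True)
        groups = []
        for p_idx, pattern in enumerate(patterns):
            obs = np.flatnonzero(~pattern)
            rows = data[inverse == p_idx][:, obs]
            groups.append((obs, rows))
            h.update(pattern.tobytes())
            h.update(np.ascontiguousarray(rows).tobytes())
        prepared[zyg] = groups
    return prepared, h.hexdigest()[:16]


def _pair_cov(source_covs: dict[str, np.ndarray], zyg: str) -> np.ndarray:
    w = 1.0 if zyg == "MZ" else 0.5
    within = source_covs["a"] + source_covs["c"] + source_covs["e"]
    cross = w * source_covs["a"] + source_covs["c"]
    return np.block([[within, cross], [cross, within]])


def _fiml_neg2ll(prepared, mean4: np.ndarray, covs: dict[str, np.ndarray]) -> float:
    total = 0.0
    for zyg, groups in prepared.items():
        sigma = _pair_cov(covs, zyg)
        for obs, rows in groups:
            sub = sigma[np.ix_(obs, obs)]
            try:
                chol = np.linalg.cholesky(sub)
            except np.linalg.LinAlgError:
                return BIG_PENALTY
            dev = rows - mean4[obs]
            z = np.linalg.solve(chol, dev.T)
            quad = float(np.einsum("ij,ij->", z, z))
            logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
            n, k = rows.shape
            total += n * (k * _LOG_2PI + logdet) + quad
    return total


def _complete_moments(prepared):
    """Sample within/cross-twin moments from complete families, per zygosity."""
    stats = {}
    for zyg, groups in prepared.items():
        rows = None
        for obs, r in groups:
            if len(obs) == 4:
                rows = r
        if rows is None or rows.shape[0] < 3:
            stats[zyg] = None
            continue
        mu = rows.mean(axis=0)
        cov = np.cov(rows.T)
        within = 0.5 * (cov[:2, :2] + cov[2:, 2:])
        cross = 0.5 * (cov[:2, 2:] + cov[2:, :2].T)
        cross = 0.5 * (cross + cross.T)
        stats[zyg] = (mu, within, cross)
    return stats


def _psd_clip(m: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    w, v = np.linalg.eigh(0.5 * (m + m.T))
    return (v * np.clip(w, floor, None)) @ v.T


def _moment_start(prepared):
    """DeFries-Fulker-style moment estimates of the source covariances."""
    stats = _complete_moments(prepared)
    if stats["MZ"] is None or stats["DZ"] is None:
        eye = np.eye(2)
        return np.zeros(2), {"a": 0.3 * eye, "c": 0.2 * eye, "e": 0.5 * eye}
    mu = 0.5 * (stats["MZ"][0][:2] + stats["MZ"][0][2:]
                + stats["DZ"][0][:2] + stats["DZ"][0][2:]) / 2.0
    within = 0.5 * (stats["MZ"][1] + stats["DZ"][1])
    sig_a = _psd_clip(2.0 * (stats["MZ"][2] - stats["DZ"][2]))
    sig_c = _psd_clip(2.0 * stats["DZ"][2] - stats["MZ"][2])
    sig_e = _psd_clip(within - sig_a - sig_c)
    return mu, {"a": sig_a, "c": sig_c, "e": sig_e}


# ---------------------------------------------------------------------------
# Cholesky decomposition
# ---------------------------------------------------------------------------

def _tri(x3) -> np.ndarray:
    return np.array([[x3[0], 0.0], [x3[1], x3[2]]])


def _decomposition_from(
    source_covs: dict[str, np.ndarray],
    common: dict[str, np.ndarray],
) -> BivariateDecomposition:
    """Assemble shares and correlations given per-source common variances."""
    totals = sum(source_covs[s] for s in _SOURCES)
    v = np.diag(totals)
    corr = correlation_decomposition(source_covs)
    common_shares, specific_shares = {}, {}
    for s in _SOURCES:
        cm = np.asarray(common[s], dtype=float)
        sp = np.diag(source_covs[s]) - cm
        common_shares[s.upper() + "c"] = tuple(cm / v)
        specific_shares[s.upper() + "s"] = tuple(np.clip(sp, 0.0, None) / v)
    return BivariateDecomposition(
        common={s: common_shares[s.upper() + "c"] for s in _SOURCES},
        specific={s: specific_shares[s.upper() + "s"] for s in _SOURCES},
        h2=tuple(np.diag(source_covs["a"]) / v),
        rP=corr.rP, rG=corr.rG, rC=corr.rC, rE=corr.rE,
    )


def fit_cholesky(
    pairs2: pd.DataFrame,
    order: tuple[int, int] = (1, 2),
    seed: int = 0,
    n_restarts: int = 3,
    drop: tuple[str, ...] = (),
) -> BivariateFit:
    """ML bivariate Cholesky fit in the requested variable order.

    ``order=(2, 1)`` swaps traits x and y before fitting.  The -2lnL is
    identical for both orders (the triangular factorisation is a
    reparameterisation), but the common/specific split of the first trait
    is not separated by a single run: a trait's specific share is read from
    the run in which it comes second.  Sources named in ``drop`` have all
    their paths fixed at zero (the usual follow-up when a source's estimated
    influence is zero or near zero).
    """
    if order not in ((1, 2), (2, 1)):
        raise ValueError("order must be (1, 2) or (2, 1)")
    for s in drop:
        if s not in _SOURCES:
            raise ValueError(f"unknown source {s!r} in drop")
        if s == "e":
            raise ValueError("the unique-environment source cannot be dropped")
    df = pairs2
    if order == (2, 1):
        df = pairs2.rename(columns={
            "x_1": "y_1", "y_1": "x_1", "x_2": "y_2", "y_2": "x_2"})
    prepared, data_hash = _prepare(df)
    mu0, covs0 = _moment_start(prepared)

    def pack(covs):
        out = []
        for s in _SOURCES:
            if s in drop:
                continue
            L = np.linalg.cholesky(_psd_clip(covs[s], 1e-8) + 1e-10 * np.eye(2))
            out.extend([L[0, 0], L[1, 0], L[1, 1]])
        return out

    x0 = np.array(pack(covs0) + list(mu0))
    kept = [s for s in _SOURCES if s not in drop]

    def unpack(x):
        tri = {s: np.zeros((2, 2)) for s in _SOURCES}
        for i, s in enumerate(kept):
            tri[s] = _tri(x[3 * i:3 * i + 3])
        paths = CholeskyPaths(a=tri["a"], c=tri["c"], e=tri["e"])
        return paths, x[3 * len(kept):3 * len(kept) + 2]

    def neg2ll(x):
        paths, mean2 = unpack(x)
        mean4 = np.concatenate([mean2, mean2])
        return _fiml_neg2ll(prepared, mean4, paths.source_covs())

    big = 10.0 * max(1.0, float(np.sqrt(np.max(np.diag(sum(covs0.values()))))))
    bounds = []
    for _ in kept:
        bounds += [(0.0, big), (-big, big), (0.0, big)]
    bounds += [(None, None)] * 2
    rng = np.random.default_rng(seed)
    res = minimize_restarts(neg2ll, x0, bounds, rng, n_restarts=n_restarts)
    paths, mean2 = unpack(res.x)
    covs = paths.source_covs()
    # common share of trait 2 flows through factor 1; trait 1's source
    # variance is carried entirely by its own factor in this order
    common = {s: np.array([covs[s][0, 0], getattr(paths, s)[1, 0] ** 2])
              for s in _SOURCES}
    decomp = _decomposition_from(covs, common)
    return BivariateFit(
        fit=ModelFit("cholesky", float(res.fun), 3 * len(kept) + 2,
                     bool(res.success), data_hash),
        source_covs=covs,
        means=(float(mean2[0]), float(mean2[1])),
        decomposition=decomp,
        paths=paths,
        order=order,
        _data=(prepared,),
    )


# ---------------------------------------------------------------------------
# independent pathway model
# ---------------------------------------------------------------------------

def fit_independent_pathway(
    pairs2: pd.DataFrame,
    constraints: tuple[str, ...] = ("a", "c", "e"),
    seed: int = 0,
    n_restarts: int = 3,
) -> BivariateFit:
    """ML constrained independent-pathway fit.

    One common factor per source loads on both traits — with equal loadings
    for every source named in ``constraints`` (the default ties all three,
    the standard identification scheme) — plus trait-specific A/C/E factors.
    The model is rejected before optimisation if the free covariance-structure
    parameters exceed the 9 distinct moment conditions of the two-group
    bivariate twin design.

    Note the equal-loadings constraint forces nonnegative cross-trait
    covariance; traits with a negative association should have one member
    sign-flipped first (see ``flip_trait``).
    """
    constraints = tuple(constraints)
    for s in constraints:
        if s not in _SOURCES:
            raise ValueError(f"unknown source {s!r} in constraints")
    n_structure = sum(1 if s in constraints else 2 for s in _SOURCES) + 6
    if n_structure > 9:
        raise ValueError(
            f"{n_structure} covariance-structure parameters exceed the 9 "
            "identified moment conditions; constrain more loadings"
        )
    prepared, data_hash = _prepare(pairs2)
    mu0, covs0 = _moment_start(prepared)

    names = []
    for s in _SOURCES:
        names.append(f"l_{s}" if s in constraints else f"l_{s}1")
        if s not in constraints:
            names.append(f"l_{s}2")
    for s in _SOURCES:
        names += [f"u_{s}1", f"u_{s}2"]

    def unpack(x):
        p = dict(zip(names, x))
        covs, loadings = {}, {}
        for s in _SOURCES:
            if s in constraints:
                lam = np.array([p[f"l_{s}"], p[f"l_{s}"]])
            else:
                lam = np.array([p[f"l_{s}1"], p[f"l_{s}2"]])
            u = np.array([p[f"u_{s}1"], p[f"u_{s}2"]])
            covs[s] = np.outer(lam, lam) + np.diag(u ** 2)
            loadings[s] = {"common": lam.copy(), "specific": u.copy()}
        return covs, loadings, x[len(names):]

    def neg2ll(x):
        covs, _, mean2 = unpack(x)
        mean4 = np.concatenate([mean2, mean2])
        return _fiml_neg2ll(prepared, mean4, covs)

    x0 = []
    for s in _SOURCES:
        cross = max(covs0[s][0, 1], 0.0)
        lam0 = np.sqrt(cross) if cross > 1e-8 else 0.1
        if s in constraints:
            x0.append(lam0)
        else:
            x0 += [lam0, lam0]
    for s in _SOURCES:
        for i in range(2):
            x0.append(np.sqrt(max(0.5 * covs0[s][i, i], 0.05)))
    x0 += list(mu0)
    big = 10.0 * max(1.0, float(np.sqrt(np.max(np.diag(sum(covs0.values()))))))
    bounds = []
    for s in _SOURCES:
        bounds.append((0.0, big))  # first (or tied) loading nonnegative
        if s not in constraints:
            bounds.append((-big, big))
    bounds += [(0.0, big)] * 6
    bounds += [(None, None)] * 2
    rng = np.random.default_rng(seed)
    res = minimize_restarts(neg2ll, np.array(x0), bounds, rng,
                            n_restarts=n_restarts)
    covs, loadings, mean2 = unpack(res.x)
    common = {s: loadings[s]["common"] ** 2 for s in _SOURCES}
    decomp = _decomposition_from(covs, common)
    return BivariateFit(
        fit=ModelFit("independent_pathway", float(res.fun),
                     n_structure + 2, bool(res.success), data_hash),
        source_covs=covs,
        means=(float(mean2[0]), float(mean2[1])),
        decomposition=decomp,
        loadings=loadings,
        _data=(prepared,),
    )


def fit_saturated_bivariate(pairs2: pd.DataFrame, seed: int = 0) -> ModelFit:
    """Fully saturated two-group 4-variate fit (baseline -2lnL).

    Per zygosity: 4 free means and an unstructured 4x4 covariance (10
    Cholesky elements) — 28 parameters.  Used as the likelihood floor when
    checking structured fits.
    """
    from scipy import optimize

    prepared, data_hash = _prepare(pairs2)
    stats = _complete_moments(prepared)

    def group_x0(zyg):
        if stats[zyg] is None:
            return list(np.zeros(4)) + list(np.linalg.cholesky(np.eye(4))[np.tril_indices(4)])
        mu, within, cross = stats[zyg]
        sigma = np.block([[within, cross], [cross, within]])
        L = np.linalg.cholesky(_psd_clip(sigma, 1e-4))
        return list(mu) + list(L[np.tril_indices(4)])

    def unpack(x, off):
        mu = x[off:off + 4]
        L = np.zeros((4, 4))
        L[np.tril_indices(4)] = x[off + 4:off + 14]
        return mu, L @ L.T

    def neg2ll(x):
        total = 0.0
        for off, zyg in ((0, "MZ"), (14, "DZ")):
            mu, sigma = unpack(x, off)
            for obs, rows in prepared[zyg]:
                sub = sigma[np.ix_(obs, obs)]
                try:
                    chol = np.linalg.cholesky(sub)
                except np.linalg.LinAlgError:
                    return float("inf")
                dev = rows - mu[obs]
                z = np.linalg.solve(chol, dev.T)
                n, k = rows.shape
                total += (n * (k * _LOG_2PI
                               + 2.0 * np.sum(np.log(np.diag(chol))))
                          + float(np.einsum("ij,ij->", z, z)))
        return total

    x0 = np.array(group_x0("MZ") + group_x0("DZ"))
    bounds = []
    for _ in range(2):
        bounds += [(None, None)] * 4
        diag_idx = {0, 2, 5, 9}
        bounds += [(1e-6, None) if i in diag_idx else (None, None)
                   for i in range(10)]
    res = optimize.minimize(neg2ll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"ftol": 1e-12, "maxiter": 5000})
    return ModelFit("saturated_bivariate", float(res.fun), 28,
                    bool(res.success), data_hash)


# ---------------------------------------------------------------------------
# correlations and shared proportions
# ---------------------------------------------------------------------------

def correlation_decomposition(
    source_covs: dict[str, np.ndarray] | BivariateFit,
) -> CorrelationDecomposition:
    """Phenotypic, genetic and environmental correlations from source covs.

    rG = cov_A(x, y) / sqrt(var_A(x) var_A(y)) and analogously for rC and
    rE; each source contributes cov_S(x, y) / sqrt(v_x v_y) to rP and the
    contributions sum to rP exactly.  A source with zero variance in either
    trait has an undefined correlation, reported as NaN.
    """
    covs = source_covs.source_covs if isinstance(source_covs, BivariateFit) else source_covs
    covs = {s: np.asarray(covs[s], dtype=float) for s in _SOURCES}
    total = sum(covs.values())
    v1, v2 = total[0, 0], total[1, 1]
    if v1 <= 0 or v2 <= 0:
        raise ValueError("trait variances must be positive")
    denom = np.sqrt(v1 * v2)
    contributions = {s: float(covs[s][0, 1] / denom) for s in _SOURCES}
    rs = {}
    for s in _SOURCES:
        va, vb = covs[s][0, 0], covs[s][1, 1]
        rs[s] = float(covs[s][0, 1] / np.sqrt(va * vb)) if va > 1e-12 and vb > 1e-12 else float("nan")
    return CorrelationDecomposition(
        rP=float(sum(contributions.values())),
        rG=rs["a"], rC=rs["c"], rE=rs["e"],
        contributions=contributions,
    )


def shared_proportion(common_share: float, total_share: float) -> int:
    """Percentage of a source's variance in a trait that is shared.

    E.g. a common-A share of 0.35 of total variance against a total A share
    of 0.63 gives 56%.  Rounded to the nearest integer percent for
    reporting.
    """
    if total_share <= 0:
        raise ValueError("total_share must be positive")
    if not 0.0 <= common_share <= total_share + 1e-12:
        raise ValueError("need 0 <= common_share <= total_share")
    return int(round(100.0 * common_share / total_share))
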