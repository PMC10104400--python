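"""Gaussian likelihood utilities shared by the univariate and bivariate twin models.

All model fitting in this package reduces to minimising a multivariate-normal
-2 log-likelihood over family-level observation vectors in which some entries
may be missing (unmatched twins, subjects with no school nights, dropped
nights).  Incomplete rows contribute the marginal likelihood of their observed
entries (full-information maximum likelihood), which is the standard treatment
of missing co-twin data in the classical twin design.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

_LOG_2PI = float(np.log(2.0 * np.pi))

# finite penalty for invalid covariance regions (keeps finite-difference
# gradients well defined where a hard inf would poison them)
BIG_PENALTY = 1e12


def mvn_neg2ll(data: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """FIML -2 log-likelihood of ``data`` rows under N(mean, cov).

    Parameters
    ----------
    data
        (n, k) array; NaN marks a missing entry.  Rows that are entirely
        missing contribute nothing.
    mean, cov
        Mean vector (k,) and covariance (k, k) of the complete observation.

    Returns
    -------
    float
        -2 log L; ``inf`` if any required sub-covariance is not positive
        definite (so optimisers can step away from invalid regions).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != len(mean):
        raise ValueError("data must be (n, k) matching the mean vector")
    miss = np.isnan(data)
    total = 0.0
    # group rows by missingness pattern: each pattern has a closed-form block
    patterns, inverse = np.unique(miss, axis=0, return_inverse=True)
    for p_idx, pattern in enumerate(patterns):
        obs = ~pattern
        if not obs.any():
            continue
        rows = data[inverse == p_idx][:, obs]
        sub_mean = mean[obs]
        sub_cov = cov[np.ix_(obs, obs)]
        try:
            chol = np.linalg.cholesky(sub_cov)
        except np.linalg.LinAlgError:
            return BIG_PENALTY
        dev = rows - sub_mean
        # solve L z = dev'  ->  quadratic form = sum z^2
        z = np.linalg.solve(chol, dev.T)
        quad = float(np.einsum("ij,ij->", z, z))
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
        n, k = rows.shape
        total += n * (k * _LOG_2PI + logdet) + quad
    return total


def minimize_restarts(
    fun,
    x0: np.ndarray,
    bounds,
    rng: np.random.Generator,
    n_restarts: int = 5,
    jitter: float = 0.3,
):
    """Bounded quasi-Newton minimisation with random restarts.

    Twin-model likelihoods are invariant to path signs, so the surface is
    multimodal; restarts from jittered starting points guard against poor
    local optima.  Returns the best ``OptimizeResult``.
    """
    best = None
    starts = [np.asarray(x0, dtype=float)]
    for _ in range(max(0, n_restarts - 1)):
        lo = np.array([b[0] if b[0] is not None else -2.0 for b in bounds])
        hi = np.array([b[1] if b[1] is not None else 2.0 for b in bounds])
        pert = starts[0] + rng.normal(0.0, jitter, size=len(starts[0]))
        starts.append(np.clip(pert, lo + 1e-9, hi - 1e-9))
    for s in starts:
        res = optimize.minimize(
            fun, s, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 2000},
        )
        if best is None or (np.isfinite(res.fun) and res.fun < best.fun - 1e-12):
            best = res
    # derivative-free polish: quasi-Newton precision is limited by
    # finite-difference gradient noise near the optimum
    polish = optimize.minimize(
        fun, best.x, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
    )
    lo = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
    hi = np.array([b[1] if b[1] is not None else np.inf for b in bounds])
    if polish.fun < best.fun and np.all(polish.x >= lo) and np.all(polish.x <= hi):
        best.x, best.fun = polish.x, polish.fun
    return best


def lrt_pvalue(minus2ll_sub: float, minus2ll_full: float, df: int) -> float:
    """Likelihood-ratio p-value for a nested comparison with ``df`` constraints."""
    from scipy.stats import chi2

    stat = max(0.0, minus2ll_sub - minus2ll_full)
    if df <= 0:
        return float("nan")
    return float(chi2.sf(stat, df))
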