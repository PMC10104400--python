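"""Shared fixtures: exact-moment twin datasets and small simulated cohorts.

``exact_moment_pairs`` builds datasets whose maximum-likelihood sample
moments (n-denominator) equal a prescribed population structure exactly, so
just-identified ML fits must reproduce the population decomposition to
optimiser precision — the oracle-equivalence device used throughout.
"""

import numpy as np
import pandas as pd
import pytest

from twinsleep import simulate as sim


def _color_to(data: np.ndarray, target_cov: np.ndarray) -> np.ndarray:
    """Transform rows so the ML (n-denominator) moments hit target exactly."""
    x = data - data.mean(axis=0)
    s = x.T @ x / len(x)
    white = x @ np.linalg.inv(np.linalg.cholesky(s)).T
    return white @ np.linalg.cholesky(target_cov).T


def make_exact_moment_pairs(rmz: float, rdz: float, n_mz: int = 400,
                            n_dz: int = 400, seed: int = 0) -> pd.DataFrame:
    """Complete twin pairs whose sample correlations equal (rmz, rdz) exactly."""
    rng = np.random.default_rng(seed)
    frames = []
    for zyg, r, n, offset in (("MZ", rmz, n_mz, 0), ("DZ", rdz, n_dz, n_mz)):
        raw = rng.standard_normal((n, 2))
        y = _color_to(raw, np.array([[1.0, r], [r, 1.0]]))
        frames.append(pd.DataFrame({
            "family_id": [f"X{offset + i:05d}" for i in range(n)],
            "zygosity": zyg, "y_1": y[:, 0], "y_2": y[:, 1],
        }))
    return pd.concat(frames, ignore_index=True)


def make_exact_moment_pairs2(paths: sim.BivariatePaths, n_mz: int = 400,
                             n_dz: int = 400, seed: int = 0) -> pd.DataFrame:
    """Complete two-trait pairs whose 4x4 sample moments match the paths."""
    rng = np.random.default_rng(seed)
    frames = []
    for zyg, n, offset in (("MZ", n_mz, 0), ("DZ", n_dz, n_mz)):
        target = paths.implied_pair_cov(zyg)
        raw = rng.standard_normal((n, 4))
        y = _color_to(raw, target)
        frames.append(pd.DataFrame({
            "family_id": [f"X{offset + i:05d}" for i in range(n)],
            "zygosity": zyg,
            "x_1": y[:, 0], "y_1": y[:, 1], "x_2": y[:, 2], "y_2": y[:, 3],
        }))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def duration_pairs_large():
    """50k+50k pairs under the full-sample sleep-duration ACE structure."""
    cfg = sim.SimConfig(n_mz_pairs=50_000, n_dz_pairs=50_000, n_singletons=0,
                        seed=101, a2=0.62, c2=0.08, e2=0.30)
    return sim.simulate_ace_pairs(cfg)


@pytest.fixture(scope="session")
def small_cohort_nights():
    """A small but structurally complete simulated night-record table."""
    cfg = sim.SimConfig(n_mz_pairs=40, n_dz_pairs=40, n_singletons=10, seed=42)
    return sim.simulate_night_records(cfg)
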