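"""Label-swapping max-|z| permutation threshold for a family of tests.

Per permutation one shared random permutation is applied to the sample
indices of every score column (breaking score-outcome links while keeping
outcome-covariate structure and inter-score correlation intact); every test
in the family is refit and the maximum absolute z-statistic recorded. The
empirical (1 - alpha) quantile of those maxima is the family-wise cutoff:
an observed test survives correction iff |z| >= z_crit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PermConfig:
    n_perm: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PermThreshold:
    z_crit: float
    null_max_abs_z: np.ndarray
    alpha: float
    n_perm: int
    seed: int
    n_failed_fits: int = 0


#: A family fit function maps (permuted score block) -> array of z-statistics,
#: one per test in the family.
FamilyFit = Callable[[np.ndarray], np.ndarray]


def empirical_quantile(null_max: np.ndarray, alpha: float) -> float:
    """Order-statistic (1 - alpha) quantile: the ceil((1-alpha) * n)-th
    smallest null maximum."""
    x = np.sort(np.asarray(null_max, dtype=float))
    k = int(np.ceil((1.0 - alpha) * len(x)))
    return float(x[max(k - 1, 0)])


def permute_family(
    scores: np.ndarray | pd.DataFrame,
    fit_family: FamilyFit,
    config: PermConfig = PermConfig(),
) -> PermThreshold:
    """Compute the empirical family-wise |z| cutoff.

    ``scores`` is the n x q block of score columns shared by the family;
    ``fit_family`` must refit every test against a row-permuted copy of that
    block and return the vector of z-statistics. A permuted fit that raises
    contributes |z| = 0 for that permutation and is counted in
    ``n_failed_fits``.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    n = S.shape[0]
    # verify the family fits on unpermuted data before burning permutations
    z0 = np.asarray(fit_family(S), dtype=float)
    if z0.size == 0:
        raise ValueError("family must contain at least one test")

    rng = np.random.default_rng(config.seed)
    null_max = np.empty(config.n_perm)
    n_failed = 0
    for b in range(config.n_perm):
        perm = rng.permutation(n)
        try:
            z = np.asarray(fit_family(S[perm]), dtype=float)
            null_max[b] = np.nanmax(np.abs(z))
        except Exception:
            null_max[b] = 0.0
            n_failed += 1
    z_crit = empirical_quantile(null_max, config.alpha)
    return PermThreshold(
        z_crit=z_crit,
        null_max_abs_z=null_max,
        alpha=config.alpha,
        n_perm=config.n_perm,
        seed=config.seed,
        n_failed_fits=n_failed,
    )


def apply_threshold(
    results: pd.DataFrame, threshold: PermThreshold, z_col: str = "z"
) -> pd.DataFrame:
    """Append a boolean ``significant`` column: |z| >= z_crit (inclusive)."""
    out = results.copy()
    out["significant"] = out[z_col].abs() >= threshold.z_crit
    return out


# ---------------------------------------------------------------------------
# fast z computations used to build family fit functions


def ols_z_family(
    outcomes: np.ndarray, covar_design: pd.DataFrame | None = None
) -> FamilyFit:
    """Family of OLS z-statistics: each score column is tested against each
    outcome column after residualizing both on the covariates.

    Returns a fit function usable with :func:`permute_family`. z-statistics
    are the usual t-statistics of the score coefficient; computed via
    partial correlations for speed, which is exact for OLS.
    """
    Y = np.asarray(outcomes, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if covar_design is not None and covar_design.shape[1] > 0:
        C = np.column_stack(
            [np.ones(n), covar_design.to_numpy(dtype=float)]
        )
    else:
        C = np.ones((n, 1))
    Q, _ = np.linalg.qr(C)
    Yr = Y - Q @ (Q.T @ Y)
    Yr /= np.linalg.norm(Yr, axis=0)
    p_cov = C.shape[1]

    def fit(scores: np.ndarray) -> np.ndarray:
        S = scores - Q @ (Q.T @ scores)
        norms = np.linalg.norm(S, axis=0)
        norms[norms == 0] = np.inf
        R = (S / norms).T @ Yr  # (q, k) partial correlations
        dof = n - p_cov - 1
        t = R * np.sqrt(dof / np.clip(1.0 - R**2, 1e-12, None))
        return t.ravel()

    return fit


def threshold_summary(threshold: PermThreshold) -> dict:
    return {
        "z_crit": threshold.z_crit,
        "alpha": threshold.alpha,
        "n_perm": threshold.n_perm,
        "seed": threshold.seed,
        "n_failed_fits": threshold.n_failed_fits,
    }
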