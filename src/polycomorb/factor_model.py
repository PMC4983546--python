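"""One-factor maximum-likelihood confirmatory factor analysis.

The five ordinal involvement levels are treated as continuous indicator
codes and fit under normal-theory ML on their sample covariance matrix:

    Sigma(theta) = lambda lambda' + diag(psi),   factor variance fixed at 1.

The discrepancy function is the Wishart ML fit function
F = log|Sigma| + tr(S Sigma^-1) - log|S| - p, giving the model chi-square
(n - 1) * F at the minimum. The baseline (independence) model fits only the
diagonal, so its chi-square is -(n - 1) * log|R| with p(p-1)/2 degrees of
freedom. Factor scores are Thomson regression scores, z-standardized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

#: Relative floor for unique variances (Heywood guard): psi >= floor * s_jj.
PSI_FLOOR = 5e-3


@dataclass
class FactorModel:
    loadings: np.ndarray  # lambda, per indicator
    uniquenesses: np.ndarray  # psi, per indicator (> 0)
    chi2: float
    df: int
    chi2_baseline: float
    df_baseline: int
    cfi: float
    rmsea: float
    n: int
    indicator_names: list[str]
    indicator_means: np.ndarray
    heywood: bool = False
    converged: bool = True

    @property
    def implied_cov(self) -> np.ndarray:
        lam = self.loadings[:, None]
        return lam @ lam.T + np.diag(self.uniquenesses)


def _ml_discrepancy(lam: np.ndarray, psi: np.ndarray, S: np.ndarray) -> float:
    sigma = np.outer(lam, lam) + np.diag(psi)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    p = S.shape[0]
    _, logdet_s = np.linalg.slogdet(S)
    return logdet + np.trace(linalg.solve(sigma, S, assume_a="pos")) - logdet_s - p


def _principal_axis_start(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # first eigenvector of S scaled to eigenvalue gives loading starts
    w, v = np.linalg.eigh(S)
    lam = v[:, -1] * np.sqrt(max(w[-1], 1e-6))
    if lam.sum() < 0:
        lam = -lam
    psi = np.clip(np.diag(S) - lam**2, 0.05 * np.diag(S), None)
    return lam, psi


def fit_indices(
    chi2_m: float, df_m: int, chi2_b: float, df_b: int, n: int
) -> tuple[float, float]:
    """Comparative fit index and root-mean-square error of approximation.

    CFI = 1 - max(chi2_m - df_m, 0) / max(chi2_b - df_b, chi2_m - df_m, 0);
    RMSEA = sqrt(max(chi2_m - df_m, 0) / (df_m * (n - 1))).
    """
    if df_m <= 0 or df_b <= 0:
        raise ValueError("degrees of freedom must be positive")
    if n <= 1:
        raise ValueError("n must exceed 1")
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    rmsea = np.sqrt(num / (df_m * (n - 1)))
    return float(cfi), float(rmsea)


def fit_one_factor(table: pd.DataFrame, min_n: int = 50) -> FactorModel:
    """ML fit of the one-factor model to the indicator covariance matrix.

    ``table`` holds one numeric column per indicator (a ``sample_id`` column,
    if present, is ignored). Optimizes loadings and log unique variances by
    L-BFGS-B from a principal-axis start; unique variances are floored at a
    small fraction of the indicator variance and the fit is flagged as a
    Heywood case when the floor binds.
    """
    cols = [c for c in table.columns if c != "sample_id"]
    X = table[cols].to_numpy(dtype=float)
    n, p = X.shape
    if n < min_n:
        raise ValueError(f"need at least {min_n} samples, got {n}")
    variances = X.var(axis=0, ddof=1)
    if (variances <= 0).any():
        bad = [cols[j] for j in np.flatnonzero(variances <= 0)]
        raise ValueError(f"zero-variance indicators: {bad}")

    S = np.cov(X, rowvar=False, ddof=1)
    lam0, psi0 = _principal_axis_start(S)
    floor = PSI_FLOOR * np.diag(S)

    def objective(theta: np.ndarray) -> float:
        lam = theta[:p]
        psi = np.exp(theta[p:])
        return _ml_discrepancy(lam, psi, S)

    x0 = np.concatenate([lam0, np.log(psi0)])
    bounds = [(None, None)] * p + [(np.log(f), None) for f in floor]
    res = optimize.minimize(
        objective, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    lam = res.x[:p]
    psi = np.exp(res.x[p:])
    if lam.sum() < 0:  # sign convention
        lam = -lam
    heywood = bool(np.any(psi <= floor * (1 + 1e-6)))

    chi2_m = max((n - 1) * res.fun, 0.0)
    df_m = p * (p + 1) // 2 - 2 * p
    R = np.corrcoef(X, rowvar=False)
    _, logdet_r = np.linalg.slogdet(R)
    chi2_b = max(-(n - 1) * logdet_r, 0.0)
    df_b = p * (p - 1) // 2
    if df_m > 0:
        cfi, rmsea = fit_indices(chi2_m, df_m, chi2_b, df_b, n)
    else:  # just-identified (p = 3): perfect fit by construction
        cfi, rmsea = 1.0, 0.0

    return FactorModel(
        loadings=lam,
        uniquenesses=psi,
        chi2=float(chi2_m),
        df=df_m,
        chi2_baseline=float(chi2_b),
        df_baseline=df_b,
        cfi=cfi,
        rmsea=rmsea,
        n=n,
        indicator_names=cols,
        indicator_means=X.mean(axis=0),
        heywood=heywood,
        converged=bool(res.success),
    )


def factor_scores(model: FactorModel, table: pd.DataFrame) -> pd.Series:
    """Standardized Thomson regression factor scores.

    score_i is proportional to lambda' Sigma^-1 (x_i - xbar) under the fitted
    model; the output is z-standardized (mean 0, sd 1, ddof 0).
    """
    X = table[model.indicator_names].to_numpy(dtype=float)
    sigma = model.implied_cov
    try:
        weights = linalg.solve(sigma, model.loadings, assume_a="pos")
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("implied covariance is singular") from exc
    raw = (X - model.indicator_means) @ weights
    sd = raw.std()
    if sd == 0:
        raise ValueError("degenerate factor scores (zero variance)")
    scores = (raw - raw.mean()) / sd
    index = (
        table["sample_id"] if "sample_id" in table.columns else table.index
    )
    return pd.Series(scores, index=index, name="gensub")


def closed_form_loading_3(S: np.ndarray) -> np.ndarray:
    """Just-identified 3-indicator solution from sample covariances:
    lambda_1 = sqrt(s12 * s13 / s23) and cyclic permutations."""
    s12, s13, s23 = S[0, 1], S[0, 2], S[1, 2]
    return np.array(
        [
            np.sqrt(s12 * s13 / s23),
            np.sqrt(s12 * s23 / s13),
            np.sqrt(s13 * s23 / s12),
        ]
    )


def model_summary(model: FactorModel) -> dict:
    """JSON-serializable fit summary."""
    return {
        "loadings": dict(zip(model.indicator_names, model.loadings.tolist())),
        "uniquenesses": dict(
            zip(model.indicator_names, model.uniquenesses.tolist())
        ),
        "chi2": model.chi2,
        "df": model.df,
        "chi2_baseline": model.chi2_baseline,
        "df_baseline": model.df_baseline,
        "cfi": model.cfi,
        "rmsea": model.rmsea,
        "n": model.n,
        "heywood": model.heywood,
        "converged": model.converged,
    }
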