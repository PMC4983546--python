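"""Association tests: OLS incremental-R², multinomial logistic regression
with baseline-category logits, Wald equality contrasts, and factor-adjusted
reruns.

The multinomial fitter is a Newton-Raphson maximizer of the
baseline-category log-likelihood with step-halving; the coefficient
covariance is the inverse observed information. Scores entering any fit are
z-standardized so coefficients are per standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

GRAD_TOL = 1e-8
MAX_ITER = 200


# ---------------------------------------------------------------------------
# design construction


def standardize(x: np.ndarray | pd.Series) -> np.ndarray:
    """z-score with population sd; errors on constant input."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def age_quartiles(age: np.ndarray | pd.Series) -> np.ndarray:
    """4-level age bins with near-equal counts; ties broken by rank order."""
    age = np.asarray(age, dtype=float)
    n = len(age)
    order = np.argsort(age, kind="mergesort")
    q = np.empty(n, dtype=int)
    q[order] = np.minimum(np.arange(n) * 4 // n, 3)
    return q


def build_covariate_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Expand the raw covariate table into a numeric design block.

    sex stays binary; age becomes three quartile indicators (reference =
    first quartile); study becomes reference-coded indicators against the
    first observed category; principal components pass through.
    """
    out = pd.DataFrame(index=covariates.index)
    out["sex"] = covariates["sex"].astype(float)
    q = age_quartiles(covariates["age"])
    for k in (1, 2, 3):
        out[f"age_q{k + 1}"] = (q == k).astype(float)
    for c in covariates.columns:
        if c.startswith("pc"):
            out[c] = covariates[c].astype(float)
    study = covariates["study"].astype(str)
    ref = study.iloc[0]
    for lvl in [s for s in study.unique() if s != ref]:
        out[f"study_{lvl}"] = (study == lvl).astype(float)
    return out


def _design_matrix(blocks: list[tuple[str, np.ndarray]]) -> tuple[np.ndarray, list[str]]:
    names = ["const"] + [name for name, _ in blocks]
    n = len(blocks[0][1])
    X = np.column_stack([np.ones(n)] + [col for _, col in blocks])
    return X, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by incremental rank
        aliased = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            cand = kept + [j]
            if np.linalg.matrix_rank(X[:, cand]) == len(kept):
                aliased.append(names[j])
            else:
                kept.append(j)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


# ---------------------------------------------------------------------------
# OLS


@dataclass
class OlsResult:
    beta_std: float
    se: float
    z: float
    pvalue: float
    r2_full: float
    r2_cov: float
    r2_inc: float
    n: int


def _ols_r2(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - resid @ resid / tss if tss > 0 else 0.0
    return coef, resid, float(r2)


def ols_incremental(
    gensub: np.ndarray | pd.Series,
    prs: np.ndarray | pd.Series,
    covar_design: pd.DataFrame | None,
) -> OlsResult:
    """OLS of the factor score on the standardized score plus covariates.

    ``beta_std`` is the PRS coefficient from the full model; ``r2_inc`` is
    R²(full) − R²(covariates only); the p-value is the two-sided t-test on
    the PRS coefficient.
    """
    y = np.asarray(gensub, dtype=float)
    z = standardize(prs)
    blocks: list[tuple[str, np.ndarray]] = [("prs", z)]
    cov_blocks: list[tuple[str, np.ndarray]] = []
    if covar_design is not None and covar_design.shape[1] > 0:
        cov_blocks = [
            (c, covar_design[c].to_numpy(dtype=float)) for c in covar_design
        ]
    X_full, names = _design_matrix(blocks + cov_blocks)
    _check_rank(X_full, names)
    n, p = X_full.shape

    coef, resid, r2_full = _ols_r2(X_full, y)
    if cov_blocks:
        X_cov, _ = _design_matrix(cov_blocks)
        _, _, r2_cov = _ols_r2(X_cov, y)
    else:
        X_cov = np.ones((n, 1))
        r2_cov = 0.0

    dof = n - p
    sigma2 = resid @ resid / dof if dof > 0 else np.nan
    xtx_inv = np.linalg.inv(X_full.T @ X_full)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    b = float(coef[1])
    t = b / se if se > 0 else np.inf
    pval = 2.0 * stats.t.sf(abs(t), dof)
    return OlsResult(
        beta_std=b,
        se=se,
        z=float(t),
        pvalue=float(pval),
        r2_full=r2_full,
        r2_cov=r2_cov,
        r2_inc=r2_full - r2_cov,
        n=n,
    )


# ---------------------------------------------------------------------------
# multinomial logistic regression (baseline-category logits)


@dataclass
class MultinomResult:
    """Fit of K-level outcome on a design; level 0 is the reference.

    ``coefs`` has shape (K-1, p): row k-1 holds the level-k logit
    coefficients. ``cov`` is the (K-1)p × (K-1)p inverse observed
    information, parameters ordered level-major (all level-1 coefficients,
    then level-2, ...).
    """

    levels: np.ndarray
    coef_names: list[str]
    coefs: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int
    n: int

    def _flat_index(self, level: int, name: str) -> int:
        k = list(self.levels).index(level) - 1
        if k < 0:
            raise ValueError("reference level has no coefficients")
        j = self.coef_names.index(name)
        return k * len(self.coef_names) + j

    def coef(self, level: int, name: str = "prs") -> float:
        return float(self.coefs[list(self.levels).index(level) - 1,
                                self.coef_names.index(name)])

    def se(self, level: int, name: str = "prs") -> float:
        i = self._flat_index(level, name)
        return float(np.sqrt(self.cov[i, i]))

    def zstat(self, level: int, name: str = "prs") -> float:
        return self.coef(level, name) / self.se(level, name)

    def odds_ratio(self, level: int, name: str = "prs") -> float:
        return float(np.exp(self.coef(level, name)))

    def table(self, name: str = "prs") -> pd.DataFrame:
        rows = []
        for lvl in self.levels[1:]:
            b = self.coef(lvl, name)
            se = self.se(lvl, name)
            z = b / se
            rows.append(
                {
                    "level": int(lvl),
                    "coef": b,
                    "se": se,
                    "z": z,
                    "odds_ratio": np.exp(b),
                    "pvalue": 2.0 * stats.norm.sf(abs(z)),
                }
            )
        return pd.DataFrame(rows)


def _multinom_loglik(B: np.ndarray, X: np.ndarray, Y: np.ndarray) -> float:
    eta = X @ B.T  # (n, K-1)
    full = np.column_stack([np.zeros(len(X)), eta])
    lse = np.logaddexp.reduce(full, axis=1)
    return float(np.sum(full[np.arange(len(X)), Y]) - np.sum(lse))


def multinomial_fit(
    outcome: np.ndarray | pd.Series,
    prs: np.ndarray | pd.Series | None,
    covar_design: pd.DataFrame | None,
    extra: dict[str, np.ndarray] | None = None,
    max_abs_coef: float = 30.0,
) -> MultinomResult:
    """Newton-Raphson ML fit of the baseline-category logit model.

    The outcome levels are sorted ascending; the lowest observed level is the
    reference. Every level must be observed at least once. The step is
    halved until the log-likelihood does not decrease; convergence requires
    gradient max-norm below 1e-8. Coefficients drifting beyond
    ``max_abs_coef`` raise a separation error naming the worst predictor.
    """
    y = np.asarray(outcome)
    levels = np.unique(y)
    if len(levels) < 2:
        raise ValueError("outcome must have at least 2 observed levels")
    Y = np.searchsorted(levels, y)

    blocks: list[tuple[str, np.ndarray]] = []
    if prs is not None:
        blocks.append(("prs", standardize(prs)))
    if covar_design is not None:
        blocks += [
            (c, covar_design[c].to_numpy(dtype=float)) for c in covar_design
        ]
    if extra:
        # identically-zero extras carry no information; dropping them keeps
        # a null adjustment equivalent to the unadjusted fit
        blocks += [
            (k, col)
            for k, v in extra.items()
            if np.any(col := np.asarray(v, dtype=float))
        ]
    if blocks:
        X, names = _design_matrix(blocks)
    else:
        X, names = np.ones((len(y), 1)), ["const"]
    _check_rank(X, names)
    n, p = X.shape
    K = len(levels)

    # one-hot outcome, reference column dropped
    Yind = np.zeros((n, K))
    Yind[np.arange(n), Y] = 1.0
    Ynr = Yind[:, 1:]  # (n, K-1)

    B = np.zeros((K - 1, p))
    ll = _multinom_loglik(B, X, Y)
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        eta = X @ B.T
        full = np.column_stack([np.zeros(n), eta])
        full -= full.max(axis=1, keepdims=True)
        P = np.exp(full)
        P /= P.sum(axis=1, keepdims=True)
        Pnr = P[:, 1:]  # (n, K-1)

        G = X.T @ (Ynr - Pnr)  # (p, K-1); flat order level-major => G.T.ravel()
        grad = G.T.ravel()
        if np.max(np.abs(grad)) < GRAD_TOL:
            break

        # observed information: H[(k,j),(l,m)] = sum_i x_ij x_im *
        #   (P_ik (delta_kl - P_il))
        H = np.empty(((K - 1) * p, (K - 1) * p))
        for k in range(K - 1):
            for l in range(k, K - 1):
                w = Pnr[:, k] * ((1.0 if k == l else 0.0) - Pnr[:, l])
                blockH = X.T @ (X * w[:, None])
                H[k * p:(k + 1) * p, l * p:(l + 1) * p] = blockH
                if l != k:
                    H[l * p:(l + 1) * p, k * p:(k + 1) * p] = blockH
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]

        scale = 1.0
        for _ in range(40):
            B_new = B + scale * step.reshape(K - 1, p)
            ll_new = _multinom_loglik(B_new, X, Y)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        B, ll = B_new, ll_new

        if np.max(np.abs(B)) > max_abs_coef:
            k, j = np.unravel_index(np.argmax(np.abs(B)), B.shape)
            raise ValueError(
                f"apparent separation: coefficient for '{names[j]}' "
                f"(level {levels[k + 1]}) exceeds {max_abs_coef}"
            )
    else:
        raise RuntimeError("multinomial fit did not converge")

    # final information for the covariance
    eta = X @ B.T
    full = np.column_stack([np.zeros(n), eta])
    full -= full.max(axis=1, keepdims=True)
    P = np.exp(full)
    P /= P.sum(axis=1, keepdims=True)
    Pnr = P[:, 1:]
    H = np.empty(((K - 1) * p, (K - 1) * p))
    for k in range(K - 1):
        for l in range(k, K - 1):
            w = Pnr[:, k] * ((1.0 if k == l else 0.0) - Pnr[:, l])
            blockH = X.T @ (X * w[:, None])
            H[k * p:(k + 1) * p, l * p:(l + 1) * p] = blockH
            if l != k:
                H[l * p:(l + 1) * p, k * p:(k + 1) * p] = blockH
    cov = np.linalg.inv(H)

    return MultinomResult(
        levels=levels,
        coef_names=names,
        coefs=B,
        cov=cov,
        loglik=ll,
        n_iter=n_iter,
        n=n,
    )


def validate_all_levels(outcome: np.ndarray | pd.Series, expected: int = 5) -> None:
    """Raise if any of the ``expected`` levels 0..expected-1 is unobserved."""
    present = set(np.unique(np.asarray(outcome)).tolist())
    missing = sorted(set(range(expected)) - present)
    if missing:
        raise ValueError(f"outcome levels with zero observations: {missing}")


# ---------------------------------------------------------------------------
# Wald contrasts


@dataclass
class WaldResult:
    level_a: int
    level_b: int
    statistic: float
    pvalue: float


def wald_pair(
    result: MultinomResult, k: int, k2: int, name: str = "prs"
) -> WaldResult:
    """1-df Wald chi-square for equality of two level coefficients:
    (b_k - b_k')² / (Var_k + Var_k' - 2 Cov)."""
    if k == k2:
        raise ValueError("contrast requires two distinct levels")
    ref = result.levels[0]
    if k == ref or k2 == ref:
        raise ValueError("contrast levels must be non-reference")
    i = result._flat_index(k, name)
    j = result._flat_index(k2, name)
    diff = result.coefs.ravel()[i] - result.coefs.ravel()[j]
    var = result.cov[i, i] + result.cov[j, j] - 2.0 * result.cov[i, j]
    if var <= 0:
        raise ValueError("non-positive variance for the contrast")
    stat = diff * diff / var
    return WaldResult(
        level_a=int(k),
        level_b=int(k2),
        statistic=float(stat),
        pvalue=float(stats.chi2.sf(stat, df=1)),
    )


def all_wald_pairs(result: MultinomResult, name: str = "prs") -> list[WaldResult]:
    non_ref = [int(l) for l in result.levels[1:]]
    return [wald_pair(result, a, b, name) for a, b in combinations(non_ref, 2)]


def adjusted_rerun(
    outcome: np.ndarray | pd.Series,
    prs: np.ndarray | pd.Series,
    covar_design: pd.DataFrame | None,
    gensub: np.ndarray | pd.Series,
) -> MultinomResult:
    """Refit with the general-involvement factor score appended to the
    covariate block."""
    return multinomial_fit(
        outcome,
        prs,
        covar_design,
        extra={"gensub": np.asarray(gensub, dtype=float)},
    )
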