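"""Binary logistic regression with Wald inference, fitted in-house.

Maximum likelihood by Newton-Raphson on the log-likelihood, standard
errors from the inverse observed information, Wald chi-square statistics
and 95% confidence intervals for the odds ratios — the "enter method"
output style of clinical statistics packages.  Also provides Nagelkerke's
R^2, the likelihood-ratio model chi-square, classification accuracy at a
0.5 probability threshold, and the Box-Tidwell check for linearity of
continuous predictors in the logit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._utils import round_half_up

MAX_ITER = 25
SCORE_TOL = 1e-8
STEP_TOL = 1e-10
#: |coefficient| beyond which the fit is treated as (quasi-)separated
SEPARATION_BOUND = 15.0
Z_95 = 1.959963984540054


class SeparationError(RuntimeError):
    """Raised when the likelihood has no finite maximum (data separation)."""


@dataclass
class LogisticFit:
    params: pd.Series
    se: pd.Series
    wald: pd.Series
    p: pd.Series
    exp_b: pd.Series
    ci95: pd.DataFrame
    cov: np.ndarray = field(repr=False)
    log_likelihood: float = math.nan
    null_log_likelihood: float = math.nan
    model_chi2: float = math.nan
    model_df: int = 0
    model_p: float = math.nan
    nagelkerke_r2: float = math.nan
    cox_snell_r2: float = math.nan
    converged: bool = False
    n_iter: int = 0
    n_obs: int = 0


def _design(design) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(dtype=float), list(design.columns)
    arr = np.asarray(design, dtype=float)
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def add_intercept(predictors: pd.DataFrame, name: str = "const") -> pd.DataFrame:
    """Prepend an all-ones intercept column to a predictor table."""
    out = predictors.copy()
    out.insert(0, name, 1.0)
    return out


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically safe log-likelihood: -sum(log(1 + exp(-(2y-1) eta)))
    s = (2 * y - 1) * eta
    return float(-np.logaddexp(0.0, -s).sum())


def fit_logistic(design, y) -> LogisticFit:
    """Fit P(y=1) = expit(X b) by Newton-Raphson.

    ``design`` must already contain the intercept column (use
    :func:`add_intercept`).  Raises :class:`SeparationError` when the fit
    does not converge or a coefficient diverges, and ``ValueError`` on a
    singular design.
    """
    x, names = _design(design)
    y = np.asarray(y, dtype=float)
    n, k = x.shape
    if y.shape != (n,):
        raise ValueError("y must align with the design rows")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if y.sum() in (0, n):
        raise ValueError("both outcome classes must be present")
    if n <= k:
        raise ValueError("need more observations than parameters")
    if np.linalg.matrix_rank(x) < k:
        raise ValueError("singular design matrix")

    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = np.clip(x @ beta, -30.0, 30.0)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        score = x.T @ (y - p)
        hess = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "information matrix singular during iteration (separation or collinearity)"
            ) from exc
        beta = beta + step
        if np.max(np.abs(score)) < SCORE_TOL or np.max(np.abs(step)) < STEP_TOL:
            converged = True
            break
    if not converged or np.max(np.abs(beta)) > SEPARATION_BOUND:
        raise SeparationError(
            "logistic fit did not converge to finite coefficients; "
            "the outcome is (quasi-)separated by the predictors"
        )

    eta = x @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    hess = (x * (p * (1 - p))[:, None]).T @ x
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    wald = (beta / se) ** 2
    pvals = sps.chi2.sf(wald, df=1)
    ll = _loglik(y, eta)
    pbar = y.mean()
    ll0 = n * (pbar * math.log(pbar) + (1 - pbar) * math.log(1 - pbar))

    chi2 = max(0.0, -2.0 * (ll0 - ll))
    df = k - 1 if "const" in names or np.allclose(x[:, 0], 1.0) else k
    r2_cs = 1.0 - math.exp(2.0 * (ll0 - ll) / n)
    r2_max = 1.0 - math.exp(2.0 * ll0 / n)
    r2_n = r2_cs / r2_max if r2_max > 0 else math.nan

    idx = pd.Index(names)
    return LogisticFit(
        params=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        wald=pd.Series(wald, index=idx),
        p=pd.Series(pvals, index=idx),
        exp_b=pd.Series(np.exp(beta), index=idx),
        ci95=pd.DataFrame(
            {"lower": np.exp(beta - Z_95 * se), "upper": np.exp(beta + Z_95 * se)},
            index=idx,
        ),
        cov=cov,
        log_likelihood=ll,
        null_log_likelihood=ll0,
        model_chi2=chi2,
        model_df=df,
        model_p=float(sps.chi2.sf(chi2, df=max(df, 1))),
        nagelkerke_r2=min(max(r2_n, 0.0), 1.0),
        cox_snell_r2=r2_cs,
        converged=converged,
        n_iter=it,
        n_obs=n,
    )


def wald_or_ci(b: float, se: float, z: float = Z_95) -> tuple[float, tuple[float, float]]:
    """Odds ratio exp(B) and its Wald 95% CI from a coefficient and its SE."""
    if se < 0:
        raise ValueError("standard error cannot be negative")
    return math.exp(b), (math.exp(b - z * se), math.exp(b + z * se))


def nagelkerke_r2(fit: LogisticFit) -> float:
    """Nagelkerke's R^2 — Cox-Snell rescaled to a [0, 1] maximum."""
    if fit.log_likelihood < fit.null_log_likelihood - 1e-8:
        raise ValueError("fitted log-likelihood below the null: optimizer failure")
    return fit.nagelkerke_r2


def model_chi2(fit: LogisticFit) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square of the model vs the intercept-only null."""
    if fit.log_likelihood < fit.null_log_likelihood - 1e-8:
        raise ValueError("fitted log-likelihood below the null: optimizer failure")
    return fit.model_chi2, fit.model_df, fit.model_p


def predict_probability(coefficients, values) -> float | np.ndarray:
    """Inverse-logit of the linear predictor for given coefficient values.

    ``coefficients`` and ``values`` must align position-for-position (or
    share an index when both are pandas Series).
    """
    if isinstance(coefficients, pd.Series) and isinstance(values, pd.Series):
        if not coefficients.index.equals(values.index):
            raise ValueError("coefficient and value indexes do not match")
        eta = float((coefficients * values).sum())
        return 1.0 / (1.0 + math.exp(-eta))
    b = np.asarray(coefficients, dtype=float)
    v = np.asarray(values, dtype=float)
    if b.shape[0] != v.shape[-1]:
        raise ValueError("coefficient/value length mismatch")
    eta = v @ b
    return 1.0 / (1.0 + np.exp(-eta))


def accuracy_at_half(fit: LogisticFit, design, y) -> float:
    """Percent of cases correctly classified at the 0.5 probability cut."""
    x, _ = _design(design)
    y = np.asarray(y, dtype=float)
    p = 1.0 / (1.0 + np.exp(-(x @ fit.params.to_numpy())))
    correct = (p >= 0.5).astype(float) == y
    return round_half_up(100.0 * correct.mean(), 1)


def box_tidwell(
    design: pd.DataFrame, y, continuous: list[str], zero_shift: float = 0.01
) -> pd.Series:
    """Box-Tidwell linearity-in-the-logit check.

    Augments the model with an x*ln(x) term for every listed continuous
    predictor (zeros shifted up by ``zero_shift`` first) and returns each
    augmentation term's Wald p-value; a small p flags non-linearity.
    Negative predictor values are an error.
    """
    if not isinstance(design, pd.DataFrame):
        raise TypeError("box_tidwell needs a DataFrame design to name columns")
    aug = design.copy()
    for col in continuous:
        if col not in design.columns:
            raise KeyError(f"unknown continuous predictor '{col}'")
        x = design[col].to_numpy(dtype=float).copy()
        x[x == 0] = zero_shift
        if (x <= 0).any():
            raise ValueError(f"predictor '{col}' has non-positive values after shift")
        aug[f"{col}:xlnx"] = x * np.log(x)
    fit = fit_logistic(aug, y)
    return fit.p[[f"{c}:xlnx" for c in continuous]].rename(
        {f"{c}:xlnx": c for c in continuous}
    )
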