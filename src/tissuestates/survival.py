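"""Enrichment-stratified survival analysis.

Binarizes signature enrichment scores, estimates Kaplan-Meier curves, tests
group differences with the log-rank statistic, and fits Cox proportional
hazards by Newton-Raphson on the Breslow partial likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tissuestates._errors import (
    ConvergenceError,
    InvalidArgumentError,
)
from tissuestates.synthetic import SurvivalTable

NEGATIVE = "negative"
POSITIVE = "positive"


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        """S(t): survival just after time t (S(0) = 1)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxResult:
    """Cox proportional-hazards fit (Breslow ties)."""

    coef: pd.Series
    hazard_ratio: pd.Series
    se: pd.Series
    p_value: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    tie_method: str
    log_likelihood: float
    n_events: int


@dataclass
class AdjustedCoxResult:
    """Cox fit before/after appending an extra enrichment covariate."""

    unadjusted: CoxResult
    adjusted: CoxResult
    focal: str

    @property
    def coef_change(self) -> float:
        return float(self.adjusted.coef[self.focal] - self.unadjusted.coef[self.focal])


# ---------------------------------------------------------------------------


def binarize_enrichment(scores) -> np.ndarray:
    """positive iff the score is strictly > 0; zero counts as negative."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise InvalidArgumentError("scores must be finite")
    return np.where(scores > 0, POSITIVE, NEGATIVE)


def km_estimate(
    table: SurvivalTable, groups: np.ndarray | pd.Series | None = None
) -> dict[str, KMCurve]:
    """Kaplan-Meier product-limit estimate per group."""
    time, event = table.time, table.event
    if np.any(time <= 0):
        raise InvalidArgumentError("times must be positive")
    if groups is None:
        groups = np.full(len(time), "all")
    groups = np.asarray(groups)
    curves: dict[str, KMCurve] = {}
    for grp in np.unique(groups):
        m = groups == grp
        t, e = time[m], event[m]
        ev_times = np.unique(t[e == 1])
        at_risk = np.array([(t >= et).sum() for et in ev_times], dtype=int)
        d = np.array([((t == et) & (e == 1)).sum() for et in ev_times], dtype=int)
        surv = np.cumprod(1.0 - d / at_risk) if len(ev_times) else np.array([])
        curves[str(grp)] = KMCurve(
            times=ev_times, at_risk=at_risk, events=d, survival=surv
        )
    return curves


def logrank_test(
    table: SurvivalTable, groups: np.ndarray | pd.Series
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) with 1 df."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise InvalidArgumentError("exactly 2 groups required")
    time, event = table.time, table.event
    g1 = groups == labels[0]
    for lab, m in ((labels[0], g1), (labels[1], ~g1)):
        if event[m].sum() == 0:
            raise InvalidArgumentError(f"group {lab} has no events")
    ev_times = np.unique(time[event == 1])
    O1 = E1 = V = 0.0
    for t in ev_times:
        at = time >= t
        n = at.sum()
        n1 = (at & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0, 1.0
    chi2 = (O1 - E1) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _design_matrix(
    table: SurvivalTable, covariates: list[str]
) -> pd.DataFrame:
    df = table.data[covariates].copy()
    obj = [c for c in df.columns if df[c].dtype == object or str(df[c].dtype) == "category"]
    if obj:
        df = pd.get_dummies(df, columns=obj, drop_first=True, dtype=float)
    df = df.astype(float)
    const = [c for c in df.columns if df[c].nunique() <= 1]
    if const:
        warnings.warn(
            f"dropping constant covariate(s): {const} "
            "(inestimable in a proportional-hazards model)",
            stacklevel=3,
        )
        df = df.drop(columns=const)
    if df.shape[1] == 0:
        raise InvalidArgumentError("no usable covariate remains")
    rank = np.linalg.matrix_rank(df.to_numpy())
    if rank < df.shape[1]:
        raise InvalidArgumentError(
            f"design matrix rank-deficient over columns {list(df.columns)}"
        )
    return df


def _breslow_score_info(
    time: np.ndarray, event: np.ndarray, X: np.ndarray, beta: np.ndarray
):
    """Log partial likelihood, score and information under Breslow ties."""
    order = np.argsort(-time, kind="stable")  # descending: risk sets accumulate
    t_s, e_s, X_s = time[order], event[order], X[order]
    eta = X_s @ beta
    theta = np.exp(eta)
    n, p = X_s.shape

    s0 = np.cumsum(theta)
    s1 = np.cumsum(theta[:, None] * X_s, axis=0)
    s2 = np.cumsum(theta[:, None, None] * (X_s[:, :, None] * X_s[:, None, :]), axis=0)

    # risk set at time t = all subjects with time >= t: because sorted
    # descending, the risk set for the subject at position i is positions
    # 0..last index sharing time >= t_i; ties share the full risk set.
    loglik = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        # risk set = positions 0..j
        S0, S1, S2 = s0[j], s1[j], s2[j]
        for idx in range(i, j + 1):
            if e_s[idx] == 1:
                xb = S1 / S0
                loglik += eta[idx] - np.log(S0)
                score += X_s[idx] - xb
                info += S2 / S0 - np.outer(xb, xb)
        i = j + 1
    return loglik, score, info


def cox_ph(
    table: SurvivalTable,
    covariates: list[str],
    tie_method: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxResult:
    """Cox proportional hazards via Newton-Raphson (Breslow ties).

    Standard errors come from the inverse observed information; Wald
    p-values and 95% confidence intervals are reported per covariate.
    """
    if tie_method != "breslow":
        raise InvalidArgumentError("only breslow tie handling is implemented")
    X_df = _design_matrix(table, covariates)
    X = X_df.to_numpy()
    time, event = table.time, table.event
    if event.sum() == 0:
        raise InvalidArgumentError("no events in the table")

    # center covariates for numerical stability (does not change beta)
    X = X - X.mean(axis=0)
    beta = np.zeros(X.shape[1])
    for it in range(max_iter):
        loglik, score, info = _breslow_score_info(time, event, X, beta)
        if np.abs(score).max() < tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix at iteration {it}", beta
            ) from exc
        # step-halving if the likelihood would decrease
        for _ in range(20):
            cand = beta + step
            ll_new, _, _ = _breslow_score_info(time, event, X, cand)
            if ll_new >= loglik - 1e-12:
                break
            step = step / 2
        beta = beta + step
        if np.abs(beta).max() > 25:
            worst = X_df.columns[int(np.argmax(np.abs(beta)))]
            raise ConvergenceError(
                f"monotone likelihood (separation) on covariate {worst}", beta
            )
    else:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations", beta
        )

    loglik, _, info = _breslow_score_info(time, event, X, beta)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    zc = stats.norm.ppf(0.975)
    names = X_df.columns
    return CoxResult(
        coef=pd.Series(beta, index=names),
        hazard_ratio=pd.Series(np.exp(beta), index=names),
        se=pd.Series(se, index=names),
        p_value=pd.Series(p, index=names),
        ci_lower=pd.Series(np.exp(beta - zc * se), index=names),
        ci_upper=pd.Series(np.exp(beta + zc * se), index=names),
        tie_method=tie_method,
        log_likelihood=float(loglik),
        n_events=int(event.sum()),
    )


def cox_score_test(table: SurvivalTable, covariates: list[str]) -> tuple[float, float]:
    """Score test of beta = 0; equals the log-rank chi2 for a binary covariate."""
    X_df = _design_matrix(table, covariates)
    X = X_df.to_numpy()
    X = X - X.mean(axis=0)
    _, score, info = _breslow_score_info(
        table.time, table.event, X, np.zeros(X.shape[1])
    )
    chi2 = float(score @ np.linalg.solve(info, score))
    return chi2, float(stats.chi2.sf(chi2, df=X.shape[1]))


def regress_out_covariate(
    table: SurvivalTable,
    covariates: list[str],
    extra: str,
    focal: str | None = None,
) -> AdjustedCoxResult:
    """Refit the Cox model with an extra enrichment covariate appended.

    Reports the focal coefficient before and after adjustment; a constant
    extra covariate is dropped with a warning (leaving the fit unchanged),
    while an extra collinear with the focal covariate raises an error.
    """
    focal = focal or covariates[0]
    unadj = cox_ph(table, covariates)
    adj = cox_ph(table, covariates + [extra])
    if focal not in adj.coef.index:
        raise InvalidArgumentError(f"focal covariate {focal} missing after fit")
    return AdjustedCoxResult(unadjusted=unadj, adjusted=adj, focal=focal)
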