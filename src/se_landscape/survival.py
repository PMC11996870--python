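"""Median-split survival screening of candidate genes.

Patients are dichotomized at the median expression of each gene; the two
groups are compared by the Kaplan-Meier estimator and log-rank test, and
the high-vs-low hazard ratio comes from a univariate Cox proportional
hazards model on the binary group indicator.  A gene is flagged as a
prognostic candidate when the log-rank p is below alpha and the hazard
ratio exceeds 1 (higher expression, poorer survival).

Kaplan-Meier curves and the log-rank test are computed with lifelines;
the univariate Cox fit uses a Newton solver on the Breslow partial
likelihood implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats


@dataclass
class KmCurve:
    """Product-limit survival estimate at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray


@dataclass
class CoxResult:
    beta: float
    hr: float
    se: float
    p: float
    ci95: tuple[float, float]
    n_iter: int = 0


@dataclass
class ScreenResult:
    gene_id: str
    logrank_chi2: float
    logrank_p: float
    hr: float
    hr_ci95: tuple[float, float]
    flagged: bool


def median_split(values: dict[str, float] | pd.Series) -> dict[str, str]:
    """Split subjects into high (> median) and low (<= median) groups.

    The median is the standard midpoint for even n; values equal to the
    median go to "low".
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 subjects")
    med = float(np.median(s.to_numpy()))
    return {str(k): ("high" if v > med else "low") for k, v in s.items()}


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise ValueError("no survival records")
    if (records["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    return records


def km_estimate(records: pd.DataFrame) -> KmCurve:
    """Kaplan-Meier product-limit estimate.

    ``records`` has columns time and event (1 = observed, 0 = censored).
    S(t) = prod over event times t_i <= t of (1 - d_i / n_i); censored
    subjects leave the risk set just after their time.
    """
    records = _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], event_observed=records["event"])
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KmCurve(
        event_times=times,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(dtype=float),
        events=ev["observed"].to_numpy(dtype=float),
    )


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test: (chi2, p) on 1 df.

    Degenerate inputs with zero hypergeometric variance (e.g. no events)
    return chi2 = 0, p = 1.
    """
    _check_records(group_a)
    _check_records(group_b)
    res = _ll_logrank(
        group_a["time"], group_b["time"],
        event_observed_A=group_a["event"], event_observed_B=group_b["event"],
    )
    chi2, p = float(res.test_statistic), float(res.p_value)
    if not (math.isfinite(chi2) and math.isfinite(p)):
        return 0.0, 1.0
    return chi2, p


def _breslow_loglik_terms(beta: float, time, event, x):
    """Log-likelihood, gradient and information of the Breslow partial
    likelihood for one covariate."""
    order = np.argsort(time, kind="stable")
    time, event, x = time[order], event[order], x[order]
    ll = grad = info = 0.0
    # iterate distinct event times; risk set = subjects with time >= t
    n = len(time)
    exb = np.exp(beta * x)
    # suffix sums over the risk set
    s0 = np.cumsum(exb[::-1])[::-1]
    s1 = np.cumsum((exb * x)[::-1])[::-1]
    s2 = np.cumsum((exb * x * x)[::-1])[::-1]
    i = 0
    while i < n:
        j = i
        d = 0
        sx = 0.0
        while j < n and time[j] == time[i]:
            if event[j] == 1:
                d += 1
                sx += x[j]
            j += 1
        if d > 0:
            ll += beta * sx - d * np.log(s0[i])
            mean1 = s1[i] / s0[i]
            grad += sx - d * mean1
            info += d * (s2[i] / s0[i] - mean1**2)
        i = j
    return ll, grad, info


def breslow_partial_loglik(beta: float, records: pd.DataFrame, covariate) -> float:
    """The Breslow partial log-likelihood at ``beta`` (for diagnostics and
    independent grid checks)."""
    x = np.asarray(covariate, dtype=float)
    ll, _, _ = _breslow_loglik_terms(
        float(beta), records["time"].to_numpy(float), records["event"].to_numpy(int), x
    )
    return float(ll)


def cox_univariate(
    records: pd.DataFrame,
    covariate,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Univariate Cox proportional-hazards fit with Breslow tie handling.

    Newton iteration on beta (tolerance 1e-8, at most 50 iterations); Wald
    standard error from the observed information; ci95 = exp(beta +/-
    1.96 se).  A constant covariate returns the degenerate convention
    beta = 0, hr = 1, p = 1.
    """
    records = _check_records(records)
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    x = np.asarray(covariate, dtype=float)
    if len(x) != len(time):
        raise ValueError("covariate must be defined for every subject")
    if event.sum() < 2:
        raise ValueError("need at least 2 observed events")
    if np.ptp(x) == 0:
        return CoxResult(beta=0.0, hr=1.0, se=np.inf, p=1.0, ci95=(0.0, np.inf))
    beta = 0.0
    for it in range(1, max_iter + 1):
        _, grad, info = _breslow_loglik_terms(beta, time, event, x)
        if info <= 0:
            return CoxResult(beta=0.0, hr=1.0, se=np.inf, p=1.0, ci95=(0.0, np.inf))
        step = grad / info
        # dampen huge steps (monotone separation can push beta to infinity)
        step = float(np.clip(step, -2.0, 2.0))
        beta += step
        if abs(step) < tol:
            break
    else:
        raise RuntimeError(f"Cox Newton iteration did not converge in {max_iter} steps")
    _, _, info = _breslow_loglik_terms(beta, time, event, x)
    se = 1.0 / math.sqrt(info)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    ci = (math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se))
    return CoxResult(beta=float(beta), hr=float(math.exp(beta)), se=float(se),
                     p=float(p), ci95=ci, n_iter=it)


def screen_candidates(
    genes: list[str],
    expression: pd.DataFrame,
    survival: pd.DataFrame,
    alpha: float = 0.05,
) -> list[ScreenResult]:
    """Median-split survival screen over a list of candidate genes.

    ``expression`` is genes x subjects; ``survival`` is indexed by subject
    with columns time and event.  Per gene: median split, log-rank
    high-vs-low, Cox hazard ratio on the binary indicator; flagged iff
    logrank_p < alpha and hr > 1.  Degenerate splits (everyone in one
    group) report p = 1, hr = 1 rather than erroring.  Sorted by p.
    """
    subjects = [s for s in survival.index if s in expression.columns]
    if not subjects:
        raise ValueError("no subjects shared between expression and survival")
    surv = survival.loc[subjects]
    results = []
    for gene in genes:
        if gene not in expression.index:
            raise KeyError(f"gene {gene!r} missing from expression matrix")
        split = median_split(expression.loc[gene, subjects])
        indicator = np.array([1.0 if split[s] == "high" else 0.0 for s in subjects])
        high = surv[indicator == 1]
        low = surv[indicator == 0]
        if len(high) == 0 or len(low) == 0 or surv["event"].sum() < 2:
            results.append(ScreenResult(gene, 0.0, 1.0, 1.0, (0.0, np.inf), False))
            continue
        chi2, p = logrank_test(high, low)
        cox = cox_univariate(surv, indicator)
        flagged = (p < alpha) and (cox.hr > 1)
        results.append(ScreenResult(gene, chi2, p, cox.hr, cox.ci95, flagged))
    results.sort(key=lambda r: (r.logrank_p, r.gene_id))
    return results


def screen_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "logrank_chi2": [r.logrank_chi2 for r in results],
            "logrank_p": [r.logrank_p for r in results],
            "hr": [r.hr for r in results],
            "hr_ci_low": [r.hr_ci95[0] for r in results],
            "hr_ci_high": [r.hr_ci95[1] for r in results],
            "flagged": [r.flagged for r in results],
        }
    ).set_index("gene_id")
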