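"""Survival machinery for age-acceleration mortality analysis.

Everything here is implemented from first principles because these
estimators are the analytical core of the package: Cox proportional-hazards
regression by Newton-Raphson on the partial likelihood (Efron tie handling
by default, Breslow optional), the Kaplan-Meier product-limit estimator,
the log-rank test, rank-based quartile stratification of age acceleration,
Benjamini-Hochberg FDR adjustment, and Spearman rank correlation.

Conventions
-----------
* Event indicator: 1 = death observed, 0 = right-censored.
* Subjects censored at a death time are still at risk for those deaths
  (censoring is taken to happen just after the deaths).
* Hazard ratios for age acceleration are expressed per ``scale_years``
  (default 5) years of delta_age, and deaths within the first
  ``exclude_years`` (default 2) of follow-up are excluded before fitting to
  limit reverse causation from terminal illness.
* 95% confidence intervals are Wald intervals exp(coef +/- 1.96 se).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "CoxResult",
    "KMCurve",
    "ConvergenceError",
    "prepare_survival",
    "cox_fit",
    "km_estimate",
    "logrank_test",
    "quartile_stratify",
    "bh_adjust",
    "spearman_corr",
]


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge or the likelihood is monotone."""


@dataclasses.dataclass
class CoxResult:
    """Fitted Cox proportional-hazards model.

    ``summary`` has one row per covariate with columns ``coef`` (log-hazard
    units), ``hr``, ``se``, ``z``, ``p``, ``ci_low``, ``ci_high``.
    """

    summary: pd.DataFrame
    loglik: float
    loglik_null: float
    n_used: int
    n_events: int
    ties: str
    n_iter: int

    def coef(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "coef"])

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def ci95(self, covariate: str) -> tuple[float, float]:
        row = self.summary.loc[covariate]
        return float(row["ci_low"]), float(row["ci_high"])

    def p_value(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])

    @property
    def lr_statistic(self) -> float:
        """Likelihood-ratio chi-square against the null model."""
        return 2.0 * (self.loglik - self.loglik_null)


@dataclasses.dataclass
class KMCurve:
    """Kaplan-Meier product-limit survival curve.

    ``times`` are the distinct event times in increasing order;
    ``survival[i]`` is S(t) just after ``times[i]``; ``at_risk[i]`` and
    ``n_events[i]`` are the risk-set size and death count at ``times[i]``.
    S(0) = 1 by construction.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float | np.ndarray) -> np.ndarray | float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return float(out) if np.isscalar(t) else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )


def prepare_survival(
    annotation: pd.DataFrame,
    delta_ages: pd.DataFrame | pd.Series | np.ndarray,
    exclude_years: float = 2.0,
    scale_years: float = 5.0,
) -> pd.DataFrame:
    """Build the model-ready table for the delta_age mortality analysis.

    Deaths occurring strictly before ``exclude_years`` of follow-up are
    removed (censored samples are retained regardless of their time); the
    covariate ``delta_scaled`` = delta_age / ``scale_years`` is added so the
    fitted hazard ratio reads "per ``scale_years`` years of age
    acceleration"; chronological age and sex (coded male=1, female=0; the
    delta_age hazard ratio is invariant to this coding) are retained as
    adjustment covariates.
    """
    ann = annotation.reset_index(drop=True)
    if isinstance(delta_ages, pd.DataFrame):
        if not {"sample_id", "delta_age"} <= set(delta_ages.columns):
            raise ValueError("delta_ages DataFrame needs 'sample_id' and 'delta_age' columns")
        merged = ann.merge(delta_ages[["sample_id", "delta_age"]], on="sample_id", how="left")
        if merged["delta_age"].isna().any():
            missing = merged.loc[merged["delta_age"].isna(), "sample_id"].tolist()
            raise ValueError(f"no delta_age for sample(s) {missing[:5]}")
        delta = merged["delta_age"].to_numpy(float)
    else:
        delta = np.asarray(delta_ages, dtype=float)
        if len(delta) != len(ann):
            raise ValueError(f"length mismatch: {len(ann)} samples vs {len(delta)} delta_ages")
    table = pd.DataFrame(
        {
            "sample_id": ann["sample_id"].astype(str),
            "surv_time": ann["surv_time"].astype(float),
            "event": ann["event"].astype(int),
            "delta_scaled": delta / float(scale_years),
            "age": ann["age"].astype(float),
            "sex_male": (ann["sex"] == "male").astype(int),
        }
    )
    early_death = (table["event"] == 1) & (table["surv_time"] < exclude_years)
    table = table.loc[~early_death].reset_index(drop=True)
    if (table["event"] == 1).sum() == 0:
        raise ValueError(
            f"no events remain after excluding deaths before {exclude_years} years of follow-up"
        )
    return table


def _cox_engine(
    times: np.ndarray,
    events: np.ndarray,
    X: np.ndarray,
    ties: str,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, float, int]:
    """Newton-Raphson maximization of the Cox partial likelihood.

    Returns (beta, covariance, loglik, loglik_null, n_iter) on the scale of
    the supplied (already standardized) covariates.
    """
    n, p = X.shape
    order = np.argsort(times, kind="stable")
    t_s, e_s, X_s = times[order], events[order].astype(bool), X[order]

    death_idx = np.flatnonzero(e_s)
    dt = t_s[death_idx]
    # group boundaries over tied death times (deaths-only ordering)
    starts = np.flatnonzero(np.concatenate([[True], dt[1:] != dt[:-1]]))
    uniq_t = dt[starts]
    d_g = np.diff(np.concatenate([starts, [len(dt)]]))
    risk_start = np.searchsorted(t_s, uniq_t, side="left")
    if ties == "efron":
        frac = np.concatenate([np.arange(d) / d for d in d_g])
    elif ties == "breslow":
        frac = np.zeros(len(dt))
    else:
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    Xd = X_s[death_idx]
    sx = Xd.sum(axis=0)

    def pieces(beta: np.ndarray):
        eta = X_s @ beta
        w = np.exp(eta)
        # suffix sums: risk-set aggregates at every entry index
        cw = np.cumsum(w[::-1])[::-1]
        cwx = np.cumsum((w[:, None] * X_s)[::-1], axis=0)[::-1]
        cwxx = np.cumsum(
            (w[:, None, None] * X_s[:, :, None] * X_s[:, None, :])[::-1], axis=0
        )[::-1]
        R0, R1, R2 = cw[risk_start], cwx[risk_start], cwxx[risk_start]
        wd = w[death_idx]
        D0 = np.add.reduceat(wd, starts)
        D1 = np.add.reduceat(wd[:, None] * Xd, starts, axis=0)
        D2 = np.add.reduceat(
            wd[:, None, None] * Xd[:, :, None] * Xd[:, None, :], starts, axis=0
        )
        rep = np.repeat(np.arange(len(uniq_t)), d_g)
        phi = R0[rep] - frac * D0[rep]
        loglik = float(eta[death_idx].sum() - np.log(phi).sum())
        inv, inv2 = 1.0 / phi, 1.0 / phi**2
        A = np.add.reduceat(inv, starts)
        B = np.add.reduceat(frac * inv, starts)
        C = np.add.reduceat(inv2, starts)
        E = np.add.reduceat(frac * inv2, starts)
        F = np.add.reduceat(frac**2 * inv2, starts)
        grad = sx - (A[:, None] * R1 - B[:, None] * D1).sum(axis=0)
        m_term = (A[:, None, None] * R2 - B[:, None, None] * D2).sum(axis=0)
        zz = (
            np.einsum("g,gi,gj->ij", C, R1, R1)
            - np.einsum("g,gi,gj->ij", E, R1, D1)
            - np.einsum("g,gi,gj->ij", E, D1, R1)
            + np.einsum("g,gi,gj->ij", F, D1, D1)
        )
        info = m_term - zz
        return loglik, grad, info

    beta = np.zeros(p)
    loglik, grad, info = pieces(beta)
    loglik_null = loglik
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular information matrix: {err}") from err
        # step-halving keeps the partial likelihood monotone
        factor = 1.0
        for _ in range(30):
            new_beta = beta + factor * step
            new_ll, new_grad, new_info = pieces(new_beta)
            if new_ll >= loglik - 1e-12:
                break
            factor /= 2.0
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        if np.abs(beta).max() > 100.0:
            raise ConvergenceError(
                "coefficients diverging (|standardized coef| > 100): monotone "
                "partial likelihood, likely perfect separation of events"
            )
        # converge on a vanishing gradient or a vanishing accepted step (the
        # gradient has a numerical noise floor ~ eps * sum of risk weights)
        if np.abs(grad).max() < tol or np.abs(factor * step).max() < 1e-10:
            break
    else:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations; "
            f"last max|gradient| = {np.abs(grad).max():.3g}"
        )
    cov = np.linalg.inv(info)
    # a monotone partial likelihood plateaus instead of peaking: the fitted
    # standardized coefficient runs away and its SE explodes
    se = np.sqrt(np.diag(cov))
    if np.abs(beta).max() > 10.0 or se.max() > 10.0:
        raise ConvergenceError(
            "monotone partial likelihood (perfect separation): standardized "
            f"coefficient {np.abs(beta).max():.3g} with SE {se.max():.3g}"
        )
    return beta, cov, loglik, loglik_null, n_iter


def cox_fit(
    table: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "surv_time",
    event_col: str = "event",
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by partial-likelihood Newton-Raphson.

    Standard errors come from the observed information; p-values are Wald
    tests; ``ci_low``/``ci_high`` are exp(coef +/- 1.96 se). Covariates that
    are constant across samples are dropped with a warning. Efron's tie
    correction is the default (it agrees exactly with Breslow's when no
    event times are tied).
    """
    covariates = list(covariates)
    if not covariates:
        raise ValueError("need at least one covariate")
    times = table[duration_col].to_numpy(float)
    events = table[event_col].to_numpy(int)
    if events.sum() == 0:
        raise ValueError("no events in the data; Cox model is not identifiable")
    X = table[covariates].to_numpy(float)
    if np.isnan(X).any() or np.isnan(times).any():
        raise ValueError("NaN in covariates or durations")
    scale = X.std(axis=0)
    keep = scale > 0
    if not keep.all():
        dropped = [c for c, k in zip(covariates, keep) if not k]
        warnings.warn(
            f"dropping constant covariate(s): {dropped}", RuntimeWarning, stacklevel=2
        )
        covariates = [c for c, k in zip(covariates, keep) if k]
        if not covariates:
            raise ValueError("all covariates are constant")
        X, scale = X[:, keep], scale[keep]
    center = X.mean(axis=0)
    Xs = (X - center) / scale

    beta_s, cov_s, loglik, loglik_null, n_iter = _cox_engine(
        times, events, Xs, ties, max_iter, tol
    )
    beta = beta_s / scale
    cov = cov_s / np.outer(scale, scale)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * _stats.norm.sf(np.abs(z))
    summary = pd.DataFrame(
        {
            "coef": beta,
            "hr": np.exp(beta),
            "se": se,
            "z": z,
            "p": pvals,
            "ci_low": np.exp(beta - 1.96 * se),
            "ci_high": np.exp(beta + 1.96 * se),
        },
        index=pd.Index(covariates, name="covariate"),
    )
    return CoxResult(
        summary=summary,
        loglik=loglik,
        loglik_null=loglik_null,
        n_used=len(times),
        n_events=int(events.sum()),
        ties=ties,
        n_iter=n_iter,
    )


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function.

    Subjects censored at a death time count as at risk for those deaths.
    With no censoring the estimate equals the empirical survival function.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("negative survival times")
    event_times = np.unique(times[events == 1])
    at_risk = np.array([(times >= t).sum() for t in event_times], dtype=int)
    n_events = np.array(
        [((times == t) & (events == 1)).sum() for t in event_times], dtype=int
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        survival = np.cumprod(1.0 - n_events / at_risk)
    return KMCurve(
        times=event_times,
        survival=survival,
        at_risk=at_risk,
        n_events=n_events,
    )


def logrank_test(
    times: np.ndarray,
    events: np.ndarray,
    groups: np.ndarray,
) -> tuple[float, float]:
    """Log-rank test comparing survival between groups.

    Returns (chi2, p) with K-1 degrees of freedom for K groups; the usual
    two-group statistic with 1 df is the K=2 case.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    K = len(labels)
    if K < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if events.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    gidx = np.searchsorted(labels, groups)
    event_times = np.unique(times[events == 1])
    O = np.zeros(K)
    E = np.zeros(K)
    V = np.zeros((K, K))
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        n_j = np.bincount(gidx[at_risk], minlength=K).astype(float)
        d_j = np.bincount(gidx[(times == t) & (events == 1)], minlength=K).astype(float)
        O += d_j
        E += d * n_j / n
        if n > 1:
            fac = d * (n - d) / (n - 1)
            V += fac * (np.diag(n_j / n) - np.outer(n_j / n, n_j / n))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    if np.allclose(Vsub, 0):
        return 0.0, 1.0
    chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    p = float(_stats.chi2.sf(chi2, df=K - 1))
    return chi2, p


def quartile_stratify(delta_ages: pd.Series | np.ndarray) -> pd.Series:
    """Assign samples to quartiles Q1 (lowest delta_age) .. Q4 (highest).

    Rank-based: the sorted samples are split into four nearly equal blocks
    (sizes differ by at most 1); ties are broken by stable input order, so
    the assignment is deterministic.
    """
    values = pd.Series(delta_ages)
    n = len(values)
    if n < 4:
        raise ValueError(f"need at least 4 samples to form quartiles, got {n}")
    order = np.argsort(values.to_numpy(), kind="stable")
    labels = np.empty(n, dtype=object)
    for q, chunk in enumerate(np.array_split(order, 4), start=1):
        labels[chunk] = f"Q{q}"
    return pd.Series(labels, index=values.index, name="quartile")


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q[i] = min_{j: p[j] >= p[i]} p[j] * m / rank[j]``, capped at 1. NaN
    entries (e.g. skipped tests) are excluded from the family size and
    returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    out[valid] = q
    return out


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties replaced by the mean rank of the tied block."""
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and xs[j + 1] == xs[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN with a warning when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            "zero variance input; Spearman correlation undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    rx, ry = _average_ranks(x), _average_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])
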