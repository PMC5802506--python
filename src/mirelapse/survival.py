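"""Survival analysis: Kaplan-Meier, log-rank, optimal cutpoints, Cox models.

Survival tables are plain DataFrames with one row per patient and columns
``patient``, ``time_months`` (>= 0), ``event`` (0/1), ``endpoint``
("OS": diagnosis to death from any cause or last follow-up;
"PFS": diagnosis to progression or death from any cause), plus arbitrary
continuous biomarker and categorical covariate columns.

Optimal-cutpoint dichotomization re-implements the "most prognostic
cutoff" scan: every midpoint between consecutive distinct biomarker values
that leaves both groups at least ``min_group_frac`` of the cohort is a
candidate, the log-rank p is computed for each, and the candidate with the
minimal p wins.  "High" means strictly above the cutoff.  The selected p
is NOT corrected for the multiplicity of the scan; the full profile is
returned so callers can apply corrections.

The Cox model maximizes the partial likelihood by Newton iterations with
Efron (default) or Breslow handling of tied event times, and reports per
term the hazard ratio RR = exp(beta), its Wald 95% CI and p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("patient", "time_months", "event")


def validate_survival_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"survival table missing columns {missing}")
    if (table["time_months"] < 0).any():
        raise ValueError("negative survival time")
    if not set(table["event"].unique()) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    if "endpoint" in table.columns and table["endpoint"].nunique() > 1:
        raise ValueError("one endpoint per table")


@dataclass
class KaplanMeierEstimate:
    """Product-limit estimator as a right-continuous step function."""

    event_times: np.ndarray  # distinct times with >= 1 death
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size at each event time
    n_deaths: np.ndarray

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "deaths": self.n_deaths,
            }
        )


def km_estimate(times, events) -> KaplanMeierEstimate:
    """Kaplan-Meier product-limit estimate; S(0) = 1, non-increasing."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("negative time")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    dead = times[events == 1]
    uniq = np.unique(dead)
    surv, risk, deaths = [], [], []
    s = 1.0
    for t in uniq:
        n_risk = int((times >= t).sum())
        d = int(((dead == t)).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        risk.append(n_risk)
        deaths.append(d)
    return KaplanMeierEstimate(
        uniq, np.asarray(surv), np.asarray(risk), np.asarray(deaths)
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square with 1 df, two-sided p).

    Sums observed-minus-expected deaths in group A over distinct event
    times with the usual hypergeometric variance.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("a group has zero subjects")
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    if len(event_times) == 0:
        return 0.0, 1.0
    na = (ta[None, :] >= event_times[:, None]).sum(axis=1)
    nb = (tb[None, :] >= event_times[:, None]).sum(axis=1)
    da = ((ta[None, :] == event_times[:, None]) & (ea[None, :] == 1)).sum(axis=1)
    db = ((tb[None, :] == event_times[:, None]) & (eb[None, :] == 1)).sum(axis=1)
    n = na + nb
    d = da + db
    keep = n > 1
    expected = d * na / n
    var = d * (na / n) * (nb / n) * (n - d) / np.where(n > 1, n - 1, 1)
    o_minus_e = float((da - expected)[keep].sum())
    v = float(var[keep].sum())
    if v == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / v
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class CutpointResult:
    biomarker: str
    cutpoint: float
    n_low: int
    n_high: int
    chi_square: float
    p_value: float
    profile: pd.DataFrame = field(repr=False)  # candidate, p, chi_square


def optimal_cutpoint(
    values,
    table: pd.DataFrame,
    min_group_frac: float = 0.1,
    biomarker: str = "biomarker",
) -> CutpointResult:
    """Most prognostic dichotomization of a continuous biomarker.

    Scans log-rank p over midpoints between consecutive distinct sorted
    values whose split leaves both groups with at least
    ``min_group_frac * n`` patients, and returns the minimizer with the
    full scan profile.  Ties on p are broken toward the larger chi-square,
    then the lower cutoff.
    """
    validate_survival_table(table)
    v = np.asarray(values, dtype=float)
    if len(v) != len(table):
        raise ValueError("biomarker length does not match table")
    distinct = np.unique(v)
    if len(distinct) < 2:
        raise ValueError("constant biomarker: no admissible cutpoint")
    times = table["time_months"].to_numpy(dtype=float)
    events = table["event"].to_numpy(dtype=int)
    n = len(v)
    min_group = min_group_frac * n

    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    rows = []
    for c in candidates:
        high = v > c
        n_high = int(high.sum())
        n_low = n - n_high
        if n_high < min_group or n_low < min_group:
            continue
        chi2, p = logrank_test(times[~high], events[~high], times[high], events[high])
        rows.append((float(c), p, chi2, n_low, n_high))
    if not rows:
        raise ValueError("no candidate cutpoint satisfies the group-size constraint")
    profile = pd.DataFrame(rows, columns=["candidate", "p", "chi_square", "n_low", "n_high"])
    best = profile.sort_values(
        ["p", "chi_square", "candidate"], ascending=[True, False, True]
    ).iloc[0]
    return CutpointResult(
        biomarker=biomarker,
        cutpoint=float(best["candidate"]),
        n_low=int(best["n_low"]),
        n_high=int(best["n_high"]),
        chi_square=float(best["chi_square"]),
        p_value=float(best["p"]),
        profile=profile[["candidate", "p", "chi_square"]].reset_index(drop=True),
    )


@dataclass
class CoxFit:
    terms: list[str]
    coef: np.ndarray
    rr: np.ndarray  # exp(coef), hazard ratio per term
    ci95: np.ndarray  # (p, 2) lower/upper
    p_values: np.ndarray
    se: np.ndarray
    converged: bool
    warnings: list[str] = field(default_factory=list)
    log_likelihood: float = np.nan

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coef,
                "RR": self.rr,
                "ci95_low": self.ci95[:, 0],
                "ci95_high": self.ci95[:, 1],
                "p": self.p_values,
            }
        )


def _cox_loglik(beta, times, events, X, ties):
    """Partial log-likelihood, gradient, Hessian (Efron or Breslow ties)."""
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard against overflow; constant shift cancels
    w = np.exp(eta)
    order = np.argsort(-times, kind="stable")  # decreasing time
    ll, g = 0.0, np.zeros(p)
    H = np.zeros((p, p))
    # running sums over the risk set (built by decreasing time)
    W = 0.0
    Wx = np.zeros(p)
    Wxx = np.zeros((p, p))
    i = 0
    ts = times[order]
    ev = events[order]
    Xs = X[order]
    ws = w[order]
    while i < n:
        t = ts[i]
        j = i
        while j < n and ts[j] == t:
            W += ws[j]
            Wx += ws[j] * Xs[j]
            Wxx += ws[j] * np.outer(Xs[j], Xs[j])
            j += 1
        # deaths at this time
        didx = [k for k in range(i, j) if ev[k] == 1]
        d = len(didx)
        if d:
            s = Xs[didx].sum(axis=0)
            ll += float(np.log(ws[didx]).sum())
            g += s
            if ties == "breslow":
                for _ in range(d):
                    mu = Wx / W
                    ll -= np.log(W)
                    g -= mu
                    H -= Wxx / W - np.outer(mu, mu)
            else:  # efron
                Wd = ws[didx].sum()
                Wdx = (ws[didx, None] * Xs[didx]).sum(axis=0)
                Wdxx = np.einsum("k,ki,kj->ij", ws[didx], Xs[didx], Xs[didx])
                for l in range(d):
                    f = l / d
                    denom = W - f * Wd
                    num = Wx - f * Wdx
                    mu = num / denom
                    ll -= np.log(denom)
                    g -= mu
                    H -= (Wxx - f * Wdxx) / denom - np.outer(mu, mu)
        i = j
    return ll, g, H


def cox_fit(
    table: pd.DataFrame,
    terms: list[str],
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Cox proportional-hazards fit for categorical (or numeric) covariates.

    Categorical columns are dummy-coded against their first level; the
    reported RR for a term is the hazard ratio of that level relative to
    the reference level.  Non-convergence and (quasi-)complete separation
    are flagged on the result, never silent.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    validate_survival_table(table)
    design = []
    for term in terms:
        col = table[term]
        if col.nunique() < 2:
            raise ValueError(f"covariate {term!r} is constant: no information")
        if col.dtype.kind in "ifu" and col.nunique() > 2:
            design.append(col.to_frame().astype(float))
        else:
            if not isinstance(col.dtype, pd.CategoricalDtype):
                col = col.astype(str)
            dummies = pd.get_dummies(col, prefix=term, drop_first=True)
            design.append(dummies.astype(float))
    X_df = pd.concat(design, axis=1)
    X = X_df.to_numpy(dtype=float)
    names = list(X_df.columns)
    times = table["time_months"].to_numpy(dtype=float)
    events = table["event"].to_numpy(dtype=int)

    beta = np.zeros(X.shape[1])
    warns: list[str] = []
    converged = False
    ll_old = -np.inf
    for _ in range(max_iter):
        ll, g, H = _cox_loglik(beta, times, events, X, ties)
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            warns.append("singular information matrix")
            break
        # step-halving if the likelihood would not improve
        for _ in range(20):
            ll_new, _, _ = _cox_loglik(beta + step, times, events, X, ties)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta = beta + step
        if np.abs(g).max() < tol or abs(ll - ll_old) < 1e-12:
            converged = True
            break
        ll_old = ll
    ll, g, H = _cox_loglik(beta, times, events, X, ties)
    if np.abs(beta).max() > 15:
        warns.append("possible complete separation: |coef| > 15")
        converged = False
    if not converged and not warns:
        warns.append("Newton iterations did not converge")
    try:
        cov = np.linalg.inv(-H)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.nan)
        warns.append("singular information matrix at optimum")
    z = stats.norm.ppf(0.975)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        wald = beta / se
        p = 2.0 * stats.norm.sf(np.abs(wald))
        ci = np.exp(np.column_stack([beta - z * se, beta + z * se]))
    return CoxFit(
        terms=names,
        coef=beta,
        rr=np.exp(beta),
        ci95=ci,
        p_values=p,
        se=se,
        converged=converged,
        warnings=warns,
        log_likelihood=float(ll),
    )


def cohort_summary(
    table: pd.DataFrame,
    group_by: str,
    characteristics: list[str] | None = None,
) -> pd.DataFrame:
    """Per-category counts and percentages, overall and by group.

    Percentages are 100 * count / column total rounded to the nearest
    integer for display.  The association p-value per characteristic is a
    chi-square test (without continuity correction) on the
    category x group contingency table; with a single category it is
    undefined and reported as NaN.
    """
    if group_by not in table.columns:
        raise ValueError(f"group column {group_by!r} not in table")
    if characteristics is None:
        characteristics = [
            c for c in table.columns if c not in (group_by, "patient")
        ]
    groups = list(pd.unique(table[group_by]))
    rows = []
    n_total = len(table)
    for char in characteristics:
        ct = pd.crosstab(table[char], table[group_by])
        if ct.shape[0] > 1 and ct.shape[1] > 1:
            chi2, p, _, _ = stats.chi2_contingency(ct.to_numpy(), correction=False)
        else:
            p = np.nan
        for cat in ct.index:
            row = {
                "characteristic": char,
                "category": cat,
                "total_n": int(ct.loc[cat].sum()),
                "total_pct": int(round(100.0 * ct.loc[cat].sum() / n_total)),
                "p": p,
            }
            for grp in groups:
                cnt = int(ct.loc[cat, grp]) if grp in ct.columns else 0
                g_total = int((table[group_by] == grp).sum())
                row[f"{grp}_n"] = cnt
                row[f"{grp}_pct"] = int(round(100.0 * cnt / g_total)) if g_total else 0
            rows.append(row)
    return pd.DataFrame(rows)
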