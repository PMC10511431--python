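"""Survival screening of the dichotomized query gene.

Expression is dichotomized at the within-context sample median (ties to
low). The hazard ratio of high-vs-low comes from a Cox proportional-
hazards fit of the partial likelihood, maximized by Newton–Raphson with
Efron (default) or Breslow handling of tied event times; Wald confidence
intervals and p-values from the observed information. Kaplan–Meier
curves and the two-group log-rank test are delegated to lifelines.

A context enters the screen only when it holds at least 10 events;
multivariate fits (tumor size, nodal status, metastasis, AURKA
expression) additionally require at least 3 of the 4 covariates to be
available in at least 20 patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps

from .datamodel import ExpressionMatrix, STRATUM_ALL

DEFAULT_MIN_EVENTS = 10
DEFAULT_MIN_COVAR_PATIENTS = 20
DEFAULT_COVARIATES = ("size_stage", "node_stage", "met_stage", "aurka")
MAX_ITER = 50
LOGLIK_TOL = 1e-9
COND_LIMIT = 1e10


def dichotomize_by_median(values) -> pd.Series:
    """High/low labels at the sample median; low iff value <= median.

    Raises if either group would be empty (all values identical).
    """
    values = pd.Series(values).astype(float)
    med = float(values.median())
    labels = pd.Series(np.where(values > med, "high", "low"), index=values.index)
    if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
        raise ValueError("median split impossible: all values identical")
    return labels


def km_logrank(times, events, groups) -> dict:
    """Product-limit curves per group + two-group log-rank test.

    Returns {"curves": {label: stepwise survival DataFrame},
    "statistic": chi-square, "p": p-value (1 df)}.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(labels)}")
    for lab in labels:
        if (groups == lab).sum() == 0:
            raise ValueError(f"group {lab!r} is empty")
    if events.sum() < 1:
        raise ValueError("no events")
    curves = {}
    for lab in labels:
        sel = groups == lab
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel], label=str(lab))
        curves[str(lab)] = kmf.survival_function_
    a, b = labels
    res = logrank_test(times[groups == a], times[groups == b],
                       events[groups == a], events[groups == b])
    return {"curves": curves, "statistic": float(res.test_statistic), "p": float(res.p_value)}


def plot_km(times, events, groups, path, title: str = "") -> None:
    """Export a Kaplan–Meier plot (PNG/PDF by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = km_logrank(times, events, groups)
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab, curve in res["curves"].items():
        ax.step(curve.index, curve.iloc[:, 0], where="post", label=lab)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    ax.set_title(f"{title} (log-rank p = {res['p']:.2g})".strip())
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class SurvivalFit:
    """One Cox fit: hazard ratio of the first covariate (the high/low
    query indicator in the screen) with Wald CI and p."""

    n: int
    n_events: int
    hr: float
    ci_low: float
    ci_high: float
    p: float
    converged: bool
    covariates: list[str] = field(default_factory=list)
    coef_table: pd.DataFrame | None = None
    cancer_type: str = ""
    stratum: str = STRATUM_ALL
    model: str = "univariate"


def _cox_loglik(beta, X, times_s, events_s, ties):
    """Partial log-likelihood, gradient and observed information.

    Rows are sorted by ascending time; risk set of an event time = rows at
    or after the first occurrence of that time.
    """
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    # suffix sums: S0[i] = sum_{j >= i} w_j, etc.
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    S2 = np.cumsum((w[:, None, None] * X[:, :, None] * X[:, None, :])[::-1], axis=0)[::-1]

    loglik, grad = 0.0, np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and times_s[j] == times_s[i]:
            j += 1
        d_idx = [k for k in range(i, j) if events_s[k]]
        d = len(d_idx)
        if d:
            s0, s1, s2 = S0[i], S1[i], S2[i]
            wd = w[d_idx]
            s0d = wd.sum()
            s1d = (wd[:, None] * X[d_idx]).sum(axis=0)
            s2d = (wd[:, None, None] * X[d_idx][:, :, None] * X[d_idx][:, None, :]).sum(axis=0)
            loglik += eta[d_idx].sum()
            for l in range(d):
                f = l / d if ties == "efron" else 0.0
                den = s0 - f * s0d
                num1 = s1 - f * s1d
                num2 = s2 - f * s2d
                loglik -= np.log(den)
                grad_term = num1 / den
                grad -= grad_term
                info += num2 / den - np.outer(grad_term, grad_term)
            grad += X[d_idx].sum(axis=0)
        i = j
    return loglik, grad, info


def cox_fit(
    covariates: pd.DataFrame,
    times,
    events,
    ties: str = "efron",
) -> SurvivalFit:
    """Cox proportional-hazards fit by Newton–Raphson.

    ``covariates``: numeric DataFrame (first column is the covariate whose
    HR the fit reports, the high/low indicator in the screen). Rows with
    any missing value are dropped. Non-convergence or a monotone
    likelihood (complete separation) yields a flagged fit with missing HR,
    not an exception.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    df = covariates.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=bool)
    df = df.dropna()
    X = df.drop(columns=["_time", "_event"]).to_numpy(dtype=float)
    t = df["_time"].to_numpy()
    e = df["_event"].to_numpy()
    n, p = X.shape
    n_events = int(e.sum())
    names = list(covariates.columns)

    def flagged():
        return SurvivalFit(n, n_events, np.nan, np.nan, np.nan, np.nan, False, names)

    if n_events < 1 or n < p + 1:
        return flagged()
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    if np.any(sd == 0):
        return flagged()
    if np.linalg.cond(Xc / sd) > COND_LIMIT:
        return flagged()

    order = np.argsort(t, kind="stable")
    Xs, ts, es = Xc[order], t[order], e[order]

    beta = np.zeros(p)
    loglik, grad, info = _cox_loglik(beta, Xs, ts, es, ties)
    converged = False
    for _ in range(MAX_ITER):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            return flagged()
        new_beta = beta + step
        new_ll, new_grad, new_info = _cox_loglik(new_beta, Xs, ts, es, ties)
        halvings = 0
        while new_ll < loglik and halvings < 20:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox_loglik(new_beta, Xs, ts, es, ties)
            halvings += 1
        done = abs(new_ll - loglik) < LOGLIK_TOL
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        if done:
            converged = True
            break
    if not converged or np.any(np.abs(beta) > 20):
        return flagged()
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return flagged()
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    zcrit = sps.norm.ppf(0.975)
    table = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - zcrit * se),
            "ci_high": np.exp(beta + zcrit * se),
            "p": pvals,
        },
        index=names,
    )
    return SurvivalFit(
        n=n,
        n_events=n_events,
        hr=float(table["hr"].iloc[0]),
        ci_low=float(table["ci_low"].iloc[0]),
        ci_high=float(table["ci_high"].iloc[0]),
        p=float(table["p"].iloc[0]),
        converged=True,
        covariates=names,
        coef_table=table,
    )


def survival_screen(
    expr: ExpressionMatrix,
    annotations: pd.DataFrame,
    query_gene: str,
    strata: tuple[str, ...] = (STRATUM_ALL, "WT", "MUT"),
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    min_events: int = DEFAULT_MIN_EVENTS,
    min_covar_patients: int = DEFAULT_MIN_COVAR_PATIENTS,
    ties: str = "efron",
) -> pd.DataFrame:
    """Univariate and multivariate Cox screen across cancer types and
    TP53 strata (the Table-1-shaped grid).

    One row per (cancer type, stratum, model); ineligible cells carry NaN
    N/HR/P (blanks, not zeros). Eligibility: >= ``min_events`` events for
    any fit; the multivariate model also requires >= 3 of the 4 covariates
    to be observed in >= ``min_covar_patients`` patients. Median
    dichotomization is computed within each context.
    """
    q = expr.gene(query_gene)
    rows = []
    for ct, grp in annotations.groupby("cancer_type"):
        for stratum in strata:
            if stratum == STRATUM_ALL:
                sub = grp
            else:
                sub = grp[(grp["tp53_status"] == stratum) & (grp["tp53_class"] != "Unknown")]
            sub = sub.dropna(subset=["os_time", "os_event"])
            sub = sub[sub["sample_id"].isin(q.index)]
            expr_vals = q.reindex(sub["sample_id"])
            sub = sub[expr_vals.notna().to_numpy()]
            expr_vals = q.reindex(sub["sample_id"])
            base = {"cancer_type": ct, "stratum": stratum}
            n_events = int(sub["os_event"].sum())

            for model in ("univariate", "multivariate"):
                row = dict(
                    base, model=model, n=np.nan, n_events=np.nan,
                    hr=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                    significant=False, eligible=False,
                )
                eligible = len(sub) >= 2 and n_events >= min_events
                if eligible and model == "multivariate":
                    present = sub[list(covariates)].notna().sum(axis=1)
                    eligible = int((present >= 3).sum()) >= min_covar_patients
                if eligible and expr_vals.nunique() > 1:
                    high = (expr_vals > expr_vals.median()).astype(float).to_numpy()
                    cov_df = pd.DataFrame({"query_high": high})
                    if model == "multivariate":
                        for c in covariates:
                            vals = sub[c].to_numpy(dtype=float)
                            if np.isfinite(vals).any():
                                cov_df[c] = vals
                    fit = cox_fit(
                        cov_df, sub["os_time"].to_numpy(), sub["os_event"].to_numpy(),
                        ties=ties,
                    )
                    if fit.converged:
                        row.update(
                            n=fit.n, n_events=fit.n_events, hr=fit.hr,
                            ci_low=fit.ci_low, ci_high=fit.ci_high, p=fit.p,
                            significant=bool(fit.p < 0.05), eligible=True,
                        )
                rows.append(row)
    return pd.DataFrame(rows)
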