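"""Marker-validation statistics for survival cohorts.

Implements the panel evaluation protocol: continuous Cox proportional-
hazards screening of standardized markers (hazard ratios per one standard
deviation, Wald tests), a Bonferroni gate at alpha/m over the marker panel
with a dual-endpoint rule (a marker is prognostic only if it passes for
both DDFS and BCSS), median dichotomization with Kaplan-Meier/log-rank
follow-up, Monte-Carlo exact association tests against categorical
clinico-pathological covariates, squared Pearson/Kendall marker
correlations, survival analysis of a binary factor within marker-defined
subgroups, and covariate-adjusted multivariate Cox models.

Cox, Kaplan-Meier and log-rank computations go through lifelines (Efron
tie handling); a fast internal Newton solver for the no-ties single-
covariate partial likelihood backs the large simulation loops and is
cross-checked against lifelines in the test suite.

Missing data are handled complete-case per analysis, with the analysis n
recorded in every result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "CoxResult",
    "KMResult",
    "PanelResult",
    "standardize",
    "bonferroni_gate",
    "fit_continuous_cox",
    "dichotomize_median",
    "km_logrank",
    "association_test",
    "marker_correlations",
    "subgroup_survival",
    "multivariate_cox",
    "evaluate_panel",
    "split_pilot_validation",
    "fast_cox_single",
]

ENDPOINTS = ("ddfs", "bcss")


def _endpoint_cols(endpoint: str) -> tuple[str, str]:
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}, got {endpoint!r}")
    return f"{endpoint}_months", f"{endpoint}_event"


def standardize(values) -> np.ndarray:
    """Z-scores with sample (n-1) standard deviation, on complete cases."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("standardization needs at least two non-missing values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    full = np.asarray(values, dtype=float)
    return (full - x.mean()) / sd


def bonferroni_gate(p_values, alpha: float = 0.05, m: int = 7):
    """Panel-wise Bonferroni decisions: pass iff p <= alpha / m.

    The inequality is non-strict: a p-value exactly at the threshold passes.
    """
    if m < 1:
        raise ValueError("the panel size m must be at least 1")
    threshold = alpha / m
    decisions = np.asarray(p_values, dtype=float) <= threshold
    return threshold, decisions


@dataclass
class CoxResult:
    hr: float
    p: float
    ci_low: float
    ci_high: float
    n: int
    n_events: int
    converged: bool = True


def fit_continuous_cox(
    cohort: pd.DataFrame, marker: str, endpoint: str
) -> CoxResult:
    """Standardized continuous Cox fit: HR per +1 SD of the marker.

    Complete-case on (marker, time, event); Efron handling of tied event
    times.  A fit with no events or that fails to converge returns a
    flagged (non-converged) result rather than raising.
    """
    tcol, ecol = _endpoint_cols(endpoint)
    df = cohort[[marker, tcol, ecol]].dropna()
    n = len(df)
    n_events = int(df[ecol].sum())
    if n_events == 0:
        return CoxResult(math.nan, math.nan, math.nan, math.nan, n, 0, converged=False)
    work = pd.DataFrame({
        "z": standardize(df[marker].to_numpy()),
        tcol: df[tcol].to_numpy(),
        ecol: df[ecol].to_numpy(),
    })
    try:
        cph = CoxPHFitter()
        cph.fit(work, duration_col=tcol, event_col=ecol)
    except ConvergenceError:
        return CoxResult(math.nan, math.nan, math.nan, math.nan, n, n_events,
                         converged=False)
    s = cph.summary.loc["z"]
    return CoxResult(
        hr=float(s["exp(coef)"]),
        p=float(s["p"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        n=n, n_events=n_events,
    )


def dichotomize_median(values) -> np.ndarray:
    """Median cut-off grouping: value <= median -> "low", else "high".

    Ties at the median go to the low group, so an odd n splits (k+1)/k.
    """
    x = np.asarray(values, dtype=float)
    finite = x[~np.isnan(x)]
    if finite.size < 2:
        raise ValueError("dichotomization needs at least two values")
    if np.all(finite == finite[0]):
        raise ValueError("all values identical: the median split is degenerate")
    med = np.median(finite)
    labels = np.where(x <= med, "low", "high")
    labels = labels.astype(object)
    labels[np.isnan(x)] = None
    return labels


@dataclass
class KMResult:
    curves: dict  # group label -> survival function DataFrame
    logrank_p: float
    hr: float
    ci_low: float
    ci_high: float
    cox_p: float
    n_per_group: dict
    events_per_group: dict


def km_logrank(
    cohort: pd.DataFrame, groups, endpoint: str, reference: str | None = None
) -> KMResult:
    """Kaplan-Meier curves, two-sided log-rank test, and the group HR.

    The hazard ratio (with 95% CI) comes from a binary-covariate Cox fit of
    the non-reference (high-risk) group versus the reference group.
    """
    tcol, ecol = _endpoint_cols(endpoint)
    g = pd.Series(groups, index=cohort.index)
    keep = cohort[[tcol, ecol]].notna().all(axis=1) & g.notna()
    df = cohort.loc[keep, [tcol, ecol]]
    g = g[keep]
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly two groups, got {levels}")
    if reference is None:
        reference = "low" if "low" in levels else levels[0]
    other = next(l for l in levels if l != reference)
    if (g == reference).sum() == 0 or (g == other).sum() == 0:
        raise ValueError("empty group")
    if df[ecol].sum() == 0:
        raise ValueError("no events: the log-rank test is undefined")

    curves = {}
    for level in (reference, other):
        kmf = KaplanMeierFitter()
        sel = g == level
        kmf.fit(df.loc[sel, tcol], df.loc[sel, ecol], label=str(level))
        curves[level] = kmf.survival_function_

    lr = logrank_test(
        df.loc[g == reference, tcol], df.loc[g == other, tcol],
        event_observed_A=df.loc[g == reference, ecol],
        event_observed_B=df.loc[g == other, ecol],
    )
    work = pd.DataFrame({
        "x": (g == other).astype(float).to_numpy(),
        tcol: df[tcol].to_numpy(), ecol: df[ecol].to_numpy(),
    })
    try:
        cph = CoxPHFitter()
        cph.fit(work, duration_col=tcol, event_col=ecol)
        s = cph.summary.loc["x"]
        hr, lo, hi, cp = (float(s["exp(coef)"]), float(s["exp(coef) lower 95%"]),
                          float(s["exp(coef) upper 95%"]), float(s["p"]))
    except ConvergenceError:
        hr = lo = hi = cp = math.nan
    return KMResult(
        curves=curves, logrank_p=float(lr.p_value), hr=hr, ci_low=lo, ci_high=hi,
        cox_p=cp,
        n_per_group={l: int((g == l).sum()) for l in levels},
        events_per_group={l: int(df.loc[g == l, ecol].sum()) for l in levels},
    )


def _chi2_statistic(tables: np.ndarray) -> np.ndarray:
    rows = tables.sum(axis=2, keepdims=True)
    cols = tables.sum(axis=1, keepdims=True)
    n = tables.sum(axis=(1, 2), keepdims=True)
    expected = rows * cols / n
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(expected > 0, (tables - expected) ** 2 / expected, 0.0)
    return stat.sum(axis=(1, 2))


def _lbl_statistic(tables: np.ndarray, r_scores: np.ndarray, c_scores: np.ndarray) -> np.ndarray:
    """Linear-by-linear association statistic (n-1) * r^2 with given scores."""
    n = tables.sum(axis=(1, 2))
    pr = tables.sum(axis=2)
    pc = tables.sum(axis=1)
    sx = (pr * r_scores).sum(axis=1)
    sy = (pc * c_scores).sum(axis=1)
    sxx = (pr * r_scores**2).sum(axis=1)
    syy = (pc * c_scores**2).sum(axis=1)
    sxy = (tables * np.outer(r_scores, c_scores)).sum(axis=(1, 2))
    cov = sxy - sx * sy / n
    varx = sxx - sx**2 / n
    vary = syy - sy**2 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where((varx > 0) & (vary > 0), cov**2 / (varx * vary), 0.0)
    return (n - 1) * r2


def association_test(
    group_labels, covariate, ordered: bool = False,
    n_resamples: int = 100_000, seed: int = 0,
) -> float:
    """Exact association p-value between a grouping and a categorical covariate.

    Pearson chi-square for nominal covariates, linear-by-linear trend
    (integer scores) for ordered ones; both realized as Monte-Carlo exact
    tests on the conditional distribution of tables given the margins
    (Patefield sampling, seeded).
    """
    g = pd.Series(group_labels)
    c = pd.Series(covariate)
    keep = g.notna() & c.notna()
    table = pd.crosstab(g[keep], c[keep])
    empty_rows = (table.sum(axis=1) == 0).sum()
    empty_cols = (table.sum(axis=0) == 0).sum()
    if empty_rows or empty_cols:
        warnings.warn("dropping empty rows/columns from the contingency table",
                      stacklevel=2)
        table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    t = table.to_numpy(dtype=float)
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("association test needs at least a 2x2 table")
    rng = np.random.default_rng(seed)
    dist = stats.random_table(t.sum(axis=1), t.sum(axis=0))
    samples = dist.rvs(n_resamples, method="patefield", random_state=rng)
    if ordered:
        r_scores = np.arange(t.shape[0], dtype=float)
        c_scores = np.arange(t.shape[1], dtype=float)
        obs = _lbl_statistic(t[None], r_scores, c_scores)[0]
        null = _lbl_statistic(samples, r_scores, c_scores)
    else:
        obs = _chi2_statistic(t[None])[0]
        null = _chi2_statistic(samples)
    return float((np.sum(null >= obs - 1e-9) + 1) / (n_resamples + 1))


def marker_correlations(
    marker_a, marker_b, categorized: bool = False
) -> tuple[float, float]:
    """Squared Pearson r and squared Kendall tau between two markers.

    With ``categorized=True`` Kendall's tau is computed on the
    median-dichotomized values (the reporting convention for grouped data);
    Pearson always uses the raw values.
    """
    a = np.asarray(marker_a, dtype=float)
    b = np.asarray(marker_b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("correlations need at least three complete pairs")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance input")
    r = stats.pearsonr(a, b).statistic
    if categorized:
        a_t = (a > np.median(a)).astype(int)
        b_t = (b > np.median(b)).astype(int)
    else:
        a_t, b_t = a, b
    tau = stats.kendalltau(a_t, b_t).statistic
    return float(r**2), float(tau**2)


@dataclass
class StratumResult:
    km: KMResult | None
    flagged: str | None = None  # reason when the stratum cannot be analysed


def subgroup_survival(
    cohort: pd.DataFrame, stratifier_groups, factor: str, endpoint: str
) -> dict:
    """Prognostic effect of a binary factor within each marker stratum.

    For every stratum of the dichotomized marker, runs the Kaplan-Meier /
    log-rank / Cox analysis of the factor and reports whether the stratum's
    hazard ratio lies outside the other stratum's confidence interval.
    """
    s = pd.Series(stratifier_groups, index=cohort.index)
    strata = [lvl for lvl in sorted(s.dropna().unique())]
    results: dict[str, StratumResult] = {}
    for lvl in strata:
        sub = cohort[s == lvl]
        try:
            res = km_logrank(sub, sub[factor].map({0: "neg", 1: "pos"}),
                             endpoint, reference="neg")
            results[lvl] = StratumResult(km=res)
        except ValueError as exc:
            results[lvl] = StratumResult(km=None, flagged=str(exc))
    # cross-stratum comparison: HR outside the other's CI
    out = {"strata": results, "hr_outside_other_ci": {}}
    if len(strata) == 2:
        a, b = strata
        ra, rb = results[a], results[b]
        if ra.km is not None and rb.km is not None:
            out["hr_outside_other_ci"][a] = bool(
                not (rb.km.ci_low <= ra.km.hr <= rb.km.ci_high)
            )
            out["hr_outside_other_ci"][b] = bool(
                not (ra.km.ci_low <= rb.km.hr <= ra.km.ci_high)
            )
    return out


def multivariate_cox(
    cohort: pd.DataFrame, covariates: list[str], endpoint: str
) -> pd.DataFrame:
    """Covariate-adjusted Cox model; one row (HR, CI, p) per covariate.

    Warns when the events-per-variable ratio drops below 10 (the usual rule
    of thumb for model stability).  Collinear covariates surface as a
    flagged (non-converged) result.
    """
    tcol, ecol = _endpoint_cols(endpoint)
    df = cohort[covariates + [tcol, ecol]].dropna()
    n_events = int(df[ecol].sum())
    if n_events < 10 * len(covariates):
        warnings.warn(
            f"{n_events} events for {len(covariates)} covariates: fewer than "
            "10 events per variable; estimates may be unstable",
            stacklevel=2,
        )
    try:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=tcol, event_col=ecol)
        summary = cph.summary
        return pd.DataFrame({
            "covariate": summary.index,
            "hr": summary["exp(coef)"].to_numpy(),
            "ci_low": summary["exp(coef) lower 95%"].to_numpy(),
            "ci_high": summary["exp(coef) upper 95%"].to_numpy(),
            "p": summary["p"].to_numpy(),
            "n": len(df),
            "n_events": n_events,
            "converged": True,
        }).reset_index(drop=True)
    except (ConvergenceError, np.linalg.LinAlgError):
        return pd.DataFrame({
            "covariate": covariates,
            "hr": math.nan, "ci_low": math.nan, "ci_high": math.nan,
            "p": math.nan, "n": len(df), "n_events": n_events,
            "converged": False,
        })


@dataclass
class PanelResult:
    """Marker-panel screening outcome."""

    table: pd.DataFrame  # marker x endpoint rows: hr, p, n, n_events, passes
    threshold: float
    alpha: float
    prognostic: dict = field(default_factory=dict)  # marker -> bool (both endpoints)


def evaluate_panel(
    cohort: pd.DataFrame, markers: list[str], alpha: float = 0.05,
    endpoints: tuple[str, ...] = ENDPOINTS,
) -> PanelResult:
    """Continuous Cox screening of a marker panel with the dual-endpoint gate.

    Each marker is standardized and fit against every endpoint; the
    Bonferroni threshold is alpha over the panel size; a marker is
    prognostic iff its Wald p passes the threshold for BOTH endpoints.
    """
    threshold = alpha / len(markers)
    rows = []
    for marker in markers:
        for ep in endpoints:
            res = fit_continuous_cox(cohort, marker, ep)
            rows.append({
                "marker": marker, "endpoint": ep, "hr_per_sd": res.hr,
                "p": res.p, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "n": res.n, "n_events": res.n_events, "converged": res.converged,
                "passes": bool(res.converged and res.p <= threshold),
            })
    table = pd.DataFrame(rows)
    prognostic = {
        m: bool(table[(table.marker == m)]["passes"].all())
        for m in markers
    }
    return PanelResult(table=table, threshold=threshold, alpha=alpha,
                       prognostic=prognostic)


def split_pilot_validation(
    cohort: pd.DataFrame, pilot_fraction: float = 0.25, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random split into pilot and validation subsets."""
    rng = np.random.default_rng(seed)
    n = len(cohort)
    n_pilot = int(round(pilot_fraction * n))
    idx = rng.permutation(n)
    pilot = cohort.iloc[np.sort(idx[:n_pilot])]
    validation = cohort.iloc[np.sort(idx[n_pilot:])]
    return pilot, validation


def fast_cox_single(
    times: np.ndarray, events: np.ndarray, x: np.ndarray,
    max_iter: int = 25, tol: float = 1e-10,
) -> tuple[float, float, float]:
    """Newton fit of the single-covariate Cox partial likelihood.

    Assumes continuous (untied) event times, where the Breslow and Efron
    partial likelihoods coincide.  Returns (log HR, its standard error,
    two-sided Wald p).  Used internally by simulation loops; cross-checked
    against lifelines in the test suite.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    xv = np.asarray(x, dtype=float)
    if not e.any():
        return math.nan, math.nan, math.nan
    order = np.argsort(-t)  # decreasing time: risk sets are prefix sums
    xv = xv[order]
    e_ord = e[order]
    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta * xv)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * xv)
        s2 = np.cumsum(w * xv * xv)
        m1 = s1[e_ord] / s0[e_ord]
        score = np.sum(xv[e_ord] - m1)
        info = np.sum(s2[e_ord] / s0[e_ord] - m1**2)
        if info <= 0:
            return math.nan, math.nan, math.nan
        step = score / info
        beta += step
        if abs(step) < tol:
            break
    se = 1.0 / math.sqrt(info)
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return float(beta), float(se), float(p)
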