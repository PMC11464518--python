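"""Survival evaluation of network indices and clinical severity scores.

Implements the statistical stage of the pipeline: distribution-gated
two-group comparisons, Z transformation of indices, Cox proportional-
hazards fits (partial likelihood with Breslow or Efron tie handling),
composite prognostic scores beta1*SOFA + beta2*delta, ROC analysis with
Youden-optimal cutoffs and PPV/NPV, Brier scores from model-based 28-day
event probabilities, continuous IDI/NRI model-improvement statistics, and
Kaplan-Meier curves with the Mantel-Cox (log-rank) test.

The Cox fitter is implemented here because tie handling must be selectable
(Breslow default, Efron optional); it is cross-checked against lifelines
and against brute-force partial-likelihood maximization in the test suite.
Kaplan-Meier estimation and the log-rank test go through lifelines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxFit",
    "CoxTerm",
    "RocResult",
    "ImprovementStats",
    "SurvivalReport",
    "compare_groups",
    "z_transform",
    "cox_fit",
    "composite_score",
    "roc_analysis",
    "brier_score",
    "idi_nri",
    "km_logrank",
    "run_full_analysis",
]


# ---------------------------------------------------------------------------
# group comparisons


def compare_groups(
    cohort: pd.DataFrame,
    variable: str,
    group_col: str = "group_label",
    categorical: bool | None = None,
) -> tuple[float, float, str]:
    """Two-group comparison of one variable.

    Continuous variables: Shapiro-Wilk normality gate (both groups, 5%)
    selects an independent-samples t test (Levene's test choosing the
    equal/unequal-variance form) or the Mann-Whitney U test. Categorical
    variables (non-numeric, or <= 2 distinct values) use the chi-squared
    test without continuity correction.

    Returns ``(statistic, p_value, test_used)``.
    """
    if group_col not in cohort.columns:
        raise ValueError(f"no group column {group_col!r}")
    groups = cohort[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {len(groups)}")
    sub = cohort[[group_col, variable]].dropna()
    a = sub.loc[sub[group_col] == groups[0], variable]
    b = sub.loc[sub[group_col] == groups[1], variable]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")

    if categorical is None:
        categorical = (
            not pd.api.types.is_numeric_dtype(sub[variable])
            or sub[variable].nunique() <= 2
        )
    if categorical:
        table = pd.crosstab(sub[group_col], sub[variable])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p), "chi-squared"

    av, bv = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        warnings.warn(
            f"variable {variable!r} constant in a group; using Mann-Whitney",
            stacklevel=2,
        )
        stat, p = stats.mannwhitneyu(av, bv, alternative="two-sided")
        return float(stat), float(p), "mann-whitney"

    normal = (
        stats.shapiro(av[:5000]).pvalue > 0.05
        and stats.shapiro(bv[:5000]).pvalue > 0.05
    )
    if normal:
        equal_var = stats.levene(av, bv).pvalue > 0.05
        stat, p = stats.ttest_ind(av, bv, equal_var=equal_var)
        return float(stat), float(p), "t-test" if equal_var else "welch-t"
    stat, p = stats.mannwhitneyu(av, bv, alternative="two-sided")
    return float(stat), float(p), "mann-whitney"


def z_transform(values) -> np.ndarray:
    """Z-score over non-missing entries: mean 0, SD 1 (ddof=1)."""
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing values")
    sd = x[ok].std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation; cannot Z-transform")
    out = np.full_like(x, np.nan)
    out[ok] = (x[ok] - x[ok].mean()) / sd
    return out


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass(frozen=True)
class CoxTerm:
    name: str
    beta: float
    se: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class CoxFit:
    terms: tuple[CoxTerm, ...]
    n: int
    n_events: int
    tie_method: str
    log_likelihood: float
    # Breslow baseline cumulative hazard at the covariate means
    baseline_times: np.ndarray = field(repr=False)
    baseline_cumhaz: np.ndarray = field(repr=False)
    covariate_means: np.ndarray = field(repr=False)
    covariate_names: tuple[str, ...] = ()

    def term(self, name: str) -> CoxTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def betas(self) -> dict[str, float]:
        return {t.name: t.beta for t in self.terms}

    def cumhaz_at(self, horizon: float) -> float:
        idx = np.searchsorted(self.baseline_times, horizon, side="right") - 1
        return float(self.baseline_cumhaz[idx]) if idx >= 0 else 0.0

    def predict_risk(self, covariates: pd.DataFrame, horizon: float) -> np.ndarray:
        """Event probability by ``horizon``: 1 - exp(-H0(t) * exp(lp))."""
        X = covariates[list(self.covariate_names)].to_numpy(dtype=float)
        lp = (X - self.covariate_means) @ np.array(
            [t.beta for t in self.terms]
        )
        return 1.0 - np.exp(-self.cumhaz_at(horizon) * np.exp(lp))


def _cox_risk_sets(
    X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, list[tuple[int, np.ndarray]]]:
    """Sort subjects by descending time and precompute, per distinct event
    time, the risk-set size (a prefix of the sorted order) and the rows of
    the tied events."""
    order = np.argsort(-time, kind="mergesort")
    Xs, ts, es = X[order], time[order], event[order]
    ev_mask = es == 1
    groups = []
    for t in np.unique(ts[ev_mask])[::-1]:
        risk_end = int(np.searchsorted(-ts, -t, side="right"))
        dead_rows = np.flatnonzero(ev_mask & (ts == t))
        groups.append((risk_end, dead_rows))
    return Xs, groups


def _cox_neg_loglik_grad(
    beta: np.ndarray,
    Xs: np.ndarray,
    groups: list[tuple[int, np.ndarray]],
    tie_method: str,
) -> tuple[float, np.ndarray]:
    eta = Xs @ beta
    w = np.exp(eta)
    cw = np.cumsum(w)
    cXw = np.cumsum(Xs * w[:, None], axis=0)
    ll = 0.0
    grad = np.zeros_like(beta)
    for risk_end, dead in groups:
        d = len(dead)
        s0_r = cw[risk_end - 1]
        s1_r = cXw[risk_end - 1]
        ll += eta[dead].sum()
        grad += Xs[dead].sum(axis=0)
        if tie_method == "breslow":
            ll -= d * math.log(s0_r)
            grad -= d * s1_r / s0_r
        else:  # efron
            s0_d = w[dead].sum()
            s1_d = Xs[dead].T @ w[dead]
            for el in range(d):
                f = el / d
                denom = s0_r - f * s0_d
                ll -= math.log(denom)
                grad -= (s1_r - f * s1_d) / denom
    return -ll, -grad


def cox_fit(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    tie_method: str = "breslow",
    duration_col: str = "time",
    event_col: str = "event",
) -> CoxFit:
    """Cox proportional-hazards fit by partial-likelihood maximization.

    Wald standard errors come from the numerically differentiated observed
    information; hazard ratios and 95% CIs are exp(beta +/- 1.96 se). Rows
    with any missing covariate are dropped. Raises on non-convergence or
    separation-like divergence of the coefficients.
    """
    if tie_method not in ("breslow", "efron"):
        raise ValueError("tie_method must be 'breslow' or 'efron'")
    covariates = list(covariates)
    sub = cohort[covariates + [duration_col, event_col]].dropna()
    time = sub[duration_col].to_numpy(dtype=float)
    event = sub[event_col].to_numpy(dtype=int)
    if event.sum() < 1:
        raise ValueError("need at least one event")
    X = sub[covariates].to_numpy(dtype=float)
    means = X.mean(axis=0)
    Xc = X - means  # centering for numerical stability only

    Xs, groups = _cox_risk_sets(Xc, time, event)
    k = len(covariates)

    def numeric_hessian(b: np.ndarray) -> np.ndarray:
        h = 1e-5
        H = np.zeros((k, k))
        for j in range(k):
            e = np.zeros(k)
            e[j] = h
            _, gp = _cox_neg_loglik_grad(b + e, Xs, groups, tie_method)
            _, gm = _cox_neg_loglik_grad(b - e, Xs, groups, tie_method)
            H[:, j] = (gp - gm) / (2 * h)
        return (H + H.T) / 2

    # damped Newton on the convex negative log partial likelihood
    beta = np.zeros(k)
    f, g = _cox_neg_loglik_grad(beta, Xs, groups, tie_method)
    gtol = 1e-6 * max(1.0, event.sum())
    converged = False
    for _ in range(100):
        if np.linalg.norm(g, np.inf) < gtol:
            converged = True
            break
        H = numeric_hessian(beta)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("Cox fit: singular information matrix") from exc
        scale = 1.0
        for _ in range(30):
            cand = beta - scale * step
            f_new, g_new = _cox_neg_loglik_grad(cand, Xs, groups, tie_method)
            if f_new <= f + 1e-12 * abs(f):
                break
            scale /= 2
        beta, f, g = cand, f_new, g_new
        if np.any(np.abs(beta) > 50):
            raise RuntimeError(
                "Cox coefficients diverged (likely complete separation)"
            )
    if not converged and np.linalg.norm(g, np.inf) >= gtol:
        raise RuntimeError("Cox fit did not converge in 100 Newton iterations")

    H = numeric_hessian(beta)
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    if np.any(~np.isfinite(se)) or np.any(se > 50):
        raise RuntimeError(
            "Cox fit is non-identifiable (flat partial likelihood, likely "
            "complete separation); standard errors diverged"
        )

    terms = []
    for name, b, s in zip(covariates, beta, se):
        z = b / s
        terms.append(
            CoxTerm(
                name=name,
                beta=float(b),
                se=float(s),
                hazard_ratio=float(math.exp(b)),
                ci_low=float(math.exp(b - 1.96 * s)),
                ci_high=float(math.exp(b + 1.96 * s)),
                p=float(2 * stats.norm.sf(abs(z))),
            )
        )

    # Breslow baseline cumulative hazard at the covariate means
    cw = np.cumsum(np.exp(Xs @ beta))
    ev_times = np.unique(time[event == 1])
    cumhaz = np.zeros(len(ev_times))
    acc = 0.0
    # groups were built over descending unique event times
    for i, (risk_end, dead) in enumerate(reversed(groups)):
        acc += len(dead) / cw[risk_end - 1]
        cumhaz[i] = acc
    neg_ll, _ = _cox_neg_loglik_grad(beta, Xs, groups, tie_method)
    return CoxFit(
        terms=tuple(terms),
        n=len(sub),
        n_events=int(event.sum()),
        tie_method=tie_method,
        log_likelihood=-neg_ll,
        baseline_times=ev_times,
        baseline_cumhaz=cumhaz,
        covariate_means=means,
        covariate_names=tuple(covariates),
    )


# ---------------------------------------------------------------------------
# composite score, ROC, Brier, IDI/NRI


def composite_score(sofa, delta, beta1: float, beta2: float) -> np.ndarray:
    """beta1 * SOFA + beta2 * delta, with the betas from the corresponding
    multivariate Cox fit and delta on the scale used in that fit."""
    return beta1 * np.asarray(sofa, dtype=float) + beta2 * np.asarray(
        delta, dtype=float
    )


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_p: float
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    brier: float = float("nan")


def _auc_mann_whitney(scores: np.ndarray, events: np.ndarray) -> float:
    """AUC by rank statistic (pair counting with ties worth 1/2)."""
    pos = scores[events == 1]
    neg = scores[events == 0]
    ranks = stats.rankdata(scores)
    r_pos = ranks[events == 1].sum()
    n1, n0 = len(pos), len(neg)
    u = r_pos - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def roc_analysis(scores, events, brier: float = float("nan")) -> RocResult:
    """ROC of a prognostic score against a binary 28-day outcome.

    AUC by the Mann-Whitney rank statistic (tied pairs count 1/2); the AUC
    p-value is the normal-approximation Mann-Whitney test. The cutoff
    maximizes Youden's J over midpoints between adjacent distinct scores
    (ties broken toward higher specificity); a score above the cutoff is
    test-positive. PPV/NPV are computed at the empirical prevalence.
    """
    s = np.asarray(scores, dtype=float)
    e = np.asarray(events, dtype=int)
    ok = np.isfinite(s)
    s, e = s[ok], e[ok]
    n1, n0 = int((e == 1).sum()), int((e == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    auc = _auc_mann_whitney(s, e)
    _, auc_p = stats.mannwhitneyu(s[e == 1], s[e == 0], alternative="two-sided")

    uniq = np.unique(s)
    if len(uniq) == 1:
        candidates = np.array([uniq[0]])
    else:
        mids = (uniq[:-1] + uniq[1:]) / 2
        candidates = np.concatenate(
            ([uniq[0] - (uniq[1] - uniq[0]) / 2], mids)
        )
    best = None
    for c in candidates:
        pred = s > c
        tp = int((pred & (e == 1)).sum())
        fp = int((pred & (e == 0)).sum())
        fn = n1 - tp
        tn = n0 - fp
        sens = tp / n1
        spec = tn / n0
        j = sens + spec - 1
        key = (j, spec, c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec, tp, fp, tn, fn)
    _, cutoff, sens, spec, tp, fp, tn, fn = best
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return RocResult(
        auc=auc,
        auc_p=float(auc_p),
        cutoff=float(cutoff),
        sensitivity=float(sens),
        specificity=float(spec),
        ppv=float(ppv),
        npv=float(npv),
        brier=float(brier),
    )


def brier_score(predicted_risk, events) -> float:
    """Mean squared error of predicted event probabilities."""
    r = np.asarray(predicted_risk, dtype=float)
    e = np.asarray(events, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("predicted risks must lie in [0, 1]")
    return float(np.mean((r - e) ** 2))


@dataclass(frozen=True)
class ImprovementStats:
    idi: float
    idi_p: float
    nri: float
    nri_p: float
    variant: str = "continuous"


def idi_nri(old_risk, new_risk, events) -> ImprovementStats:
    """Integrated discrimination improvement and continuous (category-free)
    net reclassification index of ``new_risk`` over ``old_risk``.

    IDI is the change in discrimination slope; its p-value is a two-sample
    z test on the paired risk differences within events and non-events.
    NRI sums the net proportion of events moved up and non-events moved
    down; its p-value uses the standard asymptotic variance.
    """
    old = np.asarray(old_risk, dtype=float)
    new = np.asarray(new_risk, dtype=float)
    e = np.asarray(events, dtype=int)
    ev, ne = e == 1, e == 0
    n1, n0 = int(ev.sum()), int(ne.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")

    d = new - old
    idi = float(d[ev].mean() - d[ne].mean())
    se_idi = math.sqrt(
        d[ev].var(ddof=1) / n1 + d[ne].var(ddof=1) / n0
    )
    idi_p = float(2 * stats.norm.sf(abs(idi) / se_idi)) if se_idi > 0 else 1.0

    up_e = float((d[ev] > 0).mean())
    down_e = float((d[ev] < 0).mean())
    up_ne = float((d[ne] > 0).mean())
    down_ne = float((d[ne] < 0).mean())
    nri = (up_e - down_e) + (down_ne - up_ne)
    var_nri = (up_e + down_e - (up_e - down_e) ** 2) / n1 + (
        up_ne + down_ne - (down_ne - up_ne) ** 2
    ) / n0
    nri_p = (
        float(2 * stats.norm.sf(abs(nri) / math.sqrt(var_nri)))
        if var_nri > 0
        else 1.0
    )
    return ImprovementStats(idi=idi, idi_p=idi_p, nri=nri, nri_p=nri_p)


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank


def km_logrank(
    times, events, group_indicator
) -> tuple[dict, float, float]:
    """Kaplan-Meier curves per group and the Mantel-Cox (log-rank) test.

    Returns ``(curves, chi2, p)`` where ``curves`` maps group label to a
    DataFrame with columns time, survival, at_risk.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(group_indicator)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError("group_indicator must define exactly 2 groups")
    curves = {}
    for lab in labels:
        m = g == lab
        if m.sum() == 0:
            raise ValueError(f"group {lab!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index)
        curves[lab] = pd.DataFrame(
            {
                "time": sf.index.to_numpy(dtype=float),
                "survival": sf.iloc[:, 0].to_numpy(dtype=float),
                "at_risk": at_risk.to_numpy(dtype=float),
            }
        )
    m0 = g == labels[0]
    lr = logrank_test(t[m0], t[~m0], event_observed_A=e[m0], event_observed_B=e[~m0])
    return curves, float(lr.test_statistic), float(lr.p_value)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class SurvivalReport:
    """Machine-readable analogue of the study's result tables."""

    group_comparisons: pd.DataFrame      # per index: statistic, p, test
    univariate_cox: pd.DataFrame         # per index: beta, se, HR, CI, p
    multivariate_cox: pd.DataFrame       # index + SOFA + KCC terms
    roc: pd.DataFrame                    # SOFA and composite rows
    improvement: pd.DataFrame            # IDI/NRI of composite vs SOFA
    km: dict                             # per index: logrank chi2, p
    metadata: dict

    def to_json_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "group_comparisons": self.group_comparisons.to_dict(orient="records"),
            "univariate_cox": self.univariate_cox.to_dict(orient="records"),
            "multivariate_cox": self.multivariate_cox.to_dict(orient="records"),
            "roc": self.roc.to_dict(orient="records"),
            "improvement": self.improvement.to_dict(orient="records"),
            "km": self.km,
        }


def _cox_rows(fit: CoxFit, index_name: str) -> list[dict]:
    return [
        {
            "index": index_name,
            "term": t.name,
            "beta": t.beta,
            "se": t.se,
            "hazard_ratio": t.hazard_ratio,
            "ci_low": t.ci_low,
            "ci_high": t.ci_high,
            "p": t.p,
        }
        for t in fit.terms
    ]


def run_full_analysis(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    alpha: float = 0.05,
    deviation_convention: str = "standardized_residual",
    tie_method: str = "breslow",
    horizon: float = 28.0,
    extra_indices: pd.DataFrame | None = None,
    brier_method: str = "cox",
) -> SurvivalReport:
    """Run the full parenclitic survival pipeline on a cohort table.

    The reference population is the censored (event == 0) group. For every
    significant axis (and every column of ``extra_indices``, e.g. PCA
    component scores): two-group comparison of the index, univariate Cox on
    the Z-scored index, multivariate Cox against SOFA + KCC, composite
    score ROC/Brier vs SOFA alone, IDI/NRI of the composite over SOFA, and
    a Kaplan-Meier log-rank split at the composite ROC cutoff.
    """
    from .parenclitic import deviation_matrix, fit_reference_models

    cohort = cohort.reset_index(drop=True)
    if "sofa" not in cohort.columns:
        raise ValueError("cohort lacks a 'sofa' column")
    events = cohort["event"].to_numpy(dtype=int)
    reference = cohort[cohort["event"] == 0]

    models = fit_reference_models(
        reference, variables, alpha=alpha, deviation_convention=deviation_convention
    )
    dm = deviation_matrix(models, cohort).reset_index(drop=True)
    indices = dm.copy()
    if extra_indices is not None:
        extra = extra_indices.reset_index(drop=True)
        indices = pd.concat([indices, extra], axis=1)

    has_kcc = "kcc" in cohort.columns and cohort["kcc"].nunique() > 1
    adjusters = ["sofa"] + (["kcc"] if has_kcc else [])

    comp_rows, uni_rows, multi_rows, roc_rows, imp_rows = [], [], [], [], []
    km_out: dict[str, dict] = {}

    # SOFA-alone model: reference point for composite improvement
    sofa_fit = cox_fit(cohort, ["sofa"], tie_method=tie_method)
    if brier_method == "cox":
        sofa_risk = sofa_fit.predict_risk(cohort, horizon)
    else:
        sofa_risk = _logistic_risk(cohort[["sofa"]].to_numpy(dtype=float), events)
    sofa_roc = roc_analysis(
        cohort["sofa"], events, brier=brier_score(sofa_risk, events)
    )
    roc_rows.append({"index": "SOFA", **sofa_roc.__dict__, "auc_increase_pct": 0.0})

    work = cohort.copy()
    for col in indices.columns:
        vals = indices[col].to_numpy(dtype=float)
        if not np.isfinite(vals[np.isfinite(vals)]).any():
            continue
        try:
            z = z_transform(vals)
        except ValueError:
            warnings.warn(f"index {col!r} has zero variance; skipped", stacklevel=2)
            continue
        work["_index_z"] = z

        stat, p_cmp, test = compare_groups(
            work.assign(_idx=vals),
            "_idx",
            group_col="event",
            categorical=False,
        )
        comp_rows.append({"index": col, "statistic": stat, "p": p_cmp, "test": test})

        uni = cox_fit(work, ["_index_z"], tie_method=tie_method)
        uni_rows.append({**_cox_rows(uni, col)[0], "term": col})

        multi = cox_fit(work, ["_index_z"] + adjusters, tie_method=tie_method)
        for row in _cox_rows(multi, col):
            if row["term"] == "_index_z":
                row["term"] = col
            multi_rows.append(row)

        beta_delta = multi.term("_index_z").beta
        beta_sofa = multi.term("sofa").beta
        comp = composite_score(work["sofa"], z, beta_sofa, beta_delta)
        work["_composite"] = comp
        comp_fit = cox_fit(work, ["_composite"], tie_method=tie_method)
        if brier_method == "cox":
            comp_risk = comp_fit.predict_risk(work, horizon)
        else:
            comp_risk = _logistic_risk(comp.reshape(-1, 1), events)
        ok = np.isfinite(comp)
        comp_roc = roc_analysis(
            comp[ok], events[ok], brier=brier_score(comp_risk[ok], events[ok])
        )
        roc_rows.append(
            {
                "index": f"{col} + SOFA",
                **comp_roc.__dict__,
                "auc_increase_pct": 100 * (comp_roc.auc - sofa_roc.auc) / sofa_roc.auc,
            }
        )
        imp = idi_nri(sofa_risk[ok], comp_risk[ok], events[ok])
        imp_rows.append({"index": f"{col} + SOFA", **imp.__dict__})

        above = comp > comp_roc.cutoff
        if 0 < above.sum() < ok.sum():
            _, chi2, p_km = km_logrank(
                work.loc[ok, "time"], events[ok], above[ok]
            )
            km_out[col] = {"chi2": chi2, "p": p_km, "cutoff": comp_roc.cutoff}

    return SurvivalReport(
        group_comparisons=pd.DataFrame(comp_rows),
        univariate_cox=pd.DataFrame(uni_rows),
        multivariate_cox=pd.DataFrame(multi_rows),
        roc=pd.DataFrame(roc_rows),
        improvement=pd.DataFrame(imp_rows),
        km=km_out,
        metadata={
            "n": int(len(cohort)),
            "n_events": int(events.sum()),
            "alpha": alpha,
            "deviation_convention": deviation_convention,
            "tie_method": tie_method,
            "brier_method": brier_method,
            "n_significant_axes": len(models.significant_models),
            "adjusters": adjusters,
        },
    )


def _logistic_risk(X: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Recalibrated 28-day risk from a logistic fit (Brier fallback)."""
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(penalty=None, max_iter=1000)
    lr.fit(X, events)
    return lr.predict_proba(X)[:, 1]
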