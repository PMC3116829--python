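"""Prognostic statistics for per-case texture features.

The chain mirrors a classical survival work-up of a biomarker cohort:

* Kaplan–Meier curves with a log-rank test for grouped comparisons;
* Cox proportional-hazards regression (optionally stratified, e.g. by
  ISS stage), with Wald p-values per coefficient;
* backward stepwise selection on likelihood-ratio tests (entry p < 0.05,
  removal p > 0.10 by default), with re-entry testing after removals;
* bootstrap model-stability analysis: the stepwise selection is re-run on
  resamples drawn with replacement, and each candidate's inclusion
  frequency across resamples is reported;
* a Ward-objective cut-point for dichotomizing a continuous feature;
* one-way ANOVA with Fisher LSD post-hoc tests for group comparisons of
  the texture features.

The ISS stage covariate is expanded to indicator contrasts with stage III
as the reference category, so the stage-III coefficient is identically 0.
Ties in event times are handled by Efron's approximation (identical to
Breslow's when all event times are distinct, as with the continuous-time
synthetic cohorts used throughout).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "PatientRecord",
    "CoxFit",
    "StabilityResult",
    "KMResult",
    "AnovaLSD",
    "cohort_frame",
    "km_logrank",
    "cox_fit",
    "backward_stepwise",
    "bootstrap_stability",
    "ward_cutpoint",
    "anova_lsd",
]

ISS_STAGES = ("I", "II", "III")


@dataclass(frozen=True)
class PatientRecord:
    """Clinical covariates and outcome for one patient.

    ``time_months`` is the observed survival time; patients censored at
    transplantation carry ``event=False`` with ``time_months`` equal to
    the time to transplant.
    """

    case_id: str
    time_months: float
    event: bool
    iss_stage: str = "III"
    very_poor_group: bool = False
    n_cytogenetic_abnormalities: int = 0
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.time_months > 0:
            raise ValueError("time_months must be positive")
        if self.iss_stage not in ISS_STAGES:
            raise ValueError(f"iss_stage must be one of {ISS_STAGES}")


def cohort_frame(cohort) -> pd.DataFrame:
    """Normalize a cohort (records or DataFrame) to a flat DataFrame."""
    if isinstance(cohort, pd.DataFrame):
        return cohort.copy()
    rows = []
    for rec in cohort:
        row = {
            "case_id": rec.case_id,
            "time_months": float(rec.time_months),
            "event": bool(rec.event),
            "iss_stage": rec.iss_stage,
            "very_poor_group": int(rec.very_poor_group),
            "n_cytogenetic_abnormalities": int(rec.n_cytogenetic_abnormalities),
        }
        row.update({k: float(v) for k, v in rec.covariates.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design-matrix handling


def _term_columns(df: pd.DataFrame, term: str) -> pd.DataFrame:
    """Expand one model term to numeric design columns.

    ``iss_stage`` becomes two indicator columns (stage III reference);
    anything else must be a numeric column of ``df``.
    """
    if term == "iss_stage":
        return pd.DataFrame(
            {
                "iss_I": (df["iss_stage"] == "I").astype(float),
                "iss_II": (df["iss_stage"] == "II").astype(float),
            },
            index=df.index,
        )
    if term not in df.columns:
        raise KeyError(f"unknown model term {term!r}")
    col = pd.to_numeric(df[term])
    if col.nunique() < 2:
        raise ValueError(f"covariate {term!r} is constant")
    return col.astype(float).to_frame(term)


def _design(
    df: pd.DataFrame, terms: Sequence[str], strata: Optional[str]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    parts = [df[["time_months"]].astype(float), df[["event"]].astype(bool)]
    colmap: dict[str, list[str]] = {}
    for term in terms:
        block = _term_columns(df, term)
        colmap[term] = list(block.columns)
        parts.append(block)
    if strata is not None:
        parts.append(df[[strata]])
    return pd.concat(parts, axis=1), colmap


# ---------------------------------------------------------------------------
# Kaplan–Meier / log-rank


@dataclass(frozen=True)
class KMResult:
    curves: dict
    statistic: float
    p_value: float
    no_events: bool


def km_logrank(cohort, group_by) -> KMResult:
    """Product-limit curves per group and the log-rank test across groups.

    ``group_by`` is either a column name of the cohort or an array of
    precomputed group labels.  With no events anywhere, the curves are
    flat at 1 and the test is flagged undefined rather than computed.
    """
    df = cohort_frame(cohort)
    if isinstance(group_by, str):
        labels = df[group_by].to_numpy()
    else:
        labels = np.asarray(group_by)
        if labels.shape[0] != len(df):
            raise ValueError("label vector length must match the cohort size")
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("log-rank comparison needs at least 2 groups")
    curves = {}
    for g in uniq:
        sel = labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[sel, "time_months"], df.loc[sel, "event"], label=str(g))
        curves[g] = kmf.survival_function_
    if int(df["event"].sum()) == 0:
        return KMResult(curves=curves, statistic=float("nan"),
                        p_value=float("nan"), no_events=True)
    res = multivariate_logrank_test(df["time_months"], labels, df["event"])
    return KMResult(
        curves=curves,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        no_events=False,
    )


# ---------------------------------------------------------------------------
# Cox regression


@dataclass(frozen=True)
class CoxFit:
    coefficients: dict
    p_values: dict
    std_errors: dict
    included: frozenset
    strata_variable: Optional[str]
    log_likelihood: float
    n: int
    n_events: int
    term_columns: dict = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return len(self.included) == 0


def _null_loglik(df: pd.DataFrame, strata: Optional[str]) -> float:
    """Partial log-likelihood at β = 0 (Efron tie handling).

    With no covariates each event at a time with d tied deaths and risk
    set of size n contributes −Σ_{j=0..d−1} log(n − j); summed within each
    stratum.
    """
    def one(group: pd.DataFrame) -> float:
        t = group["time_months"].to_numpy(float)
        e = group["event"].to_numpy(bool)
        ll = 0.0
        for tt in np.unique(t[e]):
            d = int(np.sum(e & (t == tt)))
            n_risk = int(np.sum(t >= tt))
            ll -= sum(np.log(n_risk - j) for j in range(d))
        return ll

    if strata is None:
        return one(df)
    return float(sum(one(g) for _, g in df.groupby(strata, observed=True)))


def cox_fit(
    cohort,
    variables: Sequence[str],
    strata: Optional[str] = None,
) -> CoxFit:
    """Maximum partial-likelihood Cox fit with Wald p-values.

    ``variables`` are model terms (``iss_stage`` expands to indicator
    contrasts with stage III as reference).  ``strata`` names a
    categorical column used to stratify the baseline hazard.
    """
    df = cohort_frame(cohort)
    if int(df["event"].sum()) < 1:
        raise ValueError("cohort has no events; Cox model is undefined")
    X, colmap = _design(df, list(variables), strata)
    if len(variables) == 0:
        return CoxFit(
            coefficients={}, p_values={}, std_errors={},
            included=frozenset(), strata_variable=strata,
            log_likelihood=_null_loglik(df, strata),
            n=len(df), n_events=int(df["event"].sum()),
        )
    cph = CoxPHFitter(penalizer=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            X,
            duration_col="time_months",
            event_col="event",
            strata=[strata] if strata is not None else None,
            # tight Newton tolerances: the default stopping rule leaves a
            # last unapplied step of ~1e-6 in the coefficients
            fit_options={"precision": 1e-12, "r_precision": 1e-14},
        )
    coefs = cph.params_.to_dict()
    pvals = cph.summary["p"].to_dict()
    ses = cph.summary["se(coef)"].to_dict()
    return CoxFit(
        coefficients=coefs,
        p_values=pvals,
        std_errors=ses,
        included=frozenset(variables),
        strata_variable=strata,
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=int(df["event"].sum()),
        term_columns=colmap,
    )


def _lr_pvalue(ll_big: float, ll_small: float, df_diff: int) -> float:
    stat = max(0.0, 2.0 * (ll_big - ll_small))
    return float(stats.chi2.sf(stat, df_diff))


def _term_df(term: str) -> int:
    return 2 if term == "iss_stage" else 1


def backward_stepwise(
    cohort,
    candidates: Sequence[str],
    p_in: float = 0.05,
    p_out: float = 0.10,
    strata: Optional[str] = None,
    max_iter: int = 50,
) -> CoxFit:
    """Backward stepwise Cox selection with re-entry testing.

    Starts from the full model; repeatedly removes the term with the
    largest likelihood-ratio p exceeding ``p_out``, and after each removal
    re-tests excluded candidates for re-entry at ``p_in``.  Deterministic
    given the data.  If the full model fails to fit, falls back to a
    forward build from the strongest single term.
    """
    if len(candidates) == 0:
        raise ValueError("no candidate variables")
    df = cohort_frame(cohort)
    candidates = list(candidates)

    def fit(terms: Sequence[str]) -> CoxFit:
        return cox_fit(df, list(terms), strata=strata)

    current: list[str]
    try:
        model = fit(candidates)
        current = list(candidates)
    except Exception:
        # forward fallback: grow from the strongest single variable
        current = []
        model = fit(current)
        improved = True
        while improved:
            improved = False
            best, best_p = None, 1.0
            for term in candidates:
                if term in current:
                    continue
                try:
                    trial = fit(current + [term])
                except Exception:
                    continue
                p = _lr_pvalue(trial.log_likelihood, model.log_likelihood,
                               _term_df(term))
                if p < best_p:
                    best, best_p = term, p
            if best is not None and best_p < p_in:
                current.append(best)
                model = fit(current)
                improved = True
        return model

    seen = {frozenset(current)}
    for _ in range(max_iter):
        changed = False
        # removal phase: largest LR p above p_out goes
        if current:
            worst, worst_p = None, -1.0
            for term in current:
                reduced = fit([t for t in current if t != term])
                p = _lr_pvalue(model.log_likelihood, reduced.log_likelihood,
                               _term_df(term))
                if p > worst_p:
                    worst, worst_p = term, p
            if worst is not None and worst_p > p_out:
                current = [t for t in current if t != worst]
                model = fit(current)
                changed = True
        # re-entry phase: smallest LR p below p_in comes back
        excluded = [t for t in candidates if t not in current]
        if excluded:
            best, best_p = None, 1.0
            for term in excluded:
                try:
                    trial = fit(current + [term])
                except Exception:
                    continue
                p = _lr_pvalue(trial.log_likelihood, model.log_likelihood,
                               _term_df(term))
                if p < best_p:
                    best, best_p = term, p
            if best is not None and best_p < p_in:
                current = current + [best]
                model = fit(current)
                changed = True
        state = frozenset(current)
        if not changed or state in seen:
            break
        seen.add(state)
    return model


@dataclass(frozen=True)
class StabilityResult:
    n_boot: int
    inclusion_freq: dict
    seed: int
    n_retries: int


def bootstrap_stability(
    cohort,
    candidates: Sequence[str],
    n_boot: int = 100,
    seed: int = 0,
    p_in: float = 0.05,
    p_out: float = 0.10,
    strata: Optional[str] = None,
    max_retries_per_sample: int = 20,
) -> StabilityResult:
    """Inclusion frequency of each candidate over bootstrap resamples.

    Each resample draws n patients with replacement and re-runs the full
    stepwise selection.  Resamples whose fit fails outright (e.g. a
    resample without events) are redrawn, keeping the denominator at
    ``n_boot``; the retry count is reported.
    """
    df = cohort_frame(cohort)
    n = len(df)
    counts = {t: 0 for t in candidates}
    retries = 0
    streams = np.random.SeedSequence(seed).spawn(n_boot)
    for ss in streams:
        rng = np.random.default_rng(ss)
        for _ in range(max_retries_per_sample):
            idx = rng.integers(0, n, size=n)
            sample = df.iloc[idx].reset_index(drop=True)
            try:
                model = backward_stepwise(
                    sample, candidates, p_in=p_in, p_out=p_out, strata=strata
                )
            except Exception:
                retries += 1
                continue
            for t in model.included:
                counts[t] += 1
            break
        else:
            raise RuntimeError(
                "bootstrap resample failed to fit after "
                f"{max_retries_per_sample} redraws"
            )
    freq = {t: counts[t] / n_boot for t in candidates}
    return StabilityResult(
        n_boot=n_boot, inclusion_freq=freq, seed=seed, n_retries=retries
    )


# ---------------------------------------------------------------------------
# Ward cut-point


def ward_cutpoint(values: Sequence[float]) -> float:
    """Two-cluster Ward cut-point of a 1-D feature.

    Minimizing the Ward objective at k = 2 on one-dimensional data is an
    exhaustive search over contiguous splits of the sorted values for the
    partition with minimal total within-cluster sum of squares; the
    cut-point returned is the midpoint between the largest value of the
    lower cluster and the smallest value of the upper cluster.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 2 or v[0] == v[-1]:
        raise ValueError("need at least 2 distinct values to dichotomize")
    csum = np.cumsum(v)
    csq = np.cumsum(v**2)
    total_sum, total_sq, n = csum[-1], csq[-1], v.size
    best_i, best_ss = 1, np.inf
    for i in range(1, n):  # lower cluster = v[:i]
        s1, q1 = csum[i - 1], csq[i - 1]
        s2, q2 = total_sum - s1, total_sq - q1
        ss = (q1 - s1**2 / i) + (q2 - s2**2 / (n - i))
        if ss < best_ss - 1e-12:
            best_ss, best_i = ss, i
    return float((v[best_i - 1] + v[best_i]) / 2.0)


# ---------------------------------------------------------------------------
# ANOVA + Fisher LSD


@dataclass(frozen=True)
class AnovaLSD:
    f_statistic: float
    p_value: float
    pairwise_p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    degenerate: bool


def anova_lsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> AnovaLSD:
    """One-way ANOVA followed by Fisher LSD pairwise tests.

    The LSD tests are plain pairwise t-tests on the pooled within-group
    variance with N − k degrees of freedom, each compared to ``alpha``
    without multiplicity correction (that is what LSD specifies).
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrs = {g: np.asarray(groups[g], dtype=float) for g in labels}
    if any(a.size < 2 for a in arrs.values()):
        raise ValueError("each group needs at least 2 observations")
    n_total = sum(a.size for a in arrs.values())
    k = len(labels)
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs.values())
    df_w = n_total - k
    msw = ssw / df_w
    degenerate = msw == 0.0
    if degenerate:
        f_stat, p_val = float("nan"), float("nan")
    else:
        f_stat, p_val = stats.f_oneway(*arrs.values())
        f_stat, p_val = float(f_stat), float(p_val)
    pw = pd.DataFrame(np.nan, index=labels, columns=labels)
    sig = pd.DataFrame(False, index=labels, columns=labels)
    if not degenerate:
        for i, gi in enumerate(labels):
            for gj in labels[i + 1:]:
                a, b = arrs[gi], arrs[gj]
                se = np.sqrt(msw * (1 / a.size + 1 / b.size))
                t = (a.mean() - b.mean()) / se
                p = 2.0 * float(stats.t.sf(abs(t), df_w))
                pw.loc[gi, gj] = pw.loc[gj, gi] = p
                sig.loc[gi, gj] = sig.loc[gj, gi] = p < alpha
    return AnovaLSD(
        f_statistic=f_stat, p_value=p_val, pairwise_p=pw,
        significant=sig, alpha=alpha, degenerate=degenerate,
    )
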