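"""Cohort-level prognostic statistics.

Implements the statistical layer applied to the per-patient parameter
vectors: two-sample t-tests between recurrence (ER/LR) and metastasis
(DM/non-DM) groups, ROC-derived optimal cutoffs (Youden's J), Kaplan–Meier
curves with log-rank tests for parameters dichotomized at those cutoffs,
multivariate Cox models with clinical covariates, and the advanced-stage
(IIB+) subset analysis.

Survival machinery (product-limit estimator, log-rank, Cox partial
likelihood with Efron ties) is delegated to ``lifelines``; the cutoff
search is enumerated here because its tie-breaking and direction rules are
part of this package's contract.

A caution that applies to any optimal-cutpoint analysis: dichotomizing at
the cutoff that maximizes separation on the *same* endpoint inflates the
log-rank type-I error well above nominal.  :func:`logrank_optimized_cutoff`
offers a permutation-corrected p-value for exactly this reason; the plain
per-parameter p-values are reported uncorrected by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SurvivalRecord",
    "GroupComparisonResult",
    "CutoffResult",
    "KMResult",
    "CoxResult",
    "records_to_frame",
    "clinical_design_matrix",
    "compare_groups",
    "roc_cutoff",
    "km_logrank",
    "logrank_optimized_cutoff",
    "cox_multivariate",
    "stage_subset",
]

LATE_STAGES = ("IIB", "IIIA", "IIIB", "IIIC", "III")


@dataclass
class SurvivalRecord:
    """One patient's follow-up outcome and clinical covariates."""

    patient_id: str
    dfs_months: float
    dfs_event: bool
    os_months: float
    os_event: bool
    recurrence: bool  # ER group membership (recurrence during follow-up)
    metastasis: bool  # DM group membership
    stage: str = ""
    age_group: str = ""
    tumor_size_cm: float = np.nan
    grade: int = 0
    ki67_pct: float = np.nan
    p53_positive: int = 0
    basal_like: int = 0

    def __post_init__(self) -> None:
        if self.dfs_months < 0 or self.os_months < 0:
            raise ValueError("survival times must be >= 0")
        if self.dfs_months > self.os_months + 1e-9:
            raise ValueError("DFS time cannot exceed OS time")


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    return df.set_index("patient_id")


AGE_ORDER = {"<40": 0, "40-50": 1, ">50": 2}
STAGE_ORDER = {"I": 1, "IIA": 2, "IIB": 3, "III": 4, "IIIA": 4, "IIIB": 5, "IIIC": 6}


def clinical_design_matrix(clinical: pd.DataFrame, ki67_threshold: float = 14.0) -> pd.DataFrame:
    """Numeric covariate encoding used by the multivariate Cox models.

    Age and stage are ordinal scores, Ki67 is dichotomized at the
    configured threshold (default 14%), grade/size enter as numeric,
    p53 and basal-like as indicators.
    """
    return pd.DataFrame(
        {
            "age": clinical["age_group"].map(AGE_ORDER).astype(float),
            "basal_like": clinical["basal_like"].astype(float),
            "stage": clinical["stage"].map(STAGE_ORDER).astype(float),
            "tumor_size": clinical["tumor_size_cm"].astype(float),
            "grade": clinical["grade"].astype(float),
            "ki67_high": (clinical["ki67_pct"] >= ki67_threshold).astype(float),
            "p53": clinical["p53_positive"].astype(float),
        },
        index=clinical.index,
    )


@dataclass
class GroupComparisonResult:
    table: pd.DataFrame  # parameter x [mean_a, mean_b, t, p, significant]
    group_a: str
    group_b: str
    alpha: float = 0.05


def compare_groups(
    parameters: pd.DataFrame,
    labels: pd.Series,
    group_names: tuple[str, str] = ("ER", "LR"),
    equal_var: bool = True,
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Per-parameter two-sample t-test between two patient groups.

    ``labels`` is boolean (True = first group).  Groups with fewer than two
    patients yield a missing p flagged as NaN.  Student's t (equal
    variances) by default; Welch with ``equal_var=False``.
    """
    labels = labels.reindex(parameters.index).astype(bool)
    a_df = parameters.loc[labels]
    b_df = parameters.loc[~labels]
    rows = []
    for col in parameters.columns:
        a = a_df[col].dropna().to_numpy()
        b = b_df[col].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            rows.append((col, np.nan, np.nan, np.nan, np.nan, False))
            continue
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        rows.append((col, a.mean(), b.mean(), float(t), float(p), bool(p < alpha)))
    table = pd.DataFrame(
        rows, columns=["parameter", "mean_a", "mean_b", "t", "p", "significant"]
    ).set_index("parameter")
    return GroupComparisonResult(table, group_names[0], group_names[1], alpha)


@dataclass(frozen=True)
class CutoffResult:
    threshold: float
    youden_j: float
    direction: str  # "high" = values above threshold predicted positive
    sensitivity: float
    specificity: float


def roc_cutoff(values: np.ndarray, outcome: np.ndarray, criterion: str = "youden") -> CutoffResult:
    """Most discriminating threshold for a continuous parameter.

    Enumerates all midpoints between consecutive sorted unique values and
    maximizes Youden's J = sensitivity + specificity - 1 (or the
    closest-to-corner criterion with ``criterion="corner"``), over both
    orientations; ties resolve to the lower threshold.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    ok = np.isfinite(v)
    v, y = v[ok], y[ok]
    if y.all() or (~y).all():
        raise ValueError("both outcome classes must be present")
    uniq = np.unique(v)
    if len(uniq) < 2:
        raise ValueError("parameter is constant; no cutoff exists")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos, n_neg = y.sum(), (~y).sum()
    best: CutoffResult | None = None
    best_score = -np.inf
    for t in mids:
        for direction in ("high", "low"):
            pred = v > t if direction == "high" else v < t
            sens = float((pred & y).sum() / n_pos)
            spec = float((~pred & ~y).sum() / n_neg)
            if criterion == "youden":
                score = sens + spec - 1.0
            elif criterion == "corner":
                score = -float(np.hypot(1 - sens, 1 - spec))
            else:
                raise ValueError(f"unknown criterion {criterion!r}")
            if score > best_score + 1e-12:
                best_score = score
                best = CutoffResult(float(t), sens + spec - 1.0, direction, sens, spec)
    assert best is not None
    return best


@dataclass
class KMResult:
    curves: dict  # stratum -> DataFrame(timeline, survival)
    statistic: float
    p_value: float
    n_per_stratum: dict


def km_logrank(
    times: np.ndarray, events: np.ndarray, strata: np.ndarray
) -> KMResult:
    """Product-limit curves per stratum and the two-sample log-rank test."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    strata = np.asarray(strata)
    if events.sum() < 1:
        raise ValueError("at least one event is required")
    labels = np.unique(strata)
    if any((strata == lab).sum() == 0 for lab in labels) or len(labels) != 2:
        raise ValueError("exactly two non-empty strata are required")
    curves = {}
    for lab in labels:
        m = strata == lab
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m], label=str(lab))
        curves[lab] = kmf.survival_function_
    m = strata == labels[0]
    res = logrank_test(times[m], times[~m], events[m], events[~m])
    return KMResult(
        curves=curves,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        n_per_stratum={lab: int((strata == lab).sum()) for lab in labels},
    )


def logrank_optimized_cutoff(
    values: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    outcome_for_cutoff: np.ndarray | None = None,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Dichotomize at the ROC-optimal cutoff, then log-rank.

    When ``n_permutations`` > 0, a permutation p-value is computed by
    re-optimizing the cutoff on each label permutation — correcting the
    selection inflation inherent to optimal-cutpoint dichotomization.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    outcome = events if outcome_for_cutoff is None else np.asarray(outcome_for_cutoff, dtype=bool)

    def run(v: np.ndarray, t: np.ndarray, e: np.ndarray, o: np.ndarray) -> tuple[float, float]:
        cut = roc_cutoff(v, o)
        strata = np.where(v > cut.threshold, "high", "low")
        if len(np.unique(strata)) < 2:
            return np.nan, np.nan
        res = km_logrank(t, e, strata)
        return res.statistic, res.p_value

    stat, p = run(values, times, events, outcome)
    out = {"statistic": stat, "p_value": p}
    if n_permutations > 0:
        rng = rng or np.random.default_rng()
        count = 0
        valid = 0
        for _ in range(n_permutations):
            perm = rng.permutation(len(values))
            s, _ = run(values[perm], times, events, outcome[perm])
            if np.isfinite(s):
                valid += 1
                if s >= stat:
                    count += 1
        out["p_permutation"] = (count + 1) / (valid + 1) if valid else np.nan
    return out


@dataclass
class CoxResult:
    summary: pd.DataFrame  # covariate x [coef, hr, p]
    converged: bool
    n: int
    n_events: int
    message: str = ""


def cox_multivariate(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str] | None = None,
) -> CoxResult:
    """Multivariate Cox proportional-hazards fit (Efron tie handling).

    Refuses underdetermined designs (events <= covariates) and collinear
    covariate columns rather than returning a silently unstable fit.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    covariates = covariates or [c for c in df.columns if c not in (duration_col, event_col)]
    data = df[[duration_col, event_col, *covariates]].dropna()
    n_events = int(data[event_col].sum())
    if n_events < len(covariates) + 1:
        raise ValueError(
            f"{n_events} events cannot identify {len(covariates)} covariates "
            "(need events >= covariates + 1)"
        )
    x = data[covariates].to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    if np.linalg.matrix_rank(xc, tol=1e-8 * max(1.0, np.abs(xc).max())) < len(covariates):
        raise ValueError("collinear covariate columns; drop or combine them")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=duration_col, event_col=event_col)
        summary = cph.summary[["coef", "exp(coef)", "p"]].rename(
            columns={"exp(coef)": "hr"}
        )
        return CoxResult(summary, True, len(data), n_events)
    except ConvergenceError as err:  # separation etc.: flagged, never silent
        summary = pd.DataFrame(
            np.nan, index=covariates, columns=["coef", "hr", "p"]
        )
        return CoxResult(summary, False, len(data), n_events, message=str(err))


def stage_subset(clinical: pd.DataFrame, rule: str = "IIB+") -> pd.DataFrame:
    """Advanced-stage subset: stage in {IIB, IIIA, IIIB, IIIC}.

    Patients with a missing stage are excluded with a warning.  Currently
    the only rule is ``"IIB+"``.
    """
    if rule != "IIB+":
        raise ValueError(f"unknown stage-subset rule {rule!r}")
    stage = clinical["stage"].astype(str)
    missing = stage.isin(["", "nan", "None"])
    if missing.any():
        warnings.warn(f"{int(missing.sum())} patient(s) with missing stage excluded", stacklevel=2)
    keep = stage.isin(LATE_STAGES) & ~missing
    return clinical.loc[keep]
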