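"""Survival-analysis chain for a cohort of feature vectors and outcomes.

Implements the statistical pipeline used to rank prognostic PET features:
administrative censoring at a horizon, Spearman correlation with
average-linkage clustering of features, horizon-anchored ROC analysis with a
sensitivity-x-specificity-product cutoff, median-split Kaplan-Meier with
log-rank tests, univariate and stepwise-backwards multivariate Cox
proportional-hazards models, treatment-by-feature subgroup curves, the
pooled-variance Student's t comparison, and reverse-Kaplan-Meier median
follow-up.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .features import FEATURE_COLUMNS

ENDPOINTS = ("os", "pfs")

#: binary encodings of the categorical covariates (value coded 1, reference 0)
CATEGORICAL_CODING = {
    "ecog_band": ("2-4", "0-1"),
    "ips_band": ("3-7", "0-2"),
    "treatment": ("BEACOPP", "ABVD"),
}


class DegenerateOutcomeError(ValueError):
    """Raised when an analysis has no positives, no negatives or no events."""


def _endpoint_cols(endpoint: str) -> tuple[str, str]:
    endpoint = endpoint.lower()
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}, got {endpoint!r}")
    return f"{endpoint}_time_years", f"{endpoint}_event"


def _design_column(cohort: pd.DataFrame, variable: str) -> pd.Series:
    """Numeric column for modelling: features pass through per natural unit,
    known categoricals are coded 0/1."""
    col = cohort[variable]
    if variable in CATEGORICAL_CODING:
        coded, ref = CATEGORICAL_CODING[variable]
        return (col == coded).astype(float)
    return pd.to_numeric(col).astype(float)


# ---------------------------------------------------------------------------
# censoring & follow-up
# ---------------------------------------------------------------------------

def censor_at_horizon(
    cohort: pd.DataFrame, horizon_years: float = 5.0, endpoints: tuple[str, ...] = ENDPOINTS
) -> pd.DataFrame:
    """Administratively censor both endpoints at the horizon.

    Times beyond the horizon are replaced by the horizon with event = 0;
    everything else is unchanged.
    """
    if horizon_years <= 0:
        raise ValueError("horizon_years must be > 0")
    out = cohort.copy()
    for ep in endpoints:
        tcol, ecol = _endpoint_cols(ep)
        over = out[tcol] > horizon_years
        out.loc[over, tcol] = horizon_years
        out.loc[over, ecol] = 0
    return out


def median_followup(cohort: pd.DataFrame, endpoint: str = "os") -> float:
    """Median follow-up by the reverse Kaplan-Meier method.

    Deaths are treated as censored and censorings as events; the median of
    that curve estimates the median potential follow-up.  Returns ``inf``
    when the median is not reached (everyone had the event).
    """
    tcol, ecol = _endpoint_cols(endpoint)
    kmf = KaplanMeierFitter()
    kmf.fit(cohort[tcol], event_observed=1 - cohort[ecol])
    return float(kmf.median_survival_time_)


# ---------------------------------------------------------------------------
# correlation clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterAssignment:
    labels: dict[str, int]  # feature -> cluster label (1..k)
    cut_height: float
    excluded: tuple[str, ...] = ()

    def partition(self) -> list[set[str]]:
        groups: dict[int, set[str]] = {}
        for feat, lab in self.labels.items():
            groups.setdefault(lab, set()).add(feat)
        return list(groups.values())


def spearman_cluster(
    cohort: pd.DataFrame, k: int = 4, feature_cols: list[str] | None = None
) -> tuple[pd.DataFrame, ClusterAssignment]:
    """Spearman correlation matrix + average-linkage clustering on 1 - |rho|.

    Constant features (zero rank variance) cannot be correlated and are
    excluded with a warning.
    """
    cols = list(feature_cols or FEATURE_COLUMNS)
    if len(cohort) < 10:
        raise ValueError("need at least 10 patients for correlation clustering")
    values = cohort[cols].to_numpy(dtype=float)
    constant = [c for c, v in zip(cols, values.T) if np.ptp(v) == 0]
    if constant:
        warnings.warn(f"constant feature(s) excluded from clustering: {constant}")
        cols = [c for c in cols if c not in constant]
        values = cohort[cols].to_numpy(dtype=float)

    rho = stats.spearmanr(values).statistic
    if np.ndim(rho) == 0:  # spearmanr returns a scalar for 2 columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    corr = pd.DataFrame(rho, index=cols, columns=cols)

    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    # height of the last merge performed when exactly k clusters remain
    cut_height = float(z[-(k - 1), 2]) if k > 1 and len(cols) > k else float(z[-1, 2])
    assignment = ClusterAssignment(
        labels=dict(zip(cols, (int(l) for l in labels))),
        cut_height=cut_height,
        excluded=tuple(constant),
    )
    return corr, assignment


# ---------------------------------------------------------------------------
# horizon ROC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocSummary:
    auc: float
    p_value: float
    cutoff: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int
    n_excluded: int
    degenerate_cutoff: bool = False


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _auc_delong(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """Concordance AUC (ties count 1/2) and its DeLong variance."""
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # structural components (DeLong, Biometrics 1988; fast midrank form)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    return float(auc), float(var)


def roc_horizon(
    cohort: pd.DataFrame, feature: str, endpoint: str, horizon_years: float = 5.0
) -> RocSummary:
    """Horizon-anchored ROC for one feature.

    Positives are patients with the event by the horizon; negatives are
    event-free patients whose follow-up reaches the horizon; patients
    censored before the horizon carry no label and are excluded.  The cutoff
    (test-positive = feature >= cutoff) maximizes sensitivity x specificity
    over midpoints between adjacent observed values, ties broken toward
    higher specificity then lower cutoff.  The AUC p-value (vs 0.5) uses the
    DeLong variance.
    """
    tcol, ecol = _endpoint_cols(endpoint)
    time = cohort[tcol].to_numpy(dtype=float)
    event = cohort[ecol].to_numpy(dtype=int)
    x = cohort[feature].to_numpy(dtype=float)

    is_pos = (event == 1) & (time <= horizon_years)
    is_neg = (event == 0) & (time >= horizon_years)
    excluded = int((~is_pos & ~is_neg).sum())
    pos, neg = x[is_pos], x[is_neg]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateOutcomeError(
            f"degenerate outcome for {feature}/{endpoint}: "
            f"{len(pos)} positives, {len(neg)} negatives"
        )

    auc, var = _auc_delong(pos, neg)
    if var > 0:
        z = (auc - 0.5) / math.sqrt(var)
        p_value = 2.0 * stats.norm.sf(abs(z))
    else:
        p_value = 1.0

    values = np.unique(x[is_pos | is_neg])
    degenerate = len(values) < 2
    if degenerate:
        warnings.warn(f"constant feature {feature}: degenerate ROC cutoff")
        candidates = np.array([values[0]])
    else:
        candidates = (values[:-1] + values[1:]) / 2.0

    sens = (pos[:, None] >= candidates[None, :]).mean(axis=0)
    spec = (neg[:, None] < candidates[None, :]).mean(axis=0)
    product = sens * spec
    # maximize product; ties -> higher specificity, then lower cutoff
    order = np.lexsort((candidates, -spec, -product))
    best = order[0]
    return RocSummary(
        auc=auc,
        p_value=float(p_value),
        cutoff=float(candidates[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        n_pos=int(len(pos)),
        n_neg=int(len(neg)),
        n_excluded=excluded,
        degenerate_cutoff=degenerate,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KmResult:
    groups: dict[str, pd.DataFrame]  # group -> survival step function
    at_risk: dict[str, pd.DataFrame]  # group -> lifelines event table
    group_sizes: dict[str, int]
    chi_square: float
    p_value: float
    threshold: float | None = None  # dichotomization value, when applicable


def _km_by_group(
    cohort: pd.DataFrame, group: pd.Series, endpoint: str
) -> tuple[dict, dict, dict]:
    tcol, ecol = _endpoint_cols(endpoint)
    curves, tables, sizes = {}, {}, {}
    for name, sub in cohort.groupby(group, sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub[tcol], event_observed=sub[ecol], label=str(name))
        curves[str(name)] = kmf.survival_function_
        tables[str(name)] = kmf.event_table
        sizes[str(name)] = len(sub)
    return curves, tables, sizes


def median_split_km(cohort: pd.DataFrame, feature: str, endpoint: str) -> KmResult:
    """Kaplan-Meier curves and log-rank test for high vs low at the median.

    ``high`` is feature >= the cohort median.
    """
    if len(cohort) < 4:
        raise ValueError("need at least 4 patients for a median split")
    tcol, ecol = _endpoint_cols(endpoint)
    med = float(cohort[feature].median())
    high = cohort[feature] >= med
    if high.all() or (~high).all():
        raise DegenerateOutcomeError(f"median split of {feature} produced an empty group")
    res = logrank_test(
        cohort.loc[high, tcol],
        cohort.loc[~high, tcol],
        event_observed_A=cohort.loc[high, ecol],
        event_observed_B=cohort.loc[~high, ecol],
    )
    group = high.map({True: "high", False: "low"})
    curves, tables, sizes = _km_by_group(cohort, group, endpoint)
    return KmResult(
        groups=curves,
        at_risk=tables,
        group_sizes=sizes,
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        threshold=med,
    )


def subgroup_treatment_feature(cohort: pd.DataFrame, feature: str, endpoint: str) -> KmResult:
    """Four-group KM: treatment arm x high/low feature at the overall median.

    Uses the whole-cohort median; the overall (4-group) log-rank statistic is
    reported.  Errors name any empty group.
    """
    arms = sorted(cohort["treatment"].unique())
    if len(arms) < 2:
        raise DegenerateOutcomeError(f"only one treatment arm present: {arms}")
    tcol, ecol = _endpoint_cols(endpoint)
    med = float(cohort[feature].median())
    level = np.where(cohort[feature] >= med, "high", "low")
    group = pd.Series(
        [f"{t}/{l}" for t, l in zip(cohort["treatment"], level)], index=cohort.index
    )
    expected = [f"{t}/{l}" for t in ("ABVD", "BEACOPP") for l in ("low", "high")]
    for name in expected:
        if (group == name).sum() == 0:
            raise DegenerateOutcomeError(f"empty subgroup: {name}")
    res = multivariate_logrank_test(cohort[tcol], group, cohort[ecol])
    curves, tables, sizes = _km_by_group(cohort, group, endpoint)
    return KmResult(
        groups=curves,
        at_risk=tables,
        group_sizes=sizes,
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        threshold=med,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxFit:
    #: one row per variable: hazard_ratio, ci_low, ci_high, p_value
    table: pd.DataFrame
    log_likelihood: float
    n_events: int
    flagged: bool = False  # monotone likelihood / separation suspicion

    @property
    def variables(self) -> list[str]:
        return list(self.table.index)


def _fit_cox(df: pd.DataFrame, tcol: str, ecol: str) -> tuple[CoxFit, CoxPHFitter]:
    if df[ecol].sum() == 0:
        raise DegenerateOutcomeError("no events: Cox model undefined")
    cph = CoxPHFitter()
    flagged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df, duration_col=tcol, event_col=ecol)
        flagged = any("convergence" in str(w.message).lower() for w in caught)
    summary = cph.summary
    if np.any(np.abs(summary["coef"]) > 10):
        flagged = True
    table = pd.DataFrame(
        {
            "hazard_ratio": np.exp(summary["coef"]),
            "ci_low": np.exp(summary["coef lower 95%"]),
            "ci_high": np.exp(summary["coef upper 95%"]),
            "p_value": summary["p"],
        },
        index=summary.index.get_level_values(-1),
    )
    fit = CoxFit(
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        n_events=int(df[ecol].sum()),
        flagged=flagged,
    )
    return fit, cph


def cox_univariate(cohort: pd.DataFrame, variable: str, endpoint: str) -> CoxFit:
    """Single-variable Cox PH fit (partial likelihood; Wald CI and p).

    Continuous features enter per natural unit (per mm, per SUV unit, per
    ml); categorical covariates are coded 0/1 per
    :data:`CATEGORICAL_CODING`.
    """
    tcol, ecol = _endpoint_cols(endpoint)
    df = pd.DataFrame(
        {variable: _design_column(cohort, variable), tcol: cohort[tcol], ecol: cohort[ecol]}
    )
    fit, _ = _fit_cox(df, tcol, ecol)
    return fit


def cox_stepwise(
    cohort: pd.DataFrame,
    variables: list[str],
    endpoint: str,
    retention_p: float = 0.15,
) -> CoxFit:
    """Stepwise-backwards multivariate Cox model.

    Starts from the full model and repeatedly drops the variable with the
    largest Wald p while that p exceeds ``retention_p``; the final model
    keeps only variables with p <= ``retention_p`` (so ``retention_p = 1.0``
    returns the full model unchanged).  May return an empty model if nothing
    is retained.
    """
    if len(variables) < 2:
        raise ValueError("stepwise selection needs at least 2 candidate variables")
    tcol, ecol = _endpoint_cols(endpoint)
    current = list(variables)
    fit = None
    while current:
        df = pd.DataFrame({v: _design_column(cohort, v) for v in current})
        df[tcol] = cohort[tcol].to_numpy()
        df[ecol] = cohort[ecol].to_numpy()
        fit, _ = _fit_cox(df, tcol, ecol)
        worst = fit.table["p_value"].idxmax()
        if fit.table.loc[worst, "p_value"] > retention_p:
            current.remove(worst)
            fit = None
        else:
            return fit
    # nothing retained: empty model
    empty = pd.DataFrame(columns=["hazard_ratio", "ci_low", "ci_high", "p_value"])
    tcol, ecol = _endpoint_cols(endpoint)
    return CoxFit(table=empty, log_likelihood=float("nan"), n_events=int(cohort[ecol].sum()))


# ---------------------------------------------------------------------------
# plain two-sample comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int


def two_sample_t(values_a, values_b) -> TTestResult:
    """Two-sided pooled-variance Student's t test."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df = len(a) + len(b) - 2
    pooled = ((len(a) - 1) * va + (len(b) - 1) * vb) / df
    if pooled == 0:
        raise DegenerateOutcomeError("zero pooled variance: t statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        t=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=len(a),
        n_b=len(b),
    )
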