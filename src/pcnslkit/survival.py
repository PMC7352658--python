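"""Survival modelling and female-vs-male cohort comparison.

Covers the analysis chain applied to the treated, immunocompetent
sub-cohort: Kaplan-Meier curves and log-rank tests, recursive-partitioning
style optimal cutoffs (exhaustive log-rank scan over candidate splits),
a univariable screen at each stratum's own cutoff, multivariable Cox
models with backward elimination, and the descriptive group-comparison
table (t-test / Mann-Whitney U / Fisher's exact by variable type).

Kaplan-Meier and Cox fits delegate to lifelines; the cutoff scan uses an
internal vectorized two-group log-rank statistic for speed (cross-checked
against lifelines in the test suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "CutoffResult",
    "CoxTerm",
    "CoxResult",
    "filter_survival_cohort",
    "km_fit",
    "logrank_test",
    "logrank_chi2_two_group",
    "optimal_cutoff",
    "univariable_screen",
    "cox_backward",
    "cohort_compare",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    ``median_os_months`` is the earliest time at which S(t) <= 0.5; NaN
    (with ``median_defined`` False) when the curve never crosses 0.5,
    e.g. a subgroup whose median OS is not reached.
    """

    event_times: np.ndarray
    survival_probabilities: np.ndarray
    n_at_risk: np.ndarray
    median_os_months: float

    @property
    def median_defined(self) -> bool:
        return np.isfinite(self.median_os_months)


@dataclass(frozen=True)
class CutoffResult:
    variable: str
    cutoff_value: float
    logrank_statistic: float
    n_low: int
    n_high: int


@dataclass(frozen=True)
class CoxTerm:
    variable: str
    coding: str  # "dichotomized_at_cutoff" or "continuous_per_unit"
    hr: float
    ci95_low: float
    ci95_high: float
    p: float


@dataclass(frozen=True)
class CoxResult:
    terms: list[CoxTerm]
    eliminated: list[str] = field(default_factory=list)

    def term(self, variable: str) -> CoxTerm:
        for t in self.terms:
            if t.variable == variable:
                return t
        raise KeyError(variable)


def filter_survival_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Homogeneous analysis cohort: intact immune status + first-line chemo.

    Rows with a missing immune or chemo flag are excluded with a warning;
    an empty result is an error.
    """
    for col in ("immune_deficient", "chemo"):
        if col not in table.columns:
            raise ValueError(f"missing required column: {col}")
    flags = table[["immune_deficient", "chemo"]]
    incomplete = flags.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(f"excluding {int(incomplete.sum())} rows with missing immune/chemo flags")
    keep = (
        ~incomplete
        & (table["immune_deficient"].astype("boolean") == False)  # noqa: E712
        & (table["chemo"].astype("boolean") == True)  # noqa: E712
    )
    out = table[keep.fillna(False)]
    if out.empty:
        raise ValueError("survival cohort empty after filtering")
    return out


def km_fit(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator (lifelines backend)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    timeline = kmf.survival_function_.index.to_numpy()
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()
    at_risk = kmf.event_table["at_risk"].reindex(timeline).to_numpy()
    median = float(kmf.median_survival_time_)
    if not np.isfinite(median):
        median = float("nan")
    if not events.any():
        warnings.warn("no events: survival curve is flat, median undefined")
    return SurvivalCurve(
        event_times=timeline,
        survival_probabilities=surv,
        n_at_risk=at_risk,
        median_os_months=median,
    )


def logrank_test(groups: list[tuple[np.ndarray, np.ndarray]]) -> tuple[float, float]:
    """Log-rank test across >= 2 groups of (times, events).

    Returns (chi2, p) against a chi-square with (#groups - 1) df.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    times, events, labels = [], [], []
    for gi, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if len(t) == 0:
            raise ValueError(f"group {gi} has no subjects")
        times.append(t)
        events.append(e)
        labels.append(np.full(len(t), gi))
    events_all = np.concatenate(events)
    if not events_all.any():
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), events_all
    )
    return float(res.test_statistic), float(res.p_value)


def logrank_chi2_two_group(times, events, in_high) -> float:
    """Vectorized two-group log-rank chi-square statistic.

    Standard Mantel-Haenszel form: at each distinct event time, observed
    minus expected events in the high group over the hypergeometric
    variance.  Used by the exhaustive cutoff scan; equals the lifelines
    statistic (tested).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    in_high = np.asarray(in_high, dtype=bool)
    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], in_high[order]
    n = len(t)
    uniq, start = np.unique(t, return_index=True)
    # subjects at risk just before each distinct time
    n_at = n - start
    cum_high = np.concatenate([[0], np.cumsum(g)])
    n_high_at = g.sum() - cum_high[start]
    d_tot = np.add.reduceat(e.astype(float), start)
    d_high = np.add.reduceat((e & g).astype(float), start)
    keep = d_tot > 0
    n_at, n_high_at, d_tot, d_high = n_at[keep], n_high_at[keep], d_tot[keep], d_high[keep]
    frac = n_high_at / n_at
    expected = d_tot * frac
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d_tot * frac * (1 - frac) * (n_at - d_tot) / np.where(n_at > 1, n_at - 1, 1)
    o_minus_e = float((d_high - expected).sum())
    v = float(var.sum())
    return o_minus_e**2 / v if v > 0 else 0.0


def optimal_cutoff(
    values, times, events, min_leaf: int = 7, variable: str = ""
) -> CutoffResult | None:
    """Best dichotomizing cutoff by exhaustive log-rank scan (rpart-style).

    Candidates are midpoints between consecutive sorted unique values;
    splits leaving fewer than ``min_leaf`` subjects on either side are
    inadmissible.  The split maximizing the log-rank statistic wins, first
    attained value on ties (scanning ascending).  Returns None (flagged)
    when no admissible split exists — e.g. a constant variable.

    Note: the resulting statistic is maximally selected, hence inflated
    relative to a prespecified split; no nominal p is attached here.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    uniq = np.unique(values[np.isfinite(values)])
    best: CutoffResult | None = None
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = (lo + hi) / 2.0
        high = values > cut
        n_high = int(high.sum())
        n_low = len(values) - n_high
        if n_low < min_leaf or n_high < min_leaf:
            continue
        chi2 = logrank_chi2_two_group(times, events, high)
        if best is None or chi2 > best.logrank_statistic:
            best = CutoffResult(
                variable=variable,
                cutoff_value=float(cut),
                logrank_statistic=float(chi2),
                n_low=n_low,
                n_high=n_high,
            )
    return best


def univariable_screen(
    table: pd.DataFrame,
    variables: list[str],
    alpha: float = 0.1,
    min_leaf: int = 7,
    duration_col: str = "os_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Screen variables by log-rank at each stratum's own optimal cutoff.

    For every variable and every stratum (female, male, all) the optimal
    cutoff is found and the log-rank p at that cutoff recorded; a variable
    is selected when p < alpha in ANY stratum.  The maximally-selected
    inflation of these p-values is a documented property of the screen,
    not corrected here.
    """
    rows = []
    strata = {"female": table[table["sex"] == "female"],
              "male": table[table["sex"] == "male"],
              "all": table}
    for var in variables:
        for stratum, sub in strata.items():
            sub = sub.dropna(subset=[var, duration_col, event_col])
            t = sub[duration_col].to_numpy(dtype=float)
            e = sub[event_col].to_numpy(dtype=bool)
            cut = optimal_cutoff(sub[var], t, e, min_leaf=min_leaf, variable=var)
            if cut is None:
                rows.append({"variable": var, "stratum": stratum, "cutoff": np.nan,
                             "chi2": np.nan, "p": np.nan})
                continue
            p = float(stats.chi2.sf(cut.logrank_statistic, df=1))
            rows.append({"variable": var, "stratum": stratum, "cutoff": cut.cutoff_value,
                         "chi2": cut.logrank_statistic, "p": p})
    out = pd.DataFrame(rows, columns=["variable", "stratum", "cutoff", "chi2", "p"])
    if out.empty:
        out["selected"] = pd.Series(dtype=bool)
        return out
    selected = out.groupby("variable")["p"].min() < alpha
    out["selected"] = out["variable"].map(selected)
    return out


def cox_backward(
    table: pd.DataFrame,
    variables: list[str],
    retention_alpha: float = 0.1,
    coding_map: dict[str, tuple[str, float | None]] | None = None,
    duration_col: str = "os_months",
    event_col: str = "event",
) -> CoxResult:
    """Backward-eliminated Cox proportional-hazards model (Efron ties).

    ``coding_map`` maps a variable to ("dichotomized_at_cutoff", cutoff)
    — entered as an indicator variable > cutoff — or to
    ("continuous_per_unit", None).  Starting from all variables, the term
    with the highest Wald p is dropped while that p >= retention_alpha;
    the elimination order is recorded.  Hazard ratios are exp(coef) with
    Wald 95% CIs.
    """
    coding_map = coding_map or {}
    design = pd.DataFrame(index=table.index)
    codings: dict[str, str] = {}
    for var in variables:
        coding, cutoff = coding_map.get(var, ("continuous_per_unit", None))
        if coding == "dichotomized_at_cutoff":
            design[var] = (table[var].astype(float) > float(cutoff)).astype(float)
        elif coding == "continuous_per_unit":
            design[var] = table[var].astype(float)
        else:
            raise ValueError(f"unknown coding {coding!r} for {var}")
        codings[var] = coding
    design[duration_col] = table[duration_col].astype(float)
    design[event_col] = table[event_col].astype(bool)
    design = design.dropna()
    n_events = int(design[event_col].sum())
    current = list(variables)
    eliminated: list[str] = []
    fitter = None
    while current:
        if n_events < 5 * len(current):
            warnings.warn(
                f"{n_events} events for {len(current)} terms (< 5 per term): "
                "estimates may be unstable"
            )
        fitter = CoxPHFitter()
        fitter.fit(
            design[current + [duration_col, event_col]],
            duration_col=duration_col,
            event_col=event_col,
        )
        pvals = fitter.summary["p"]
        worst = pvals.idxmax()
        if pvals[worst] >= retention_alpha:
            eliminated.append(str(worst))
            current.remove(worst)
        else:
            break
    terms: list[CoxTerm] = []
    if current and fitter is not None:
        s = fitter.summary
        for var in current:
            terms.append(
                CoxTerm(
                    variable=var,
                    coding=codings[var],
                    hr=float(s.loc[var, "exp(coef)"]),
                    ci95_low=float(s.loc[var, "exp(coef) lower 95%"]),
                    ci95_high=float(s.loc[var, "exp(coef) upper 95%"]),
                    p=float(s.loc[var, "p"]),
                )
            )
    return CoxResult(terms=terms, eliminated=eliminated)


def _fmt_numeric(x: pd.Series) -> str:
    return f"{x.mean():.1f} ± {x.std(ddof=1):.1f}"


def _fmt_ordinal(x: pd.Series) -> str:
    q1, q3 = x.quantile([0.25, 0.75])
    return f"{x.median():g} (IQR {q1:g}–{q3:g})"


def _fmt_nominal(x: pd.Series) -> str:
    n = int(x.sum())
    return f"{n} ({100.0 * n / len(x):.1f}%)"


def cohort_compare(
    table: pd.DataFrame,
    column_types: dict[str, str],
    group_col: str = "sex",
    groups: tuple[str, str] = ("female", "male"),
    equal_var: bool = True,
) -> pd.DataFrame:
    """Female-vs-male comparison table with type-appropriate tests.

    Numerical variables: two-sample t-test, descriptives mean ± SD.
    Ordinal: Mann-Whitney U (normal approximation with tie correction for
    n > 20, exact otherwise), descriptives median (IQR).  Nominal
    (boolean): two-sided Fisher's exact on the 2x2 count table,
    descriptives n (%).
    """
    a = table[table[group_col] == groups[0]]
    b = table[table[group_col] == groups[1]]
    if a.empty or b.empty:
        raise ValueError("both comparison groups must be non-empty")
    rows = []
    for var, kind in column_types.items():
        xa, xb = a[var].dropna(), b[var].dropna()
        if kind == "numerical":
            _, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
            da, db = _fmt_numeric(xa), _fmt_numeric(xb)
        elif kind == "ordinal":
            method = "asymptotic" if min(len(xa), len(xb)) > 20 else "exact"
            try:
                _, p = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
            except ValueError:  # exact method with ties falls back
                _, p = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
            da, db = _fmt_ordinal(xa), _fmt_ordinal(xb)
        elif kind == "nominal":
            ya, yb = xa.astype(bool), xb.astype(bool)
            tab = [[int(ya.sum()), int((~ya).sum())], [int(yb.sum()), int((~yb).sum())]]
            _, p = stats.fisher_exact(tab, alternative="two-sided")
            da, db = _fmt_nominal(ya), _fmt_nominal(yb)
        else:
            raise ValueError(f"unknown column type {kind!r} for {var}")
        rows.append({"variable": var, "type": kind, groups[0]: da, groups[1]: db,
                     "p": float(p)})
    return pd.DataFrame(rows)
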