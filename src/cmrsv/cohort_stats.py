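"""Outcome statistics for the CRT cohort analysis.

Response (reverse remodeling) is a >= 15% reduction in echocardiographic LV
end-systolic volume from baseline to 6-month follow-up.  Group comparisons
use unpaired Student t-tests (equal variances) for continuous variables and
Pearson chi-squared (uncorrected) or Fisher's exact test (any expected cell
below 5) for categorical ones; paired baseline/follow-up data use paired
t-tests.  Odds ratios carry Woolf (log-normal Wald) 95% confidence
intervals with a Haldane-Anscombe 0.5 correction for zero cells.  Candidate
predictors are screened with univariable logistic regression; those with
p < 0.25 enter a joint multivariable fit, and predictors with p < 0.05 are
retained.  Post-hoc sample sizes for a two-sided two-sample t-test are
computed by iterating the noncentral-t power equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .geometry_core import InputError

__all__ = [
    "RESPONSE_THRESHOLD_PCT",
    "ContingencyTable2x2",
    "OddsRatioResult",
    "GroupCompareResult",
    "LogisticResult",
    "SampleSizeResult",
    "classify_responder",
    "add_outcome_columns",
    "build_table2x2",
    "odds_ratio",
    "group_compare",
    "logistic_screen",
    "sample_size_t",
]

#: Reverse-remodeling threshold: response is a reduction of LVESV by at
#: least this many percent (boundary inclusive).
RESPONSE_THRESHOLD_PCT = 15.0

#: Univariable p-value below which a candidate enters the multivariable fit.
SCREENING_ALPHA = 0.25

#: Multivariable p-value below which a predictor is retained.
RETENTION_ALPHA = 0.05


def classify_responder(baseline_ml: float, followup_ml: float) -> tuple[float, bool]:
    """LVESV change in percent (signed; negative = reduction) and responder
    flag (change <= -15%, boundary inclusive)."""
    if not baseline_ml > 0:
        raise InputError(f"baseline LVESV must be positive, got {baseline_ml}")
    delta_pct = 100.0 * (followup_ml - baseline_ml) / baseline_ml
    return delta_pct, delta_pct <= -RESPONSE_THRESHOLD_PCT


def add_outcome_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append ``delta_lvesv_pct``, ``responder`` and ``neg_sept`` columns.

    ``neg_sept`` flags a strictly negative septal contribution (a septal
    contribution of exactly 0% counts as positive).
    """
    out = cohort.copy()
    deltas, flags = zip(
        *(
            classify_responder(b, f)
            for b, f in zip(out["lvesv_base_ml"], out["lvesv_fu_ml"])
        )
    ) if len(out) else ((), ())
    out["delta_lvesv_pct"] = list(deltas)
    out["responder"] = [float(f) for f in flags]
    if "sv_sept_pct" in out:
        out["neg_sept"] = (out["sv_sept_pct"] < 0).astype(float)
    return out


@dataclass
class ContingencyTable2x2:
    """Counts: a = exposed with event, b = exposed without, c = unexposed
    with event, d = unexposed without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise InputError(f"cell {name} must be a non-negative integer, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    def swapped_exposure(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


def _predicate_column(cohort: pd.DataFrame, spec) -> pd.Series:
    if callable(spec):
        return pd.Series(spec(cohort), index=cohort.index)
    return cohort[spec]


def build_table2x2(cohort: pd.DataFrame, exposure, outcome) -> tuple[ContingencyTable2x2, int]:
    """2x2 table of an exposure against an outcome.

    ``exposure`` and ``outcome`` are either column names holding 0/1 (NaN =
    missing) or callables mapping the cohort frame to a boolean series.
    Records with a missing value in either are dropped; the second return
    value counts them.
    """
    if len(cohort) == 0:
        raise InputError("empty cohort")
    e = _predicate_column(cohort, exposure).astype(float)
    o = _predicate_column(cohort, outcome).astype(float)
    keep = e.notna() & o.notna()
    dropped = int((~keep).sum())
    e, o = e[keep].astype(bool), o[keep].astype(bool)
    return (
        ContingencyTable2x2(
            a=int((e & o).sum()),
            b=int((e & ~o).sum()),
            c=int((~e & o).sum()),
            d=int((~e & ~o).sum()),
        ),
        dropped,
    )


@dataclass
class OddsRatioResult:
    oddsratio: float
    ci_low: float
    ci_high: float
    zero_cell_corrected: bool = False


_Z95 = 1.959963984540054  # two-sided 95% normal quantile


def odds_ratio(table: ContingencyTable2x2) -> OddsRatioResult:
    """Odds ratio ad/(bc) with the Woolf 95% confidence interval
    exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)).

    A zero cell triggers the Haldane-Anscombe correction (0.5 added to every
    cell), flagged in the result.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_)
    return OddsRatioResult(
        oddsratio=or_,
        ci_low=float(np.exp(log_or - _Z95 * se)),
        ci_high=float(np.exp(log_or + _Z95 * se)),
        zero_cell_corrected=corrected,
    )


@dataclass
class GroupCompareResult:
    test: str  # "t" | "paired-t" | "chi2" | "fisher"
    statistic: float
    p_value: float
    table: ContingencyTable2x2 | None = None
    n_dropped: int = 0
    flags: list[str] = field(default_factory=list)


def group_compare(
    cohort: pd.DataFrame,
    variable,
    grouping,
    kind: str = "auto",
    paired_with: str | None = None,
) -> GroupCompareResult:
    """Compare a variable between the two levels of a binary grouping.

    Continuous variables use the unpaired two-sided Student t-test (equal
    variances); categorical (0/1) variables use Pearson's chi-squared
    without continuity correction, falling back to Fisher's exact test when
    any expected cell count is below 5.  ``paired_with`` names a second
    column for a paired t-test (e.g. baseline vs follow-up), in which case
    ``grouping`` is ignored.
    """
    if paired_with is not None:
        x = cohort[variable].astype(float)
        y = cohort[paired_with].astype(float)
        keep = x.notna() & y.notna()
        res = stats.ttest_rel(x[keep], y[keep])
        return GroupCompareResult("paired-t", float(res.statistic), float(res.pvalue),
                                  n_dropped=int((~keep).sum()))
    values = _predicate_column(cohort, variable).astype(float)
    groups = _predicate_column(cohort, grouping).astype(float)
    keep = values.notna() & groups.notna()
    dropped = int((~keep).sum())
    values, groups = values[keep], groups[keep].astype(bool)
    if kind == "auto":
        kind = "categorical" if set(values.unique()) <= {0.0, 1.0} else "continuous"
    if kind == "continuous":
        x, y = values[groups], values[~groups]
        if len(x) < 2 or len(y) < 2:
            raise InputError("need at least 2 observations per group for a t-test")
        flags = []
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            flags.append("zero variance in both groups: test undefined")
            return GroupCompareResult("t", float("nan"), float("nan"),
                                      n_dropped=dropped, flags=flags)
        res = stats.ttest_ind(x, y, equal_var=True)
        return GroupCompareResult("t", float(res.statistic), float(res.pvalue),
                                  n_dropped=dropped)
    table, _ = build_table2x2(
        cohort.loc[keep.index[keep]], variable, grouping
    )
    arr = table.as_array()
    expected = stats.contingency.expected_freq(arr)
    if (expected < 5).any():
        res = stats.fisher_exact(arr)
        return GroupCompareResult("fisher", float(res[0]), float(res[1]),
                                  table=table, n_dropped=dropped)
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return GroupCompareResult("chi2", float(chi2), float(p),
                              table=table, n_dropped=dropped)


@dataclass
class LogisticResult:
    """Univariable screening plus multivariable logistic fit.

    ``univariable`` has one row per candidate (odds ratio, Wald 95% CI,
    p-value, convergence/separation flags); ``multivariable`` covers the
    candidates passing the p < 0.25 screen (empty when none pass, flagged).
    ``retained`` lists multivariable predictors with p < 0.05.
    """

    univariable: pd.DataFrame
    multivariable: pd.DataFrame
    included: list[str]
    retained: list[str]
    flags: list[str] = field(default_factory=list)


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> tuple:
    """Newton-fitted logistic regression; returns (result, converged flag,
    separation flag)."""
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    separated = False
    try:
        with np.errstate(all="ignore"):
            res = model.fit(disp=0, maxiter=100, tol=1e-10)
        converged = bool(res.mle_retvals.get("converged", False))
        # detect quasi-separation: diverging coefficient magnitude
        if np.any(np.abs(res.params.iloc[1:]) > 15):
            separated = True
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return None, False, True
    return res, converged, separated


def logistic_screen(
    cohort: pd.DataFrame,
    outcome,
    candidates: Sequence[str],
) -> LogisticResult:
    """Univariable screening followed by a multivariable logistic model.

    Each candidate is fitted alone against the binary outcome; candidates
    with Wald p < 0.25 enter the joint fit.  Rows with missing values are
    dropped per model.  Odds ratios are per unit of the predictor.
    """
    y_all = _predicate_column(cohort, outcome).astype(float)
    if set(y_all.dropna().unique()) - {0.0, 1.0}:
        raise InputError("outcome must be binary (0/1)")
    if y_all.dropna().nunique() < 2:
        raise InputError("outcome must have both classes present")
    flags: list[str] = []
    uni_rows = []
    for name in candidates:
        x = cohort[name].astype(float)
        keep = x.notna() & y_all.notna()
        res, converged, separated = _fit_logit(
            y_all[keep].to_numpy(), x[keep].to_frame(name)
        )
        if res is None or separated:
            uni_rows.append(
                dict(predictor=name, oddsratio=np.inf, ci_low=np.nan,
                     ci_high=np.nan, p=np.nan, converged=False, separated=True)
            )
            flags.append(f"{name}: separation detected in univariable fit")
            continue
        beta = res.params[name]
        se = res.bse[name]
        uni_rows.append(
            dict(
                predictor=name,
                oddsratio=float(np.exp(beta)),
                ci_low=float(np.exp(beta - _Z95 * se)),
                ci_high=float(np.exp(beta + _Z95 * se)),
                p=float(res.pvalues[name]),
                converged=converged,
                separated=False,
            )
        )
    univariable = pd.DataFrame(uni_rows).set_index("predictor")
    included = [
        str(name)
        for name, row in univariable.iterrows()
        if np.isfinite(row["p"]) and row["p"] < SCREENING_ALPHA
    ]
    multi_cols = ["oddsratio", "ci_low", "ci_high", "p", "converged", "separated"]
    if not included:
        flags.append("no candidate passed the p < 0.25 screen: multivariable table empty")
        multivariable = pd.DataFrame(columns=multi_cols)
        retained: list[str] = []
    else:
        X = cohort[included].astype(float)
        keep = X.notna().all(axis=1) & y_all.notna()
        res, converged, separated = _fit_logit(y_all[keep].to_numpy(), X[keep])
        rows = []
        if res is None:
            flags.append("multivariable fit failed (separation)")
            multivariable = pd.DataFrame(columns=multi_cols)
            retained = []
        else:
            if separated:
                flags.append("separation suspected in multivariable fit")
            for name in included:
                beta = res.params[name]
                se = res.bse[name]
                rows.append(
                    dict(
                        predictor=name,
                        oddsratio=float(np.exp(beta)),
                        ci_low=float(np.exp(beta - _Z95 * se)),
                        ci_high=float(np.exp(beta + _Z95 * se)),
                        p=float(res.pvalues[name]),
                        converged=converged,
                        separated=separated,
                    )
                )
            multivariable = pd.DataFrame(rows).set_index("predictor")
            retained = [
                str(name)
                for name, row in multivariable.iterrows()
                if np.isfinite(row["p"]) and row["p"] < RETENTION_ALPHA
            ]
    return LogisticResult(
        univariable=univariable,
        multivariable=multivariable,
        included=included,
        retained=retained,
        flags=flags,
    )


@dataclass
class SampleSizeResult:
    """Required size of the experimental group for a two-sided two-sample
    t-test; the control group has ``ratio`` times as many subjects."""

    n: int
    ratio: float
    delta: float
    sd: float
    alpha: float
    power: float
    achieved_power: float


def _t_power(n1: float, n2: float, delta: float, sd: float, alpha: float) -> float:
    df = n1 + n2 - 2.0
    if df < 1:
        return 0.0
    ncp = abs(delta) / (sd * np.sqrt(1.0 / n1 + 1.0 / n2))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        1.0 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    )


def sample_size_t(
    delta: float,
    sd: float,
    ratio: float = 1.0,
    alpha: float = 0.05,
    power: float = 0.8,
    n_max: int = 1_000_000,
) -> SampleSizeResult:
    """Smallest experimental-group size reaching the target power.

    The test is a two-sided two-sample Student t-test for a true mean
    difference ``delta`` with common SD ``sd``; the control group holds
    ``ratio * n`` subjects.  Power is evaluated exactly from the noncentral
    t distribution and ``n`` is increased until it meets the target.
    """
    if delta == 0:
        raise InputError("delta must be non-zero")
    if sd <= 0 or ratio <= 0:
        raise InputError("sd and ratio must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise InputError("alpha and power must be in (0, 1)")
    n = 2
    while n <= n_max:
        achieved = _t_power(n, ratio * n, delta, sd, alpha)
        if achieved >= power and n + ratio * n - 2 >= 1:
            return SampleSizeResult(
                n=n, ratio=ratio, delta=delta, sd=sd, alpha=alpha,
                power=power, achieved_power=achieved,
            )
        n += 1
    raise InputError(f"required n exceeds {n_max}")
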