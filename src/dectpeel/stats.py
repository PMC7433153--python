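"""Cohort-level statistics for MVI prediction.

Implements the statistical battery applied to the per-patient feature
table: two-group comparison (Mann-Whitney, chi-square), ROC analysis with
DeLong confidence intervals and paired AUC comparison, Youden-optimal
cutoffs, Woolf odds ratios, univariate/multivariate logistic regression
with a multicollinearity guard among NIC features, and reader-reliability
metrics (ICC, Cohen kappa) with the conventional agreement categories
(<0.4 poor, 0.4-0.6 moderate, 0.6-0.8 good, >0.8 excellent).

No multiple-testing correction is applied; raw p-values are reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score, roc_curve

from .errors import (
    DegenerateDataError,
    DegenerateTableError,
    UndefinedOddsRatioError,
    ValidationError,
)

logger = logging.getLogger(__name__)

_Z95 = float(sps.norm.ppf(0.975))


# ---------------------------------------------------------------- group tests

def mann_whitney(group_a, group_b):
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when ``n_a * n_b <= 400`` and there are no ties,
    otherwise the tie-corrected normal approximation. Returns ``(U, p)``
    with U counted for the first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if np.isnan(p):  # zero tie-corrected variance: every value identical
        p = 1.0
    return float(res.statistic), min(p, 1.0)


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 counts. Layout: rows = outcome (case, control), columns =
    (exposed, unexposed): ``a`` exposed cases, ``b`` unexposed cases,
    ``c`` exposed controls, ``d`` unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValidationError("counts must be non-negative integers")

    @property
    def table(self):
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def n(self):
        return self.a + self.b + self.c + self.d


def chi_square_2x2(t: TwoByTwo, correction: bool = False):
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction
    by default. Returns ``(statistic, p)``."""
    tab = t.table
    if t.n == 0:
        raise DegenerateTableError("empty table")
    expected = sps.contingency.expected_freq(tab)
    if (expected == 0).any():
        raise DegenerateTableError("a zero expected count makes the test undefined")
    stat, p, _, _ = sps.chi2_contingency(tab, correction=correction)
    return float(stat), float(p)


def odds_ratio(t: TwoByTwo):
    """Cross-product odds ratio with a Woolf 95% CI.

    ``OR = (a*d)/(b*c)``; CI = ``exp(ln OR +/- 1.96*sqrt(1/a+1/b+1/c+1/d))``.
    When any cell is zero the Haldane-Anscombe +0.5 correction is applied
    to every cell; two zero cells in a cross pattern leave the OR
    undefined. Returns ``(or, ci_low, ci_high)``.
    """
    a, b, c, d = (float(v) for v in (t.a, t.b, t.c, t.d))
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        raise UndefinedOddsRatioError("two zero cells in a cross pattern")
    if 0.0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oratio = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(oratio) - _Z95 * se))
    hi = float(np.exp(np.log(oratio) + _Z95 * se))
    return float(oratio), lo, hi


# ----------------------------------------------------------------- ROC / AUC

@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int

    def to_dict(self):
        return asdict(self)


def _clean_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(scores)
    scores, labels = scores[keep], labels[keep]
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1} or len(uniq) < 2:
        raise ValidationError("labels must contain both classes 0 and 1")
    return scores, labels.astype(int)


def _delong(score_list, labels):
    """DeLong AUC estimates and their covariance matrix.

    ``score_list`` holds k score vectors measured on the same subjects.
    Returns ``(aucs, cov)`` where ``cov`` is the k x k covariance of the
    AUC estimates (Sun & Xu fast DeLong via midranks).
    """
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    neg = labels == 0
    m, n = int(pos.sum()), int(neg.sum())
    k = len(score_list)
    aucs = np.empty(k)
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    for i, sc in enumerate(score_list):
        sc = np.asarray(sc, dtype=float)
        x, y = sc[pos], sc[neg]
        tx = sps.rankdata(x)
        ty = sps.rankdata(y)
        tz = sps.rankdata(np.concatenate([x, y]))
        aucs[i] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v10[i] = (tz[:m] - tx) / n
        v01[i] = 1.0 - (tz[m:] - ty) / m
    s10 = np.atleast_2d(np.cov(v10, ddof=1)) if m > 1 else np.zeros((k, k))
    s01 = np.atleast_2d(np.cov(v01, ddof=1)) if n > 1 else np.zeros((k, k))
    return aucs, s10 / m + s01 / n


def roc_auc(scores, labels) -> RocResult:
    """ROC analysis of one score: AUC (tie half-credit, identical to the
    normalized Mann-Whitney U), DeLong 95% CI, and the Youden-optimal
    cutoff with its sensitivity/specificity.

    The cutoff maximizes J = sensitivity + specificity - 1; ties are broken
    toward higher specificity. A case is called positive when
    ``score >= cutoff``. Missing scores are dropped pairwise.
    """
    scores, labels = _clean_scores(scores, labels)
    aucs, cov = _delong([scores], labels)
    auc = float(aucs[0])
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    ci_low = max(0.0, auc - _Z95 * se)
    ci_high = min(1.0, auc + _Z95 * se)

    fpr, tpr, thresholds = roc_curve(labels, scores)
    j = tpr - fpr
    # lexicographic: max J, then min fpr (higher specificity), then higher cutoff
    order = np.lexsort((-thresholds, fpr, -j))
    best = order[0]
    return RocResult(
        auc=auc, ci_low=ci_low, ci_high=ci_high,
        cutoff=float(thresholds[best]),
        sensitivity=float(tpr[best]), specificity=float(1.0 - fpr[best]),
        n_pos=int((labels == 1).sum()), n_neg=int((labels == 0).sum()),
    )


def compare_auc(scores_a, scores_b, labels):
    """DeLong paired test for the difference between two correlated AUCs.

    Returns ``(delta_auc, p)`` with ``delta = auc_a - auc_b``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValidationError("paired scores and labels must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, labels_k = a[keep], labels[keep]
    b = b[keep]
    _, labels_k = _clean_scores(a, labels_k)
    aucs, cov = _delong([a, b], labels_k)
    delta = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    if var <= 0:
        return delta, 1.0 if abs(delta) < 1e-12 else 0.0
    z = delta / np.sqrt(var)
    return delta, float(2.0 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------- regression

@dataclass
class LogisticFit:
    variables: list
    coefficients: dict
    std_errors: dict
    odds_ratios: dict
    ci_low: dict
    ci_high: dict
    p_values: dict
    converged: bool
    n: int
    dropped_collinear: list = field(default_factory=list)

    def to_dict(self):
        return asdict(self)


def logistic_fit(
    table: pd.DataFrame,
    outcome: str,
    predictors,
    dichotomize: dict | None = None,
    nic_prefix: str = "nic_",
    guard_collinear: bool = True,
) -> LogisticFit:
    """Binary logistic regression (maximum likelihood, Wald intervals).

    Continuous predictors listed in ``dichotomize`` are converted to 0/1 at
    the supplied cutoff (``value > cutoff``) before fitting. When several
    predictors share the NIC prefix, only the one with the highest AUC is
    admitted (multicollinearity guard: the layer NICs are nested measures
    of the same enhancement signal). Separation is reported via
    ``converged=False`` with a warning rather than an exception.
    """
    import statsmodels.api as sm

    predictors = list(predictors)
    if not predictors:
        raise ValidationError("no predictors supplied")
    missing_cols = [c for c in [outcome, *predictors] if c not in table.columns]
    if missing_cols:
        raise ValidationError(f"columns not in table: {missing_cols}")
    dichotomize = dichotomize or {}

    df = table[[outcome, *predictors]].dropna().copy()
    y = df[outcome].astype(int)
    if set(y.unique()) != {0, 1}:
        raise ValidationError("outcome must contain both classes 0 and 1")

    dropped = []
    if guard_collinear:
        nic_vars = [p for p in predictors if p.startswith(nic_prefix)]
        if len(nic_vars) > 1:
            aucs = {p: roc_auc(df[p], y).auc for p in nic_vars}
            best = max(sorted(aucs), key=lambda p: aucs[p])
            dropped = [p for p in nic_vars if p != best]
            predictors = [p for p in predictors if p not in dropped]

    X = pd.DataFrame(index=df.index)
    for p in predictors:
        X[p] = ((df[p] > dichotomize[p]).astype(float) if p in dichotomize
                else df[p].astype(float))
    X = sm.add_constant(X, has_constant="add")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            # Newton fails on separated data (singular Hessian); BFGS still
            # yields a usable (diverging) estimate to report with a flag
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200, method="bfgs")
    converged = bool(fit.mle_retvals.get("converged", False))
    if (np.abs(fit.params.drop("const")).max() > 15
            or not np.isfinite(fit.bse.drop("const")).all()):
        converged = False
    if not converged:
        warnings.warn("logistic fit did not converge (possible separation)",
                      stacklevel=2)

    coefs = fit.params.drop("const")
    ses = fit.bse.drop("const")
    return LogisticFit(
        variables=predictors,
        coefficients={p: float(coefs[p]) for p in predictors},
        std_errors={p: float(ses[p]) for p in predictors},
        odds_ratios={p: float(np.exp(coefs[p])) for p in predictors},
        ci_low={p: float(np.exp(coefs[p] - _Z95 * ses[p])) for p in predictors},
        ci_high={p: float(np.exp(coefs[p] + _Z95 * ses[p])) for p in predictors},
        p_values={p: float(fit.pvalues[p]) for p in predictors},
        converged=converged,
        n=int(len(df)),
        dropped_collinear=dropped,
    )


# --------------------------------------------------------------- reliability

def agreement_category(value: float) -> str:
    """Conventional reliability bands for ICC and kappa."""
    if value > 0.8:
        return "excellent"
    if value > 0.6:
        return "good"
    if value >= 0.4:
        return "moderate"
    return "poor"


def icc(ratings_a, ratings_b):
    """Two-way mixed-effects, absolute-agreement, single-measurement ICC.

    Computed from the two-way ANOVA decomposition (McGraw & Wong A-1 form,
    numerically identical to the two-way random absolute-agreement single
    ICC). Returns ``(icc, category)``.
    """
    import pingouin as pg

    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("ratings must be paired 1-D arrays")
    if a.size < 3:
        raise ValidationError("need at least 3 paired observations")
    allv = np.concatenate([a, b])
    if np.var(allv) == 0:
        raise DegenerateDataError("zero total variance; ICC undefined")
    long = pd.DataFrame({
        "targets": np.tile(np.arange(a.size), 2),
        "raters": np.repeat(["A", "B"], a.size),
        "ratings": allv,
    })
    res = pg.intraclass_corr(long, targets="targets", raters="raters",
                             ratings="ratings")
    typed = res.set_index("Type")["ICC"]
    for label in ("ICC(A,1)", "ICC2"):  # pingouin renamed the row across versions
        if label in typed.index:
            value = float(typed[label])
            break
    else:  # pragma: no cover - unexpected pingouin output
        raise DegenerateDataError("absolute-agreement single-measure ICC not returned")
    return value, agreement_category(value)


def cohen_kappa(ratings_a, ratings_b):
    """Cohen's kappa for two categorical raters; returns ``(kappa, category)``."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("ratings must be paired 1-D arrays")
    if (a == b).all():
        return 1.0, agreement_category(1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        value = cohen_kappa_score(a, b)
    if np.isnan(value):
        raise DegenerateDataError("chance agreement is 1; kappa undefined")
    return float(value), agreement_category(float(value))


# -------------------------------------------------------------------- report

@dataclass
class CohortReport:
    group_comparison: pd.DataFrame  # mean +/- SD per group, Mann-Whitney p
    roc: pd.DataFrame               # per-feature RocResult
    univariate: pd.DataFrame        # dichotomized univariate logistic ORs
    multivariate: LogisticFit | None
    screened_in: list
    excluded_features: list
    screen_alpha: float

    def to_dict(self):
        return {
            "group_comparison": self.group_comparison.to_dict(orient="records"),
            "roc": self.roc.to_dict(orient="records"),
            "univariate": self.univariate.to_dict(orient="records"),
            "multivariate": None if self.multivariate is None
            else self.multivariate.to_dict(),
            "screened_in": self.screened_in,
            "excluded_features": self.excluded_features,
            "screen_alpha": self.screen_alpha,
        }


def _is_binary(series: pd.Series) -> bool:
    vals = set(series.dropna().unique().tolist())
    return vals <= {0, 1, 0.0, 1.0}


def cohort_report(
    table: pd.DataFrame,
    outcome: str = "mvi",
    feature_cols=None,
    screen_alpha: float = 0.10,
) -> CohortReport:
    """Full cohort analysis of a feature table.

    Per feature: group means +/- SD with the Mann-Whitney p (chi-square for
    binary features); ROC with DeLong CI and Youden cutoff; a univariate
    screen at ``p < screen_alpha``; and a multivariate logistic model of
    the screened features (continuous ones dichotomized at their Youden
    cutoffs, NIC features deduplicated to the highest AUC). Missing cells
    are dropped pairwise per feature; all-missing features are excluded
    with a log entry. Deterministic given the table.
    """
    if outcome not in table.columns:
        raise ValidationError(f"outcome column {outcome!r} missing")
    if feature_cols is None:
        feature_cols = [c for c in table.columns
                        if c not in (outcome, "patient_id")
                        and pd.api.types.is_numeric_dtype(table[c])]
    if not feature_cols:
        raise ValidationError("no feature columns to analyse")
    y_all = table[outcome].astype(int)
    if set(y_all.unique()) != {0, 1}:
        raise ValidationError("outcome must contain both classes 0 and 1")

    excluded = []
    comp_rows, roc_rows, uni_rows = [], [], []
    screened, cutoffs = [], {}
    for col in feature_cols:
        x = table[col]
        keep = ~x.isna()
        if not keep.any():
            excluded.append(col)
            logger.info("feature %s excluded: all values missing", col)
            continue
        xv = x[keep].to_numpy(dtype=float)
        yv = y_all[keep].to_numpy()
        neg, pos = xv[yv == 0], xv[yv == 1]
        binary = _is_binary(x)
        if binary:
            t = TwoByTwo(a=int(pos.sum()), b=int((yv == 1).sum() - pos.sum()),
                         c=int(neg.sum()), d=int((yv == 0).sum() - neg.sum()))
            _, p = chi_square_2x2(t)
        else:
            _, p = mann_whitney(neg, pos)
        comp_rows.append({
            "feature": col, "binary": binary,
            "n_neg": int((yv == 0).sum()), "n_pos": int((yv == 1).sum()),
            "mean_neg": float(neg.mean()), "sd_neg": float(neg.std(ddof=1)),
            "mean_pos": float(pos.mean()), "sd_pos": float(pos.std(ddof=1)),
            "p_value": p,
        })
        rr = roc_auc(xv, yv)
        roc_rows.append({"feature": col, **rr.to_dict()})
        if p < screen_alpha:
            screened.append(col)
            if not binary:
                cutoffs[col] = rr.cutoff

    if not comp_rows:
        raise ValidationError("every feature column is entirely missing")

    for col in screened:
        fit = logistic_fit(table, outcome, [col],
                           dichotomize={col: cutoffs[col]} if col in cutoffs else None,
                           guard_collinear=False)
        uni_rows.append({
            "feature": col,
            "cutoff": cutoffs.get(col, float("nan")),
            "odds_ratio": fit.odds_ratios[col],
            "ci_low": fit.ci_low[col], "ci_high": fit.ci_high[col],
            "p_value": fit.p_values[col],
        })

    multivariate = None
    if len(screened) >= 2:
        multivariate = logistic_fit(table, outcome, screened,
                                    dichotomize=cutoffs, guard_collinear=True)

    return CohortReport(
        group_comparison=pd.DataFrame(comp_rows),
        roc=pd.DataFrame(roc_rows),
        univariate=pd.DataFrame(uni_rows),
        multivariate=multivariate,
        screened_in=screened,
        excluded_features=excluded,
        screen_alpha=screen_alpha,
    )
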