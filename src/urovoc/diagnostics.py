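"""Diagnostic-biomarker statistics for dichotomized sensor features.

The cascade mirrors common clinical biomarker practice: per-feature
two-group tests screen candidates; ROC analysis with a confidence interval
and a test of AUC = 0.5 quantifies discrimination; Youden's index picks a
dichotomizing cut-off; the resulting 2x2 table yields sensitivity,
specificity, predictive values, accuracy and a Woolf-interval odds ratio;
univariable logistic regression confirms the association; and several
single-feature rules can be combined into an ordinal rule-count biomarker.

Cancer is the positive class throughout and every rule is oriented
"feature >= cut-off implies cancer".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "CutoffMetrics",
    "RocResult",
    "ScreeningReport",
    "SeparationError",
    "two_sample_t",
    "chi_square_2x2",
    "spearman_rho",
    "empirical_auc",
    "auc_inference",
    "youden_cutoff",
    "confusion_from_rates",
    "diagnostic_metrics",
    "fit_logistic_univariable",
    "combined_biomarker",
    "screen_features",
]

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class SeparationError(ValueError):
    """Raised when logistic regression meets (quasi-)complete separation."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 diagnostic counts; cancer = positive, test-positive = score >= cut-off."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg


@dataclass
class CutoffMetrics:
    """One row of a cut-off performance table.

    Proportions are on [0, 1]; PPV/NPV are NaN when their denominator is
    zero, and the odds ratio is +inf when FN*FP = 0 (with its CI bounds NaN
    whenever any cell is zero).
    """

    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    youden_j: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    or_p: float
    table: ContingencyTable | None = None


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str = "hanley_mcneil"
    se: float = float("nan")


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    cases, controls = scores[y], scores[~y]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present")
    return cases, controls


def two_sample_t(values_a, values_b, variant: str = "student") -> tuple[float, float]:
    """Two-sided two-sample t test.

    ``student`` (default) pools variances; ``welch`` does not.  Degenerate
    zero-variance input returns p = 1 for equal means and p = 0 otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(table: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    obs = np.array([[table.tp, table.fn], [table.fp, table.tn]], dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("chi-square requires all margins > 0")
    stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), float(p)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties), t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def empirical_auc(scores, labels) -> float:
    """Nonparametric AUC: P(case score > control score) + 0.5 P(tie).

    Higher score indicates cancer.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    _split(scores, y)  # class-presence check
    return float(roc_auc_score(y, scores))


def _hanley_mcneil_se(auc: float, n1: int, n0: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n1 - 1) * (q1 - auc * auc)
        + (n0 - 1) * (q2 - auc * auc)
    ) / (n1 * n0)
    return math.sqrt(max(var, 0.0))


def _delong_se(cases: np.ndarray, controls: np.ndarray) -> float:
    """DeLong covariance-based SE of the empirical AUC (single curve)."""
    n1, n0 = len(cases), len(controls)
    # placement values
    v10 = np.empty(n1)
    v01 = np.empty(n0)
    for i, x in enumerate(cases):
        v10[i] = (np.sum(x > controls) + 0.5 * np.sum(x == controls)) / n0
    for j, x in enumerate(controls):
        v01[j] = (np.sum(cases > x) + 0.5 * np.sum(cases == x)) / n1
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    return math.sqrt(s10 / n1 + s01 / n0)


def auc_inference(scores, labels, method: str = "hanley_mcneil") -> RocResult:
    """AUC with 95% CI and a two-sided test of AUC = 0.5.

    ``hanley_mcneil`` (default) uses the Hanley-McNeil variance; ``delong``
    uses the DeLong placement-based variance.  The CI is AUC +- 1.96 SE
    clipped to [0, 1]; p comes from z = (AUC - 0.5)/SE.
    """
    cases, controls = _split(scores, labels)
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need >= 2 per class for AUC inference")
    auc = empirical_auc(scores, labels)
    if method == "hanley_mcneil":
        se = _hanley_mcneil_se(auc, len(cases), len(controls))
    elif method == "delong":
        se = _delong_se(cases, controls)
    else:
        raise ValueError(f"unknown method {method!r}")
    if se == 0.0:
        p = 1.0 if auc == 0.5 else 0.0
    else:
        p = 2.0 * stats.norm.sf(abs(auc - 0.5) / se)
    lo = max(0.0, auc - Z95 * se)
    hi = min(1.0, auc + Z95 * se)
    return RocResult(auc, lo, hi, float(p), method, se)


def confusion_from_rates(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> ContingencyTable:
    """Reconstruct integer 2x2 counts from printed rates and group sizes.

    TP = round(sensitivity * n_pos), TN = round(specificity * n_neg) with
    half-away-from-zero rounding, FN and FP by complement.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("group sizes must be >= 1")
    tp = int(math.floor(sensitivity * n_pos + 0.5))
    tn = int(math.floor(specificity * n_neg + 0.5))
    return ContingencyTable(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)


def diagnostic_metrics(
    table: ContingencyTable, cutoff: float = float("nan")
) -> CutoffMetrics:
    """All diagnostic metrics of a 2x2 table, with the Woolf OR interval.

    OR = (TP*TN)/(FN*FP); 95% CI = exp(ln OR +- 1.96 * sqrt(sum of
    reciprocal cells)); p from the Wald z on the log odds ratio.
    """
    if table.total == 0:
        raise ValueError("empty contingency table")
    if table.n_pos == 0 or table.n_neg == 0:
        raise ValueError("both classes must be present")
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    sens = tp / table.n_pos
    spec = tn / table.n_neg
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    npv = tn / (tn + fn) if tn + fn > 0 else float("nan")
    acc = (tp + tn) / table.total
    if fn * fp == 0:
        orr = float("inf") if tp * tn > 0 else float("nan")
    else:
        orr = (tp * tn) / (fn * fp)
    if min(tp, fp, fn, tn) > 0:
        se_ln = math.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
        lo = math.exp(math.log(orr) - Z95 * se_ln)
        hi = math.exp(math.log(orr) + Z95 * se_ln)
        p = 2.0 * stats.norm.sf(abs(math.log(orr)) / se_ln)
    else:
        lo = hi = p = float("nan")
    return CutoffMetrics(
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=acc,
        youden_j=sens + spec - 1.0,
        odds_ratio=orr,
        or_ci_low=lo,
        or_ci_high=hi,
        or_p=float(p),
        table=table,
    )


def _table_at_cutoff(cases, controls, cutoff) -> ContingencyTable:
    return ContingencyTable(
        tp=int(np.sum(cases >= cutoff)),
        fp=int(np.sum(controls >= cutoff)),
        fn=int(np.sum(cases < cutoff)),
        tn=int(np.sum(controls < cutoff)),
    )


def youden_cutoff(scores, labels) -> tuple[float, CutoffMetrics]:
    """Pick the cut-off maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the distinct observed scores; positivity is score >=
    cut-off.  Ties on J are broken by higher accuracy, then by the smaller
    cut-off value.
    """
    cases, controls = _split(scores, labels)
    best = None
    for c in np.unique(np.concatenate([cases, controls])):
        tab = _table_at_cutoff(cases, controls, c)
        sens = tab.tp / tab.n_pos
        spec = tab.tn / tab.n_neg
        j = sens + spec - 1.0
        acc = (tab.tp + tab.tn) / tab.total
        key = (j, acc, -c)  # maximize J, then accuracy, then prefer smaller c
        if best is None or key > best[0]:
            best = (key, float(c))
    cutoff = best[1]
    return cutoff, diagnostic_metrics(
        _table_at_cutoff(cases, controls, cutoff), cutoff=cutoff
    )


def fit_logistic_univariable(
    predictor, labels, tol: float = 1e-8, max_iter: int = 100
) -> tuple[float, float, float, float]:
    """Univariable logistic fit (intercept + slope) by IRLS.

    Returns (odds_ratio, ci_low, ci_high, p): OR = exp(slope), Wald 95% CI
    and two-sided Wald p.  Complete or quasi-complete separation raises
    SeparationError.
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(labels).astype(float)
    if x.shape != y.shape:
        raise ValueError("predictor and labels must have the same length")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    if np.min(x[y == 1]) > np.max(x[y == 0]) or np.max(x[y == 1]) < np.min(x[y == 0]):
        raise SeparationError("complete separation: classes do not overlap")
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        xtwx = X.T @ (w[:, None] * X)
        try:
            delta = np.linalg.solve(xtwx, X.T @ (y - mu))
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix") from exc
        beta = beta + delta
        if np.abs(beta).max() > 40.0:
            raise SeparationError(
                "diverging coefficients: quasi-complete separation"
            )
        if np.abs(delta).max() < tol:
            break
    else:
        raise SeparationError("IRLS did not converge")
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    cov = np.linalg.inv(X.T @ (w[:, None] * X))
    slope, se = beta[1], math.sqrt(cov[1, 1])
    orr = math.exp(slope)
    lo = math.exp(slope - Z95 * se)
    hi = math.exp(slope + Z95 * se)
    p = float(2.0 * stats.norm.sf(abs(slope) / se))
    return orr, lo, hi, p


def combined_biomarker(
    feature_table: pd.DataFrame, rules: list[tuple[str, float]]
) -> pd.Series:
    """Ordinal rule-count biomarker: per subject, how many rules are met.

    Each rule is (feature name, cut-off) and counts when feature >= cut-off.
    Subjects with a missing value in any rule feature get a missing score
    (logged, excluded from downstream analyses).
    """
    if not rules:
        raise ValueError("rules must be non-empty")
    names = [r[0] for r in rules]
    missing_cols = [n for n in names if n not in feature_table.columns]
    if missing_cols:
        raise KeyError(f"features not in table: {missing_cols}")
    sub = feature_table[names]
    score = sum(
        (sub[name] >= cut).astype(float) for name, cut in rules
    )
    incomplete = sub.isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "combined biomarker: %d subjects excluded for missing features",
            int(incomplete.sum()),
        )
        score[incomplete] = np.nan
    score.name = "+".join(f"{n}>={c:g}" for n, c in rules)
    return score


@dataclass
class ScreeningReport:
    """Staged screening of a feature table against binary labels.

    ``records`` has one row per feature: t-test statistic/p, then (for
    features carried into ROC) AUC with CI and p, then (for features with
    significant ROC) the Youden cut-off row.  ``alpha`` is the raw
    significance threshold (no multiplicity correction by default).
    """

    records: pd.DataFrame
    alpha: float
    cutoff_metrics: dict[str, CutoffMetrics] = field(default_factory=dict)
    three_group: pd.DataFrame | None = None

    @property
    def significant_t(self) -> list[str]:
        return list(self.records.index[self.records["t_significant"]])

    @property
    def significant_roc(self) -> list[str]:
        m = self.records["roc_significant"].fillna(False)
        return list(self.records.index[m])


def screen_features(
    feature_table: pd.DataFrame,
    labels,
    alpha: float = 0.05,
    forced: tuple[str, ...] = (),
    t_variant: str = "student",
    auc_method: str = "hanley_mcneil",
    bh_column: bool = False,
    subclasses: dict[str, str] | None = None,
) -> ScreeningReport:
    """Three-stage biomarker screen over all feature columns.

    Stage 1: per-feature two-group t test (p <= alpha flags).  Stage 2: ROC
    inference for stage-1 passes plus any ``forced`` features.  Stage 3:
    Youden cut-off and diagnostic metrics for features whose ROC p <=
    alpha.  Features are ordered by AUC descending (screened-out features
    last).  ``bh_column`` adds a Benjamini-Hochberg adjusted-p column for
    reference without altering the cascade.  ``subclasses`` (subject ->
    cancer/other_disease/normal) adds pairwise three-group t-test p-values.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    if isinstance(labels, dict):
        y = feature_table.index.map(lambda s: labels[s] == "cancer").to_numpy()
    else:
        y = np.asarray(labels).astype(bool)
    rec = {}
    for col in feature_table.columns:
        vals = feature_table[col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        stat, p = two_sample_t(vals[ok & y], vals[ok & ~y], variant=t_variant)
        rec[col] = {"t_stat": stat, "t_p": p}
    df = pd.DataFrame.from_dict(rec, orient="index")
    df.index.name = "feature"
    df["t_significant"] = df["t_p"] <= alpha
    if bh_column:
        df["t_p_bh"] = multipletests(df["t_p"].to_numpy(), method="fdr_bh")[1]

    stage2 = [f for f in df.index if df.loc[f, "t_significant"] or f in forced]
    for col in ("auc", "auc_ci_low", "auc_ci_high", "auc_p"):
        df[col] = np.nan
    for f in stage2:
        vals = feature_table[f].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        roc = auc_inference(vals[ok], y[ok], method=auc_method)
        df.loc[f, ["auc", "auc_ci_low", "auc_ci_high", "auc_p"]] = (
            roc.auc, roc.ci_low, roc.ci_high, roc.p_value,
        )
    df["roc_significant"] = df["auc_p"] <= alpha

    cut_metrics: dict[str, CutoffMetrics] = {}
    cut_cols = (
        "cutoff", "sensitivity", "specificity", "ppv", "npv", "accuracy",
        "youden_j", "odds_ratio", "or_ci_low", "or_ci_high", "or_p",
    )
    for col in cut_cols:
        df[col] = np.nan
    for f in df.index[df["roc_significant"].fillna(False)]:
        vals = feature_table[f].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        cut, cm = youden_cutoff(vals[ok], y[ok])
        cut_metrics[f] = cm
        df.loc[f, list(cut_cols)] = (
            cm.cutoff, cm.sensitivity, cm.specificity, cm.ppv, cm.npv,
            cm.accuracy, cm.youden_j, cm.odds_ratio, cm.or_ci_low,
            cm.or_ci_high, cm.or_p,
        )
    df = df.sort_values("auc", ascending=False, na_position="last", kind="stable")

    three = None
    if subclasses is not None:
        sub = feature_table.index.map(subclasses.get)
        pairs = [
            ("cancer", "other_disease"),
            ("cancer", "normal"),
            ("other_disease", "normal"),
        ]
        rows = {}
        for col in feature_table.columns:
            vals = feature_table[col].to_numpy(dtype=float)
            row = {}
            for g1, g2 in pairs:
                a = vals[(sub == g1) & np.isfinite(vals)]
                b = vals[(sub == g2) & np.isfinite(vals)]
                if len(a) >= 2 and len(b) >= 2:
                    _, row[f"p_{g1}_vs_{g2}"] = two_sample_t(a, b, t_variant)
                else:
                    row[f"p_{g1}_vs_{g2}"] = np.nan
            rows[col] = row
        three = pd.DataFrame.from_dict(rows, orient="index")
        three.index.name = "feature"

    return ScreeningReport(df, alpha, cut_metrics, three)
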