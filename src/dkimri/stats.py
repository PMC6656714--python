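"""Cohort-level inference: response comparison, histology correlation, observer agreement.

The inference chain mirrors standard small-cohort imaging-biomarker
practice:

* RECIST categories are dichotomised (CR/PR responder, SD/PD
  non-responder);
* each imaging metric is compared between the two groups with a
  normality-gated test — Shapiro-Wilk per group at alpha, then Student's
  two-sample t if both groups pass, otherwise a two-sided Mann-Whitney U
  (exact null distribution for small tie-free samples, tie-corrected
  normal approximation with continuity correction otherwise);
* imaging metrics are correlated with histology covariates using Spearman's
  rank correlation (t-approximation p-values, exact permutation optional at
  small n);
* intra-/inter-observer agreement is measured with the intraclass
  correlation coefficient, by default the two-way random-effects,
  absolute-agreement, single-rater form, with a 95% CI from the standard
  F-distribution construction.

No multiple-testing correction is applied; p = 0.05 is the conventional
cut-off throughout.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import CohortTable

__all__ = [
    "GroupComparisonResult",
    "CorrelationResult",
    "ICCResult",
    "CohortReport",
    "classify_response",
    "compare_groups",
    "spearman_corr",
    "icc_agreement",
    "run_cohort_analysis",
]

_RECIST_MAP = {
    "CR": "responder",
    "PR": "responder",
    "SD": "non-responder",
    "PD": "non-responder",
}

#: Metric VOI columns analysed by :func:`run_cohort_analysis`.
METRIC_COLUMNS = (("k_app_voi", "K_app"), ("d_app_voi", "D_app"), ("adc_voi", "ADC"))
HISTOLOGY_COLUMNS = (
    ("cellularity_cells_per_um2", "cellularity"),
    ("ki67_percent", "Ki-67"),
)

# Exact Mann-Whitney is used up to this combined sample size (tie-free data).
_MW_EXACT_MAX_N = 25


def classify_response(recist_category) -> str:
    """Dichotomise a RECIST v1.1 category: CR/PR responder, SD/PD non-responder.

    A missing category (None, NaN or empty string) maps to "unclassified";
    any other string is an error.
    """
    if recist_category is None:
        return "unclassified"
    if isinstance(recist_category, float) and math.isnan(recist_category):
        return "unclassified"
    cat = str(recist_category).strip().upper()
    if cat == "":
        return "unclassified"
    try:
        return _RECIST_MAP[cat]
    except KeyError:
        raise ValueError(
            f"unknown RECIST category {recist_category!r}; expected one of {sorted(_RECIST_MAP)}"
        ) from None


@dataclass
class GroupComparisonResult:
    """Two-group comparison of one metric with the normality-gated test."""

    metric: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    test_used: str  # "student_t" | "mann_whitney"
    statistic: float
    p_value: float
    shapiro_p_a: float
    shapiro_p_b: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value out of range: {self.p_value}")
        if self.test_used not in ("student_t", "mann_whitney"):
            raise ValueError(f"unknown test {self.test_used!r}")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class CorrelationResult:
    """Spearman rank correlation between one variable pair."""

    variables: tuple[str, str]
    n: int
    spearman_rho: float
    p_value: float
    method: str = "t-approximation"

    def __post_init__(self) -> None:
        if abs(self.spearman_rho) > 1 + 1e-12:
            raise ValueError(f"|rho| > 1: {self.spearman_rho}")
        if self.n < 3:
            raise ValueError("need n >= 3 for a rank correlation")


@dataclass
class ICCResult:
    """Intraclass correlation with its 95% confidence interval."""

    metric: str
    icc_value: float
    ci_low: float
    ci_high: float
    model: str  # e.g. "two-way random, absolute agreement, single rater"
    n_units: int
    n_raters: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.icc_value <= 1.0 + 1e-9:
            raise ValueError(f"ICC out of range: {self.icc_value}")
        if not self.ci_low <= self.icc_value + 1e-9 or not self.icc_value <= self.ci_high + 1e-9:
            raise ValueError("confidence interval must bracket the estimate")


def _shapiro_p(values: np.ndarray) -> float:
    # Degenerate (constant) samples are treated as non-normal so that the
    # gate falls through to the rank test rather than erroring.
    if np.ptp(values) == 0:
        return 0.0
    return float(sps.shapiro(values).pvalue)


def compare_groups(
    values_a,
    values_b,
    alpha: float = 0.05,
    metric: str = "",
    test: str = "auto",
) -> GroupComparisonResult:
    """Normality-gated two-group comparison.

    With ``test="auto"`` (default), Shapiro-Wilk is run on each group and
    Student's two-sample t-test is used only when both groups look normal at
    ``alpha``; otherwise a two-sided Mann-Whitney U. The Mann-Whitney null
    distribution is exact when the combined sample is tie-free and
    n_a + n_b <= 25, else a mid-rank, tie-corrected normal approximation
    with continuity correction. ``test`` can force either branch.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError(f"each group needs n >= 3, got {a.size} and {b.size}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("group values must be finite")
    shap_a, shap_b = _shapiro_p(a), _shapiro_p(b)
    if test == "auto":
        use_t = shap_a > alpha and shap_b > alpha
    elif test == "student_t":
        use_t = True
    elif test == "mann_whitney":
        use_t = False
    else:
        raise ValueError(f"test must be auto|student_t|mann_whitney, got {test!r}")

    if use_t:
        res = sps.ttest_ind(a, b, equal_var=True)
        test_used, statistic, p = "student_t", float(res.statistic), float(res.pvalue)
    else:
        pooled = np.concatenate([a, b])
        tie_free = np.unique(pooled).size == pooled.size
        method = "exact" if tie_free and pooled.size <= _MW_EXACT_MAX_N else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test_used, statistic, p = "mann_whitney", float(res.statistic), float(res.pvalue)

    return GroupComparisonResult(
        metric=metric,
        n_a=int(a.size), n_b=int(b.size),
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        test_used=test_used, statistic=statistic, p_value=min(p, 1.0),
        shapiro_p_a=shap_a, shapiro_p_b=shap_b, alpha=alpha,
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p-value over all n! rank assignments (n <= 10)."""
    n = x.size
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    # rho is an increasing affine function of sum(rx * ry_perm) for fixed
    # marginal ranks, so permutations are compared on the dot product alone.
    sx, sy = rx.std(), ry.std()
    mx, my = rx.mean(), ry.mean()

    def rho_of(dots: np.ndarray) -> np.ndarray:
        return (dots / n - mx * my) / (sx * sy)

    count = 0
    total = 0
    chunk = []
    for perm in itertools.permutations(ry):
        chunk.append(perm)
        if len(chunk) == 100_000:
            dots = np.asarray(chunk) @ rx
            count += int((np.abs(rho_of(dots)) >= abs(rho_obs) - 1e-12).sum())
            total += len(chunk)
            chunk = []
    if chunk:
        dots = np.asarray(chunk) @ rx
        count += int((np.abs(rho_of(dots)) >= abs(rho_obs) - 1e-12).sum())
        total += len(chunk)
    return count / total


def spearman_corr(x, y, variables=("x", "y"), method: str = "approx") -> CorrelationResult:
    """Mid-rank Spearman correlation with a two-sided p-value.

    ``method="approx"`` uses the t-distribution approximation;
    ``method="exact"`` enumerates all rank permutations (n <= 10 only).
    A constant input vector leaves rho undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation is undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    rho, p = float(rho), float(p)
    if method == "exact":
        if x.size > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        p = _exact_spearman_p(x, y, rho)
        meth = "exact permutation"
    elif method == "approx":
        meth = "t-approximation"
    else:
        raise ValueError(f"method must be approx|exact, got {method!r}")
    return CorrelationResult(
        variables=tuple(variables), n=int(x.size), spearman_rho=rho,
        p_value=min(p, 1.0), method=meth,
    )


def icc_agreement(ratings, model: str = "absolute", metric: str = "") -> ICCResult:
    """Single-rater intraclass correlation from a complete units × raters matrix.

    ``model="absolute"`` gives the two-way random-effects absolute-agreement
    form ICC(2,1); ``model="consistency"`` the consistency form ICC(3,1).
    The 95% CI comes from the F-distribution construction.
    """
    import pingouin as pg

    mat = np.asarray(ratings, dtype=float)
    if mat.ndim != 2:
        raise ValueError("ratings must be a 2-D units × raters matrix")
    n_units, n_raters = mat.shape
    if n_units < 5:
        raise ValueError(f"need at least 5 units, got {n_units}")
    if n_raters < 2:
        raise ValueError(f"need at least 2 raters, got {n_raters}")
    if not np.isfinite(mat).all():
        raise ValueError("ratings matrix must be complete (no missing cells)")
    if model not in ("absolute", "consistency"):
        raise ValueError(f"model must be absolute|consistency, got {model!r}")

    long = pd.DataFrame(
        {
            "target": np.repeat(np.arange(n_units), n_raters),
            "rater": np.tile(np.arange(n_raters), n_units),
            "score": mat.ravel(),
        }
    )
    with warnings.catch_warnings():
        # zero within-rater error (perfect agreement) divides by zero inside
        # the F-based CI construction; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            data=long, targets="target", raters="rater", ratings="score"
        )
    icc_type = "ICC(A,1)" if model == "absolute" else "ICC(C,1)"
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    row = table.set_index("Type").loc[icc_type]
    icc = float(np.clip(row["ICC"], -1.0, 1.0))
    ci_low, ci_high = (float(v) for v in row[ci_col])
    if math.isnan(ci_low) or math.isnan(ci_high):
        # degenerate zero-error case (e.g. duplicated ratings): point interval
        ci_low = ci_high = icc
    descriptor = (
        "two-way random, absolute agreement, single rater"
        if model == "absolute"
        else "two-way mixed, consistency, single rater"
    )
    return ICCResult(
        metric=metric,
        icc_value=icc,
        ci_low=ci_low, ci_high=ci_high,
        model=descriptor, n_units=n_units, n_raters=n_raters,
    )


@dataclass
class CohortReport:
    """Structured output of the cohort analysis: comparisons, correlations, ICCs."""

    comparisons: list[GroupComparisonResult] = field(default_factory=list)
    correlations: list[CorrelationResult] = field(default_factory=list)
    iccs: list[ICCResult] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.comparisons:
            rows.append(
                {
                    "analysis": "group_comparison", "name": c.metric,
                    "n": c.n_a + c.n_b, "test": c.test_used,
                    "estimate": c.mean_a - c.mean_b, "statistic": c.statistic,
                    "p_value": c.p_value,
                }
            )
        for r in self.correlations:
            rows.append(
                {
                    "analysis": "spearman_correlation", "name": " vs ".join(r.variables),
                    "n": r.n, "test": r.method,
                    "estimate": r.spearman_rho, "statistic": r.spearman_rho,
                    "p_value": r.p_value,
                }
            )
        for i in self.iccs:
            rows.append(
                {
                    "analysis": "icc", "name": i.metric, "n": i.n_units,
                    "test": i.model, "estimate": i.icc_value,
                    "statistic": i.icc_value, "p_value": float("nan"),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        def _clean(obj):
            if isinstance(obj, float) and math.isnan(obj):
                return None
            return obj

        payload = {
            "alpha": self.alpha,
            "comparisons": [vars(c).copy() for c in self.comparisons],
            "correlations": [
                {**vars(r), "variables": list(r.variables)} for r in self.correlations
            ],
            "iccs": [vars(i).copy() for i in self.iccs],
            "skipped": self.skipped,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=_clean)

    def summary(self) -> str:
        lines = ["Cohort analysis report", "======================"]
        for c in self.comparisons:
            flag = "*" if c.significant else " "
            lines.append(
                f"{flag} {c.metric:>6}: responders {c.mean_a:.3g} ± {c.sd_a:.3g} (n={c.n_a}) vs "
                f"non-responders {c.mean_b:.3g} ± {c.sd_b:.3g} (n={c.n_b}); "
                f"{c.test_used} P = {c.p_value:.3g}"
            )
        for r in self.correlations:
            flag = "*" if r.p_value < self.alpha else " "
            lines.append(
                f"{flag} {r.variables[0]} vs {r.variables[1]}: rho = {r.spearman_rho:.2f}, "
                f"P = {r.p_value:.3g} (n={r.n})"
            )
        for i in self.iccs:
            lines.append(
                f"  ICC[{i.metric}] = {i.icc_value:.3f} "
                f"({i.ci_low:.3f} to {i.ci_high:.3f}); {i.model}"
            )
        for s in self.skipped:
            lines.append(f"  skipped {s['analysis']} ({s['name']}): {s['reason']}")
        return "\n".join(lines)


def run_cohort_analysis(
    cohort: CohortTable,
    alpha: float = 0.05,
    icc_ratings: dict[str, np.ndarray] | None = None,
    icc_model: str = "absolute",
) -> CohortReport:
    """Run the full inference chain on a cohort table.

    Group comparisons (responders vs non-responders) are run for each VOI
    metric present; patients with unclassified response are excluded from
    the comparisons but kept for the metric-histology correlations.
    Analyses with insufficient data are recorded in ``report.skipped``
    rather than raising. ``icc_ratings`` optionally maps a metric name to a
    units × raters matrix for observer-agreement ICCs.
    """
    df = cohort.to_frame()
    report = CohortReport(alpha=alpha)
    resp = df[df["response_class"] == "responder"]
    nonresp = df[df["response_class"] == "non-responder"]

    for col, label in METRIC_COLUMNS:
        if col not in df.columns:
            report.skipped.append(
                {"analysis": "group_comparison", "name": label, "reason": f"no column {col}"}
            )
            continue
        a = resp[col].dropna().to_numpy()
        b = nonresp[col].dropna().to_numpy()
        if a.size < 3 or b.size < 3:
            report.skipped.append(
                {
                    "analysis": "group_comparison", "name": label,
                    "reason": f"need >= 3 patients per group, have {a.size} and {b.size}",
                }
            )
            continue
        report.comparisons.append(compare_groups(a, b, alpha=alpha, metric=label))

    for hist_col, hist_label in HISTOLOGY_COLUMNS:
        for col, label in METRIC_COLUMNS:
            name = f"{label} vs {hist_label}"
            if hist_col not in df.columns or col not in df.columns:
                report.skipped.append(
                    {"analysis": "spearman_correlation", "name": name, "reason": "column absent"}
                )
                continue
            sub = df[[col, hist_col]].dropna()
            if len(sub) < 3:
                report.skipped.append(
                    {
                        "analysis": "spearman_correlation", "name": name,
                        "reason": f"need >= 3 paired observations, have {len(sub)}",
                    }
                )
                continue
            report.correlations.append(
                spearman_corr(
                    sub[col].to_numpy(), sub[hist_col].to_numpy(), variables=(label, hist_label)
                )
            )

    for metric, ratings in (icc_ratings or {}).items():
        report.iccs.append(icc_agreement(ratings, model=icc_model, metric=metric))
    return report
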