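"""Cohort-level statistics: eye-clustered group comparisons, correlations,
ROC analysis, and logistic composite indices.

Because many patients contribute both eyes, eye-level observations are not
independent.  Group comparisons therefore use cluster-robust (patient-
clustered) covariances on a group-mean regression: with one eye per patient
this reduces to ordinary one-way ANOVA.  ROC analysis reports the empirical
(Mann–Whitney) AUC oriented to be >= 0.5, Youden-optimal cutoffs, and — for
two-marker composites — the AUC of the fitted probability from a two-
predictor logistic regression, with one cutoff per component evaluated at
the Youden-optimal operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

GROUPS = ("control", "nonDON", "DON")

#: Single-indicator ROC panel: GCC thickness and the per-slab densities.
SINGLE_ROC_MEASURES: Tuple[str, ...] = (
    "GCC_TAZ", "GCC_S", "GCC_T", "GCC_I", "GCC_N",
    "SRCL_TAZ", "SRCL_C6", "SRCL_S", "SRCL_T", "SRCL_I", "SRCL_N",
    "DRCL_TAZ", "DRCL_C6", "DRCL_S", "DRCL_T", "DRCL_I", "DRCL_N",
)
#: Composite panel: GCC region paired with the C6 density of each slab.
COMPOSITE_ROC_PAIRS: Tuple[Tuple[str, str], ...] = tuple(
    (f"GCC_{region}", f"{layer}_C6")
    for layer in ("SRCL", "DRCL")
    for region in ("TAZ", "S", "T", "I", "N")
)


@dataclass
class GroupComparison:
    """Three-group comparison of one measure with eye-cluster adjustment."""

    measure: str
    group_stats: Dict[str, Tuple[float, float, int]]   # group -> (mean, sd, n)
    anova_p: float
    robust_overall_p: float
    pairwise_p: Dict[str, float]   # "control_vs_nonDON" etc.
    alpha: float
    significant: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.significant = {k: p < self.alpha for k, p in self.pairwise_p.items()}


@dataclass
class ROCResult:
    """AUC with operating-point cutoffs for one indicator or a composite."""

    indicators: Tuple[str, ...]
    auc: float
    cutoffs: Tuple[float, ...]
    sensitivity: float            # percent
    specificity: float            # percent
    p_value: float
    orientation: str = "higher_in_positive"
    converged: bool = True

    def __post_init__(self) -> None:
        if not 0.5 - 1e-12 <= self.auc <= 1.0 + 1e-12:
            raise ValueError("oriented AUC must lie in [0.5, 1]")


def group_compare(
    records: pd.DataFrame,
    measure: str,
    alpha: float = 0.01,
    cluster_col: str = "patient_id",
    pairwise_method: str = "patient_mean",
) -> GroupComparison:
    """One-way comparison of `measure` across the three groups.

    Reports per-group eye-level mean ± SD, a plain one-way ANOVA F-test, a
    patient-clustered robust Wald test of the group effect, and the three
    pairwise contrasts.  Pairwise p-values default to Welch t-tests on
    patient means (``pairwise_method="patient_mean"``): with one or two
    eyes per patient this collapse removes the inter-eye dependence exactly
    and is well calibrated at the cluster counts of a typical cohort,
    whereas plain cluster-robust Wald tests over-reject slightly at these
    sizes.  ``pairwise_method="cluster_robust"`` selects the sandwich-based
    tests from the eye-level fit instead.  With one eye per patient both
    reduce to ordinary two-sample comparisons.
    """
    if pairwise_method not in ("patient_mean", "cluster_robust"):
        raise ValueError("unknown pairwise_method")
    df = records.dropna(subset=[measure])
    samples = []
    for g in GROUPS:
        vals = df.loc[df["group"] == g, measure].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValueError(f"group {g} has fewer than 2 eyes for {measure}")
        samples.append(vals)

    group_stats = {
        g: (float(v.mean()), float(v.std(ddof=1)), int(v.size))
        for g, v in zip(GROUPS, samples)
    }
    anova_p = float(sps.f_oneway(*samples).pvalue)

    y = df[measure].to_numpy(dtype=float)
    x1 = (df["group"] == "nonDON").to_numpy(float)
    x2 = (df["group"] == "DON").to_numpy(float)
    X = np.column_stack([np.ones_like(y), x1, x2])
    clusters = df[cluster_col].to_numpy()
    fit = sm.OLS(y, X).fit(
        cov_type="cluster", cov_kwds={"groups": clusters}, use_t=True
    )
    overall = fit.wald_test(np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]),
                            scalar=True)

    if pairwise_method == "cluster_robust":
        pairwise = {
            "control_vs_nonDON": float(fit.t_test([0, 1, 0]).pvalue),
            "control_vs_DON": float(fit.t_test([0, 0, 1]).pvalue),
            "nonDON_vs_DON": float(fit.t_test([0, -1, 1]).pvalue),
        }
    else:
        pmeans = {
            g: df.loc[df["group"] == g].groupby(cluster_col)[measure]
                 .mean().to_numpy()
            for g in GROUPS
        }
        def welch(a, b):
            return float(sps.ttest_ind(pmeans[a], pmeans[b],
                                       equal_var=False).pvalue)
        pairwise = {
            "control_vs_nonDON": welch("control", "nonDON"),
            "control_vs_DON": welch("control", "DON"),
            "nonDON_vs_DON": welch("nonDON", "DON"),
        }
    return GroupComparison(measure, group_stats, anova_p,
                           float(overall.pvalue), pairwise, alpha)


def pearson(
    records: pd.DataFrame,
    x_measure: str,
    y_measure: str,
    subset: Optional[pd.Series] = None,
) -> Tuple[float, float]:
    """Pearson product-moment correlation between two eye-level measures."""
    df = records if subset is None else records[subset]
    df = df.dropna(subset=[x_measure, y_measure])
    x = df[x_measure].to_numpy(float)
    y = df[y_measure].to_numpy(float)
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the measures")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def empirical_auc(
    scores: np.ndarray, labels: np.ndarray
) -> Tuple[float, str]:
    """Empirical (Mann–Whitney) AUC, oriented to be >= 0.5.

    AUC = U / (n1·n0) with ties counted half.  Returns the oriented AUC and
    which direction separated the classes ("higher_in_positive" or
    "lower_in_positive").
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    if auc >= 0.5:
        return float(auc), "higher_in_positive"
    return float(1.0 - auc), "lower_in_positive"


def binormal_auc(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Closed-form AUC for two normal score distributions.

    Phi(|mean1 − mean2| / sqrt(sd1² + sd2²)) — the probability that a draw
    from the higher-mean population exceeds one from the other.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    return float(sps.norm.cdf(abs(mean1 - mean2) / np.hypot(sd1, sd2)))


def _youden_point(scores: np.ndarray, labels: np.ndarray) -> Tuple[float, float, float]:
    """Youden-optimal cutoff on `scores` (positive iff score > cutoff).

    Returns (cutoff, sensitivity%, specificity%); ties resolved toward the
    first (lowest) optimal cutoff for determinism.
    """
    order = np.argsort(scores, kind="stable")
    s, lab = scores[order], labels[order].astype(bool)
    n1, n0 = lab.sum(), (~lab).sum()
    # candidate cutoffs: each unique score value (positive iff score > c)
    uniq = np.unique(s)
    best = (-np.inf, 0.0, 0.0, 0.0)
    for c in np.r_[uniq[0] - 1.0, uniq]:
        pos = s > c
        sens = (pos & lab).sum() / n1
        spec = (~pos & ~lab).sum() / n0
        j = sens + spec - 1.0
        if j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    return best[1], 100.0 * best[2], 100.0 * best[3]


def composite_index(
    records: pd.DataFrame,
    indicator_a: str,
    indicator_b: str,
    positive_group: str = "DON",
    negative_group: str = "control",
) -> ROCResult:
    """Two-marker composite: logistic prediction probability and its ROC.

    Fits ``class ~ a + b`` by maximum likelihood, computes the empirical
    AUC of the fitted probabilities, finds the Youden-optimal probability
    cutoff, and reports per-component cutoffs: the value of each component
    at the operating point when the other sits at its sample mean.
    Zero-variance components are dropped (the composite then degenerates to
    the remaining indicator); separation falls back to a ridge-penalized
    fit, flagged via ``converged=False``.
    """
    df = records[records["group"].isin([positive_group, negative_group])]
    df = df.dropna(subset=[indicator_a, indicator_b])
    y = (df["group"] == positive_group).to_numpy(float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")
    a = df[indicator_a].to_numpy(float)
    b = df[indicator_b].to_numpy(float)

    cols, names = [], []
    for vec, name in ((a, indicator_a), (b, indicator_b)):
        if vec.std() > 0:
            cols.append(vec)
            names.append(name)
    if not cols:
        raise ValueError("both indicators are constant")
    X = sm.add_constant(np.column_stack(cols))

    converged = True
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise sps.FitError("logistic ML did not converge")
        params = fit.params
    except Exception:
        converged = False
        fit = sm.Logit(y, X).fit_regularized(disp=0, alpha=1.0, L1_wt=0.0)
        params = np.asarray(fit.params)

    eta = X @ params
    prob = 1.0 / (1.0 + np.exp(-eta))
    auc, orientation = empirical_auc(prob, y.astype(bool))
    p_cut, sens, spec = _youden_point(prob, y.astype(bool))
    # translate the probability cutoff into one cutoff per component:
    # solve beta0 + beta_i * x_i + beta_j * mean_j = logit(p_cut)
    p_cut = min(max(p_cut, 1e-12), 1 - 1e-12)
    target = np.log(p_cut / (1.0 - p_cut))
    cutoffs: List[float] = []
    means = {indicator_a: a.mean(), indicator_b: b.mean()}
    for name in (indicator_a, indicator_b):
        if name not in names:
            cutoffs.append(float("nan"))
            continue
        i = names.index(name)
        beta_i = params[1 + i]
        other = sum(
            params[1 + j] * means[n2]
            for j, n2 in enumerate(names) if j != i
        )
        if beta_i == 0:
            cutoffs.append(float("nan"))
        else:
            cutoffs.append(float((target - params[0] - other) / beta_i))

    p_value = float(sps.mannwhitneyu(prob[y == 1], prob[y == 0],
                                     alternative="two-sided").pvalue)
    return ROCResult((indicator_a, indicator_b), auc, tuple(cutoffs),
                     sens, spec, p_value, orientation, converged)


def single_roc(
    records: pd.DataFrame,
    measure: str,
    positive_group: str = "DON",
    negative_group: str = "control",
) -> ROCResult:
    """Empirical ROC of one indicator with its Youden-optimal cutoff."""
    df = records[records["group"].isin([positive_group, negative_group])]
    df = df.dropna(subset=[measure])
    y = (df["group"] == positive_group).to_numpy(bool)
    x = df[measure].to_numpy(float)
    auc, orientation = empirical_auc(x, y)
    scores = x if orientation == "higher_in_positive" else -x
    cut, sens, spec = _youden_point(scores, y)
    cutoff = cut if orientation == "higher_in_positive" else -cut
    p_value = float(sps.mannwhitneyu(x[y], x[~y],
                                     alternative="two-sided").pvalue)
    return ROCResult((measure,), auc, (float(cutoff),), sens, spec,
                     p_value, orientation)


def roc_report(
    records: pd.DataFrame,
    single_measures: Sequence[str] = SINGLE_ROC_MEASURES,
    composite_pairs: Sequence[Tuple[str, str]] = COMPOSITE_ROC_PAIRS,
    positive_group: str = "DON",
    negative_group: str = "control",
) -> pd.DataFrame:
    """Single-indicator and composite ROC table (DON vs control by default)."""
    rows = []
    for m in single_measures:
        if m not in records.columns:
            import warnings

            warnings.warn(f"measure {m} missing; ROC row skipped")
            continue
        r = single_roc(records, m, positive_group, negative_group)
        rows.append({
            "kind": "single", "indicators": m, "auc": r.auc,
            "cutoff_a": r.cutoffs[0], "cutoff_b": np.nan,
            "sensitivity_pct": r.sensitivity, "specificity_pct": r.specificity,
            "p_value": r.p_value, "orientation": r.orientation,
        })
    for a, b in composite_pairs:
        if a not in records.columns or b not in records.columns:
            import warnings

            warnings.warn(f"pair {a},{b} missing; ROC row skipped")
            continue
        r = composite_index(records, a, b, positive_group, negative_group)
        rows.append({
            "kind": "composite", "indicators": f"{a}+{b}", "auc": r.auc,
            "cutoff_a": r.cutoffs[0], "cutoff_b": r.cutoffs[1],
            "sensitivity_pct": r.sensitivity, "specificity_pct": r.specificity,
            "p_value": r.p_value, "orientation": r.orientation,
        })
    return pd.DataFrame(rows)
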