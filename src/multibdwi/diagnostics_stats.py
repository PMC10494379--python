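"""Diagnostic statistics for two-group lesion parameter tables.

Implements the full inference chain used to separate tumour progression
from pseudoprogression on per-lesion DWI parameters:

* Kolmogorov-Smirnov normality screening (Lilliefors correction, since the
  normal's parameters are estimated from the sample);
* pooled-variance independent two-sample t-test, also computable directly
  from published summary statistics (n, mean, SD per group);
* interobserver agreement: ICC(2,1) (two-way random effects, absolute
  agreement, single measures) with an F-based 95% CI, and Bland-Altman
  bias / limits of agreement;
* ROC analysis with the Mann-Whitney tie convention (ties count 1/2),
  Youden-optimal cutoff, and DeLong variance for AUC confidence intervals
  and paired AUC comparisons.

The DeLong machinery uses the placement-value (midrank) formulation. No
multiple-testing correction is applied; this is recorded in the report
metadata.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .model_fitting import MAP_NAMES

__all__ = [
    "TTestResult",
    "IccResult",
    "BlandAltmanResult",
    "RocResult",
    "DiagnosticReport",
    "ks_normality",
    "independent_t_test",
    "summary_t_test",
    "icc_two_reader",
    "bland_altman",
    "roc_analysis",
    "youden_from_rates",
    "delong_compare",
    "build_report",
]

POSITIVE_GROUP = "progression"

_BANDS = [
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "good"),
    (1.00, "excellent"),
]


def _agreement_band(icc: float) -> str:
    for cut, label in _BANDS:
        if icc <= cut:
            return label
    return "excellent"


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    degenerate: bool = False


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str = "ICC(2,1)"
    band: str = ""
    n_subjects: int = 0
    n_dropped: int = 0


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    higher_is_positive: bool


@dataclass
class DiagnosticReport:
    """Per-parameter statistics plus pairwise AUC comparisons."""

    t_tests: dict[str, TTestResult]
    normality: dict[str, dict[str, tuple[float, float]]]
    roc: dict[str, RocResult]
    icc: dict[str, IccResult] | None
    bland_altman: dict[str, BlandAltmanResult] | None
    delong_pairs: dict[str, float]
    positive_group: str = POSITIVE_GROUP
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "positive_group": self.positive_group,
            "metadata": self.metadata,
            "t_tests": {k: asdict(v) for k, v in self.t_tests.items()},
            "normality": self.normality,
            "roc": {k: asdict(v) for k, v in self.roc.items()},
            "delong_pairs": self.delong_pairs,
        }
        out["icc"] = (
            {k: asdict(v) for k, v in self.icc.items()} if self.icc else None
        )
        out["bland_altman"] = (
            {k: asdict(v) for k, v in self.bland_altman.items()}
            if self.bland_altman
            else None
        )
        return out

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))

    def group_comparison_table(self) -> pd.DataFrame:
        """Means +/- SD per group with t, p, ICC (diffusivities x 1e3)."""
        rows = []
        for name in self.t_tests:
            scale = 1e3 if name in ("adc", "d", "d_star", "ddc") else 1.0
            r = self.t_tests[name]
            rows.append(
                {
                    "parameter": name,
                    "mean_pos": r.mean1 * scale,
                    "sd_pos": r.sd1 * scale,
                    "mean_neg": r.mean2 * scale,
                    "sd_neg": r.sd2 * scale,
                    "t": abs(r.t),
                    "p": r.p,
                    "icc": self.icc[name].icc if self.icc else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def diagnostic_table(self) -> pd.DataFrame:
        """AUC, 95% CI, cutoff, Youden, sensitivity, specificity."""
        rows = []
        for name, r in self.roc.items():
            scale = 1e3 if name in ("adc", "d", "d_star", "ddc") else 1.0
            rows.append(
                {
                    "parameter": name,
                    "auc": r.auc,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "cutoff": r.cutoff * scale,
                    "youden": r.youden_j,
                    "sensitivity_pct": r.sensitivity * 100,
                    "specificity_pct": r.specificity * 100,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# normality and t-tests


def ks_normality(sample: Sequence[float]) -> tuple[float, float, bool]:
    """Lilliefors-corrected KS test against a fitted normal.

    Returns (D, p, degenerate); a zero-variance sample is flagged
    degenerate rather than tested.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("normality test needs at least 3 observations")
    if np.ptp(x) == 0:
        return 0.0, float("nan"), True
    d, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(d), float(p), False


def independent_t_test(
    group1: Sequence[float], group2: Sequence[float]
) -> TTestResult:
    """Pooled-variance (Student) two-sample t-test, two-sided."""
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each group needs at least 2 observations")
    return summary_t_test(
        x1.size, x1.mean(), x1.std(ddof=1), x2.size, x2.mean(), x2.std(ddof=1)
    )


def summary_t_test(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> TTestResult:
    """Pooled t-test straight from per-group summary statistics."""
    df = n1 + n2 - 2
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return TTestResult(
                float("nan"), df, float("nan"), mean1, sd1, n1, mean2, sd2, n2,
                degenerate=True,
            )
        t = float("inf") if mean1 > mean2 else float("-inf")
        return TTestResult(t, df, 0.0, mean1, sd1, n1, mean2, sd2, n2)
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return TTestResult(float(t), df, float(p), mean1, sd1, n1, mean2, sd2, n2)


# ---------------------------------------------------------------------------
# interobserver agreement


def icc_two_reader(
    reader1: Sequence[float], reader2: Sequence[float], alpha: float = 0.05
) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the two-way ANOVA mean squares; the 95% CI uses the
    F-distribution approximation with Satterthwaite degrees of freedom.
    Pairs with a missing value are dropped listwise (count reported).
    """
    r1 = np.asarray(reader1, dtype=float)
    r2 = np.asarray(reader2, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError("reader vectors must be paired (equal length)")
    keep = np.isfinite(r1) & np.isfinite(r2)
    dropped = int((~keep).sum())
    r1, r2 = r1[keep], r2[keep]
    n = r1.size
    if n < 5:
        raise ValueError("ICC needs at least 5 complete pairs")
    k = 2
    data = np.column_stack([r1, r2])
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ssr = k * np.sum((subj_means - grand) ** 2)
    ssc = n * np.sum((rater_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:  # all readings identical
        return IccResult(1.0, 1.0, 1.0, band="excellent", n_subjects=n,
                         n_dropped=dropped)
    icc = (msr - mse) / denom

    if mse == 0:
        lb = ub = 1.0
    else:
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (
            k * icc * fj + n * (1 + (k - 1) * icc) - k * icc
        ) ** 2
        vd = (n - 1) * (k * icc * fj) ** 2 + (
            n * (1 + (k - 1) * icc) - k * icc
        ) ** 2
        v = vn / vd
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lb = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        ub = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr
        )
    lb, ub = float(min(lb, icc)), float(max(ub, icc))
    return IccResult(
        float(icc), lb, ub, band=_agreement_band(icc), n_subjects=n,
        n_dropped=dropped,
    )


def bland_altman(
    reader1: Sequence[float], reader2: Sequence[float]
) -> BlandAltmanResult:
    """Bias and 95% limits of agreement (bias +/- 1.96 SD of differences)."""
    r1 = np.asarray(reader1, dtype=float)
    r2 = np.asarray(reader2, dtype=float)
    if r1.shape != r2.shape or r1.size < 2:
        raise ValueError("Bland-Altman needs >= 2 paired observations")
    diff = r1 - r2
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        n=r1.size,
    )


# ---------------------------------------------------------------------------
# ROC / DeLong


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_placements(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Placement values and AUCs for k score vectors on shared subjects.

    ``scores`` is (k, N); labels are binary with 1 = positive. Returns
    (aucs, v_pos, v_neg) where v_pos is (k, m) and v_neg is (k, n).
    """
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    k = scores.shape[0]
    aucs = np.empty(k)
    v_pos = np.empty((k, m))
    v_neg = np.empty((k, n))
    for r in range(k):
        x, y = scores[r, pos], scores[r, ~pos]
        tx = _midrank(x)
        ty = _midrank(y)
        tz = _midrank(np.concatenate([x, y]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
        v_pos[r] = (tz[:m] - tx) / n
        v_neg[r] = 1.0 - (tz[m:] - ty) / m
    return aucs, v_pos, v_neg


def _delong_cov(v_pos: np.ndarray, v_neg: np.ndarray) -> np.ndarray:
    # a class with a single subject contributes no estimable variance
    k = v_pos.shape[0]
    m, n = v_pos.shape[1], v_neg.shape[1]
    s_pos = np.atleast_2d(np.cov(v_pos)) if m > 1 else np.zeros((k, k))
    s_neg = np.atleast_2d(np.cov(v_neg)) if n > 1 else np.zeros((k, k))
    return s_pos / m + s_neg / n


def _check_labels(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly two classes present")


def youden_from_rates(sensitivity: float, specificity: float) -> float:
    """Youden index J = sensitivity + specificity - 1."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return sensitivity + specificity - 1.0


def roc_analysis(values: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Empirical ROC with Youden-optimal cutoff and DeLong 95% CI.

    Ties follow the Mann-Whitney convention (1/2 credit). Orientation is
    chosen automatically so AUC >= 0.5 and recorded in
    ``higher_is_positive``; the cutoff is reported on the original scale,
    at a midpoint between consecutive observed values. Among cutoffs tying
    on Youden J, the one with higher specificity wins.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    _check_labels(y)
    y = (y == np.max(y)).astype(int)
    aucs, v_pos, v_neg = _delong_placements(v[None, :], y)
    auc = float(aucs[0])
    higher_is_positive = auc >= 0.5
    scores = v if higher_is_positive else -v
    if not higher_is_positive:
        auc = 1.0 - auc
    var = float(_delong_cov(v_pos, v_neg)[0, 0])
    half = 1.96 * np.sqrt(var)
    ci_low, ci_high = max(0.0, auc - half), min(1.0, auc + half)

    pos_scores = scores[y == 1]
    neg_scores = scores[y == 0]
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = (pos_scores[None, :] > thresholds[:, None]).mean(axis=1)
    spec = (neg_scores[None, :] <= thresholds[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    best_j = j.max()
    candidates = np.nonzero(np.isclose(j, best_j))[0]
    best = candidates[np.argmax(spec[candidates])]
    cutoff = float(thresholds[best] if higher_is_positive else -thresholds[best])
    return RocResult(
        auc=auc,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        cutoff=cutoff,
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        youden_j=float(j[best]),
        higher_is_positive=higher_is_positive,
    )


def delong_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    labels: Sequence[int],
    higher_is_positive: tuple[bool, bool] = (True, True),
) -> tuple[float, float, float]:
    """Paired DeLong test for two correlated AUCs on the same subjects.

    ``higher_is_positive`` states, per marker, which direction counts as
    disease-positive; markers whose flag is False are negated before the
    comparison. The orientation must be chosen by the caller (e.g. from
    the known direction of the group difference) — deciding it from the
    same data inside the test would bias it. Returns (auc_a, auc_b,
    two-sided p); identical oriented scores give p = 1 exactly.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    y = np.asarray(labels)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("both score vectors must cover the same subjects")
    _check_labels(y)
    y = (y == np.max(y)).astype(int)
    scores = np.vstack(
        [a if higher_is_positive[0] else -a, b if higher_is_positive[1] else -b]
    )
    aucs, v_pos, v_neg = _delong_placements(scores, y)
    cov = _delong_cov(v_pos, v_neg)
    diff = aucs[0] - aucs[1]
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        p = 1.0 if np.isclose(diff, 0.0) else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), p


# ---------------------------------------------------------------------------
# full report


def build_report(
    table: pd.DataFrame, positive_group: str = POSITIVE_GROUP
) -> DiagnosticReport:
    """Run the full statistics chain on a per-(subject, reader) lesion table.

    Group statistics (t-test, ROC, DeLong) use reader-averaged values per
    subject; agreement statistics (ICC, Bland-Altman) use the first two
    readers and are omitted (None) for single-reader tables.
    """
    required = {"subject", "group", "reader"} | set(MAP_NAMES)
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"lesion table is missing columns: {sorted(missing)}")
    groups = sorted(table["group"].unique())
    if len(groups) != 2 or positive_group not in groups:
        raise ValueError(
            f"need two groups including {positive_group!r}, got {groups}"
        )
    negative_group = next(g for g in groups if g != positive_group)

    readers = sorted(table["reader"].unique())
    averaged = (
        table.groupby(["subject", "group"], as_index=False)[list(MAP_NAMES)]
        .mean()
        .sort_values("subject")
        .reset_index(drop=True)
    )
    labels = (averaged["group"] == positive_group).astype(int).to_numpy()

    t_tests, normality, roc = {}, {}, {}
    for name in MAP_NAMES:
        pos_vals = averaged.loc[labels == 1, name].to_numpy()
        neg_vals = averaged.loc[labels == 0, name].to_numpy()
        t_tests[name] = independent_t_test(pos_vals, neg_vals)
        normality[name] = {
            positive_group: ks_normality(pos_vals)[:2],
            negative_group: ks_normality(neg_vals)[:2],
        }
        roc[name] = roc_analysis(averaged[name].to_numpy(), labels)

    icc_res = ba_res = None
    if len(readers) >= 2:
        wide = table[table["reader"].isin(readers[:2])].pivot(
            index="subject", columns="reader", values=list(MAP_NAMES)
        )
        icc_res, ba_res = {}, {}
        for name in MAP_NAMES:
            r1 = wide[(name, readers[0])].to_numpy()
            r2 = wide[(name, readers[1])].to_numpy()
            icc_res[name] = icc_two_reader(r1, r2)
            ba_res[name] = bland_altman(r1, r2)

    # marker orientation fixed by each ROC's reported direction
    delong_pairs = {
        f"{a}_vs_{b}": delong_compare(
            averaged[a].to_numpy(),
            averaged[b].to_numpy(),
            labels,
            higher_is_positive=(
                roc[a].higher_is_positive, roc[b].higher_is_positive,
            ),
        )[2]
        for a, b in combinations(MAP_NAMES, 2)
    }

    return DiagnosticReport(
        t_tests=t_tests,
        normality=normality,
        roc=roc,
        icc=icc_res,
        bland_altman=ba_res,
        delong_pairs=delong_pairs,
        positive_group=positive_group,
        metadata={
            "n_readers": len(readers),
            "multiple_testing_correction": "none",
            "groups": {
                positive_group: int(labels.sum()),
                negative_group: int((1 - labels).sum()),
            },
        },
    )
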