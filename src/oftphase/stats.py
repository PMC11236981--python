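"""Nonparametric screening of phase-derived features.

Each feature is evaluated independently: assumption checks (Shapiro-Wilk on
standardized residuals, Levene across groups) justify the nonparametric
branch; a Kruskal-Wallis omnibus test asks whether the feature's median
differs between any of the particle classes, and pairwise Mann-Whitney tests
localize which class pairs differ. The significance level defaults to 0.05
and, mirroring the per-feature evaluation protocol, no multiple-testing
correction is applied by default; Holm correction within each feature's
pairwise family is available and labeled in the report.

Mann-Whitney U convention: U counts the first sample's wins — (a, b) pairs
with a > b plus half the ties — so 0 <= U <= n1*n2 and U = n1*n2/2 under
exchangeability. The p-value is exact (enumeration) for tie-free samples
with n1+n2 <= 12, and a tie-corrected normal approximation with continuity
correction otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError
from .features import FEATURE_COLUMNS

__all__ = [
    "TestResult",
    "AssumptionReport",
    "StatReport",
    "check_assumptions",
    "kruskal_wallis",
    "mann_whitney",
    "screen_features",
]

EXACT_MW_MAX_N = 12


@dataclass
class TestResult:
    """One hypothesis-test outcome for one feature."""

    feature: str
    method: str
    test: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    alpha: float
    n_per_group: dict[str, int]
    p_adjusted: float | None = None

    @property
    def reject(self) -> bool:
        p = self.p_value if self.p_adjusted is None else self.p_adjusted
        return bool(p < self.alpha)

    def to_row(self) -> dict:
        return {
            "feature": self.feature,
            "method": self.method,
            "test": self.test,
            "groups": "|".join(self.groups),
            "statistic": self.statistic,
            "p_value": self.p_value,
            "p_adjusted": np.nan if self.p_adjusted is None else self.p_adjusted,
            "alpha": self.alpha,
            "reject": self.reject,
            "n_total": sum(self.n_per_group.values()),
        }


def _clean_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {}
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        if len(arr):
            out[str(label)] = arr
    return out


def kruskal_wallis(
    groups: Mapping[str, Sequence[float]],
    feature: str = "",
    method: str = "",
    alpha: float = 0.05,
) -> TestResult:
    """Rank-based omnibus test (tie-corrected H, chi-squared p, k-1 df)."""
    clean = _clean_groups(groups)
    if len(clean) < 2:
        raise DataError("Kruskal-Wallis requires at least 2 non-empty groups")
    pooled = np.concatenate(list(clean.values()))
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0  # every observation tied; tie-corrected H is 0
    else:
        h, p = _stats.kruskal(*clean.values())
    return TestResult(
        feature=feature, method=method, test="kruskal_wallis",
        groups=tuple(clean), statistic=float(h), p_value=float(p), alpha=alpha,
        n_per_group={k: len(v) for k, v in clean.items()},
    )


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
    feature: str = "",
    method: str = "",
    labels: tuple[str, str] = ("a", "b"),
    alpha: float = 0.05,
) -> TestResult:
    """Two-group rank test; see the module docstring for conventions."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise DataError("Mann-Whitney requires two non-empty groups")

    ranks = _stats.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0  # #(a > b) + ties/2

    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < n1 + n2
    if np.all(pooled == pooled[0]):
        p = 1.0
    elif not has_ties and n1 + n2 <= EXACT_MW_MAX_N:
        p = float(_stats.mannwhitneyu(a, b, alternative=alternative,
                                      method="exact").pvalue)
    else:
        p = float(_stats.mannwhitneyu(a, b, alternative=alternative,
                                      method="asymptotic",
                                      use_continuity=True).pvalue)
    return TestResult(
        feature=feature, method=method, test="mann_whitney",
        groups=labels, statistic=float(u), p_value=p, alpha=alpha,
        n_per_group={labels[0]: n1, labels[1]: n2},
    )


@dataclass
class AssumptionReport:
    """Normality / homogeneity-of-variance check for one feature."""

    feature: str
    method: str
    shapiro_p: float
    levene_p: float
    alpha: float
    flagged: bool = False

    @property
    def verdict(self) -> str:
        if self.flagged:
            return "nonparametric_required"
        bad = (self.shapiro_p < self.alpha) or (self.levene_p < self.alpha)
        return "nonparametric_required" if bad else "parametric_ok"

    def to_row(self) -> dict:
        return {
            "feature": self.feature, "method": self.method,
            "shapiro_p": self.shapiro_p, "levene_p": self.levene_p,
            "verdict": self.verdict, "alpha": self.alpha,
        }


def check_assumptions(
    groups: Mapping[str, Sequence[float]],
    feature: str = "",
    method: str = "",
    alpha: float = 0.05,
) -> AssumptionReport:
    """Shapiro-Wilk on standardized residuals, Levene across groups.

    Residuals are (value - group mean) / group std. Groups smaller than 3
    observations or with zero variance cannot be checked: the report is
    flagged and the verdict defaults to ``nonparametric_required``.
    """
    clean = _clean_groups(groups)
    if len(clean) < 2:
        raise DataError("assumption checks require at least 2 non-empty groups")
    if any(len(v) < 3 or v.std() == 0.0 for v in clean.values()):
        return AssumptionReport(feature=feature, method=method,
                                shapiro_p=float("nan"), levene_p=float("nan"),
                                alpha=alpha, flagged=True)
    residuals = np.concatenate([(v - v.mean()) / v.std() for v in clean.values()])
    shapiro_p = float(_stats.shapiro(residuals).pvalue)
    levene_p = float(_stats.levene(*clean.values()).pvalue)
    return AssumptionReport(feature=feature, method=method,
                            shapiro_p=shapiro_p, levene_p=levene_p, alpha=alpha)


@dataclass
class StatReport:
    """Omnibus + pairwise screening results over all (feature, method) cells."""

    alpha: float
    correction: str
    level: str
    omnibus: list[TestResult] = field(default_factory=list)
    pairwise: list[TestResult] = field(default_factory=list)
    assumptions: list[AssumptionReport] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(r.to_row(), stage="omnibus") for r in self.omnibus]
        rows += [dict(r.to_row(), stage="pairwise") for r in self.pairwise]
        frame = pd.DataFrame(rows)
        frame["correction"] = self.correction
        frame["level"] = self.level
        return frame

    def omnibus_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.omnibus])

    def pairwise_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.pairwise])

    def assumptions_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.assumptions])

    def summary(self) -> str:
        lines = [
            f"feature screening at alpha={self.alpha} "
            f"(correction={self.correction}, level={self.level})",
            f"omnibus cells: {len(self.omnibus)}  "
            f"significant: {sum(r.reject for r in self.omnibus)}",
            f"pairwise cells: {len(self.pairwise)}  "
            f"significant: {sum(r.reject for r in self.pairwise)}",
        ]
        if self.omnibus:
            frame = self.omnibus_frame()
            for method, sub in frame.groupby("method"):
                coeff = sub[sub.feature.str.startswith("Coeff_")]
                if len(coeff):
                    lines.append(
                        f"  {method}: coefficient omnibus p range "
                        f"[{coeff.p_value.min():.3g}, {coeff.p_value.max():.3g}]"
                    )
        return "\n".join(lines)


def _grouped(table: pd.DataFrame, feature: str, level: str) -> dict[str, np.ndarray]:
    if level == "acquisition_median":
        agg = table.groupby(["class_label", "parent_id"])[feature].median()
        return {lbl: agg.xs(lbl).to_numpy() for lbl in agg.index.get_level_values(0).unique()}
    return {
        str(lbl): sub[feature].to_numpy()
        for lbl, sub in table.groupby("class_label")
    }


def screen_features(
    table: pd.DataFrame,
    alpha: float = 0.05,
    correction: Literal["none", "holm"] = "none",
    level: Literal["epoch", "acquisition_median"] = "epoch",
    features: Sequence[str] | None = None,
) -> StatReport:
    """Run the full screening protocol on a feature table.

    For every (feature, method) cell: one omnibus Kruskal-Wallis test across
    all classes and Mann-Whitney tests for every class pair. ``level``
    selects the replication unit: raw epochs (default) or per-acquisition
    medians (which treats epochs from one trapped particle as
    pseudo-replicates).
    """
    if "class_label" not in table.columns:
        raise DataError("feature table lacks a class_label column")
    if table["class_label"].nunique() < 2:
        raise DataError("screening requires at least 2 classes")
    if "epoch_id" in table.columns:
        # canonical row order so results are bit-reproducible regardless of
        # how the table was assembled
        table = table.sort_values(["method", "class_label", "epoch_id"],
                                  kind="stable", ignore_index=True)
    features = list(features) if features is not None else [
        c for c in FEATURE_COLUMNS if c in table.columns
    ]
    report = StatReport(alpha=alpha, correction=correction, level=level)
    for method, sub in table.groupby("method", sort=True):
        labels = sorted(sub["class_label"].unique())
        for feat in features:
            groups = _grouped(sub, feat, level)
            report.assumptions.append(
                check_assumptions(groups, feature=feat, method=method, alpha=alpha)
            )
            report.omnibus.append(
                kruskal_wallis(groups, feature=feat, method=method, alpha=alpha)
            )
            family = []
            for la, lb in itertools.combinations(labels, 2):
                if la not in groups or lb not in groups:
                    continue
                family.append(
                    mann_whitney(groups[la], groups[lb], feature=feat,
                                 method=method, labels=(la, lb), alpha=alpha)
                )
            if correction == "holm" and family:
                adj = multipletests([r.p_value for r in family],
                                    alpha=alpha, method="holm")[1]
                for res, p_adj in zip(family, adj):
                    res.p_adjusted = float(p_adj)
            report.pairwise.extend(family)
    return report
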