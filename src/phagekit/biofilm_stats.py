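"""Normality-gated two-group comparison for biofilm assay data.

Biofilm experiments yield either crystal-violet absorbance (paired wells,
treated vs untreated) or confocal viable-cell counts per field (independent
groups).  The analysis route is gated on normality: both groups are tested
with Shapiro-Wilk; if both pass (p > alpha) and the design is paired, a
two-sided paired t-test compares the means; otherwise a two-sided
Mann-Whitney U test is used (exact enumeration when both groups have n <= 8
and no ties, tie-corrected normal approximation with continuity correction
otherwise).  Significance is declared at p < 0.05.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

ALPHA = 0.05
EXACT_MWU_MAX_N = 8


@dataclass
class TwoGroupData:
    group_a: np.ndarray
    group_b: np.ndarray
    paired: bool = False
    labels: tuple[str, str] = ("control", "treated")

    def __post_init__(self):
        self.group_a = np.asarray(self.group_a, dtype=float)
        self.group_b = np.asarray(self.group_b, dtype=float)
        if len(self.group_a) < 3 or len(self.group_b) < 3:
            raise ValueError("each group needs at least 3 measurements")
        if self.paired and len(self.group_a) != len(self.group_b):
            raise ValueError("paired comparison requires equal group sizes")


@dataclass
class TestReport:
    normality_p: tuple[float, float]
    test_used: str  # "paired_t" or "mann_whitney_u"
    statistic: float
    p_value: float
    significant: bool
    labels: tuple[str, str] = ("control", "treated")

    def to_dict(self) -> dict:
        return {
            "normality_p": list(self.normality_p),
            "test_used": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "significant": self.significant,
            "labels": list(self.labels),
        }

    def summary(self) -> str:
        p = "p < 0.001" if self.p_value < 0.001 else f"p = {self.p_value:.3g}"
        verdict = "significant" if self.significant else "not significant"
        return f"{self.labels[0]} vs {self.labels[1]}: {self.test_used}, {p} ({verdict})"


def shapiro_wilk(sample) -> float:
    """Shapiro-Wilk normality p-value (higher = more consistent with normal)."""
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if len(x) > 5000:
        raise ValueError("Shapiro-Wilk p-value unreliable above n = 5000")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: zero variance")
    return float(stats.shapiro(x).pvalue)


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if len(a) <= EXACT_MWU_MAX_N and len(b) <= EXACT_MWU_MAX_N and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def gated_compare(data: TwoGroupData, alpha_normality: float = ALPHA) -> TestReport:
    """Two-group comparison with the normality-gated test choice.

    Paired t-test only when both groups pass Shapiro-Wilk at alpha_normality
    AND the design is paired; Mann-Whitney U otherwise.
    """
    p_a = shapiro_wilk(data.group_a)
    p_b = shapiro_wilk(data.group_b)
    normal = p_a > alpha_normality and p_b > alpha_normality
    if normal and data.paired:
        res = stats.ttest_rel(data.group_a, data.group_b)
        stat, p = float(res.statistic), float(res.pvalue)
        test = "paired_t"
    else:
        stat, p = _mann_whitney(data.group_a, data.group_b)
        test = "mann_whitney_u"
    return TestReport(
        normality_p=(p_a, p_b),
        test_used=test,
        statistic=stat,
        p_value=p,
        significant=p < ALPHA,
        labels=data.labels,
    )


def read_two_group_tsv(path: str | Path, paired: bool = False) -> TwoGroupData:
    """Read two-column or long-format (group, value) TSV into TwoGroupData."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if {"group", "value"}.issubset(df.columns):
        labels = list(dict.fromkeys(df["group"].astype(str)))
        if len(labels) != 2:
            raise ValueError(f"expected exactly 2 groups, found {labels}")
        a = df.loc[df["group"].astype(str) == labels[0], "value"].to_numpy()
        b = df.loc[df["group"].astype(str) == labels[1], "value"].to_numpy()
        return TwoGroupData(a, b, paired=paired, labels=(labels[0], labels[1]))
    if df.shape[1] >= 2:
        cols = list(df.columns[:2])
        return TwoGroupData(
            df[cols[0]].dropna().to_numpy(),
            df[cols[1]].dropna().to_numpy(),
            paired=paired,
            labels=(str(cols[0]), str(cols[1])),
        )
    raise ValueError("TSV must be two-column or long format with group/value columns")


def write_report(report: TestReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
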