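"""Effectiveness statistics over gRNA cohorts.

A guide is *effective* when its efficiency (mutation rate) is strictly
greater than 1%. Between two chromatin groups the module forms the 2x2
effective/ineffective contingency table and its odds ratio ad/(bc), compares
mean efficiencies with a Welch (unpaired) or paired t-test, discretizes
rates into the <=1% / 1-15% / 15-30% / >30% bins, and computes per-pair rate
differences for the co-injection design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

EFFECTIVE_THRESHOLD = 0.01
RATE_CUTS = (0.01, 0.15, 0.30)
RATE_BIN_LABELS = ("<=1%", "1-15%", "15-30%", ">30%")


def classify_effective(efficiency: float, threshold: float = EFFECTIVE_THRESHOLD) -> bool:
    """Effective iff efficiency is strictly greater than the threshold."""
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError(f"efficiency {efficiency} outside [0, 1]")
    return efficiency > threshold


@dataclass(frozen=True)
class ContingencyTable:
    """a/b: group-1 effective/ineffective; c/d: group-2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def group1_proportion(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def group2_proportion(self) -> float:
        return self.c / (self.c + self.d)


@dataclass
class OddsRatioResult:
    odds_ratio: float
    table: ContingencyTable
    group1_proportion: float
    group2_proportion: float
    haldane_corrected: bool = False


def odds_ratio(table: ContingencyTable) -> OddsRatioResult:
    """OR = ad/(bc); zero cells fall back to the Haldane +0.5 correction."""
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        warnings.warn("zero cell in contingency table; applying Haldane +0.5 correction")
        or_ = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        or_ = (a * d) / (b * c)
    return OddsRatioResult(
        odds_ratio=float(or_),
        table=table,
        group1_proportion=table.group1_proportion,
        group2_proportion=table.group2_proportion,
        haldane_corrected=corrected,
    )


def contingency_from_counts(
    n1: int, pct1: float, n2: int, pct2: float
) -> ContingencyTable:
    """Build the 2x2 table from group sizes and printed effective percentages.

    The effective counts are the percentages times the group sizes rounded to
    the nearest integer (the convention used to reconstruct counts from a
    published proportion).
    """
    a = int(round(pct1 * n1))
    c = int(round(pct2 * n2))
    return ContingencyTable(a=a, b=n1 - a, c=c, d=n2 - c)


def cohort_contingency(
    cohort: pd.DataFrame,
    group1: str,
    group2: str,
    label_col: str = "label",
    threshold: float = EFFECTIVE_THRESHOLD,
) -> ContingencyTable:
    eff = cohort["efficiency"].apply(lambda x: classify_effective(x, threshold))
    g1 = cohort[label_col] == group1
    g2 = cohort[label_col] == group2
    return ContingencyTable(
        a=int((g1 & eff).sum()), b=int((g1 & ~eff).sum()),
        c=int((g2 & eff).sum()), d=int((g2 & ~eff).sum()),
    )


@dataclass
class GroupComparison:
    statistic: float
    pvalue: float
    mean1: float
    mean2: float
    n1: int
    n2: int
    paired: bool
    degenerate: bool = False


def compare_groups(
    values1: Sequence[float],
    values2: Sequence[float],
    paired: bool = False,
    equal_var: bool = False,
) -> GroupComparison:
    """Two-sided comparison of mean efficiency between two groups.

    Unpaired uses the Welch t-test by default (``equal_var=True`` for the
    pooled-variance variant); paired tests the within-pair differences, which
    requires equal-length, pair-ordered inputs.
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if paired:
        if v1.size != v2.size:
            raise ValueError("paired comparison needs equal-length groups")
        if v1.size < 2:
            raise ValueError("need >= 2 complete pairs")
        diffs = v1 - v2
        if np.allclose(diffs.std(ddof=1), 0.0):
            return GroupComparison(0.0, 1.0, v1.mean(), v2.mean(), v1.size, v2.size,
                                   paired=True, degenerate=True)
        stat, p = sps.ttest_rel(v1, v2)
    else:
        if v1.size < 2 or v2.size < 2:
            raise ValueError("need >= 2 values per group")
        if np.allclose(v1.std(ddof=1), 0.0) and np.allclose(v2.std(ddof=1), 0.0):
            equal_means = np.isclose(v1.mean(), v2.mean())
            return GroupComparison(
                0.0 if equal_means else np.inf, 1.0 if equal_means else 0.0,
                v1.mean(), v2.mean(), v1.size, v2.size, paired=False, degenerate=True,
            )
        stat, p = sps.ttest_ind(v1, v2, equal_var=equal_var)
    return GroupComparison(float(stat), float(p), float(v1.mean()), float(v2.mean()),
                           int(v1.size), int(v2.size), paired=paired)


def compare_cohort_groups(
    cohort: pd.DataFrame,
    group1: str,
    group2: str,
    label_col: str = "label",
    paired: bool = False,
    effective_only: bool = False,
    threshold: float = EFFECTIVE_THRESHOLD,
    equal_var: bool = False,
) -> GroupComparison:
    """Group comparison straight from a cohort table.

    ``effective_only`` restricts to effective guides (the restriction used
    when comparing mutation-rate distributions among working guides). Paired
    mode orders both groups by pair identifier and requires complete pairs.
    """
    df = cohort
    if effective_only:
        df = df[df["efficiency"].apply(lambda x: classify_effective(x, threshold))]
    if paired:
        diffs = pair_differences(df, group1, group2, label_col)
        return compare_groups(diffs[f"rate_{group1}"], diffs[f"rate_{group2}"], paired=True)
    v1 = df.loc[df[label_col] == group1, "efficiency"]
    v2 = df.loc[df[label_col] == group2, "efficiency"]
    return compare_groups(v1, v2, paired=False, equal_var=equal_var)


def discretize_rates(
    efficiencies: Sequence[float], cuts: Tuple[float, ...] = RATE_CUTS
) -> Dict[str, int]:
    """Bin efficiencies into (<=1%], (1,15%], (15,30%], (>30%) with strict '>'.

    A rate exactly at a cut point falls in the lower bin.
    """
    vals = np.asarray(efficiencies, dtype=float)
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("efficiencies outside [0, 1]")
    labels = _bin_labels(cuts)
    counts = {lab: 0 for lab in labels}
    for v in vals:
        idx = int(sum(v > c for c in cuts))
        counts[labels[idx]] += 1
    return counts


def _bin_labels(cuts: Tuple[float, ...]) -> List[str]:
    if cuts == RATE_CUTS:
        return list(RATE_BIN_LABELS)
    labs = [f"<={cuts[0]:g}"]
    labs += [f"{cuts[i]:g}-{cuts[i + 1]:g}" for i in range(len(cuts) - 1)]
    labs.append(f">{cuts[-1]:g}")
    return labs


def pair_differences(
    cohort: pd.DataFrame,
    group1: str = "OC",
    group2: str = "CC",
    label_col: str = "label",
) -> pd.DataFrame:
    """Per-pair signed rate difference (group1 - group2), ordered by pair id."""
    rows = []
    for pair_id, grp in cohort[cohort["pair_id"] != ""].groupby("pair_id"):
        g1 = grp[grp[label_col] == group1]
        g2 = grp[grp[label_col] == group2]
        if len(g1) != 1 or len(g2) != 1:
            raise ValueError(f"incomplete or malformed pair {pair_id!r}")
        r1 = float(g1["efficiency"].iloc[0])
        r2 = float(g2["efficiency"].iloc[0])
        rows.append({"pair_id": pair_id, f"rate_{group1}": r1, f"rate_{group2}": r2,
                     "difference": r1 - r2})
    out = pd.DataFrame(rows, columns=["pair_id", f"rate_{group1}", f"rate_{group2}",
                                      "difference"]).sort_values("pair_id")
    return out.reset_index(drop=True)


def cohort_report(
    cohort: pd.DataFrame,
    group1: str,
    group2: str,
    label_col: str = "label",
    paired: bool = False,
    threshold: float = EFFECTIVE_THRESHOLD,
) -> Dict:
    """Full statistics bundle for one cohort comparison (JSON-serializable)."""
    table = cohort_contingency(cohort, group1, group2, label_col, threshold)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        orr = odds_ratio(table)
    full = compare_cohort_groups(cohort, group1, group2, label_col, paired=paired)
    eff_only = None
    n_eff = int(cohort["efficiency"].gt(threshold).sum())
    if not paired and n_eff >= 4:
        try:
            cmp_eff = compare_cohort_groups(
                cohort, group1, group2, label_col, effective_only=True
            )
            eff_only = {"statistic": cmp_eff.statistic, "pvalue": cmp_eff.pvalue}
        except ValueError:
            eff_only = None
    bins = {
        grp: discretize_rates(cohort.loc[cohort[label_col] == grp, "efficiency"])
        for grp in (group1, group2)
    }
    report = {
        "groups": [group1, group2],
        "contingency": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "odds_ratio": orr.odds_ratio,
        "haldane_corrected": orr.haldane_corrected,
        "effective_proportions": {
            group1: table.group1_proportion,
            group2: table.group2_proportion,
        },
        "comparison": {
            "paired": paired,
            "statistic": full.statistic,
            "pvalue": full.pvalue,
            "means": {group1: full.mean1, group2: full.mean2},
        },
        "effective_only_comparison": eff_only,
        "rate_bins": bins,
    }
    if paired:
        diffs = pair_differences(cohort, group1, group2, label_col)
        report["mean_pair_difference"] = float(diffs["difference"].mean())
    return report
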