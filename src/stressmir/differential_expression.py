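"""RPM normalization, chi-square testing and two-tier significance.

Per-miRNA abundances are normalized to reads per million (RPM) of the
library's clean-read total; a zero raw expression is adjusted to an
RPM of 0.01 before comparison.  Fold change is log2(treatment 1 /
treatment 2).  Significance uses a Pearson chi-square test on the 2x2
table [count, remainder] x [library 1, library 2] (df = 1, no
continuity correction) combined with the fold change:

* ``**`` (extremely significant): |fold change| >= 1 and p <= 0.01
* ``*``  (significant):           |fold change| >= 1 and 0.01 < p <= 0.05
* ``ns`` otherwise

A Benjamini-Hochberg FDR column is emitted alongside the raw p-values
but plays no part in the classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ZERO_ADJUST = 0.01

PAIRS = (("drought", "control"), ("salt", "control"), ("salt", "drought"))


@dataclass
class ComparisonResult:
    mirna_id: str
    pair: tuple[str, str]
    fold_change: float
    chi2: float
    p_value: float
    stat_tier: str  # chi-square alone: ** / * / ns
    expr_tier: str  # fold change + p combined: ** / * / ns
    testable: bool = True


def normalize_rpm(
    raw_counts: Mapping[str, Mapping[str, int]] | pd.DataFrame,
    library_totals: Mapping[str, int],
) -> pd.DataFrame:
    """Reads-per-million matrix: count / clean-library-total * 1e6."""
    df = pd.DataFrame(raw_counts).T if not isinstance(raw_counts, pd.DataFrame) else raw_counts
    totals = pd.Series(library_totals, dtype=float)
    if (totals <= 0).any():
        raise ValueError("library totals must be positive")
    return df / totals * 1e6


def adjust_zero(rpm: float) -> float:
    """Zero expression is reported as 0.01 RPM; positives untouched."""
    return ZERO_ADJUST if rpm == 0 else rpm


def fold_change(rpm_t1: float, rpm_t2: float) -> float:
    """log2(treatment 1 / treatment 2) on zero-adjusted RPM values."""
    return float(np.log2(adjust_zero(rpm_t1) / adjust_zero(rpm_t2)))


def chi2_test(count1: int, total1: int, count2: int, total2: int) -> tuple[float, float]:
    """Pearson chi-square on [[c1, t1-c1], [c2, t2-c2]], df=1, no correction.

    Returns (0, 1) when both counts are zero (a degenerate table with an
    expected cell of zero).
    """
    if not (0 <= count1 <= total1 and 0 <= count2 <= total2):
        raise ValueError("counts must satisfy 0 <= count <= total")
    if total1 <= 0 or total2 <= 0:
        raise ValueError("totals must be positive")
    if count1 + count2 == 0 or (total1 - count1) + (total2 - count2) == 0:
        return 0.0, 1.0
    obs = np.array([[count1, total1 - count1], [count2, total2 - count2]], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def classify(fc: float, p_value: float) -> str:
    """Two-tier expression significance from fold change and p-value."""
    if abs(fc) >= 1.0:
        if p_value <= 0.01:
            return "**"
        if p_value <= 0.05:
            return "*"
    return "ns"


def _stat_tier(p_value: float) -> str:
    if p_value <= 0.01:
        return "**"
    if p_value <= 0.05:
        return "*"
    return "ns"


def compare_pair(
    mirna_id: str,
    count1: int,
    total1: int,
    count2: int,
    total2: int,
    pair: tuple[str, str],
) -> ComparisonResult:
    """Full comparison of one miRNA between two libraries."""
    rpm1 = count1 / total1 * 1e6
    rpm2 = count2 / total2 * 1e6
    testable = not (count1 == 0 and count2 == 0)
    fc = fold_change(rpm1, rpm2) if testable else 0.0
    chi2, p = chi2_test(count1, total1, count2, total2)
    return ComparisonResult(
        mirna_id=mirna_id,
        pair=pair,
        fold_change=fc,
        chi2=chi2,
        p_value=p,
        stat_tier=_stat_tier(p) if testable else "ns",
        expr_tier=classify(fc, p) if testable else "ns",
        testable=testable,
    )


def compare_all(
    counts: pd.DataFrame,
    library_totals: Mapping[str, int],
    pairs: Sequence[tuple[str, str]] = PAIRS,
) -> pd.DataFrame:
    """Comparison table over all miRNAs and library pairs (Table-3 style).

    ``counts`` has one row per miRNA/family and one integer column per
    library.  Adds a Benjamini-Hochberg FDR per pair (informational;
    the tier classification uses the raw p-value).
    """
    rows = []
    for mid, row in counts.iterrows():
        for t1, t2 in pairs:
            r = compare_pair(
                mid, int(row[t1]), int(library_totals[t1]),
                int(row[t2]), int(library_totals[t2]), (t1, t2),
            )
            rows.append(
                {
                    "id": mid,
                    "pair": f"{t1}_vs_{t2}",
                    "fold_change": r.fold_change,
                    "chi2": r.chi2,
                    "p_value": r.p_value,
                    "stat_tier": r.stat_tier,
                    "expr_tier": r.expr_tier,
                    "testable": r.testable,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["fdr"] = df.groupby("pair")["p_value"].transform(_bh_fdr)
    return df


def _bh_fdr(p: pd.Series) -> pd.Series:
    n = len(p)
    order = np.argsort(p.values)
    ranked = p.values[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return pd.Series(out, index=p.index)


# ---------------------------------------------------------------------------
# Venn partition and summaries


def venn_partition(counts: pd.DataFrame) -> dict[frozenset, set]:
    """Partition ids by the set of libraries in which they are present.

    Presence means a raw count > 0.  Returns the seven non-empty
    membership patterns (patterns with no members map to empty sets).
    """
    libs = list(counts.columns)
    regions: dict[frozenset, set] = {
        frozenset(c): set()
        for k in range(1, len(libs) + 1)
        for c in combinations(libs, k)
    }
    for mid, row in counts.iterrows():
        present = frozenset(l for l in libs if row[l] > 0)
        if present:
            regions[present].add(mid)
    return regions


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Sample Pearson r, r^2 and the two-sided p (t distribution, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    r, p = stats.pearsonr(x, y)
    return float(r), float(r) ** 2, float(p)


def summarize(
    counts: pd.DataFrame,
    comparisons: pd.DataFrame,
    regions: Mapping[frozenset, set],
    category_percentages: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Named summary statistics over the whole experiment.

    Emits the totals, shared-in-all percentage (1 decimal), the DE
    fractions at p <= 0.05 and under the combined |FC| >= 1 rule
    (2 decimals), and, when a category table is given, the per-category
    mean percentages over the libraries.
    """
    libs = list(counts.columns)
    n = len(counts)
    shared = len(regions.get(frozenset(libs), set()))
    per_id_p05 = comparisons[comparisons.p_value <= 0.05]["id"].nunique()
    per_id_sig = comparisons[comparisons.expr_tier != "ns"]["id"].nunique()

    report: dict[str, float] = {
        "n_ids": float(n),
        "total_reads": float(counts.values.sum()),
        "shared_in_all_count": float(shared),
        "shared_in_all_pct": round(100.0 * shared / n, 1) if n else 0.0,
        "de_p05_count": float(per_id_p05),
        "de_p05_pct": round(100.0 * per_id_p05 / n, 2) if n else 0.0,
        "de_sig_count": float(per_id_sig),
        "de_sig_pct": round(100.0 * per_id_sig / n, 2) if n else 0.0,
    }
    if category_percentages is not None:
        pct_cols = [c for c in category_percentages.columns if c.endswith("_pct")]
        for kind in ("unique", "redundant"):
            cols = [c for c in pct_cols if c.startswith(kind)]
            if cols:
                means = category_percentages[cols].mean(axis=1)
                for name, val in means.items():
                    key = f"mean_{kind}_{name}_pct".replace(" ", "_").replace("(", "").replace(")", "").replace("/", "_")
                    report[key] = round(float(val), 2)
    return report


def mean_percentage(
    counts: Sequence[float],
    totals: Sequence[float],
    decimals: int = 2,
    per_library_decimals: int | None = 2,
) -> float:
    """Mean of per-library percentages 100*count/total.

    ``per_library_decimals`` rounds each library's percentage before
    averaging, matching how such means are reported from a printed
    categorization table; pass None to average the unrounded ratios.
    """
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if (totals <= 0).any():
        raise ValueError("totals must be positive")
    pct = 100.0 * counts / totals
    if per_library_decimals is not None:
        pct = np.round(pct, per_library_decimals)
    return round(float(np.mean(pct)), decimals)


def percentage(numerator: float, denominator: float, decimals: int = 1) -> float:
    """A printed percentage 100*num/den rounded as reported."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)
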