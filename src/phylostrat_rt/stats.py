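"""The nonparametric test battery used by the analysis report.

All tests report raw (uncorrected) two-sided p-values, mirroring common
practice for this kind of enrichment/correlation screen; the report layer
records how many tests were run.  Numerical work is delegated to
scipy.stats; the wrappers own the conventions: tie handling by midranks,
the exact/asymptotic switch for the rank-sum test, the Fisher fallback flag
for sparse 2x2 tables, and the effect sizes (fold enrichment, rank-biserial
correlation, Spearman rho, proportion difference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

__all__ = [
    "TestResult",
    "chi_squared_independence",
    "two_proportion_test",
    "wilcoxon_rank_sum",
    "spearman_correlation",
    "fold_enrichment",
    "results_to_frame",
]


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    df: Optional[float] = None
    effect: Optional[float] = None
    n: dict = field(default_factory=dict)
    method_notes: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise DataError(f"p-value {self.p_value} outside [0, 1]")


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise DataError("contingency table must be at least 2x2")
    if (arr < 0).any() or not np.all(np.mod(arr, 1) == 0):
        raise DataError("contingency table cells must be non-negative integers")
    return arr


def chi_squared_independence(table) -> TestResult:
    """Pearson chi-squared test of independence on an RxC table.

    No continuity correction.  For 2x2 tables with any expected cell below
    5 the Fisher exact p-value is reported alongside in ``method_notes``.
    Raises if any row or column sum is zero.
    """
    arr = _as_table(table)
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    if (row_sums == 0).any():
        raise DataError(f"zero row sum at row(s) {np.flatnonzero(row_sums == 0).tolist()}")
    if (col_sums == 0).any():
        raise DataError(
            f"zero column sum at column(s) {np.flatnonzero(col_sums == 0).tolist()}"
        )
    stat, p, dof, expected = sps.chi2_contingency(arr, correction=False)
    notes = ""
    if arr.shape == (2, 2) and (expected < 5).any():
        fisher_p = sps.fisher_exact(arr.astype(int))[1]
        notes = f"expected<5; fisher_p={fisher_p:.6g}"
    return TestResult(
        test_name="chi_squared",
        statistic=float(stat),
        df=float(dof),
        p_value=float(p),
        n={"total": int(arr.sum())},
        method_notes=notes,
    )


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Compare k1/n1 against k2/n2 via the 2x2 chi-squared test; effect is
    the difference of proportions."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise DataError(f"invalid proportion counts k={k}, n={n}")
    res = chi_squared_independence([[k1, n1 - k1], [k2, n2 - k2]])
    return TestResult(
        test_name="two_proportion",
        statistic=res.statistic,
        df=res.df,
        p_value=res.p_value,
        effect=k1 / n1 - k2 / n2,
        n={"n1": n1, "n2": n2},
        method_notes=res.method_notes,
    )


def wilcoxon_rank_sum(
    values_a: Sequence[float],
    values_b: Sequence[float],
    exact_threshold: int = 20,
) -> TestResult:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Uses the exact null distribution when both groups are small
    (min(n) <= ``exact_threshold``) and tie-free; otherwise the normal
    approximation with tie correction.  Effect is the rank-biserial
    correlation (positive when group A tends to be larger).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    use_exact = min(a.size, b.size) <= exact_threshold and not has_ties
    if use_exact:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        notes = "exact"
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        notes = "normal approximation, tie-corrected"
    u1 = float(res.statistic)
    p = float(min(res.pvalue, 1.0))
    effect = 2.0 * u1 / (a.size * b.size) - 1.0
    if np.isnan(p):  # zero variance everywhere: complete overlap
        p, effect = 1.0, 0.0
    return TestResult(
        test_name="wilcoxon_rank_sum",
        statistic=u1,
        p_value=p,
        effect=effect,
        n={"n_a": int(a.size), "n_b": int(b.size)},
        method_notes=notes,
    )


def spearman_correlation(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: Optional[int] = None,
    seed: Optional[int] = None,
) -> TestResult:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Pairs with a missing value are dropped; at least 3 complete pairs are
    required and both rank vectors must vary.  ``n_perm`` switches to a
    permutation p-value (useful at small n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise DataError(f"need at least 3 complete pairs, got {n}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DataError("zero variance in a rank vector; rho undefined")
    rho, p = sps.spearmanr(x, y)
    notes = "t approximation"
    if n_perm:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            r_perm, _ = sps.spearmanr(x, rng.permutation(y))
            if abs(r_perm) >= abs(rho) - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        notes = f"permutation ({n_perm})"
    return TestResult(
        test_name="spearman",
        statistic=float(rho),
        p_value=float(min(p, 1.0)),
        df=float(n - 2),
        effect=float(rho),
        n={"n": int(n)},
        method_notes=notes,
    )


def fold_enrichment(
    in_region_with_trait: int,
    in_region_total: int,
    genome_with_trait: int,
    genome_total: int,
) -> TestResult:
    """Fold enrichment of a trait in a region relative to the genome-wide
    rate, with a 2x2 chi-squared p-value (region vs rest of genome).

    The region must be a subset of the genome-wide universe.
    """
    if in_region_total <= 0 or genome_total <= 0:
        raise DataError("denominators must be positive")
    if genome_with_trait <= 0:
        raise DataError("zero genome-wide trait count")
    if in_region_with_trait > in_region_total or genome_with_trait > genome_total:
        raise DataError("counts exceed totals")
    if in_region_total > genome_total or in_region_with_trait > genome_with_trait:
        raise DataError("region counts exceed genome-wide counts")
    fold = (in_region_with_trait / in_region_total) / (
        genome_with_trait / genome_total
    )
    out_with = genome_with_trait - in_region_with_trait
    out_without = (genome_total - in_region_total) - out_with
    res = chi_squared_independence(
        [
            [in_region_with_trait, in_region_total - in_region_with_trait],
            [out_with, out_without],
        ]
    )
    return TestResult(
        test_name="fold_enrichment",
        statistic=res.statistic,
        df=res.df,
        p_value=res.p_value,
        effect=float(fold),
        n={"region": int(in_region_total), "genome": int(genome_total)},
        method_notes=res.method_notes,
    )


def results_to_frame(results: dict) -> pd.DataFrame:
    """Serialize named TestResults as a tidy table."""
    rows = []
    for name, r in results.items():
        rows.append(
            {
                "test": name,
                "method": r.test_name,
                "n": ";".join(f"{k}={v}" for k, v in r.n.items()),
                "statistic": r.statistic,
                "df": r.df,
                "effect": r.effect,
                "p_value": r.p_value,
                "method_notes": r.method_notes,
            }
        )
    frame = pd.DataFrame(rows)
    frame["n_tests_in_battery"] = len(rows)
    return frame
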