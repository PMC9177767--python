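"""Frequentist differential feature analysis.

Per-feature two-class comparisons with Welch's t, the two-sample
Kolmogorov-Smirnov test, and the Wilcoxon rank-sum test, each followed by
Benjamini-Hochberg adjustment across the feature family.  The rank-sum test
is exact (full enumeration) when both classes have fewer than 20 slides and
no ties, and otherwise uses the normal approximation with continuity and
tie corrections.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["DifferentialResult", "run_tests", "consensus_sets", "top_k_markers", "TESTS"]

TESTS = ("t", "ks", "wrs")
_EXACT_WRS_MAX_N = 20


@dataclass
class DifferentialResult:
    """Per-feature test statistics with BH-adjusted p-values.

    ``table`` has one row per feature (index = feature id) and, per test
    ``x`` in the run, columns ``stat_x``, ``p_x``, ``q_x``; plus ``direction``
    (sign of class-1 mean minus class-0 mean), ``degenerate`` (constant
    feature flag) and the class sizes.
    """

    table: pd.DataFrame
    n0: int
    n1: int
    tests: tuple[str, ...]

    def significant(self, test: str, alpha: float = 0.05) -> set[int]:
        """Feature ids with adjusted p below alpha for one test."""
        q = self.table[f"q_{test}"]
        return set(self.table.index[q < alpha])


def _welch(x0: np.ndarray, x1: np.ndarray) -> tuple[float, float, bool]:
    if np.var(x0) == 0 and np.var(x1) == 0:
        if x0.mean() == x1.mean():
            return 0.0, 1.0, True
        return np.inf, 0.0, True
    res = stats.ttest_ind(x1, x0, equal_var=False)
    return float(res.statistic), float(res.pvalue), False


def _ks(x0: np.ndarray, x1: np.ndarray) -> tuple[float, float]:
    res = stats.ks_2samp(x1, x0)
    return float(res.statistic), float(res.pvalue)


def _wrs(x0: np.ndarray, x1: np.ndarray) -> tuple[float, float]:
    has_ties = np.unique(np.concatenate([x0, x1])).size < x0.size + x1.size
    small = max(x0.size, x1.size) < _EXACT_WRS_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x1, x0, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def run_tests(
    values: np.ndarray,
    labels: np.ndarray,
    tests: tuple[str, ...] = TESTS,
    feature_ids: np.ndarray | None = None,
) -> DifferentialResult:
    """Run the selected two-class tests on every column of ``values``.

    ``labels`` is boolean/0-1 per slide (True = class 1).  BH adjustment is
    applied separately per test across all features.  Constant features get
    t-test p = 1 and a ``degenerate`` flag instead of NaN.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    unknown = set(tests) - set(TESTS)
    if unknown:
        raise ValueError(f"unknown tests: {sorted(unknown)}")
    x0_all, x1_all = values[~labels], values[labels]
    n0, n1 = x0_all.shape[0], x1_all.shape[0]
    if n0 < 2 or n1 < 2:
        raise ValueError(f"each class needs at least 2 slides (got {n0}, {n1})")
    if feature_ids is None:
        feature_ids = np.arange(values.shape[1])

    rows = []
    for j in range(values.shape[1]):
        x0, x1 = x0_all[:, j], x1_all[:, j]
        row: dict[str, float] = {
            "direction": float(np.sign(x1.mean() - x0.mean())),
            "degenerate": False,
        }
        if "t" in tests:
            row["stat_t"], row["p_t"], degen = _welch(x0, x1)
            row["degenerate"] = degen
        if "ks" in tests:
            row["stat_ks"], row["p_ks"] = _ks(x0, x1)
        if "wrs" in tests:
            row["stat_wrs"], row["p_wrs"] = _wrs(x0, x1)
        rows.append(row)

    table = pd.DataFrame(rows, index=pd.Index(feature_ids, name="feature"))
    for t in tests:
        table[f"q_{t}"] = multipletests(table[f"p_{t}"].to_numpy(), method="fdr_bh")[1]
    return DifferentialResult(table=table, n0=n0, n1=n1, tests=tuple(tests))


def consensus_sets(sets: dict[str, set[int]]) -> dict:
    """Venn-style region counts for per-test significant-feature sets.

    Returns exact counts per inclusion pattern (keys are frozensets of test
    names), plus ``intersection_over_union`` — the fraction of features
    significant by at least one test that are significant by all tests
    (None when the union is empty).
    """
    names = sorted(sets)
    union: set[int] = set().union(*sets.values()) if sets else set()
    inter = set.intersection(*[sets[n] for n in names]) if names else set()
    regions: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*[sets[n] for n in combo])
            outside = set().union(*[sets[n] for n in names if n not in combo]) if len(combo) < len(names) else set()
            regions[frozenset(combo)] = len(inside - outside)
    ratio = len(inter) / len(union) if union else None
    return {
        "regions": regions,
        "union": len(union),
        "intersection": len(inter),
        "intersection_over_union": ratio,
    }


def top_k_markers(result: DifferentialResult, k: int, by: str = "t") -> list[int]:
    """First k features ranked by raw p (ties: larger |statistic|, then id)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if by not in result.tests:
        raise ValueError(f"test {by!r} was not run")
    if k > len(result.table):
        raise ValueError("k exceeds the number of features")
    tbl = result.table
    order = sorted(
        tbl.index,
        key=lambda f: (tbl.at[f, f"p_{by}"], -abs(tbl.at[f, f"stat_{by}"]), f),
    )
    return order[:k]
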