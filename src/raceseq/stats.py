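"""Cohort statistics for marker-by-subtype tables.

The biliary tract cancer cohort splits into three groups (iCCA, eCCA,
GBA: intrahepatic/extrahepatic cholangiocarcinoma and gallbladder
adenocarcinoma); markers are present/absent with some samples not
determined.  Group comparisons use the exact r x 2 Fisher test
(two-sided, probability-mass criterion, full enumeration over the
margin-constrained lattice), Pearson chi-squared without continuity
correction, Kruskal-Wallis, and Mann-Whitney U.

The published marker counts for the 168-sample cohort ship as module
data so the printed table can be reproduced end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, exp
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

GROUPS = ("iCCA", "eCCA", "GBA")

# Published per-group marker counts (present, absent, not determined) of the
# 168-sample biliary tract cancer cohort; groups ordered iCCA, eCCA, GBA.
BTC_MARKER_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    "MSI": {"present": (2, 0, 1), "absent": (76, 41, 38), "nd": (4, 3, 2)},
    "ERBB2 amplification": {"present": (2, 0, 3), "absent": (74, 44, 38), "nd": (7, 0, 0)},
    "FGFR2 alteration": {"present": (17, 1, 0), "absent": (65, 42, 40), "nd": (1, 1, 1)},
    "IDH1/2 mutation": {"present": (23, 0, 0), "absent": (59, 43, 40), "nd": (1, 1, 1)},
    "KRAS mutation": {"present": (11, 16, 4), "absent": (71, 27, 36), "nd": (1, 1, 1)},
    "NRAS mutation": {"present": (3, 0, 1), "absent": (79, 43, 39), "nd": (1, 1, 1)},
    "BRAF mutation": {"present": (2, 0, 1), "absent": (80, 43, 39), "nd": (1, 1, 1)},
    "ERBB2 mutation": {"present": (1, 0, 1), "absent": (81, 43, 39), "nd": (1, 1, 1)},
    "PIK3CA mutation": {"present": (9, 6, 3), "absent": (73, 37, 37), "nd": (1, 1, 1)},
}

BTC_GROUP_N = {"iCCA": 83, "eCCA": 44, "GBA": 41}
BTC_FEMALE_PCT = {"iCCA": 60.2, "eCCA": 63.6, "GBA": 73.2}


def marker_counts_matrix(marker: str) -> list[list[int]]:
    """The r x 2 (present, absent) matrix for a published cohort marker."""
    entry = BTC_MARKER_COUNTS[marker]
    return [[p, a] for p, a in zip(entry["present"], entry["absent"])]


def gender_counts_matrix() -> list[list[int]]:
    """Female/male counts per group reconstructed from printed percentages."""
    rows = []
    for g in GROUPS:
        n = BTC_GROUP_N[g]
        female = round(BTC_FEMALE_PCT[g] / 100 * n)
        rows.append([female, n - female])
    return rows


# ---------------------------------------------------------------------------
# tests


def _log_binom(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_exact_rxc(counts: Sequence[Sequence[int]]) -> float:
    """Exact two-sided Fisher test for an r x 2 table.

    The two-sided p-value is the total hypergeometric probability of all
    tables with the observed margins whose probability does not exceed
    the observed table's (with a 1e-7 relative tolerance for floating
    ties) -- the probability-mass criterion used by mainstream
    statistical environments.  Computed by complete enumeration over the
    margin-constrained lattice, so it is practical for the small r x 2
    tables that arise in cohort work.
    """
    table = [list(map(int, row)) for row in counts]
    if any(len(row) != 2 for row in table):
        raise ValueError("fisher_exact_rxc expects an r x 2 table")
    if any(x < 0 for row in table for x in row):
        raise ValueError("counts must be non-negative")
    row_sums = [sum(row) for row in table]
    col1 = sum(row[0] for row in table)
    col2 = sum(row[1] for row in table)
    if col1 == 0 or col2 == 0 or any(r == 0 for r in row_sums):
        import warnings

        warnings.warn("degenerate table (zero margin); p = 1", stacklevel=2)
        return 1.0
    n = col1 + col2
    denom = _log_binom(n, col1)
    obs_logp = sum(_log_binom(r, row[0]) for r, row in zip(row_sums, table)) - denom

    r = len(table)
    total = 0.0
    cutoff = obs_logp + 1e-7 * abs(obs_logp) + 1e-12

    def recurse(i: int, remaining: int, logp: float) -> None:
        nonlocal total
        if i == r - 1:
            if remaining <= row_sums[i]:
                lp = logp + _log_binom(row_sums[i], remaining) - denom
                if lp <= cutoff:
                    total += exp(lp)
            return
        lo = max(0, remaining - sum(row_sums[i + 1 :]))
        hi = min(row_sums[i], remaining)
        for a in range(lo, hi + 1):
            recurse(i + 1, remaining - a, logp + _log_binom(row_sums[i], a))

    recurse(0, col1, 0.0)
    return min(1.0, total)


def chi_squared_rxc(counts: Sequence[Sequence[int]]) -> float:
    """Pearson chi-squared p-value (no continuity correction)."""
    arr = np.asarray(counts, dtype=float)
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if (expected <= 0).any():
        raise ValueError("zero expected cell; use the exact test instead")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(p)


def kruskal_wallis(*groups: Sequence[float]) -> float:
    """Tie-corrected Kruskal-Wallis p (chi-squared approximation)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    flat = set()
    for g in groups:
        flat.update(g)
    if len(flat) == 1:
        return 1.0
    return float(sps.kruskal(*groups).pvalue)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration over all label assignments when n_x + n_y <= 12
    (valid with ties); otherwise the tie-corrected normal approximation.
    """
    x = list(x)
    y = list(y)
    if not x or not y:
        raise ValueError("both samples must be nonempty")
    if sorted(x) == sorted(y):
        return 1.0
    if len(x) + len(y) <= 12:
        return _mann_whitney_exact(x, y)
    return float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").pvalue)


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def _mann_whitney_exact(x: list[float], y: list[float]) -> float:
    from itertools import combinations

    pooled = x + y
    nx = len(x)
    u_obs = _u_statistic(x, y)
    us = []
    idx = range(len(pooled))
    for combo in combinations(idx, nx):
        chosen = set(combo)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in idx if i not in chosen]
        us.append(_u_statistic(xs, ys))
    us = np.asarray(us)
    lower = float(np.mean(us <= u_obs + 1e-9))
    upper = float(np.mean(us >= u_obs - 1e-9))
    return min(1.0, 2.0 * min(lower, upper))


# ---------------------------------------------------------------------------
# cohort tables


@dataclass
class MarkerTable:
    marker: str
    groups: tuple[str, ...]
    counts: list[list[int]]  # r x 2: present, absent
    nd: list[int]
    p_value: float
    percentages: list[float] = field(default_factory=list)

    @property
    def prevalence(self) -> tuple[int, int]:
        present = sum(row[0] for row in self.counts)
        total = sum(sum(row) for row in self.counts)
        return present, total


def build_marker_tables(cohort: pd.DataFrame) -> list[MarkerTable]:
    """Per-marker group comparison tables from a per-sample cohort matrix.

    *cohort* needs a ``group`` column; every other column is a marker
    with values in {present, absent, nd}.  'nd' samples are excluded
    listwise per marker.  The exact Fisher p is attached; an all-absent
    marker yields p = 1 with a warning.
    """
    if "group" not in cohort.columns:
        raise ValueError("cohort matrix needs a 'group' column")
    groups = tuple(dict.fromkeys(cohort["group"]))
    if len(groups) < 2:
        raise ValueError("cohort must contain >= 2 groups")
    tables = []
    for marker in [c for c in cohort.columns if c != "group"]:
        counts = []
        nd = []
        for g in groups:
            sub = cohort.loc[cohort["group"] == g, marker]
            counts.append([int((sub == "present").sum()), int((sub == "absent").sum())])
            nd.append(int((sub == "nd").sum()))
        if sum(row[0] for row in counts) == 0:
            import warnings

            warnings.warn(f"marker {marker} absent in all samples; p = 1", stacklevel=2)
            p = 1.0
        else:
            p = fisher_exact_rxc(counts)
        pct = [round(100 * row[0] / (row[0] + row[1]), 1) if row[0] + row[1] else 0.0
               for row in counts]
        tables.append(MarkerTable(marker, groups, counts, nd, p, pct))
    return tables


def synth_cohort(
    prevalences: dict[str, dict[str, float]],
    n_per_group: dict[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a cohort matrix with independent Bernoulli marker statuses.

    ``prevalences[marker][group]`` is the probability of 'present'.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in n_per_group.items():
        for _ in range(n):
            row = {"group": group}
            for marker, per_group in prevalences.items():
                p = per_group[group]
                if not 0 <= p <= 1:
                    raise ValueError(f"prevalence {p} outside [0, 1]")
                row[marker] = "present" if rng.random() < p else "absent"
            rows.append(row)
    return pd.DataFrame(rows)


def published_marker_tables() -> list[MarkerTable]:
    """Marker tables rebuilt from the published cohort counts."""
    tables = []
    for marker in BTC_MARKER_COUNTS:
        counts = marker_counts_matrix(marker)
        nd = list(BTC_MARKER_COUNTS[marker]["nd"])
        p = fisher_exact_rxc(counts)
        pct = [round(100 * row[0] / (row[0] + row[1]), 1) for row in counts]
        tables.append(MarkerTable(marker, GROUPS, counts, nd, p, pct))
    return tables
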