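"""Cohort statistics: per-rib count tables, positional group comparisons,
and upper-rib association tests.

The comparisons mirror a standard trauma-registry analysis: fracture-line
positions (percent along the rib) are compared between patients with and
without each associated thoracic fracture using the Mann-Whitney U test
(positions are bounded and bimodal, so a rank test rather than a t-test), and
the link between clavicle fractures and upper-rib (1st-3rd) involvement is
tested on a per-patient 2x2 contingency table with an uncorrected chi-square,
switching to Fisher's exact test when expected cell counts fall below 5.

The statistical unit for positional comparisons is the fracture record, not
the patient (a patient contributes one observation per fracture line); a
patient-level variant using per-patient mean positions is available via
``unit="patient"``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mapping import Cohort, FLAG_NAMES

#: Exact Mann-Whitney enumeration is used at or below this pooled sample size.
EXACT_ENUMERATION_MAX = 12


# ---------------------------------------------------------------------------
# Per-rib count table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RibCountTable:
    """Fracture-line counts per rib and side, with shares of the grand total."""

    left: np.ndarray   # counts per rib 1-12
    right: np.ndarray

    @property
    def total_per_rib(self) -> np.ndarray:
        return self.left + self.right

    @property
    def grand_total(self) -> int:
        return int(self.left.sum() + self.right.sum())

    @property
    def percent_per_rib(self) -> np.ndarray:
        """Share of the grand total per rib (full precision; NaN when empty)."""
        g = self.grand_total
        if g == 0:
            return np.full(12, np.nan)
        return 100.0 * self.total_per_rib / g

    @property
    def left_share(self) -> float:
        g = self.grand_total
        return float("nan") if g == 0 else 100.0 * float(self.left.sum()) / g

    @property
    def right_share(self) -> float:
        g = self.grand_total
        return float("nan") if g == 0 else 100.0 * float(self.right.sum()) / g

    def to_frame(self) -> pd.DataFrame:
        """Display table: left/right/total counts and 2-d.p. percentages."""
        return pd.DataFrame(
            {
                "rib": np.arange(1, 13),
                "left": self.left,
                "right": self.right,
                "total": self.total_per_rib,
                "percent": np.round(self.percent_per_rib, 2),
            }
        )


def rib_count_table(cohort: Cohort) -> RibCountTable:
    """Tally fracture lines per rib and side.

    An empty cohort yields a zero table whose percentage shares are NaN
    (flagged rather than fabricated).  Totals are invariant under patient and
    record ordering.
    """
    left = np.zeros(12, dtype=int)
    right = np.zeros(12, dtype=int)
    for rec in cohort.fracture_records():
        (left if rec.side == "left" else right)[rec.rib_index - 1] += 1
    return RibCountTable(left, right)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    exact_max: int = EXACT_ENUMERATION_MAX,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (Wilcoxon rank-sum) with midrank ties.

    Returns ``(U, p)`` where U is the statistic of ``sample_a`` (number of
    pairwise wins of a over b, counting ties as half).  For pooled sizes up to
    ``exact_max`` the p-value is exact: every assignment of the pooled
    midranks to group a is enumerated and the two-sided tail is the share of
    assignments at least as far from the null mean n_a*n_b/2 as observed.
    Larger samples use the normal approximation with tie-corrected variance
    (no continuity correction).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    mu = n_a * n_b / 2.0
    n = n_a + n_b

    if n <= exact_max:
        dev = abs(u_a - mu)
        hits = total = 0
        offset = n_a * (n_a + 1) / 2.0
        for combo in itertools.combinations(range(n), n_a):
            u = ranks[list(combo)].sum() - offset
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        return u_a, hits / total

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return u_a, 1.0
    z = (u_a - mu) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return u_a, p


@dataclass(frozen=True)
class GroupComparisonResult:
    """Positional comparison between flag-positive and flag-negative groups."""

    flag: str
    n_yes: int
    n_no: int
    mean_yes: float
    mean_no: float
    sd_yes: float
    sd_no: float
    u_statistic: float
    p_value: float
    test_name: str = "mann_whitney"

    @property
    def shift(self) -> float:
        """Estimated location effect: mean(yes) - mean(no), percent points."""
        return self.mean_yes - self.mean_no

    def to_dict(self) -> dict:
        return {
            "flag": self.flag,
            "n_yes": self.n_yes, "n_no": self.n_no,
            "mean_yes": round(self.mean_yes, 2), "mean_no": round(self.mean_no, 2),
            "sd_yes": round(self.sd_yes, 2), "sd_no": round(self.sd_no, 2),
            "shift": round(self.shift, 2),
            "u_statistic": self.u_statistic, "p_value": self.p_value,
            "test": self.test_name,
        }


def position_comparison(
    cohort: Cohort,
    flag: str,
    unit: Literal["record", "fracture", "patient"] = "record",
) -> GroupComparisonResult:
    """Compare fracture-line positions between patients with and without a flag.

    With ``unit="record"`` (default) every fracture line is one observation;
    ``unit="patient"`` first averages each patient's positions.  Both flag
    groups must contribute at least one observation.
    """
    if flag not in FLAG_NAMES:
        raise ValueError(f"unknown flag {flag!r}; expected one of {FLAG_NAMES}")
    yes: list[float] = []
    no: list[float] = []
    for p in cohort.patients:
        if unit == "patient":
            if not p.fractures:
                continue
            vals = [float(np.mean([f.percent for f in p.fractures]))]
        else:
            vals = [f.percent for f in p.fractures]
        (yes if p.flags[flag] else no).extend(vals)
    if not yes or not no:
        raise ValueError(f"flag {flag!r}: a group contributes zero records")
    u, pval = mann_whitney(yes, no)
    return GroupComparisonResult(
        flag=flag,
        n_yes=len(yes), n_no=len(no),
        mean_yes=float(np.mean(yes)), mean_no=float(np.mean(no)),
        sd_yes=float(np.std(yes, ddof=1)) if len(yes) > 1 else 0.0,
        sd_no=float(np.std(no, ddof=1)) if len(no) > 1 else 0.0,
        u_statistic=u, p_value=pval,
    )


# ---------------------------------------------------------------------------
# 2x2 contingency tests
# ---------------------------------------------------------------------------

ContingencyMethod = Literal["auto", "chi_square", "chi_square_yates", "fisher"]


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 test outcome; ``method`` records which test actually ran."""

    counts: np.ndarray            # rows = groups, cols = (event, no event)
    method: str
    statistic: float | None       # chi-square statistic; None for Fisher
    p_value: float

    @property
    def rates(self) -> tuple[float, float]:
        """Event rate per group row (cell / row total)."""
        row_tot = self.counts.sum(axis=1)
        return (
            float(self.counts[0, 0] / row_tot[0]),
            float(self.counts[1, 0] / row_tot[1]),
        )

    def to_dict(self) -> dict:
        r0, r1 = self.rates
        return {
            "counts": self.counts.tolist(),
            "rate_group0": round(100 * r0, 2), "rate_group1": round(100 * r1, 2),
            "method": self.method,
            "statistic": self.statistic, "p_value": self.p_value,
        }


def contingency_2x2(
    counts: Sequence[Sequence[int]] | np.ndarray,
    method: ContingencyMethod = "auto",
) -> ContingencyResult:
    """Two-sided 2x2 test: chi-square (uncorrected or Yates) or Fisher exact.

    ``auto`` applies the conventional rule: Fisher's exact test when any
    expected cell count is below 5, otherwise the uncorrected chi-square.
    Both margins must be positive.
    """
    c = np.asarray(counts)
    if c.shape != (2, 2) or (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
        raise ValueError("counts must be a 2x2 array of non-negative integers")
    row, col = c.sum(axis=1), c.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("both margins of the 2x2 table must be positive")

    if method == "auto":
        expected = np.outer(row, col) / c.sum()
        method = "fisher" if (expected < 5).any() else "chi_square"

    if method == "fisher":
        _, p = sps.fisher_exact(c, alternative="two-sided")
        return ContingencyResult(c, "fisher", None, float(p))
    if method in ("chi_square", "chi_square_yates"):
        stat, p, _, _ = sps.chi2_contingency(
            c, correction=(method == "chi_square_yates")
        )
        return ContingencyResult(c, method, float(stat), float(p))
    raise ValueError(f"unknown method {method!r}")


def upper_rib_association(
    cohort: Cohort,
    flag: str,
    rib_range: Iterable[int] = range(1, 4),
    method: ContingencyMethod = "auto",
) -> ContingencyResult:
    """Test whether a flag raises the per-patient rate of fractures in a rib range.

    Each patient contributes one indicator — any fracture line on a rib in
    ``rib_range`` — and the flag x indicator 2x2 table goes through
    :func:`contingency_2x2`.  Row 0 is the flag-positive group, so
    ``result.rates`` reads (rate with flag, rate without).

    If the indicator is constant (e.g. rib_range 1-12 in a cohort where every
    patient has a fracture) the association is undefined; the result then
    carries method ``"degenerate"`` with p = 1 so the group rates stay
    readable.
    """
    if flag not in FLAG_NAMES:
        raise ValueError(f"unknown flag {flag!r}; expected one of {FLAG_NAMES}")
    ribs = set(rib_range)
    table = np.zeros((2, 2), dtype=int)
    for p in cohort.patients:
        g = 0 if p.flags[flag] else 1
        hit = 0 if p.has_fracture_in(ribs) else 1
        table[g, hit] += 1
    if (table.sum(axis=0) == 0).any() and (table.sum(axis=1) > 0).all():
        return ContingencyResult(table, "degenerate", None, 1.0)
    return contingency_2x2(table, method)
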