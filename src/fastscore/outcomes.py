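"""Rank-based outcome comparisons across a FAST cut point.

Ventilator days, PICU days and hospital days are compared between
encounters below vs at-or-above a chosen cut with the Mann-Whitney
(Wilcoxon rank-sum) test.  The statistic is reported in chi-squared form:
z from the tie-corrected normal approximation (no continuity correction),
chi2 = z^2 with 1 degree of freedom.  An exact-enumeration mode covers
small samples (combined n <= 12), where the normal approximation is
rough.  Quartiles use Tukey hinges (median-of-halves).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import rankdata

from .validation import LabeledScore

logger = logging.getLogger(__name__)

__all__ = [
    "OutcomeRecord",
    "GroupComparison",
    "MannWhitneyResult",
    "mann_whitney",
    "tukey_hinges",
    "compare_outcomes",
    "comparison_frame",
    "read_outcomes",
]

OUTCOME_NAMES = ("ventilator_days", "picu_days", "hospital_days")


@dataclass(frozen=True)
class OutcomeRecord:
    """Length-of-stay outcomes for one encounter, in days."""

    encounter_id: str
    ventilator_days: Optional[float] = None
    picu_days: Optional[float] = None
    hospital_days: Optional[float] = None

    def __post_init__(self) -> None:
        present = [
            (n, getattr(self, n)) for n in OUTCOME_NAMES if getattr(self, n) is not None
        ]
        for n, v in present:
            if v < 0:
                raise ValueError(f"{n} must be non-negative, got {v}")
        vals = dict(present)
        if len(vals) == 3 and not (
            vals["ventilator_days"] <= vals["picu_days"] <= vals["hospital_days"]
        ):
            # real charts can violate the nesting; flag, don't reject
            logger.warning(
                "encounter %s: ventilator (%s) <= PICU (%s) <= hospital (%s) ordering violated",
                self.encounter_id,
                vals["ventilator_days"],
                vals["picu_days"],
                vals["hospital_days"],
            )


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float        #: rank-sum U for the first group
    z: float        #: tie-corrected normal deviate (no continuity correction)
    chi2: float     #: z**2, 1 df
    p_value: float
    method: str     #: "asymptotic" or "exact"


@dataclass(frozen=True)
class GroupComparison:
    """One outcome compared between the below-cut and at-or-above-cut groups."""

    outcome_name: str
    cut: int
    n_lo: int
    n_hi: int
    median_lo: float
    iqr_lo: tuple
    median_hi: float
    iqr_hi: tuple
    chi2: float
    p_value: float


def _rank_u(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a via midranks: R_a - n_a(n_a+1)/2."""
    n_a = len(a)
    ranks = rankdata(np.concatenate([a, b]))
    return float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided p by full enumeration of all C(n, n_a) group labelings.

    The two-sided region is |U - n_a n_b / 2| >= |U_obs - n_a n_b / 2|,
    evaluated over every relabeling of the pooled values (ties handled
    exactly through midranks).
    """
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)
    mu = n_a * (n - n_a) / 2
    obs = abs(_rank_u(a, b) - mu)
    ranks = rankdata(pooled)
    hits = total = 0
    base = n_a * (n_a + 1) / 2
    for idx in combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - base
        total += 1
        if abs(u - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float], method: str = "auto"
) -> MannWhitneyResult:
    """Mann-Whitney rank-sum test between two groups.

    Returns U (for ``group_a``, midrank convention), the tie-corrected
    z without continuity correction, chi2 = z^2, and the two-sided
    p-value from the chi-squared distribution with 1 df.  With
    ``method="exact"`` (or "auto" and combined n <= 12) the p-value is
    instead computed by full enumeration of group labelings.  All-tied
    data yield chi2 = 0 and p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    u = _rank_u(a, b)
    mu = n_a * n_b / 2
    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12 * ((n + 1) - tie_term)
    if var <= 0:  # every value tied
        return MannWhitneyResult(u=u, z=0.0, chi2=0.0, p_value=1.0, method="degenerate")
    z = (u - mu) / np.sqrt(var)
    chi2 = z**2
    if method == "exact" or (method == "auto" and n <= 12):
        p = _exact_two_sided_p(a, b)
        return MannWhitneyResult(u=u, z=float(z), chi2=float(chi2), p_value=float(p), method="exact")
    if method not in ("auto", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    p = float(chi2_dist.sf(chi2, df=1))
    return MannWhitneyResult(u=u, z=float(z), chi2=float(chi2), p_value=p, method="asymptotic")


def tukey_hinges(values: Sequence[float]) -> tuple:
    """(lower, upper) hinges: medians of the lower and upper halves,
    each half including the overall median position when n is odd."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    h = (n + 1) // 2
    return float(np.median(x[:h])), float(np.median(x[n - h:]))


def compare_outcomes(
    scores: Sequence[LabeledScore],
    outcomes: Sequence[OutcomeRecord],
    cut: int,
) -> list[GroupComparison]:
    """Compare each outcome between the score < cut and score >= cut groups.

    Joins on encounter_id; encounters missing either side are dropped.
    Each group must retain at least two encounters per outcome.
    """
    score_by_id = {s.encounter_id: s.score for s in scores}
    out_by_id = {o.encounter_id: o for o in outcomes}
    ids = [i for i in score_by_id if i in out_by_id]
    comparisons = []
    for name in OUTCOME_NAMES:
        lo, hi = [], []
        for i in ids:
            v = getattr(out_by_id[i], name)
            if v is None:
                continue
            (hi if score_by_id[i] >= cut else lo).append(v)
        if len(lo) < 2 or len(hi) < 2:
            raise ValueError(
                f"degenerate comparison at cut {cut} for {name}: "
                f"{len(lo)} below vs {len(hi)} at-or-above"
            )
        mw = mann_whitney(lo, hi, method="asymptotic")
        comparisons.append(
            GroupComparison(
                outcome_name=name,
                cut=cut,
                n_lo=len(lo),
                n_hi=len(hi),
                median_lo=float(np.median(lo)),
                iqr_lo=tukey_hinges(lo),
                median_hi=float(np.median(hi)),
                iqr_hi=tukey_hinges(hi),
                chi2=mw.chi2,
                p_value=mw.p_value,
            )
        )
    return comparisons


def comparison_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Render comparisons as a report table (one row per outcome)."""
    rows = []
    for c in comparisons:
        rows.append(
            {
                "outcome": c.outcome_name,
                "cut": c.cut,
                "n_below": c.n_lo,
                "below_cut_median_iqr": f"{c.median_lo:g} ({c.iqr_lo[0]:g}-{c.iqr_lo[1]:g})",
                "n_at_or_above": c.n_hi,
                "at_or_above_median_iqr": f"{c.median_hi:g} ({c.iqr_hi[0]:g}-{c.iqr_hi[1]:g})",
                "chi2": round(c.chi2, 4),
                "p_value": round(c.p_value, 4),
            }
        )
    return pd.DataFrame(rows)


def read_outcomes(path) -> list[OutcomeRecord]:
    """Read an outcomes CSV keyed by encounter_id (empty cell = missing)."""
    df = pd.read_csv(path)
    if "encounter_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'encounter_id'")
    records = []
    for _, row in df.iterrows():
        kwargs = {"encounter_id": str(row["encounter_id"])}
        for name in OUTCOME_NAMES:
            if name in df.columns and pd.notna(row[name]):
                kwargs[name] = float(row[name])
        records.append(OutcomeRecord(**kwargs))
    return records
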