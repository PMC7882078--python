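"""Tissue-microarray scoring and clinical association statistics.

In situ hybridization (ISH) and immunohistochemistry (IHC) staining of
tissue-microarray dots is summarized by a weighted score: the
percent-positive-cells bin (0–4) plus the staining-intensity grade (0–3).
The summed 0–7 score maps onto four categories (0–1 "–", 2–3 "+",
4–5 "++", 6–7 "+++"), and a specimen is called *high*-expressing when the
weighted score is at least 4 (categories ++/+++).

Association of the resulting high/low dichotomy with clinicopathological
variables uses Pearson's χ² (without continuity correction), group
comparison of raw scores uses the Mann–Whitney U test, and overall
survival uses Kaplan–Meier curves compared by the log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "Intensity",
    "TmaRecord",
    "ContingencyResult",
    "SurvivalRecord",
    "percent_bin",
    "weighted_score",
    "chi2_association",
    "mann_whitney",
    "km_logrank",
]

#: Intensity grades in order: negative, weak, moderate, strong.
INTENSITY_GRADES = ("negative", "weak", "moderate", "strong")

CATEGORY_BY_SCORE = {0: "-", 1: "-", 2: "+", 3: "+", 4: "++", 5: "++", 6: "+++", 7: "+++"}
HIGH_CUTOFF = 4


@dataclass(frozen=True)
class TmaRecord:
    case_id: str
    percent_score: int  # 0–4
    intensity_score: int  # 0–3
    tissue: str  # "tumor" or "normal"
    weighted_score: int  # 0–7
    category: str  # -, +, ++, +++
    expression_class: str  # "high" or "low"


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    chi2: float
    p_value: float


@dataclass(frozen=True)
class SurvivalRecord:
    case_id: str
    time: float
    event: int
    group: str  # "high" or "low"


def percent_bin(percent_positive: float) -> int:
    """Bin the percentage of positive cells into the 0–4 score.

    Cuts at 5/25/50/75 with the upper category winning at a boundary
    (anchored by the ≥75% → 4 rule), so 5 → 1, 25 → 2, 50 → 3, 75 → 4.
    """
    if not 0 <= percent_positive <= 100:
        raise ValueError(f"percent {percent_positive} outside [0, 100]")
    for score, cut in ((4, 75), (3, 50), (2, 25), (1, 5)):
        if percent_positive >= cut:
            return score
    return 0


def weighted_score(
    percent_positive: float,
    intensity: str | int,
    case_id: str = "",
    tissue: str = "tumor",
) -> TmaRecord:
    """Weighted ISH/IHC score for one tissue dot.

    ``intensity`` may be a grade name (negative/weak/moderate/strong) or
    the 0–3 integer directly.
    """
    if isinstance(intensity, str):
        try:
            intensity_score = INTENSITY_GRADES.index(intensity.lower())
        except ValueError:
            raise ValueError(f"unknown intensity grade {intensity!r}") from None
    else:
        intensity_score = int(intensity)
        if not 0 <= intensity_score <= 3:
            raise ValueError(f"intensity score {intensity_score} outside 0–3")
    pscore = percent_bin(percent_positive)
    total = pscore + intensity_score
    return TmaRecord(
        case_id=case_id,
        percent_score=pscore,
        intensity_score=intensity_score,
        tissue=tissue,
        weighted_score=total,
        category=CATEGORY_BY_SCORE[total],
        expression_class="high" if total >= HIGH_CUTOFF else "low",
    )


def chi2_association(table: Sequence[Sequence[int]]) -> ContingencyResult:
    """Pearson χ² (df=1, no continuity correction) for a 2×2 table."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2×2")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    t = tuple(tuple(int(v) for v in row) for row in table)
    return ContingencyResult(table=t, chi2=float(chi2), p_value=float(p))


def mann_whitney(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Uses the exact null distribution when the combined sample size is at
    most 20 and there are no ties, otherwise the normal approximation with
    tie correction.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def km_logrank(
    records: Sequence[SurvivalRecord],
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan–Meier curves per group and the log-rank comparison.

    Returns (curves, chi2, p) where ``curves`` maps group name to a frame
    with columns time, at_risk, survival. At tied times events precede
    censorings (standard convention, as applied by the product-limit
    estimator).
    """
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    if not any(r.event for r in records):
        raise ValueError("need at least one event")
    curves: dict[str, pd.DataFrame] = {}
    by_group: dict[str, list[SurvivalRecord]] = {g: [] for g in groups}
    for r in records:
        if r.time <= 0:
            raise ValueError(f"non-positive survival time for case {r.case_id!r}")
        by_group[r.group].append(r)
    for g, recs in by_group.items():
        if not recs:
            raise ValueError(f"group {g!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit([r.time for r in recs], [r.event for r in recs], label=g)
        tbl = kmf.event_table
        curves[g] = pd.DataFrame(
            {
                "time": tbl.index.to_numpy(dtype=float),
                "at_risk": tbl["at_risk"].to_numpy(dtype=int),
                "survival": kmf.survival_function_[g]
                .reindex(tbl.index)
                .to_numpy(dtype=float),
            }
        )
    g0, g1 = groups
    res = logrank_test(
        [r.time for r in by_group[g0]],
        [r.time for r in by_group[g1]],
        event_observed_A=[r.event for r in by_group[g0]],
        event_observed_B=[r.event for r in by_group[g1]],
    )
    return curves, float(res.test_statistic), float(res.p_value)
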