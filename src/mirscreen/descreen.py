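"""Differential-expression screening for two-group microarray studies.

mRNA screening uses six statistics — the ordinary (Welch) t statistic and
five *cancer outlier* statistics (COPA, OS, ORT, MOST, LSOSS) designed to
detect features shifted in only a subset of disease samples — and selects
the statistic whose top-ranked lists are most consistent across datasets.
miRNA screening uses the two-sided t test at a fixed significance level.

All expression values are assumed to be on a log scale; missing values can
be filled by k-nearest-neighbour imputation in feature space before
screening.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DeMethod",
    "ExpressionStudy",
    "DeResult",
    "MethodOverlapReport",
    "read_expression",
    "knn_impute",
    "mad",
    "outlier_statistic",
    "two_sided_outlier_statistic",
    "de_genes",
    "select_method_by_overlap",
    "de_mirnas",
]

DISEASE = "disease"
CONTROL = "control"


class DeMethod(Enum):
    """The six differential-expression statistics, in tie-break order."""

    T = "t"
    COPA = "COPA"
    OS = "OS"
    ORT = "ORT"
    MOST = "MOST"
    LSOSS = "LSOSS"


@dataclass
class ExpressionStudy:
    """A feature × sample expression matrix with two-group sample labels.

    ``values`` rows are features, columns samples; ``sample_groups`` maps
    every sample to ``"disease"`` or ``"control"``.
    """

    values: pd.DataFrame
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        self.sample_groups = pd.Series(self.sample_groups)
        if not self.values.index.is_unique:
            raise ValueError("feature ids must be unique")
        missing = set(self.values.columns) - set(self.sample_groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        bad = set(self.sample_groups.unique()) - {DISEASE, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for grp in (DISEASE, CONTROL):
            if (self.sample_groups.loc[self.values.columns] == grp).sum() < 2:
                raise ValueError(f"need at least 2 {grp!r} samples")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def group_values(self, feature: str) -> tuple[np.ndarray, np.ndarray]:
        """(disease values, control values) for one feature."""
        row = self.values.loc[feature]
        labels = self.sample_groups.loc[self.values.columns]
        return (
            row[labels[labels == DISEASE].index].to_numpy(dtype=float),
            row[labels[labels == CONTROL].index].to_numpy(dtype=float),
        )

    def group_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        labels = self.sample_groups.loc[self.values.columns]
        dis = self.values.loc[:, labels[labels == DISEASE].index]
        ctl = self.values.loc[:, labels[labels == CONTROL].index]
        return dis.to_numpy(dtype=float), ctl.to_numpy(dtype=float)


@dataclass(frozen=True)
class DeResult:
    feature_id: str
    method: DeMethod
    statistic: float
    p_value: float | None
    direction: str  # "up" or "down"


@dataclass(frozen=True)
class MethodOverlapReport:
    method: DeMethod
    per_study_lists: tuple[tuple[str, ...], ...]
    pairwise_overlaps: tuple[float, ...]
    mean_overlap: float


def read_expression(matrix_path: str | Path, groups_path: str | Path) -> ExpressionStudy:
    """Read a TSV matrix (first column feature id) and a sample→group TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups = pd.read_csv(
        groups_path, sep="\t", index_col=0, header=None, names=["sample", "group"]
    )["group"]
    return ExpressionStudy(values=values, sample_groups=groups)


# ---------------------------------------------------------------------------
# imputation


def knn_impute(study: ExpressionStudy, k: int = 10) -> ExpressionStudy:
    """Fill missing cells from the k nearest features.

    The distance between two features is the Euclidean distance over the
    samples where both are observed. A missing cell (f, s) becomes the mean
    value at sample s over the k nearest features that are observed at s
    (ties broken by feature id). Observed cells are never altered.
    """
    X = study.values.to_numpy(dtype=float)
    n_features = X.shape[0]
    if k < 1 or k > n_features - 1:
        raise ValueError(f"k={k} must be in [1, n_features-1]")
    obs = ~np.isnan(X)
    empty = np.where(~obs.any(axis=1))[0]
    if empty.size:
        raise ValueError(
            f"feature entirely missing: {study.values.index[empty[0]]!r}"
        )
    if obs.all():
        return study

    ids = list(study.values.index)
    out = X.copy()
    for f in np.where(~obs.all(axis=1))[0]:
        diff = X - X[f]
        diff[~(obs & obs[f])] = 0.0
        shared = (obs & obs[f]).sum(axis=1)
        dist = np.sqrt(np.nansum(diff**2, axis=1))
        dist[shared == 0] = np.inf
        dist[f] = np.inf
        for s in np.where(~obs[f])[0]:
            candidates = [
                (dist[j], ids[j], j)
                for j in range(n_features)
                if j != f and obs[j, s] and np.isfinite(dist[j])
            ]
            if not candidates:
                warnings.warn(
                    f"no observed neighbour for cell ({ids[f]}, column {s})",
                    stacklevel=2,
                )
                continue
            candidates.sort()
            chosen = candidates[:k]
            if len(chosen) < k:
                warnings.warn(
                    f"only {len(chosen)} neighbours available for ({ids[f]}, {s})",
                    stacklevel=2,
                )
            out[f, s] = float(np.mean([X[j, s] for _, _, j in chosen]))
    return ExpressionStudy(
        values=pd.DataFrame(out, index=study.values.index, columns=study.values.columns),
        sample_groups=study.sample_groups,
    )


# ---------------------------------------------------------------------------
# outlier statistics

#: Consistency constant making the MAD estimate the normal SD.
MAD_SCALE = 1.4826


def mad(x: np.ndarray) -> float:
    """Median absolute deviation, scaled for normal consistency."""
    x = np.asarray(x, dtype=float)
    return MAD_SCALE * float(np.median(np.abs(x - np.median(x))))


class DegenerateScaleError(ValueError):
    """Raised when a robust scale estimate is exactly zero."""


def _checked_mad(x: np.ndarray, what: str) -> float:
    m = mad(x)
    if m == 0.0:
        raise DegenerateScaleError(f"MAD of {what} is zero")
    return m


@lru_cache(maxsize=32)
def _gaussian_topk_moments(n: int, n_draws: int = 200_000) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Mean and SD of the sum of the k largest of n iid standard normals.

    Estimated once per n by seeded Monte Carlo (internal fixed seed, so the
    table is deterministic and independent of any user-level seed).
    """
    rng = np.random.default_rng(987654321 + n)
    draws = np.sort(rng.standard_normal((n_draws, n)), axis=1)[:, ::-1]
    csums = np.cumsum(draws, axis=1)
    return tuple(csums.mean(axis=0)), tuple(csums.std(axis=0, ddof=0))


def _copa(disease: np.ndarray, control: np.ndarray, r: float) -> float:
    pooled = np.concatenate([disease, control])
    centered = (disease - np.median(pooled)) / _checked_mad(pooled, "pooled values")
    return float(np.percentile(centered, r))  # linear interpolation


def _os(disease: np.ndarray, control: np.ndarray) -> float:
    pooled = np.concatenate([disease, control])
    med = np.median(pooled)
    scale = _checked_mad(pooled, "pooled values")
    q25, q75 = np.percentile(pooled, [25, 75])
    thr = q75 + (q75 - q25)
    outliers = disease[disease > thr]
    return float(np.sum((outliers - med) / scale)) if outliers.size else 0.0


def _ort(disease: np.ndarray, control: np.ndarray) -> float:
    med = np.median(control)
    scale = _checked_mad(control, "control values")
    q25, q75 = np.percentile(control, [25, 75])
    thr = q75 + (q75 - q25)
    outliers = disease[disease > thr]
    return float(np.sum((outliers - med) / scale)) if outliers.size else 0.0


def _most(disease: np.ndarray, control: np.ndarray) -> float:
    med = np.median(control)
    scale = _checked_mad(control, "control values")
    z = np.sort((disease - med) / scale)[::-1]
    expect, sd = _gaussian_topk_moments(len(z))
    csum = np.cumsum(z)
    stats_k = (csum - np.asarray(expect)) / np.asarray(sd)
    return float(np.max(stats_k))


def _lsoss(disease: np.ndarray, control: np.ndarray) -> float:
    d = np.sort(disease)[::-1]
    n = len(d)
    best_k, best_ss = None, np.inf
    for k in range(1, n):
        hi, lo = d[:k], d[k:]
        ss = float(np.sum((hi - hi.mean()) ** 2) + np.sum((lo - lo.mean()) ** 2))
        if ss < best_ss:
            best_ss, best_k = ss, k
    hi, lo = d[:best_k], d[best_k:]
    ss_c = float(np.sum((control - control.mean()) ** 2))
    dof = len(control) + n - 3
    s2 = (ss_c + best_ss) / dof
    if s2 == 0.0:
        raise DegenerateScaleError("pooled within-group variance is zero")
    return float((hi.mean() - control.mean()) / math.sqrt(s2))


def outlier_statistic(
    disease: Sequence[float],
    control: Sequence[float],
    method: DeMethod | str,
    r: float = 90.0,
) -> float:
    """One scalar differential-expression statistic for a single feature.

    ``t`` is the Welch two-sample t statistic (disease minus control). The
    five outlier statistics score *up*-outliers in the disease group:

    * COPA — the r-th percentile of disease values after centring by the
      pooled median and scaling by the pooled MAD;
    * OS — sum of centred/scaled disease values beyond the pooled
      q75 + IQR outlier threshold;
    * ORT — as OS but centred/scaled by the control median/MAD with the
      threshold from the control quartiles;
    * MOST — maximum over k of the sum of the k largest standardized
      disease values, normalized by the mean/SD of the matching sum of
      Gaussian order statistics;
    * LSOSS — split the sorted disease values at the change point
      minimizing the within-subset sum of squares; the statistic is the
      outlier-subset mean minus the control mean over the pooled
      within-group standard deviation.

    Percentiles use linear interpolation between closest ranks throughout.
    """
    method = DeMethod(method) if not isinstance(method, DeMethod) else method
    disease = np.asarray(disease, dtype=float)
    control = np.asarray(control, dtype=float)
    if disease.size < 2 or control.size < 2:
        raise ValueError("need at least 2 values per group")
    if method is DeMethod.T:
        return float(stats.ttest_ind(disease, control, equal_var=False).statistic)
    if method is DeMethod.COPA:
        return _copa(disease, control, r)
    if method is DeMethod.OS:
        return _os(disease, control)
    if method is DeMethod.ORT:
        return _ort(disease, control)
    if method is DeMethod.MOST:
        return _most(disease, control)
    return _lsoss(disease, control)


def two_sided_outlier_statistic(
    disease: Sequence[float],
    control: Sequence[float],
    method: DeMethod | str,
    r: float = 90.0,
) -> float:
    """Signed two-sided version of :func:`outlier_statistic`.

    The outlier statistics score up-outliers only; the mirrored run on the
    negated data scores down-outliers. The larger of the two (in
    magnitude) is returned, negative when the down direction wins. The t
    statistic is already two-sided and returned as is.
    """
    method = DeMethod(method) if not isinstance(method, DeMethod) else method
    if method is DeMethod.T:
        return outlier_statistic(disease, control, method)
    up = outlier_statistic(disease, control, method, r)
    down = outlier_statistic(
        -np.asarray(disease, dtype=float), -np.asarray(control, dtype=float), method, r
    )
    return up if abs(up) >= abs(down) else -down


# ---------------------------------------------------------------------------
# screening


def de_genes(
    studies: Sequence[ExpressionStudy],
    method: DeMethod | str,
    top_fraction: float = 0.4,
    r: float = 90.0,
    intersect_first: bool = True,
) -> list[list[str]]:
    """Per-study ranked top-fraction DE feature lists for one statistic.

    Features are restricted to the studies' common feature universe (by
    default before ranking), ranked by |statistic| descending with a
    deterministic feature-id tie-break, and truncated to
    ceil(top_fraction · n) features.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    method = DeMethod(method) if not isinstance(method, DeMethod) else method
    common: set[str] = set(studies[0].feature_ids)
    for study in studies[1:]:
        common &= set(study.feature_ids)
    if not common:
        raise ValueError("studies share no features")

    out: list[list[str]] = []
    for study in studies:
        universe = sorted(common) if intersect_first else study.feature_ids
        scores = []
        for fid in universe:
            dis, ctl = study.group_values(fid)
            try:
                s = two_sided_outlier_statistic(dis, ctl, method, r)
            except DegenerateScaleError:
                warnings.warn(f"degenerate scale for feature {fid!r}; skipped",
                              stacklevel=2)
                continue
            scores.append((fid, s))
        scores.sort(key=lambda t: (-abs(t[1]), t[0]))
        ranked = [fid for fid, _ in scores]
        if not intersect_first:
            ranked = [fid for fid in ranked if fid in common]
        n_keep = math.ceil(top_fraction * len(common))
        out.append(ranked[:n_keep])
    return out


def _overlap_pct(a: Sequence[str], b: Sequence[str]) -> float:
    length = min(len(a), len(b))
    if length == 0:
        return 0.0
    return 100.0 * len(set(a) & set(b)) / length


def select_method_by_overlap(
    lists_by_method: Mapping[DeMethod, Sequence[Sequence[str]]],
    mode: str = "pairwise",
) -> tuple[DeMethod, list[MethodOverlapReport]]:
    """Pick the statistic whose DE lists agree best across studies.

    For each method the percentage overlap of its per-study top lists is
    computed over all study pairs (``mode="pairwise"``, the default) or as
    the all-study intersection (``mode="threeway"``); the method with the
    highest mean overlap wins, ties broken by method order with a warning.
    """
    reports: list[MethodOverlapReport] = []
    for method in DeMethod:
        if method not in lists_by_method:
            continue
        lists = [tuple(lst) for lst in lists_by_method[method]]
        if len(lists) == 1:
            overlaps = (100.0,)
        elif mode == "pairwise":
            overlaps = tuple(
                _overlap_pct(lists[i], lists[j])
                for i in range(len(lists))
                for j in range(i + 1, len(lists))
            )
        elif mode == "threeway":
            inter = set(lists[0])
            for lst in lists[1:]:
                inter &= set(lst)
            length = min(len(lst) for lst in lists)
            overlaps = (100.0 * len(inter) / length if length else 0.0,)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        reports.append(
            MethodOverlapReport(
                method=method,
                per_study_lists=tuple(lists),
                pairwise_overlaps=overlaps,
                mean_overlap=float(np.mean(overlaps)),
            )
        )
    if not reports:
        raise ValueError("no method lists supplied")
    best = max(reports, key=lambda rep: rep.mean_overlap)
    ties = [rep for rep in reports if rep.mean_overlap == best.mean_overlap]
    if len(ties) > 1:
        warnings.warn(
            f"overlap tie between {[t.method.value for t in ties]}; "
            f"keeping {ties[0].method.value}",
            stacklevel=2,
        )
        best = ties[0]
    return best.method, reports


def de_mirnas(
    study: ExpressionStudy, alpha: float = 0.05, equal_var: bool = False
) -> list[DeResult]:
    """Two-sided t test per feature; keep features with p strictly < alpha.

    The Welch (unequal-variance) variant is the default; ``equal_var=True``
    gives the classical pooled-variance test. Features with zero variance
    in both groups and equal means are untestable and skipped with a
    warning.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    dis, ctl = study.group_matrices()
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(dis, ctl, axis=1, equal_var=equal_var)
    out: list[DeResult] = []
    for i, fid in enumerate(study.feature_ids):
        t, p = float(res.statistic[i]), float(res.pvalue[i])
        if math.isnan(t):
            if np.allclose(dis[i].mean(), ctl[i].mean()):
                warnings.warn(f"feature {fid!r} has no variance; skipped",
                              stacklevel=2)
                continue
            t, p = math.inf if dis[i].mean() > ctl[i].mean() else -math.inf, 0.0
        if p < alpha:
            out.append(
                DeResult(
                    feature_id=fid,
                    method=DeMethod.T,
                    statistic=t,
                    p_value=p,
                    direction="up" if dis[i].mean() > ctl[i].mean() else "down",
                )
            )
    return out


def results_table(results: Iterable[DeResult]) -> pd.DataFrame:
    """DE results as a tidy frame (feature, method, statistic, p, direction)."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature_id,
                "method": r.method.value,
                "statistic": r.statistic,
                "p": r.p_value,
                "direction": r.direction,
            }
            for r in results
        ]
    )
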