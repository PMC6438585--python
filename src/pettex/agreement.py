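"""Agreement and robustness statistics: Pearson correlation grouping and
index selection, Bland-Altman comparison, Friedman / Wilcoxon inter-method
tests, and inter-observer intraclass correlation with Landis-Koch labels.

Flagged-missing feature values (NaN, e.g. degenerate GLCM Correlation or
NGLDM Busyness) are handled pairwise-complete throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class CorrelationGroup:
    """A set of mutually highly correlated indices (complete linkage)."""

    members: list[str]
    mean_abs_r: float | None = None
    sd_abs_r: float | None = None


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement of paired measurements."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


@dataclass
class MethodVariabilityResult:
    """Friedman p over the three methods plus pairwise Wilcoxon p-values."""

    feature: str
    friedman_p: float
    pairwise_wilcoxon_p: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass(frozen=True)
class ReproducibilityResult:
    """Inter-observer ICC for one feature under one segmentation method."""

    feature: str
    method: str
    icc: float
    label: str


def pearson_matrix(features: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of a feature table
    (rows = VOIs, columns = features).

    Zero-variance or mostly-missing columns yield NaN entries (flagged, not
    silently imputed); the diagonal is 1 for well-defined columns.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = features.corr(method="pearson", min_periods=min_n)
    for col in features.columns:
        valid = features[col].dropna()
        if len(valid) >= min_n and valid.std() > 0:
            r.loc[col, col] = 1.0
    return r


def extract_correlated_groups(
    r_matrix: pd.DataFrame, threshold: float = 0.8,
    order: list[str] | None = None,
) -> list[CorrelationGroup]:
    """Greedy complete-linkage grouping of features at ``|r| > threshold``.

    Features are processed in ``order`` (default: the matrix's column
    order).  A group opens with the first unassigned feature; any unassigned
    feature whose ``|r|`` with *every* current member exceeds the threshold
    joins.  Singleton groups report no mean/SD.
    """
    names = list(order) if order is not None else list(r_matrix.columns)
    absr = r_matrix.abs()
    unassigned = list(names)
    groups: list[CorrelationGroup] = []
    while unassigned:
        seedf = unassigned.pop(0)
        members = [seedf]
        for cand in list(unassigned):
            rs = [absr.loc[cand, m] for m in members]
            if all(np.isfinite(r) and r > threshold for r in rs):
                members.append(cand)
                unassigned.remove(cand)
        if len(members) > 1:
            pair_r = [
                absr.loc[a, b]
                for k, a in enumerate(members) for b in members[k + 1:]
            ]
            groups.append(CorrelationGroup(
                members=members,
                mean_abs_r=float(np.mean(pair_r)),
                sd_abs_r=float(np.std(pair_r, ddof=1)) if len(pair_r) > 1 else 0.0,
            ))
        else:
            groups.append(CorrelationGroup(members=members))
    return groups


def select_independent_indices(
    groups: list[CorrelationGroup],
    r_with_standard: dict[str, tuple[float, float]],
    threshold: float = 0.8,
    representatives: dict[int, str] | None = None,
) -> list[str]:
    """Pick one representative per correlation group (the first member,
    overridable per group index), then drop representatives whose ``|r|``
    with SUVmax or MTV exceeds the threshold."""
    representatives = representatives or {}
    selected = []
    for g_idx, group in enumerate(groups):
        rep = representatives.get(g_idx, group.members[0])
        if rep not in group.members:
            raise ValueError(f"{rep} is not a member of group {g_idx}")
        r_suv, r_mtv = r_with_standard.get(rep, (np.nan, np.nan))
        if np.isfinite(r_suv) and abs(r_suv) > threshold:
            continue
        if np.isfinite(r_mtv) and abs(r_mtv) > threshold:
            continue
        selected.append(rep)
    return selected


def bland_altman(a, b) -> BlandAltmanResult:
    """Bias = mean(a - b); limits of agreement = bias +/- 1.96 SD(a - b)
    (SD with n - 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, sd_diff=sd,
                             loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
                             n=int(a.size))


def friedman_test(values: np.ndarray) -> tuple[float, float]:
    """Friedman rank test over an ``n_subjects x k_conditions`` table.

    Average ranks for ties; the chi-square statistic
    ``12 / (n k (k+1)) * sum Rj^2 - 3 n (k+1)`` is referred to a
    chi-square with ``k - 1`` degrees of freedom.  Identical conditions give
    statistic 0 and p = 1.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2D table with at least 2 subjects")
    n, k = values.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, values)
    rj = ranks.sum(axis=0)
    statistic = 12.0 / (n * k * (k + 1)) * (rj**2).sum() - 3.0 * n * (k + 1)
    statistic = max(statistic, 0.0)
    p = float(sps.chi2.sf(statistic, k - 1)) if statistic > 0 else 1.0
    return float(statistic), p


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired series.

    Zero differences are dropped; the null distribution is exact for
    n <= 25 without ties, otherwise a tie/continuity-corrected normal
    approximation.  All-zero differences give p = 1 (degenerate)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    if d.size < 5:
        raise ValueError("need at least 5 non-zero differences")
    has_ties = np.unique(np.abs(d)).size < d.size
    mode = "approx" if (has_ties or d.size > 25) else "exact"
    res = sps.wilcoxon(d, alternative="two-sided", correction=(mode == "approx"),
                       method=mode)
    return float(res.statistic), float(res.pvalue)


def icc_agreement(obs1, obs2) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measure, for two raters scoring the same subjects.

    Computed from the classical mean squares:
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``.
    Zero between-subject variance is flagged as NaN.
    """
    y1 = np.asarray(obs1, dtype=float)
    y2 = np.asarray(obs2, dtype=float)
    if y1.shape != y2.shape or y1.size < 3:
        raise ValueError("need two equal-length series of at least 3 subjects")
    data = np.column_stack([y1, y2])
    ok = np.all(np.isfinite(data), axis=1)
    data = data[ok]
    n, k = data.shape
    if n < 3:
        raise ValueError("fewer than 3 complete subject pairs")
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    msr = k * ((subj_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((rater_means - grand) ** 2).sum() / (k - 1)
    mse = (
        ((data - subj_means[:, None] - rater_means[None, :] + grand) ** 2).sum()
        / ((n - 1) * (k - 1))
    )
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300 or (msr <= 1e-300 and mse <= 1e-300 and msc <= 1e-300):
        return float("nan")
    return float((msr - mse) / denom)


def landis_koch_label(icc: float) -> str:
    """Categorize an ICC on the Landis-Koch scale: excellent strictly above
    0.8, great (0.6, 0.8], moderate (0.4, 0.6], low (0.2, 0.4], poor at or
    below 0.2 (so 0.8 is great and 0.2 is poor)."""
    if not np.isfinite(icc):
        return "undefined"
    if icc > 1.0 + 1e-9:
        raise ValueError("ICC cannot exceed 1")
    if icc > 0.8:
        return "excellent"
    if icc > 0.6:
        return "great"
    if icc > 0.4:
        return "moderate"
    if icc > 0.2:
        return "low"
    return "poor"
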