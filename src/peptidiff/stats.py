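"""Per-peak Wilcoxon–Mann–Whitney testing, fold changes and incidences.

For every peak (matrix row) the two groups' intensity vectors are compared
with a two-sided Wilcoxon–Mann–Whitney (rank-sum) test.  Absent cells are
handled by a *missing policy*:

``"zero"`` (default)
    Absences enter the rank test as zeros — an undetected peak is below
    the detection limit, hence tied at the bottom of the ranking.  Tie
    correction absorbs the resulting ties.  Fold changes are still
    computed over detected samples only, so a peak undetected in one
    whole group gets a well-defined p-value but an undefined fold change.
``"detected-only"``
    Only detected samples enter the test; peaks where either group has no
    detections get an undefined (NaN) p-value.

No multiple-testing correction is applied; the study design instead
compares the count of p < alpha peaks against a label-scrambling
permutation background (see :mod:`peptidiff.permutation`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError
from .matrix import AnalysisMatrix

EXACT_MAX_N = 20  # exact null enumeration up to this pooled size (no ties)


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon–Mann–Whitney p-value for two samples.

    Uses the exact null distribution when the pooled size is at most 20 and
    there are no ties, and the normal approximation with tie and continuity
    corrections otherwise.  Symmetric in its arguments.  Two groups with no
    variation at all (every pooled value identical) give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigurationError("groups: both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    if pooled.size <= EXACT_MAX_N and not _has_ties(pooled):
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


@dataclass
class ComparisonResult:
    """Per-peak statistics for one pairwise group comparison.

    ``table`` has one row per matrix peak with columns ``mz``, ``p_value``,
    ``fold_change`` (>= 1, NaN when undefined), ``direction`` (``up-in-A``,
    ``down-in-A`` or ``undefined``), ``incidence_a`` and ``incidence_b``
    (integer percent).
    """

    name: str
    group_a: str
    group_b: str
    alpha: float
    table: pd.DataFrame

    @property
    def p_values(self) -> np.ndarray:
        return self.table["p_value"].to_numpy()

    @property
    def significant_set(self) -> np.ndarray:
        """Row positions of peaks with p < alpha (strict)."""
        p = self.p_values
        return np.flatnonzero(~np.isnan(p) & (p < self.alpha))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _incidence(n_detected: int, n_total: int, rounding: str) -> int:
    pct = 100.0 * n_detected / n_total
    if rounding == "truncate":
        return int(pct)
    if rounding == "round":
        return int(math.floor(pct + 0.5))
    raise ConfigurationError(f"incidence_rounding: unknown mode {rounding!r}")


def peak_pvalues(
    values: np.ndarray,
    in_a: np.ndarray,
    in_b: np.ndarray,
    missing_policy: str = "zero",
) -> np.ndarray:
    """Vector of per-row Mann–Whitney p-values for a peaks x samples array.

    ``values`` may contain NaN for absences; ``in_a``/``in_b`` are boolean
    sample masks.  This is the fast path shared by :func:`peak_statistics`
    and the permutation background: under the zero policy with more than 20
    samples the asymptotic test is evaluated for all rows in one vectorized
    call.
    """
    if missing_policy not in {"zero", "detected-only"}:
        raise ConfigurationError(f"missing_policy: unknown policy {missing_policy!r}")
    values = np.asarray(values, dtype=float)
    n_peaks = values.shape[0]
    out = np.full(n_peaks, np.nan)
    if n_peaks == 0:
        return out

    if missing_policy == "zero":
        filled = np.nan_to_num(values, nan=0.0)
        A = filled[:, in_a]
        B = filled[:, in_b]
        n_total = A.shape[1] + B.shape[1]
        degenerate = np.ptp(np.concatenate([A, B], axis=1), axis=1) == 0
        if n_total > EXACT_MAX_N:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = sps.mannwhitneyu(
                    A, B, alternative="two-sided", method="asymptotic",
                    use_continuity=True, axis=1,
                )
            out = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
        else:
            for i in range(n_peaks):
                out[i] = mann_whitney(A[i], B[i])
        out[degenerate] = 1.0
        return out

    for i in range(n_peaks):
        row = values[i]
        xa = row[in_a]
        xb = row[in_b]
        xa = xa[~np.isnan(xa)]
        xb = xb[~np.isnan(xb)]
        if xa.size == 0 or xb.size == 0:
            continue  # undefined under detected-only
        out[i] = mann_whitney(xa, xb)
    return out


def peak_statistics(
    m: AnalysisMatrix,
    group_a: str,
    group_b: str,
    missing_policy: str = "zero",
    alpha: float = 0.01,
    incidence_rounding: str = "round",
    name: str | None = None,
) -> ComparisonResult:
    """Full per-peak comparison of two groups of an analysis matrix.

    For each peak: the Mann–Whitney p-value under ``missing_policy``; the
    detection incidence of each group in integer percent; the fold change
    (larger group mean over smaller, means over detected samples only,
    undefined when either group has zero detections); and the direction of
    the change in group A relative to group B.
    """
    samples_a = m.group_samples(group_a)
    samples_b = m.group_samples(group_b)
    if not samples_a:
        raise ConfigurationError(f"groups: unknown or empty group {group_a!r}")
    if not samples_b:
        raise ConfigurationError(f"groups: unknown or empty group {group_b!r}")

    cols = list(m.intensities.columns)
    in_a = np.array([s in set(samples_a) for s in cols])
    in_b = np.array([s in set(samples_b) for s in cols])
    values = m.intensities.to_numpy(dtype=float)
    pvals = peak_pvalues(values, in_a, in_b, missing_policy)

    va = values[:, in_a]
    vb = values[:, in_b]
    det_a = (~np.isnan(va)).sum(axis=1)
    det_b = (~np.isnan(vb)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a_det = np.nanmean(va, axis=1)
        mean_b_det = np.nanmean(vb, axis=1)
    mean_a_zero = np.nan_to_num(va, nan=0.0).mean(axis=1)
    mean_b_zero = np.nan_to_num(vb, nan=0.0).mean(axis=1)

    n_peaks = values.shape[0]
    fold = np.full(n_peaks, np.nan)
    direction = np.full(n_peaks, "undefined", dtype=object)
    both = (det_a > 0) & (det_b > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        hi = np.maximum(mean_a_det, mean_b_det)
        lo = np.minimum(mean_a_det, mean_b_det)
        fold[both] = np.where(lo[both] > 0, hi[both] / lo[both], np.nan)
    direction[mean_a_zero > mean_b_zero] = "up-in-A"
    direction[mean_a_zero < mean_b_zero] = "down-in-A"

    inc_a = [_incidence(int(k), len(samples_a), incidence_rounding) for k in det_a]
    inc_b = [_incidence(int(k), len(samples_b), incidence_rounding) for k in det_b]

    table = pd.DataFrame(
        {
            "mz": m.peak_mzs,
            "p_value": pvals,
            "fold_change": fold,
            "direction": direction,
            "incidence_a": inc_a,
            "incidence_b": inc_b,
        }
    )
    return ComparisonResult(
        name=name or f"{group_a}_vs_{group_b}",
        group_a=group_a,
        group_b=group_b,
        alpha=alpha,
        table=table,
    )


def count_significant(r: ComparisonResult) -> int:
    """Number of peaks with p strictly below alpha."""
    return int(r.significant_set.size)


def overlap_significant(
    r1: ComparisonResult, r2: ComparisonResult, mz_tol_ppm: float = 5.0
) -> int:
    """Count of peaks significant in both comparisons.

    When both results come from the same matrix (identical m/z rows) the
    overlap is index-based; otherwise significant peaks are paired by m/z
    within ``mz_tol_ppm``.
    """
    mz1 = r1.table["mz"].to_numpy()
    mz2 = r2.table["mz"].to_numpy()
    s1 = r1.significant_set
    s2 = r2.significant_set
    if mz1.size == mz2.size and np.array_equal(mz1, mz2):
        return int(np.intersect1d(s1, s2).size)
    count = 0
    used: set[int] = set()
    for i in s1:
        for j in s2:
            if j in used:
                continue
            if abs(1e6 * (mz1[i] - mz2[j]) / mz2[j]) <= mz_tol_ppm:
                used.add(int(j))
                count += 1
                break
    return count
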