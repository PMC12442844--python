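"""Cross-method validation: repeatability, error budgets and agreement.

Two assay methods run on the same fruits will disagree; the question is
whether they disagree by more than their combined measurement error.  The
error budget sums, per calibration-standard level, the maximum
|known - predicted| calibration error of each method, averages those sums
over levels, and adds the repeat-sampling error of slurry replicates to
give a worst-case between-method tolerance.  Pairwise agreement is then
screened against that tolerance, taking the two-method mean as the best
estimate of truth so each method's deviation is half the pair difference.
A Wilcoxon signed-rank test (the paired analogue of the Mann-Whitney U
test, with conventional statistic V) compares the paired methods overall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidArgumentError

IQR_COEFFICIENT = 1.5
EXACT_SIGNED_RANK_MAX_N = 25


@dataclass(frozen=True)
class ErrorBudget:
    """Worst-case between-method disagreement tolerance, % w/w."""

    per_bin_error: dict[float, float]
    mean_calibration_error: float
    repeat_sampling_error: float

    @property
    def total_max_error(self) -> float:
        return self.mean_calibration_error + self.repeat_sampling_error


@dataclass(frozen=True)
class PairedMeasurement:
    sample_id: str
    method_a_pct: float
    method_b_pct: float

    def __post_init__(self) -> None:
        if self.method_a_pct < 0 or self.method_b_pct < 0:
            raise InvalidArgumentError("concentrations must be nonnegative")


def repeatability_mae(
    replicate_sets: list[list[float]],
) -> tuple[float, list[float]]:
    """Mean absolute deviation from the set mean, averaged over sets.

    Each set holds repeated assays of one pool of fruit slurry; the overall
    MAE is the mean of the per-set mean absolute deviations.
    """
    if not replicate_sets:
        raise InsufficientDataError("no replicate sets")
    per_set = []
    for reps in replicate_sets:
        if len(reps) < 2:
            raise InsufficientDataError("replicate sets need >= 2 measurements")
        arr = np.asarray(reps, dtype=float)
        per_set.append(float(np.mean(np.abs(arr - arr.mean()))))
    return float(np.mean(per_set)), per_set


def error_budget(
    calib_errors_by_method: dict[str, dict[float, float]],
    repeat_error: float,
) -> ErrorBudget:
    """Combine per-level maximum calibration errors across methods.

    ``calib_errors_by_method`` maps each method to {standard level: max
    |known - predicted|}.  All methods must cover the same levels.  The
    per-level errors are summed across methods, averaged over levels, and
    the repeat-sampling error is added on top.
    """
    if not calib_errors_by_method:
        raise InvalidArgumentError("no calibration errors supplied")
    if repeat_error < 0:
        raise InvalidArgumentError("repeat_error must be nonnegative")
    level_sets = [frozenset(d) for d in calib_errors_by_method.values()]
    if len(set(level_sets)) != 1:
        raise InvalidArgumentError("methods cover different standard levels")
    levels = sorted(level_sets[0])
    if not levels:
        raise InvalidArgumentError("no standard levels")
    per_bin = {
        lvl: float(sum(d[lvl] for d in calib_errors_by_method.values()))
        for lvl in levels
    }
    mean_err = float(np.mean(list(per_bin.values())))
    return ErrorBudget(
        per_bin_error=per_bin,
        mean_calibration_error=mean_err,
        repeat_sampling_error=float(repeat_error),
    )


def agreement_screen(
    pairs: list[PairedMeasurement], threshold: float
) -> tuple[list[float], int, float]:
    """Per-pair deviation from the two-method mean, screened at a tolerance.

    Taking both methods as unbiased, the best estimate for each fruit is
    the pair mean and each method deviates from it by |a - b| / 2.
    Returns (per-pair deviations, count under threshold, mean deviation).
    """
    if not pairs:
        raise InsufficientDataError("no paired measurements")
    if threshold <= 0:
        raise InvalidArgumentError("threshold must be positive")
    devs = [abs(p.method_a_pct - p.method_b_pct) / 2.0 for p in pairs]
    n_within = sum(d < threshold for d in devs)
    return devs, int(n_within), float(np.mean(devs))


def iqr_outliers(values: list[float], coefficient: float = IQR_COEFFICIENT) -> list[int]:
    """Indices outside [Q1 - c*IQR, Q3 + c*IQR], linear-interpolation quartiles."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise InsufficientDataError("IQR outlier detection needs >= 4 values")
    q1, q3 = np.percentile(arr, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - coefficient * iqr, q3 + coefficient * iqr
    return [int(i) for i in np.flatnonzero((arr < lo) | (arr > hi))]


def _signed_rank_exact_p(ranks2: np.ndarray, v2: float) -> float:
    """Exact two-sided p for the signed-rank statistic with midranks.

    ``ranks2`` are the absolute-difference ranks doubled so midranks become
    integers; ``v2`` is twice the observed V.  The null distribution of
    2V is built by dynamic programming over the 2^n equiprobable sign
    assignments (each rank independently contributes with probability 1/2),
    which is exactly the brute-force enumeration, aggregated.
    """
    total = int(round(ranks2.sum()))
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        r = int(round(r))
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    v2i = int(round(v2))
    p_le = float(dist[: v2i + 1].sum())
    p_ge = float(dist[v2i:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def paired_rank_test(pairs: list[PairedMeasurement]) -> tuple[float, float]:
    """Wilcoxon signed-rank test of paired method measurements.

    V is the sum of the ranks of positive differences (a - b), with zero
    differences dropped and midranks for tied absolute differences.  The
    two-sided p-value is exact (full sign-assignment enumeration) for up to
    25 informative pairs and a normal approximation with tie correction and
    continuity correction beyond.  If every difference is zero the test is
    degenerate: V = 0, p = 1.
    """
    if len(pairs) < 2:
        raise InsufficientDataError("need >= 2 pairs")
    d = np.array([p.method_a_pct - p.method_b_pct for p in pairs])
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))  # midranks for ties
    v = float(ranks[d > 0].sum())
    if n <= EXACT_SIGNED_RANK_MAX_N:
        p = _signed_rank_exact_p(np.round(ranks * 2), v * 2)
        return v, p
    mean = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over tie groups
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(np.sum(counts**3 - counts)) / 48.0
    if var == 0:
        return v, 1.0
    z = (v - mean - 0.5 * np.sign(v - mean)) / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return v, min(1.0, p)
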