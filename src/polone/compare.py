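"""Two-condition occupancy analytics.

Implements the conservative envelope difference (the smallest gap between two
conditions' replicate min-max envelopes), the low-coverage-masked log2 ratio
of mean frequency tracks, per-region summed-frequency statistics with Welch
two-sample t-tests, and cumulative-distribution (CDF) shift analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import RdnaAnnotation
from .coverage import CoverageProfile, ReplicateAggregate

__all__ = [
    "ComparisonTrack",
    "RegionSummary",
    "CdfProfile",
    "compare_tracks",
    "envelope_difference",
    "log2_ratio",
    "region_stats",
    "cdf",
    "cdf_shift",
    "star_label",
    "welch_ttest",
]

DEFAULT_CMIN = 5  # minimum raw count (any replicate, either condition)


def star_label(p: float) -> str:
    """Significance stars: *** p<0.005, ** p<0.01, * p<0.05, else ns."""
    if np.isnan(p):
        return "na"
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test.

    Degenerate zero-variance samples with equal means are reported as
    t = 0, p = 1 (no evidence of difference) rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        return np.nan, np.nan
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Envelope difference and masked log2 ratio
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonTrack:
    """Conservative difference, masked log2 ratio and low-coverage mask
    between two conditions (orientation: condition_a over/minus condition_b)."""

    difference: np.ndarray        # d(x), frequency units, signed
    log2_ratio: np.ndarray        # r(x); NaN at masked positions
    mask: np.ndarray              # True = excluded for low coverage
    condition_a: str = "A"
    condition_b: str = "B"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pos": np.arange(1, self.difference.size + 1),
             "difference": self.difference,
             "log2_ratio": self.log2_ratio,
             "masked": self.mask}
        )


def envelope_difference(agg_a: ReplicateAggregate,
                        agg_b: ReplicateAggregate) -> np.ndarray:
    """Conservative signed difference between two replicate envelopes.

    Where the envelopes are disjoint, d(x) is the (smallest) gap between
    them, positive when condition A lies above B; where they overlap,
    d(x) = 0.  This is the "lowest difference" between replicate ranges, a
    lower bound on |mean_A - mean_B| at every position.
    """
    if agg_a.unit_length != agg_b.unit_length:
        raise ValueError("aggregates have different lengths")
    above = agg_a.min - agg_b.max   # > 0 where A entirely above B
    below = agg_b.min - agg_a.max   # > 0 where B entirely above A
    d = np.where(above > 0, above, np.where(below > 0, -below, 0.0))
    return d


def log2_ratio(agg_a: ReplicateAggregate, agg_b: ReplicateAggregate,
               raw_counts: Sequence[CoverageProfile] | np.ndarray | None = None,
               c_min: int = DEFAULT_CMIN) -> tuple[np.ndarray, np.ndarray]:
    """Masked log2 of mean-frequency ratio A/B.

    A position is masked for low coverage when the minimum raw count over
    *all* replicates of both conditions falls below ``c_min``.  ``raw_counts``
    is the list of all per-replicate CoverageProfiles (both conditions) or a
    (n_replicates, L) count matrix; with ``raw_counts=None`` masking falls
    back to positions where either mean is zero.

    Returns ``(r, mask)`` with r = NaN at masked positions.
    """
    if agg_a.unit_length != agg_b.unit_length:
        raise ValueError("aggregates have different lengths")
    if raw_counts is None:
        mask = (agg_a.mean == 0) | (agg_b.mean == 0)
    else:
        if isinstance(raw_counts, np.ndarray):
            counts = raw_counts
        else:
            counts = np.stack([p.counts for p in raw_counts])
        if counts.shape[1] != agg_a.unit_length:
            raise ValueError("raw counts length mismatch")
        mask = counts.min(axis=0) < c_min
        # guard: a zero mean at an unmasked position cannot be log-ratioed
        mask |= (agg_a.mean == 0) | (agg_b.mean == 0)
    r = np.full(agg_a.unit_length, np.nan)
    ok = ~mask
    r[ok] = np.log2(agg_a.mean[ok] / agg_b.mean[ok])
    return r, mask


def compare_tracks(agg_a: ReplicateAggregate, agg_b: ReplicateAggregate,
                   raw_counts=None, c_min: int = DEFAULT_CMIN) -> ComparisonTrack:
    """Bundle envelope difference + masked log2 ratio into one track."""
    d = envelope_difference(agg_a, agg_b)
    r, mask = log2_ratio(agg_a, agg_b, raw_counts, c_min)
    return ComparisonTrack(difference=d, log2_ratio=r, mask=mask,
                           condition_a=agg_a.condition or "A",
                           condition_b=agg_b.condition or "B")


# ---------------------------------------------------------------------------
# Per-region summed frequencies with t-tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionSummary:
    """Per-region replicate sums and Welch test results.

    ``sums`` has one row per (region, condition, replicate) with the summed
    per-million frequency; ``table`` one row per region with mean ± SD per
    condition, the t statistic, two-sided p and the star label.
    """

    sums: pd.DataFrame
    table: pd.DataFrame
    condition_a: str
    condition_b: str


def _region_sums(profiles: Sequence[CoverageProfile],
                 annotation: RdnaAnnotation, condition: str) -> pd.DataFrame:
    rows = []
    for prof in profiles:
        if prof.unit_length != annotation.unit_length:
            raise ValueError("profile length does not match annotation")
        freq = prof.freq
        for reg in annotation.regions:
            rows.append((reg.name, condition, prof.replicate,
                         float(freq[reg.start - 1 : reg.end].sum())))
    return pd.DataFrame(rows, columns=["region", "condition", "replicate",
                                       "freq_sum"])


def region_stats(profiles_a: Sequence[CoverageProfile],
                 profiles_b: Sequence[CoverageProfile],
                 annotation: RdnaAnnotation,
                 condition_a: str = "A", condition_b: str = "B") -> RegionSummary:
    """Sum each replicate's frequency per annotated region and compare the
    two conditions region-wise with two-sided Welch t-tests.

    With fewer than two replicates on a side the sums are still reported and
    the test columns are NaN (marked not computable).
    """
    sums_a = _region_sums(profiles_a, annotation, condition_a)
    sums_b = _region_sums(profiles_b, annotation, condition_b)
    sums = pd.concat([sums_a, sums_b], ignore_index=True)

    rows = []
    for reg in annotation.regions:
        va = sums_a.loc[sums_a["region"] == reg.name, "freq_sum"].to_numpy()
        vb = sums_b.loc[sums_b["region"] == reg.name, "freq_sum"].to_numpy()
        t, p = welch_ttest(va, vb)
        rows.append(
            (reg.name, reg.start, reg.end,
             va.mean(), va.std(ddof=1) if va.size > 1 else np.nan,
             vb.mean(), vb.std(ddof=1) if vb.size > 1 else np.nan,
             t, p, star_label(p))
        )
    table = pd.DataFrame(
        rows,
        columns=["region", "start", "end", "mean_a", "sd_a", "mean_b", "sd_b",
                 "t", "p", "stars"],
    )
    return RegionSummary(sums=sums, table=table,
                         condition_a=condition_a, condition_b=condition_b)


# ---------------------------------------------------------------------------
# Cumulative distribution profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CdfProfile:
    """Mean cumulative occupancy distribution with its replicate envelope."""

    mean: np.ndarray
    min: np.ndarray
    max: np.ndarray
    condition: str = ""

    @property
    def unit_length(self) -> int:
        return self.mean.size

    @property
    def median_position(self) -> int:
        """First 1-based position where the mean CDF reaches 0.5."""
        return int(np.argmax(self.mean >= 0.5)) + 1


def _single_cdf(values: np.ndarray) -> np.ndarray:
    total = values.sum()
    if total <= 0:
        raise ValueError("all-zero profile has no CDF")
    return np.cumsum(values) / total


def cdf(profiles, condition: str | None = None) -> CdfProfile:
    """Cumulative distribution of occupancy along the unit.

    Accepts a ReplicateAggregate (envelope from its min/max tracks is not
    available, so mean CDF only is duplicated into the envelope), a list of
    CoverageProfiles (per-replicate CDFs give the envelope), or a bare
    per-base array.
    """
    if isinstance(profiles, ReplicateAggregate):
        c = _single_cdf(profiles.mean)
        return CdfProfile(mean=c, min=c.copy(), max=c.copy(),
                          condition=condition or profiles.condition)
    if isinstance(profiles, np.ndarray):
        c = _single_cdf(profiles)
        return CdfProfile(mean=c, min=c.copy(), max=c.copy(),
                          condition=condition or "")
    cdfs = np.stack([_single_cdf(p.freq) for p in profiles])
    conditions = {p.condition for p in profiles if p.condition}
    if condition is None:
        condition = next(iter(conditions), "") if len(conditions) <= 1 else ""
    return CdfProfile(mean=cdfs.mean(axis=0), min=cdfs.min(axis=0),
                      max=cdfs.max(axis=0), condition=condition)


def cdf_shift(cdf_a: CdfProfile, cdf_b: CdfProfile) -> tuple[int, float]:
    """Shift metrics between two mean CDFs.

    Returns ``(delta_median, signed_area)`` where delta_median is the
    difference of first positions reaching 0.5 (A minus B, ties toward
    smaller x) and signed_area = sum_x (C_A(x) - C_B(x)) / L.  A condition
    accumulating more occupancy 5'-proximally has the higher CDF, so with A
    the 5'-accumulated condition both metrics come out (delta_median <= 0,
    signed_area >= 0) for a rightward-shifted B.
    """
    if cdf_a.unit_length != cdf_b.unit_length:
        raise ValueError("CDFs have different lengths")
    delta_median = cdf_a.median_position - cdf_b.median_position
    signed_area = float((cdf_a.mean - cdf_b.mean).sum() / cdf_a.unit_length)
    return delta_median, signed_area
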