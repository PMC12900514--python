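"""Read-level CRAC processing: PCR-duplicate removal keyed on (start, end,
strand, UMI), per-base 3'-end coverage, hits-per-million normalization, and
replicate aggregation into mean / min-max envelope tracks."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import as_read_frame

__all__ = [
    "CoverageProfile",
    "ReplicateAggregate",
    "dedup",
    "coverage_3p",
    "aggregate",
]

DEDUP_KEY = ["start", "end", "strand", "umi"]


@dataclass(frozen=True)
class CoverageProfile:
    """Per-base 3'-end counts over the unit plus per-million frequencies.

    ``freq`` sums to 1e6 whenever ``total`` > 0 (hits repartition per million
    of reads mapped to the unit), and is identically zero otherwise.
    """

    counts: np.ndarray
    condition: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def unit_length(self) -> int:
        return self.counts.size

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def freq(self) -> np.ndarray:
        total = self.total
        if total == 0:
            return np.zeros(self.counts.size, dtype=float)
        return self.counts * (1e6 / total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pos": np.arange(1, self.unit_length + 1),
             "count": self.counts, "freq": self.freq}
        )


def dedup(reads, return_frame: bool | None = None):
    """Collapse PCR duplicates: one record per distinct (start, end, strand,
    UMI), keeping the first in input order.

    Returns ``(unique, n_removed)``; ``unique`` matches the input container
    type (DataFrame in, DataFrame out).
    """
    frame = as_read_frame(reads)
    unique = frame.drop_duplicates(subset=DEDUP_KEY, keep="first")
    n_removed = len(frame) - len(unique)
    unique = unique.reset_index(drop=True)
    if isinstance(reads, pd.DataFrame) or return_frame:
        return unique, n_removed
    from .annotation import frame_to_records

    return frame_to_records(unique), n_removed


def coverage_3p(reads, unit_length: int, strand_policy: str = "sense",
                condition: str = "", replicate: str = "") -> CoverageProfile:
    """Per-base coverage based on the 3' end of the reads.

    For a + strand read the 3' end is ``end``; for a - strand read it is
    ``start`` (leftmost coordinate under the inclusive convention).  The
    default ``sense`` policy drops - strand reads; ``both`` counts them too.
    """
    if strand_policy not in ("sense", "both"):
        raise ValueError("strand_policy must be 'sense' or 'both'")
    frame = as_read_frame(reads)
    if len(frame) and (
        (frame["start"].min() < 1) or (frame["end"].max() > unit_length)
    ):
        raise ValueError("read coordinates outside 1..unit_length")
    plus = frame[frame["strand"] == "+"]
    ends = plus["end"].to_numpy()
    if strand_policy == "both":
        minus = frame[frame["strand"] == "-"]
        ends = np.concatenate([ends, minus["start"].to_numpy()])
    counts = np.bincount(ends - 1, minlength=unit_length) if ends.size else \
        np.zeros(unit_length, dtype=np.int64)
    return CoverageProfile(counts=counts, condition=condition,
                           replicate=replicate)


@dataclass(frozen=True)
class ReplicateAggregate:
    """Pointwise mean and min-max envelope of replicate frequency tracks."""

    condition: str
    mean: np.ndarray
    min: np.ndarray
    max: np.ndarray
    n_replicates: int

    @property
    def unit_length(self) -> int:
        return self.mean.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pos": np.arange(1, self.unit_length + 1),
             "mean": self.mean, "min": self.min, "max": self.max}
        )


def aggregate(profiles: Sequence[CoverageProfile],
              condition: str | None = None) -> ReplicateAggregate:
    """Aggregate >= 1 same-condition coverage profiles into mean / min / max
    frequency tracks (with a single replicate the three coincide)."""
    if not profiles:
        raise ValueError("need at least one profile")
    lengths = {p.unit_length for p in profiles}
    if len(lengths) != 1:
        raise ValueError(f"mismatched unit lengths: {sorted(lengths)}")
    conditions = {p.condition for p in profiles if p.condition}
    if condition is None:
        if len(conditions) > 1:
            raise ValueError(f"mixed conditions: {sorted(conditions)}")
        condition = next(iter(conditions), "")
    elif conditions and conditions != {condition}:
        raise ValueError(f"profiles labelled {sorted(conditions)}, "
                         f"expected {condition!r}")
    freqs = np.stack([p.freq for p in profiles])
    return ReplicateAggregate(
        condition=condition,
        mean=freqs.mean(axis=0),
        min=freqs.min(axis=0),
        max=freqs.max(axis=0),
        n_replicates=len(profiles),
    )
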