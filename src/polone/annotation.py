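"""rDNA coordinate system, region annotation, probe catalog, and shared file I/O.

All internal coordinates are 1-based inclusive on the sense (+) strand of the
35S transcription unit; conversion to the 0-based half-open convention happens
only at file boundaries (bedGraph, BED).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "RdnaAnnotation",
    "Probe",
    "ProbeCatalog",
    "ReadRecord",
    "default_annotation",
    "default_probe_catalog",
    "region_of",
    "read_reads",
    "write_reads",
    "read_bedgraph",
    "write_bedgraph",
    "to_zero_based",
    "to_one_based",
    "read_annotation",
    "write_annotation",
    "annotation_to_bed",
]

READ_COLUMNS = ["start", "end", "strand", "umi", "replicate", "condition"]


@dataclass(frozen=True)
class Region:
    """A named interval of the 35S unit, 1-based inclusive."""

    name: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RdnaAnnotation:
    """Partition of the 35S rDNA unit into named regions.

    Regions must be non-overlapping, contiguous, sorted, start at 1 and end at
    ``unit_length``: every transcribed position belongs to exactly one region.
    """

    unit_length: int
    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        if self.unit_length <= 0:
            raise ValueError("unit_length must be positive")
        if not self.regions:
            raise ValueError("annotation needs at least one region")
        if self.regions[0].start != 1:
            raise ValueError("first region must start at position 1")
        if self.regions[-1].end != self.unit_length:
            raise ValueError(
                f"last region ends at {self.regions[-1].end}, expected unit_length "
                f"{self.unit_length}"
            )
        prev = self.regions[0]
        if prev.start > prev.end:
            raise ValueError(f"region {prev.name!r} has start > end")
        for reg in self.regions[1:]:
            if reg.start > reg.end:
                raise ValueError(f"region {reg.name!r} has start > end")
            if reg.start != prev.end + 1:
                raise ValueError(
                    f"regions {prev.name!r} and {reg.name!r} are not contiguous"
                )
            prev = reg
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def __getitem__(self, name: str) -> Region:
        for reg in self.regions:
            if reg.name == name:
                return reg
        raise KeyError(name)

    def region_of(self, position: int) -> str:
        return region_of(self, position)

    def region_labels(self) -> np.ndarray:
        """Region name for every position 1..unit_length (index 0 = position 1)."""
        out = np.empty(self.unit_length, dtype=object)
        for reg in self.regions:
            out[reg.start - 1 : reg.end] = reg.name
        return out


# Region coordinates of the S. cerevisiae 35S unit (1-based inclusive).
_DEFAULT_REGIONS = (
    Region("5'ETS", 1, 700),
    Region("18S", 701, 2499),
    Region("ITS1", 2500, 2858),
    Region("5.8S", 2859, 3019),
    Region("ITS2", 3020, 3250),
    Region("25S", 3251, 6647),
    Region("3'ETS", 6648, 6859),
)


def default_annotation() -> RdnaAnnotation:
    """The seven-region map of the 35S unit (5'ETS … 3'ETS, 6859 nt)."""
    return RdnaAnnotation(unit_length=6859, regions=_DEFAULT_REGIONS)


def region_of(annotation: RdnaAnnotation, position: int) -> str:
    """Name of the unique region containing a 1-based position."""
    if not 1 <= position <= annotation.unit_length:
        raise ValueError(
            f"position {position} outside unit 1..{annotation.unit_length}"
        )
    for reg in annotation.regions:
        if reg.start <= position <= reg.end:
            return reg.name
    raise AssertionError("annotation partition invariant violated")


# ---------------------------------------------------------------------------
# Probe catalog (slot-blot / northern oligonucleotides)
# ---------------------------------------------------------------------------

PROBE_ROLES = ("polI_signal", "control_5S", "background_IGS2")


@dataclass(frozen=True)
class Probe:
    name: str
    target_region: str  # region label, or "external" for non-35S targets
    role: str

    def __post_init__(self) -> None:
        if self.role not in PROBE_ROLES:
            raise ValueError(f"unknown probe role {self.role!r}")


@dataclass(frozen=True)
class ProbeCatalog:
    probes: tuple[Probe, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.probes]
        if len(set(names)) != len(names):
            raise ValueError("probe names must be unique")
        n_5s = sum(p.role == "control_5S" for p in self.probes)
        if n_5s != 2:
            raise ValueError(f"expected exactly two control_5S probes, got {n_5s}")
        if not any(p.role == "background_IGS2" for p in self.probes):
            raise ValueError("at least one background_IGS2 probe required")

    def __getitem__(self, name: str) -> Probe:
        for p in self.probes:
            if p.name == name:
                return p
        raise KeyError(name)

    def with_role(self, role: str) -> list[Probe]:
        return [p for p in self.probes if p.role == role]

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.probes]


def default_probe_catalog() -> ProbeCatalog:
    """Antisense oligo set along the rDNA unit: three 5'ETS probes, probes in
    18S/25S/3'ETS, two 5S loading controls and an intergenic IGS2 background."""
    return ProbeCatalog(
        (
            Probe("5'ETS.1", "5'ETS", "polI_signal"),
            Probe("5'ETS.2", "5'ETS", "polI_signal"),
            Probe("5'ETS.3", "5'ETS", "polI_signal"),
            Probe("18S.1", "18S", "polI_signal"),
            Probe("18S.2", "18S", "polI_signal"),
            Probe("25S.1", "25S", "polI_signal"),
            Probe("25S.2", "25S", "polI_signal"),
            Probe("3'ETS", "3'ETS", "polI_signal"),
            Probe("5S.1", "external", "control_5S"),
            Probe("5S.2", "external", "control_5S"),
            Probe("IGS2", "external", "background_IGS2"),
        )
    )


# ---------------------------------------------------------------------------
# Read records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadRecord:
    """One aligned CRAC read on the rDNA unit (1-based inclusive ends)."""

    start: int
    end: int
    strand: str
    umi: str
    replicate: str
    condition: str


def records_to_frame(records: Iterable[ReadRecord]) -> pd.DataFrame:
    rows = [
        (r.start, r.end, r.strand, r.umi, r.replicate, r.condition) for r in records
    ]
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[ReadRecord]:
    return [
        ReadRecord(int(t.start), int(t.end), t.strand, t.umi, t.replicate, t.condition)
        for t in frame.itertuples(index=False)
    ]


def as_read_frame(reads) -> pd.DataFrame:
    """Accept a read DataFrame or an iterable of ReadRecord."""
    if isinstance(reads, pd.DataFrame):
        missing = [c for c in READ_COLUMNS if c not in reads.columns]
        if missing:
            raise ValueError(f"read table missing columns: {missing}")
        return reads
    return records_to_frame(reads)


def _validate_read_frame(frame: pd.DataFrame, path) -> pd.DataFrame:
    # line numbers: header is line 1, first data row line 2
    for col in ("start", "end"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() | (coerced != coerced.round())
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(f"{path}: non-integer {col!r} at line {line}")
        frame[col] = coerced.astype(int)
    bad = frame["start"] < 1
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"{path}: start < 1 (coordinates are 1-based) at line {line}")
    bad = frame["start"] > frame["end"]
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"{path}: start > end at line {line}")
    bad = ~frame["strand"].isin(["+", "-"])
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"{path}: strand must be '+' or '-' at line {line}")
    return frame


def read_reads(path) -> pd.DataFrame:
    """Read a tab-separated read table (columns start, end, strand, umi,
    replicate, condition); malformed rows are rejected with their line number."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in READ_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    frame = frame[READ_COLUMNS].copy()
    return _validate_read_frame(frame, path)


def write_reads(reads, path) -> None:
    frame = as_read_frame(reads)
    frame.to_csv(path, sep="\t", index=False, columns=READ_COLUMNS)


# ---------------------------------------------------------------------------
# Coordinate conversion and bedGraph
# ---------------------------------------------------------------------------


def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open [start0, end0)."""
    return start - 1, end


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open [start0, end0) -> 1-based inclusive interval."""
    return start0 + 1, end0


def write_bedgraph(profile, path, track_name: str | None = None,
                   chrom: str = "rDNA", emit_zero: bool = True) -> None:
    """Write per-base values as bedGraph (0-based half-open), merging runs of
    equal value into single intervals.

    ``profile`` may be a CoverageProfile (its ``freq`` is written) or a plain
    per-base array indexed from position 1.
    """
    values = np.asarray(getattr(profile, "freq", profile), dtype=float)
    path = Path(path)
    with path.open("w") as fh:
        if track_name is not None:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        if values.size == 0:
            return
        # run-length encode equal adjacent values
        change = np.flatnonzero(values[1:] != values[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [values.size]))
        for s, e in zip(starts, ends):
            v = values[s]
            if v == 0 and not emit_zero:
                continue
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def read_bedgraph(path, unit_length: int) -> np.ndarray:
    """Expand a single-chromosome bedGraph back to a per-base value array
    (index 0 = position 1); positions not covered by any interval are 0."""
    values = np.zeros(unit_length, dtype=float)
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            _, s0, e0, v = line.split("\t")
            s0, e0 = int(s0), int(e0)
            if not 0 <= s0 < e0 <= unit_length:
                raise ValueError(f"{path}: interval [{s0},{e0}) outside unit")
            values[s0:e0] = float(v)
    return values


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------


def write_annotation(annotation: RdnaAnnotation, path) -> None:
    """Native TSV export (1-based inclusive): region, start, end."""
    frame = pd.DataFrame(
        [(r.name, r.start, r.end) for r in annotation.regions],
        columns=["region", "start", "end"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> RdnaAnnotation:
    frame = pd.read_csv(path, sep="\t")
    regions = tuple(
        Region(str(t.region), int(t.start), int(t.end))
        for t in frame.itertuples(index=False)
    )
    return RdnaAnnotation(unit_length=regions[-1].end, regions=regions)


def annotation_to_bed(annotation: RdnaAnnotation, path, chrom: str = "rDNA") -> None:
    """BED6-compatible export (0-based half-open)."""
    with open(path, "w") as fh:
        for reg in annotation.regions:
            s0, e0 = to_zero_based(reg.start, reg.end)
            fh.write(f"{chrom}\t{s0}\t{e0}\t{reg.name}\t0\t+\n")
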