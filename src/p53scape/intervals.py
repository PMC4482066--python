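"""Genomic interval data model and overlap engine.

All coordinates are 0-based half-open, matching BED. Coordinate strings in
the UCSC browser style ("chrN:x-y", 1-based inclusive) are converted on
ingest via :func:`parse_ucsc_region`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Raised for a malformed BED line; the message names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp. Strand is ignored."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def parse_ucsc_region(region: str, strand: str = ".", name: str | None = None) -> GenomicInterval:
    """Convert a browser-style region string to a half-open interval.

    "chr17:67,603,115-67,604,105" is read as 1-based inclusive, so
    start = x - 1 and end = y.
    """
    chrom, _, coords = region.partition(":")
    lo, _, hi = coords.replace(",", "").replace("–", "-").partition("-")
    return GenomicInterval(chrom, int(lo) - 1, int(hi), strand=strand, name=name)


class IntervalSet:
    """A queryable collection of intervals with union-based coverage.

    Coverage is always the length of the union of the member intervals;
    duplicated or overlapping members never count twice.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), source: str = ""):
        self.source = source
        self._intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    @property
    def intervals(self) -> list[GenomicInterval]:
        return list(self._intervals)

    def chromosomes(self) -> list[str]:
        return sorted({iv.chrom for iv in self._intervals})

    def by_chrom(self, chrom: str) -> list[GenomicInterval]:
        return [iv for iv in self._intervals if iv.chrom == chrom]

    # -- union / coverage ---------------------------------------------------------
    def _merged_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) of the merged union, both ascending."""
        if self._merged is None:
            merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            cur_chrom: str | None = None
            starts: list[int] = []
            ends: list[int] = []

            def flush() -> None:
                if cur_chrom is not None:
                    merged[cur_chrom] = (
                        np.asarray(starts, dtype=np.int64),
                        np.asarray(ends, dtype=np.int64),
                    )

            for iv in self._intervals:
                if iv.chrom != cur_chrom:
                    flush()
                    cur_chrom, starts, ends = iv.chrom, [], []
                if ends and iv.start <= ends[-1]:
                    ends[-1] = max(ends[-1], iv.end)
                else:
                    starts.append(iv.start)
                    ends.append(iv.end)
            flush()
            self._merged = merged
        return self._merged

    def merged(self) -> "IntervalSet":
        """The union of this set as non-overlapping intervals."""
        out = []
        for chrom, (starts, ends) in self._merged_arrays().items():
            out.extend(
                GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)
            )
        return IntervalSet(out, source=self.source)

    def coverage(self) -> int:
        """Total nucleotides covered by the union of the set."""
        total = 0
        for starts, ends in self._merged_arrays().values():
            total += int((ends - starts).sum())
        return total

    # -- queries ------------------------------------------------------------------
    def overlaps_interval(self, iv: GenomicInterval) -> bool:
        """True iff `iv` shares >= 1 bp with any member interval."""
        arrs = self._merged_arrays().get(iv.chrom)
        if arrs is None:
            return False
        starts, ends = arrs
        j = int(np.searchsorted(starts, iv.end, side="left"))
        return j > 0 and int(ends[j - 1]) > iv.start

    def overlap_flags(self, intervals: Sequence[GenomicInterval]) -> np.ndarray:
        """Vectorized membership test: which query intervals touch the set."""
        flags = np.zeros(len(intervals), dtype=bool)
        merged = self._merged_arrays()
        for i, iv in enumerate(intervals):
            arrs = merged.get(iv.chrom)
            if arrs is None:
                continue
            starts, ends = arrs
            j = int(np.searchsorted(starts, iv.end, side="left"))
            flags[i] = j > 0 and int(ends[j - 1]) > iv.start
        return flags

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Exact base-pair intersection (merged). Commutative."""
        out: list[GenomicInterval] = []
        a_merged = self._merged_arrays()
        b_merged = other._merged_arrays()
        for chrom in set(a_merged) & set(b_merged):
            a_s, a_e = a_merged[chrom]
            b_s, b_e = b_merged[chrom]
            i = j = 0
            while i < len(a_s) and j < len(b_s):
                lo = max(a_s[i], b_s[j])
                hi = min(a_e[i], b_e[j])
                if lo < hi:
                    out.append(GenomicInterval(chrom, int(lo), int(hi)))
                if a_e[i] < b_e[j]:
                    i += 1
                else:
                    j += 1
        return IntervalSet(out, source=f"{self.source}&{other.source}")

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Base pairs of this set's union not covered by `other`."""
        out: list[GenomicInterval] = []
        b_merged = other._merged_arrays()
        for chrom, (a_s, a_e) in self._merged_arrays().items():
            if chrom not in b_merged:
                out.extend(
                    GenomicInterval(chrom, int(s), int(e)) for s, e in zip(a_s, a_e)
                )
                continue
            b_s, b_e = b_merged[chrom]
            for s, e in zip(a_s, a_e):
                pos = int(s)
                # walk blockers overlapping [s, e)
                j = int(np.searchsorted(b_e, pos, side="right"))
                while j < len(b_s) and b_s[j] < e:
                    if b_s[j] > pos:
                        out.append(GenomicInterval(chrom, pos, int(b_s[j])))
                    pos = max(pos, int(b_e[j]))
                    j += 1
                if pos < e:
                    out.append(GenomicInterval(chrom, pos, int(e)))
        return IntervalSet(out, source=self.source)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """>= 1 shared bp on the same chromosome; strand ignored."""
    return a.overlaps(b)


def intersect_sets(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.intersect(b)


def coverage(a: IntervalSet) -> int:
    return a.coverage()


# -- peaks ------------------------------------------------------------------------


@dataclass(frozen=True)
class Peak:
    """A binding-site interval with a read-density intensity.

    Intensity is in FPKM units: fragments per kilobase of peak per million
    mapped fragments in the immunoprecipitated sample.
    """

    interval: GenomicInterval
    intensity: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("peak intensity must be >= 0")

    @property
    def name(self) -> str | None:
        return self.interval.name


class PeakSet:
    """An ordered collection of peaks; subject of filtering and enrichment."""

    def __init__(self, peaks: Iterable[Peak] = (), source: str = "",
                 filters: tuple[str, ...] = ()):
        self.peaks: list[Peak] = sorted(
            peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )
        self.source = source
        self.filters = filters

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]

    def interval_set(self) -> IntervalSet:
        return IntervalSet(self.intervals, source=self.source)

    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)


def merge_peak_sets(a: PeakSet, b: PeakSet) -> PeakSet:
    """Peaks of `a` that overlap >= 1 peak of `b` (reference-asymmetric).

    Peak boundaries differ between replicates, so the shared set is reported
    in the reference (`a`) coordinates; the convention is recorded in the
    result's source label.
    """
    b_set = b.interval_set()
    flags = b_set.overlap_flags(a.intervals)
    shared = [p for p, keep in zip(a.peaks, flags) if keep]
    return PeakSet(shared, source=f"common({a.source},{b.source};ref={a.source})")


# -- BED I/O ----------------------------------------------------------------------


def read_bed(path: str | Path, has_score: bool = False) -> IntervalSet:
    """Read BED3/4/6 into an IntervalSet (coordinates taken verbatim).

    Column 4 becomes the interval name and column 6 the strand when present.
    Use :func:`read_peaks` when column 5 carries peak intensities.
    """
    intervals = []
    for lineno, fields in _bed_lines(path):
        iv = _interval_from_fields(fields, lineno, path)
        intervals.append(iv)
    return IntervalSet(intervals, source=str(path))


def read_peaks(path: str | Path) -> PeakSet:
    """Read BED5/6 where column 5 is the peak intensity (FPKM)."""
    peaks = []
    for lineno, fields in _bed_lines(path):
        iv = _interval_from_fields(fields, lineno, path)
        if len(fields) < 5:
            raise BedParseError(f"{path}:{lineno}: peak line lacks intensity column")
        try:
            intensity = float(fields[4])
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: non-numeric intensity") from exc
        peaks.append(Peak(iv, intensity))
    return PeakSet(peaks, source=str(path))


def _bed_lines(path: str | Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            yield lineno, fields


def _interval_from_fields(fields: list[str], lineno: int, path) -> GenomicInterval:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    name = fields[3] if len(fields) >= 4 and fields[3] != "." else None
    strand = fields[5] if len(fields) >= 6 else "."
    if start >= end or start < 0:
        raise BedParseError(f"{path}:{lineno}: invalid interval {start}-{end}")
    return GenomicInterval(fields[0], start, end, strand=strand, name=name)


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              scores: Mapping[str, float] | None = None) -> None:
    """Write BED sorted by (chrom, start); name/strand emitted when present."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in ivs:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand != ".":
                fields.append(iv.name or ".")
            if iv.strand != ".":
                fields.extend(["0", iv.strand])
            fh.write("\t".join(fields) + "\n")


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            # repr round-trips the float exactly
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{p.intensity!r}\n"
            )
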