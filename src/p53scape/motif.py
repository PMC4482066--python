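"""Stringent scanner for the p53 response element (RE).

The canonical RE is a pair of degenerate 7-mer half-sites, RCWWGYY and
RRCWWGY in IUPAC notation, separated by a 2-4 nt spacer of arbitrary
sequence. Tetrameric p53 binds the two half-sites as a dimer of dimers,
which is why the default motif is its own reverse complement.

Matching is exact against the degenerate consensus: no mismatches are
allowed, and `N` in the genome never matches a pattern letter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .intervals import GenomicInterval, Peak, PeakSet

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "N": "ACGT",
}
# complement within the IUPAC subset we accept
IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "W": "W", "N": "N",
}
_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class MotifSpec:
    """Two degenerate half-sites with a variable-length spacer."""

    half_site_1: str = "RCWWGYY"
    half_site_2: str = "RRCWWGY"
    spacer_min: int = 2
    spacer_max: int = 4

    def __post_init__(self) -> None:
        if not (0 <= self.spacer_min <= self.spacer_max):
            raise MotifError("require 0 <= spacer_min <= spacer_max")
        for half in (self.half_site_1, self.half_site_2):
            bad = set(half.upper()) - set(IUPAC)
            if bad:
                raise MotifError(f"invalid IUPAC letters {sorted(bad)} in {half!r}")
            if not half:
                raise MotifError("empty half-site pattern")

    @property
    def spacer_lengths(self) -> range:
        return range(self.spacer_min, self.spacer_max + 1)

    @property
    def min_length(self) -> int:
        return len(self.half_site_1) + self.spacer_min + len(self.half_site_2)

    def is_self_reverse_complement(self) -> bool:
        """True iff the degenerate pattern family equals its own reverse
        complement (the default p53 RE does)."""
        return iupac_reverse_complement(self.half_site_1) == self.half_site_2


def iupac_reverse_complement(pattern: str) -> str:
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(pattern.upper()))


def _half_regex(pattern: str) -> str:
    parts = []
    for c in pattern.upper():
        opts = IUPAC[c]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


@dataclass(frozen=True)
class MotifHit:
    """A single motif occurrence; the interval is the full match footprint."""

    interval: GenomicInterval
    spacer_len: int
    matched_seq: str
    strand: str  # "+", "-", or "both" for self-reverse-complement motifs


class CompiledMotif:
    """A scanner recognizing h1 . spacer . h2 for all admissible spacers."""

    def __init__(self, spec: MotifSpec):
        self.spec = spec
        self.palindromic = spec.is_self_reverse_complement()
        h1 = _half_regex(spec.half_site_1)
        h2 = _half_regex(spec.half_site_2)
        # lookahead so overlapping occurrences are all reported
        self._fwd = {
            k: re.compile(f"(?=({h1}[ACGT]{{{k}}}{h2}))")
            for k in spec.spacer_lengths
        }

    def scan(self, seq: str, chrom: str = "", offset: int = 0) -> list[MotifHit]:
        """All hits in `seq`, ordered by (start, spacer_len).

        For a self-reverse-complement spec scanning the forward strand covers
        both strands and hits carry strand "both"; otherwise both strands are
        scanned and double-counted footprints are merged to "both".
        """
        seq = seq.upper()
        hits: dict[tuple[int, int], MotifHit] = {}
        for k, rx in self._fwd.items():
            for m in rx.finditer(seq):
                start = m.start()
                matched = m.group(1)
                key = (start, k)
                strand = "both" if self.palindromic else "+"
                hits[key] = self._hit(chrom, offset, start, k, matched, strand)
        if not self.palindromic:
            rc = seq.translate(_DNA_COMPLEMENT)[::-1]
            n = len(seq)
            for k, rx in self._fwd.items():
                for m in rx.finditer(rc):
                    length = len(m.group(1))
                    start = n - m.start() - length
                    key = (start, k)
                    if key in hits:
                        prev = hits[key]
                        hits[key] = MotifHit(prev.interval, prev.spacer_len,
                                             prev.matched_seq, "both")
                    else:
                        hits[key] = self._hit(chrom, offset, start, k,
                                              seq[start:start + length], "-")
        return [hits[k] for k in sorted(hits)]

    def _hit(self, chrom, offset, start, spacer_len, matched, strand) -> MotifHit:
        iv = GenomicInterval(chrom or "seq", offset + start,
                             offset + start + len(matched),
                             name=f"p53RE_s{spacer_len}")
        return MotifHit(iv, spacer_len, matched, strand)


def compile_motif(spec: MotifSpec) -> CompiledMotif:
    return CompiledMotif(spec)


def scan_sequence(seq: str, spec: MotifSpec | CompiledMotif,
                  chrom: str = "", offset: int = 0) -> list[MotifHit]:
    scanner = spec if isinstance(spec, CompiledMotif) else CompiledMotif(spec)
    return scanner.scan(seq, chrom=chrom, offset=offset)


def peaks_with_motif(
    peaks: PeakSet,
    genome: Mapping[str, object],
    spec: MotifSpec | None = None,
) -> tuple[PeakSet, PeakSet, dict[str, int]]:
    """Partition peaks by presence of >= 1 exact motif hit.

    `genome` is any chrom -> sliceable-sequence mapping (a dict of strings,
    a pyfaidx.Fasta, or the simulator's genome object). Returns the
    (with_motif, without_motif) peak sets and a count summary.
    """
    scanner = CompiledMotif(spec or MotifSpec())
    with_m, without_m = [], []
    for peak in peaks:
        iv = peak.interval
        try:
            record = genome[iv.chrom]
        except KeyError as exc:
            raise KeyError(
                f"peak {iv.name or str(iv)}: chromosome {iv.chrom!r} absent from genome"
            ) from exc
        seq = str(record[iv.start:iv.end])
        if scanner.scan(seq):
            with_m.append(peak)
        else:
            without_m.append(peak)
    summary = {
        "n_with_motif": len(with_m),
        "n_without_motif": len(without_m),
        "n_total": len(peaks),
    }
    return (
        PeakSet(with_m, source=f"{peaks.source}|with_motif", filters=peaks.filters),
        PeakSet(without_m, source=f"{peaks.source}|without_motif", filters=peaks.filters),
        summary,
    )


def write_hits_bed(hits: Iterable[MotifHit], path) -> None:
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.interval.chrom, h.interval.start)):
            iv = h.interval
            strand = {"both": ".", "+": "+", "-": "-"}[h.strand]
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{strand}\n")
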