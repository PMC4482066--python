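"""Direct-target calling from ChIP peaks and TSS windows.

A gene is called a direct target when at least one binding-site peak falls
inside a symmetric window around its transcription start site (30 kb each
way for human, 20 kb for mouse). Expression changes of bound vs unbound
genes are compared with the two-sample Kolmogorov-Smirnov test.

Two distance conventions coexist, both strand-aware (negative = upstream of
the gene):

* target calls record the signed distance from the TSS to the nearest edge
  of the supporting peak (0 if the TSS lies inside the peak), so the
  distance of any supporting peak is bounded by the window half-width;
* genome-wide distance profiles use the peak midpoint, matching how
  peak-to-TSS histograms are conventionally drawn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionRecord, ExpressionTable
from .intervals import GenomicInterval, Peak, PeakSet


@dataclass(frozen=True)
class TargetCall:
    gene_id: str
    direction: str  # "up" or "down", from the sign of log2fc
    supporting_peaks: tuple[Peak, ...]
    min_tss_distance: int  # signed, strand-aware; negative = upstream

    def __post_init__(self) -> None:
        if not self.supporting_peaks:
            raise ValueError("a target call requires >= 1 supporting peak")


@dataclass
class TargetCallResult:
    calls: list[TargetCall]
    n_peaks_supporting: int  # peaks supporting >= 1 target
    n_peaks_total: int

    @property
    def fraction_peaks_supporting(self) -> float:
        """Fraction of binding sites associated with regulation of a nearby
        transcript."""
        return self.n_peaks_supporting / self.n_peaks_total if self.n_peaks_total else 0.0

    def target_ids(self) -> set[str]:
        return {c.gene_id for c in self.calls}

    def counts_by_direction(self) -> dict[str, int]:
        out = {"up": 0, "down": 0}
        for c in self.calls:
            out[c.direction] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": c.gene_id,
                "direction": c.direction,
                "n_peaks": len(c.supporting_peaks),
                "min_tss_distance": c.min_tss_distance,
            }
            for c in sorted(self.calls, key=lambda c: c.gene_id)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "direction", "n_peaks",
                                           "min_tss_distance"])


@dataclass
class DistanceProfile:
    """Signed peak-midpoint to nearest-TSS distances, one per usable peak."""

    distances: list[int]
    bin_width: int = 1000
    n_excluded: int = 0  # peaks on chromosomes without any gene

    def histogram(self, max_distance: int = 50000) -> tuple[np.ndarray, np.ndarray]:
        edges = np.arange(-max_distance, max_distance + self.bin_width, self.bin_width)
        counts, edges = np.histogram(self.distances, bins=edges)
        return counts, edges


def tss_window(
    gene: ExpressionRecord,
    half_width: int,
    chrom_sizes: Mapping[str, int] | None = None,
) -> GenomicInterval:
    """Symmetric window [TSS - W, TSS + W] around the TSS, half-open
    [TSS - W, TSS + W + 1); both flanks are inclusive. Clipped at the
    chromosome origin always, and at the chromosome end when sizes are
    supplied."""
    if half_width <= 0:
        raise ValueError("window half-width must be positive")
    tss = gene.tss.start
    lo = max(0, tss - half_width)
    hi = tss + half_width + 1
    if chrom_sizes is not None:
        if gene.tss.chrom not in chrom_sizes:
            raise KeyError(f"no chromosome length for {gene.tss.chrom!r}")
        hi = min(hi, chrom_sizes[gene.tss.chrom])
    return GenomicInterval(gene.tss.chrom, lo, hi, strand=gene.tss.strand,
                           name=gene.gene_id)


def _signed_edge_distance(tss: int, peak: GenomicInterval, strand: str) -> int:
    """Signed distance from the TSS to the nearest base of the peak; 0 if the
    TSS is inside the peak. Positive downstream of the gene."""
    if peak.start <= tss < peak.end:
        return 0
    raw = peak.start - tss if tss < peak.start else peak.end - 1 - tss
    return -raw if strand == "-" else raw


def call_direct_targets(
    de: ExpressionTable,
    peaks: PeakSet,
    half_width: int,
    chrom_sizes: Mapping[str, int] | None = None,
) -> TargetCallResult:
    """Intersect peaks with TSS windows of the (filtered) DE table.

    Every record of `de` is treated as a differentially expressed gene; pass
    a table that has been through the expression filters. A warning (not an
    error) is emitted when the table carries no filter provenance.
    """
    if not de.filters:
        warnings.warn(
            "expression table carries no filter provenance; "
            "direct-target calling expects a filtered table",
            stacklevel=2,
        )
    # per-chrom sorted peak arrays for the window query
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, p in enumerate(peaks):
        by_chrom.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end, idx)
        )
    arrs = {}
    for chrom, triples in by_chrom.items():
        triples.sort()
        starts = np.array([t[0] for t in triples])
        ends = np.array([t[1] for t in triples])
        idxs = np.array([t[2] for t in triples])
        arrs[chrom] = (starts, ends, idxs)

    peak_list = list(peaks)
    calls: list[TargetCall] = []
    supporting: set[int] = set()
    for gene in de:
        win = tss_window(gene, half_width, chrom_sizes)
        got = arrs.get(win.chrom)
        if got is None:
            continue
        starts, ends, idxs = got
        # overlap: peak.start < win.end and peak.end > win.start
        cand = np.flatnonzero((starts < win.end) & (ends > win.start))
        if cand.size == 0:
            continue
        sel = [int(idxs[i]) for i in cand]
        supporting.update(sel)
        tss = gene.tss.start
        dists = [
            _signed_edge_distance(tss, peak_list[i].interval, gene.tss.strand)
            for i in sel
        ]
        # min by |d|; ties resolved toward the upstream (negative) side
        best = min(dists, key=lambda d: (abs(d), d))
        calls.append(TargetCall(
            gene_id=gene.gene_id,
            direction="up" if gene.log2fc >= 0 else "down",
            supporting_peaks=tuple(peak_list[i] for i in sel),
            min_tss_distance=best,
        ))
    return TargetCallResult(calls, len(supporting), len(peaks))


def peak_tss_distances(
    peaks: PeakSet,
    genes: ExpressionTable,
    bin_width: int = 1000,
) -> DistanceProfile:
    """Distance from each peak midpoint to its nearest TSS.

    Nearest is chosen by absolute genomic distance; ties break toward the
    upstream (smaller-coordinate) TSS. The sign is strand-aware for the
    chosen gene. Peaks on chromosomes with no annotated gene are excluded
    and counted in `n_excluded`.
    """
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.tss.chrom, []).append((g.tss.start, g.tss.strand))
    sorted_tss = {
        c: (np.array([t[0] for t in sorted(v)]), [t[1] for t in sorted(v)])
        for c, v in tss_by_chrom.items()
    }

    distances: list[int] = []
    n_excluded = 0
    for p in peaks:
        chrom = p.interval.chrom
        if chrom not in sorted_tss:
            n_excluded += 1
            continue
        positions, strands = sorted_tss[chrom]
        mid = p.interval.midpoint
        j = int(np.searchsorted(positions, mid))
        cand = [k for k in (j - 1, j) if 0 <= k < len(positions)]
        # nearest by |distance|, tie toward the smaller coordinate
        best = min(cand, key=lambda k: (abs(int(positions[k]) - mid), positions[k]))
        raw = mid - int(positions[best])
        distances.append(-raw if strands[best] == "-" else raw)
    return DistanceProfile(distances, bin_width=bin_width, n_excluded=n_excluded)


def ks_bound_vs_unbound(
    de: ExpressionTable, bound_ids: set[str]
) -> tuple[float, float]:
    """Two-sample KS test on log2 fold changes of bound vs unbound genes.

    Returns (D, asymptotic p). D = sup |F_bound - F_unbound| in [0, 1].
    """
    bound = [r.log2fc for r in de if r.gene_id in bound_ids]
    unbound = [r.log2fc for r in de if r.gene_id not in bound_ids]
    if not bound or not unbound:
        raise ValueError("both the bound and unbound groups must be non-empty")
    res = stats.ks_2samp(bound, unbound, method="asymp")
    return float(res.statistic), float(res.pvalue)
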