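"""Differential-expression tables and the study's filtering rules.

The upstream differential-expression caller (e.g. Cuffdiff2) supplies the
per-gene FPKM values, fold changes and significance flags; this module only
models that output and applies the downstream filters:

* significant protein-coding genes restricted to the top 75% of expressed
  genes by FPKM,
* significant lincRNAs restricted to those with FPKM > 1 in at least one
  sample,
* ChIP peaks restricted to the top 75% by read coverage (FPKM).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Peak, PeakSet

BIOTYPES = ("mRNA", "lincRNA")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    biotype: str
    tss: GenomicInterval  # length-1 interval carrying the strand
    fpkm_by_sample: dict[str, float]
    log2fc: float
    significant: bool

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if any(v < 0 for v in self.fpkm_by_sample.values()):
            raise ValueError(f"negative FPKM for {self.gene_id}")
        if self.tss.length != 1:
            raise ValueError("TSS must be a length-1 interval")

    def summary_fpkm(self, how: str = "max") -> float:
        vals = list(self.fpkm_by_sample.values())
        return max(vals) if how == "max" else float(np.mean(vals))


class ExpressionTable:
    """Per-gene expression records with unique gene ids.

    `filters` records which filtering rules have already been applied, making
    the filters idempotent and letting downstream stages warn when handed an
    unfiltered table.
    """

    def __init__(self, records: Iterable[ExpressionRecord], samples: Sequence[str],
                 filters: tuple[str, ...] = ()):
        self.records = list(records)
        self.samples = list(samples)
        self.filters = filters
        ids = [r.gene_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in expression table")
        self._by_id = {r.gene_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ExpressionRecord]:
        return iter(self.records)

    def __getitem__(self, gene_id: str) -> ExpressionRecord:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def subset(self, biotype: str | None = None, significant: bool | None = None) -> "ExpressionTable":
        recs = self.records
        if biotype is not None:
            recs = [r for r in recs if r.biotype == biotype]
        if significant is not None:
            recs = [r for r in recs if r.significant == significant]
        return ExpressionTable(recs, self.samples, self.filters)

    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def log2fc_by_id(self) -> dict[str, float]:
        return {r.gene_id: r.log2fc for r in self.records}

    # -- tabular I/O --------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "gene_id": r.gene_id,
                "biotype": r.biotype,
                "chrom": r.tss.chrom,
                "tss": r.tss.start,
                "strand": r.tss.strand,
                "log2fc": r.log2fc,
                "significant": int(r.significant),
            }
            for s in self.samples:
                row[f"fpkm_{s}"] = r.fpkm_by_sample[s]
            rows.append(row)
        cols = ["gene_id", "biotype", "chrom", "tss", "strand"] + [
            f"fpkm_{s}" for s in self.samples
        ] + ["log2fc", "significant"]
        return pd.DataFrame(rows, columns=cols)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            if self.filters:
                fh.write("# filters: " + ";".join(self.filters) + "\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "ExpressionTable":
        filters: tuple[str, ...] = ()
        with open(path) as fh:
            first = fh.readline()
        skip = 0
        if first.startswith("# filters: "):
            filters = tuple(first[len("# filters: "):].strip().split(";"))
            skip = 1
        df = pd.read_csv(path, sep="\t", skiprows=skip)
        samples = [c[len("fpkm_"):] for c in df.columns if c.startswith("fpkm_")]
        records = []
        for row in df.itertuples(index=False):
            d = row._asdict()
            tss = GenomicInterval(str(d["chrom"]), int(d["tss"]), int(d["tss"]) + 1,
                                  strand=str(d["strand"]))
            records.append(ExpressionRecord(
                gene_id=str(d["gene_id"]),
                biotype=str(d["biotype"]),
                tss=tss,
                fpkm_by_sample={s: float(d[f"fpkm_{s}"]) for s in samples},
                log2fc=float(d["log2fc"]),
                significant=bool(int(d["significant"])),
            ))
        return cls(records, samples, filters)


def lower_nearest_cutoff(values: np.ndarray, quantile: float) -> float:
    """Observed-value cutoff keeping the top `quantile` fraction of `values`.

    The cutoff is the value at sorted index floor((1 - quantile) * n), i.e.
    the lower-nearest (1 - quantile) quantile, so it is always an observed
    value and keeping `>= cutoff` retains ceil(quantile * n) items when the
    values are distinct.
    """
    if len(values) == 0:
        raise ValueError("cannot compute a cutoff on an empty set of values")
    srt = np.sort(np.asarray(values, dtype=float))
    idx = min(int(math.floor((1.0 - quantile) * len(srt))), len(srt) - 1)
    return float(srt[idx])


def filter_mrna_top_expressed(
    table: ExpressionTable,
    quantile: float = 0.75,
    baseline: str = "all_expressed",
    summary: str = "max",
) -> tuple[ExpressionTable, float]:
    """Significant mRNAs restricted to the top `quantile` of expressed genes.

    The FPKM cutoff is computed over all genes with nonzero summary FPKM
    (``baseline="all_expressed"``, the default: "expressed genes" means the
    transcriptome, not the significant subset) or over the significant subset
    only (``baseline="significant"``). Returns the filtered table and the
    cutoff used. Idempotent: a table already carrying this filter tag is
    returned unchanged.
    """
    if len(table) == 0:
        raise ValueError("empty expression table")
    tag = f"mrna_top_expressed(q={quantile},baseline={baseline},summary={summary})"
    if tag in table.filters:
        return table, float("nan")

    mrnas = [r for r in table.records if r.biotype == "mRNA"]
    base_pool = mrnas if baseline == "all_expressed" else [
        r for r in mrnas if r.significant
    ]
    base_vals = np.array(
        [r.summary_fpkm(summary) for r in base_pool if r.summary_fpkm(summary) > 0]
    )
    cutoff = lower_nearest_cutoff(base_vals, quantile)
    kept = [
        r for r in mrnas
        if r.significant and r.summary_fpkm(summary) >= cutoff
    ]
    out = ExpressionTable(kept, table.samples, table.filters + (tag,))
    return out, cutoff


def filter_lincrna_expressed(
    table: ExpressionTable, min_fpkm: float = 1.0
) -> ExpressionTable:
    """Significant lincRNAs with FPKM strictly greater than `min_fpkm` in
    at least one sample."""
    tag = f"lincrna_expressed(min_fpkm={min_fpkm})"
    if tag in table.filters:
        return table
    kept = [
        r for r in table.records
        if r.biotype == "lincRNA" and r.significant
        and max(r.fpkm_by_sample.values()) > min_fpkm
    ]
    return ExpressionTable(kept, table.samples, table.filters + (tag,))


def filter_peaks_top_covered(
    peaks: PeakSet, quantile: float = 0.75
) -> tuple[PeakSet, float]:
    """Peaks restricted to the top `quantile` by intensity (read FPKM).

    Returns the filtered set and the intensity cutoff. Idempotent via the
    peak set's filter tags.
    """
    tag = f"peaks_top_covered(q={quantile})"
    if tag in peaks.filters:
        return peaks, float("nan")
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    cutoff = lower_nearest_cutoff(peaks.intensities(), quantile)
    kept = [p for p in peaks if p.intensity >= cutoff]
    out = PeakSet(kept, source=peaks.source, filters=peaks.filters + (tag,))
    return out, cutoff
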