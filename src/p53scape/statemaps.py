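"""Chromatin state maps, hybrid-map construction, and TF co-occurrence.

A state map partitions (part of) a genome into non-overlapping labeled
segments, one map per cell type. The hybrid map across cell types keeps
exactly the base pairs assigned the *same* state in every map, which makes
the construction associative and order-invariant. Pairwise TF co-occurrence
over enhancers is scored with the upper tail of the hypergeometric
distribution and Bonferroni-corrected over all factor pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import reduce
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalSet, PeakSet


class StateMap:
    """Labeled, non-overlapping genome segments for one cell type."""

    def __init__(self, cell_type: str,
                 segments: Iterable[tuple[GenomicInterval, str]]):
        self.cell_type = cell_type
        self.segments: list[tuple[GenomicInterval, str]] = sorted(
            segments, key=lambda s: (s[0].chrom, s[0].start, s[0].end)
        )
        self._check_disjoint()

    def _check_disjoint(self) -> None:
        prev: GenomicInterval | None = None
        for iv, _ in self.segments:
            if prev is not None and prev.chrom == iv.chrom and iv.start < prev.end:
                raise ValueError(
                    f"overlapping segments in state map {self.cell_type!r}: "
                    f"{prev} and {iv}"
                )
            prev = iv

    def __len__(self) -> int:
        return len(self.segments)

    def labels(self) -> list[str]:
        return sorted({lab for _, lab in self.segments})

    def by_label(self, label: str) -> IntervalSet:
        return IntervalSet(
            [iv for iv, lab in self.segments if lab == label],
            source=f"{self.cell_type}:{label}",
        )

    def coverage_by_label(self) -> dict[str, int]:
        return {lab: self.by_label(lab).coverage() for lab in self.labels()}

    # -- BED4 I/O (4th column = state label) --------------------------------------
    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv, lab in self.segments:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{lab}\n")

    @classmethod
    def read_bed(cls, path: str | Path, cell_type: str | None = None) -> "StateMap":
        segments = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: BED4 state line expected")
                segments.append(
                    (GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                     fields[3])
                )
        return cls(cell_type or Path(path).stem, segments)


def intersect_state_maps(maps: Sequence[StateMap]) -> StateMap:
    """Hybrid map: base pairs where every input map assigns the same label.

    Agreement is per base pair, not per segment boundary; the output is
    merged per label. Associative and order-invariant.
    """
    if len(maps) < 2:
        raise ValueError("need at least two state maps to intersect")
    shared = set(maps[0].labels())
    for m in maps[1:]:
        shared &= set(m.labels())
    if not shared:
        warnings.warn("state maps share no state labels; hybrid map is empty",
                      stacklevel=2)
    segments: list[tuple[GenomicInterval, str]] = []
    for lab in sorted(shared):
        common = reduce(
            lambda acc, m: acc.intersect(m.by_label(lab)),
            maps[1:],
            maps[0].by_label(lab).merged(),
        )
        segments.extend((iv, lab) for iv in common)
    name = "hybrid(" + "+".join(m.cell_type for m in maps) + ")"
    return StateMap(name, segments)


def p53_bound_enhancers(
    peaks: PeakSet, hybrid: StateMap, enhancer_state: str = "Enhancer"
) -> IntervalSet:
    """Enhancer-state segments of the hybrid map overlapping >= 1 peak."""
    enhancers = hybrid.by_label(enhancer_state)
    peak_set = peaks.interval_set()
    flags = peak_set.overlap_flags(enhancers.intervals)
    bound = [iv for iv, f in zip(enhancers.intervals, flags) if f]
    return IntervalSet(bound, source=f"p53_bound:{enhancer_state}")


def hypergeom_cooccurrence(N: int, K_a: int, K_b: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K_a, K_b).

    X counts the enhancers bound by both factors when K_b enhancers are
    drawn uniformly from N of which K_a are bound by the other factor;
    symmetric in (K_a, K_b). Computed through the survival function, which
    scipy evaluates in log space for stability.
    """
    if not (0 <= k <= min(K_a, K_b) <= max(K_a, K_b) <= N):
        raise ValueError(
            f"inconsistent counts N={N}, K_a={K_a}, K_b={K_b}, k={k}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K_a, K_b))


@dataclass
class CooccurrenceMatrix:
    """Pairwise shared-enhancer counts and hypergeometric significance."""

    factors: list[str]
    N: int
    K: dict[str, int]
    k_matrix: pd.DataFrame
    p_matrix: pd.DataFrame
    p_adj_matrix: pd.DataFrame
    zero_bound_factors: list[str] = field(default_factory=list)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for a, b in combinations(self.factors, 2):
            rows.append({
                "factor_a": a, "factor_b": b, "N": self.N,
                "K_a": self.K[a], "K_b": self.K[b],
                "k": int(self.k_matrix.loc[a, b]),
                "p": float(self.p_matrix.loc[a, b]),
                "p_adj": float(self.p_adj_matrix.loc[a, b]),
            })
        return pd.DataFrame(rows)


def cooccurrence_matrix(
    tf_catalog: Mapping[str, IntervalSet],
    all_enhancers: IntervalSet,
) -> CooccurrenceMatrix:
    """Global pairwise TF binding-site co-occurrence over enhancers.

    For each factor pair, counts enhancers bound by each factor and by both
    (>= 1 bp site overlap), scores the shared count with the hypergeometric
    upper tail, and Bonferroni-corrects over the C(F, 2) pairs. The diagonal
    is not applicable and left as NaN. A factor binding zero enhancers gets
    p = 1 against every partner and is flagged.
    """
    factors = sorted(tf_catalog)
    enhancers = all_enhancers.intervals
    N = len(enhancers)
    if N == 0:
        raise ValueError("no enhancers supplied")
    flags = {
        f: tf_catalog[f].overlap_flags(enhancers) for f in factors
    }
    K = {f: int(flags[f].sum()) for f in factors}
    zero = [f for f in factors if K[f] == 0]
    k_mat = pd.DataFrame(0, index=factors, columns=factors, dtype=int)
    p_mat = pd.DataFrame(np.nan, index=factors, columns=factors, dtype=float)
    m = len(list(combinations(factors, 2)))
    for a, b in combinations(factors, 2):
        k = int((flags[a] & flags[b]).sum())
        k_mat.loc[a, b] = k_mat.loc[b, a] = k
        p = 1.0 if (K[a] == 0 or K[b] == 0) else hypergeom_cooccurrence(N, K[a], K[b], k)
        p_mat.loc[a, b] = p_mat.loc[b, a] = p
    p_adj = (p_mat * m).clip(upper=1.0)
    return CooccurrenceMatrix(
        factors=factors, N=N, K=K,
        k_matrix=k_mat, p_matrix=p_mat, p_adj_matrix=p_adj,
        zero_bound_factors=zero,
    )


def read_tf_catalog(path: str | Path) -> dict[str, IntervalSet]:
    """BED with the factor name in column 4 -> per-factor interval sets."""
    by_factor: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: need >= 4 columns (factor name)")
            by_factor.setdefault(fields[3], []).append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            )
    return {
        f: IntervalSet(ivs, source=f"{path}:{f}") for f, ivs in by_factor.items()
    }


def write_tf_catalog(catalog: Mapping[str, IntervalSet], path: str | Path) -> None:
    rows = []
    for factor in sorted(catalog):
        rows.extend((iv.chrom, iv.start, iv.end, factor) for iv in catalog[factor])
    rows.sort()
    with open(path, "w") as fh:
        for chrom, s, e, f in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{f}\n")
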