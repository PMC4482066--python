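"""Coverage-normalized enrichment with label-shuffling permutation nulls.

The observed statistic is a ratio of per-nucleotide feature densities: the
number of feature occurrences in a selected subset of units, normalized by
the subset's nucleotide coverage, divided by the same density over the
background. In the literal bookkeeping each count is divided by
(coverage of the data set / coverage of the feature); the feature coverage
cancels algebraically, and :func:`literal_enrichment_ratio` exists so the
cancellation can be verified numerically.

Significance comes from shuffling subset-membership labels across units and
recomputing the ratio; with n shuffles the permutation p-value uses the
(1 + b) / (1 + n) pseudocount convention, so its floor is 1/(n + 1) (0.0099
for the default 100 shuffles). Enrichment and depletion p-values are both
reported, each one-sided. Multiple testing is handled by Bonferroni.

Three analyses share this machinery, each shuffling at the granularity its
design dictates:

* repeat elements in transcript subsets (units = transcripts),
* chromatin states at ChIP peaks (labels shuffled across state segments),
* TF sites within p53-bound enhancers (units = enhancers).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, PeakSet


def _substream_seed(seed: int, label: str) -> int:
    """Per-label RNG substream so adding a label never perturbs another's
    null distribution. Kept below 2**31."""
    return (int(seed) ^ zlib.crc32(label.encode("utf-8"))) & 0x7FFFFFFF


@dataclass
class EnrichmentResult:
    label: str
    ratio: float | None  # None when the background count is zero
    p_perm: float  # one-sided, enrichment
    p_depl: float  # one-sided, depletion
    count_subset: int
    count_background: int
    cov_subset: int
    cov_background: int
    p_adj: float | None = None
    note: str = ""


def enrichment_ratio(
    count_subset: float, cov_subset: float, count_bg: float, cov_bg: float
) -> float | None:
    """Density ratio (count_subset / cov_subset) / (count_bg / cov_bg).

    Returns None (undefined, not infinity) when the background count is 0.
    """
    if cov_subset <= 0 or cov_bg <= 0:
        raise ValueError("coverages must be positive")
    if count_bg == 0:
        return None
    return (count_subset / cov_subset) / (count_bg / cov_bg)


def literal_enrichment_ratio(
    count_subset: float, cov_subset: float, count_bg: float, cov_bg: float,
    cov_element: float,
) -> float:
    """The literal normalization: each count divided by
    (coverage of its data set / coverage of the feature). The feature
    coverage cancels, so this equals :func:`enrichment_ratio` to machine
    precision for positive inputs."""
    if cov_element <= 0:
        raise ValueError("feature coverage must be positive")
    num = count_subset / (cov_subset / cov_element)
    den = count_bg / (cov_bg / cov_element)
    return num / den


@dataclass
class LabeledFeatureSpace:
    """Units (transcripts or enhancers) with lengths and per-label feature
    counts, plus the selected subset of unit ids."""

    unit_ids: list[str]
    lengths: np.ndarray  # nt per unit, > 0
    counts: pd.DataFrame  # index = unit ids, columns = labels
    subset_ids: frozenset[str]

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if len(self.unit_ids) != len(self.lengths) or len(self.unit_ids) != len(self.counts):
            raise ValueError("unit ids, lengths and counts must align")
        if (self.lengths <= 0).any():
            raise ValueError("unit lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("feature counts must be >= 0")
        unknown = set(self.subset_ids) - set(self.unit_ids)
        if unknown:
            raise KeyError(f"subset ids not among units: {sorted(unknown)[:5]}")
        self._subset_mask = np.array(
            [u in self.subset_ids for u in self.unit_ids], dtype=bool
        )

    @property
    def labels(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def subset_mask(self) -> np.ndarray:
        return self._subset_mask


def _ratio_for_mask(space: LabeledFeatureSpace, counts_col: np.ndarray,
                    mask: np.ndarray) -> tuple[float | None, int, int, int, int]:
    c_sub = float(counts_col[mask].sum())
    c_bg = float(counts_col.sum())  # background = all units (the transcriptome)
    cov_sub = float(space.lengths[mask].sum())
    cov_bg = float(space.lengths.sum())
    r = enrichment_ratio(c_sub, cov_sub, c_bg, cov_bg)
    return r, int(c_sub), int(c_bg), int(cov_sub), int(cov_bg)


def permutation_test(
    space: LabeledFeatureSpace,
    label: str,
    n_perm: int = 100,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation enrichment test for one feature label.

    The observed ratio compares the subset's feature density against the
    whole unit universe. Null ratios come from `n_perm` random subsets of
    the same cardinality (membership labels shuffled across all units).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    mask = space.subset_mask
    k = int(mask.sum())
    n = len(space.unit_ids)
    if k < 1:
        raise ValueError("subset must contain at least one unit")
    if k == n:
        raise ValueError("subset equals the full unit universe; test is degenerate")
    if label not in space.counts.columns:
        raise KeyError(f"unknown label {label!r}")
    col = space.counts[label].to_numpy(dtype=float)
    obs, c_sub, c_bg, cov_sub, cov_bg = _ratio_for_mask(space, col, mask)

    rng = np.random.default_rng(_substream_seed(seed, label))
    obs_val = np.nan if obs is None else obs
    b_ge = b_le = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)[:k]
        null_mask = np.zeros(n, dtype=bool)
        null_mask[idx] = True
        null, *_ = _ratio_for_mask(space, col, null_mask)
        null_val = np.nan if null is None else null
        if not (np.isnan(null_val) or np.isnan(obs_val)):
            if null_val >= obs_val:
                b_ge += 1
            if null_val <= obs_val:
                b_le += 1
    p_enr = (1 + b_ge) / (1 + n_perm)
    p_dep = (1 + b_le) / (1 + n_perm)
    note = "" if obs is not None else "background count is zero; ratio undefined"
    return EnrichmentResult(
        label=label, ratio=obs, p_perm=p_enr, p_depl=p_dep,
        count_subset=c_sub, count_background=c_bg,
        cov_subset=cov_sub, cov_background=cov_bg, note=note,
    )


def permutation_test_all(
    space: LabeledFeatureSpace,
    n_perm: int = 100,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> list[EnrichmentResult]:
    return [
        permutation_test(space, lab, n_perm=n_perm, seed=seed)
        for lab in (labels if labels is not None else space.labels)
    ]


def complement_density_ratio(result: EnrichmentResult) -> float | None:
    """Subset density divided by the density of the complement of the subset.

    The reported `ratio` uses the whole unit universe as background (the
    transcriptome, as the enrichment statistic defines it), which dilutes a
    planted density contrast whenever the subset is a non-negligible share
    of the universe. This estimator removes the subset from the background
    and is therefore the consistent estimator of a planted subset-vs-rest
    density ratio. None when the complement carries no features.
    """
    c_rest = result.count_background - result.count_subset
    cov_rest = result.cov_background - result.cov_subset
    if cov_rest <= 0 or result.cov_subset <= 0 or c_rest == 0:
        return None
    return (result.count_subset / result.cov_subset) / (c_rest / cov_rest)


def bonferroni(results: Sequence[EnrichmentResult]) -> list[EnrichmentResult]:
    """p_adj = min(1, p_perm * m); order preserved."""
    m = len(results)
    if m < 1:
        raise ValueError("need at least one result")
    return [replace(r, p_adj=min(1.0, r.p_perm * m)) for r in results]


# -- repeats in transcript subsets ------------------------------------------------


def build_repeat_space(
    repeats: pd.DataFrame,
    transcripts: pd.DataFrame,
    subset_ids: Iterable[str],
    background: str = "transcriptome",
    level: str = "family",
) -> LabeledFeatureSpace:
    """Assemble the unit/label space for repeat-element enrichment.

    `repeats` has columns (transcript_id, element, family, start, end) with
    positions in transcript coordinates; `transcripts` has columns
    (transcript_id, biotype, length). `background` selects the unit
    universe: the whole transcriptome, or the lincRNA catalog only.
    """
    if background not in ("transcriptome", "lincrna"):
        raise ValueError("background must be 'transcriptome' or 'lincrna'")
    units = transcripts
    if background == "lincrna":
        units = transcripts[transcripts["biotype"] == "lincRNA"]
    unit_ids = list(units["transcript_id"])
    subset_ids = frozenset(subset_ids)
    unknown = subset_ids - set(unit_ids)
    if unknown:
        raise KeyError(f"subset transcripts absent from background: {sorted(unknown)[:5]}")
    label_col = level if level in ("element", "family") else "family"
    rep = repeats[repeats["transcript_id"].isin(unit_ids)]
    counts = (
        rep.groupby(["transcript_id", label_col]).size().unstack(fill_value=0)
        .reindex(unit_ids, fill_value=0)
    )
    counts.columns = [str(c) for c in counts.columns]
    return LabeledFeatureSpace(
        unit_ids=unit_ids,
        lengths=units["length"].to_numpy(dtype=float),
        counts=counts,
        subset_ids=subset_ids,
    )


def repeat_enrichment(
    repeats: pd.DataFrame,
    transcripts: pd.DataFrame,
    subset_ids: Iterable[str],
    background: str = "transcriptome",
    level: str = "family",
    n_perm: int = 100,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Per repeat element/family enrichment of a transcript subset against
    the transcriptome (or the lincRNA catalog), Bonferroni-corrected."""
    space = build_repeat_space(repeats, transcripts, subset_ids,
                               background=background, level=level)
    results = permutation_test_all(space, n_perm=n_perm, seed=seed)
    return bonferroni(results)


def te_coverage_fraction(
    repeats: pd.DataFrame,
    transcripts: pd.DataFrame,
    subset_ids: Iterable[str],
) -> float:
    """Fraction of exonic nucleotides of the subset covered by >= 1 repeat.

    Repeat occurrences are intervals in transcript coordinates; overlapping
    occurrences are merged per transcript before coverage is summed.
    """
    subset_ids = set(subset_ids)
    lengths = transcripts.set_index("transcript_id")["length"]
    unknown = subset_ids - set(lengths.index)
    if unknown:
        raise KeyError(f"unknown subset transcripts: {sorted(unknown)[:5]}")
    total = float(lengths.loc[sorted(subset_ids)].sum())
    if total <= 0:
        raise ValueError("subset has zero total length")
    covered = 0.0
    rep = repeats[repeats["transcript_id"].isin(subset_ids)]
    for tid, grp in rep.groupby("transcript_id"):
        tlen = int(lengths.loc[tid])
        ivs = [
            GenomicInterval(str(tid), max(0, int(s)), min(tlen, int(e)))
            for s, e in zip(grp["start"], grp["end"])
            if int(s) < tlen and int(e) > 0 and max(0, int(s)) < min(tlen, int(e))
        ]
        covered += IntervalSet(ivs).coverage()
    return covered / total


# -- chromatin states at peaks ----------------------------------------------------


def _segment_peak_index(
    segments: Sequence[tuple[GenomicInterval, str]], peaks: PeakSet
) -> list[np.ndarray]:
    """For each segment, the indices of peaks overlapping it (sweep per
    chromosome over both sorted lists)."""
    peak_ivs = peaks.intervals
    by_chrom_peaks: dict[str, list[int]] = {}
    for i, iv in enumerate(peak_ivs):
        by_chrom_peaks.setdefault(iv.chrom, []).append(i)
    out: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * len(segments)
    by_chrom_segs: dict[str, list[int]] = {}
    for j, (iv, _lab) in enumerate(segments):
        by_chrom_segs.setdefault(iv.chrom, []).append(j)
    for chrom, seg_idx in by_chrom_segs.items():
        p_idx = by_chrom_peaks.get(chrom, [])
        if not p_idx:
            continue
        p_sorted = sorted(p_idx, key=lambda i: peak_ivs[i].start)
        starts = np.array([peak_ivs[i].start for i in p_sorted])
        ends = np.array([peak_ivs[i].end for i in p_sorted])
        ids = np.array(p_sorted)
        for j in seg_idx:
            seg = segments[j][0]
            cand = np.flatnonzero((starts < seg.end) & (ends > seg.start))
            out[j] = ids[cand]
    return out


def state_enrichment(
    peaks: PeakSet,
    states: "object",
    genome_size: int,
    n_perm: int = 100,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Enrichment of ChIP peaks within each chromatin state.

    `states` is a StateMap (segments labeled with states) or a mapping
    mark -> IntervalSet for the histone-mark variant, where each mark's
    intervals play the role of a state's segments. The observed statistic
    per state is (peaks overlapping the state / state coverage) divided by
    (all peaks / genome coverage). The null shuffles state labels across
    segments, which moves both the peak counts and the coverages.
    """
    segments = _states_as_segments(states)
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    n_peaks = len(peaks)
    if n_peaks == 0:
        raise ValueError("empty peak set")
    seg_peaks = _segment_peak_index(segments, peaks)
    seg_lengths = np.array([iv.length for iv, _ in segments], dtype=float)
    seg_labels = np.array([lab for _, lab in segments])
    labels = sorted(set(seg_labels))

    def stats_for(assign: np.ndarray) -> dict[str, tuple[float | None, int, int]]:
        per: dict[str, tuple[float | None, int, int]] = {}
        for lab in labels:
            sel = np.flatnonzero(assign == lab)
            cov = float(seg_lengths[sel].sum())
            if sel.size and cov > 0:
                uniq = np.unique(np.concatenate([seg_peaks[j] for j in sel])) \
                    if sel.size else np.empty(0)
                cnt = int(uniq.size)
                ratio = (cnt / cov) / (n_peaks / genome_size)
            else:
                cnt, ratio = 0, None
            per[lab] = (ratio, cnt, int(cov))
        return per

    observed = stats_for(seg_labels)
    null_ge = {lab: 0 for lab in labels}
    null_le = {lab: 0 for lab in labels}
    # one shuffle provides a null draw for every label simultaneously,
    # mirroring a single relabeling of the whole state map
    rng = np.random.default_rng(_substream_seed(seed, "state_labels"))
    for _ in range(n_perm):
        perm = rng.permutation(len(seg_labels))
        null = stats_for(seg_labels[perm])
        for lab in labels:
            o = observed[lab][0]
            v = null[lab][0]
            if o is None or v is None:
                continue
            if v >= o:
                null_ge[lab] += 1
            if v <= o:
                null_le[lab] += 1
    out = []
    for lab in labels:
        ratio, cnt, cov = observed[lab]
        out.append(EnrichmentResult(
            label=lab, ratio=ratio,
            p_perm=(1 + null_ge[lab]) / (1 + n_perm),
            p_depl=(1 + null_le[lab]) / (1 + n_perm),
            count_subset=cnt, count_background=n_peaks,
            cov_subset=cov, cov_background=int(genome_size),
            note="" if ratio is not None else "state has zero coverage",
        ))
    return out


def _states_as_segments(states: object) -> list[tuple[GenomicInterval, str]]:
    from .statemaps import StateMap  # local import to avoid a cycle

    if isinstance(states, StateMap):
        return [(iv, lab) for iv, lab in states.segments]
    if isinstance(states, Mapping):
        segs: list[tuple[GenomicInterval, str]] = []
        for mark, iset in states.items():
            segs.extend((iv, str(mark)) for iv in iset)
        return segs
    raise TypeError("states must be a StateMap or a mapping mark -> IntervalSet")


# -- TF sites within p53-bound enhancers ------------------------------------------


def tf_in_enhancer_enrichment(
    p53_enhancers: IntervalSet,
    tf_catalog: Mapping[str, IntervalSet],
    all_enhancers: IntervalSet,
    n_perm: int = 100,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Per TF, enrichment of the factor within p53-bound enhancers.

    An enhancer is "bound" by a factor when >= 1 of the factor's sites
    overlaps it. The observed ratio compares the density of p53-bound
    enhancers among the factor-bound enhancers against the density of
    p53-bound enhancers over all annotated enhancers (so a factor bound at
    every enhancer scores exactly 1). The null shuffles the factor-bound
    labels across enhancers, preserving how many enhancers the factor binds.
    """
    enhancers = all_enhancers.intervals
    n = len(enhancers)
    if n == 0:
        raise ValueError("no enhancers supplied")
    lengths = np.array([iv.length for iv in enhancers], dtype=float)
    p53_flags = p53_enhancers.overlap_flags(enhancers)
    n_p53 = int(p53_flags.sum())
    cov_all = float(lengths.sum())
    results = []
    for factor in sorted(tf_catalog):
        f_flags = tf_catalog[factor].overlap_flags(enhancers)
        obs, c_common, cov_f = _tf_ratio(p53_flags, f_flags, lengths, n_p53, cov_all)
        rng = np.random.default_rng(_substream_seed(seed, factor))
        b_ge = b_le = 0
        for _ in range(n_perm):
            null_flags = f_flags[rng.permutation(n)]
            v, *_ = _tf_ratio(p53_flags, null_flags, lengths, n_p53, cov_all)
            if obs is None or v is None:
                continue
            if v >= obs:
                b_ge += 1
            if v <= obs:
                b_le += 1
        results.append(EnrichmentResult(
            label=factor, ratio=obs,
            p_perm=(1 + b_ge) / (1 + n_perm),
            p_depl=(1 + b_le) / (1 + n_perm),
            count_subset=c_common, count_background=n_p53,
            cov_subset=int(cov_f), cov_background=int(cov_all),
            note="" if obs is not None else "factor binds no enhancer",
        ))
    return results


def _tf_ratio(p53_flags, f_flags, lengths, n_p53, cov_all):
    c_common = int((p53_flags & f_flags).sum())
    cov_f = float(lengths[f_flags].sum())
    if cov_f <= 0 or n_p53 == 0:
        return None, c_common, cov_f
    return (c_common / cov_f) / (n_p53 / cov_all), c_common, cov_f


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "label": r.label,
            "ratio": np.nan if r.ratio is None else r.ratio,
            "p_perm": r.p_perm,
            "p_depl": r.p_depl,
            "p_adj": np.nan if r.p_adj is None else r.p_adj,
            "count_subset": r.count_subset,
            "count_background": r.count_background,
            "cov_subset": r.cov_subset,
            "cov_background": r.cov_background,
            "note": r.note,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
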