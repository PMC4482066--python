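"""Synthetic genomes, expression tables, peaks, repeats, state maps and TF
catalogs with known planted structure.

Every pipeline input can be generated here with a recorded ground truth, so
each analysis stage is testable end-to-end without external downloads. All
randomness flows from a single seed through per-stage substreams; two runs
with equal configurations are byte-identical.

What is emulated, and what is not: sequences are i.i.d. uniform nucleotides
(no GC structure or repeats at the sequence level), genes are placed without
overlap on a slot grid, fold changes are log-normal around the planted
effects, and repeat occurrences are Poisson counts — enough to exercise the
statistics, not a read-level simulation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionRecord, ExpressionTable
from .intervals import GenomicInterval, IntervalSet, Peak, PeakSet
from .motif import IUPAC, MotifSpec
from .statemaps import StateMap

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_TF_FACTORS = (
    "cFos", "cJun", "KAP1", "JunD", "POLR2A", "EP300", "CTCF", "MAX", "MYC",
    "GABPA", "SRF", "YY1", "USF1", "ELF1", "EGR1", "SP1", "NRF1", "RFX5",
    "STAT3", "TEAD4",
)

DEFAULT_TE_ELEMENTS = {
    # element -> (family, share of background occurrences)
    "AluSx": ("Alu", 0.25),
    "AluJb": ("Alu", 0.15),
    "AluY": ("Alu", 0.10),
    "L1PA3": ("L1", 0.20),
    "L2a": ("L2", 0.10),
    "MIRb": ("MIR", 0.10),
    "MLT1A": ("ERVL", 0.10),
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults are desk-scale: two 5 Mb chromosomes, 400 protein-coding genes,
    60 lincRNAs and 300 binding-site peaks — large enough for stable
    permutation calibration, small enough for minutes-scale tests.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    n_genes: int = 400
    n_lincrnas: int = 60
    n_peaks: int = 300
    frac_significant: float = 0.25   # transcripts flagged DE by the upstream caller
    frac_targets: float = 0.25       # fraction of DE genes that are bound
    effect_log2fc: float = 2.0       # mean |log2FC| planted at direct targets
    effect_sigma: float = 0.3
    log2fc_sigma: float = 0.5        # background fold-change spread
    frac_down: float = 0.3           # fraction of planted targets repressed
    tss_window: int = 30_000         # human preset half-width W
    peak_min_len: int = 200
    peak_max_len: int = 800
    motif_plant_rate: float = 0.4    # fraction of peaks receiving an exact RE
    te_density_background: float = 0.5   # occurrences per kb of transcript
    te_density_subset: float = 2.5       # planted 5x density in the subset
    te_elements: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_TE_ELEMENTS)
    )
    repeat_len_mean: float = 300.0
    state_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "ActivePromoter": 0.02,
            "Enhancer": 0.05,
            "WeakTranscription": 0.50,  # 10x the enhancer share
            "Repressed": 0.15,
        }
    )
    segment_min_len: int = 1_000
    segment_max_len: int = 3_000
    state_label_noise: float = 0.10
    n_cell_types: int = 3
    peak_enhancer_bias: float = 0.8
    tf_factors: tuple[str, ...] = DEFAULT_TF_FACTORS
    tf_marginal_rate: float = 0.15
    # cFos and cJun bind as the obligate AP-1 heterodimer, so their planted
    # co-binding odds are far above any incidental pair
    cobound_pair: tuple[str, str] = ("cFos", "cJun")
    cobound_odds: float = 30.0
    tf_p53_lifts: dict[str, float] = field(default_factory=lambda: {"KAP1": 3.0})
    samples: tuple[str, ...] = ("ctrl_1", "ctrl_2", "dox_1", "dox_2")

    def __post_init__(self) -> None:
        for name in ("frac_significant", "frac_targets", "frac_down",
                     "motif_plant_rate", "peak_enhancer_bias",
                     "tf_marginal_rate", "state_label_noise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if sum(self.state_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("state fractions must sum to <= 1 "
                             "(the remainder is unannotated)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "te_elements" in raw:
            raw["te_elements"] = {k: tuple(v) for k, v in raw["te_elements"].items()}
        for key in ("tf_factors", "samples", "cobound_pair"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["te_elements"] = {k: list(v) for k, v in raw["te_elements"].items()}
        for key in ("tf_factors", "samples", "cobound_pair"):
            raw[key] = list(raw[key])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Planted facts, sufficient to score every downstream recovery."""

    target_ids: list[str] = field(default_factory=list)
    bound_peak_ids: list[str] = field(default_factory=list)
    motif_peak_ids: list[str] = field(default_factory=list)
    significant_ids: list[str] = field(default_factory=list)
    repeat_subset_ids: list[str] = field(default_factory=list)
    enriched_te_labels: dict[str, float] = field(default_factory=dict)
    cobound_pairs: list[list] = field(default_factory=list)
    tf_lifts: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# -- genome -----------------------------------------------------------------------


class _ChromView:
    def __init__(self, data: bytearray):
        self._data = data

    def __len__(self) -> int:
        return len(self._data)

    def __getitem__(self, key) -> str:
        out = self._data[key]
        return out.decode("ascii") if isinstance(out, (bytes, bytearray)) else chr(out)

    def __str__(self) -> str:
        return self._data.decode("ascii")


class SimulatedGenome:
    """Chromosome name -> sequence, mutable so motifs can be planted.

    Supports the same read access pattern as a FASTA handle:
    ``genome[chrom][start:end]`` returns a string.
    """

    def __init__(self, seqs: dict[str, bytearray]):
        self._seqs = seqs

    def __getitem__(self, chrom: str) -> _ChromView:
        return _ChromView(self._seqs[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def plant(self, chrom: str, pos: int, seq: str) -> None:
        encoded = seq.encode("ascii")
        if pos < 0 or pos + len(encoded) > len(self._seqs[chrom]):
            raise ValueError("planted sequence out of chromosome bounds")
        self._seqs[chrom][pos:pos + len(encoded)] = encoded

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom in self._seqs:
                fh.write(f">{chrom}\n")
                seq = self._seqs[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width].decode("ascii") + "\n")


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ("genome", "expression", "peaks", "motif", "repeats", "states",
             "tfs", "compendium")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def simulate_genome_and_annotation(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[SimulatedGenome, pd.DataFrame]:
    """Uniform-random genome plus non-overlapping gene/lincRNA annotation.

    Transcripts are dropped into randomly chosen 12 kb slots so they can
    never overlap; strand is random and the TSS is the strand-aware 5' end.
    """
    rng = rng or _stage_rngs(cfg.seed)["genome"]
    seqs = {}
    for chrom, length in cfg.chrom_lengths.items():
        codes = rng.integers(0, 4, size=length, dtype=np.uint8)
        seqs[chrom] = bytearray(_BASES[codes].tobytes())
    genome = SimulatedGenome(seqs)

    slot = 12_000
    slots = [
        (chrom, i * slot)
        for chrom, length in cfg.chrom_lengths.items()
        for i in range(length // slot)
    ]
    n_tx = cfg.n_genes + cfg.n_lincrnas
    if n_tx > len(slots):
        raise ValueError("genome too small for the requested transcript count")
    chosen = rng.permutation(len(slots))[:n_tx]
    ids = [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)] + [
        f"LINC{i + 1:04d}" for i in range(cfg.n_lincrnas)
    ]
    biotypes = ["mRNA"] * cfg.n_genes + ["lincRNA"] * cfg.n_lincrnas
    rows = []
    for tid, biotype, slot_idx in zip(ids, biotypes, chosen):
        chrom, base = slots[slot_idx]
        glen = int(rng.integers(2_000, 8_001))
        offset = int(rng.integers(0, slot - glen))
        start = base + offset
        end = start + glen
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else end - 1
        rows.append({
            "gene_id": tid, "biotype": biotype, "chrom": chrom,
            "start": start, "end": end, "strand": strand,
            "tss": tss, "length": glen,
        })
    annotation = pd.DataFrame(rows).sort_values(
        ["chrom", "start"]).reset_index(drop=True)
    return genome, annotation


# -- expression and peaks ---------------------------------------------------------


def _sample_gap_position(gaps: IntervalSet, size: int,
                         rng: np.random.Generator) -> int | None:
    """Uniform position over the union of gaps, restricted to gaps that can
    hold an interval of `size`; None when no gap fits."""
    fit = [iv for iv in gaps.merged() if iv.length >= size]
    if not fit:
        return None
    weights = np.array([iv.length - size + 1 for iv in fit], dtype=float)
    pick = fit[int(rng.choice(len(fit), p=weights / weights.sum()))]
    return int(rng.integers(pick.start, pick.end - size + 1))


def simulate_de_and_peaks(
    cfg: SimulationConfig,
    genome: SimulatedGenome,
    annotation: pd.DataFrame,
    rngs: Mapping[str, np.random.Generator] | None = None,
) -> tuple[ExpressionTable, PeakSet, GroundTruth]:
    """Expression table with planted direct targets, plus binding peaks.

    Planted targets receive a peak inside their own TSS window but outside
    every other significant gene's window; decoy peaks avoid all significant
    windows. The significance flag emulates the upstream caller's
    classification and is assigned independently of the fold changes, so
    when no targets are planted the bound/unbound comparison is an exact
    null.
    """
    rngs = rngs or _stage_rngs(cfg.seed)
    rng_e = rngs["expression"]
    rng_p = rngs["peaks"]
    rng_m = rngs["motif"]

    n = len(annotation)
    base = rng_e.lognormal(mean=1.0, sigma=1.2, size=n)
    significant = rng_e.random(n) < cfg.frac_significant
    # targets are drawn among significant transcripts expressed clearly above
    # the downstream top-75% FPKM cutoff, so a planted target is never lost
    # to the expression filter itself
    expressed_ok = base >= np.quantile(base, 0.40)
    wants_target = significant & expressed_ok & (rng_e.random(n) < cfg.frac_targets)

    # a planted target must admit a peak placement inside its own TSS window
    # and outside every other significant gene's window, otherwise the
    # planted fact would not be recoverable from the emitted files; genes in
    # fully shadowed neighborhoods are skipped
    W = cfg.tss_window
    pmax = cfg.peak_max_len
    sig_window_list = [
        (i, GenomicInterval(
            annotation.at[i, "chrom"],
            max(0, int(annotation.at[i, "tss"]) - W - pmax + 1),
            min(int(annotation.at[i, "tss"]) + W + 1,
                cfg.chrom_lengths[annotation.at[i, "chrom"]]),
        ))
        for i in np.flatnonzero(significant)
    ]
    target_gaps: dict[int, IntervalSet] = {}
    is_target = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(wants_target):
        chrom = annotation.at[i, "chrom"]
        tss = int(annotation.at[i, "tss"])
        own = IntervalSet([GenomicInterval(
            chrom, max(0, tss - W), min(tss + W + 1, cfg.chrom_lengths[chrom]),
        )])
        others = IntervalSet([iv for j, iv in sig_window_list if j != i]).merged()
        allowed = own.subtract(others)
        if any(iv.length >= cfg.peak_min_len for iv in allowed):
            is_target[i] = True
            target_gaps[i] = allowed

    log2fc = rng_e.normal(0.0, cfg.log2fc_sigma, size=n)
    magnitudes = np.abs(rng_e.normal(cfg.effect_log2fc, cfg.effect_sigma,
                                     size=n))
    signs = np.where(rng_e.random(n) < cfg.frac_down, -1.0, 1.0)
    log2fc = np.where(is_target, signs * magnitudes, log2fc)

    n_ctrl = sum(s.startswith("ctrl") for s in cfg.samples)
    records = []
    for i, row in enumerate(annotation.itertuples(index=False)):
        fpkm = {}
        for j, sample in enumerate(cfg.samples):
            noise = rng_e.lognormal(0.0, 0.2)
            level = base[i] if j < n_ctrl else base[i] * 2.0 ** log2fc[i]
            fpkm[sample] = float(level * noise)
        records.append(ExpressionRecord(
            gene_id=row.gene_id, biotype=row.biotype,
            tss=GenomicInterval(row.chrom, int(row.tss), int(row.tss) + 1,
                                strand=row.strand),
            fpkm_by_sample=fpkm,
            log2fc=float(log2fc[i]),
            significant=bool(significant[i]),
        ))
    table = ExpressionTable(records, list(cfg.samples))

    # --- peaks ---
    all_sig_forbidden = IntervalSet([iv for _, iv in sig_window_list]).merged()

    peaks: list[Peak] = []
    bound_peak_ids: list[str] = []
    peak_counter = 0

    def new_peak(chrom: str, pos: int, plen: int, bound: bool = False) -> Peak:
        nonlocal peak_counter
        peak_counter += 1
        name = f"peak_{peak_counter:04d}"
        iv = GenomicInterval(chrom, pos, pos + plen, name=name)
        # functional binding sites carry higher read density than noise
        # peaks, which is what the top-75% read-coverage filter exploits
        mu, sigma = (2.2, 0.8) if bound else (1.0, 1.0)
        return Peak(iv, float(rng_p.lognormal(mu, sigma)))

    for i in sorted(target_gaps):
        allowed = target_gaps[i]
        plen = int(rng_p.integers(cfg.peak_min_len, cfg.peak_max_len + 1))
        pos = _sample_gap_position(allowed, plen, rng_p)
        if pos is None:  # gap fits the minimum length only
            plen = cfg.peak_min_len
            pos = _sample_gap_position(allowed, plen, rng_p)
        chrom = annotation.at[i, "chrom"]
        peak = new_peak(chrom, pos, plen, bound=True)
        peaks.append(peak)
        bound_peak_ids.append(peak.name)

    genome_iv = IntervalSet([
        GenomicInterval(c, 0, l) for c, l in cfg.chrom_lengths.items()
    ])
    decoy_space = genome_iv.subtract(all_sig_forbidden)
    n_decoys = max(0, cfg.n_peaks - len(peaks))
    for _ in range(n_decoys):
        plen = int(rng_p.integers(cfg.peak_min_len, cfg.peak_max_len + 1))
        pos_set = decoy_space
        # decoys may sit near non-significant genes but never inside a
        # significant gene's regulatory window
        fit = [iv for iv in pos_set.merged() if iv.length >= plen]
        weights = np.array([iv.length - plen + 1 for iv in fit], dtype=float)
        pick = fit[int(rng_p.choice(len(fit), p=weights / weights.sum()))]
        pos = int(rng_p.integers(pick.start, pick.end - plen + 1))
        peaks.append(new_peak(pick.chrom, pos, plen))

    peak_set = PeakSet(peaks, source="simulated")

    # --- plant exact response elements in a fraction of peaks ---
    motif_ids = _plant_motifs(cfg, genome, peak_set, rng_m)

    truth = GroundTruth(
        target_ids=sorted(annotation.loc[is_target, "gene_id"]),
        bound_peak_ids=sorted(bound_peak_ids),
        motif_peak_ids=sorted(motif_ids),
        significant_ids=sorted(annotation.loc[significant, "gene_id"]),
    )
    return table, peak_set, truth


def sample_concrete_motif(spec: MotifSpec, rng: np.random.Generator) -> str:
    """A concrete string drawn uniformly from the degenerate consensus
    expansion, with a random admissible spacer."""
    def concretize(pattern: str) -> str:
        return "".join(IUPAC[c][int(rng.integers(len(IUPAC[c])))] for c in pattern)

    k = int(rng.integers(spec.spacer_min, spec.spacer_max + 1))
    spacer = "".join("ACGT"[int(rng.integers(4))] for _ in range(k))
    return concretize(spec.half_site_1) + spacer + concretize(spec.half_site_2)


def _plant_motifs(cfg: SimulationConfig, genome: SimulatedGenome,
                  peaks: PeakSet, rng: np.random.Generator) -> list[str]:
    spec = MotifSpec()
    n_plant = int(round(cfg.motif_plant_rate * len(peaks)))
    order = rng.permutation(len(peaks))[:n_plant]
    planted = []
    peak_list = list(peaks)
    for idx in sorted(order):
        peak = peak_list[int(idx)]
        iv = peak.interval
        motif = sample_concrete_motif(spec, rng)
        offset = int(rng.integers(0, iv.length - len(motif) + 1))
        genome.plant(iv.chrom, iv.start + offset, motif)
        planted.append(peak.name)
    return planted


# -- repeats ----------------------------------------------------------------------


def simulate_repeats(
    cfg: SimulationConfig,
    annotation: pd.DataFrame,
    subset_ids: Sequence[str],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-transcript repeat occurrences with a planted enriched subset.

    Occurrence counts per transcript and element are Poisson at the
    background density (per kb of exonic sequence); Alu-family elements in
    the designated subset use the subset density instead, planting an
    enrichment ratio of te_density_subset / te_density_background for every
    Alu element. Positions are in transcript coordinates.
    """
    rng = rng or _stage_rngs(cfg.seed)["repeats"]
    subset = set(subset_ids)
    unknown = subset - set(annotation["gene_id"])
    if unknown:
        raise KeyError(f"subset ids absent from annotation: {sorted(unknown)[:5]}")
    rows = []
    ratio = cfg.te_density_subset / cfg.te_density_background
    enriched = {
        el: ratio for el, (fam, _share) in cfg.te_elements.items() if fam == "Alu"
    }
    for r in annotation.itertuples(index=False):
        tlen = int(r.length)
        in_subset = r.gene_id in subset
        for element, (family, share) in cfg.te_elements.items():
            dens = cfg.te_density_background * share
            if in_subset and family == "Alu":
                dens = cfg.te_density_subset * share
            k = int(rng.poisson(dens * tlen / 1000.0))
            for _ in range(k):
                rlen = int(np.clip(rng.normal(cfg.repeat_len_mean,
                                              cfg.repeat_len_mean / 5.0),
                                   50, tlen))
                start = int(rng.integers(0, max(1, tlen - rlen + 1)))
                rows.append({
                    "transcript_id": r.gene_id, "element": element,
                    "family": family, "start": start, "end": start + rlen,
                })
    df = pd.DataFrame(rows, columns=["transcript_id", "element", "family",
                                     "start", "end"])
    truth = GroundTruth(repeat_subset_ids=sorted(subset),
                        enriched_te_labels=enriched)
    return df, truth


def transcripts_frame(annotation: pd.DataFrame) -> pd.DataFrame:
    """The (transcript_id, biotype, length) view used by repeat enrichment."""
    return annotation.rename(columns={"gene_id": "transcript_id"})[
        ["transcript_id", "biotype", "length"]
    ].copy()


# -- chromatin states and TF catalogs ---------------------------------------------


@dataclass
class StatesBundle:
    backbone: StateMap
    cell_maps: list[StateMap]
    tf_catalog: dict[str, IntervalSet]
    truth: GroundTruth


def simulate_states_and_tfs(
    cfg: SimulationConfig,
    chrom_lengths: Mapping[str, int] | None = None,
    peaks: PeakSet | None = None,
    rngs: Mapping[str, np.random.Generator] | None = None,
) -> StatesBundle:
    """Per-cell-type state maps sharing a backbone, plus TF site catalogs.

    Each cell type's map is the backbone with independent label noise, so
    the hybrid intersection is nontrivial but recovers the backbone where
    all cell types agree. TF sites are dropped into backbone enhancer
    segments with a common marginal rate; one designated pair co-occurs
    with the configured odds ratio, and factors with a configured lift
    concentrate in p53-bound enhancers when peaks are supplied.
    """
    rngs = rngs or _stage_rngs(cfg.seed)
    rng_s = rngs["states"]
    rng_t = rngs["tfs"]
    chrom_lengths = dict(chrom_lengths or cfg.chrom_lengths)

    labels = sorted(cfg.state_fractions)

    # segment the genome first, then assign labels as an exact multiset so
    # each state's realized genome share tracks its configured fraction
    # closely (i.i.d. per-segment draws would leave rare states like
    # enhancers with a large coverage variance)
    raw_segments: list[GenomicInterval] = []
    for chrom, length in chrom_lengths.items():
        pos = 0
        while pos < length:
            seg_len = int(rng_s.integers(cfg.segment_min_len,
                                         cfg.segment_max_len + 1))
            end = min(pos + seg_len, length)
            raw_segments.append(GenomicInterval(chrom, pos, end))
            pos = end
    n_seg = len(raw_segments)
    label_pool: list[str | None] = []
    for lab in labels:
        label_pool.extend([lab] * int(round(cfg.state_fractions[lab] * n_seg)))
    label_pool.extend([None] * (n_seg - len(label_pool)))  # unannotated rest
    assignment = [label_pool[int(i)] for i in rng_s.permutation(n_seg)]
    backbone_segments: list[tuple[GenomicInterval, str]] = [
        (iv, lab) for iv, lab in zip(raw_segments, assignment) if lab is not None
    ]
    backbone = StateMap("backbone", backbone_segments)

    cell_maps = []
    for ct in range(cfg.n_cell_types):
        segs = []
        for iv, lab in backbone_segments:
            if cfg.state_label_noise > 0 and rng_s.random() < cfg.state_label_noise:
                others = [l for l in labels if l != lab]
                lab = others[int(rng_s.integers(len(others)))]
            segs.append((iv, lab))
        cell_maps.append(StateMap(f"cell_type_{ct + 1}", segs))

    # --- TF catalogs over backbone enhancers ---
    enhancers = [iv for iv, lab in backbone_segments if lab == "Enhancer"]
    n_enh = len(enhancers)
    factors = list(cfg.tf_factors)
    rate = cfg.tf_marginal_rate
    bound = {f: np.zeros(n_enh, dtype=bool) for f in factors}

    a, b = cfg.cobound_pair
    pair_planted = a in factors and b in factors
    if pair_planted:
        p11 = _joint_prob_from_odds(rate, rate, cfg.cobound_odds)
        u = rng_t.random(n_enh)
        both = u < p11
        only_a = (u >= p11) & (u < rate)  # P(a, not b) = rate - p11
        only_b = (u >= rate) & (u < 2 * rate - p11)
        bound[a] = both | only_a
        bound[b] = both | only_b

    p53_flags = np.zeros(n_enh, dtype=bool)
    if peaks is not None:
        p53_flags = peaks.interval_set().overlap_flags(enhancers)
    q = float(p53_flags.mean()) if n_enh else 0.0

    for f in factors:
        if pair_planted and f in (a, b):
            continue
        lift = cfg.tf_p53_lifts.get(f)
        if lift is not None and peaks is not None and 0 < q < 1:
            r_hi = min(1.0, rate * lift)
            r_lo = max(0.0, (rate - q * r_hi) / (1.0 - q))
            p = np.where(p53_flags, r_hi, r_lo)
            bound[f] = rng_t.random(n_enh) < p
        else:
            bound[f] = rng_t.random(n_enh) < rate

    site_len = 200
    catalog: dict[str, IntervalSet] = {}
    for f in factors:
        sites = []
        for i in np.flatnonzero(bound[f]):
            iv = enhancers[int(i)]
            slen = min(site_len, iv.length)
            off = int(rng_t.integers(0, iv.length - slen + 1))
            sites.append(GenomicInterval(iv.chrom, iv.start + off,
                                         iv.start + off + slen, name=f))
        catalog[f] = IntervalSet(sites, source=f"sim:{f}")

    truth = GroundTruth(
        cobound_pairs=[[a, b, cfg.cobound_odds]] if pair_planted else [],
        tf_lifts=dict(cfg.tf_p53_lifts),
    )
    return StatesBundle(backbone=backbone, cell_maps=cell_maps,
                        tf_catalog=catalog, truth=truth)


def _joint_prob_from_odds(pa: float, pb: float, theta: float) -> float:
    """P(both) for two Bernoulli margins with the given odds ratio
    (Plackett construction)."""
    if theta == 1.0:
        return pa * pb
    s = 1.0 + (pa + pb) * (theta - 1.0)
    disc = s * s - 4.0 * theta * (theta - 1.0) * pa * pb
    p11 = (s - np.sqrt(disc)) / (2.0 * (theta - 1.0))
    return float(np.clip(p11, max(0.0, pa + pb - 1.0), min(pa, pb)))


def place_peaks_with_state_bias(
    cfg: SimulationConfig,
    state_map: StateMap,
    chrom_lengths: Mapping[str, int] | None = None,
    enhancer_state: str = "Enhancer",
    rng: np.random.Generator | None = None,
) -> PeakSet:
    """Peaks placed inside the enhancer state with probability
    peak_enhancer_bias, otherwise uniformly in the complement."""
    rng = rng or _stage_rngs(cfg.seed)["peaks"]
    chrom_lengths = dict(chrom_lengths or cfg.chrom_lengths)
    enh = state_map.by_label(enhancer_state).merged()
    genome_iv = IntervalSet([
        GenomicInterval(c, 0, l) for c, l in chrom_lengths.items()
    ])
    complement = genome_iv.subtract(enh)
    peaks = []
    for i in range(cfg.n_peaks):
        plen = int(rng.integers(cfg.peak_min_len, cfg.peak_max_len + 1))
        space = enh if rng.random() < cfg.peak_enhancer_bias else complement
        fit = [iv for iv in space if iv.length >= plen]
        if not fit:
            fit = [iv for iv in space if iv.length > 0]
            plen = min(plen, max(iv.length for iv in fit))
            fit = [iv for iv in fit if iv.length >= plen]
        weights = np.array([iv.length - plen + 1 for iv in fit], dtype=float)
        pick = fit[int(rng.choice(len(fit), p=weights / weights.sum()))]
        pos = int(rng.integers(pick.start, pick.end - plen + 1))
        peaks.append(Peak(
            GenomicInterval(pick.chrom, pos, pos + plen, name=f"peak_{i + 1:04d}"),
            float(rng.lognormal(1.0, 1.0)),
        ))
    return PeakSet(peaks, source="simulated_state_bias")


# -- expression compendium for guilt-by-association -------------------------------


def simulate_compendium(
    cfg: SimulationConfig,
    n_coding: int = 300,
    n_module: int = 30,
    n_tissues: int = 12,
    rng: np.random.Generator | None = None,
) -> tuple["pd.DataFrame", np.ndarray, list[str], dict[str, set[str]]]:
    """Gene x tissue compendium with a planted co-regulated module.

    Returns (values frame, query profile, module gene ids, GMT-style sets).
    Module genes share the query's archetype profile up to multiplicative
    noise; the remaining genes are unrelated.
    """
    rng = rng or _stage_rngs(cfg.seed)["compendium"]
    archetype = rng.lognormal(0.0, 1.0, size=n_tissues)
    ids = [f"PC{i + 1:04d}" for i in range(n_coding)]
    module = ids[:n_module]
    values = np.empty((n_coding, n_tissues))
    for i in range(n_coding):
        if i < n_module:
            values[i] = archetype * rng.lognormal(0.0, 0.25, size=n_tissues)
        else:
            values[i] = rng.lognormal(0.0, 1.0, size=n_tissues)
    frame = pd.DataFrame(values, index=ids,
                         columns=[f"tissue_{t + 1:02d}" for t in range(n_tissues)])
    query = archetype * rng.lognormal(0.0, 0.25, size=n_tissues)
    sets: dict[str, set[str]] = {"PLANTED_MODULE": set(module)}
    for s in range(4):
        pick = rng.permutation(n_coding)[:n_module]
        sets[f"RANDOM_SET_{s + 1}"] = {ids[int(i)] for i in pick}
    return frame, query, module, sets


# -- one-call bundle --------------------------------------------------------------


@dataclass
class SimBundle:
    config: SimulationConfig
    genome: SimulatedGenome
    annotation: pd.DataFrame
    expression: ExpressionTable
    peaks: PeakSet
    repeats: pd.DataFrame
    states: StatesBundle
    compendium: pd.DataFrame
    query_profile: np.ndarray
    gene_sets: dict[str, set[str]]
    truth: GroundTruth


def simulate_all(cfg: SimulationConfig) -> SimBundle:
    """Generate every pipeline input from one seed."""
    rngs = _stage_rngs(cfg.seed)
    genome, annotation = simulate_genome_and_annotation(cfg, rngs["genome"])
    expression, peaks, truth = simulate_de_and_peaks(cfg, genome, annotation, rngs)
    linc_targets = [t for t in truth.target_ids if t.startswith("LINC")]
    subset = linc_targets or list(
        annotation.loc[annotation["biotype"] == "lincRNA", "gene_id"].head(10)
    )
    repeats, rep_truth = simulate_repeats(cfg, annotation, subset, rngs["repeats"])
    states = simulate_states_and_tfs(cfg, cfg.chrom_lengths, peaks, rngs)
    compendium, query, module, sets = simulate_compendium(cfg, rng=rngs["compendium"])

    truth.repeat_subset_ids = rep_truth.repeat_subset_ids
    truth.enriched_te_labels = rep_truth.enriched_te_labels
    truth.cobound_pairs = states.truth.cobound_pairs
    truth.tf_lifts = states.truth.tf_lifts
    return SimBundle(
        config=cfg, genome=genome, annotation=annotation, expression=expression,
        peaks=peaks, repeats=repeats, states=states, compendium=compendium,
        query_profile=query, gene_sets=sets, truth=truth,
    )


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every simulated input as plain text; returns the path map."""
    from .association import write_gmt
    from .intervals import write_peaks
    from .statemaps import write_tf_catalog

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "config": outdir / "sim_config.yaml",
        "genome": outdir / "genome.fa",
        "chrom_sizes": outdir / "chrom.sizes",
        "annotation": outdir / "annotation.tsv",
        "expression": outdir / "expression.tsv",
        "peaks": outdir / "peaks.bed",
        "repeats": outdir / "repeats.tsv",
        "tf_sites": outdir / "tf_sites.bed",
        "compendium": outdir / "compendium.tsv",
        "query_profile": outdir / "query_profile.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "ground_truth": outdir / "ground_truth.json",
    }
    bundle.config.to_yaml(paths["config"])
    bundle.genome.write_fasta(paths["genome"])
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in bundle.genome.chrom_sizes().items():
            fh.write(f"{chrom}\t{size}\n")
    bundle.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    bundle.expression.write(paths["expression"])
    write_peaks(bundle.peaks, paths["peaks"])
    bundle.repeats.to_csv(paths["repeats"], sep="\t", index=False)
    write_tf_catalog(bundle.states.tf_catalog, paths["tf_sites"])
    bundle.compendium.to_csv(paths["compendium"], sep="\t")
    pd.Series(bundle.query_profile,
              index=bundle.compendium.columns).to_csv(
        paths["query_profile"], sep="\t", header=False)
    write_gmt(bundle.gene_sets, paths["gene_sets"])
    bundle.truth.to_json(paths["ground_truth"])
    for i, cmap in enumerate(bundle.states.cell_maps, start=1):
        p = outdir / f"states_cell_type_{i}.bed"
        cmap.write_bed(p)
        paths[f"states_{i}"] = p
    return paths
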