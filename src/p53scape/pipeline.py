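"""End-to-end orchestration of the analysis stages.

Stage order mirrors the study: expression/peak filters, direct-target
calling with the species window, peak-TSS distance profile and the
bound-vs-unbound KS comparison, motif scan, repeat enrichment, hybrid
state-map construction, state enrichment at peaks, TF enrichment within
p53-bound enhancers, the global co-occurrence matrix, and (optionally)
guilt-by-association for a query profile.

Every stage writes its result table plus a JSON provenance record, so any
stage can be re-run independently from the files on disk.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (ExpressionCompendium, preranked_set_score,
                          rank_by_association, read_gmt)
from .enrichment import (bonferroni, repeat_enrichment, results_to_frame,
                         state_enrichment, te_coverage_fraction,
                         tf_in_enhancer_enrichment)
from .expression import (ExpressionTable, filter_lincrna_expressed,
                         filter_mrna_top_expressed, filter_peaks_top_covered)
from .intervals import IntervalSet, PeakSet, read_peaks, write_peaks
from .motif import MotifSpec, peaks_with_motif
from .statemaps import (StateMap, cooccurrence_matrix, intersect_state_maps,
                        p53_bound_enhancers, read_tf_catalog)
from .targets import call_direct_targets, ks_bound_vs_unbound, peak_tss_distances

SPECIES_WINDOWS = {"human": 30_000, "mouse": 20_000}


@dataclass
class PipelineConfig:
    """Validated configuration for a full run."""

    species: str = "human"
    expression_path: str = ""
    peaks_path: str = ""
    genome_path: str = ""
    annotation_path: str = ""
    repeats_path: str = ""
    state_map_paths: list[str] = field(default_factory=list)
    tf_sites_path: str = ""
    chrom_sizes_path: str = ""
    compendium_path: str = ""
    query_profile_path: str = ""
    gene_sets_path: str = ""
    repeat_subset_source: str = "lincrna_targets"
    mrna_quantile: float = 0.75
    peak_quantile: float = 0.75
    lincrna_min_fpkm: float = 1.0
    n_perm: int = 100
    seed: int = 0
    enhancer_state: str = "Enhancer"

    def __post_init__(self) -> None:
        if self.species not in SPECIES_WINDOWS:
            raise ValueError(f"species must be one of {sorted(SPECIES_WINDOWS)}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        for q in (self.mrna_quantile, self.peak_quantile):
            if not (0.0 < q <= 1.0):
                raise ValueError("quantiles must be in (0, 1]")

    @property
    def window(self) -> int:
        return SPECIES_WINDOWS[self.species]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _provenance(outdir: Path, stage: str, params: Mapping[str, Any]) -> None:
    record = {"stage": stage, "package_version": __version__, **params}
    with open(outdir / f"{stage}.provenance.json", "w") as fh:
        json.dump(record, fh, indent=1, sort_keys=True, default=str)


def run_all(cfg: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Run the full analysis on the configured input bundle.

    Returns the in-memory results keyed by stage; all tables are also
    written under `outdir`. Any stage failure propagates with the stage
    name; previously written outputs are left in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}
    stage = "setup"
    try:
        table = ExpressionTable.read(cfg.expression_path)
        peaks = read_peaks(cfg.peaks_path)
        chrom_sizes = _read_chrom_sizes(cfg.chrom_sizes_path) \
            if cfg.chrom_sizes_path else None

        stage = "filter"
        mrna, mrna_cutoff = filter_mrna_top_expressed(table, cfg.mrna_quantile)
        lincs = filter_lincrna_expressed(table, cfg.lincrna_min_fpkm)
        filtered = ExpressionTable(
            mrna.records + lincs.records, table.samples,
            mrna.filters + lincs.filters,
        )
        peaks_f, peak_cutoff = filter_peaks_top_covered(peaks, cfg.peak_quantile)
        filtered.write(outdir / "filtered_expression.tsv")
        write_peaks(peaks_f, outdir / "filtered_peaks.bed")
        _provenance(outdir, "filter", {
            "mrna_quantile": cfg.mrna_quantile, "mrna_cutoff": mrna_cutoff,
            "peak_quantile": cfg.peak_quantile, "peak_cutoff": peak_cutoff,
            "lincrna_min_fpkm": cfg.lincrna_min_fpkm,
            "inputs": [cfg.expression_path, cfg.peaks_path],
        })
        results["filter"] = {"expression": filtered, "peaks": peaks_f,
                             "mrna_cutoff": mrna_cutoff,
                             "peak_cutoff": peak_cutoff}

        stage = "targets"
        calls = call_direct_targets(filtered, peaks_f, cfg.window, chrom_sizes)
        calls.to_frame().to_csv(outdir / "direct_targets.tsv", sep="\t",
                                index=False)
        supporting = IntervalSet(
            sorted({p.interval for c in calls.calls for p in c.supporting_peaks},
                   key=lambda iv: (iv.chrom, iv.start)),
        )
        from .intervals import write_bed
        write_bed(supporting, outdir / "supporting_peaks.bed")
        profile = peak_tss_distances(peaks_f, table)
        pd.DataFrame({"distance": profile.distances}).to_csv(
            outdir / "peak_tss_distances.tsv", sep="\t", index=False)
        bound_ids = calls.target_ids()
        ks_d, ks_p = (float("nan"), float("nan"))
        unbound_exists = any(r.gene_id not in bound_ids for r in table)
        if bound_ids and unbound_exists:
            ks_d, ks_p = ks_bound_vs_unbound(table, bound_ids)
        _provenance(outdir, "targets", {
            "window": cfg.window, "species": cfg.species,
            "n_targets": len(calls.calls),
            "counts": calls.counts_by_direction(),
            "fraction_peaks_supporting": calls.fraction_peaks_supporting,
            "ks_D": ks_d, "ks_p": ks_p,
        })
        results["targets"] = {"calls": calls, "profile": profile,
                              "ks": (ks_d, ks_p)}

        stage = "motif"
        if cfg.genome_path:
            genome = _open_genome(cfg.genome_path)
            with_m, without_m, summary = peaks_with_motif(peaks_f, genome,
                                                          MotifSpec())
            write_peaks(with_m, outdir / "peaks_with_motif.bed")
            _provenance(outdir, "motif", summary)
            results["motif"] = summary

        stage = "repeats"
        if cfg.repeats_path and cfg.annotation_path:
            repeats = pd.read_csv(cfg.repeats_path, sep="\t")
            annotation = pd.read_csv(cfg.annotation_path, sep="\t")
            transcripts = annotation.rename(
                columns={"gene_id": "transcript_id"}
            )[["transcript_id", "biotype", "length"]]
            subset = sorted(
                gid for gid in bound_ids
                if gid in table and table[gid].biotype == "lincRNA"
            )
            if subset:
                rep_res = repeat_enrichment(
                    repeats, transcripts, subset, n_perm=cfg.n_perm,
                    seed=cfg.seed)
                results_to_frame(rep_res).to_csv(
                    outdir / "repeat_enrichment.tsv", sep="\t", index=False)
                te_frac = te_coverage_fraction(repeats, transcripts, subset)
                _provenance(outdir, "repeats", {
                    "n_subset": len(subset), "te_coverage_fraction": te_frac,
                    "n_perm": cfg.n_perm, "seed": cfg.seed,
                })
                results["repeats"] = {"enrichment": rep_res,
                                      "te_coverage_fraction": te_frac}

        stage = "hybrid_map"
        hybrid = None
        if cfg.state_map_paths:
            maps = [StateMap.read_bed(p) for p in cfg.state_map_paths]
            hybrid = intersect_state_maps(maps) if len(maps) > 1 else maps[0]
            hybrid.write_bed(outdir / "hybrid_state_map.bed")
            _provenance(outdir, "hybrid_map", {
                "inputs": list(cfg.state_map_paths),
                "coverage_by_state": hybrid.coverage_by_label(),
            })
            results["hybrid_map"] = hybrid

        stage = "state_enrichment"
        if hybrid is not None and chrom_sizes:
            genome_size = sum(chrom_sizes.values())
            st_res = bonferroni(state_enrichment(
                peaks_f, hybrid, genome_size, n_perm=cfg.n_perm, seed=cfg.seed))
            results_to_frame(st_res).to_csv(
                outdir / "state_enrichment.tsv", sep="\t", index=False)
            _provenance(outdir, "state_enrichment", {
                "genome_size": genome_size, "n_perm": cfg.n_perm,
                "seed": cfg.seed,
            })
            results["state_enrichment"] = st_res

        stage = "tf_enrichment"
        if hybrid is not None and cfg.tf_sites_path:
            catalog = read_tf_catalog(cfg.tf_sites_path)
            enhancers = hybrid.by_label(cfg.enhancer_state)
            bound_enh = p53_bound_enhancers(peaks_f, hybrid, cfg.enhancer_state)
            if len(bound_enh) and len(enhancers):
                tf_res = bonferroni(tf_in_enhancer_enrichment(
                    bound_enh, catalog, enhancers, n_perm=cfg.n_perm,
                    seed=cfg.seed))
                results_to_frame(tf_res).to_csv(
                    outdir / "tf_enrichment.tsv", sep="\t", index=False)
                results["tf_enrichment"] = tf_res
            stage = "cooccurrence"
            catalog_with_p53 = dict(catalog)
            catalog_with_p53["p53"] = peaks_f.interval_set()
            matrix = cooccurrence_matrix(catalog_with_p53, enhancers)
            matrix.to_long().to_csv(outdir / "tf_cooccurrence.tsv", sep="\t",
                                    index=False)
            matrix.p_adj_matrix.to_csv(outdir / "tf_cooccurrence_padj_matrix.tsv",
                                       sep="\t")
            _provenance(outdir, "cooccurrence", {
                "n_enhancers": matrix.N, "n_factors": len(matrix.factors),
            })
            results["cooccurrence"] = matrix

        stage = "association"
        if cfg.compendium_path and cfg.query_profile_path and cfg.gene_sets_path:
            comp = ExpressionCompendium.read(cfg.compendium_path)
            query = pd.read_csv(cfg.query_profile_path, sep="\t", header=None,
                                index_col=0).iloc[:, 0].to_numpy(dtype=float)
            ranked = rank_by_association(query, comp)
            sets = read_gmt(cfg.gene_sets_path)
            rows = []
            for name in sorted(sets):
                members = sets[name] & set(ranked.genes())
                if not members:
                    continue
                es, p = preranked_set_score(ranked, members, n_perm=cfg.n_perm,
                                            seed=cfg.seed)
                rows.append({"gene_set": name, "es": es, "p": p})
            assoc = pd.DataFrame(rows, columns=["gene_set", "es", "p"])
            if len(assoc):
                assoc["p_adj"] = (assoc["p"] * len(assoc)).clip(upper=1.0)
            assoc.to_csv(outdir / "association.tsv", sep="\t", index=False)
            results["association"] = assoc
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _provenance(outdir, "run_all", {
        "config": dataclasses.asdict(cfg), "stages": sorted(results),
    })
    return results


def _read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split("\t")[:2]
                sizes[chrom] = int(size)
    return sizes


def _open_genome(path: str | Path):
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True)
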