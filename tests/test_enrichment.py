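"""Coverage-normalized enrichment: formula fidelity, permutation-null
behavior, and planted-effect recovery for repeats, states and TFs."""

import numpy as np
import pandas as pd
import pytest

from p53scape.enrichment import (LabeledFeatureSpace, bonferroni,
                                 complement_density_ratio, enrichment_ratio,
                                 literal_enrichment_ratio, permutation_test,
                                 repeat_enrichment, state_enrichment,
                                 te_coverage_fraction,
                                 tf_in_enhancer_enrichment)
from p53scape.intervals import GenomicInterval, IntervalSet, Peak, PeakSet
from p53scape.simulate import (SimulationConfig, place_peaks_with_state_bias,
                               simulate_genome_and_annotation,
                               simulate_repeats, simulate_states_and_tfs,
                               transcripts_frame)
from p53scape.statemaps import StateMap


class TestEnrichmentRatio:
    def test_hand_arithmetic_example(self):
        # 4 hits in 1 kb against 10 hits in 10 kb: densities 4/1000 vs 1/1000
        assert enrichment_ratio(4, 1000, 10, 10000) == pytest.approx(4.0)

    def test_identity_and_zero(self):
        assert enrichment_ratio(10, 1000, 10, 1000) == 1.0
        assert enrichment_ratio(0, 1000, 10, 10000) == 0.0

    def test_zero_background_is_undefined_not_infinite(self):
        assert enrichment_ratio(5, 1000, 0, 10000) is None

    def test_literal_formula_cancels_feature_coverage(self, rng):
        """The bookkeeping with the coverage-of-feature normalization must
        equal the reduced density ratio to machine precision."""
        for _ in range(2000):
            c_s, c_b = rng.integers(1, 1000, size=2)
            cov_s, cov_b, cov_e = rng.uniform(1, 1e8, size=3)
            lit = literal_enrichment_ratio(c_s, cov_s, c_b, cov_b, cov_e)
            red = enrichment_ratio(c_s, cov_s, c_b, cov_b)
            assert abs(lit - red) <= 1e-12 * red

    def test_scale_invariance(self, rng):
        c_s, cov_s, c_b, cov_b = 7, 1234.0, 55, 98765.0
        base = enrichment_ratio(c_s, cov_s, c_b, cov_b)
        for f in rng.uniform(0.1, 100, size=20):
            assert enrichment_ratio(c_s * f, cov_s * f, c_b * f, cov_b * f) \
                == pytest.approx(base)

    def test_monotone_in_subset_count(self):
        rs = [enrichment_ratio(c, 1000, 50, 100000) for c in range(0, 30)]
        assert all(b >= a for a, b in zip(rs, rs[1:]))


def toy_space(rng, n_units=60, n_labels=4, subset_size=15, seed_ids=""):
    ids = [f"t{seed_ids}{i}" for i in range(n_units)]
    lengths = rng.uniform(500, 3000, n_units)
    counts = pd.DataFrame(
        rng.poisson(2.0, size=(n_units, n_labels)), index=ids,
        columns=[f"lab{j}" for j in range(n_labels)])
    subset = frozenset(np.array(ids)[rng.permutation(n_units)[:subset_size]])
    return LabeledFeatureSpace(ids, lengths, counts, subset)


class TestPermutationTest:
    def test_pvalue_floor_under_pseudocount_convention(self, rng):
        """An observed ratio exceeding every null gives p = 1/(n+1)."""
        ids = [f"u{i}" for i in range(40)]
        lengths = np.full(40, 1000.0)
        col = np.zeros(40)
        col[:5] = 50  # all features inside the subset
        counts = pd.DataFrame({"x": col}, index=ids)
        space = LabeledFeatureSpace(ids, lengths, counts,
                                    frozenset(ids[:5]))
        res = permutation_test(space, "x", n_perm=100, seed=1)
        assert res.p_perm == pytest.approx(1 / 101)
        # and the depleted side saturates
        assert res.p_depl == pytest.approx(1.0)

    def test_depleted_label_saturates_enrichment_p(self, rng):
        ids = [f"u{i}" for i in range(40)]
        lengths = np.full(40, 1000.0)
        col = np.zeros(40)
        col[20:] = 10  # features only outside the subset
        counts = pd.DataFrame({"x": col}, index=ids)
        space = LabeledFeatureSpace(ids, lengths, counts,
                                    frozenset(ids[:20]))
        res = permutation_test(space, "x", n_perm=100, seed=1)
        assert res.p_perm == pytest.approx(1.0)
        assert res.p_depl == pytest.approx(1 / 101)

    def test_reproducible_under_fixed_seed(self, rng):
        space = toy_space(rng)
        a = permutation_test(space, "lab0", n_perm=50, seed=9)
        b = permutation_test(space, "lab0", n_perm=50, seed=9)
        assert (a.p_perm, a.p_depl, a.ratio) == (b.p_perm, b.p_depl, b.ratio)

    def test_adding_labels_does_not_perturb_other_nulls(self, rng):
        """Per-label RNG substreams: the p-value of lab0 is identical
        whether or not other labels are tested."""
        space = toy_space(rng)
        alone = permutation_test(space, "lab0", n_perm=50, seed=3).p_perm
        extended = LabeledFeatureSpace(
            space.unit_ids, space.lengths,
            space.counts.assign(extra=1), space.subset_ids)
        assert permutation_test(extended, "lab0", n_perm=50, seed=3).p_perm \
            == alone

    def test_degenerate_subsets_rejected(self, rng):
        space = toy_space(rng)
        with pytest.raises(ValueError):
            permutation_test(
                LabeledFeatureSpace(space.unit_ids, space.lengths,
                                    space.counts,
                                    frozenset(space.unit_ids)),
                "lab0")

    def test_bonferroni_arithmetic(self, rng):
        space = toy_space(rng)
        res = [permutation_test(space, l, n_perm=100, seed=0)
               for l in space.labels]
        adj = bonferroni(res)
        for r, a in zip(res, adj):
            assert a.p_adj == pytest.approx(min(1.0, r.p_perm * len(res)))
        # spot values from the counting convention
        assert bonferroni([res[0].__class__(**{**res[0].__dict__,
                                               "p_perm": 0.0099})] * 5
                          )[0].p_adj == pytest.approx(0.0495)


class TestRepeatEnrichment:
    def test_planted_density_ratio_recovered(self):
        cfg = SimulationConfig(seed=21, n_lincrnas=120)
        _, ann = simulate_genome_and_annotation(cfg)
        lincs = list(ann.loc[ann.biotype == "lincRNA", "gene_id"])
        subset = lincs[:50]
        reps, truth = simulate_repeats(cfg, ann, subset)
        res = repeat_enrichment(reps, transcripts_frame(ann), subset,
                                n_perm=50, seed=4)
        alu = next(r for r in res if r.label == "Alu")
        planted = cfg.te_density_subset / cfg.te_density_background
        assert complement_density_ratio(alu) == pytest.approx(planted, rel=0.2)
        # non-planted families hover near 1
        for r in res:
            if r.label != "Alu":
                assert 0.5 < complement_density_ratio(r) < 1.7

    def test_null_subset_ratios_near_one(self, rng):
        cfg = SimulationConfig(seed=31,
                               te_density_subset=0.5)  # no planted contrast
        _, ann = simulate_genome_and_annotation(cfg)
        subset = list(ann["gene_id"].sample(40, random_state=1))
        reps, _ = simulate_repeats(cfg, ann, subset)
        res = repeat_enrichment(reps, transcripts_frame(ann), subset,
                                n_perm=50, seed=2)
        for r in res:
            assert r.ratio == pytest.approx(1.0, abs=0.35)

    def test_unknown_subset_id_errors(self):
        cfg = SimulationConfig(seed=5)
        _, ann = simulate_genome_and_annotation(cfg)
        reps, _ = simulate_repeats(cfg, ann, [])
        with pytest.raises(KeyError):
            repeat_enrichment(reps, transcripts_frame(ann), ["NOPE"])

    def test_lincrna_background_switch(self):
        cfg = SimulationConfig(seed=6)
        _, ann = simulate_genome_and_annotation(cfg)
        lincs = list(ann.loc[ann.biotype == "lincRNA", "gene_id"])
        reps, _ = simulate_repeats(cfg, ann, lincs[:10])
        res = repeat_enrichment(reps, transcripts_frame(ann), lincs[:10],
                                background="lincrna", n_perm=20, seed=0)
        assert all(r.cov_background < ann["length"].sum() for r in res)


class TestTeCoverage:
    def make(self, rows, lengths):
        reps = pd.DataFrame(rows, columns=["transcript_id", "element",
                                           "family", "start", "end"])
        tx = pd.DataFrame({
            "transcript_id": list(lengths), "biotype": "lincRNA",
            "length": list(lengths.values()),
        })
        return reps, tx

    def test_repeat_free_and_fully_covered(self):
        reps, tx = self.make([("a", "AluY", "Alu", 0, 1000)],
                             {"a": 1000, "b": 500})
        assert te_coverage_fraction(reps, tx, ["b"]) == 0.0
        assert te_coverage_fraction(reps, tx, ["a"]) == 1.0

    def test_overlapping_occurrences_merged(self):
        reps, tx = self.make(
            [("a", "AluY", "Alu", 0, 300), ("a", "AluSx", "Alu", 200, 500)],
            {"a": 1000})
        assert te_coverage_fraction(reps, tx, ["a"]) == pytest.approx(0.5)

    def test_simulated_coverage_tracks_density(self):
        cfg = SimulationConfig(seed=41)
        _, ann = simulate_genome_and_annotation(cfg)
        lincs = list(ann.loc[ann.biotype == "lincRNA", "gene_id"])
        reps, _ = simulate_repeats(cfg, ann, lincs[:20])
        frac = te_coverage_fraction(reps, transcripts_frame(ann), lincs[:20])
        # subset density 2.5/kb of ~300 nt repeats -> high but partial cover
        assert 0.2 < frac < 0.95


class TestStateEnrichment:
    def test_whole_genome_state_has_ratio_one(self):
        segs = [(GenomicInterval("chr1", 0, 100000), "Everything")]
        smap = StateMap("x", segs)
        peaks = PeakSet([Peak(GenomicInterval("chr1", i * 1000, i * 1000 + 100),
                              1.0) for i in range(20)])
        res = state_enrichment(peaks, smap, 100000, n_perm=10, seed=0)
        assert res[0].ratio == pytest.approx(1.0)

    def test_planted_enhancer_bias_recovers_analytic_ratio(self):
        cfg = SimulationConfig(
            seed=17,
            state_fractions={"Enhancer": 0.01, "ActivePromoter": 0.02,
                             "WeakTranscription": 0.30, "Repressed": 0.15},
            peak_enhancer_bias=0.8)
        sb = simulate_states_and_tfs(cfg)
        peaks = place_peaks_with_state_bias(cfg, sb.backbone)
        G = sum(cfg.chrom_lengths.values())
        res = state_enrichment(peaks, sb.backbone, G, n_perm=100, seed=3)
        enh = next(r for r in res if r.label == "Enhancer")
        assert enh.ratio == pytest.approx(80.0, rel=0.15)
        assert enh.p_perm == pytest.approx(1 / 101)  # at the floor

    def test_uniform_peaks_give_flat_ratios(self):
        # narrow peaks so boundary-straddling does not inflate counts
        cfg = SimulationConfig(seed=19)
        sb = simulate_states_and_tfs(cfg)
        rng = np.random.default_rng(3)
        peaks = []
        for i in range(3000):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            s = int(rng.integers(0, 4_999_000))
            peaks.append(Peak(GenomicInterval(chrom, s, s + 10,
                                              name=f"p{i}"), 1.0))
        G = sum(cfg.chrom_lengths.values())
        res = state_enrichment(PeakSet(peaks), sb.backbone, G, n_perm=30,
                               seed=5)
        for r in res:
            assert r.ratio == pytest.approx(1.0, abs=0.45)

    def test_histone_mark_variant_accepts_interval_sets(self):
        marks = {
            "H3K4me1": IntervalSet([GenomicInterval("chr1", 0, 5000)]),
            "H3K27me3": IntervalSet([GenomicInterval("chr1", 20000, 30000)]),
        }
        peaks = PeakSet([Peak(GenomicInterval("chr1", 100, 400), 1.0),
                         Peak(GenomicInterval("chr1", 1000, 1300), 1.0)])
        res = state_enrichment(peaks, marks, 100000, n_perm=10, seed=0)
        by = {r.label: r for r in res}
        assert by["H3K4me1"].count_subset == 2
        assert by["H3K27me3"].count_subset == 0


class TestTfInEnhancerEnrichment:
    def enhancers(self, n=50, length=1000):
        return IntervalSet([
            GenomicInterval("chr1", i * 5000, i * 5000 + length)
            for i in range(n)
        ])

    def sites_at(self, enhancers, idx):
        return IntervalSet([
            GenomicInterval(iv.chrom, iv.start + 10, iv.start + 110)
            for i, iv in enumerate(enhancers.intervals) if i in set(idx)
        ])

    def test_factor_bound_everywhere_scores_one(self):
        enh = self.enhancers()
        p53 = self.sites_at(enh, range(0, 10))
        catalog = {"ubiquitous": self.sites_at(enh, range(50))}
        res = tf_in_enhancer_enrichment(p53, catalog, enh, n_perm=10, seed=0)
        assert res[0].ratio == pytest.approx(1.0)

    def test_planted_cooccurrence_lift_recovered(self):
        cfg = SimulationConfig(seed=23, n_peaks=900, tf_p53_lifts={"KAP1": 3.0})
        from p53scape.simulate import (simulate_de_and_peaks,
                                       simulate_genome_and_annotation)
        genome, ann = simulate_genome_and_annotation(cfg)
        _, peaks, _ = simulate_de_and_peaks(cfg, genome, ann)
        sb = simulate_states_and_tfs(cfg, peaks=peaks)
        enh = sb.backbone.by_label("Enhancer")
        bound_flags = peaks.interval_set().overlap_flags(enh.intervals)
        p53_bound = IntervalSet(
            [iv for iv, f in zip(enh.intervals, bound_flags) if f])
        res = tf_in_enhancer_enrichment(p53_bound, sb.tf_catalog, enh,
                                        n_perm=50, seed=1)
        by = {r.label: r for r in res}
        assert by["KAP1"].ratio == pytest.approx(3.0, rel=0.45)
        # independent factors hover near 1
        others = [by[f].ratio for f in by
                  if f not in ("KAP1", "cFos", "cJun") and by[f].ratio]
        assert np.median(others) == pytest.approx(1.0, abs=0.35)

    def test_independent_factor_p_not_extreme(self):
        enh = self.enhancers(n=80)
        rng = np.random.default_rng(0)
        p53 = self.sites_at(enh, rng.permutation(80)[:20])
        catalog = {"x": self.sites_at(enh, rng.permutation(80)[:20])}
        res = tf_in_enhancer_enrichment(p53, catalog, enh, n_perm=100, seed=2)
        assert res[0].p_perm > 0.01 or res[0].p_depl > 0.01
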