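"""Hybrid state-map construction and hypergeometric TF co-occurrence."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from p53scape.intervals import GenomicInterval, IntervalSet, Peak, PeakSet
from p53scape.simulate import SimulationConfig, simulate_states_and_tfs
from p53scape.statemaps import (StateMap, cooccurrence_matrix,
                                hypergeom_cooccurrence, intersect_state_maps,
                                p53_bound_enhancers)


def exact_upper_tail(N, Ka, Kb, k):
    """Oracle: exact rational enumeration of P(X >= k)."""
    total = Fraction(0)
    for j in range(k, min(Ka, Kb) + 1):
        total += Fraction(comb(Ka, j) * comb(N - Ka, Kb - j), comb(N, Kb))
    return total


def random_state_map(rng, name, labels=("Enhancer", "Promoter", "Tx"),
                     n=30, span=30000):
    cuts = np.sort(rng.choice(np.arange(100, span, 100), size=n, replace=False))
    segments = []
    pos = 0
    for c in cuts:
        if rng.random() < 0.8:  # leave some gaps unannotated
            segments.append((GenomicInterval("chr1", pos, int(c)),
                             str(rng.choice(labels))))
        pos = int(c)
    return StateMap(name, segments)


def labels_per_bp(smap, span=30000):
    out = np.full(span, None, dtype=object)
    for iv, lab in smap.segments:
        out[iv.start:iv.end] = lab
    return out


class TestStateMap:
    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError):
            StateMap("x", [(GenomicInterval("chr1", 0, 100), "A"),
                           (GenomicInterval("chr1", 50, 150), "B")])

    def test_bed4_roundtrip(self, tmp_path, rng):
        smap = random_state_map(rng, "ct1")
        path = tmp_path / "states.bed"
        smap.write_bed(path)
        back = StateMap.read_bed(path, "ct1")
        assert (labels_per_bp(back) == labels_per_bp(smap)).all()


class TestIntersectStateMaps:
    def test_identical_maps_idempotent(self, rng):
        smap = random_state_map(rng, "a")
        hybrid = intersect_state_maps([smap, StateMap("b", smap.segments)])
        assert (labels_per_bp(hybrid) == labels_per_bp(smap)).all()

    def test_same_label_partial_overlap(self):
        a = StateMap("a", [(GenomicInterval("chr1", 0, 100), "Enhancer")])
        b = StateMap("b", [(GenomicInterval("chr1", 50, 150), "Enhancer")])
        out = intersect_state_maps([a, b])
        assert [(iv.start, iv.end, lab) for iv, lab in out.segments] \
            == [(50, 100, "Enhancer")]

    def test_label_mismatch_is_empty(self):
        a = StateMap("a", [(GenomicInterval("chr1", 0, 100), "Enhancer")])
        b = StateMap("b", [(GenomicInterval("chr1", 0, 100), "Promoter")])
        with pytest.warns(UserWarning):
            out = intersect_state_maps([a, b])
        assert len(out) == 0

    def test_per_base_pair_agreement_oracle(self, rng):
        for _ in range(10):
            maps = [random_state_map(rng, f"ct{i}") for i in range(3)]
            hybrid = intersect_state_maps(maps)
            bps = [labels_per_bp(m) for m in maps]
            want = np.where(
                (bps[0] == bps[1]) & (bps[1] == bps[2]) & (bps[0] != None),  # noqa: E711
                bps[0], None)
            got = labels_per_bp(hybrid)
            assert (got == want).all()

    def test_associative_and_order_invariant(self, rng):
        maps = [random_state_map(rng, f"ct{i}") for i in range(3)]
        a = labels_per_bp(intersect_state_maps(maps))
        b = labels_per_bp(intersect_state_maps(maps[::-1]))
        c = labels_per_bp(intersect_state_maps(
            [intersect_state_maps(maps[:2]), maps[2]]))
        assert (a == b).all() and (a == c).all()

    def test_coverage_bounded_by_inputs(self, rng):
        maps = [random_state_map(rng, f"ct{i}") for i in range(2)]
        hybrid = intersect_state_maps(maps)
        cov = sum(hybrid.coverage_by_label().values())
        for m in maps:
            assert cov <= sum(m.coverage_by_label().values())


class TestP53BoundEnhancers:
    def test_no_peaks_no_bound_enhancers(self, rng):
        smap = random_state_map(rng, "a")
        assert len(p53_bound_enhancers(PeakSet([]), smap)) == 0

    def test_every_enhancer_with_peak_is_bound(self, rng):
        smap = random_state_map(rng, "a")
        enh = smap.by_label("Enhancer")
        peaks = PeakSet([Peak(GenomicInterval(iv.chrom, iv.start,
                                              iv.start + 10), 1.0)
                         for iv in enh])
        assert len(p53_bound_enhancers(peaks, smap)) == len(enh)

    def test_matches_naive_all_pairs(self, rng):
        for _ in range(10):
            smap = random_state_map(rng, "a")
            peaks = PeakSet([
                Peak(GenomicInterval("chr1",
                                     s := int(rng.integers(0, 29000)),
                                     s + int(rng.integers(50, 500))), 1.0)
                for _ in range(20)
            ])
            got = {str(iv) for iv in p53_bound_enhancers(peaks, smap)}
            want = {
                str(iv) for iv, lab in smap.segments if lab == "Enhancer"
                and any(iv.overlaps(p.interval) for p in peaks)
            }
            assert got == want


class TestHypergeomCooccurrence:
    def test_exact_example(self):
        # N=10 enhancers, factors bound at 5 and 4, all 4 shared
        assert hypergeom_cooccurrence(10, 5, 4, 4) \
            == pytest.approx(5 / 210, rel=1e-12)

    def test_zero_overlap_has_p_one(self):
        assert hypergeom_cooccurrence(100, 20, 30, 0) == 1.0

    def test_symmetric_in_margins(self):
        assert hypergeom_cooccurrence(60, 20, 11, 7) \
            == pytest.approx(hypergeom_cooccurrence(60, 11, 20, 7), rel=1e-12)

    def test_matches_exact_enumeration_on_grids(self):
        for N in (2, 3, 5, 8, 13, 21, 34, 47, 60):
            for Ka in range(0, N + 1, max(1, N // 5)):
                for Kb in range(0, Ka + 1, max(1, N // 5)):
                    for k in range(0, Kb + 1):
                        got = hypergeom_cooccurrence(N, Ka, Kb, k)
                        want = float(exact_upper_tail(N, Ka, Kb, k))
                        assert got == pytest.approx(want, rel=1e-9, abs=1e-300)

    def test_median_overlap_near_half(self):
        # k at the rounded-down expectation leaves roughly half the mass above
        N, Ka, Kb = 400, 100, 80
        k = (Ka * Kb) // N
        assert 0.3 < hypergeom_cooccurrence(N, Ka, Kb, k) < 0.8

    def test_nonincreasing_in_k(self):
        ps = [hypergeom_cooccurrence(80, 30, 25, k) for k in range(26)]
        assert all(b <= a for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_cooccurrence(10, 5, 4, 5)
        with pytest.raises(ValueError):
            hypergeom_cooccurrence(10, 12, 4, 2)


class TestCooccurrenceMatrix:
    def enhancers(self, n):
        return IntervalSet([GenomicInterval("chr1", i * 2000, i * 2000 + 500)
                            for i in range(n)])

    def catalog_from_flags(self, enh, flags):
        out = {}
        for f, mask in flags.items():
            out[f] = IntervalSet([
                GenomicInterval(iv.chrom, iv.start, iv.start + 50)
                for iv, m in zip(enh.intervals, mask) if m
            ])
        return out

    def test_identical_factors_minimal_p(self, rng):
        enh = self.enhancers(60)
        mask = rng.random(60) < 0.4
        catalog = self.catalog_from_flags(
            enh, {"a": mask, "b": mask, "c": rng.random(60) < 0.4})
        m = cooccurrence_matrix(catalog, enh)
        assert m.k_matrix.loc["a", "b"] == int(mask.sum())
        assert m.p_matrix.loc["a", "b"] == m.p_matrix.min().min()

    def test_zero_bound_factor_flagged_with_p_one(self, rng):
        enh = self.enhancers(30)
        catalog = self.catalog_from_flags(
            enh, {"dead": np.zeros(30, bool), "x": rng.random(30) < 0.5})
        m = cooccurrence_matrix(catalog, enh)
        assert "dead" in m.zero_bound_factors
        assert m.p_matrix.loc["dead", "x"] == 1.0

    def test_independent_factors_not_significant_after_bonferroni(self, rng):
        enh = self.enhancers(100)
        flags = {f"f{i}": rng.random(100) < 0.3 for i in range(8)}
        m = cooccurrence_matrix(self.catalog_from_flags(enh, flags), enh)
        off_diag = m.p_adj_matrix.to_numpy()
        assert np.nanmin(off_diag) > 0.05
        # symmetry and diagonal convention
        assert np.allclose(m.p_matrix.to_numpy(),
                           m.p_matrix.to_numpy().T, equal_nan=True)
        assert np.isnan(np.diag(m.p_matrix.to_numpy())).all()

    def test_planted_pair_is_minimal_p(self):
        cfg = SimulationConfig(seed=29, cobound_odds=10.0)
        sb = simulate_states_and_tfs(cfg)
        m = cooccurrence_matrix(sb.tf_catalog,
                                sb.backbone.by_label("Enhancer"))
        long = m.to_long().sort_values("p")
        top = long.iloc[0]
        assert {top.factor_a, top.factor_b} == set(cfg.cobound_pair)
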