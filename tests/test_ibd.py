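import copy

import numpy as np
import pandas as pd
import pytest

import admixkit as ak
from admixkit.ancestry import LocalAncestryCalls, cohort_truth_calls
from admixkit.ibd import (
    IBDSegment,
    find_ibd_haploid,
    jackknife_se,
    length_ancestry_regression,
    read_germline_match,
    segment_ancestry_profile,
    sharing_matrix,
    write_germline_match,
)


@pytest.fixture(scope="module")
def planted():
    """Painted single-chromosome cohort (20 markers/cM) with one planted
    5 cM IBD segment and one 2 cM segment on different pairs."""
    chroms = ak.ChromosomeSet.uniform(1, 50.0)
    sch = ak.MigrationSchedule.from_pulses(("EUR", "NAT"), 2, {"EUR": 1.0})
    cohort = ak.simulate_pedigree_tracts(sch, chroms, 10, seed=61)
    freqs = ak.draw_ancestral_frequencies(
        1000, 2, 0.2, chroms, seed=62, populations=("EUR", "NAT")
    )
    ak.paint_haplotypes(cohort, freqs, seed=63)
    ak.plant_ibd_segment(cohort, 0, 5, "chr1", 10.0, 15.0)
    ak.plant_ibd_segment(cohort, 2, 9, "chr1", 30.0, 32.0)
    return cohort


class TestFindIBD:
    def test_identical_haplotypes_share_whole_chromosome(self):
        rng = np.random.default_rng(0)
        h = rng.integers(0, 2, 1000)
        H = np.vstack([h, h, rng.integers(0, 2, 1000)])
        pos = np.linspace(0, 50, 1000)
        segs = find_ibd_haploid(H, pos, slice_markers=128, min_cM=3.0)
        assert len(segs) == 1
        s = segs[0]
        assert {s.hap_a, s.hap_b} == {"hap0", "hap1"}
        assert s.start_cM == pytest.approx(0.0)
        assert s.end_cM == pytest.approx(50.0)

    def test_planted_segment_recovered_within_slice_span(self, planted):
        pos = planted.frequencies.pos_cM
        segs = find_ibd_haploid(
            planted.alleles["chr1"], pos, planted.haplotype_ids(), "chr1",
            slice_markers=32, max_mismatch_per_slice=2, min_cM=3.0,
        )
        span = 32 / 20.0  # one slice in cM at 20 markers/cM
        hits = [
            s for s in segs
            if {s.hap_a, s.hap_b}
            == {planted.haplotype_ids()[0], planted.haplotype_ids()[5]}
        ]
        assert len(hits) == 1
        assert abs(hits[0].start_cM - 10.0) <= span
        assert abs(hits[0].end_cM - 15.0) <= span

    def test_short_planted_segment_not_reported(self, planted):
        pos = planted.frequencies.pos_cM
        segs = find_ibd_haploid(
            planted.alleles["chr1"], pos, planted.haplotype_ids(), "chr1",
            slice_markers=32, max_mismatch_per_slice=2, min_cM=3.0,
        )
        pair = {planted.haplotype_ids()[2], planted.haplotype_ids()[9]}
        assert not any({s.hap_a, s.hap_b} == pair for s in segs)
        assert all(s.length_cM >= 3.0 for s in segs)

    def test_switched_slice_interrupts_match(self):
        # haploid-mode conservatism: corrupting one interior slice splits
        # or truncates the match
        rng = np.random.default_rng(1)
        h = rng.integers(0, 2, 640)
        other = rng.integers(0, 2, 640)
        H = np.vstack([h, h.copy()])
        H[1, 320:352] = other[320:352]  # overwrite one 32-marker slice
        pos = np.linspace(0, 32, 640)  # 20 markers/cM
        segs = find_ibd_haploid(H, pos, slice_markers=32, max_mismatch_per_slice=2, min_cM=3.0)
        assert len(segs) >= 2
        assert all(not (s.start_cM < 16.2 < s.end_cM) for s in segs)

    def test_unsorted_map_rejected(self):
        H = np.zeros((2, 100), dtype=np.int8)
        pos = np.linspace(0, 10, 100)[::-1]
        with pytest.raises(ValueError, match="sorted"):
            find_ibd_haploid(H, pos)

    def test_single_slice_fallback_warns(self):
        rng = np.random.default_rng(2)
        h = rng.integers(0, 2, 50)
        H = np.vstack([h, h])
        pos = np.linspace(0, 10, 50)
        with pytest.warns(UserWarning, match="single slice"):
            segs = find_ibd_haploid(H, pos, slice_markers=128, min_cM=3.0)
        assert len(segs) == 1


class TestMatchFiles:
    def test_round_trip(self, tmp_path, planted):
        pos = planted.frequencies.pos_cM
        segs = find_ibd_haploid(
            planted.alleles["chr1"], pos, planted.haplotype_ids(), "chr1",
            slice_markers=32, min_cM=3.0,
        )
        path = tmp_path / "out.match"
        write_germline_match(segs, path)
        back = read_germline_match(path)
        assert len(back) == len(segs)
        for a, b in zip(segs, back):
            assert a.hap_a == b.hap_a and a.hap_b == b.hap_b
            assert a.start_cM == pytest.approx(b.start_cM, abs=1e-5)
            assert a.end_cM == pytest.approx(b.end_cM, abs=1e-5)

    def test_mb_unit_needs_map(self, tmp_path):
        p = tmp_path / "mb.match"
        p.write_text(
            "0\th1\t0\th2\tchr1\t1000000\t5000000\ts\te\t100\t4.0\tMB\t0\t0\t0\n"
        )
        with pytest.raises(ValueError, match="unit"):
            read_germline_match(p)
        gm = ak.GeneticMap(
            {"chr1": np.array([0.0, 1e7])}, {"chr1": np.array([0.0, 10.0])}
        )
        segs = read_germline_match(p, genetic_map=gm)
        assert segs[0].start_cM == pytest.approx(1.0)
        assert segs[0].end_cM == pytest.approx(5.0)

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.match"
        p.write_text("only\tthree\tfields\n")
        with pytest.raises(ValueError, match=":1"):
            read_germline_match(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.match"
        p.write_text("")
        assert read_germline_match(p) == []


def _calls_for(hap_specs):
    rows = []
    for hap, spec in hap_specs.items():
        for start, end, anc in spec:
            rows.append((hap, "chr1", start, end, anc, 1.0))
    return LocalAncestryCalls(
        windows=pd.DataFrame(
            rows, columns=["haplotype_id", "chrom", "start_cM", "end_cM", "ancestry", "posterior"]
        )
    )


class TestAncestryProfile:
    def test_uniform_ancestry(self):
        seg = IBDSegment("a", "b", "chr1", 10.0, 20.0)
        calls = _calls_for({"a": [(0, 50, "EUR")], "b": [(0, 50, "EUR")]})
        segment_ancestry_profile(seg, calls)
        assert seg.ancestry_profile == {"EUR": 1.0}
        assert not seg.discordant_ancestry

    def test_split_ancestry_averages(self):
        seg = IBDSegment("a", "b", "chr1", 0.0, 10.0)
        calls = _calls_for(
            {"a": [(0, 5, "EUR"), (5, 50, "NAT")], "b": [(0, 5, "EUR"), (5, 50, "NAT")]}
        )
        segment_ancestry_profile(seg, calls)
        assert seg.ancestry_profile["EUR"] == pytest.approx(0.5)
        assert seg.ancestry_profile["NAT"] == pytest.approx(0.5)
        assert not seg.discordant_ancestry

    def test_disagreeing_haplotypes_flagged(self):
        seg = IBDSegment("a", "b", "chr1", 0.0, 10.0)
        calls = _calls_for({"a": [(0, 50, "EUR")], "b": [(0, 50, "NAT")]})
        segment_ancestry_profile(seg, calls)
        assert seg.ancestry_profile == {"EUR": 0.5, "NAT": 0.5}
        assert seg.discordant_ancestry

    def test_uncovered_segment_rejected(self):
        seg = IBDSegment("a", "b", "chr1", 40.0, 45.0)
        calls = _calls_for({"a": [(0, 42, "EUR")], "b": [(0, 50, "EUR")]})
        with pytest.raises(ValueError, match="cover"):
            segment_ancestry_profile(seg, calls)


class TestSharing:
    LABELS = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "b3": "B"}

    def test_between_population_normalizer(self):
        segs = [
            IBDSegment("a1", "b1", "chr1", 0, 10),
            IBDSegment("a2", "b2", "chr1", 0, 20),
        ]
        m = sharing_matrix(segs, self.LABELS)
        i, j = m.populations.index("A"), m.populations.index("B")
        assert m.normalized[i, j] == pytest.approx(30 / (2 * 3))

    def test_within_population_normalizer(self):
        segs = [IBDSegment("a1", "a2", "chr1", 0, 10)]
        m = sharing_matrix(segs, {"a1": "A", "a2": "A"})
        assert m.normalized[0, 0] == pytest.approx(10 / 1)

    def test_no_segments_gives_zeros(self):
        m = sharing_matrix([], self.LABELS)
        assert np.all(m.normalized == 0)

    def test_unlabeled_haplotype_rejected(self):
        with pytest.raises(ValueError, match="label"):
            sharing_matrix([IBDSegment("zz", "a1", "chr1", 0, 5)], self.LABELS)

    def test_invariance_under_relabeling_within_population(self):
        segs = [
            IBDSegment("a1", "b1", "chr1", 0, 10),
            IBDSegment("a2", "b3", "chr2", 5, 12),
        ]
        m1 = sharing_matrix(segs, self.LABELS)
        swapped = [
            IBDSegment("a2", "b2", "chr1", 0, 10),
            IBDSegment("a1", "b1", "chr2", 5, 12),
        ]
        m2 = sharing_matrix(swapped, self.LABELS)
        np.testing.assert_allclose(m1.normalized, m2.normalized)


class TestJackknife:
    def test_homogeneous_rates_give_zero_se(self):
        chroms = ak.ChromosomeSet.uniform(4, 100.0)
        labels = {"a1": "A", "b1": "B"}
        segs = [IBDSegment("a1", "b1", c, 0, 10) for c, _ in chroms]
        m = jackknife_se(segs, chroms, labels)
        np.testing.assert_allclose(m.se, 0.0, atol=1e-12)

    def test_hand_worked_two_chromosome_example(self):
        # chr1 120 cM with 8 cM shared, chr2 80 cM with 2 + 4 cM shared,
        # one pair of individuals -> theta = 14, rescaled leave-one-out:
        #   drop chr1: 6 * 200/80 = 15 ; drop chr2: 8 * 200/120 = 40/3
        # h = (200/120, 200/80); pseudovalues tau_j = h_j*14 - (h_j-1)*loo_j
        #   tau_1 = (5/3)*14 - (2/3)*15 = 40/3
        #   tau_2 = (5/2)*14 - (3/2)*(40/3) = 15
        # theta_J = 2*14 - [(1-120/200)*15 + (1-80/200)*(40/3)] = 14
        # var = (1/2)[ (40/3-14)^2/(2/3) + (15-14)^2/(3/2) ] = 1/3 + 1/3
        chroms = ak.ChromosomeSet(("chr1", "chr2"), (120.0, 80.0))
        labels = {"x": "A", "y": "B"}
        segs = [
            IBDSegment("x", "y", "chr1", 0, 8),
            IBDSegment("x", "y", "chr2", 0, 2),
            IBDSegment("x", "y", "chr2", 10, 14),
        ]
        m = jackknife_se(segs, chroms, labels)
        i, j = m.populations.index("A"), m.populations.index("B")
        assert m.normalized[i, j] == pytest.approx(14.0)
        assert m.se[i, j] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_single_chromosome_rejected(self):
        chroms = ak.ChromosomeSet.uniform(1, 100.0)
        with pytest.raises(ValueError, match="2 chromosomes"):
            jackknife_se([IBDSegment("a", "b", "chr1", 0, 5)], chroms, {"a": "A", "b": "B"})


class TestLengthRegression:
    def _segs(self, lengths, props):
        out = []
        for i, (l, p) in enumerate(zip(lengths, props)):
            s = IBDSegment("a", "b", "chr1", 0.0, l)
            s.ancestry_profile = {"EUR": p, "NAT": 1 - p}
            out.append(s)
        return out

    def test_exact_linear_relation(self):
        lengths = np.array([4.0, 8.0, 12.0, 20.0])
        segs = self._segs(lengths, 0.01 * lengths)
        slope, se, p = length_ancestry_regression(segs, "EUR")
        assert slope == pytest.approx(0.01, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-10)

    def test_constant_profiles_give_zero_slope(self):
        segs = self._segs([4.0, 8.0, 12.0], [0.4, 0.4, 0.4])
        slope, _, _ = length_ancestry_regression(segs, "EUR")
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equation_closed_form(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(3, 30, 40)
        y = np.clip(0.3 + 0.005 * x + rng.normal(0, 0.05, 40), 0, 1)
        segs = self._segs(x, y)
        slope, se, p = length_ancestry_regression(segs, "EUR")
        xc = x - x.mean()
        beta = float(np.sum(xc * y) / np.sum(xc**2))
        resid = y - y.mean() - beta * xc
        s2 = float(resid @ resid) / (len(x) - 2)
        want_se = np.sqrt(s2 / np.sum(xc**2))
        assert slope == pytest.approx(beta)
        assert se == pytest.approx(want_se)

    def test_zero_length_variance_rejected(self):
        segs = self._segs([5.0, 5.0, 5.0], [0.2, 0.3, 0.4])
        with pytest.raises(ValueError, match="variance"):
            length_ancestry_regression(segs, "EUR")
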