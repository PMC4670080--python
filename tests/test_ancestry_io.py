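import numpy as np
import pandas as pd
import pytest

import admixkit as ak
from admixkit import io as akio
from admixkit.ancestry import (
    MISSING,
    AncestryTract,
    LocalAncestryCalls,
    calls_to_tracts,
    cohort_truth_calls,
    frame_to_tracts,
    tracts_to_frame,
)


def _calls(rows, window=0.2):
    return LocalAncestryCalls(
        windows=pd.DataFrame(
            rows, columns=["haplotype_id", "chrom", "start_cM", "end_cM", "ancestry", "posterior"]
        ),
        window_cM=window,
    )


class TestTracts:
    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            AncestryTract("h1", "chr1", 5.0, 5.0, "EUR")

    def test_calls_merge_to_single_tract(self):
        rows = [("h1", "chr1", 0.2 * i, 0.2 * (i + 1), "NAT", 0.99) for i in range(10)]
        tracts = calls_to_tracts(_calls(rows))
        assert len(tracts) == 1
        assert tracts[0].length_cM == pytest.approx(2.0)

    def test_ancestry_switch_splits_tracts(self):
        rows = [
            ("h1", "chr1", 0.0, 0.2, "EUR", 1.0),
            ("h1", "chr1", 0.2, 0.4, "NAT", 1.0),
            ("h1", "chr1", 0.4, 0.6, "EUR", 1.0),
        ]
        assert len(calls_to_tracts(_calls(rows))) == 3

    def test_tract_posterior_is_minimum_over_run(self):
        rows = [
            ("h1", "chr1", 0.0, 0.2, "NAT", 0.99),
            ("h1", "chr1", 0.2, 0.4, "NAT", 0.90),
            ("h1", "chr1", 0.4, 0.6, "NAT", 0.99),
        ]
        assert calls_to_tracts(_calls(rows))[0].posterior == pytest.approx(0.90)

    def test_small_gap_is_bridged_large_gap_splits(self):
        rows = [
            ("h1", "chr1", 0.0, 0.2, "NAT", 1.0),
            ("h1", "chr1", 0.3, 0.5, "NAT", 1.0),  # 0.1 gap < window
            ("h1", "chr1", 1.5, 1.7, "NAT", 1.0),  # 1.0 gap >= window
        ]
        tracts = calls_to_tracts(_calls(rows))
        assert len(tracts) == 2

    def test_truth_calls_round_trip_on_cohort(self, small_cohort):
        calls = cohort_truth_calls(small_cohort)
        tracts = calls_to_tracts(calls)
        got = tracts_to_frame(tracts).sort_values(
            ["haplotype_id", "chrom", "start_cM"], ignore_index=True
        )
        want = small_cohort.tracts_dataframe().sort_values(
            ["haplotype_id", "chrom", "start_cM"], ignore_index=True
        )
        pd.testing.assert_frame_equal(got[want.columns], want, check_dtype=False)


class TestAncestryProportions:
    def test_single_full_tract(self, chroms_small):
        tracts = [
            AncestryTract("h1.0", c, 0.0, L, "EUR") for c, L in chroms_small
        ]
        table = ak.ancestry_proportions(tracts, chroms_small)
        assert table.loc["h1.0", "EUR"] == pytest.approx(1.0)

    def test_mixed_fractions(self):
        chroms = ak.ChromosomeSet.uniform(1, 100.0)
        tracts = [
            AncestryTract("h1.0", "chr1", 0.0, 60.0, "EUR"),
            AncestryTract("h1.0", "chr1", 60.0, 100.0, "NAT"),
        ]
        table = ak.ancestry_proportions(tracts, chroms)
        assert table.loc["h1.0", "EUR"] == pytest.approx(0.6)
        assert table.loc["h1.0", "NAT"] == pytest.approx(0.4)

    def test_individual_level_averages_haplotypes(self):
        chroms = ak.ChromosomeSet.uniform(1, 100.0)
        tracts = [
            AncestryTract("ind1.0", "chr1", 0.0, 100.0, "EUR"),
            AncestryTract("ind1.1", "chr1", 0.0, 40.0, "EUR"),
            AncestryTract("ind1.1", "chr1", 40.0, 100.0, "NAT"),
        ]
        table = ak.ancestry_proportions(tracts, chroms, level="individual")
        assert table.loc["ind1", "EUR"] == pytest.approx(0.7)

    def test_non_tiling_tracts_rejected(self, chroms_small):
        tracts = [AncestryTract("h1.0", "chr1", 0.0, 10.0, "EUR")]
        with pytest.raises(ValueError, match="tile"):
            ak.ancestry_proportions(tracts, chroms_small)


class TestMasking:
    def test_posterior_and_ancestry_rules(self):
        # three loci: kept (target, high posterior), masked (low posterior),
        # masked (wrong ancestry)
        hm = ak.MaskedHaplotypeMatrix(
            haplotype_ids=["h1"],
            locus_ids=["l1", "l2", "l3"],
            chrom=np.array(["chr1"] * 3, dtype=object),
            pos_cM=np.array([1.0, 3.0, 5.0]),
            alleles=np.array([[1, 0, 1]], dtype=np.int8),
        )
        rows = [
            ("h1", "chr1", 0.0, 2.0, "NAT", 0.96),
            ("h1", "chr1", 2.0, 4.0, "NAT", 0.90),
            ("h1", "chr1", 4.0, 6.0, "EUR", 1.0),
        ]
        masked = ak.mask_haplotypes(hm, _calls(rows), "NAT", 0.95)
        assert masked.alleles[0, 0] == 1
        assert masked.alleles[0, 1] == MISSING
        assert masked.alleles[0, 2] == MISSING

    def test_masking_never_alters_observed_values(self, painted_cohort):
        hm = painted_cohort.haplotype_matrix()
        calls = cohort_truth_calls(painted_cohort)
        masked = ak.mask_haplotypes(hm, calls, "NAT", 0.95)
        obs = masked.alleles != MISSING
        np.testing.assert_array_equal(masked.alleles[obs], hm.alleles[obs])

    def test_uncovered_locus_rejected(self):
        hm = ak.MaskedHaplotypeMatrix(
            haplotype_ids=["h1"],
            locus_ids=["l1"],
            chrom=np.array(["chr1"], dtype=object),
            pos_cM=np.array([9.0]),
            alleles=np.array([[1]], dtype=np.int8),
        )
        rows = [("h1", "chr1", 0.0, 2.0, "NAT", 1.0)]
        with pytest.raises(ValueError, match="not covered"):
            ak.mask_haplotypes(hm, _calls(rows), "NAT", 0.95)


class TestCohortFilters:
    @pytest.fixture()
    def props(self):
        return pd.DataFrame(
            {
                "EUR": [0.70, 0.50, 0.11, 0.96, 0.10],
                "NAT": [0.24, 0.40, 0.79, 0.02, 0.85],
                "AFR": [0.06, 0.10, 0.10, 0.02, 0.05],
            },
            index=["u1", "u2", "u3", "u4", "u5"],
        )

    def test_min_target_ancestry_is_strict(self, props):
        keep, log = ak.apply_cohort_filters(
            props, ak.CohortFilters(), "aspca_admixed", target="NAT"
        )
        assert "u1" not in keep  # 0.24 < 0.25 (strict)
        assert set(keep) == {"u2", "u3", "u5"}
        assert set(log["unit"]) == {"u1", "u4"}

    def test_reference_contamination_is_strict(self, props):
        keep, _ = ak.apply_cohort_filters(props, ak.CohortFilters(), "aspca_reference")
        # EUR > 0.10 excluded; 0.10 itself retained
        assert set(keep) == {"u5"}

    def test_single_ancestry_cap(self, props):
        keep, _ = ak.apply_cohort_filters(props, ak.CohortFilters(), "tracts")
        assert "u4" not in keep  # 0.96 > 0.95

    def test_degenerate_thresholds(self, props):
        all_pass = ak.CohortFilters(0.0, 0.95, 1.0, 1.0)
        keep, log = ak.apply_cohort_filters(props, all_pass, "aspca_admixed", target="NAT")
        assert len(keep) == len(props) and len(log) == 0
        none_pass = ak.CohortFilters(1.0, 0.95, 1.0, 1.0)
        keep, _ = ak.apply_cohort_filters(props, none_pass, "aspca_admixed", target="NAT")
        assert keep == []

    def test_unknown_mode(self, props):
        with pytest.raises(ValueError):
            ak.apply_cohort_filters(props, ak.CohortFilters(), "nope")


class TestSpectrumBinning:
    def test_bin_assignment_and_half_open_edges(self, chroms_small):
        tracts = pd.DataFrame(
            {
                "haplotype_id": ["h1"] * 2,
                "chrom": ["chr1"] * 2,
                "start_cM": [0.0, 20.0],
                "end_cM": [5.0, 30.0],
                "ancestry": ["EUR", "EUR"],
                "posterior": [1.0, 1.0],
            }
        )
        spec = ak.TractLengthSpectrum.from_tracts(
            tracts, np.array([0.0, 10.0, 20.0]), chroms_small
        )
        assert spec.counts[0, 0] == 1  # 5 cM -> [0, 10)
        assert spec.counts[0, 1] == 1  # exactly 10 -> [10, 20)

    def test_total_count_conservation(self, small_cohort, chroms_small):
        edges = ak.default_bin_edges(chroms_small, 25)
        spec = ak.TractLengthSpectrum.from_cohort(small_cohort, edges)
        lengths = []
        for chrom, _ in chroms_small:
            ends = small_cohort.tract_ends[chrom]
            off = small_cohort.tract_offsets[chrom]
            starts = ends.copy()
            starts[1:] = ends[:-1]
            starts[off[:-1]] = 0.0
            lengths.append(ends - starts)
        lengths = np.concatenate(lengths)
        n_sub_floor = int((lengths < edges[0]).sum())
        assert spec.total_tracts == lengths.size - n_sub_floor

    def test_whole_chromosome_category(self):
        chroms = ak.ChromosomeSet.uniform(1, 100.0)
        tracts = pd.DataFrame(
            {
                "haplotype_id": ["h1"],
                "chrom": ["chr1"],
                "start_cM": [0.0],
                "end_cM": [100.0],
                "ancestry": ["EUR"],
                "posterior": [1.0],
            }
        )
        spec = ak.TractLengthSpectrum.from_tracts(tracts, np.array([0.2, 50.0]), chroms)
        assert spec.full_counts[0, 0] == 1
        assert spec.counts.sum() == 0


class TestFileFormats:
    def test_tract_bed_round_trip(self, tmp_path, small_cohort):
        path = tmp_path / "tracts.tsv"
        df = small_cohort.tracts_dataframe()
        akio.write_tracts_bed(df, path)
        back = tracts_to_frame(akio.read_tracts_bed(path))
        pd.testing.assert_frame_equal(
            back.sort_values(["haplotype_id", "chrom", "start_cM"], ignore_index=True),
            df.sort_values(["haplotype_id", "chrom", "start_cM"], ignore_index=True),
            check_dtype=False,
        )

    def test_bad_tract_files_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        header = "haplotype_id\tchrom\tstart_cM\tend_cM\tancestry\tposterior\n"
        p.write_text(header + "h1\tchr1\t5.0\t4.0\tEUR\t1.0\n")
        with pytest.raises(akio.FormatError, match="end <= start"):
            akio.read_tracts_bed(p)
        p.write_text(header + "h1\tchr1\t0\t5\tEUR\t1.0\nh1\tchr1\t3\t8\tEUR\t1.0\n")
        with pytest.raises(akio.FormatError, match="overlap"):
            akio.read_tracts_bed(p)
        p.write_text(header + "h1\tchr1\t0\t5\tMARS\t1.0\n")
        with pytest.raises(akio.FormatError, match="MARS"):
            akio.read_tracts_bed(p, allowed_ancestries=["EUR", "NAT", "AFR"])

    def test_empty_tract_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert akio.read_tracts_bed(p) == []

    def test_msp_round_trip(self, tmp_path):
        rows = []
        for hap in ("s1.0", "s1.1"):
            for w in range(5):
                anc = "NAT" if (w + (hap == "s1.1")) % 2 else "EUR"
                rows.append((hap, "chr1", 0.2 * w, 0.2 * (w + 1), anc, 1.0))
        calls = _calls(rows)
        path = tmp_path / "out.msp.tsv"
        akio.write_msp(calls, path)
        back = akio.read_rfmix_calls(path)
        merged_a = tracts_to_frame(calls_to_tracts(calls))
        merged_b = tracts_to_frame(calls_to_tracts(back))
        pd.testing.assert_frame_equal(
            merged_a.sort_values(["haplotype_id", "start_cM"], ignore_index=True),
            merged_b.sort_values(["haplotype_id", "start_cM"], ignore_index=True),
            check_dtype=False,
        )

    def test_msp_single_window_all_nat(self, tmp_path):
        p = tmp_path / "one.msp.tsv"
        p.write_text(
            "#Subpopulation order/codes: EUR=0\tNAT=1\tAFR=2\n"
            "#chm\tspos\tepos\tsgpos\tegpos\tn snps\ts1.0\ts1.1\n"
            "1\t0\t50000000\t0.0\t50.0\t100\t1\t1\n"
        )
        calls = akio.read_rfmix_calls(p)
        assert set(calls.windows["ancestry"]) == {"NAT"}
        assert len(calls.windows) == 2

    def test_msp_truncated_header(self, tmp_path):
        p = tmp_path / "trunc.msp.tsv"
        p.write_text("#Subpopulation order/codes: EUR=0\n1\t2\t3\n")
        with pytest.raises(akio.FormatError, match="trunc.msp.tsv"):
            akio.read_rfmix_calls(p)

    def test_legacy_viterbi_runs_collapse(self, tmp_path):
        vit = tmp_path / "vit.txt"
        # 6 markers, 2 haplotypes; hap0 alternates each marker, hap1 constant
        vit.write_text("\n".join(["1 2", "2 2", "1 2", "2 2", "1 2", "2 2"]) + "\n")
        mp = tmp_path / "markers.map"
        mp.write_text(
            "\n".join(f"chr1\tsnp{i}\t{0.2 * i:.1f}\t{int(2e5 * i) + 1}" for i in range(6)) + "\n"
        )
        calls = akio.read_rfmix_calls(vit, marker_map_path=mp)
        h0 = calls.windows[calls.windows["haplotype_id"] == "hap0.0"]
        h1 = calls.windows[calls.windows["haplotype_id"] == "hap0.1"]
        assert len(h0) == 6 and len(h1) == 1

    def test_vcf_round_trip(self, tmp_path, painted_cohort):
        path = tmp_path / "cohort.vcf"
        akio.write_phased_vcf(painted_cohort, path)
        hm = akio.read_phased_vcf(path)
        want = painted_cohort.haplotype_matrix()
        assert hm.alleles.shape == want.alleles.shape
        np.testing.assert_array_equal(hm.alleles, want.alleles)
        np.testing.assert_allclose(hm.pos_cM, want.pos_cM, atol=1e-6)

    def test_plink_map_and_genetic_map(self, tmp_path, painted_cohort):
        path = tmp_path / "cohort.map"
        akio.write_plink_map(painted_cohort.frequencies, path)
        df = akio.read_plink_map(path)
        assert len(df) == painted_cohort.frequencies.n_loci
        gm = akio.genetic_map_from_plink(path)
        cm = gm.bp_to_cM("chr1", df[df.chrom == "chr1"]["bp"].to_numpy())
        np.testing.assert_allclose(cm, df[df.chrom == "chr1"]["cM"], atol=1e-5)

    def test_labels_round_trip(self, tmp_path):
        labels = {"ind1": "PEL", "ind2": "CLM"}
        p = tmp_path / "labels.tsv"
        akio.write_labels(labels, p)
        assert akio.read_labels(p) == labels


class TestGeneticMap:
    def test_interpolation_and_clamping(self):
        gm = ak.GeneticMap(
            {"chr1": np.array([0.0, 1e6, 2e6])}, {"chr1": np.array([0.0, 1.0, 3.0])}
        )
        np.testing.assert_allclose(gm.bp_to_cM("chr1", [5e5, 1.5e6]), [0.5, 2.0])
        np.testing.assert_allclose(gm.bp_to_cM("chr1", [5e6]), [3.0])  # clamped
        with pytest.raises(KeyError):
            gm.bp_to_cM("chr2", [0.0])
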