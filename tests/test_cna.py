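"""Copy-number profiling: library QC rule, GC normalization, changepoint
recovery, integer calling, coverage-uniformity metrics, concordance, and
driver annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarecell.cna import (
    CNAProfile,
    QCRecord,
    annotate_drivers,
    call_cna_profile,
    call_integer_cn,
    normalize_bins,
    profile_concordance,
    profile_quality,
    qc_library,
    read_bed,
    read_bins_tsv,
    segment_profile,
    write_profile_tsv,
)
from rarecell.simulate import (
    GroundTruthCN,
    default_cn_truth,
    simulate_bin_counts,
    toy_genome_bins,
)


def qc_record(n_good=8, ct_good=25.0, ct_bad=35.0):
    amplified = [True] * n_good + [False] * (12 - n_good)
    ct = [ct_good] * n_good + [ct_bad] * (12 - n_good)
    return QCRecord("lib1", tuple(amplified), tuple(ct))


class TestLibraryQC:
    def test_eight_good_loci_pass(self):
        assert qc_library(qc_record(8)).passed

    def test_seven_good_loci_fail(self):
        res = qc_library(qc_record(7))
        assert not res.passed
        assert res.n_loci_pass == 7

    def test_ct_exactly_30_fails_that_locus(self):
        rec = qc_record(8, ct_good=30.0)
        res = qc_library(rec)
        assert res.n_loci_pass == 0 and not res.passed

    def test_amplified_but_hot_ct_fails(self):
        rec = QCRecord("lib2", tuple([True] * 12), tuple([29.9] * 11 + [30.1]))
        res = qc_library(rec)
        assert res.n_loci_pass == 11 and res.passed

    def test_wrong_locus_count_rejected(self):
        with pytest.raises(ValueError, match="12"):
            QCRecord("lib3", (True,) * 11, (25.0,) * 11)


def diploid_truth():
    return GroundTruthCN(segments=pd.DataFrame(
        [("chr1", 0, 60_000_000, 2), ("chr2", 0, 45_000_000, 2),
         ("chr3", 0, 30_000_000, 2)],
        columns=["chrom", "start", "end", "cn"]))


class TestNormalization:
    def test_uniform_counts_give_unit_ratios(self):
        bins = toy_genome_bins(seed=0)
        bins["count"] = 100
        ratios = normalize_bins(bins)
        np.testing.assert_allclose(ratios, 1.0, atol=1e-6)

    def test_injected_quadratic_gc_bias_removed(self):
        bins = toy_genome_bins(seed=1)
        counts = simulate_bin_counts(diploid_truth(), bins, mean_depth=20_000,
                                     dispersion=None,
                                     gc_bias_coeffs=(0.6, -2.0), seed=1)
        gc = counts["gc"].to_numpy()
        raw_ratio = counts["count"] / counts["count"].mean()
        slope_before = np.polyfit(gc, raw_ratio, 1)[0]
        ratios = normalize_bins(counts)
        slope_after = np.polyfit(gc, ratios, 1)[0]
        assert abs(slope_before) > 0.3
        assert abs(slope_after) < 0.02

    def test_quadratic_method_also_flattens(self):
        bins = toy_genome_bins(seed=2)
        counts = simulate_bin_counts(diploid_truth(), bins, mean_depth=20_000,
                                     dispersion=None,
                                     gc_bias_coeffs=(0.6, -2.0), seed=2)
        ratios = normalize_bins(counts, method="quadratic")
        slope = np.polyfit(counts["gc"], ratios, 1)[0]
        assert abs(slope) < 0.02

    def test_gained_region_doubles_mean_ratio(self):
        truth = default_cn_truth()
        bins = toy_genome_bins(seed=3)
        counts = simulate_bin_counts(truth, bins, mean_depth=200,
                                     dispersion=50.0, seed=3)
        ratios = normalize_bins(counts)
        cn = truth.cn_at(bins)
        ratio_gain = ratios[cn == 4].mean()
        ratio_dip = ratios[cn == 2].mean()
        assert ratio_gain / ratio_dip == pytest.approx(2.0, rel=0.1)

    def test_too_few_bins_rejected(self):
        bins = toy_genome_bins(seed=0).head(50)
        bins["count"] = 10
        with pytest.raises(ValueError, match="bins"):
            normalize_bins(bins)

    def test_all_zero_counts_rejected(self):
        bins = toy_genome_bins(seed=0)
        bins["count"] = 0
        with pytest.raises(ValueError, match="zero"):
            normalize_bins(bins)


class TestSegmentation:
    def test_constant_profile_one_segment_per_chromosome(self):
        bins = toy_genome_bins(seed=0)
        ratios = np.ones(len(bins))
        segs = segment_profile(ratios, bins["chrom"].to_numpy())
        assert len(segs) == 3

    def test_single_step_localized_within_two_bins(self):
        # CN2 -> CN4 step at bin 60 of chr1, low noise
        truth = GroundTruthCN(segments=pd.DataFrame(
            [("chr1", 0, 30_000_000, 2), ("chr1", 30_000_000, 60_000_000, 4),
             ("chr2", 0, 45_000_000, 2), ("chr3", 0, 30_000_000, 2)],
            columns=["chrom", "start", "end", "cn"]))
        bins = toy_genome_bins(seed=4)
        counts = simulate_bin_counts(truth, bins, mean_depth=200,
                                     dispersion=50.0, seed=4)
        ratios = normalize_bins(counts)
        segs = segment_profile(ratios, bins["chrom"].to_numpy())
        breaks = sorted({a for a, _ in segs} | {b for _, b in segs})
        assert any(abs(b - 60) <= 2 for b in breaks)

    def test_shuffled_profile_collapses(self):
        truth = default_cn_truth()
        bins = toy_genome_bins(seed=5)
        counts = simulate_bin_counts(truth, bins, mean_depth=100,
                                     dispersion=10.0, seed=5)
        ratios = normalize_bins(counts)
        chroms = bins["chrom"].to_numpy()
        ordered = segment_profile(ratios, chroms)
        rng = np.random.default_rng(0)
        shuffled = segment_profile(ratios[rng.permutation(len(ratios))], chroms)
        assert len(shuffled) < len(ordered)
        assert len(shuffled) <= 5  # toward 1 per chromosome (3 total)

    def test_tiny_chromosome_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            segment_profile(np.array([1.0, 1.0, 1.0]),
                            np.array(["chr1", "chr1", "chr2"]))


class TestIntegerCalls:
    def test_unit_ratio_calls_diploid(self):
        cn = call_integer_cn(np.ones(10), [(0, 10)], ploidy=2)
        assert cn.tolist() == [2]

    def test_rounding_to_nearest_integer(self):
        cn = call_integer_cn(np.full(10, 2.05), [(0, 10)], ploidy=2)
        assert cn.tolist() == [4]

    def test_negative_ratios_clamped(self):
        cn = call_integer_cn(np.full(10, 0.01), [(0, 10)], ploidy=2)
        assert cn.tolist() == [0]

    def test_ploidy_grid_search_rescues_aneuploid_mean(self):
        # unbalanced genome: mean CN != ploidy biases the fixed-scale calls
        truth = GroundTruthCN(segments=pd.DataFrame(
            [("chr1", 0, 30_000_000, 2), ("chr1", 30_000_000, 60_000_000, 4),
             ("chr2", 0, 45_000_000, 2), ("chr3", 0, 30_000_000, 2)],
            columns=["chrom", "start", "end", "cn"]))
        bins = toy_genome_bins(seed=6)
        counts = simulate_bin_counts(truth, bins, mean_depth=300,
                                     dispersion=100.0, seed=6)
        fixed = call_cna_profile(counts)
        searched = call_cna_profile(counts, optimize_ploidy=True)
        tc = truth.cn_at(bins)
        assert (searched.bin_cn == tc).mean() > (fixed.bin_cn == tc).mean()

    @pytest.mark.parametrize("seed", range(5))
    def test_full_pipeline_recovers_true_copy_numbers(self, seed):
        truth = default_cn_truth()
        bins = toy_genome_bins(seed=3)
        counts = simulate_bin_counts(truth, bins, mean_depth=100,
                                     dispersion=10.0,
                                     gc_bias_coeffs=(0.6, -2.0), seed=seed)
        profile = call_cna_profile(counts)
        assert (profile.bin_cn == truth.cn_at(bins)).mean() >= 0.95


class TestCoverageQuality:
    def test_constant_counts_are_perfectly_uniform(self):
        q = profile_quality(np.full(100, 50.0))
        assert q.index_of_dispersion == 0.0
        assert q.gini == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(q.lorenz_y, q.lorenz_x)

    def test_poisson_counts_have_unit_dispersion(self, rng):
        counts = rng.poisson(80.0, 5000)
        q = profile_quality(counts)
        assert abs(q.index_of_dispersion - 1.0) < 3 * np.sqrt(2 / 4999)

    def test_point_mass_gini_closed_form(self):
        n = 50
        counts = np.zeros(n)
        counts[0] = 1000.0
        q = profile_quality(counts)
        assert q.gini == pytest.approx((n - 1) / n)

    def test_gini_invariant_under_rescaling(self, rng):
        counts = rng.poisson(10.0, 200) + 1
        assert profile_quality(counts).gini == pytest.approx(
            profile_quality(counts * 7).gini)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_lorenz_curve_properties(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 100, size=int(rng.integers(2, 200)))
        if counts.sum() == 0:
            counts[0] = 1
        q = profile_quality(counts)
        assert q.lorenz_y[0] == 0.0 and q.lorenz_y[-1] == pytest.approx(1.0)
        assert (np.diff(q.lorenz_y) >= -1e-12).all()          # monotone
        assert (np.diff(q.lorenz_y, 2) >= -1e-9).all()        # convex
        assert 0.0 <= q.gini <= 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            profile_quality([5.0])
        with pytest.raises(ValueError):
            profile_quality([0.0, 0.0])


def profile_from_cn(bins, cn_per_chrom):
    """Build a CNAProfile with prescribed per-chromosome constant CN."""
    segs, ratios = [], np.empty(len(bins))
    start = 0
    for chrom, cn in cn_per_chrom.items():
        idx = np.flatnonzero((bins["chrom"] == chrom).to_numpy())
        a, b = int(idx[0]), int(idx[-1]) + 1
        ratios[a:b] = cn / 2.0
        segs.append({"chrom": chrom, "start": int(bins["start"].iloc[a]),
                     "end": int(bins["end"].iloc[b - 1]), "start_bin": a,
                     "end_bin": b, "mean_ratio": cn / 2.0, "cn": cn})
    out = bins.copy()
    out["count"] = 1
    return CNAProfile(bins=out, ratios=ratios, segments=pd.DataFrame(segs))


class TestConcordance:
    def test_self_concordance_is_one(self):
        bins = toy_genome_bins(seed=0)
        p = profile_from_cn(bins, {"chr1": 4, "chr2": 2, "chr3": 1})
        assert profile_concordance(p, p) == pytest.approx(1.0)

    def test_reflection_around_ploidy_is_minus_one(self):
        bins = toy_genome_bins(seed=0)
        a = profile_from_cn(bins, {"chr1": 4, "chr2": 2, "chr3": 1})
        b = profile_from_cn(bins, {"chr1": 0, "chr2": 2, "chr3": 3})
        assert profile_concordance(a, b) == pytest.approx(-1.0)

    def test_mismatched_grids_rejected(self):
        a = profile_from_cn(toy_genome_bins(seed=0), {"chr1": 2, "chr2": 2,
                                                      "chr3": 4})
        b = profile_from_cn(toy_genome_bins(bin_size=250_000, seed=0),
                            {"chr1": 2, "chr2": 2, "chr3": 4})
        with pytest.raises(ValueError, match="grid"):
            profile_concordance(a, b)

    def test_single_cell_simulation_matches_its_truth(self):
        truth = default_cn_truth()
        bins = toy_genome_bins(seed=7)
        counts = simulate_bin_counts(truth, bins, mean_depth=100,
                                     dispersion=10.0, seed=7)
        called = call_cna_profile(counts)
        r = np.corrcoef(called.bin_cn, truth.cn_at(bins))[0, 1]
        assert r >= 0.95

    def test_same_truth_beats_different_truth_by_margin(self):
        truth_a = default_cn_truth()
        truth_b = GroundTruthCN(segments=pd.DataFrame(
            [("chr1", 0, 60_000_000, 2), ("chr2", 0, 20_000_000, 4),
             ("chr2", 20_000_000, 45_000_000, 2), ("chr3", 0, 30_000_000, 1)],
            columns=["chrom", "start", "end", "cn"]))
        bins = toy_genome_bins(seed=8)
        pa1 = call_cna_profile(simulate_bin_counts(truth_a, bins, 100, 10.0,
                                                   seed=81))
        pa2 = call_cna_profile(simulate_bin_counts(truth_a, bins, 100, 10.0,
                                                   seed=82))
        pb = call_cna_profile(simulate_bin_counts(truth_b, bins, 100, 10.0,
                                                  seed=83))
        r_same = profile_concordance(pa1, pa2)
        r_diff = profile_concordance(pa1, pb)
        assert r_same - r_diff > 0.2


class TestDriverAnnotation:
    @pytest.fixture()
    def profile(self):
        bins = toy_genome_bins(seed=0)
        return profile_from_cn(bins, {"chr1": 4, "chr2": 2, "chr3": 1})

    def test_gene_inside_gain_reported_gained(self, profile):
        genes = pd.DataFrame([("chr1", 1_000_000, 2_000_000, "MYC")],
                             columns=["chrom", "start", "end", "name"])
        hits = annotate_drivers(profile, genes)
        assert len(hits) == 1
        assert hits.iloc[0]["direction"] == "gained"
        assert hits.iloc[0]["cn"] == 4

    def test_gene_in_loss_reported_lost(self, profile):
        genes = pd.DataFrame([("chr3", 0, 500_000, "TP53")],
                             columns=["chrom", "start", "end", "name"])
        hits = annotate_drivers(profile, genes)
        assert hits.iloc[0]["direction"] == "lost"

    def test_neutral_only_gene_not_reported(self, profile):
        genes = pd.DataFrame([("chr2", 0, 500_000, "GAPDH")],
                             columns=["chrom", "start", "end", "name"])
        assert annotate_drivers(profile, genes).empty

    def test_boundary_spanning_gene_assigned_maximal_overlap(self):
        bins = toy_genome_bins(seed=0)
        segs = pd.DataFrame([
            {"chrom": "chr1", "start": 0, "end": 30_000_000, "start_bin": 0,
             "end_bin": 60, "mean_ratio": 1.0, "cn": 2},
            {"chrom": "chr1", "start": 30_000_000, "end": 60_000_000,
             "start_bin": 60, "end_bin": 120, "mean_ratio": 2.0, "cn": 4},
            {"chrom": "chr2", "start": 0, "end": 45_000_000, "start_bin": 120,
             "end_bin": 210, "mean_ratio": 1.0, "cn": 2},
            {"chrom": "chr3", "start": 0, "end": 30_000_000, "start_bin": 210,
             "end_bin": 270, "mean_ratio": 1.0, "cn": 2},
        ])
        bins2 = bins.copy()
        bins2["count"] = 1
        ratios = np.where(np.arange(len(bins)) < 60, 1.0, 1.0)
        profile = CNAProfile(bins=bins2, ratios=ratios, segments=segs)
        # 10 Mb in the CN-4 segment, 5 Mb in the CN-2 segment
        genes = pd.DataFrame([("chr1", 25_000_000, 40_000_000, "NOTCH1")],
                             columns=["chrom", "start", "end", "name"])
        hits = annotate_drivers(profile, genes)
        assert hits.iloc[0]["cn"] == 4
        assert bool(hits.iloc[0]["boundary_spanning"])

    def test_empty_gene_table(self, profile):
        assert annotate_drivers(profile, pd.DataFrame()).empty

    def test_malformed_intervals_rejected(self, profile):
        genes = pd.DataFrame([("chr1", 10, 5, "BAD")],
                             columns=["chrom", "start", "end", "name"])
        with pytest.raises(ValueError, match="malformed"):
            annotate_drivers(profile, genes)


class TestProfileInvariants:
    def test_segments_must_partition_bins(self):
        bins = toy_genome_bins(seed=0)
        bins["count"] = 1
        segs = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 1,
                              "start_bin": 0, "end_bin": 100,
                              "mean_ratio": 1.0, "cn": 2}])
        with pytest.raises(ValueError, match="span|partition"):
            CNAProfile(bins=bins, ratios=np.ones(len(bins)), segments=segs)

    def test_negative_cn_rejected(self):
        bins = toy_genome_bins(seed=0)
        bins["count"] = 1
        segs = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 1,
                              "start_bin": 0, "end_bin": len(bins),
                              "mean_ratio": 1.0, "cn": -1}])
        with pytest.raises(ValueError, match=">= 0"):
            CNAProfile(bins=bins, ratios=np.ones(len(bins)), segments=segs)


class TestIO:
    def test_bins_tsv_roundtrip(self, tmp_path):
        truth = default_cn_truth()
        bins = toy_genome_bins(seed=9)
        counts = simulate_bin_counts(truth, bins, mean_depth=50, seed=9)
        path = tmp_path / "bins.tsv"
        counts.to_csv(path, sep="\t", index=False)
        back = read_bins_tsv(path)
        pd.testing.assert_frame_equal(back, counts)

    def test_headerless_bed_and_profile_output(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t100\t200\tMYC\nchr2\t5\t50\tTP53\n")
        genes = read_bed(bed)
        assert list(genes["name"]) == ["MYC", "TP53"]

        truth = default_cn_truth()
        bins = toy_genome_bins(seed=10)
        counts = simulate_bin_counts(truth, bins, mean_depth=100, seed=10)
        profile = call_cna_profile(counts)
        out = tmp_path / "profile.tsv"
        write_profile_tsv(profile, out)
        written = pd.read_csv(out, sep="\t")
        assert {"chrom", "start", "end", "ratio", "cn"}.issubset(written.columns)
        assert out.with_suffix(".segments.json").exists()
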