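"""Coverage, deamination, edit-distance, identity and PMD computations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paleometa import authmetrics as am
from paleometa import simdata as sd
from conftest import make_alignment


class TestCoverage:
    def test_stacked_reads_depth_and_breadth(self):
        # 4 reads of length L on a 4L genome: depth 1X however they land
        alns = [make_alignment(0, "A" * 50) for _ in range(4)]
        assert am.compute_depth(alns, 200) == 1.0
        assert am.compute_breadth(alns, 200) == 0.25

    def test_tiling_reads_full_breadth(self):
        alns = [make_alignment(s, "A" * 50) for s in (0, 50, 100, 150)]
        assert am.compute_depth(alns, 200) == 1.0
        assert am.compute_breadth(alns, 200) == 1.0

    def test_depth_counts_overlap(self):
        alns = [make_alignment(0, "A" * 50), make_alignment(0, "A" * 50)]
        assert am.compute_depth(alns, 50) == 2.0

    def test_single_read_breadth(self):
        assert am.compute_breadth([make_alignment(10, "A" * 10)], 100) == 0.10

    def test_no_reads(self):
        assert am.compute_depth([], 100) == 0.0
        assert am.compute_breadth([], 100) == 0.0

    def test_evenness_full_tiling(self):
        alns = [make_alignment(s, "A" * 50) for s in range(0, 1000, 50)]
        prof = am.compute_evenness_profile(alns, 1000, n_bins=100)
        assert (prof.bin_breadth == 1.0).all()

    def test_evenness_stacked_localized(self):
        alns = [make_alignment(100, "A" * 50) for _ in range(4)]
        prof = am.compute_evenness_profile(alns, 1000, n_bins=100)
        covered_bins = np.flatnonzero(prof.bin_breadth)
        assert covered_bins.tolist() == list(range(10, 15))
        assert prof.breadth == 0.05

    def test_evenness_no_reads(self):
        prof = am.compute_evenness_profile([], 500, n_bins=100)
        assert (prof.bin_breadth == 0.0).all()

    def test_reference_shorter_than_bins_rejected(self):
        with pytest.raises(ValueError, match="n_bins"):
            am.compute_evenness_profile([], 50, n_bins=100)

    @settings(deadline=None)
    @given(st.integers(0, 40), st.integers(0, 2**31 - 1), st.integers(1, 7))
    def test_breadth_equals_weighted_mean_of_bins(self, n_reads, seed, nb_seed):
        # conservation: genome-wide breadth is the bin-size-weighted mean of
        # the local per-bin breadths, whatever the remainder bin does
        rng = np.random.default_rng(seed)
        ref_len = int(rng.integers(100, 2000))
        n_bins = min(int(rng.integers(2, 150)), ref_len)
        alns = []
        for _ in range(n_reads):
            L = int(rng.integers(1, 80))
            pos = int(rng.integers(0, max(ref_len - L, 1)))
            alns.append(make_alignment(pos, "A" * L))
        prof = am.compute_evenness_profile(alns, ref_len, n_bins)
        weighted = np.average(prof.bin_breadth, weights=prof.bin_sizes)
        assert prof.breadth == pytest.approx(weighted, abs=1e-12)

    def test_nonoverlapping_breadth_equals_depth_bound(self):
        alns = [make_alignment(s, "A" * 20) for s in range(0, 400, 40)]
        ref_len = 400
        assert am.compute_breadth(alns, ref_len) == pytest.approx(
            am.compute_depth(alns, ref_len))


class TestDeamination:
    def test_single_terminal_ct(self):
        aln = make_alignment(0, "TAAA", ref_seq="CAAA")
        prof = am.compute_deamination_profile([aln])
        assert prof.p5_ct[0] == 1.0
        assert prof.n5_informative[0] == 1

    def test_clean_reads_zero_profile(self):
        alns = [make_alignment(0, "CCGGAATT")]
        prof = am.compute_deamination_profile(alns)
        finite = np.isfinite(prof.p5_ct)
        assert (prof.p5_ct[finite] == 0).all()

    def test_strand_symmetry(self):
        # reverse-complementing the record and flipping the strand flag must
        # leave molecule-orientation tallies unchanged
        ref = "CATTGCAGTCGGATCGATCG"
        read = "TATTGCAGTCGGATCGATCG"  # C>T at molecule 5' position 1
        fwd = make_alignment(0, read, ref_seq=ref, strand="+")
        rev = make_alignment(0, sd.revcomp(read), ref_seq=sd.revcomp(ref),
                             strand="-")
        p1 = am.compute_deamination_profile([fwd])
        p2 = am.compute_deamination_profile([rev])
        np.testing.assert_array_equal(p1.n5_informative, p2.n5_informative)
        finite = np.isfinite(p1.p5_ct)
        np.testing.assert_array_equal(p1.p5_ct[finite], p2.p5_ct[finite])

    def test_simulated_ancient_profile_matches_damage_oracle(self, small_sample):
        *_, result = small_sample
        recs = [r for r in am.read_sam(result.truth_sam)
                if r.read_id.split("|")[2].startswith("a")]
        prof = am.compute_deamination_profile(recs)
        expected = sd.terminal_ct_rate(sd.DamageParams(), 0)
        n = prof.n5_informative[0]
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(prof.p5_ct[0] - expected) < 3 * se
        # monotone non-increasing over the first positions up to noise
        assert prof.p5_ct[0] > prof.p5_ct[2] > prof.p5_ct[6]


class TestDamagedReads:
    def test_terminal_ct_flags_damaged(self):
        aln = make_alignment(0, "ATAAAAAA", ref_seq="ACAAAAAA")  # C>T at pos 2
        assert am.is_damaged(aln)

    def test_interior_mismatch_not_damaged(self):
        ref = "A" * 9 + "ACCG" + "A" * 9  # A>G mismatch at interior position
        read = "A" * 9 + "GCCG" + "A" * 9
        assert not am.is_damaged(make_alignment(0, read, ref_seq=ref))

    def test_damaged_fraction_matches_simulator(self, small_sample):
        *_, result = small_sample
        recs = [r for r in am.read_sam(result.truth_sam)
                if r.read_id.split("|")[2].startswith("a")]
        frac = np.mean([am.is_damaged(r) for r in recs])
        # analytic probability that >= 1 terminal deamination event falls in
        # the 5-bp windows, marginalized over the geometric overhang length
        # (per-position events are correlated through the shared overhang).
        # 5' C sites: ss inside the overhang, ds+nick interior; 3' G sites:
        # ss inside the overhang only. Base composition: 1/4 C resp. G.
        params = sd.DamageParams()
        w = 5
        p = params.overhang_param
        interior = params.ds_deam + (1 - params.ds_deam) * \
            params.nick_rate * params.ss_deam
        q_in = 1 - 0.25 * interior
        q_ss = 1 - 0.25 * params.ss_deam
        no5 = sum(p * (1 - p) ** j * q_ss ** j * q_in ** (w - j)
                  for j in range(w)) + (1 - p) ** w * q_ss ** w
        no3 = sum(p * (1 - p) ** j * q_ss ** j
                  for j in range(w)) + (1 - p) ** w * q_ss ** w
        expected = 1 - no5 * no3
        se = math.sqrt(expected * (1 - expected) / len(recs))
        assert abs(frac - expected) < 3 * se


class TestEditAndIdentity:
    def test_edit_histogram_counts(self):
        alns = [make_alignment(0, "AAAA"), make_alignment(0, "AAAA"),
                make_alignment(0, "AAAT", ref_seq="AAAA")]
        edit_all, _ = am.edit_distance_histograms(alns)
        assert edit_all[0] == 2 and edit_all[1] == 1

    def test_overflow_pooled_in_last_bin(self):
        aln = make_alignment(0, "T" * 20, ref_seq="A" * 20)
        edit_all, _ = am.edit_distance_histograms([aln])
        assert edit_all[10] == 1

    def test_no_damaged_reads_zero_histogram(self):
        alns = [make_alignment(0, "AAAA")]
        _, edit_damaged = am.edit_distance_histograms(alns)
        assert edit_damaged.sum() == 0

    def test_single_mismatch_reads_all_in_bin_one(self):
        ref = sd.generate_reference(50, 0.5, seed=1)
        read = ref[:25] + ("A" if ref[25] != "A" else "C") + ref[26:]
        alns = [make_alignment(0, read, ref_seq=ref) for _ in range(1000)]
        edit_all, _ = am.edit_distance_histograms(alns)
        assert edit_all[1] == 1000 and edit_all.sum() == 1000

    @pytest.mark.parametrize("nm,expected", [(1, 98.0), (0, 100.0)])
    def test_percent_identity(self, nm, expected):
        aln = make_alignment(0, "A" * 50, nm=nm)
        assert am.percent_identity(aln) == expected

    def test_identity_histogram_binning(self):
        # NM 0,1,2,5,10 at length 50 -> identities 100,98,96,90,80
        # direct binning: 80 -> [80,85); 90 -> [90,95); 96,98,100 -> [95,100]
        alns = [make_alignment(0, "A" * 50, nm=n) for n in (0, 1, 2, 5, 10)]
        np.testing.assert_array_equal(am.identity_histogram(alns), [1, 0, 1, 3])


class TestPmd:
    def test_no_cg_sites_zero(self):
        aln = make_alignment(0, "ATATAT", ref_seq="ATATAT")
        assert am.pmd_score(aln) == 0.0

    def test_terminal_ct_positive(self):
        aln = make_alignment(0, "TAAAAA", ref_seq="CAAAAA")
        assert am.pmd_score(aln) > 0

    def test_three_site_toy_value(self):
        # ref CAG / read TAG: 5' C>T at z=0, 3' G match at z=0; middle A: 0
        params = am.PmdParams(decay_rate=0.5, p_max=0.3, p_base=0.01, err=0.001)
        aln = make_alignment(0, "TAG", ref_seq="CAG")
        d0 = 0.01 + 0.29 * math.exp(0.0)
        expected = math.log(d0 / 0.001) + math.log((1 - d0) / (1 - 0.001))
        assert am.pmd_score(aln, params) == pytest.approx(expected)

    def test_ancient_scores_dominate_modern(self, small_sample):
        from scipy.stats import mannwhitneyu
        *_, result = small_sample
        recs = am.read_sam(result.truth_sam)
        anc = [am.pmd_score(r) for r in recs
               if r.read_id.split("|")[2].startswith("a")]
        mod = [am.pmd_score(r) for r in recs
               if r.read_id.split("|")[2].startswith("m")]
        stat = mannwhitneyu(anc, mod, alternative="greater")
        assert stat.pvalue < 0.01


class TestCountAssigned:
    def test_strict_mapq_filter(self):
        alns = [make_alignment(0, "AAAA", mapq=30, ref_id="refA"),
                make_alignment(0, "AAAA", mapq=0, ref_id="refA"),
                make_alignment(0, "AAAA", mapq=12, ref_id="refA")]
        assert am.count_assigned(alns, min_mapq=0) == {"refA": 2}

    def test_empty(self):
        assert am.count_assigned([]) == {}

    def test_simulated_counts_match_truth(self, small_sample):
        *_, result = small_sample
        recs = am.read_sam(result.truth_sam)
        counts = am.count_assigned(recs, min_mapq=0)
        truth = result.truth.table
        per_taxid = truth.groupby("taxid")["n_fragments"].sum()
        for taxid, n in per_taxid.items():
            assert counts.get(f"taxid|{taxid}", 0) == n


class TestSerialization:
    def test_metrics_json_round_trip(self, tmp_path, small_sample):
        _, species, genomes, result = small_sample
        recs = am.read_sam(result.truth_sam)
        ref_lengths = {f"taxid|{t}": len(g) for t, g in genomes.items()}
        metrics = am.metrics_by_reference(recs, ref_lengths)
        path = tmp_path / "m.json"
        am.save_metrics(metrics, path)
        loaded = am.load_metrics(path)
        assert set(loaded) == set(metrics)
        for k in metrics:
            np.testing.assert_array_equal(loaded[k].edit_all, metrics[k].edit_all)
            assert loaded[k].ani_mean == pytest.approx(metrics[k].ani_mean)
            np.testing.assert_allclose(loaded[k].deamination.p5_ct,
                                       metrics[k].deamination.p5_ct)
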