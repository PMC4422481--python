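"""Variant classification and the staged filter cascade."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from perimeso import synth, variants
from perimeso.variants import VariantCall, VariantConfig

from _oracles import fisher_greater_oracle
from conftest import make_site

CFG = VariantConfig()


class TestBasicFilter:
    def test_low_tumor_coverage_fails(self):
        ok, label = variants.basic_filter(make_site(t_ref=6, t_alt=3))
        assert not ok and label == "min_coverage_tumor"

    def test_vaf_threshold_is_a_minimum(self):
        ok, _ = variants.basic_filter(make_site(t_ref=90, t_alt=10))
        assert ok  # exactly 0.10 passes

    def test_low_quality_fails(self):
        ok, label = variants.basic_filter(make_site(avg_qual=16.9))
        assert not ok and label == "min_avg_qual"

    def test_low_normal_coverage_fails(self):
        ok, label = variants.basic_filter(make_site(n_ref=5, n_alt=0))
        assert not ok and label == "min_coverage_normal"


class TestClassifySite:
    def test_clean_somatic(self):
        call = variants.classify_site(make_site(n_ref=30, n_alt=0,
                                                t_ref=20, t_alt=10))
        assert call.category == "somatic"
        oracle = fisher_greater_oracle(30, 0, 20, 10)
        assert call.somatic_p == pytest.approx(oracle, abs=1e-9)
        assert call.somatic_p == pytest.approx(3.985e-4, abs=1e-6)

    def test_matched_heterozygote_is_germline(self):
        call = variants.classify_site(make_site(n_ref=15, n_alt=15,
                                                t_ref=14, t_alt=16))
        assert call.category == "germline"

    def test_het_normal_extreme_tumor_is_loh(self):
        call = variants.classify_site(make_site(n_ref=15, n_alt=15,
                                                t_ref=1, t_alt=29))
        assert call.category == "loh"

    def test_het_normal_without_significance_is_unknown(self):
        # two-sided p for [[6,5],[9,1]] is 0.149: shifted but not significant
        call = variants.classify_site(make_site(n_ref=6, n_alt=5,
                                                t_ref=9, t_alt=1))
        assert call.category == "unknown"

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            variants.classify_site(make_site(t_ref=0, t_alt=0))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30), st.integers(0, 30))
    def test_somatic_p_matches_enumeration(self, n_ref, n_alt, t_ref, t_alt):
        if n_ref + n_alt == 0 or t_ref + t_alt == 0:
            return
        site = make_site(n_ref=n_ref, n_alt=n_alt, t_ref=t_ref, t_alt=t_alt)
        assert variants.somatic_fisher_p(site) == pytest.approx(
            fisher_greater_oracle(n_ref, n_alt, t_ref, t_alt), abs=1e-9)


class TestIndelFilter:
    def _call(self, **kw):
        kw.setdefault("is_indel", True)
        kw.setdefault("indel_len", -3)
        site = make_site(**kw)
        return VariantCall(site=site, category="somatic",
                           t_vaf=site.t_vaf, n_vaf=site.n_vaf)

    def test_two_supporting_reads_fail(self):
        ok, label = variants.filter_indel(self._call(t_ref=48, t_alt=2))
        assert not ok and label == "indel_support"

    def test_germline_frequency_boundary_is_strict(self):
        ok, _ = variants.filter_indel(self._call(n_ref=95, n_alt=5))
        assert ok  # exactly 5% passes ("more than 5%" removes)
        ok, label = variants.filter_indel(self._call(n_ref=93, n_alt=7))
        assert not ok and label == "indel_germline_freq"

    def test_all_boundary_pass(self):
        ok, _ = variants.filter_indel(self._call(t_ref=7, t_alt=3, n_ref=50,
                                                 n_alt=0))
        assert ok

    def test_requires_indel(self):
        with pytest.raises(ValueError):
            variants.filter_indel(VariantCall(site=make_site()))


class TestProximityAndClusters:
    def _snv(self, pos):
        return VariantCall(site=make_site(pos=pos), category="somatic")

    def _indel(self, pos):
        return VariantCall(site=make_site(pos=pos, is_indel=True,
                                          indel_len=2), category="somatic")

    def test_three_snvs_within_ten_bp_all_flagged(self):
        calls = [self._snv(p) for p in (100, 105, 109)]
        flags = variants.filter_proximity_and_clusters(calls)
        assert all("snv_cluster" in flags.get(i, []) for i in range(3))

    def test_spread_snvs_unflagged(self):
        calls = [self._snv(p) for p in (100, 111, 122)]
        assert variants.filter_proximity_and_clusters(calls) == {}

    def test_snv_near_indel_flagged(self):
        calls = [self._snv(200), self._indel(203)]
        flags = variants.filter_proximity_and_clusters(calls)
        assert flags.get(0) == ["near_indel"] and 1 not in flags

    def test_other_chromosome_indel_ignored(self):
        calls = [self._snv(200),
                 VariantCall(site=make_site(pos=203, chrom="2",
                                            is_indel=True, indel_len=1))]
        assert variants.filter_proximity_and_clusters(calls) == {}


class TestSomaticQuality:
    def _somatic(self, **kw):
        site = make_site(**kw)
        call = variants.classify_site(site)
        call.category = "somatic"
        return call

    def test_normal_contamination_removed(self):
        call = self._somatic(n_ref=94, n_alt=6, t_ref=60, t_alt=40)
        ok, label = variants.filter_somatic_quality(call)
        assert not ok and label == "somatic_normal_alt"

    def test_indel_any_normal_alt_removed(self):
        call = self._somatic(n_ref=99, n_alt=1, t_ref=60, t_alt=40,
                             is_indel=True, indel_len=-2)
        ok, label = variants.filter_somatic_quality(call)
        assert not ok and label == "somatic_normal_alt_indel"

    def test_insignificant_fisher_removed(self):
        call = self._somatic(n_ref=10, n_alt=0, t_ref=9, t_alt=2)
        call.somatic_p = 0.5
        ok, label = variants.filter_somatic_quality(call)
        assert not ok and label == "somatic_fisher"

    def test_clean_somatic_retained(self):
        call = self._somatic(n_ref=100, n_alt=0, t_ref=60, t_alt=40)
        assert variants.filter_somatic_quality(call) == (True, None)


class TestFpFilter:
    def _call(self, **kw):
        site = make_site(**kw)
        return VariantCall(site=site, category="somatic",
                           t_vaf=site.t_vaf, n_vaf=site.n_vaf)

    def test_ideal_site_passes(self):
        assert variants.fp_filter(self._call()) == (True, None)

    def test_total_strand_bias_fails(self):
        call = self._call(t_ref=0, t_alt=40, fwd_alt=40, rev_alt=0)
        ok, label = variants.fp_filter(call)
        assert not ok and label == "fp_strand_bias"
        # oracle: two-sided exact binomial p for 40/40 heads is 2 * 0.5^40
        assert 2 * 0.5 ** 40 < CFG.fp_strand_alpha

    def test_balanced_strands_pass(self):
        assert variants.fp_filter(self._call(fwd_alt=18, rev_alt=22))[0]

    def test_long_homopolymer_fails(self):
        ok, label = variants.fp_filter(self._call(homopolymer_len=8,
                                                  is_indel=True, indel_len=1))
        assert not ok and label == "fp_homopolymer"

    def test_few_variant_reads_fail(self):
        ok, label = variants.fp_filter(self._call(t_ref=97, t_alt=3,
                                                  n_ref=100, n_alt=0))
        assert not ok and label == "fp_var_reads"

    def test_read_position_tail_fails(self):
        ok, label = variants.fp_filter(self._call(read_pos=0.95))
        assert not ok and label == "fp_read_pos"

    def test_missing_fields_unscorable(self):
        ok, label = variants.fp_filter(self._call(read_pos=float("nan")))
        assert not ok and label == "fp_unscorable"


class TestConsequence:
    def test_stop_gain_is_nonsense(self, toy_genome):
        gene = toy_genome.gene("TG")
        pos, ref, alt = synth.stop_gain_substitution(gene, k=0)
        cons = variants.annotate_consequence(
            make_site(pos=pos, ref=ref, alt=alt), toy_genome)
        assert cons.gene == "TG" and cons.effect == "nonsense"
        assert cons.non_silent

    def test_silent_substitution(self, toy_genome):
        gene = toy_genome.gene("TG")
        pos, ref, alt = synth.silent_substitution(gene, k=0)
        cons = variants.annotate_consequence(
            make_site(pos=pos, ref=ref, alt=alt), toy_genome)
        assert cons.effect == "silent" and not cons.non_silent

    def test_codon_multiple_deletion_is_inframe(self, toy_genome):
        gene = toy_genome.gene("TG")
        pos, ref, alt, ilen = synth.coding_deletion(gene, 42)
        cons = variants.annotate_consequence(
            make_site(pos=pos, ref=ref, alt=alt, is_indel=True,
                      indel_len=ilen), toy_genome)
        assert cons.effect == "inframe_indel"  # 42 % 3 == 0

    def test_single_base_insertion_is_frameshift(self, toy_genome):
        gene = toy_genome.gene("TG")
        pos = gene.coding[0][0] + 5  # inside first exon (1-based ok)
        cons = variants.annotate_consequence(
            make_site(pos=pos + 1, ref="A", alt="AT", is_indel=True,
                      indel_len=1), toy_genome)
        assert cons.effect == "frameshift" and cons.non_silent

    def test_intergenic_variant_has_no_effect(self, toy_genome):
        cons = variants.annotate_consequence(make_site(pos=4_999_999),
                                             toy_genome)
        assert cons.gene is None and not cons.non_silent


class TestCascade:
    def _counts(self, truth, genome, seed=0, **kw):
        return synth.simulate_counts(genome, truth, seed=seed, **kw)

    def test_conservation_per_stage(self, toy_genome):
        truth = synth.TruthSet(purity=0.7, variants=tuple(
            synth.VariantTruth("S1", "1", 1000 * (i + 1), "A", "T",
                               "somatic" if i % 2 else "germline_het")
            for i in range(40)))
        res = variants.run_cascade(self._counts(truth, toy_genome,
                                                n_background_sites=200))
        for st_ in res.accounting:
            assert st_.n_in == st_.n_retained + st_.n_removed
        assert len(res.retained) + len(res.removed) == len(res.calls)
        assert res.accounting[0].n_in == len(res.calls)
        names = [s.stage for s in res.accounting]
        assert names == ["basic", "indel_quality", "proximity_cluster",
                         "somatic_quality", "fp_filter"]

    def test_sensitivity_and_vaf_unbiased(self, toy_genome):
        # clonal somatic variants at AF 0.3, depth 50: >= 95% recovered
        recovered = total = 0
        vafs = []
        for seed in range(20):
            truth = synth.TruthSet(purity=1.0, variants=tuple(
                synth.VariantTruth("S1", "1", 5_000 + 400 * i, "A", "T",
                                   "somatic", target_af=0.3)
                for i in range(50)))
            res = variants.run_cascade(
                self._counts(truth, toy_genome, seed=seed, mean_depth=50))
            total += 50
            for c in res.retained:
                if c.category == "somatic":
                    recovered += 1
                    vafs.append(c.t_vaf)
        assert recovered / total >= 0.95
        se = np.sqrt(0.3 * 0.7 / (50 * len(vafs)))
        assert abs(np.mean(vafs) - 0.3) < 4 * se

    def test_germline_never_called_somatic(self, toy_genome):
        truth = synth.TruthSet(purity=0.7, variants=tuple(
            synth.VariantTruth("S1", "1", 2_000 + 500 * i, "A", "T",
                               "germline_het")
            for i in range(500)))
        res = variants.run_cascade(self._counts(truth, toy_genome, seed=3,
                                                mean_depth=100))
        somatic = [c for c in res.calls
                   if c.category == "somatic" and c.site.n_depth >= 30]
        assert somatic == []


class TestCohortSummaries:
    def test_mutation_rate_direct_division(self):
        assert variants.mutation_rate(66, 51e6) == pytest.approx(1.294e-6,
                                                                 rel=1e-3)
        assert variants.mutation_rate(0, 51e6) == 0.0
        with pytest.raises(ValueError):
            variants.mutation_rate(1, 0)

    def test_median_rate_lower_median(self):
        assert variants.median_rate([1e-6, 2e-6, 3e-6]) == 2e-6
        assert variants.median_rate([1e-6, 2e-6, 3e-6, 4e-6]) == 2e-6

    def _passed_somatic(self, sample, gene, pos=100):
        call = VariantCall(site=make_site(sample=sample, pos=pos),
                           category="somatic")
        call.gene, call.effect, call.non_silent = gene, "nonsense", True
        return call

    def test_recurrent_genes_counted_per_sample(self):
        calls = [self._passed_somatic(f"S{i}", "BAP1") for i in range(3)]
        calls += [self._passed_somatic("S9", "OTHER", pos=10),
                  self._passed_somatic("S9", "OTHER", pos=20)]
        rec = variants.recurrent_genes(calls, min_samples=2)
        assert [(r.gene, r.n_samples) for r in rec] == [("BAP1", 3)]

    def test_empty_calls_empty_report(self):
        assert variants.recurrent_genes([], min_samples=2) == []


class TestVcf:
    def test_written_vcf_is_readable_and_carries_info(self, toy_genome,
                                                      tmp_path):
        import pysam
        site = make_site(n_ref=30, n_alt=0, t_ref=20, t_alt=10)
        call = variants.classify_site(site)
        failed = VariantCall(site=make_site(pos=2000, avg_qual=10.0),
                             filters=["min_avg_qual"])
        path = tmp_path / "calls.vcf"
        variants.write_vcf([call, failed], toy_genome, path)
        recs = list(pysam.VariantFile(str(path)))
        assert len(recs) == 2
        by_pos = {r.pos: r for r in recs}
        assert by_pos[1000].info["CATEGORY"] == "somatic"
        assert by_pos[1000].info["SOMATIC_P"] == pytest.approx(
            call.somatic_p, rel=1e-4)
        assert list(by_pos[2000].filter) == ["min_avg_qual"]
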