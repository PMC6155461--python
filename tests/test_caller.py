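import numpy as np
import pytest

from mhcamplicon import caller, demux, simulate
from mhcamplicon.caller import (
    CallerConfig,
    PhaseAmbiguousError,
    VariantCall,
    align_reads,
    call_likelihood,
    call_ratio,
    call_sample,
    detect_chimeric_haplotypes,
    phase_haplotypes,
    reconcile_calls,
)
from mhcamplicon.io import SeqRead
from mhcamplicon.simulate import SimConfig

CFG = CallerConfig()


def counts_at(L, ref_base_counts, overrides=None):
    """(L, 4) pileup with ``ref_base_counts`` everywhere, plus per-position
    {pos: {base: count}} overrides replacing that column."""
    counts = np.zeros((L, 4), dtype=np.int64)
    counts[:, caller._BASES.index("A")] = ref_base_counts
    for pos, base_counts in (overrides or {}).items():
        counts[pos] = 0
        for base, n in base_counts.items():
            counts[pos, caller._BASES.index(base)] = n
    return counts


class TestAlignReads:
    REF = "ACGT" * 25  # 100 bp

    def test_identical_read_gives_clean_pileup(self):
        aligned = align_reads([SeqRead("r", self.REF)], self.REF)
        counts, dels = aligned.pileup_arrays()
        ref_codes = caller.encode(self.REF)
        totals = counts.sum(axis=0)
        assert all(totals[i, ref_codes[i]] == 1 for i in range(100))
        assert dels.sum() == 0

    def test_single_substitution_single_nonref_column(self):
        read = self.REF[:50] + "A" + self.REF[51:]  # G -> A
        aligned = align_reads([SeqRead("r", read)], self.REF)
        mismatches = (aligned.base_matrix[0] != caller.encode(self.REF)).sum()
        assert mismatches == 1

    def test_deletion_in_homopolymer_run_flagged(self):
        ref = "ACGTACGTAC" + "TTTTTT" + "GACGTACGTA" * 3
        read = ref[:12] + ref[13:]  # drop one T from the run
        aligned = align_reads([SeqRead("r", read)], ref)
        _, dels = aligned.pileup_arrays()
        del_cols = np.nonzero(dels.sum(axis=0))[0]
        assert len(del_cols) == 1
        assert aligned.homopolymer[del_cols[0]]
        # deletions are left-aligned to the start of the run
        assert del_cols[0] == 10

    def test_low_identity_read_discarded_and_counted(self):
        junk = "T" * 100
        aligned = align_reads([SeqRead("r", junk)], self.REF)
        assert aligned.n_discarded == 1
        assert aligned.base_matrix.shape[0] == 0


class TestCallRatio:
    REF = "A" * 10

    def test_balanced_site_called_heterozygous(self):
        counts = counts_at(10, 100, {5: {"A": 52, "G": 48}})
        calls = call_ratio(counts, self.REF, CFG)
        assert [(c.pos, c.genotype) for c in calls] == [(5, ("A", "G"))]

    def test_one_percent_minor_called_homozygous(self):
        ref = "C" + "A" * 9
        counts = counts_at(10, 100, {0: {"A": 99, "G": 1}})
        calls = call_ratio(counts, ref, CFG)
        assert calls[0].genotype == ("A", "A")

    def test_chimera_distorted_ratio_no_call_flagged(self):
        counts = counts_at(10, 100, {5: {"A": 67, "G": 33}})
        calls = call_ratio(counts, self.REF, CFG)
        assert calls[0].genotype is None
        assert "ratio_distortion" in calls[0].flags

    def test_zero_depth_no_call(self):
        counts = counts_at(10, 100, {5: {}})
        assert call_ratio(counts, self.REF, CFG) == []


class TestCallLikelihood:
    def test_both_nonreference_genotype_supported(self):
        ref = "G" * 10
        counts = counts_at(10, 0, {i: {"G": 100} for i in range(10)})
        counts[4] = 0
        counts[4, caller._BASES.index("C")] = 50
        counts[4, caller._BASES.index("T")] = 50
        calls = call_likelihood(counts, ref, CFG)
        assert [(c.pos, c.genotype) for c in calls] == [(4, ("C", "T"))]

    def test_all_reference_silent(self):
        counts = counts_at(10, 100)
        assert call_likelihood(counts, "A" * 10, CFG) == []

    def test_two_discordant_reads_of_1000_fail_lod(self):
        """At Q30 the het likelihood loses by far more than 40 LOD."""
        counts = counts_at(10, 1000, {3: {"A": 998, "G": 2}})
        calls = call_likelihood(counts, "A" * 10, CFG)
        assert calls == []


class TestChimeraDetection:
    def test_recombinant_third_cluster_flagged(self):
        a, b = "CCAAA", "AAACC"
        c = "CCACC"  # A before crossover 3, B after
        verdicts = detect_chimeric_haplotypes([a, b, c], [50, 40, 10])
        assert verdicts[c] == "chimeric"
        assert verdicts[a] == verdicts[b] == "parental"

    def test_two_clusters_no_chimera(self):
        verdicts = detect_chimeric_haplotypes(["CC", "AA"], [60, 40])
        assert "chimeric" not in verdicts.values()

    def test_non_recombinant_third_cluster_negative(self):
        """Exhaustive crossover scan fails at every k for pattern 101."""
        a, b, c = "CCA", "ACC", "CAC"
        verdicts = detect_chimeric_haplotypes([a, b, c], [45, 40, 15])
        assert verdicts[c] == "negative"

    def test_single_variant_site_indeterminate(self):
        verdicts = detect_chimeric_haplotypes(["C", "A", "G"], [50, 40, 10])
        assert verdicts["G"] == "indeterminate"


class TestReconcile:
    REF = "A" * 20

    def _recon(self, ratio, lik, counts2, dels=None, patterns=(), sites=()):
        counts = np.zeros((2, 20, 4), dtype=np.int64)
        counts[0] = counts2 // 2
        counts[1] = counts2 - counts2 // 2
        if dels is None:
            dels = np.zeros((2, 20), dtype=np.int64)
        hp = np.zeros(20, dtype=bool)
        return reconcile_calls(ratio, lik, counts, dels, self.REF, hp,
                               list(patterns), list(sites), CFG)

    def test_concordant_calls_pass_through(self):
        counts = counts_at(20, 100, {5: {"A": 50, "G": 50}})
        call = VariantCall(5, "A", ("A", "G"), "x", qual=100.0)
        final, _ = self._recon([call], [VariantCall(5, "A", ("A", "G"), "y", qual=100.0)],
                               counts)
        assert final[0].status == "concordant"
        assert final[0].genotype == ("A", "G")

    def test_likelihood_only_low_fraction_rejected_as_sequencing_error(self):
        counts = counts_at(20, 100, {7: {"A": 98, "G": 2}})
        lik = [VariantCall(7, "A", ("A", "G"), "likelihood", qual=50.0)]
        final, notes = self._recon([], lik, counts)
        assert final[0].status == "rejected:sequencing_error"
        assert final[0].genotype is None

    def test_strand_biased_deletion_resolved_on_clean_strand(self):
        counts2 = counts_at(20, 100)
        dels = np.zeros((2, 20), dtype=np.int64)
        dels[0, 9] = 30  # forward-only deletions
        ratio = [VariantCall(9, "A", None, "ratio", status="no_call",
                             flags={"ratio_distortion"})]
        final, notes = self._recon(ratio, [], counts_at(20, 100), dels)
        assert any("strand_bias" in c.status for c in final)
        assert all(c.genotype in (None, ("A", "A")) for c in final)

    def test_tri_allelic_accepted_from_likelihood_caller(self):
        counts = counts_at(20, 100, {3: {"C": 50, "T": 50}})
        lik = [VariantCall(3, "A", ("C", "T"), "likelihood", qual=99.0)]
        ratio = [VariantCall(3, "A", ("C", "T"), "ratio", qual=99.0)]
        # disagreement variant: ratio no-call at the site
        final, _ = self._recon(
            [VariantCall(3, "A", None, "ratio", status="no_call")], lik, counts)
        assert final[0].status == "reconciled:tri_allelic"
        assert final[0].genotype == ("C", "T")

    def test_homopolymer_variant_kept_from_ratio_caller(self):
        counts = np.zeros((2, 20, 4), dtype=np.int64)
        for s in (0, 1):
            counts[s, :, 0] = 50
            counts[s, 11, 0] = 25
            counts[s, 11, 3] = 25  # A/T balanced on both strands
        hp = np.zeros(20, dtype=bool)
        hp[11] = True
        dels = np.zeros((2, 20), dtype=np.int64)
        ratio = [VariantCall(11, "A", ("A", "T"), "ratio", qual=90.0)]
        final, _ = reconcile_calls(ratio, [], counts, dels, self.REF, hp,
                                   [], [], CFG)
        assert final[0].status == "reconciled:homopolymer"

    def test_unresolved_disagreement_flagged_for_manual_review(self):
        counts = counts_at(20, 100, {2: {"A": 88, "G": 12}})
        ratio = [VariantCall(2, "A", None, "ratio", status="no_call",
                             flags={"ratio_distortion"})]
        lik = [VariantCall(2, "A", ("A", "G"), "likelihood", qual=60.0)]
        final, _ = self._recon(ratio, lik, counts)
        assert final[0].status in ("manual_review", "rejected:sequencing_error")
        assert final[0].genotype is None


class TestPhasing:
    REF = "A" * 30

    def _aligned(self, reads):
        return align_reads([SeqRead(f"r{i}", s) for i, s in enumerate(reads)],
                           self.REF)

    def test_perfect_linkage_two_sites(self):
        h1 = "C" + "A" * 19 + "A" + "A" * 9
        h1 = list(self.REF)
        h2 = list(self.REF)
        h1[3], h1[20] = "C", "A"
        h2[3], h2[20] = "T", "G"
        reads = ["".join(h1)] * 12 + ["".join(h2)] * 10
        calls = [VariantCall(3, "A", ("C", "T"), "both", status="concordant"),
                 VariantCall(20, "A", ("A", "G"), "both", status="concordant")]
        pair = phase_haplotypes(self._aligned(reads), calls)
        assert sorted(pair.haplotypes) == sorted(["".join(h1), "".join(h2)])
        assert sorted(pair.support, reverse=True) == [12, 10]

    def test_homozygous_sample_duplicates_consensus(self):
        calls = [VariantCall(6, "A", ("G", "G"), "both", status="concordant")]
        hap = self.REF[:6] + "G" + self.REF[7:]
        pair = phase_haplotypes(self._aligned([hap] * 8), calls)
        assert pair.haplotypes == (hap, hap)

    def test_triallelic_column_phased_by_cooccurrence(self):
        h1, h2 = list(self.REF), list(self.REF)
        h1[2], h1[10], h1[25] = "C", "C", "G"
        h2[2], h2[10], h2[25] = "T", "A", "A"
        reads = ["".join(h1)] * 15 + ["".join(h2)] * 14
        calls = [VariantCall(2, "A", ("C", "T"), "both"),
                 VariantCall(10, "A", ("A", "C"), "both"),
                 VariantCall(25, "A", ("A", "G"), "both")]
        pair = phase_haplotypes(self._aligned(reads), calls)
        assert sorted(pair.haplotypes) == sorted(["".join(h1), "".join(h2)])

    def test_ambiguous_linkage_raises(self):
        h1, h2 = list(self.REF), list(self.REF)
        h1[3], h1[20] = "C", "A"
        h2[3], h2[20] = "T", "G"
        x1, x2 = list(self.REF), list(self.REF)
        x1[3], x1[20] = "C", "G"
        x2[3], x2[20] = "T", "A"
        reads = ["".join(h1)] * 10 + ["".join(h2)] * 10 \
            + ["".join(x1)] * 10 + ["".join(x2)] * 10
        calls = [VariantCall(3, "A", ("C", "T"), "both"),
                 VariantCall(20, "A", ("A", "G"), "both")]
        with pytest.raises(PhaseAmbiguousError):
            phase_haplotypes(self._aligned(reads), calls)


class TestEndToEnd:
    def _run(self, sim_cfg, rng, alleles=None, n_var=12):
        if alleles is None:
            alleles = simulate.gen_allele_set("L", 6, 300, n_var, rng)
        truth = simulate.gen_population_genotypes(alleles, sim_cfg, rng)
        reads, panel = simulate.gen_amplicon_reads(truth, alleles, sim_cfg, rng)
        per_sample, _ = demux.run_demux(reads, panel, min_len=250,
                                        min_reads=min(400, sim_cfg.reads_per_sample))
        ref = alleles.sequences[0]
        hits = total = 0
        for rec in truth:
            res = call_sample(per_sample[rec.sample], ref, rec.sample)
            total += 1
            if res.phased is None:
                continue
            want = sorted(alleles.by_name(a) for a in rec.alleles)
            hits += sorted(res.phased.haplotypes) == want
        return hits, total

    def test_zero_noise_round_trip_recovers_truth_exactly(self, rng):
        cfg = SimConfig(n_individuals={"P": 6}, reads_per_sample=200,
                        substitution_error_rate=0.0, chimera_rate=0.0)
        hits, total = self._run(cfg, rng)
        assert hits == total == 6

    def test_caller_equivalence_in_clean_limit(self, rng, two_allele_set):
        cfg = SimConfig(n_individuals={"P": 4}, reads_per_sample=100,
                        substitution_error_rate=0.0, chimera_rate=0.0)
        truth = simulate.gen_population_genotypes(two_allele_set, cfg, rng)
        reads, panel = simulate.gen_amplicon_reads(truth, two_allele_set, cfg, rng)
        per_sample, _ = demux.run_demux(reads, panel, min_len=30, min_reads=50)
        ref = two_allele_set.sequences[0]
        for rec in truth:
            res = call_sample(per_sample[rec.sample], ref, rec.sample)
            r = {(c.pos, c.genotype) for c in res.ratio_calls if c.genotype}
            l = {(c.pos, c.genotype) for c in res.likelihood_calls if c.genotype}
            assert r == l

    def test_chimera_removal_is_conservative(self, rng):
        """chimera_rate 0.2 at depth >= 500: parental truth recovered."""
        cfg = SimConfig(n_individuals={"P": 12}, reads_per_sample=500,
                        substitution_error_rate=0.001, chimera_rate=0.2,
                        rng_seed=5)
        hits, total = self._run(cfg, rng)
        assert hits == total == 12

    def test_no_more_than_two_haplotypes_per_sample(self, rng):
        cfg = SimConfig(n_individuals={"P": 5}, reads_per_sample=400,
                        substitution_error_rate=0.002, chimera_rate=0.1)
        alleles = simulate.gen_allele_set("L", 6, 300, 12, rng)
        truth = simulate.gen_population_genotypes(alleles, cfg, rng)
        reads, panel = simulate.gen_amplicon_reads(truth, alleles, cfg, rng)
        per_sample, _ = demux.run_demux(reads, panel, min_len=250, min_reads=300)
        for rec in truth:
            res = call_sample(per_sample[rec.sample], alleles.sequences[0])
            if res.phased is not None:
                assert len(set(res.phased.haplotypes)) <= 2
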