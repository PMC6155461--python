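import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from mhcamplicon import selection
from mhcamplicon.selection import (
    PocketMask,
    codon_path_counts,
    codon_sites,
    codon_usage,
    exon_to_peptides,
    load_pocket_masks,
    pairwise_dnds,
    pocket_enrichment_test,
    site_dnds_scan,
    titv_ratio,
)

CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon):
    return "*" if codon in STOPS else str(Seq(codon).translate())


class TestExonToPeptides:
    def test_dqa_frame_249_to_82aa(self):
        seq = "GG" + "GCT" * 82 + "A"     # 249 nt, partial codon at each end
        assert len(seq) == 249
        aln = exon_to_peptides([seq], ["a"], locus="DQA")
        assert len(aln.nucleotides[0]) == 246
        assert len(aln.peptides[0]) == 82

    def test_dqb_frame_270_to_89aa(self):
        seq = "GG" + "GCT" * 89 + "A"
        assert len(seq) == 270
        aln = exon_to_peptides([seq], ["b"], locus="DQB")
        assert len(aln.peptides[0]) == 89

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            exon_to_peptides(["A" * 250], ["x"])

    def test_variable_column_census(self):
        a = "GG" + "GCTGCA" + "A"
        b = "GG" + "GCAGCA" + "A"
        aln = exon_to_peptides([a, b], ["a", "b"])
        assert aln.variable_nt_columns == [2]
        assert aln.variable_aa_columns == []      # GCT/GCA both Ala


class TestPocketEnrichment:
    def test_census_matches_direct_formula(self):
        """Direct two-cell G evaluation as an independent oracle."""
        mask = PocketMask("DQA", set(range(1, 16)))
        var = list(range(1, 9)) + [20, 21, 22, 23]  # 8 in / 4 out of 12
        res = pocket_enrichment_test(var, mask, 82)
        e_in, e_out = 12 * 15 / 82, 12 * 67 / 82
        g = 2 * (8 * math.log(8 / e_in) + 4 * math.log(4 / e_out))
        assert res.g == pytest.approx(g)
        chi2 = (8 - e_in) ** 2 / e_in + (4 - e_out) ** 2 / e_out
        assert res.chi2 == pytest.approx(chi2)
        assert res.p_g < 0.001

    def test_proportional_counts_give_zero_g(self):
        mask = PocketMask("L", set(range(1, 11)))   # 10 of 40 positions
        var = [1, 2, 20, 30, 35, 38, 11, 12]        # 2 in / 6 out = 10/30 ratio
        res = pocket_enrichment_test(var, mask, 40)
        assert res.g == pytest.approx(0.0, abs=1e-12)

    def test_zero_variable_sites(self):
        res = pocket_enrichment_test([], PocketMask("L", {1}), 10)
        assert res.g == 0.0 and res.p_g == 1.0

    def test_g_and_chi2_agree_asymptotically(self, rng):
        """|G - chi2|/chi2 < 0.1 whenever expected counts are >= 10."""
        for _ in range(50):
            total = int(rng.integers(50, 120))
            mask = PocketMask("L", set(range(1, int(rng.integers(20, 40)))))
            n_var = int(rng.integers(30, total - 1))
            k = len(mask.positions)
            positions = list(rng.choice(total, size=n_var, replace=False) + 1)
            res = pocket_enrichment_test(positions, mask, total)
            if min(res.expected) >= 10 and res.chi2 > 1e-6:
                assert abs(res.g - res.chi2) / res.chi2 < 0.1

    def test_default_masks_validate_published_totals(self):
        masks = load_pocket_masks()
        assert masks["DQA"].size == 15
        assert masks["DQB"].size == 19


class TestTiTv:
    def test_counting_mode_matches_random_expectation(self):
        a = "ACGTAA"
        b = "GCGTCT"   # A->G (ts), A->C (tv), A->T (tv)
        r = titv_ratio([a, b], method="counting")
        assert r["R"] == pytest.approx(0.5)

    def test_transitions_only_undefined(self):
        r = titv_ratio(["AAAA", "GGGG"])
        assert r["R"] == math.inf

    def test_k2p_parameter_recovery(self, rng):
        """Seeded K2P simulation at kappa = 2 recovered within 10%.

        Sites are mutated with the closed-form K2P substitution
        probabilities P(t), Q(t) for alpha = 4 beta (R = alpha/2beta = 2),
        so the corrected s/v estimator should return ~2.
        """
        import math as _m
        n = 10_000
        bases = "ACGT"
        ts_map = {"A": "G", "G": "A", "C": "T", "T": "C"}
        bt = 0.02                       # beta * t
        at = 4 * bt                     # alpha * t
        Q = 0.5 * (1 - _m.exp(-4 * bt))
        P = 0.25 * (1 - 2 * _m.exp(-2 * (at + bt)) + _m.exp(-4 * bt))
        anc = rng.choice(list(bases), size=n)
        derived = []
        for b in anc:
            u = rng.random()
            if u < P:
                derived.append(ts_map[b])
            elif u < P + Q:
                tvs = [x for x in bases if x != b and x != ts_map[b]]
                derived.append(tvs[int(rng.integers(2))])
            else:
                derived.append(b)
        r = titv_ratio(["".join(anc), "".join(derived)])
        assert abs(r["R"] - 2.0) / 2.0 < 0.10


def oracle_path_counts(c1, c2):
    """Independent exhaustive enumeration over mutation orders."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    results = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in STOPS:
                ok = False
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return None
    return (float(np.mean([r[0] for r in results])),
            float(np.mean([r[1] for r in results])))


class TestNeiGojobori:
    def test_identical_alleles_undefined_omega(self):
        seq = "GG" + "GCTGCA" * 3 + "A"
        res = pairwise_dnds(exon_to_peptides([seq, seq], ["a", "b"]))
        assert res.mean_dn == 0.0 and res.mean_ds == 0.0
        assert res.omega_undefined

    def test_synonymous_only_change_zero_dn(self):
        a = "GG" + "TTT" + "A"
        b = "GG" + "TTC" + "A"
        res = pairwise_dnds(exon_to_peptides([a, b], ["a", "b"]))
        row = res.pairs.iloc[0]
        assert row["Nd"] == 0.0 and row["dN"] == 0.0
        assert row["Sd"] == 1.0

    def test_all_two_difference_codon_pairs_match_path_oracle(self):
        """Equal-path averaging equals exhaustive order enumeration on every
        sense-codon pair differing at exactly two positions."""
        sense = [c for c in CODONS if c not in STOPS]
        checked = 0
        for c1 in sense:
            for c2 in sense:
                if sum(a != b for a, b in zip(c1, c2)) != 2:
                    continue
                expected = oracle_path_counts(c1, c2)
                if expected is None:
                    continue
                sd, nd = codon_path_counts(c1, c2)
                assert (sd, nd) == pytest.approx(expected), (c1, c2)
                checked += 1
        assert checked > 100

    def test_site_counts_sum_to_three(self):
        for codon in ("TTT", "GCT", "ATG", "CGA"):
            s, n = codon_sites(codon)
            assert s + n == pytest.approx(3.0)

    def test_positive_selection_detectable(self, rng):
        """w > 1 on an alignment enriched for nonsynonymous differences."""
        base = ["GCT"] * 20  # Ala
        seqs = []
        nonsyn = ["CCT", "ACT", "TCT", "GTT", "GAT"]  # first/second-position changes
        syn = ["GCA", "GCC", "GCG"]                    # third-position Ala codons
        for i in range(6):
            codons = list(base)
            for j in rng.choice(20, size=6, replace=False):
                codons[j] = nonsyn[int(rng.integers(len(nonsyn)))]
            for j in rng.choice(20, size=2, replace=False):
                if codons[j] == "GCT":
                    codons[j] = syn[int(rng.integers(3))]
            seqs.append("GG" + "".join(codons) + "A")
        res = pairwise_dnds(exon_to_peptides(seqs, [f"a{i}" for i in range(6)]))
        assert res.omega is not None and res.omega > 1.0


class TestCodonUsage:
    def test_uniform_usage_nc_61_and_rscu_one(self):
        uniform = "".join(c for c in CODONS if c not in STOPS)
        stats = codon_usage([uniform * 20])
        assert stats.nc == pytest.approx(61.0)
        assert all(v == pytest.approx(1.0) for v in stats.rscu.values())

    def test_single_codon_per_aa_nc_20(self):
        one_each = "".join(sorted(min(f) for f in selection._FAMILIES.values()))
        stats = codon_usage([one_each * 20])
        assert stats.nc == pytest.approx(20.0)
        assert stats.cbi == pytest.approx(1.0)

    def test_nc_on_large_uniform_simulation_close_to_61(self, rng):
        sense = [c for c in CODONS if c not in STOPS]
        draw = rng.choice(sense, size=10_000)
        stats = codon_usage(["".join(draw)])
        assert abs(stats.nc - 61.0) <= 0.5

    def test_gc_fraction(self):
        assert codon_usage(["GGGCCCAAATTT"]).gc == pytest.approx(0.5)


class TestSiteScan:
    def test_synonymous_only_column_classified_low(self):
        seqs = ["GG" + "TTT" + "GCT" + "A", "GG" + "TTC" + "GCT" + "A"]
        scan = site_dnds_scan(exon_to_peptides(seqs, ["a", "b"]))
        assert scan.iloc[0]["class"] in ("w<1", "w~1")
        assert scan.iloc[0]["sd"] > 0 and scan.iloc[0]["nd"] == 0

    def test_invariant_column_no_signal(self):
        seqs = ["GG" + "GCT" + "A"] * 3
        scan = site_dnds_scan(exon_to_peptides(seqs, list("abc")))
        assert scan.iloc[0]["class"] == "no signal"

    def test_power_on_strongly_selected_codons(self, rng):
        """Columns evolved with heavy nonsynonymous turnover are flagged."""
        n_alleles, n_codons = 20, 12
        hot = [0, 3, 5, 8, 10]
        # six codons, six amino acids, all with 4-fold degenerate 3rd position
        hot_variants = ["GCT", "GTT", "CCT", "ACT", "CGT", "TCT"]
        rows = []
        for i in range(n_alleles):
            codons = ["GGT"] * n_codons
            for h in hot:
                codons[h] = hot_variants[int(rng.integers(len(hot_variants)))]
            rows.append("GG" + "".join(codons) + "A")
        scan = site_dnds_scan(exon_to_peptides(rows, [f"a{i}" for i in range(n_alleles)]))
        flagged = set(scan[scan["class"] == "w>1"]["codon"] - 1)
        assert len(flagged & set(hot)) >= 4
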