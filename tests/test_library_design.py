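"""PAM scanning, candidate enumeration, uniqueness filtering, selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from guidekit.genome import Genome, GeneModel, reverse_complement
from guidekit.design import (GuideRecord, IUPAC, find_pam_sites,
                             enumerate_candidates, build_uniqueness_index,
                             uniqueness_filter, seed_prefix,
                             select_guides_for_gene, select_library,
                             design_library, design_nontargeting,
                             reverse_complement_iupac)


def naive_pam_scan(seq, pattern, both_strands=True):
    """Oracle: check every window against the IUPAC pattern, per strand."""
    def matches(window, pat):
        return len(window) == len(pat) and all(
            b in IUPAC[p] for b, p in zip(window, pat))
    hits = []
    m = len(pattern)
    for i in range(len(seq) - m + 1):
        w = seq[i:i + m]
        if matches(w, pattern):
            hits.append((i, "+"))
        if both_strands and matches(reverse_complement(w), pattern):
            hits.append((i, "-"))
    return hits


class TestFindPamSites:
    def test_matches_bruteforce_on_random_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 1000))
        g = Genome({"c": seq})
        for pattern in ["TTTN", "TTTV", "NGG", "RYSW"]:
            got = sorted((p, s) for _, p, s in find_pam_sites(g, pattern))
            assert got == sorted(naive_pam_scan(seq, pattern))

    @given(seq=st.text(alphabet="ACGT", min_size=10, max_size=10_000),
           pattern=st.text(alphabet="ACGTRYSWKMBDHVN", min_size=2, max_size=6))
    @settings(max_examples=25, deadline=None)
    def test_oracle_equivalence_property(self, seq, pattern):
        g = Genome({"c": seq})
        got = sorted((p, s) for _, p, s in find_pam_sites(g, pattern))
        assert got == sorted(naive_pam_scan(seq, pattern))

    def test_cccc_vs_ngg_by_hand(self):
        g = Genome({"c": "CCCC"})
        hits = find_pam_sites(g, "NGG")
        assert [h for h in hits if h[2] == "+"] == []
        assert sorted(h[1] for h in hits if h[2] == "-") == [0, 1]

    def test_invalid_iupac_code_rejected(self, small_genome):
        genome, _ = small_genome
        with pytest.raises(ValueError, match="IUPAC"):
            find_pam_sites(genome, "TTTX")

    def test_revcomp_iupac(self):
        assert reverse_complement_iupac("TTTV") == "BAAA"
        assert reverse_complement_iupac("NGG") == "CCN"


def _seeded_cds():
    """60 bp CDS with exactly 3 plus-strand TTTV sites and no minus sites."""
    rng = np.random.default_rng(11)
    # GC-rich background suppresses accidental TTTV/BAAA
    seq = list(rng.choice(list("CG"), 120))
    for pos in (10, 44, 78):  # TTTA + 25 bp spacer fits in [0, 120)
        seq[pos:pos + 4] = list("TTTA")
    return Genome({"c": "".join(seq)}), GeneModel("g1", "c", [(0, 120)], "+")


class TestEnumerateCandidates:
    def test_seeded_fixture_counts(self):
        g, gene = _seeded_cds()
        cands = enumerate_candidates(g, gene, "cas12a")
        assert len(cands) == 3
        assert all(c.pam == "TTTA" and len(c.spacer) == 25 for c in cands)

    def test_tttt_pam_not_tttv(self):
        # the only in-CDS PAM window is TTTT (T is not a V); the trailing
        # TTTC has no room for a 25 bp spacer inside the CDS
        g = Genome({"c": "C" * 35 + "TTTT" + "C" * 5})
        gene = GeneModel("g", "c", [(0, 44)], "+")
        assert enumerate_candidates(g, gene, "cas12a") == []

    def test_cas9_matches_regex_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 400))
        g = Genome({"c": seq})
        gene = GeneModel("g", "c", [(0, 400)], "+")
        cands = enumerate_candidates(g, gene, "cas9")
        # oracle: NGG PAM with full 20 bp spacer inside CDS, both strands
        expect = 0
        for p, s in naive_pam_scan(seq, "NGG"):
            if s == "+" and p - 20 >= 0:
                expect += 1
            if s == "-" and p + 23 <= 400:
                expect += 1
        assert len(cands) == expect

    def test_pamless_gene_empty(self):
        g = Genome({"c": "C" * 100})
        gene = GeneModel("g", "c", [(0, 100)], "+")
        assert enumerate_candidates(g, gene, "cas12a") == []


class TestUniqueness:
    def test_all_pairs_oracle_on_synthetic_genome(self, small_genome):
        genome, genes = small_genome
        index = build_uniqueness_index(genome, "cas12a", p=14)
        cands = []
        for gene in genes[:12]:
            cands.extend(enumerate_candidates(genome, gene, "cas12a"))
        kept = uniqueness_filter(cands, index, "cas12a")
        # oracle: all-pairs comparison against every genome-wide TTTN prefix
        all_prefixes = []
        for chrom in genome.chromosomes:
            seq = genome[chrom]
            for p, s in naive_pam_scan(seq, "TTTN"):
                if s == "+" and p + 29 <= len(seq):
                    all_prefixes.append(seq[p + 4:p + 4 + 14])
                elif s == "-" and p - 25 >= 0:
                    all_prefixes.append(reverse_complement(seq[p - 14:p]))
        expect = [c for c in cands
                  if all_prefixes.count(seed_prefix(c.spacer, 14, "cas12a")) == 1]
        assert [c.guide_id for c in kept] == [c.guide_id for c in expect]

    def test_duplicated_segment_guides_excluded(self, rng):
        seg = "".join(rng.choice(list("ACGT"), 200))
        unique = "".join(rng.choice(list("ACGT"), 300))
        genome = Genome({"c": seg + unique + seg})  # exact tandem-style repeat
        gene_dup = GeneModel("gd", "c", [(0, 200)], "+")
        index = build_uniqueness_index(genome, "cas12a", p=14)
        cands = enumerate_candidates(genome, gene_dup, "cas12a")
        assert len(cands) > 0, "fixture must seed at least one candidate"
        assert uniqueness_filter(cands, index, "cas12a") == []

    def test_single_copy_genome_keeps_all(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 2000))
        genome = Genome({"c": seq})
        gene = GeneModel("g", "c", [(0, 2000)], "+")
        index = build_uniqueness_index(genome, "cas12a", p=14)
        cands = enumerate_candidates(genome, gene, "cas12a")
        kept = uniqueness_filter(cands, index, "cas12a")
        assert len(kept) == len(cands)

    def test_prefix_longer_than_spacer_errors(self):
        with pytest.raises(ValueError, match="prefix length"):
            seed_prefix("ACGT" * 5, 25, "cas9")


def _mk(gid, start, strand, gene_strand="+"):
    return GuideRecord(gid, "A" * 25, "TTTA", "c", start, strand, "g")


class TestSelectLibrary:
    GENE = GeneModel("g", "c", [(0, 1000)], "+")

    def test_even_strand_representation(self):
        plus = [_mk(f"p{i}", 50 + 100 * i, "+") for i in range(5)]
        minus = [_mk(f"m{i}", 80 + 100 * i, "-") for i in range(5)]
        picked = select_guides_for_gene(plus + minus, self.GENE, 8)
        assert len(picked) == 8
        assert sum(g.strand == "+" for g in picked) == 4
        # the 5'-most of each strand survive
        assert {g.guide_id for g in picked} == {f"p{i}" for i in range(4)} | \
            {f"m{i}" for i in range(4)}

    def test_under_covered_gene_takes_all_and_flagged(self):
        cands = {"g": [_mk(f"p{i}", 10 * i, "+") for i in range(3)]}
        lib = select_library(cands, {"g": self.GENE}, 8)
        assert len(lib) == 3 and lib.under_covered == {"g": 3}

    def test_single_strand_fallback(self):
        cands = [_mk(f"p{i}", 10 + 30 * i, "+") for i in range(12)]
        picked = select_guides_for_gene(cands, self.GENE, 8)
        assert [g.guide_id for g in picked] == [f"p{i}" for i in range(8)]

    def test_minus_strand_gene_walks_from_its_5prime(self):
        gene = GeneModel("g", "c", [(0, 1000)], "-")
        cands = [_mk(f"p{i}", 100 * i, "+") for i in range(10)]
        picked = select_guides_for_gene(cands, gene, 2)
        # 5' end of a minus-strand gene is the highest coordinate
        assert picked[0].guide_id == "p9"


class TestNonTargeting:
    def test_prefix_absent_by_substring_oracle(self, small_genome):
        genome, _ = small_genome
        guides = design_nontargeting(genome, 10, p=10, seed=3)
        joined = "N".join(genome[c] for c in genome.chromosomes)
        both = joined + "N" + reverse_complement(joined)
        for g in guides:
            assert g.spacer[:10] not in both
            assert g.gene_id == "non-targeting" and not g.targeting

    def test_count_zero_empty(self, small_genome):
        genome, _ = small_genome
        assert design_nontargeting(genome, 0, seed=1) == []

    def test_seeded_determinism(self, small_genome):
        genome, _ = small_genome
        a = design_nontargeting(genome, 25, seed=9)
        b = design_nontargeting(genome, 25, seed=9)
        assert [g.spacer for g in a] == [g.spacer for g in b]

    def test_impossible_request_errors(self):
        # a tiny alphabet-saturating genome leaves no absent 2-mers
        genome = Genome({"c": "ACGT" * 100 + reverse_complement("ACGT" * 100)})
        with pytest.raises(RuntimeError, match="attempts"):
            design_nontargeting(genome, 5, p=1, seed=0,
                                max_attempts_per_guide=20)


class TestEndToEnd:
    def test_every_library_guide_relocates_uniquely(self, small_genome,
                                                    small_library):
        """Each designed guide's 14-nt seed exact-searches to one locus."""
        genome, _ = small_genome
        rng = np.random.default_rng(2)
        targeting = [g for g in small_library if g.targeting]
        for g in [targeting[i] for i in
                  rng.choice(len(targeting), 25, replace=False)]:
            seed = seed_prefix(g.spacer, 14, "cas12a")
            n = 0
            for chrom in genome.chromosomes:
                seq = genome[chrom]
                n += seq.count(seed) + seq.count(reverse_complement(seed))
            assert n == 1
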