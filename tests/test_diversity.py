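import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from mlstpg.diversity import (
    classify_snp_sites,
    diversity_table,
    dn_ds,
    gc_content,
    nucleotide_diversity,
    polymorphic_sites,
)
from mlstpg.mlst_core import type_isolates


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def pi_bruteforce(seqs):
    """All-pairs O(n^2 L) nucleotide diversity."""
    n = len(seqs)
    total = 0
    for a, b in itertools.combinations(seqs, 2):
        total += sum(x != y for x, y in zip(a, b))
    return total / (n * (n - 1) / 2) / len(seqs[0])


def _aa(codon):
    return "*" if str(Seq(codon).translate()) == "*" else str(Seq(codon).translate())


def ng86_pair(c1_codons, c2_codons):
    """Direct Nei-Gojobori site/difference counts for one sequence pair."""
    stops = {"TAA", "TAG", "TGA"}

    def syn_sites(codon):
        s = 0.0
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if alt not in stops and _aa(alt) == _aa(codon):
                    s += 1 / 3
        return s

    S = sum((syn_sites(a) + syn_sites(b)) / 2 for a, b in zip(c1_codons, c2_codons))
    N = 3 * len(c1_codons) - S
    Sd = Nd = 0.0
    for a, b in zip(c1_codons, c2_codons):
        positions = [i for i in range(3) if a[i] != b[i]]
        if not positions:
            continue
        paths = []
        for order in itertools.permutations(positions):
            cur, sd, nd, bad = a, 0.0, 0.0, False
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                if nxt in stops:
                    bad = True
                if _aa(cur) == _aa(nxt) and nxt not in stops:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd, bad))
        good = [(sd, nd) for sd, nd, bad in paths if not bad] or [
            (sd, nd) for sd, nd, _ in paths
        ]
        Sd += sum(p[0] for p in good) / len(good)
        Nd += sum(p[1] for p in good) / len(good)
    return S, N, Sd, Nd


# ---------------------------------------------------------------------------
# polymorphic sites / GC / pi
# ---------------------------------------------------------------------------

def test_polymorphic_sites_identical_and_constructed():
    assert polymorphic_sites(["ACGTACGTACGT"] * 4) == (0, [])
    aln = [
        "ACGTACGTACGT",
        "ACGAACGTACGT",  # site 4
        "ACGTACCTACGT",  # site 7
        "ACGTACGTACGG",  # site 12
    ]
    count, positions = polymorphic_sites(aln)
    assert count == 3
    assert positions == [4, 7, 12]


def test_polymorphic_sites_rejects_ragged():
    with pytest.raises(ValueError, match="ragged"):
        polymorphic_sites(["ACGT", "ACG"])


@pytest.mark.parametrize(
    "aln,expected", [(["GGCC"], 100.0), (["ATAT"], 0.0), (["ATGC", "ATGC"], 50.0)]
)
def test_gc_content(aln, expected):
    assert gc_content(aln) == pytest.approx(expected)


def test_pi_simple_pair_and_bruteforce_oracle(rng):
    assert nucleotide_diversity(["AAAAAAAAAA", "AAAAAAAAAC"]) == pytest.approx(0.1)
    assert nucleotide_diversity(["ACGT", "ACGT"]) == 0.0
    seqs = [
        "".join(rng.choice(list("ACGT"), size=30)) for _ in range(5)
    ]
    assert nucleotide_diversity(seqs) == pytest.approx(
        pi_bruteforce(seqs), abs=1e-15
    )


def test_pi_invariant_under_sequence_permutation(rng):
    seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(6)]
    perm = rng.permutation(6)
    assert nucleotide_diversity(seqs) == nucleotide_diversity(
        [seqs[i] for i in perm]
    )


def test_pi_requires_two_sequences():
    with pytest.raises(ValueError):
        nucleotide_diversity(["ACGT"])


def test_concatenated_pi_is_length_weighted_mean(small_population):
    from conftest import SMALL_PANEL
    from mlstpg.mlst_core import concatenate

    records, _ = small_population
    per_locus = [
        (
            l.expected_length,
            nucleotide_diversity([r.sequences[l.name] for r in records]),
        )
        for l in SMALL_PANEL
    ]
    total_len = sum(L for L, _ in per_locus)
    weighted = sum(L * pi for L, pi in per_locus) / total_len
    concat_pi = nucleotide_diversity(
        [concatenate(r, loci=SMALL_PANEL) for r in records]
    )
    assert abs(concat_pi - weighted) < 1e-12


# ---------------------------------------------------------------------------
# SNP classification
# ---------------------------------------------------------------------------

class TestClassifySnpSites:
    def test_synonymous_third_position(self):
        # GAA (Glu) vs GAG (Glu)
        n, s, classes = classify_snp_sites(["GAA", "GAG"])
        assert (n, s) == (0, 1)
        assert classes == {3: "s"}

    def test_nonsynonymous_second_position(self):
        # GAA (Glu) vs GGA (Gly)
        n, s, classes = classify_snp_sites(["GAA", "GGA"])
        assert (n, s) == (1, 0)
        assert classes == {2: "n"}

    def test_monomorphic_alignment_is_empty(self):
        assert classify_snp_sites(["ATGGCA", "ATGGCA"])[:2] == (0, 0)

    def test_mixed_pairs_count_as_nonsynonymous(self):
        # third position with Leu CTA/CTG (syn pair) and Met ATG background:
        # column 1 varies C/A (Leu vs Met context) -> nonsynonymous
        n, s, classes = classify_snp_sites(["CTA", "CTG", "ATG"])
        assert classes[1] == "n"

    def test_trailing_incomplete_codon_excluded(self):
        n, s, classes = classify_snp_sites(["GAAGA", "GAGGC"])
        assert 3 in classes and 5 not in classes

    def test_stop_codon_raises(self):
        with pytest.raises(ValueError, match="stop"):
            classify_snp_sites(["TAA", "TAC"])


# ---------------------------------------------------------------------------
# dN/dS
# ---------------------------------------------------------------------------

class TestDnDs:
    def test_hand_enumerated_two_codon_pair(self):
        # TTT GAA vs TTC GGA: by hand, per-sequence synonymous sites are
        # 1/3+1/3 and 1/3+1 -> S = 1, N = 5; one synonymous and one
        # nonsynonymous single-base difference -> Sd = Nd = 1.
        res = dn_ds(["TTTGAA", "TTCGGA"])
        assert res.s_sites == pytest.approx(1.0, abs=1e-12)
        assert res.n_sites == pytest.approx(5.0, abs=1e-12)
        assert res.sd == pytest.approx(1.0)
        assert res.nd == pytest.approx(1.0)
        assert res.ps == pytest.approx(1.0)
        assert res.pn == pytest.approx(0.2)

    def test_matches_direct_oracle_on_random_small_alignments(self, rng):
        sense = [
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if a + b + c not in {"TAA", "TAG", "TGA"}
        ]
        for _ in range(5):
            ncod = int(rng.integers(2, 10))
            base = [sense[i] for i in rng.integers(0, len(sense), size=ncod)]
            aln = []
            for _ in range(4):
                cods = list(base)
                for _ in range(int(rng.integers(1, 4))):
                    k = int(rng.integers(ncod))
                    cods[k] = sense[int(rng.integers(len(sense)))]
                aln.append("".join(cods))
            res = dn_ds(aln)
            S = N = Sd = Nd = 0.0
            pairs = list(itertools.combinations(range(4), 2))
            for i, j in pairs:
                ci = [aln[i][3 * k : 3 * k + 3] for k in range(ncod)]
                cj = [aln[j][3 * k : 3 * k + 3] for k in range(ncod)]
                s, n, sd, nd = ng86_pair(ci, cj)
                S += s
                N += n
                Sd += sd
                Nd += nd
            assert res.s_sites == pytest.approx(S / len(pairs), abs=1e-10)
            assert res.n_sites == pytest.approx(N / len(pairs), abs=1e-10)
            assert res.sd == pytest.approx(Sd / len(pairs), abs=1e-10)
            assert res.nd == pytest.approx(Nd / len(pairs), abs=1e-10)

    def test_symmetric_in_sequence_order(self):
        a = "TTTGAAATGGCAGCTAAATTT"
        b = "TTCGGAATGGCAGCGAAATTT"
        r1, r2 = dn_ds([a, b]), dn_ds([b, a])
        assert r1.dn == pytest.approx(r2.dn)
        assert r1.ds == pytest.approx(r2.ds)
        assert r1.dnds == pytest.approx(r2.dnds)

    def test_synonymous_only_alignment_gives_zero_ratio(self):
        # one GAA<->GAG third-position change: purely synonymous variation
        # (the recA pattern); enough codons for the correction to be defined
        a = "GAA" * 8
        b = "GAA" * 7 + "GAG"
        res = dn_ds([a, b])
        assert res.dn == 0.0
        assert res.dnds == 0.0
        assert res.ratio_defined

    def test_identical_sequences_flagged(self):
        res = dn_ds(["GAAGAA", "GAAGAA"])
        assert res.dnds == 0.0
        assert not res.ratio_defined

    def test_stop_codon_and_short_alignment_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            dn_ds(["TAAGAA", "TACGAA"])
        with pytest.raises(ValueError):
            dn_ds(["GA", "GA"])


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

class TestDiversityTable:
    def test_counts_match_allele_registry(self, small_population):
        from conftest import SMALL_PANEL

        records, _ = small_population
        typing = type_isolates(records, SMALL_PANEL)
        table = diversity_table(records, SMALL_PANEL).set_index("locus")
        for l in SMALL_PANEL:
            observed = {typing.db.lookup(l.name, r.sequences[l.name]) for r in records}
            assert table.loc[l.name, "n_alleles"] == len(observed)

    def test_concatenated_row_aggregates_locus_rows(self, small_population):
        from conftest import SMALL_PANEL

        records, _ = small_population
        table = diversity_table(records, SMALL_PANEL)
        concat = table[table.locus == "concatenated"].iloc[0]
        per_locus = table[table.locus != "concatenated"]
        assert concat.n_polymorphic == per_locus.n_polymorphic.sum()
        assert concat.n_nsnp == per_locus.n_nsnp.sum()
        assert concat.size_bp == per_locus.size_bp.sum()

    def test_single_isolate_subset_flags_pi(self, small_population):
        records, _ = small_population
        from conftest import SMALL_PANEL

        table = diversity_table(
            records, SMALL_PANEL, subset=[records[0].isolate_id]
        )
        assert (table.n_alleles == 1).all()
        assert table.pi.isna().all()

    def test_empty_subset_rejected(self, small_population):
        records, _ = small_population
        with pytest.raises(ValueError, match="empty"):
            diversity_table(records, subset=["nope"])

    def test_truth_injected_variants_are_counted(self):
        # two haplotypes differing at exactly two engineered sites
        from mlstpg.mlst_core import IsolateRecord, LocusDef

        loci = (LocusDef("g", 12, 0, 1),)
        a = "ATGGCAGGGCCA"
        b = "ATGGCAGGCCCA"  # one substitution at site 9 (syn or nonsyn known)
        recs = [
            IsolateRecord("i1", {"g": a}),
            IsolateRecord("i2", {"g": b}),
            IsolateRecord("i3", {"g": a}),
        ]
        table = diversity_table(recs, loci).set_index("locus")
        assert table.loc["g", "n_polymorphic"] == 1
        assert table.loc["g", "n_alleles"] == 2
        # pi over isolates: 2 mismatching pairs of 3, at 1 of 12 sites
        assert table.loc["g", "pi"] == pytest.approx(2 / 3 / 12)
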