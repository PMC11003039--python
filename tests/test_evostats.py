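"""NG86 Ka/Ks against an independent pathway oracle; nucleotide diversity."""

import itertools
import math

import numpy as np
import pytest

from mitocharter import evostats
from mitocharter.evostats import (
    CodonAlignment, ng86_kaks, nucleotide_diversity, pairwise_kaks_table,
    pathway_differences, selection_label, syn_nonsyn_sites,
)
from mitocharter.sequtil import CODON_TABLE, SENSE_CODONS, revcomp


def oracle_pathways(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Independent exhaustive enumeration of substitution orders.

    Pathways through stop codons are excluded unless all are blocked; each
    step counts as synonymous iff the amino acid is unchanged.
    """
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    results = []
    for order in itertools.permutations(diffs):
        cur, sd, nd, blocked = codon_a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if CODON_TABLE[nxt] == "*" and nxt != codon_b:
                blocked = True
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, blocked))
    ok = [(s, n) for s, n, b in results if not b] or [(s, n) for s, n, _ in results]
    return (sum(s for s, _ in ok) / len(ok), sum(n for _, n in ok) / len(ok))


class TestSites:
    def test_s_plus_n_is_three_for_every_sense_codon(self):
        for codon in SENSE_CODONS:
            s, n = syn_nonsyn_sites(codon)
            assert s + n == pytest.approx(3.0, abs=1e-12)

    def test_fourfold_third_position(self):
        s, _n = syn_nonsyn_sites("GCT")  # Ala: third position fully degenerate
        assert s == pytest.approx(1.0)

    def test_met_has_no_synonymous_sites(self):
        assert syn_nonsyn_sites("ATG")[0] == 0.0


class TestPathways:
    def test_two_codon_pairs_match_oracle_sample(self):
        rng = np.random.default_rng(0)
        pairs = rng.choice(len(SENSE_CODONS), size=(200, 2))
        for ia, ib in pairs:
            a, b = SENSE_CODONS[ia], SENSE_CODONS[ib]
            assert pathway_differences(a, b) == pytest.approx(
                oracle_pathways(a, b), abs=1e-12)

    def test_three_substitution_codon_pair_vs_oracle(self):
        # ATG TTT AAA vs ATG CTT AGA: codons 2 and 3 differ
        aln = CodonAlignment("g", {"a": "ATGTTTAAA", "b": "ATGCTTAGA"})
        r = ng86_kaks(aln, "a", "b")
        sd = nd = 0.0
        s_sites = n_sites = 0.0
        for ca, cb in [("ATG", "ATG"), ("TTT", "CTT"), ("AAA", "AGA")]:
            ds, dn = oracle_pathways(ca, cb)
            sd += ds
            nd += dn
            s1, n1 = syn_nonsyn_sites(ca)
            s2, n2 = syn_nonsyn_sites(cb)
            s_sites += (s1 + s2) / 2
            n_sites += (n1 + n2) / 2
        ps, pn = sd / s_sites, nd / n_sites
        assert r.ks == pytest.approx(-0.75 * math.log(1 - 4 * ps / 3), abs=1e-12)
        assert r.ka == pytest.approx(-0.75 * math.log(1 - 4 * pn / 3), abs=1e-12)


class TestKaKs:
    def test_identical_sequences(self):
        aln = CodonAlignment("g", {"a": "ATGGCTAAA", "b": "ATGGCTAAA"})
        r = ng86_kaks(aln, "a", "b")
        assert r.ka == 0.0 and r.ks == 0.0 and r.ratio is None
        assert "ks-zero" in r.flags

    def test_single_synonymous_change(self):
        aln = CodonAlignment("g", {"a": "TTTGAA", "b": "TTCGAA"})
        r = ng86_kaks(aln, "a", "b")
        assert r.ka == 0.0
        assert r.pn == 0.0 and r.ps > 0
        # so few synonymous sites that ps > 3/4: correction flagged undefined
        assert "jc-correction-undefined" in r.flags or r.ks > 0

    def test_gap_codons_excluded_pairwise(self):
        aln = CodonAlignment("g", {"a": "ATG---AAA", "b": "ATGGCTAAA"})
        r = ng86_kaks(aln, "a", "b")
        assert r.n_codons == 2

    def test_no_comparable_codons_rejected(self):
        aln = CodonAlignment("g", {"a": "---", "b": "ATG"})
        with pytest.raises(ValueError):
            ng86_kaks(aln, "a", "b")

    def test_neutral_simulation_converges_to_one(self):
        rng = np.random.default_rng(3)
        codons = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=3333)]
        anc = "".join(codons)

        def mutate(seq):
            arr = list(seq)
            for i in range(len(arr)):
                if rng.random() < 0.03:
                    arr[i] = "ACGT"[rng.integers(0, 4)]
            return "".join(arr)

        aln = CodonAlignment("neutral", {"a": mutate(anc), "b": mutate(anc)})
        with pytest.warns(UserWarning):
            r = ng86_kaks(aln, "a", "b")
        assert r.ratio == pytest.approx(1.0, abs=0.1)

    def test_elevated_nonsynonymous_rate_recovered(self):
        """A mutation sampler accepting nonsynonymous changes twice as often
        as synonymous ones should yield Ka/Ks near 2."""
        rng = np.random.default_rng(9)
        codons = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=500)]
        anc = "".join(codons)

        def mutate(seq):
            arr = list(seq)
            for _ in range(400):
                i = int(rng.integers(0, len(arr)))
                old_codon = "".join(arr[3 * (i // 3) : 3 * (i // 3) + 3])
                new = "ACGT"[rng.integers(0, 4)]
                arr2 = arr.copy()
                arr2[i] = new
                new_codon = "".join(arr2[3 * (i // 3) : 3 * (i // 3) + 3])
                if CODON_TABLE[new_codon] == "*":
                    continue
                syn = CODON_TABLE[new_codon] == CODON_TABLE[old_codon]
                accept = 0.5 if syn else 1.0
                if rng.random() < accept:
                    arr = arr2
            return "".join(arr)

        aln = CodonAlignment("sel", {"a": mutate(anc), "b": mutate(anc)})
        r = ng86_kaks(aln, "a", "b")
        assert 1.5 <= r.ratio <= 2.5

    def test_selection_labels(self):
        assert selection_label(2.0) == "positive"
        assert selection_label(1.0) == "neutral"
        assert selection_label(0.3) == "purifying"
        assert selection_label(None) == "undefined"


class TestPairwiseTable:
    def test_three_taxa_give_three_pairs(self):
        aln = CodonAlignment("g", {"a": "ATGGCT", "b": "ATGGCC", "c": "ATGGCA"})
        table, summary = pairwise_kaks_table([aln])
        assert len(table) == 3

    def test_identical_taxa_all_zero(self):
        aln = CodonAlignment("g", {t: "ATGGCTAAA" for t in "abc"})
        table, _ = pairwise_kaks_table([aln])
        assert (table["ka"] == 0).all() and (table["ks"] == 0).all()

    def test_single_taxon_gene_skipped_with_warning(self):
        aln = CodonAlignment("solo", {"a": "ATGGCT"})
        with pytest.warns(UserWarning, match="solo"):
            table, _ = pairwise_kaks_table([aln])
        assert table.empty


class TestPi:
    def test_identical(self):
        aln = CodonAlignment("g", {"a": "ACGTACGTA", "b": "ACGTACGTA"})
        assert nucleotide_diversity(aln).pi == 0.0

    def test_two_sequences_one_difference(self):
        aln = CodonAlignment("g", {"a": "A" * 9 + "T", "b": "A" * 10})
        assert nucleotide_diversity(aln).pi == pytest.approx(0.1)

    def test_three_sequences_direct_enumeration(self):
        base = "A" * 100
        seqs = {"a": base, "b": "T" + base[1:], "c": "TG" + base[2:]}
        # pairwise differences: ab=1, ac=2, bc=... b vs c: pos0 T==T, pos1 A vs G -> 1
        # use an explicit alignment with differences {1, 2, 3}
        seqs = {
            "a": base,
            "b": "C" + base[1:],                      # ab = 1
            "c": "G" + "GC" + base[3:],               # ac = 3, bc = ?
        }
        d = lambda x, y: sum(i != j for i, j in zip(seqs[x], seqs[y]))
        total = d("a", "b") + d("a", "c") + d("b", "c")
        r = nucleotide_diversity(CodonAlignment("g", seqs))
        assert r.pi == pytest.approx(total / (3 * 100))

    def test_invariant_under_reordering_and_revcomp(self, rng):
        cols = rng.integers(0, 4, size=(5, 99))
        seqs = {f"t{i}": "".join("ACGT"[b] for b in row)
                for i, row in enumerate(cols)}
        pi1 = nucleotide_diversity(CodonAlignment("g", seqs)).pi
        reordered = dict(reversed(list(seqs.items())))
        pi2 = nucleotide_diversity(CodonAlignment("g", reordered)).pi
        rc = {k: revcomp(v) for k, v in seqs.items()}
        pi3 = nucleotide_diversity(CodonAlignment("g", rc)).pi
        assert pi1 == pi2 == pi3

    def test_pairwise_vs_complete_deletion(self):
        seqs = {"a": "ACGTAC", "b": "A-GTAC", "c": "ACGTAT"}
        pairwise = nucleotide_diversity(CodonAlignment("g", seqs)).pi
        complete = nucleotide_diversity(CodonAlignment("g", seqs),
                                        complete_deletion=True).pi
        assert pairwise >= 0 and complete >= 0

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(CodonAlignment("g", {"a": "ACG"}))
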