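"""Read-recruitment stages: matching, candidate selection, iteration."""

import numpy as np
import pytest

from mitocharter import recruit
from mitocharter.recruit import (
    choose_seed, estimate_local_matches, recruit_iteratively, select_candidates,
)
from mitocharter.records import LocalMatch
from mitocharter.sequtil import revcomp


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[(("ACGT".index(out[i])) + 1 + rng.integers(0, 3)) % 4]
    return "".join(out)


class TestEstimateLocalMatches:
    def test_exact_substring_containment(self, rng):
        target = _random_seq(rng, 10_000)
        read = target[3_000:5_000]
        matches = estimate_local_matches(("r", read), {"t": target})
        assert matches
        best = matches[0]
        assert best.matched_length_bp >= 2_000 * 0.99
        assert best.identity_fraction == pytest.approx(1.0, abs=0.005)
        assert best.orientation == "forward"

    def test_reverse_strand_found(self, rng):
        target = _random_seq(rng, 8_000)
        read = revcomp(target[2_000:4_000])
        matches = estimate_local_matches(("r", read), {"t": target})
        assert matches and matches[0].orientation == "reverse"

    def test_unrelated_sequences_null(self):
        """No >= 50 bp match between independent random 10 kb sequences
        across repeated seeded trials."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            a, b = _random_seq(rng, 10_000), _random_seq(rng, 10_000)
            hits = estimate_local_matches(("r", a), {"t": b}, k=15)
            assert all(h.matched_length_bp < 50 for h in hits)

    def test_substituted_read_identity_matches_global_alignment_oracle(self, rng):
        target = _random_seq(rng, 10_000)
        read = _mutate(rng, target[2_000:4_000], 0.10)
        matches = estimate_local_matches(("r", read), {"t": target})
        assert matches
        got = matches[0].identity_fraction
        # oracle: Needleman-Wunsch identity of the planted interval
        from Bio import Align
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aln = aligner.align(read, target[2_000:4_000])[0]
        oracle = aln.counts().identities / aln.length
        assert got == pytest.approx(oracle, abs=0.03)
        assert got == pytest.approx(0.90, abs=0.03)

    def test_empty_inputs(self):
        assert estimate_local_matches(("r", ""), {"t": "ACGT" * 100}) == []
        assert estimate_local_matches(("r", "ACGT" * 100), {}) == []

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            estimate_local_matches(("r", "ACGT"), {"t": "ACGT"}, k=7)


class TestSelectCandidates:
    def test_full_gene_containment_is_candidate(self, rng):
        gene = _random_seq(rng, 1_500)
        read = _random_seq(rng, 2_000) + gene + _random_seq(rng, 2_000)
        cands = select_candidates({"r1": read}, {"g": gene})
        assert "r1" in cands

    def test_forty_bp_best_match_is_not_candidate(self, rng):
        gene = _random_seq(rng, 1_000)
        read = _random_seq(rng, 3_000) + gene[:40] + _random_seq(rng, 3_000)
        cands = select_candidates({"r1": read}, {"g": gene})
        assert "r1" not in cands

    def test_threshold_off_admits_any_match(self, rng):
        gene = _random_seq(rng, 1_000)
        read = _random_seq(rng, 1_000) + gene[:40] + _random_seq(rng, 1_000)
        cands = select_candidates({"r1": read}, {"g": gene}, min_match_bp=0)
        assert "r1" in cands

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            select_candidates({"r": "ACGT"}, {})


class TestChooseSeed:
    def _match(self, rid, gene, bp, ident=1.0):
        return LocalMatch(rid, gene, 0, bp, 0, bp, "forward", bp, ident)

    def test_more_genes_ranks_first(self):
        cands = {
            "B": [self._match("B", "g1", 1_000)],
            "A": [self._match("A", g, 300) for g in ("g1", "g2", "g3")],
        }
        assert choose_seed(cands)[0] == "A"

    def test_equal_genes_higher_weighted_bp_wins(self):
        cands = {
            "B": [self._match("B", "g1", 1_000, 0.8)],
            "A": [self._match("A", "g1", 1_000, 0.99)],
        }
        assert choose_seed(cands)[0] == "A"

    def test_single_candidate_is_seed(self):
        cands = {"only": [self._match("only", "g1", 100)]}
        assert choose_seed(cands) == ["only"]

    def test_tie_breaks_by_read_id(self):
        cands = {rid: [self._match(rid, "g1", 500)] for rid in ("b", "a")}
        assert choose_seed(cands)[0] == "a"

    def test_per_gene_covers_all_genes(self):
        cands = {
            "A": [self._match("A", "g1", 2_000)],
            "B": [self._match("B", "g2", 100)],
        }
        seeds = choose_seed(cands, per_gene=True)
        assert set(seeds) == {"A", "B"}

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="seed"):
            choose_seed({})


class TestRecruitIteratively:
    def test_sufficient_overlap_recruited_first_iteration(self, rng):
        seed = _random_seq(rng, 5_000)
        read = seed[-1_200:] + _random_seq(rng, 4_000)
        state = recruit_iteratively({"s": seed, "r": read}, ["s"])
        assert "r" in state.recruited
        assert state.additions_per_iteration[0] == 1

    def test_short_overlap_never_recruited(self, rng):
        seed = _random_seq(rng, 5_000)
        read = seed[-500:] + _random_seq(rng, 4_000)
        state = recruit_iteratively({"s": seed, "r": read}, ["s"])
        assert "r" not in state.recruited
        assert state.stop_reason == "fixpoint"

    def test_three_read_chain_recruits_transitively(self, rng):
        """seed -> R1 -> R2 chain: R2 joins in iteration 2, fixpoint after.

        Hand-constructed layout on a 12 kb template; every pairwise overlap
        is verifiable by direct substring identity.
        """
        template = _random_seq(rng, 12_000)
        seed = template[0:5_000]
        r1 = template[3_500:8_500]   # overlaps seed by 1.5 kb
        r2 = template[7_000:12_000]  # overlaps r1 by 1.5 kb, seed by 0
        assert seed[3_500:] == r1[:1_500]  # oracle: exact pairwise overlap
        assert r1[3_500:] == r2[:1_500]
        state = recruit_iteratively({"s": seed, "r1": r1, "r2": r2}, ["s"])
        assert state.recruited == {"s", "r1", "r2"}
        assert state.additions_per_iteration == [1, 1, 0]
        assert state.stop_reason == "fixpoint"

    def test_monotonicity_under_threshold_tightening(self, rng):
        template = _random_seq(rng, 30_000)
        pool = {f"r{i}": _mutate(rng, template[i * 2_000 : i * 2_000 + 6_000], 0.03)
                for i in range(12)}
        loose = recruit_iteratively(pool, ["r0"], min_overlap_bp=1_000,
                                    min_identity=0.70)
        tight_id = recruit_iteratively(pool, ["r0"], min_overlap_bp=1_000,
                                       min_identity=0.97)
        tight_ov = recruit_iteratively(pool, ["r0"], min_overlap_bp=5_000,
                                       min_identity=0.70)
        assert tight_id.recruited <= loose.recruited
        assert tight_ov.recruited <= loose.recruited

    def test_recruited_set_monotone_across_iterations(self, rng):
        template = _random_seq(rng, 20_000)
        pool = {f"r{i}": template[i * 1_500 : i * 1_500 + 4_000] for i in range(10)}
        state = recruit_iteratively(pool, ["r0"])
        assert all(n >= 0 for n in state.additions_per_iteration)
        assert state.additions_per_iteration[-1] == 0  # fixpoint proof

    def test_fixpoint_soundness(self, rng):
        """After fixpoint no unrecruited read satisfies the predicate."""
        template = _random_seq(rng, 20_000)
        pool = {f"r{i}": template[i * 1_500 : i * 1_500 + 4_000] for i in range(10)}
        pool["stray"] = _random_seq(rng, 4_000)
        state = recruit_iteratively(pool, ["r0"])
        assert state.stop_reason == "fixpoint"
        for rid in set(pool) - state.recruited:
            for tid in state.recruited:
                hits = estimate_local_matches((rid, pool[rid]),
                                              {tid: pool[tid]})
                assert not any(h.matched_length_bp >= 1_000
                               and h.identity_fraction >= 0.70 for h in hits)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            recruit_iteratively({"a": "ACGT"}, ["a"], max_iter=0)
        with pytest.raises(ValueError, match="not in pool"):
            recruit_iteratively({"a": "ACGT"}, ["missing"])
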