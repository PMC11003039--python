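"""Repeat detection: MISA semantics, tandem scoring, dispersed orientation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitocharter import repeatscan
from mitocharter.records import CircularSequence
from mitocharter.repeatscan import (
    canonical_motif, find_dispersed_repeats, find_ssrs, find_tandem_repeats,
    repeat_summary, ssr_class_summary,
)
from mitocharter.sequtil import revcomp


def _random_seq(rng, n, gc=0.44):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


class TestCanonicalMotif:
    @pytest.mark.parametrize("motif,expected", [
        ("GT", "AC/GT"),
        ("TTTG", "AAAC/GTTT"),
        ("AT", "AT/AT"),
        ("A", "A/T"),
        ("T", "A/T"),
        ("CT", "AG/CT"),
        ("AGAGG", "AGAGG/CCTCT"),
    ])
    def test_published_class_rendering(self, motif, expected):
        assert canonical_motif(motif) == expected

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            canonical_motif("AN")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=6))
    def test_rotation_and_complement_invariance(self, motif):
        cls = canonical_motif(motif)
        for i in range(len(motif)):
            assert canonical_motif(motif[i:] + motif[:i]) == cls
        assert canonical_motif(revcomp(motif)) == cls


class TestFindSsrs:
    def test_planted_monomer(self, rng):
        seq = _random_seq(rng, 500) + "G" + "A" * 12 + "G" + _random_seq(rng, 500)
        hits = [r for r in find_ssrs(seq) if r.unit_length == 1 and r.copy_number >= 10]
        assert any(r.motif == "A" and r.copy_number == 12 and
                   r.canonical_class == "A/T" for r in hits)

    def test_dimer_minimum_five_copies(self):
        background = "GGGG"
        assert any(r.canonical_class == "AC/GT" and r.copy_number == 5
                   for r in find_ssrs(background + "AC" * 5 + background))
        assert not find_ssrs(background + "AC" * 4 + background)

    def test_composite_run_reported_at_shortest_unit(self):
        seq = "GTGT" + "A" * 12 + "GTGT"
        hits = find_ssrs(seq)
        assert all(r.unit_length == 1 for r in hits if "A" in r.motif)

    def test_reverse_complement_invariance(self, small_sim):
        _cfg, chroms, _genes, _m = small_sim
        seq = chroms[0].seq
        fwd = find_ssrs(seq)
        rev = find_ssrs(revcomp(seq))
        assert sorted((r.canonical_class, r.copy_number) for r in fwd) == \
            sorted((r.canonical_class, r.copy_number) for r in rev)
        # coordinates mirror
        L = len(seq)
        assert sorted((L - r.end, L - r.start) for r in fwd) == \
            sorted((r.start, r.end) for r in rev)

    def test_planted_recovery_with_exact_coordinates(self, small_sim):
        _cfg, chroms, _genes, manifest = small_sim
        found = []
        for c in chroms:
            found += find_ssrs(c.seq, chrom=c.id, circular=True)
        for feat in manifest.of_kind("ssr"):
            assert any(r.chrom == feat["chrom"] and r.start == feat["start"]
                       and r.end == feat["end"]
                       and r.canonical_class == canonical_motif(feat["motif"])
                       for r in found), feat

    def test_no_ssr_below_minima(self, small_sim):
        _cfg, chroms, _genes, _m = small_sim
        params = repeatscan.DEFAULT_SSR_PARAMS
        for c in chroms:
            for r in find_ssrs(c.seq, chrom=c.id):
                assert r.copy_number >= params[r.unit_length]


class TestFindTandem:
    def test_perfect_nine_bp_array(self, rng):
        unit = "GATCCATGA"
        seq = _random_seq(rng, 300) + unit * 4 + _random_seq(rng, 300)
        hits = find_tandem_repeats(seq)
        assert len(hits) == 1
        t = hits[0]
        assert t.unit_length == 9 and t.percent_match == 1.0
        assert t.copy_number == pytest.approx(4.0, abs=0.3)

    def test_imperfect_twenty_bp_array(self, rng):
        unit = _random_seq(rng, 20)
        copy2 = unit[:7] + ("A" if unit[7] != "A" else "C") + unit[8:]
        seq = _random_seq(rng, 300) + unit + copy2 + unit + _random_seq(rng, 300)
        hits = find_tandem_repeats(seq)
        assert hits and hits[0].percent_match >= 0.9
        # oracle: direct per-copy comparison to the consensus unit
        array = unit + copy2 + unit
        direct = sum(array[i] == array[i % 20] for i in range(len(array))) / len(array)
        assert hits[0].percent_match == pytest.approx(direct, abs=0.08)

    def test_random_sequence_null(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            seq = _random_seq(rng, 1000)
            assert find_tandem_repeats(seq) == []

    def test_planted_recovery(self, small_sim):
        _cfg, chroms, _genes, manifest = small_sim
        found = []
        for c in chroms:
            found += find_tandem_repeats(c.seq, chrom=c.id, circular=True)
        for feat in manifest.of_kind("tandem"):
            match = [t for t in found if t.chrom == feat["chrom"]
                     and min(t.end, feat["end"]) - max(t.start, feat["start"])
                     > 0.8 * (feat["end"] - feat["start"])]
            assert match, feat
            assert match[0].unit_length == feat["unit_length"]
            assert match[0].percent_match >= 0.68


class TestFindDispersed:
    def test_forward_copy_between_chromosomes(self, rng):
        segment = _random_seq(rng, 100)
        a = CircularSequence("a", _random_seq(rng, 2000) + segment + _random_seq(rng, 2000))
        b = CircularSequence("b", _random_seq(rng, 1500) + segment + _random_seq(rng, 1500))
        hits = find_dispersed_repeats([a, b])
        fw = [h for h in hits if h.orientation == "forward"]
        assert fw and fw[0].length >= 100 and fw[0].identity == 1.0

    def test_palindromic_copy(self, rng):
        segment = _random_seq(rng, 100)
        a = CircularSequence("a", _random_seq(rng, 2000) + segment + _random_seq(rng, 2000))
        b = CircularSequence("b", _random_seq(rng, 1500) + revcomp(segment) + _random_seq(rng, 1500))
        hits = find_dispersed_repeats([a, b])
        assert any(h.orientation == "palindromic" and h.length >= 100 for h in hits)

    def test_identity_of_degraded_copy(self, rng):
        segment = _random_seq(rng, 200)
        degraded = list(segment)
        pos = rng.choice(200, size=10, replace=False)
        for p in pos:
            degraded[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[degraded[p]]
        a = CircularSequence("a", _random_seq(rng, 2000) + segment + _random_seq(rng, 2000))
        b = CircularSequence("b", _random_seq(rng, 1500) + "".join(degraded) + _random_seq(rng, 1500))
        hits = find_dispersed_repeats([a, b])
        assert hits and hits[0].identity == pytest.approx(0.95, abs=0.02)

    def test_no_mirrored_duplicates(self, small_sim):
        _cfg, chroms, _genes, _m = small_sim
        hits = find_dispersed_repeats(chroms)
        keys = set()
        for h in hits:
            key = frozenset([(h.chrom_a, h.start_a, h.end_a),
                             (h.chrom_b, h.start_b, h.end_b)])
            assert key not in keys
            keys.add(key)

    def test_orientation_flips_under_reverse_complement(self, rng):
        segment = _random_seq(rng, 120)
        a = CircularSequence("a", _random_seq(rng, 1500) + segment + _random_seq(rng, 1500))
        b = CircularSequence("b", _random_seq(rng, 1500) + segment + _random_seq(rng, 1500))
        before = {h.orientation for h in find_dispersed_repeats([a, b])}
        b_rc = CircularSequence("b", revcomp(b.seq))
        after = {h.orientation for h in find_dispersed_repeats([a, b_rc])}
        assert "forward" in before and "palindromic" in after


class TestSummary:
    def test_published_class_aggregation(self):
        counts = {"A/T": 53, "AC/GT": 24, "AAC/GTT": 29, "AAAC/GTTT": 53,
                  "AGAGG/CCTCT": 3}
        agg = ssr_class_summary(counts)
        assert agg["total"] == 162
        assert agg["unit_percent"]["monomer"] + agg["unit_percent"]["tetramer"] \
            == pytest.approx(65.43, abs=0.01)

    def test_empty_records(self):
        summary = repeat_summary([], [], [])
        assert summary["total"] == 0

    def test_totals_are_sums_of_parts(self, small_sim):
        _cfg, chroms, _genes, _m = small_sim
        ssrs, tandems = [], []
        for c in chroms:
            ssrs += find_ssrs(c.seq, chrom=c.id)
            tandems += find_tandem_repeats(c.seq, chrom=c.id)
        dispersed = find_dispersed_repeats(chroms, tandem_records=tandems)
        summary = repeat_summary(ssrs, tandems, dispersed, chroms)
        assert summary["total"] == len(ssrs) + len(tandems) + len(dispersed)
        assert sum(summary["dispersed_orientation"].values()) == len(dispersed)
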