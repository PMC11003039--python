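"""Repeat detection: SSRs, tandem arrays, and dispersed repeats.

Three repeat families are scanned with the conventions their canonical
tools established:

* SSRs (microsatellites) — maximal *perfect* tandem runs of a 1-6 bp unit,
  with per-unit minimum copy numbers (default ``1-10 2-5 3-4 4-3 5-3 6-3``),
  reported under a complement-aware canonical motif class (e.g. ``AC/GT``).
* Tandem repeats — arrays of a unit longer than 6 bp, allowing imperfect
  copies; candidate periods are seeded by exact self-matches at the period
  lag and scored with tandem-repeat-finder weights (match +2, mismatch -7),
  reporting arrays with match fraction >= 0.68 and score >= 50.
* Dispersed repeats — non-adjacent similar segment pairs found by seeded
  self-comparison of the genome (word size 7, both strands), labelled
  forward (same strand) or palindromic (reverse-complement match), with
  tandem-like and redundant hits removed.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from mitocharter.homology import find_local_hits
from mitocharter.records import CircularSequence, DispersedRecord, SsrRecord, TandemRecord
from mitocharter.sequtil import encode, revcomp

DEFAULT_SSR_PARAMS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}

TRF_MATCH = 2
TRF_MISMATCH = 7


def canonical_motif(motif: str) -> str:
    """Complement-aware canonical class of an SSR motif.

    The class representative is the lexicographic minimum over all rotations
    of the motif and of its reverse complement; it is paired with the
    minimum rotation of its own reverse complement, rendered ``"REP/MATE"``
    (e.g. GT -> "AC/GT", AGC -> "AGC/CTG", AT -> "AT/AT").
    """
    motif = motif.upper()
    if not 1 <= len(motif) <= 6 or not set(motif) <= set("ACGT"):
        raise ValueError(f"invalid SSR motif {motif!r}")

    def rotations(s: str) -> list[str]:
        return [s[i:] + s[:i] for i in range(len(s))]

    rc = revcomp(motif)
    rep = min(rotations(motif) + rotations(rc))
    mate = min(rotations(revcomp(rep)))
    return f"{rep}/{mate}"


def _primitive_period(s: str) -> int:
    for d in range(1, len(s)):
        if len(s) % d == 0 and s == s[: d] * (len(s) // d):
            return d
    return len(s)


def find_ssrs(seq: str, params: dict[int, int] | None = None, *,
              chrom: str = "", circular: bool = False) -> list[SsrRecord]:
    """Maximal perfect microsatellite runs meeting per-unit copy minima.

    A run whose motif is itself a repetition of a shorter motif is reported
    at the shortest unit only; runs fully contained in another run are
    dropped. On circular sequences an origin-spanning window (twice the
    longest admissible SSR seed span) is appended before scanning and
    duplicate wrap reports removed.
    """
    params = dict(params or DEFAULT_SSR_PARAMS)
    L = len(seq)
    scan_seq = seq.upper()
    if circular and L > 12:
        wrap = min(L - 1, 2 * max(u * params[u] for u in params))
        scan_seq = scan_seq + scan_seq[:wrap]
    codes = encode(scan_seq)
    records: list[SsrRecord] = []
    for unit in sorted(params):
        min_copies = params[unit]
        if len(codes) <= unit:
            continue
        m = (codes[unit:] == codes[:-unit]) & (codes[unit:] != 255)
        # maximal runs of lag-matches
        padded = np.concatenate(([False], m, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for a, b in zip(starts, ends):
            total = (b - a) + unit  # bases in the perfect run
            copies = total // unit
            if copies < min_copies:
                continue
            start = int(a)
            motif = scan_seq[start : start + unit]
            if _primitive_period(motif) != unit:
                continue  # reported at the shorter unit
            if start >= L:
                continue  # wrap duplicate
            records.append(SsrRecord(
                chrom=chrom, start=start, end=start + unit * copies,
                motif=motif, canonical_class=canonical_motif(motif),
                unit_length=unit, copy_number=int(copies)))
    # drop records fully contained in a longer record (MISA dedup)
    records.sort(key=lambda r: (r.start, -(r.end - r.start)))
    kept: list[SsrRecord] = []
    for r in records:
        if any(g.start <= r.start and r.end <= g.end and g is not r for g in kept):
            continue
        kept.append(r)
    return kept


def _extend_lag_run(m: np.ndarray, a: int, b: int, x_drop: int = 30) -> tuple[int, int, int]:
    """Greedy X-drop extension of a seed run [a, b) in the lag-match array.

    Returns (start, end, n_matches) of the best-scoring segment found.
    """
    n = len(m)
    # extend right
    best_j, score, best_score = b, 0, 0
    j = b
    while j < n and score > best_score - x_drop:
        score += TRF_MATCH if m[j] else -TRF_MISMATCH
        j += 1
        if score > best_score:
            best_score, best_j = score, j
    # extend left
    best_i, score, best_score = a, 0, 0
    i = a
    while i > 0 and score > best_score - x_drop:
        i -= 1
        score += TRF_MATCH if m[i] else -TRF_MISMATCH
        if score > best_score:
            best_score, best_i = score, i
    matches = int(np.count_nonzero(m[best_i:best_j]))
    return best_i, best_j, matches


def find_tandem_repeats(seq: str, *, min_unit: int = 7, max_unit: int = 120,
                        min_match: float = 0.68, min_score: int = 50,
                        seed_len: int = 7, chrom: str = "",
                        circular: bool = False) -> list[TandemRecord]:
    """Imperfect tandem arrays with unit length > 6 bp.

    Candidate periods are positions where the sequence matches itself at lag
    p over a seed of ``seed_len`` exact matches, extended by X-drop under
    the +2/-7 match/mismatch weights. Overlapping reports of the same array
    at different periods are merged to the highest-scoring (then shortest)
    period; arrays whose consensus is itself a repeat of a <=6 bp unit are
    left to the SSR scanner.
    """
    L = len(seq)
    scan_seq = seq.upper()
    if circular and L > 2 * min_unit:
        wrap = min(L - 1, 2 * max_unit * 4)
        scan_seq = scan_seq + scan_seq[:wrap]
    codes = encode(scan_seq)
    candidates: list[tuple[int, TandemRecord]] = []
    for p in range(min_unit, min(max_unit, len(codes) // 2) + 1):
        m = (codes[p:] == codes[:-p]) & (codes[p:] != 255)
        if not m.any():
            continue
        padded = np.concatenate(([False], m, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        long_enough = (ends - starts) >= seed_len
        seen_until = -1
        for a, b in zip(starts[long_enough], ends[long_enough]):
            if a < seen_until:
                continue
            i, j, matches = _extend_lag_run(m, int(a), int(b))
            seen_until = j
            run = j - i
            if run < p:  # fewer than 2 copies
                continue
            # score over the full array: lag matches plus one period of
            # definitional matches (the first copy), TRF-style
            score = TRF_MATCH * (matches + p) - TRF_MISMATCH * (run - matches)
            pm = matches / run
            if score < min_score or pm < min_match:
                continue
            start, end = i, j + p
            if start >= L:
                continue
            consensus = _consensus_unit(scan_seq[start:end], p)
            if _primitive_period(consensus) <= 6:
                continue
            candidates.append((score, TandemRecord(
                chrom=chrom, start=start, end=end, unit_length=p,
                copy_number=round((end - start) / p, 1),
                percent_match=pm, consensus=consensus)))
    return _merge_tandem(candidates)


def _consensus_unit(array: str, p: int) -> str:
    cols = [Counter() for _ in range(p)]
    for i, base in enumerate(array):
        cols[i % p][base] += 1
    return "".join(c.most_common(1)[0][0] for c in cols)


def _merge_tandem(candidates: list[tuple[int, TandemRecord]]) -> list[TandemRecord]:
    # smallest valid period first: a doubled-period reading of the same
    # array always exists and would otherwise mask the primitive unit
    candidates.sort(key=lambda c: (c[1].unit_length, -c[0], c[1].start))
    kept: list[TandemRecord] = []
    for _score, rec in candidates:
        overlap = False
        for g in kept:
            if g.chrom != rec.chrom:
                continue
            inter = min(g.end, rec.end) - max(g.start, rec.start)
            if inter > 0.5 * min(g.end - g.start, rec.end - rec.start):
                overlap = True
                break
        if not overlap:
            kept.append(rec)
    kept.sort(key=lambda r: (r.chrom, r.start))
    return kept


def find_dispersed_repeats(chromosomes: list[CircularSequence], *,
                           min_len: int = 27, min_identity: float = 0.90,
                           max_e: float = 1e-5, word_size: int = 7,
                           tandem_records: list[TandemRecord] | None = None,
                           ) -> list[DispersedRecord]:
    """Forward and palindromic dispersed repeats within/between chromosomes.

    Tandem-like hits (same-chromosome forward hits whose intervals overlap
    or nearly abut) and hits covering a supplied tandem array are removed;
    reciprocal duplicates are collapsed so each segment pair is reported
    once. The E-value search space is the product of the two compared
    chromosome lengths (per-comparison, as in a pairwise scan) — a
    genome-wide space would push even perfect ~27 bp copies above the
    default E cutoff.
    """
    tandem_by_chrom: dict[str, list[TandemRecord]] = {}
    for t in tandem_records or []:
        tandem_by_chrom.setdefault(t.chrom, []).append(t)
    records: list[DispersedRecord] = []
    n = len(chromosomes)
    for i in range(n):
        for j in range(i, n):
            a, b = chromosomes[i], chromosomes[j]
            hits = find_local_hits(
                a.seq, b.seq, k=word_size, max_gap=40, band=20, min_seeds=3,
                min_len=min_len, min_identity=min_identity, max_e=max_e,
                search_space=float(len(a)) * float(len(b)),
                self_compare=(i == j))
            for h in hits:
                orientation = "forward" if h.strand == "+" else "palindromic"
                if i == j and orientation == "forward":
                    gap = max(h.t_start, h.q_start) - min(h.t_end, h.q_end)
                    if gap < 10:  # adjacent/overlapping copies = tandem, not dispersed
                        continue
                if _covers_tandem(a.id, h.q_start, h.q_end, tandem_by_chrom) or \
                        _covers_tandem(b.id, h.t_start, h.t_end, tandem_by_chrom):
                    continue
                records.append(DispersedRecord(
                    chrom_a=a.id, start_a=h.q_start, end_a=h.q_end,
                    chrom_b=b.id, start_b=h.t_start, end_b=h.t_end,
                    orientation=orientation, length=h.length,
                    identity=h.identity, e_value=h.e_value))
    records.sort(key=lambda r: (r.chrom_a, r.start_a, r.chrom_b, r.start_b))
    return records


def _covers_tandem(chrom: str, start: int, end: int,
                   tandem_by_chrom: dict[str, list[TandemRecord]]) -> bool:
    for t in tandem_by_chrom.get(chrom, []):
        inter = min(end, t.end) - max(start, t.start)
        if inter > 0.8 * (t.end - t.start):
            return True
    return False


def ssr_class_summary(class_counts: dict[str, int]) -> dict:
    """Aggregate an SSR tally keyed by canonical class into per-unit totals.

    Returns per-unit-length counts (monomer..hexamer), the grand total, and
    each unit class's percentage share.
    """
    unit_names = {1: "monomer", 2: "dimer", 3: "trimer", 4: "tetramer",
                  5: "pentamer", 6: "hexamer"}
    by_unit: Counter = Counter()
    for cls, count in class_counts.items():
        unit = len(cls.split("/")[0])
        by_unit[unit_names[unit]] += count
    total = sum(class_counts.values())
    share = {name: (100.0 * c / total if total else 0.0) for name, c in by_unit.items()}
    return {"unit_counts": dict(by_unit), "total": total, "unit_percent": share}


def repeat_summary(ssrs: list[SsrRecord], tandems: list[TandemRecord],
                   dispersed: list[DispersedRecord],
                   chromosomes: list[CircularSequence] | None = None) -> dict:
    """Genome-wide repeat totals, SSR class breakdown, per-chromosome counts
    and the dispersed-repeat length histogram (10-bp bins from 20 bp)."""
    class_counts = Counter(r.canonical_class for r in ssrs)
    per_chrom: dict[str, dict[str, int]] = {}
    chrom_ids = [c.id for c in chromosomes] if chromosomes else []
    for cid in chrom_ids:
        per_chrom[cid] = {"ssr": 0, "tandem": 0, "dispersed": 0}
    for r in ssrs:
        per_chrom.setdefault(r.chrom, {"ssr": 0, "tandem": 0, "dispersed": 0})["ssr"] += 1
    for t in tandems:
        per_chrom.setdefault(t.chrom, {"ssr": 0, "tandem": 0, "dispersed": 0})["tandem"] += 1
    hist: Counter = Counter()
    orient: Counter = Counter()
    for d in dispersed:
        per_chrom.setdefault(d.chrom_a, {"ssr": 0, "tandem": 0, "dispersed": 0})["dispersed"] += 1
        orient[d.orientation] += 1
        lo = max(20, 10 * (d.length // 10))
        hist[f"{lo}-{lo + 9}"] += 1
    return {
        "n_ssr": len(ssrs),
        "n_tandem": len(tandems),
        "n_dispersed": len(dispersed),
        "total": len(ssrs) + len(tandems) + len(dispersed),
        "ssr_classes": ssr_class_summary(dict(class_counts)),
        "ssr_class_counts": dict(class_counts),
        "dispersed_orientation": dict(orient),
        "dispersed_length_hist": dict(sorted(hist.items(), key=lambda kv: int(kv[0].split("-")[0]))),
        "per_chromosome": per_chrom,
    }
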