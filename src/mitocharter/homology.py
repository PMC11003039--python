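"""Seeded local-similarity engine shared by read recruitment, dispersed-repeat
detection, and inter-genome homologous-fragment search.

The algorithm is classic seed-chain-verify:

1. exact k-mer seed matching between query and target (both strands);
2. clustering of seed hits on (near-)identical diagonals, allowing a
   configurable positional gap and a diagonal band for small indels;
3. verification of each chained candidate window with a global edit-distance
   alignment (edlib); terminal non-matching columns are trimmed so reported
   intervals cover the aligned homologous core only;
4. screening on alignment length, identity (matches / alignment columns,
   gap columns included) and a Karlin-Altschul E-value.

Scoring for the E-value uses the blastn default reward/penalty (+2/-3) with
the corresponding ungapped Karlin-Altschul parameters (lambda = 0.625,
K = 0.41); gap columns are scored as mismatches. The search space is the
product of the two sequence lengths (per strand).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import edlib
import numpy as np

from mitocharter.sequtil import kmer_codes, revcomp

KA_LAMBDA = 0.625
KA_K = 0.41
MATCH_REWARD = 2
MISMATCH_PENALTY = 3

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class RawHit:
    """One verified local alignment between two sequences."""

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str  # '+' or '-'
    length: int  # alignment columns
    matches: int
    identity: float
    score: float
    e_value: float


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _trim_terminal(ops: list[tuple[int, str]]) -> tuple[list[tuple[int, str]], int, int, int, int]:
    """Strip non-match columns from both ends; return trimmed ops and the
    number of (query, target) bases consumed at the head and tail."""
    head_q = head_t = tail_q = tail_t = 0
    lo, hi = 0, len(ops)
    while lo < hi and ops[lo][1] != "=":
        n, op = ops[lo]
        if op in "XM":
            head_q += n
            head_t += n
        elif op == "I":  # consumes query
            head_q += n
        elif op == "D":  # consumes target
            head_t += n
        lo += 1
    while hi > lo and ops[hi - 1][1] != "=":
        n, op = ops[hi - 1]
        if op in "XM":
            tail_q += n
            tail_t += n
        elif op == "I":
            tail_q += n
        elif op == "D":
            tail_t += n
        hi -= 1
    return ops[lo:hi], head_q, head_t, tail_q, tail_t


def _cluster_seeds(qpos: np.ndarray, tpos: np.ndarray, max_gap: int, band: int,
                   min_seeds: int) -> list[tuple[int, int, int, int, int]]:
    """Chain seed hits into candidate regions.

    Returns (q_lo, q_hi, t_lo, t_hi, n_seeds) tuples where hi is the last
    seed start (exclusive of k). Hits are first clustered on exact diagonals,
    then nearby diagonal clusters (|ddiag| <= band) with overlapping or
    nearly adjacent query spans are merged. Exact-diagonal component
    clusters are returned alongside the merged ones: a stray seed merged
    into a genuine cluster would otherwise widen its verification window
    and dilute the measured identity.
    """
    if len(qpos) == 0:
        return []
    diag = qpos.astype(np.int64) - tpos.astype(np.int64)
    order = np.lexsort((qpos, diag))
    qs, ts, ds = qpos[order], tpos[order], diag[order]
    # split where the diagonal changes or the query gap exceeds max_gap
    brk = np.flatnonzero((np.diff(ds) != 0) | (np.diff(qs) > max_gap)) + 1
    bounds = np.concatenate(([0], brk, [len(qs)]))
    clusters = []
    for i in range(len(bounds) - 1):
        a, b = bounds[i], bounds[i + 1]
        clusters.append([int(qs[a]), int(qs[b - 1]), int(ts[a]), int(ts[b - 1]),
                         int(b - a), int(ds[a])])
    exact = [(c[0], c[1], c[2], c[3], c[4]) for c in clusters
             if c[4] >= min_seeds]
    # merge clusters on nearby diagonals with close query spans
    clusters.sort(key=lambda c: (c[0], c[5]))
    merged: list[list[int]] = []
    for c in clusters:
        hit = None
        for m in reversed(merged):
            if c[0] - m[1] > max_gap:
                break
            if abs(c[5] - m[5]) <= band:
                hit = m
                break
        if hit is None:
            merged.append(c)
        else:
            hit[1] = max(hit[1], c[1])
            hit[0] = min(hit[0], c[0])
            hit[2] = min(hit[2], c[2])
            hit[3] = max(hit[3], c[3])
            hit[4] += c[4]
    out = {(q0, q1, t0, t1): n for q0, q1, t0, t1, n in exact}
    for c in merged:
        if c[4] >= min_seeds:
            out.setdefault((c[0], c[1], c[2], c[3]), c[4])
    return [(q0, q1, t0, t1, n) for (q0, q1, t0, t1), n in out.items()]


def _verify(query: str, target: str, q_lo: int, q_hi: int, t_lo: int, t_hi: int,
            k: int, pad: int, x_drop: int = 12,
            ) -> tuple[int, int, int, int, int, int] | None:
    """Align and extend the candidate region; return trimmed
    (q_start, q_end, t_start, t_end, columns, matches).

    The seed-chained core is located within a padded target window by infix
    (HW) alignment, so window padding never contributes alignment columns;
    the flanks beyond the outermost seeds are then grown by ungapped X-drop
    extension under the +2/-3 scoring."""
    qa, qb = q_lo, min(len(query), q_hi + k)
    ta, tb = max(0, t_lo - pad), min(len(target), t_hi + k + pad)
    res = edlib.align(query[qa:qb], target[ta:tb], mode="HW", task="path")
    cigar = res.get("cigar")
    if not cigar or not res.get("locations"):
        return None
    loc_start, _loc_end = res["locations"][0]
    if loc_start is None:
        loc_start = 0
    ops, hq, ht, _tq, _tt = _trim_terminal(_parse_cigar(cigar))
    if not ops:
        return None
    cols = sum(n for n, _ in ops)
    matches = sum(n for n, op in ops if op == "=")
    q_start = qa + hq
    q_end = q_start + sum(n for n, op in ops if op in "=XMI")
    t_start = ta + loc_start + ht
    t_end = t_start + sum(n for n, op in ops if op in "=XMD")
    # ungapped X-drop extension of both flanks
    for step in (-1, +1):
        qi = q_start - 1 if step < 0 else q_end
        ti = t_start - 1 if step < 0 else t_end
        score = best = 0
        best_cols = best_matches = ext_cols = ext_matches = 0
        while 0 <= qi < len(query) and 0 <= ti < len(target):
            if query[qi] == target[ti]:
                score += MATCH_REWARD
                ext_matches += 1
            else:
                score -= MISMATCH_PENALTY
            ext_cols += 1
            if score > best:
                best, best_cols, best_matches = score, ext_cols, ext_matches
            elif score < best - x_drop:
                break
            qi += step
            ti += step
        cols += best_cols
        matches += best_matches
        if step < 0:
            q_start -= best_cols
            t_start -= best_cols
        else:
            q_end += best_cols
            t_end += best_cols
    return q_start, q_end, t_start, t_end, cols, matches


def find_local_hits(
    query: str,
    target: str,
    *,
    k: int = 11,
    max_gap: int = 500,
    band: int = 50,
    min_seeds: int = 2,
    min_len: int = 30,
    min_identity: float = 0.70,
    max_e: float | None = None,
    search_space: float | None = None,
    both_strands: bool = True,
    self_compare: bool = False,
) -> list[RawHit]:
    """All verified local alignments between ``query`` and ``target``.

    ``self_compare=True`` (query is target) suppresses the trivial identity
    diagonal and mirrored duplicates (only hits with q_start <= t_start are
    kept on the forward strand; palindromic self-hits are canonicalized).
    """
    hits: list[RawHit] = []
    if not query or not target:
        return hits
    if search_space is None:
        search_space = float(len(query)) * float(len(target))
    qk = kmer_codes(query, k)
    if qk.size == 0:
        return hits
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        tseq = target if strand == "+" else revcomp(target)
        tk = kmer_codes(tseq, k)
        if tk.size == 0:
            continue
        t_order = np.argsort(tk, kind="stable")
        tk_sorted = tk[t_order]
        valid = qk >= 0
        lo = np.searchsorted(tk_sorted, qk, side="left")
        hi = np.searchsorted(tk_sorted, qk, side="right")
        counts = np.where(valid, hi - lo, 0)
        total = int(counts.sum())
        if total == 0:
            continue
        qpos = np.repeat(np.arange(len(qk)), counts)
        # gather target positions for each query k-mer occurrence
        offsets = np.concatenate([np.arange(l, h) for l, h, c in
                                  zip(lo, hi, counts) if c > 0]) if total else np.empty(0, int)
        tpos = t_order[offsets]
        if self_compare and strand == "+":
            keep = qpos != tpos
            qpos, tpos = qpos[keep], tpos[keep]
        for q_lo, q_hi, t_lo, t_hi, _n in _cluster_seeds(qpos, tpos, max_gap, band, min_seeds):
            ver = _verify(query, tseq, q_lo, q_hi, t_lo, t_hi, k, pad=k)
            if ver is None:
                continue
            qs, qe, ts, te, cols, matches = ver
            if cols < min_len:
                continue
            identity = matches / cols
            if identity < min_identity:
                continue
            score = MATCH_REWARD * matches - MISMATCH_PENALTY * (cols - matches)
            e_value = KA_K * search_space * math.exp(-KA_LAMBDA * max(score, 0.0))
            if max_e is not None and e_value > max_e:
                continue
            if strand == "-":
                ts, te = len(target) - te, len(target) - ts
            if self_compare:
                if strand == "+" and qs == ts and qe == te:
                    continue  # residual self-identity
                if qs > ts or (qs == ts and qe > te):
                    qs, qe, ts, te = ts, te, qs, qe
            hits.append(RawHit(qs, qe, ts, te, strand, cols, matches, identity,
                               score, e_value))
    return _dedupe(hits)


def _dedupe(hits: list[RawHit]) -> list[RawHit]:
    """Collapse duplicate/contained reports of the same region pair."""
    hits.sort(key=lambda h: (-h.length * h.identity, h.q_start, h.t_start))
    kept: list[RawHit] = []
    for h in hits:
        redundant = False
        for g in kept:
            if g.strand != h.strand:
                continue
            if (g.q_start <= h.q_start and h.q_end <= g.q_end
                    and g.t_start <= h.t_start and h.t_end <= g.t_end):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.q_start, h.q_end, h.t_start))
    return kept
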