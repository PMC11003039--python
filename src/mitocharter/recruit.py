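"""Iterative seed-extension recruitment of mitochondrial long reads.

The organelle fraction of a mixed long-read pool is recovered the way
organelle assemblers bait reads: reads sharing a similar fragment longer
than 50 bp with a conserved mitochondrial core gene become candidates, the
candidates matching the most genes at the highest alignment quality become
seeds, and the seed set then grows iteratively — any read overlapping a
recruited read by at least 1 kb at >= 70% identity joins — until a fixpoint
(or an iteration cap) is reached.

"Overlap" means the matched alignment span, not a proper dovetail, so
contained reads are recruited too; identity is matches / alignment columns
including gap columns.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from mitocharter.homology import _cluster_seeds, _verify
from mitocharter.records import LocalMatch, RecruitmentState
from mitocharter.sequtil import kmer_codes, revcomp

DEFAULT_K = 15
DEFAULT_BAND = 50
DEFAULT_MAX_GAP = 500


def _as_read_dict(reads) -> dict[str, str]:
    if isinstance(reads, dict):
        return reads
    out = {}
    for item in reads:
        rid, seq = item[0], item[1]
        out[rid] = seq
    return out


def estimate_local_matches(read: tuple[str, str], targets, *, k: int = DEFAULT_K,
                           band: int = DEFAULT_BAND, max_gap: int = DEFAULT_MAX_GAP,
                           min_seeds: int = 2) -> list[LocalMatch]:
    """Maximal chained local matches of one read against target sequences.

    Both strands are searched; each match reports the matched alignment
    length and identity (matches / alignment columns). Empty read or target
    set yields an empty list.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    rid, rseq = read
    targets = _as_read_dict(targets)
    matches: list[LocalMatch] = []
    if not rseq or not targets:
        return matches
    qk = kmer_codes(rseq, k)
    if qk.size == 0:
        return matches
    for tid, tseq in targets.items():
        for strand, ts in (("forward", tseq), ("reverse", revcomp(tseq))):
            tk = kmer_codes(ts, k)
            if tk.size == 0:
                continue
            order = np.argsort(tk, kind="stable")
            tk_sorted = tk[order]
            lo = np.searchsorted(tk_sorted, qk, side="left")
            hi = np.searchsorted(tk_sorted, qk, side="right")
            counts = np.where(qk >= 0, hi - lo, 0)
            if counts.sum() == 0:
                continue
            qpos = np.repeat(np.arange(len(qk)), counts)
            offsets = np.concatenate([np.arange(l, h) for l, h, c in
                                      zip(lo, hi, counts) if c > 0])
            tpos = order[offsets]
            for q_lo, q_hi, t_lo, t_hi, _n in _cluster_seeds(
                    qpos, tpos, max_gap, band, min_seeds):
                ver = _verify(rseq, ts, q_lo, q_hi, t_lo, t_hi, k, pad=k)
                if ver is None:
                    continue
                qs, qe, tstart, tend, cols, n_match = ver
                if strand == "reverse":
                    tstart, tend = len(tseq) - tend, len(tseq) - tstart
                matches.append(LocalMatch(
                    read_id=rid, target_id=tid, read_start=qs, read_end=qe,
                    target_start=tstart, target_end=tend, orientation=strand,
                    matched_length_bp=cols, identity_fraction=n_match / cols))
    matches.sort(key=lambda m: (-m.matched_length_bp * m.identity_fraction,
                                m.target_id, m.read_start))
    return matches


def select_candidates(reads, core_genes, *, min_match_bp: int = 50,
                      k: int = DEFAULT_K) -> dict[str, list[LocalMatch]]:
    """Reads with a similar fragment longer than ``min_match_bp`` against
    any core gene. Returns candidate read id -> its gene matches."""
    genes = _as_read_dict(core_genes)
    if not genes:
        raise ValueError("core gene set must be non-empty")
    candidates: dict[str, list[LocalMatch]] = {}
    for rid, rseq in _as_read_dict(reads).items():
        hits = [m for m in estimate_local_matches((rid, rseq), genes, k=k)
                if m.matched_length_bp > min_match_bp]
        if hits:
            candidates[rid] = hits
    return candidates


def choose_seed(candidates: dict[str, list[LocalMatch]], *,
                n_seeds: int = 1, per_gene: bool = False) -> list[str]:
    """Rank candidates by (distinct genes matched, identity-weighted matched
    bp) descending, read id as the deterministic tie-break.

    ``per_gene=True`` additionally keeps, for every core gene, the
    best-ranked candidate matching it — on a multichromosomal genome this
    guarantees the seed set touches every chromosome that carries a core
    gene, which a single top-ranked seed need not.
    """
    if not candidates:
        raise ValueError("no candidate reads: cannot choose a seed")

    def rank_key(rid: str):
        return (
            -len({m.target_id for m in candidates[rid]}),
            -sum(m.matched_length_bp * m.identity_fraction for m in candidates[rid]),
            rid,
        )

    ranked = sorted(candidates, key=rank_key)
    if not per_gene:
        return ranked[:n_seeds] if n_seeds else ranked
    seeds: list[str] = []
    covered: set[str] = set()
    for rid in ranked:
        genes = {m.target_id for m in candidates[rid]}
        if genes - covered or len(seeds) < n_seeds:
            seeds.append(rid)
            covered |= genes
    return seeds


class _KmerIndex:
    """Incrementally built k-mer index over recruited reads."""

    def __init__(self, k: int):
        self.k = k
        self.index: dict[int, list[tuple[str, int]]] = defaultdict(list)
        self.seqs: dict[str, str] = {}

    def add(self, rid: str, seq: str) -> None:
        self.seqs[rid] = seq
        for pos, code in enumerate(kmer_codes(seq, self.k)):
            if code >= 0:
                self.index[int(code)].append((rid, pos))

    def query(self, seq: str) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
        """Seed hits of ``seq`` (both orientations) grouped by (read, strand)."""
        grouped: dict[tuple[str, str], tuple[list[int], list[int]]] = defaultdict(
            lambda: ([], []))
        for strand, s in (("forward", seq), ("reverse", revcomp(seq))):
            for qpos, code in enumerate(kmer_codes(s, self.k)):
                if code < 0:
                    continue
                for rid, tpos in self.index.get(int(code), ()):
                    qp, tp = grouped[(rid, strand)]
                    qp.append(qpos)
                    tp.append(tpos)
        return {key: (np.array(qp), np.array(tp))
                for key, (qp, tp) in grouped.items()}


def recruit_iteratively(reads, seed_ids, *, min_overlap_bp: int = 1000,
                        min_identity: float = 0.70, max_iter: int = 50,
                        k: int = DEFAULT_K, band: int = DEFAULT_BAND,
                        max_gap: int = DEFAULT_MAX_GAP) -> RecruitmentState:
    """Grow the recruited set until fixpoint or ``max_iter``.

    Each iteration adds every unrecruited read that matches some read
    recruited in a *previous* iteration with alignment span >=
    ``min_overlap_bp`` and identity >= ``min_identity`` — a breadth-first
    sweep, so the result does not depend on read order within an iteration.
    """
    if max_iter <= 0:
        raise ValueError("max_iter must be positive")
    pool = _as_read_dict(reads)
    missing = set(seed_ids) - set(pool)
    if missing:
        raise ValueError(f"seed reads not in pool: {sorted(missing)[:3]}")
    state = RecruitmentState(recruited=set(seed_ids))
    index = _KmerIndex(k)
    for rid in sorted(state.recruited):
        index.add(rid, pool[rid])
    # reads too short to ever satisfy the overlap threshold can be skipped
    pending = {rid for rid in pool if rid not in state.recruited
               and len(pool[rid]) >= min_overlap_bp}
    min_seed_span = max(k, int(min_overlap_bp * 0.3))
    for _ in range(max_iter):
        state.iterations += 1
        newly: list[str] = []
        for rid in sorted(pending):
            rseq = pool[rid]
            if _matches_recruited(rseq, index, min_overlap_bp, min_identity,
                                  max_gap, band, k, min_seed_span):
                newly.append(rid)
        state.additions_per_iteration.append(len(newly))
        if not newly:
            state.stop_reason = "fixpoint"
            return state
        for rid in newly:
            state.recruited.add(rid)
            pending.discard(rid)
            index.add(rid, pool[rid])
    state.stop_reason = "max_iter"
    return state


def _matches_recruited(rseq: str, index: _KmerIndex, min_overlap: int,
                       min_identity: float, max_gap: int, band: int, k: int,
                       min_seed_span: int) -> bool:
    for (tid, strand), (qpos, tpos) in index.query(rseq).items():
        tseq = index.seqs[tid] if strand == "forward" else revcomp(index.seqs[tid])
        for q_lo, q_hi, t_lo, t_hi, _n in _cluster_seeds(
                qpos, tpos, max_gap, band, min_seeds=3):
            if (q_hi - q_lo) + k < min_seed_span:
                continue
            ver = _verify(rseq, tseq, q_lo, q_hi, t_lo, t_hi, k, pad=k)
            if ver is None:
                continue
            _qs, _qe, _ts, _te, cols, n_match = ver
            if cols >= min_overlap and n_match / cols >= min_identity:
                return True
    return False
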