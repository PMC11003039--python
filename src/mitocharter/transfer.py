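"""Intracellular DNA-transfer detection between genome pairs.

Finds local homologous fragments between a (multichromosomal) query genome
and a subject genome — mitochondrial vs plastid for MTPT detection,
mitochondrial vs nuclear for NUMT-analogue detection — with BLAST-style
screening thresholds (identity >= 70%, length >= 30 bp, E <= 1e-5 by
default), merges fragment coverage on the query axis, tests which annotated
genes lie fully inside homologous regions, and emits >= 300 bp synteny
blocks for collinearity/dot-plot rendering.
"""

from __future__ import annotations

from typing import Iterable, Iterator

from mitocharter.homology import find_local_hits
from mitocharter.records import CircularSequence, GeneModel, HomologyFragment


def _as_list(genome) -> list[CircularSequence]:
    if isinstance(genome, CircularSequence):
        return [genome]
    return list(genome)


def find_homologous_fragments(
    genome_a,
    genome_b,
    *,
    min_identity: float = 0.70,
    min_len: int = 30,
    max_e: float = 1e-5,
    word_size: int = 9,
) -> list[HomologyFragment]:
    """All local similarity fragments between two genomes passing the
    identity / length / E-value screen, both strands.

    The E-value search space is the product of the two genome lengths.
    Ordering is deterministic: query chromosome and coordinate, then
    subject. Subject chromosomes are streamed one at a time, so memory is
    constant in the number of subject chromosomes.
    """
    qchroms = _as_list(genome_a)
    schroms = _as_list(genome_b)
    if not qchroms or not schroms:
        raise ValueError("both genomes must be non-empty")
    space = float(sum(len(c) for c in qchroms)) * float(sum(len(c) for c in schroms))
    fragments: list[HomologyFragment] = []
    for sub in schroms:
        for qry in qchroms:
            hits = find_local_hits(
                qry.seq, sub.seq, k=word_size, max_gap=60, band=30, min_seeds=2,
                min_len=min_len, min_identity=min_identity, max_e=max_e,
                search_space=space, self_compare=False)
            for h in hits:
                fragments.append(HomologyFragment(
                    query_chrom=qry.id, query_start=h.q_start, query_end=h.q_end,
                    subject_chrom=sub.id, subject_start=h.t_start,
                    subject_end=h.t_end,
                    orientation="forward" if h.strand == "+" else "reverse",
                    length_bp=h.length, identity_fraction=h.identity,
                    e_value=h.e_value))
    fragments.sort(key=lambda f: (f.query_chrom, f.query_start, f.query_end,
                                  f.subject_chrom, f.subject_start))
    return fragments


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def merged_coverage(fragments: Iterable[HomologyFragment], genome) -> dict:
    """Overlap-merged fragment coverage on the query genome.

    Returns per-chromosome covered bp and fraction plus genome-wide totals;
    merging makes the combined length well-defined when fragments overlap.
    """
    chroms = {c.id: len(c) for c in _as_list(genome)}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in fragments:
        if f.query_chrom not in chroms:
            raise ValueError(f"fragment on unknown chromosome {f.query_chrom!r}")
        if f.query_start < 0 or f.query_end > chroms[f.query_chrom]:
            raise ValueError(
                f"fragment [{f.query_start},{f.query_end}) outside {f.query_chrom!r}")
        by_chrom.setdefault(f.query_chrom, []).append((f.query_start, f.query_end))
    per_chrom = {}
    total_cov = 0
    for cid, length in chroms.items():
        merged = _merge_intervals(by_chrom.get(cid, []))
        cov = sum(e - s for s, e in merged)
        total_cov += cov
        per_chrom[cid] = {"length": length, "covered_bp": cov,
                          "fraction": cov / length, "intervals": merged}
    genome_len = sum(chroms.values())
    unmerged = sum(e - s for ivs in by_chrom.values() for s, e in ivs)
    return {
        "per_chromosome": per_chrom,
        "covered_bp": total_cov,
        "genome_length": genome_len,
        "fraction": total_cov / genome_len,
        "unmerged_total_bp": unmerged,
        "n_chromosomes_hit": sum(1 for v in per_chrom.values() if v["covered_bp"] > 0),
    }


def genes_fully_contained(fragments: Iterable[HomologyFragment],
                          gene_models: Iterable[GeneModel],
                          ) -> list[tuple[GeneModel, float]]:
    """Genes whose full span lies inside a single merged homologous region.

    Each reported gene carries the best identity among fragments overlapping
    it.
    """
    frags = list(fragments)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in frags:
        by_chrom.setdefault(f.query_chrom, []).append((f.query_start, f.query_end))
    merged = {cid: _merge_intervals(ivs) for cid, ivs in by_chrom.items()}
    out = []
    for gene in gene_models:
        regions = merged.get(gene.chrom, [])
        if not any(s <= gene.start and gene.end <= e for s, e in regions):
            continue
        identities = [f.identity_fraction for f in frags
                      if f.query_chrom == gene.chrom
                      and min(f.query_end, gene.end) > max(f.query_start, gene.start)]
        out.append((gene, max(identities)))
    return out


def synteny_blocks(genome_a, genome_b, *, min_block: int = 300,
                   min_identity: float = 0.70, max_e: float = 1e-5,
                   word_size: int = 11) -> list[HomologyFragment]:
    """Collinearity blocks (>= ``min_block`` bp) for dot-plot export, with
    forward/reverse orientation labels, sorted by query then subject."""
    return find_homologous_fragments(
        genome_a, genome_b, min_identity=min_identity, min_len=min_block,
        max_e=max_e, word_size=word_size)
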