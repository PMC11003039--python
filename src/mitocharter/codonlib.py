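"""Codon-usage statistics for protein-coding genes.

Covers codon counting, positional GC content (GC1/GC2/GC3), relative
synonymous codon usage (RSCU), Wright's effective number of codons (Nc),
and start/stop-codon tallies. The standard genetic code is used throughout
(plant mitochondria translate with the standard code).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from mitocharter.sequtil import CODON_TABLE, STOP_CODONS, SYNONYMOUS_FAMILIES

#: degeneracy of each amino-acid family under the standard code
FAMILY_SIZES = {aa: len(codons) for aa, codons in SYNONYMOUS_FAMILIES.items()}


@dataclass
class CodonUsageTable:
    """Per-codon counts over the 64 DNA codons, stops tallied separately."""

    counts: Counter = field(default_factory=Counter)
    stop_counts: Counter = field(default_factory=Counter)

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())


@dataclass
class CodonStats:
    gc1: float
    gc2: float
    gc3: float
    gc_all: float
    nc: float
    rscu: dict[str, float]


def count_codons(cds_set, gene_ids=None, require_start: bool = False) -> CodonUsageTable:
    """Tally codons across a set of in-frame CDS sequences.

    Stop codons (terminal or internal) go to a separate tally and are
    excluded from RSCU/Nc families; an internal stop raises a warning naming
    the gene and position.
    """
    table = CodonUsageTable()
    gene_ids = gene_ids or [f"cds{i}" for i in range(len(cds_set))]
    for gid, cds in zip(gene_ids, cds_set):
        cds = cds.upper().replace("U", "T")
        if len(cds) % 3:
            raise ValueError(f"CDS {gid!r}: length {len(cds)} not divisible by 3")
        if require_start and cds[:3] != "ATG":
            raise ValueError(f"CDS {gid!r}: start codon {cds[:3]} is not ATG")
        n = len(cds) // 3
        for i in range(n):
            codon = cds[3 * i : 3 * i + 3]
            if codon in STOP_CODONS:
                if i < n - 1:
                    warnings.warn(f"internal stop {codon} in {gid!r} at codon {i}")
                table.stop_counts[codon] += 1
            elif set(codon) <= set("ACGT"):
                table.counts[codon] += 1
    return table


def positional_gc(table: CodonUsageTable) -> tuple[float, float, float, float]:
    """GC fraction at codon positions 1/2/3 plus their arithmetic mean."""
    n = table.n_codons
    if n == 0:
        raise ValueError("empty codon table")
    gc = [0, 0, 0]
    for codon, cnt in table.counts.items():
        for pos in range(3):
            if codon[pos] in "GC":
                gc[pos] += cnt
    g1, g2, g3 = (g / n for g in gc)
    return g1, g2, g3, (g1 + g2 + g3) / 3


def rscu(table: CodonUsageTable) -> dict[str, float]:
    """Relative synonymous codon usage: family_size * count / family_total.

    Families with zero usage are omitted; stop codons are excluded.
    """
    out: dict[str, float] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        total = sum(table.counts.get(c, 0) for c in codons)
        if total == 0:
            continue
        size = len(codons)
        for c in codons:
            out[c] = size * table.counts.get(c, 0) / total
    return out


def _family_f_hat(counts: list[int]) -> float | None:
    """Wright's homozygosity estimator F^ = (n*sum(p^2) - 1) / (n - 1)."""
    n = sum(counts)
    if n < 2:
        return None
    sum_p2 = sum((c / n) ** 2 for c in counts)
    return (n * sum_p2 - 1) / (n - 1)


def effective_number_of_codons(table: CodonUsageTable) -> float:
    """Wright's Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 (mean F per degeneracy
    class), clamped to [20, 61].

    A degeneracy class with no estimable family (all families with fewer
    than 2 codons counted, or F^ = 0) borrows the mean of the estimable
    classes' mean-F values (Wright's convention for missing classes).
    """
    if table.n_codons == 0:
        raise ValueError("empty codon table")
    class_members = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        size = len(codons)
        if size == 1:
            continue
        class_members[size].append([table.counts.get(c, 0) for c in codons])
    class_fbar: dict[int, float | None] = {}
    for size, fams in class_members.items():
        fs = [f for fam in fams if (f := _family_f_hat(fam)) is not None and f > 0]
        class_fbar[size] = sum(fs) / len(fs) if fs else None
    estimable = [f for f in class_fbar.values() if f is not None]
    if not estimable:
        raise ValueError("no degeneracy class has an estimable family")
    fallback = sum(estimable) / len(estimable)
    f2, f3, f4, f6 = (class_fbar[s] if class_fbar[s] is not None else fallback
                      for s in (2, 3, 4, 6))
    nc = 2 + 9 / f2 + 1 / f3 + 5 / f4 + 3 / f6
    return min(61.0, max(20.0, nc))


def codon_stats(table: CodonUsageTable) -> CodonStats:
    g1, g2, g3, gall = positional_gc(table)
    return CodonStats(g1, g2, g3, gall, effective_number_of_codons(table), rscu(table))


def start_stop_summary(gene_records) -> dict:
    """Tally start and stop codons over protein-coding gene copies.

    ``gene_records`` is an iterable of mappings/objects with ``start_codon``,
    ``stop_codon`` and ``copies``. Edited codons annotated as e.g.
    "CGA(TGA)" (genomic codon with post-editing codon in parentheses) are
    counted as the post-editing codon — the codon the ribosome actually sees.
    """
    starts: Counter = Counter()
    stops: Counter = Counter()
    total = 0
    for rec in gene_records:
        get = rec.get if hasattr(rec, "get") else lambda k, r=rec: getattr(r, k)
        copies = int(get("copies") or 1)
        start = _effective_codon(str(get("start_codon")))
        stop = _effective_codon(str(get("stop_codon")))
        if stop not in STOP_CODONS:
            raise ValueError(f"unknown stop codon {get('stop_codon')!r}")
        starts[start] += copies
        stops[stop] += copies
        total += copies
    return {
        "n_gene_copies": total,
        "start_counts": dict(starts),
        "stop_counts": dict(stops),
        "start_fractions": {c: n / total for c, n in starts.items()},
        "stop_fractions": {c: n / total for c, n in stops.items()},
    }


def _effective_codon(label: str) -> str:
    """'CGA(TGA)' -> 'TGA'; plain codons pass through."""
    label = label.strip().upper()
    if "(" in label:
        label = label[label.index("(") + 1 : label.index(")")]
    if len(label) != 3 or not set(label) <= set("ACGT"):
        raise ValueError(f"invalid codon label {label!r}")
    return label
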