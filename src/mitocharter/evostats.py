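"""Molecular-evolution statistics on pre-aligned gene sequences.

Implements Nei-Gojobori (1986) Ka/Ks — per-codon synonymous/nonsynonymous
site counting, pathway-averaged difference counting for codons differing at
more than one position, Jukes-Cantor correction — and Nei's nucleotide
diversity (pi), the average pairwise proportion of differing sites.

Conventions (documented because implementations differ):

* Site counting keeps S + N = 3 per codon: mutations that create a stop
  codon are counted as nonsynonymous rather than being dropped from the
  denominator.
* For codons differing at d positions, all d! substitution orders are
  averaged; orders passing through a stop codon are excluded, unless every
  order does, in which case all orders are used.
* Trailing stop codons are stripped; an internal stop excludes that codon
  column from the pairwise comparison with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations

import pandas as pd

from mitocharter.sequtil import CODON_TABLE, STOP_CODONS

_BASES = "ACGT"


@dataclass
class CodonAlignment:
    """A gap-containing codon alignment of one gene across taxa."""

    gene_id: str
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene_id}: aligned sequences differ in length")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0


@dataclass
class KaKsResult:
    gene_id: str
    taxon_a: str
    taxon_b: str
    ka: float
    ks: float
    ratio: float | None  # None when Ks = 0 or a correction is undefined
    n_codons: int
    ps: float = 0.0  # uncorrected synonymous difference proportion
    pn: float = 0.0  # uncorrected nonsynonymous difference proportion
    method: str = "NG86"
    flags: list[str] = field(default_factory=list)


@dataclass
class PiResult:
    gene_id: str
    n_sequences: int
    n_sites_used: int
    pi: float


def syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous site counts of one sense codon.

    At each position the fraction of the three possible changes that are
    synonymous contributes to S; the rest (including changes to stops)
    to N, so S + N = 3.
    """
    aa = CODON_TABLE[codon]
    if aa == "*":
        raise ValueError("site counting is undefined for stop codons")
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if CODON_TABLE[mutant] == aa:
                s += 1 / 3
    return s, 3.0 - s


def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between two
    sense codons, excluding substitution orders passing through a stop."""
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    pathway_counts = []
    for order in permutations(diffs):
        current = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if CODON_TABLE[nxt] == "*" and nxt != codon_b:
                blocked = True
            if CODON_TABLE[nxt] == CODON_TABLE[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        pathway_counts.append((sd, nd, blocked))
    usable = [(sd, nd) for sd, nd, blocked in pathway_counts if not blocked]
    if not usable:
        usable = [(sd, nd) for sd, nd, _ in pathway_counts]
    sd_mean = sum(sd for sd, _ in usable) / len(usable)
    nd_mean = sum(nd for _, nd in usable) / len(usable)
    return sd_mean, nd_mean


def _jukes_cantor(p: float) -> float | None:
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


def _clean_codon_pair(ca: str, cb: str, gene_id: str, idx: int) -> bool:
    for c in (ca, cb):
        if "-" in c or not set(c) <= set(_BASES):
            return False
    if ca in STOP_CODONS or cb in STOP_CODONS:
        warnings.warn(f"{gene_id}: internal stop at codon {idx}; column excluded")
        return False
    return True


def ng86_kaks(alignment: CodonAlignment, taxon_a: str, taxon_b: str) -> KaKsResult:
    """Nei-Gojobori Ka/Ks for one taxon pair of a codon alignment."""
    sa = alignment.sequences[taxon_a].upper().replace("U", "T")
    sb = alignment.sequences[taxon_b].upper().replace("U", "T")
    if len(sa) % 3:
        raise ValueError(f"{alignment.gene_id}: alignment length not divisible by 3")
    n_codons = len(sa) // 3
    # strip a trailing stop shared position
    if n_codons and (sa[-3:] in STOP_CODONS or sb[-3:] in STOP_CODONS):
        n_codons -= 1
    s_sites = n_sites = sd = nd = 0.0
    used = 0
    for i in range(n_codons):
        ca, cb = sa[3 * i : 3 * i + 3], sb[3 * i : 3 * i + 3]
        if not _clean_codon_pair(ca, cb, alignment.gene_id, i):
            continue
        s1, n1 = syn_nonsyn_sites(ca)
        s2, n2 = syn_nonsyn_sites(cb)
        s_sites += (s1 + s2) / 2
        n_sites += (n1 + n2) / 2
        dsd, dnd = pathway_differences(ca, cb)
        sd += dsd
        nd += dnd
        used += 1
    if used == 0:
        raise ValueError(f"{alignment.gene_id}: no comparable codons for "
                         f"({taxon_a}, {taxon_b})")
    flags = []
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    if ks is None or ka is None:
        flags.append("jc-correction-undefined")
        ratio = None
        ks = float("nan") if ks is None else ks
        ka = float("nan") if ka is None else ka
    elif ks == 0.0:
        flags.append("ks-zero")
        ratio = None
    else:
        ratio = ka / ks
    return KaKsResult(alignment.gene_id, taxon_a, taxon_b, ka, ks, ratio,
                      used, ps=ps, pn=pn, flags=flags)


def selection_label(ratio: float | None) -> str:
    """Ka/Ks interpretation: >1 positive, =1 neutral, <1 purifying."""
    if ratio is None:
        return "undefined"
    if ratio > 1:
        return "positive"
    if ratio == 1:
        return "neutral"
    return "purifying"


def pairwise_kaks_table(alignments: list[CodonAlignment]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """KaKs for every unordered taxon pair of every gene.

    Returns a long table (gene, pair, Ka, Ks, ratio, selection) and a
    per-gene summary (mean/median/min/max of defined ratios). Genes with
    fewer than two taxa are skipped with a warning.
    """
    rows = []
    for aln in alignments:
        taxa = sorted(aln.sequences)
        if len(taxa) < 2:
            warnings.warn(f"{aln.gene_id}: fewer than 2 taxa; skipped")
            continue
        for ta, tb in combinations(taxa, 2):
            r = ng86_kaks(aln, ta, tb)
            rows.append({"gene": r.gene_id, "taxon_a": ta, "taxon_b": tb,
                         "ka": r.ka, "ks": r.ks, "ratio": r.ratio,
                         "selection": selection_label(r.ratio),
                         "n_codons": r.n_codons})
    table = pd.DataFrame(rows)
    if table.empty:
        return table, pd.DataFrame()
    summary = (table.dropna(subset=["ratio"]).groupby("gene")["ratio"]
               .agg(["mean", "median", "min", "max", "count"]).reset_index())
    return table, summary


def nucleotide_diversity(alignment: CodonAlignment, *,
                         complete_deletion: bool = False) -> PiResult:
    """Nei's pi: average pairwise proportion of differing sites.

    Pairwise deletion by default (each pair compared over its own gap- and
    ambiguity-free sites); ``complete_deletion=True`` restricts every pair
    to columns clean in all sequences.
    """
    taxa = sorted(alignment.sequences)
    if len(taxa) < 2:
        raise ValueError(f"{alignment.gene_id}: pi needs at least 2 sequences")
    seqs = {t: alignment.sequences[t].upper().replace("U", "T") for t in taxa}
    length = alignment.length
    clean_all = None
    if complete_deletion:
        clean_all = [all(seqs[t][i] in _BASES for t in taxa) for i in range(length)]
    total = 0.0
    n_pairs = 0
    min_sites = length
    for ta, tb in combinations(taxa, 2):
        a, b = seqs[ta], seqs[tb]
        diff = sites = 0
        for i in range(length):
            if clean_all is not None:
                if not clean_all[i]:
                    continue
            elif a[i] not in _BASES or b[i] not in _BASES:
                continue
            sites += 1
            if a[i] != b[i]:
                diff += 1
        if sites == 0:
            raise ValueError(f"{alignment.gene_id}: no comparable sites for "
                             f"({ta}, {tb})")
        total += diff / sites
        n_pairs += 1
        min_sites = min(min_sites, sites)
    pi = total / n_pairs
    return PiResult(alignment.gene_id, len(taxa), min_sites, pi)
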