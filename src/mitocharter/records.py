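"""Shared domain records.

Coordinates are 0-based half-open on the forward strand throughout the
package; GFF3 emission converts to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class CircularSequence:
    """One chromosome/genome record with topology flag."""

    id: str
    seq: str
    circular: bool = True

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        """GC fraction over unambiguous bases (ambiguity codes excluded)."""
        s = self.seq.upper()
        gc = s.count("G") + s.count("C")
        at = s.count("A") + s.count("T")
        if gc + at == 0:
            raise ValueError(f"sequence {self.id!r} has no unambiguous bases")
        return gc / (gc + at)


@dataclass
class GeneModel:
    """A stranded (possibly multi-part) gene anchored to a chromosome.

    ``parts`` are (start, end) half-open intervals in transcription order on
    the forward-strand coordinate system; for minus-strand genes the spliced
    sequence is reverse-complemented after concatenation.
    """

    gene_id: str
    chrom: str
    parts: list[tuple[int, int]]
    strand: str = "+"
    kind: str = "gene"  # gene | tRNA | rRNA
    copies: int = 1

    @property
    def start(self) -> int:
        return min(s for s, _ in self.parts)

    @property
    def end(self) -> int:
        return max(e for _, e in self.parts)

    def extract(self, chrom_seq: str) -> str:
        from mitocharter.sequtil import revcomp

        spliced = "".join(chrom_seq[s:e] for s, e in self.parts)
        return revcomp(spliced) if self.strand == "-" else spliced


@dataclass
class EditingEvent:
    """One C-to-U edit with codon context and hydrophobicity transition."""

    gene_id: str
    codon_index: int
    codon_position: int  # 1-based within codon; 5'-most edited base
    ref_codon: str
    edited_codon: str
    aa_before: str
    aa_after: str  # single-letter amino acid or "*" for STOP
    transition_class: str
    n_edited_bases: int = 1
    support: float | None = None


@dataclass
class SsrRecord:
    """A perfect microsatellite run (unit length 1-6)."""

    chrom: str
    start: int
    end: int
    motif: str
    canonical_class: str
    unit_length: int
    copy_number: int

    def __post_init__(self) -> None:
        assert self.end - self.start == self.unit_length * self.copy_number


@dataclass
class TandemRecord:
    """A tandem array of a unit longer than 6 bp, possibly imperfect."""

    chrom: str
    start: int
    end: int
    unit_length: int
    copy_number: float
    percent_match: float
    consensus: str = ""


@dataclass
class DispersedRecord:
    """A pair of similar non-adjacent segments (forward or palindromic)."""

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    orientation: str  # forward | palindromic
    length: int
    identity: float
    e_value: float = 0.0


@dataclass
class HomologyFragment:
    """One local similarity segment between two genomes."""

    query_chrom: str
    query_start: int
    query_end: int
    subject_chrom: str
    subject_start: int
    subject_end: int
    orientation: str  # forward | reverse
    length_bp: int
    identity_fraction: float
    e_value: float


@dataclass
class LocalMatch:
    """A chained local alignment between a read and a target sequence."""

    read_id: str
    target_id: str
    read_start: int
    read_end: int
    target_start: int
    target_end: int
    orientation: str  # forward | reverse
    matched_length_bp: int
    identity_fraction: float


@dataclass
class RecruitmentState:
    """Progress log of iterative read recruitment."""

    recruited: set[str] = field(default_factory=set)
    iterations: int = 0
    additions_per_iteration: list[int] = field(default_factory=list)
    stop_reason: str = ""  # fixpoint | max_iter
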