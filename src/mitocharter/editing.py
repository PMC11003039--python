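"""C-to-U RNA-editing prediction and classification.

Plant mitochondrial transcripts undergo cytidine-to-uridine editing,
observed as C->T differences between the genomic codon and the codon the
ribosome sees. Each edit is classified by its amino-acid effect using a
two-class hydrophobicity partition, and a PREP-style predictor proposes
edits by comparing the translated CDS against homologous reference
proteins: wherever the unedited residue disagrees with the reference
consensus, the minimal C->T change at codon positions 1-2 that restores the
consensus residue is proposed.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations

from Bio import Align

from mitocharter.records import EditingEvent
from mitocharter.sequtil import CODON_TABLE, translate

#: The two-class hydrophobicity partition of the 20 amino acids.
HYDROPHOBIC = frozenset("AILFMPVW")
HYDROPHILIC = frozenset("RNDCQEGHKSTY")

CLASSES = (
    "hydrophilic-hydrophilic",
    "hydrophilic-hydrophobic",
    "hydrophilic-stop",
    "hydrophobic-hydrophilic",
    "hydrophobic-hydrophobic",
)


def _hclass(aa: str) -> str:
    if aa in HYDROPHOBIC:
        return "hydrophobic"
    if aa in HYDROPHILIC:
        return "hydrophilic"
    raise ValueError(f"not an amino acid: {aa!r}")


def classify_edit(ref_codon: str, edited_codon: str, *, gene_id: str = "",
                  codon_index: int = 0) -> EditingEvent:
    """Classify one C->T codon transition.

    The edited codon must differ from the genomic codon only by C->T
    substitutions (one or two positions). The reported ``codon_position`` is
    the 5'-most edited base (1-based).
    """
    ref_codon = ref_codon.upper().replace("U", "T")
    edited_codon = edited_codon.upper().replace("U", "T")
    if len(ref_codon) != 3 or len(edited_codon) != 3:
        raise ValueError("codons must be 3 bases")
    diffs = [i for i in range(3) if ref_codon[i] != edited_codon[i]]
    if not diffs:
        raise ValueError("edited codon equals the genomic codon")
    for i in diffs:
        if not (ref_codon[i] == "C" and edited_codon[i] == "T"):
            raise ValueError("editing type must be C-to-U")
    aa_before = CODON_TABLE[ref_codon]
    aa_after = CODON_TABLE[edited_codon]
    if aa_before == "*":
        raise ValueError("genomic codon is a stop codon")
    if aa_after == "*":
        cls = f"{_hclass(aa_before)}-stop"
    else:
        cls = f"{_hclass(aa_before)}-{_hclass(aa_after)}"
    return EditingEvent(
        gene_id=gene_id,
        codon_index=codon_index,
        codon_position=diffs[0] + 1,
        ref_codon=ref_codon,
        edited_codon=edited_codon,
        aa_before=aa_before,
        aa_after=aa_after,
        transition_class=cls,
        n_edited_bases=len(diffs),
    )


def classify_spectrum(spectrum: dict[tuple[str, str], int]) -> list[EditingEvent]:
    """Expand a {(genomic codon, edited codon): count} spectrum into events."""
    events = []
    for (ref, edited), count in spectrum.items():
        proto = classify_edit(ref, edited)
        events.extend([proto] * count)
    return events


def summarize_edits(events: list[EditingEvent]) -> dict:
    """Per-class, per-position and per-target-amino-acid tallies.

    'Unchanged hydrophobicity' is the hydrophilic-hydrophilic plus
    hydrophobic-hydrophobic share. Percentages are None when there are no
    events.
    """
    n = len(events)
    class_counts = Counter(e.transition_class for e in events)
    position_counts = Counter(e.codon_position for e in events)
    target_aa_counts = Counter(e.aa_after for e in events)
    pct = (lambda c: 100.0 * c / n) if n else (lambda c: None)
    unchanged = class_counts["hydrophilic-hydrophilic"] + class_counts["hydrophobic-hydrophobic"]
    return {
        "n_events": n,
        "class_counts": {c: class_counts.get(c, 0) for c in CLASSES},
        "class_percent": {c: pct(class_counts.get(c, 0)) for c in CLASSES},
        "unchanged_hydrophobicity_percent": pct(unchanged),
        "position_counts": dict(position_counts),
        "target_aa_counts": dict(target_aa_counts),
        "target_aa_percent": {aa: pct(c) for aa, c in target_aa_counts.items()},
        "stop_gains": class_counts.get("hydrophilic-stop", 0),
    }


def _c_to_t_variants(codon: str) -> list[tuple[str, int, int]]:
    """All single/double C->T edits of a codon at positions 1-2.

    Returns (edited codon, 5'-most edited position 0-based, n_edited),
    single edits first.
    """
    c_positions = [i for i in (0, 1) if codon[i] == "C"]
    variants = []
    for r in (1, 2):
        for combo in combinations(c_positions, r):
            edited = list(codon)
            for i in combo:
                edited[i] = "T"
            variants.append(("".join(edited), combo[0], r))
    return variants


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    return aligner


def _aligned_residues(protein: str, reference: str) -> dict[int, str]:
    """Map protein positions to the reference residue aligned opposite."""
    aligner = _protein_aligner()
    alignment = aligner.align(protein, reference)[0]
    mapping: dict[int, str] = {}
    for (qs, qe), (ts, te) in zip(*alignment.aligned):
        for off in range(qe - qs):
            mapping[qs + off] = reference[ts + off]
    return mapping


def predict_edit_sites(cds: str, reference_proteins: list[str], *,
                       gene_id: str = "", cutoff: float = 0.5) -> list[EditingEvent]:
    """Propose C->U editing sites by reference-protein comparison.

    The translated CDS is globally aligned to each reference protein. At
    codons whose unedited residue differs from the reference consensus, the
    minimal C->T edit at codon positions 1-2 whose translation matches the
    consensus is proposed, provided the fraction of references supporting
    the edited residue is at least ``cutoff``.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if not reference_proteins:
        raise ValueError("at least one reference protein required")
    protein = translate(cds)
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError(f"CDS {gene_id!r} has an internal stop; not translatable")
    refs = [r.upper().rstrip("*") for r in reference_proteins]
    maps = [_aligned_residues(protein, r) for r in refs]
    events: list[EditingEvent] = []
    for idx in range(len(protein)):
        residues = [m[idx] for m in maps if idx in m]
        if not residues:
            continue
        consensus, _ = Counter(residues).most_common(1)[0]
        if consensus == protein[idx]:
            continue
        codon = cds[3 * idx : 3 * idx + 3]
        best = None
        for edited, pos0, n_edit in _c_to_t_variants(codon):
            aa = CODON_TABLE[edited]
            if aa != consensus or aa == "*":
                continue
            support = sum(1 for r in residues if r == aa) / len(residues)
            if support < cutoff:
                continue
            key = (n_edit, -support, edited)
            if best is None or key < best[0]:
                best = (key, edited, pos0, n_edit, support)
        if best is not None:
            _, edited, pos0, n_edit, support = best
            event = classify_edit(codon, edited, gene_id=gene_id, codon_index=idx)
            event.support = support
            events.append(event)
    return events
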