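"""Synthetic multichromosomal-genome generator with ground-truth manifests.

Emulates the study system every stage of this package analyses: a plant
mitogenome of N circular chromosomes (tens of kb each, ~44% GC) carrying
planted protein-coding genes, microsatellites, tandem arrays, dispersed
repeat copies and plastid-derived insertions; companion plastid/nuclear
genomes sharing transfer segments at controlled identity; C-to-U editing
events applied to transcripts; and long/short reads drawn from a
mitochondrial + nuclear mixture with per-read origin labels.

Background sequence is i.i.d. at the GC target (no higher-order structure);
read errors are substitution-only by default, with an optional indel rate.
All outputs are deterministic functions of the configuration, including its
seed. Coordinates are 0-based half-open on the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mitocharter.editing import classify_edit
from mitocharter.records import CircularSequence, EditingEvent, GeneModel
from mitocharter.sequtil import CODON_TABLE, SENSE_CODONS, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class ReadParams:
    mean_len_bp: int = 10_000
    error_rate: float = 0.05
    depth: float = 20.0
    indel_rate: float = 0.0
    min_len_bp: int = 1_000
    len_sd_bp: int | None = None  # default mean/10


@dataclass
class SimConfig:
    """Parameters of one synthetic study system.

    Defaults mirror the scale of a multichromosomal orchid mitogenome:
    19 circular chromosomes of 22-48 kb at 44% GC, PacBio-like ~10 kb long
    reads. Repeat/insert plans are lists of descriptors:

    * ``ssr_plan``: (motif, copy_number)
    * ``tandem_plan``: (unit_length, copy_number, per_copy_substitutions)
    * ``dispersed_plan``: (length_bp, identity_fraction, orientation)
    * ``plastid_insert_spec`` / ``nuclear_insert_spec``: (length_bp, identity)
    """

    n_chromosomes: int = 19
    chrom_length_range: tuple[int, int] = (21_995, 48_212)
    gc_target: float = 0.44
    n_genes_per_chrom: int = 2
    gene_length_range: tuple[int, int] = (300, 1_500)
    plastid_insert_spec: list[tuple[int, float]] = field(default_factory=list)
    nuclear_insert_spec: list[tuple[int, float]] = field(default_factory=list)
    ssr_plan: list[tuple[str, int]] = field(default_factory=list)
    tandem_plan: list[tuple[int, int, int]] = field(default_factory=list)
    dispersed_plan: list[tuple[int, float, str]] = field(default_factory=list)
    editing_rate: float = 3.0  # expected edits per CDS
    read_params: ReadParams = field(default_factory=ReadParams)
    plastome_length: int = 40_000
    nuclear_chrom_lengths: tuple[int, ...] = (100_000, 100_000)
    rng_seed: int = 0

    def validate(self) -> None:
        lo, hi = self.chrom_length_range
        if not (0 < lo <= hi):
            raise ValueError("chrom_length_range must be positive and ordered")
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must be in (0, 1)")
        for spec in (self.plastid_insert_spec, self.nuclear_insert_spec):
            for length, ident in spec:
                if length <= 0:
                    raise ValueError("insert length must be positive")
                if not 0 <= ident <= 1:
                    raise ValueError("identity must be in [0, 1]")
        if self.read_params.depth <= 0:
            raise ValueError("read depth must be positive")


@dataclass
class TruthManifest:
    """Ground-truth records of every planted feature and read origin."""

    features: list[dict] = field(default_factory=list)
    read_origins: dict[str, dict] = field(default_factory=dict)

    def add(self, kind: str, chrom: str, start: int, end: int, strand: str = "+",
            **payload) -> None:
        self.features.append({"kind": kind, "chrom": chrom, "start": start,
                              "end": end, "strand": strand, **payload})

    def of_kind(self, kind: str) -> list[dict]:
        return [f for f in self.features if f["kind"] == kind]

    def to_rows(self) -> list[dict]:
        return list(self.features)


class _Placer:
    """Rejection-sampling placement of non-overlapping feature intervals."""

    def __init__(self, chrom_id: str, length: int, rng: np.random.Generator,
                 margin: int = 60):
        self.chrom_id = chrom_id
        self.length = length
        self.rng = rng
        self.margin = margin
        self.occupied: list[tuple[int, int]] = []

    def place(self, size: int) -> int:
        if size + 2 * self.margin > self.length:
            raise ValueError(
                f"feature of {size} bp does not fit on chromosome "
                f"{self.chrom_id!r} ({self.length} bp)")
        for _ in range(500):
            start = int(self.rng.integers(self.margin, self.length - size - self.margin))
            if all(start - self.margin >= e or start + size + self.margin <= s
                   for s, e in self.occupied):
                self.occupied.append((start, start + size))
                return start
        raise ValueError(
            f"could not place a {size} bp feature on chromosome "
            f"{self.chrom_id!r}: plan exceeds available space")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG + random internal sense codons (C-bearing codons favoured so
    editing truth always has candidates) + stop codon."""
    n_internal = length // 3 - 2
    stops = ("TAA", "TAG", "TGA")
    internal = [SENSE_CODONS[int(i)] for i in
                rng.integers(0, len(SENSE_CODONS), size=n_internal)]
    stop = stops[int(rng.integers(0, 3))]
    return "ATG" + "".join(internal) + stop


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply exactly ``n_subs`` substitutions at distinct positions."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    if n_subs <= 0:
        return seq
    pos = rng.choice(len(arr), size=min(n_subs, len(arr)), replace=False)
    for p in pos:
        old = arr[p]
        choices = [b for b in _BASES if b != old]
        arr[p] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode()


def generate_mitogenome(config: SimConfig,
                        ) -> tuple[list[CircularSequence], list[GeneModel], TruthManifest]:
    """Generate the synthetic mitogenome with planted genes and repeats.

    Returns the chromosomes, the planted gene models, and a manifest whose
    coordinates recover every planted feature by direct string search.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    manifest = TruthManifest()
    lo, hi = config.chrom_length_range
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_chromosomes)]
    chroms: list[CircularSequence] = []
    genes: list[GeneModel] = []
    arrays = []
    placers = []
    for ci, L in enumerate(lengths):
        cid = f"chr{ci + 1}"
        arr = _random_bases(rng, L, config.gc_target)
        arrays.append(arr)
        placers.append(_Placer(cid, L, rng))

    # genes
    for ci, (arr, placer) in enumerate(zip(arrays, placers)):
        cid = placer.chrom_id
        for gi in range(config.n_genes_per_chrom):
            glo, ghi = config.gene_length_range
            glen = 3 * int(rng.integers(glo // 3, ghi // 3 + 1))
            cds = _random_cds(rng, glen)
            strand = "+" if rng.random() < 0.5 else "-"
            start = placer.place(glen)
            planted = cds if strand == "+" else revcomp(cds)
            arr[start : start + glen] = np.frombuffer(planted.encode(), dtype="S1")
            gene = GeneModel(gene_id=f"{cid}g{gi + 1}", chrom=cid,
                             parts=[(start, start + glen)], strand=strand)
            genes.append(gene)
            manifest.add("gene", cid, start, start + glen, strand,
                         gene_id=gene.gene_id, cds=cds)

    # SSRs / tandem arrays / dispersed copies, round-robin over chromosomes
    def _plant_array(kind: str, unit: str, copies: int, idx: int,
                     per_copy_subs: int = 0) -> None:
        ci = idx % len(arrays)
        arr, placer = arrays[ci], placers[ci]
        u = len(unit)
        block = unit * copies
        if per_copy_subs:
            mutated = [unit] + [
                _mutate(rng, unit, per_copy_subs) for _ in range(copies - 1)]
            block = "".join(mutated)
        start = placer.place(len(block))
        arr[start : start + len(block)] = np.frombuffer(block.encode(), dtype="S1")
        # pin flanks so the perfect run is exactly the planted interval
        left_bad = unit[-1].encode()
        arr[start - 1] = [b for b in _BASES if b != left_bad][0]
        right_bad = unit[len(block) % u].encode()
        arr[start + len(block)] = [b for b in _BASES if b != right_bad][0]
        manifest.add(kind, placer.chrom_id, start, start + len(block), "+",
                     motif=unit, copies=copies, unit_length=u,
                     per_copy_subs=per_copy_subs)

    for idx, (motif, copies) in enumerate(config.ssr_plan):
        _plant_array("ssr", motif.upper(), copies, idx)
    for idx, (unit_len, copies, subs) in enumerate(config.tandem_plan):
        unit = _random_bases(rng, unit_len, config.gc_target).tobytes().decode()
        _plant_array("tandem", unit, copies, idx + 3, per_copy_subs=subs)

    for idx, (length, identity, orientation) in enumerate(config.dispersed_plan):
        if orientation not in ("forward", "palindromic"):
            raise ValueError(f"unknown orientation {orientation!r}")
        ci_a = idx % len(arrays)
        ci_b = (idx + 1) % len(arrays) if len(arrays) > 1 else ci_a
        segment = _random_bases(rng, length, config.gc_target).tobytes().decode()
        n_subs = int(round((1 - identity) * length))
        copy = _mutate(rng, segment, n_subs)
        if orientation == "palindromic":
            copy = revcomp(copy)
        start_a = placers[ci_a].place(length)
        arrays[ci_a][start_a : start_a + length] = np.frombuffer(segment.encode(), dtype="S1")
        start_b = placers[ci_b].place(length)
        arrays[ci_b][start_b : start_b + length] = np.frombuffer(copy.encode(), dtype="S1")
        manifest.add("dispersed", placers[ci_a].chrom_id, start_a, start_a + length,
                     "+", mate_chrom=placers[ci_b].chrom_id, mate_start=start_b,
                     mate_end=start_b + length, orientation=orientation,
                     identity=identity, length=length)

    for ci, arr in enumerate(arrays):
        chroms.append(CircularSequence(f"chr{ci + 1}", arr.tobytes().decode(), True))
    return chroms, genes, manifest


def generate_companion_genomes(mito: list[CircularSequence], config: SimConfig,
                               ) -> tuple[CircularSequence, list[CircularSequence], TruthManifest]:
    """Plastome and nuclear chromosomes sharing planted transfer segments
    with the mitogenome.

    Each (length, identity) descriptor copies a mitochondrial segment into
    the companion genome with point mutations at rate 1 - identity; the
    manifest records both coordinate pairs.
    """
    if not mito:
        raise ValueError("mitogenome must be non-empty")
    config.validate()
    rng = np.random.default_rng(config.rng_seed + 101)
    manifest = TruthManifest()

    def _build(name: str, length: int, spec: list[tuple[int, float]],
               start_idx: int) -> CircularSequence:
        arr = _random_bases(rng, length, config.gc_target)
        placer = _Placer(name, length, rng)
        for idx, (seg_len, identity) in enumerate(spec):
            mi = (start_idx + idx) % len(mito)
            msrc = mito[mi]
            if seg_len + 120 > len(msrc):
                raise ValueError(f"insert of {seg_len} bp exceeds {msrc.id}")
            mstart = int(rng.integers(60, len(msrc) - seg_len - 60))
            segment = msrc.seq[mstart : mstart + seg_len]
            n_subs = int(round((1 - identity) * seg_len))
            copy = _mutate(rng, segment, n_subs)
            start = placer.place(seg_len)
            arr[start : start + seg_len] = np.frombuffer(copy.encode(), dtype="S1")
            manifest.add("transfer", msrc.id, mstart, mstart + seg_len, "+",
                         companion=name, companion_start=start,
                         companion_end=start + seg_len, identity=identity,
                         length=seg_len)
        return CircularSequence(name, arr.tobytes().decode(), name == "plastome")

    plastome = _build("plastome", config.plastome_length,
                      config.plastid_insert_spec, 0)
    nuclear = []
    n_spec = config.nuclear_insert_spec
    per_chrom = len(n_spec) // max(1, len(config.nuclear_chrom_lengths)) + 1
    for ni, nlen in enumerate(config.nuclear_chrom_lengths):
        spec = n_spec[ni * per_chrom : (ni + 1) * per_chrom]
        chrom = _build(f"nuc{ni + 1}", nlen, spec, ni)
        chrom.circular = False
        nuclear.append(chrom)
    return plastome, nuclear, manifest


def apply_editing_truth(gene_models: list[GeneModel],
                        chromosomes: list[CircularSequence],
                        editing_rate: float, seed: int,
                        ) -> tuple[dict[str, str], list[EditingEvent]]:
    """Apply random C->U edits to each gene's transcript.

    Only nonsynonymous C->T changes at codon positions 1-2 that do not
    create a stop codon are drawn (one edited base per event); the number of
    events per CDS is Poisson(``editing_rate``) capped by the candidate
    count. Returns edited transcript sequences keyed by gene id plus the
    exact truth events.
    """
    rng = np.random.default_rng(seed)
    chrom_seq = {c.id: c.seq for c in chromosomes}
    transcripts: dict[str, str] = {}
    events: list[EditingEvent] = []
    for gene in gene_models:
        cds = gene.extract(chrom_seq[gene.chrom])
        candidates = []
        for idx in range(1, len(cds) // 3 - 1):  # skip start codon and stop
            codon = cds[3 * idx : 3 * idx + 3]
            for pos in (0, 1):
                if codon[pos] != "C":
                    continue
                edited = codon[:pos] + "T" + codon[pos + 1 :]
                if CODON_TABLE[edited] in ("*", CODON_TABLE[codon]):
                    continue
                candidates.append((idx, pos, codon, edited))
        n_edit = min(int(rng.poisson(editing_rate)), len(candidates))
        chosen = sorted(rng.choice(len(candidates), size=n_edit, replace=False)) \
            if n_edit else []
        # at most one edit per codon
        edited_cds = list(cds)
        used_codons: set[int] = set()
        for c in chosen:
            idx, pos, codon, edited = candidates[int(c)]
            if idx in used_codons:
                continue
            used_codons.add(idx)
            edited_cds[3 * idx + pos] = "T"
            ev = classify_edit(codon, edited, gene_id=gene.gene_id, codon_index=idx)
            events.append(ev)
        transcripts[gene.gene_id] = "".join(edited_cds)
    return transcripts, events


def simulate_reads(genomes: dict[str, list[CircularSequence]],
                   read_params: ReadParams, seed: int,
                   ) -> tuple[list[tuple[str, str, str]], dict[str, dict]]:
    """Draw substitution-error long reads from labelled genomes.

    ``genomes`` maps an origin label (e.g. "mito", "nuclear") to its
    chromosomes. Circular templates yield origin-spanning reads. Returns
    FASTQ-ready (id, sequence, quality) tuples and per-read origin records
    (label, chromosome, start, end, strand).
    """
    if read_params.depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str, str]] = []
    origins: dict[str, dict] = {}
    sd = read_params.len_sd_bp if read_params.len_sd_bp is not None \
        else read_params.mean_len_bp // 10
    counter = 0
    for label in sorted(genomes):
        for chrom in genomes[label]:
            L = len(chrom)
            if read_params.mean_len_bp > L and not chrom.circular:
                raise ValueError(
                    f"mean read length {read_params.mean_len_bp} exceeds linear "
                    f"chromosome {chrom.id} ({L} bp)")
            n_reads = max(1, int(round(read_params.depth * L / read_params.mean_len_bp)))
            template = chrom.seq + chrom.seq if chrom.circular else chrom.seq
            for _ in range(n_reads):
                rlen = int(np.clip(rng.normal(read_params.mean_len_bp, sd),
                                   read_params.min_len_bp, L))
                if chrom.circular:
                    start = int(rng.integers(0, L))
                else:
                    start = int(rng.integers(0, max(1, L - rlen + 1)))
                raw = template[start : start + rlen]
                seq = _apply_read_errors(rng, raw, read_params)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    seq = revcomp(seq)
                rid = f"read_{label}_{counter:06d}"
                counter += 1
                reads.append((rid, seq, "I" * len(seq)))
                origins[rid] = {"label": label, "chrom": chrom.id,
                                "start": start, "end": start + rlen,
                                "strand": strand}
    return reads, origins


def _apply_read_errors(rng: np.random.Generator, seq: str,
                       params: ReadParams) -> str:
    if params.error_rate <= 0 and params.indel_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    if params.error_rate > 0:
        mask = rng.random(len(arr)) < params.error_rate
        for p in np.flatnonzero(mask):
            choices = [b for b in _BASES if b != arr[p]]
            arr[p] = choices[int(rng.integers(0, 3))]
    out = arr.tobytes().decode()
    if params.indel_rate > 0:
        chars = []
        for ch in out:
            r = rng.random()
            if r < params.indel_rate / 2:
                continue  # deletion
            chars.append(ch)
            if r > 1 - params.indel_rate / 2:
                chars.append("ACGT"[int(rng.integers(0, 4))])  # insertion
        out = "".join(chars)
    return out
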