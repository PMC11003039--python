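"""End-to-end orchestration: run enabled stages on a config, collect TSVs.

The pipeline wires the stages in dependency order — simulate (or load
genomes) -> genome stats -> codon usage -> RNA editing -> repeats (SSR,
then tandem, then dispersed with tandem exclusion) -> transfer -> Ka/Ks and
Pi on supplied alignments — and emits one TSV per stage plus a summary
whose numbers are cross-checked against the stage outputs at build time.
All intermediate formats are plain text (FASTA/FASTQ/GFF3/TSV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from mitocharter import codonlib, editing, evostats, io, repeatscan, synthio, transfer
from mitocharter.records import CircularSequence

logger = logging.getLogger("mitocharter")


@dataclass
class RunConfig:
    """Stage toggles, per-stage parameters, inputs and output directory."""

    outdir: str = "mitocharter_out"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {
        "simulate": False, "stats": True, "codon": True, "editing": True,
        "repeats": True, "transfer": False, "kaks": False, "pi": False,
    })
    # file inputs (unused when simulate is enabled)
    mito_fasta: str | None = None
    gff3: str | None = None
    plastid_fasta: str | None = None
    reference_proteins: str | None = None
    aln_dir: str | None = None
    # per-stage parameter blocks
    simulate_params: dict = field(default_factory=dict)
    repeat_params: dict = field(default_factory=dict)
    transfer_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict) and isinstance(value, dict):
                getattr(cfg, key).update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in (
            "outdir", "seed", "stages", "mito_fasta", "gff3", "plastid_fasta",
            "reference_proteins", "aln_dir", "simulate_params", "repeat_params",
            "transfer_params")}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def validate(self) -> None:
        if not self.stages.get("simulate"):
            needs_genome = any(self.stages.get(s) for s in
                               ("stats", "codon", "repeats", "transfer"))
            if needs_genome and not self.mito_fasta:
                raise ValueError("mito_fasta is required when simulate is disabled")
            if self.stages.get("transfer") and not self.plastid_fasta:
                raise ValueError("transfer stage requires plastid_fasta")
        if (self.stages.get("kaks") or self.stages.get("pi")) and not self.aln_dir:
            raise ValueError("kaks/pi stages require aln_dir")


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    outdir: Path | None = None

    def write(self) -> None:
        if self.outdir is None:
            return
        self.outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            io.write_tsv(df, self.outdir / f"{name}.tsv")
        with open(self.outdir / "summary.yaml", "w") as fh:
            yaml.safe_dump(_plain(self.summary), fh, sort_keys=True)


def _plain(obj):
    """YAML-serializable copy (numpy scalars to python, tuples to lists)."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def genome_stats(genomes: list[CircularSequence]) -> tuple[pd.DataFrame, dict]:
    """Per-chromosome length and GC table plus genome-level aggregates.

    Genome GC is computed over the concatenated bases, not as the mean of
    per-chromosome values; ambiguity codes are excluded from the
    denominator.
    """
    if not genomes:
        raise ValueError("no chromosomes")
    rows = []
    for c in genomes:
        if len(c) == 0:
            raise ValueError(f"chromosome {c.id!r} is empty")
        rows.append({"chrom": c.id, "length_bp": len(c), "gc_fraction": c.gc,
                     "circular": c.circular})
    df = pd.DataFrame(rows)
    concat_gc = sum(c.seq.upper().count("G") + c.seq.upper().count("C")
                    for c in genomes)
    concat_valid = sum(c.seq.upper().count(b) for c in genomes for b in "ACGT")
    agg = {
        "n_chromosomes": len(genomes),
        "total_length_bp": int(df["length_bp"].sum()),
        "min_length_bp": int(df["length_bp"].min()),
        "max_length_bp": int(df["length_bp"].max()),
        "gc_fraction": concat_gc / concat_valid,
    }
    return df, agg


def run(config: RunConfig) -> ReportBundle:
    """Execute the enabled stages in dependency order."""
    config.validate()
    outdir = Path(config.outdir)
    bundle = ReportBundle(outdir=outdir)
    genomes: list[CircularSequence] = []
    genes = []
    plastome = None
    transcripts = {}
    truth_events = []

    if config.stages.get("simulate"):
        sim = synthio.SimConfig(**{**config.simulate_params,
                                   "rng_seed": config.seed})
        genomes, genes, manifest = synthio.generate_mitogenome(sim)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fasta(genomes, outdir / "mito.fasta")
        io.write_gff3(genes, {c.id: len(c) for c in genomes}, outdir / "mito.gff3")
        io.write_manifest(manifest, outdir / "truth_manifest.tsv")
        if sim.plastid_insert_spec or sim.nuclear_insert_spec:
            plastome, nuclear, tmanifest = synthio.generate_companion_genomes(
                genomes, sim)
            io.write_fasta([plastome], outdir / "plastome.fasta")
            io.write_fasta(nuclear, outdir / "nuclear.fasta")
            io.write_manifest(tmanifest, outdir / "transfer_manifest.tsv")
        transcripts, truth_events = synthio.apply_editing_truth(
            genes, genomes, sim.editing_rate, sim.rng_seed + 7)
        logger.info("simulated %d chromosomes, %d genes", len(genomes), len(genes))
    else:
        if config.mito_fasta:
            genomes = io.read_fasta(config.mito_fasta, circular=True)
        if config.gff3:
            genes = io.read_gff3(config.gff3)
        if config.plastid_fasta:
            plastome = io.read_fasta(config.plastid_fasta, circular=True)[0]

    if config.stages.get("stats"):
        df, agg = genome_stats(genomes)
        bundle.tables["genome_stats"] = df
        bundle.summary["genome"] = agg

    cds = {}
    if genomes and genes:
        cds = io.extract_cds(genomes, genes)

    if config.stages.get("codon") and cds:
        table = codonlib.count_codons(list(cds.values()), list(cds))
        stats = codonlib.codon_stats(table)
        bundle.tables["codon_usage"] = pd.DataFrame(
            [{"codon": c, "count": n, "rscu": stats.rscu.get(c)}
             for c, n in sorted(table.counts.items())])
        bundle.summary["codon"] = {
            "n_codons": table.n_codons, "gc1": stats.gc1, "gc2": stats.gc2,
            "gc3": stats.gc3, "gc_all": stats.gc_all, "nc": stats.nc,
        }

    if config.stages.get("editing") and cds:
        events = []
        if transcripts:  # synthetic truth available: predict against it
            for gid, seq in cds.items():
                refs = [_translate_safe(transcripts[gid])]
                events.extend(editing.predict_edit_sites(seq, refs, gene_id=gid))
        elif config.reference_proteins:
            refs = [c.seq for c in io.read_fasta(config.reference_proteins)]
            for gid, seq in cds.items():
                events.extend(editing.predict_edit_sites(seq, refs, gene_id=gid))
        summary = editing.summarize_edits(events)
        bundle.tables["editing_events"] = pd.DataFrame(
            [{"gene": e.gene_id, "codon_index": e.codon_index,
              "codon_position": e.codon_position, "ref_codon": e.ref_codon,
              "edited_codon": e.edited_codon, "aa_before": e.aa_before,
              "aa_after": e.aa_after, "class": e.transition_class}
             for e in events])
        bundle.summary["editing"] = {
            "n_events": summary["n_events"],
            "class_counts": summary["class_counts"],
            "n_truth_events": len(truth_events),
        }

    if config.stages.get("repeats") and genomes:
        params = dict(config.repeat_params)
        ssrs, tandems, dispersed = [], [], []
        for c in genomes:
            ssrs.extend(repeatscan.find_ssrs(c.seq, chrom=c.id,
                                             circular=c.circular))
            tandems.extend(repeatscan.find_tandem_repeats(
                c.seq, chrom=c.id, circular=c.circular,
                **{k: v for k, v in params.items()
                   if k in ("min_unit", "max_unit", "min_match", "min_score")}))
        dispersed = repeatscan.find_dispersed_repeats(
            genomes, tandem_records=tandems,
            **{k: v for k, v in params.items()
               if k in ("min_len", "min_identity", "max_e", "word_size")})
        bundle.tables["ssr"] = pd.DataFrame(
            [{"chrom": r.chrom, "start": r.start, "end": r.end, "motif": r.motif,
              "class": r.canonical_class, "unit": r.unit_length,
              "copies": r.copy_number} for r in ssrs])
        bundle.tables["tandem"] = pd.DataFrame(
            [{"chrom": t.chrom, "start": t.start, "end": t.end,
              "unit": t.unit_length, "copies": t.copy_number,
              "percent_match": t.percent_match} for t in tandems])
        bundle.tables["dispersed"] = pd.DataFrame(
            [{"chrom_a": d.chrom_a, "start_a": d.start_a, "end_a": d.end_a,
              "chrom_b": d.chrom_b, "start_b": d.start_b, "end_b": d.end_b,
              "orientation": d.orientation, "length": d.length,
              "identity": d.identity} for d in dispersed])
        bundle.summary["repeats"] = repeatscan.repeat_summary(
            ssrs, tandems, dispersed, genomes)

    if config.stages.get("transfer") and genomes and plastome is not None:
        tp = dict(config.transfer_params)
        fragments = transfer.find_homologous_fragments(genomes, plastome, **tp)
        coverage = transfer.merged_coverage(fragments, genomes)
        bundle.tables["transfer_fragments"] = pd.DataFrame(
            [{"query_chrom": f.query_chrom, "query_start": f.query_start,
              "query_end": f.query_end, "subject_chrom": f.subject_chrom,
              "subject_start": f.subject_start, "subject_end": f.subject_end,
              "orientation": f.orientation, "length": f.length_bp,
              "identity": f.identity_fraction, "evalue": f.e_value}
             for f in fragments])
        bundle.summary["transfer"] = {
            "n_fragments": len(fragments),
            "covered_bp": coverage["covered_bp"],
            "fraction": coverage["fraction"],
            "n_chromosomes_hit": coverage["n_chromosomes_hit"],
        }

    if config.stages.get("kaks") or config.stages.get("pi"):
        alignments = _load_alignments(config.aln_dir)
        if config.stages.get("kaks"):
            table, summary = evostats.pairwise_kaks_table(alignments)
            bundle.tables["kaks"] = table
            bundle.tables["kaks_summary"] = summary
        if config.stages.get("pi"):
            rows = []
            for aln in alignments:
                r = evostats.nucleotide_diversity(aln)
                rows.append({"gene": r.gene_id, "n_sequences": r.n_sequences,
                             "n_sites": r.n_sites_used, "pi": r.pi})
            bundle.tables["pi"] = pd.DataFrame(rows)

    _cross_check(bundle)
    bundle.write()
    return bundle


def _translate_safe(cds: str) -> str:
    from mitocharter.sequtil import translate

    protein = translate(cds)
    return protein[:-1] if protein.endswith("*") else protein


def _load_alignments(aln_dir) -> list[evostats.CodonAlignment]:
    alignments = []
    for path in sorted(Path(aln_dir).glob("*.fa*")):
        seqs = {c.id: c.seq for c in io.read_fasta(path)}
        alignments.append(evostats.CodonAlignment(path.stem, seqs))
    return alignments


def _cross_check(bundle: ReportBundle) -> None:
    """Summary numbers must equal the corresponding stage-table aggregates."""
    rep = bundle.summary.get("repeats")
    if rep is not None:
        assert rep["n_ssr"] == len(bundle.tables["ssr"])
        assert rep["n_tandem"] == len(bundle.tables["tandem"])
        assert rep["n_dispersed"] == len(bundle.tables["dispersed"])
        assert rep["total"] == rep["n_ssr"] + rep["n_tandem"] + rep["n_dispersed"]
    ed = bundle.summary.get("editing")
    if ed is not None:
        assert ed["n_events"] == len(bundle.tables["editing_events"])
    gen = bundle.summary.get("genome")
    if gen is not None:
        assert gen["total_length_bp"] == int(
            bundle.tables["genome_stats"]["length_bp"].sum())
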