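"""File I/O: FASTA (70-column wrap), FASTQ (Phred+33), GFF3, TSV manifests."""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mitocharter.records import CircularSequence, GeneModel

MANIFEST_COLUMNS = ["kind", "chrom", "start", "end", "strand", "payload"]


def _to_seqrecords(sequences) -> list[SeqRecord]:
    records = []
    for item in sequences:
        if isinstance(item, CircularSequence):
            rec = SeqRecord(Seq(item.seq), id=item.id, description="")
        elif isinstance(item, tuple):
            rec = SeqRecord(Seq(item[1]), id=item[0], description="")
        else:
            rec = item
        records.append(rec)
    return records


def write_fasta(sequences, path, width: int = 70) -> None:
    from Bio.SeqIO.FastaIO import FastaWriter

    with open(path, "w") as fh:
        FastaWriter(fh, wrap=width).write_file(_to_seqrecords(sequences))


def read_fasta(path, circular: bool = False) -> list[CircularSequence]:
    return [CircularSequence(rec.id, str(rec.seq).upper(), circular)
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fastq(reads, path) -> None:
    """``reads`` is an iterable of (id, sequence, quality-string)."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), qual))
    return out


def write_gff3(genes: list[GeneModel], chrom_lengths: dict[str, int], path) -> None:
    """Emit gene/CDS (or exon) features, 1-based inclusive coordinates.

    Multi-part genes share one ID across parts (used for origin-spanning
    features on circular chromosomes).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for gene in genes:
            attrs = f"ID={gene.gene_id}"
            fh.write("\t".join([
                gene.chrom, "mitocharter", "gene", str(gene.start + 1),
                str(gene.end), ".", gene.strand, ".", attrs]) + "\n")
            part_type = "CDS" if gene.kind == "gene" else "exon"
            for s, e in gene.parts:
                fh.write("\t".join([
                    gene.chrom, "mitocharter", part_type, str(s + 1), str(e),
                    ".", gene.strand, "0" if part_type == "CDS" else ".",
                    f"ID={gene.gene_id}.{part_type.lower()};Parent={gene.gene_id}",
                ]) + "\n")


def read_gff3(path) -> list[GeneModel]:
    """Parse gene models (CDS/exon parts grouped by Parent or ID)."""
    genes: dict[str, GeneModel] = {}
    parts: dict[str, list[tuple[str, int, int, str, str]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = \
                line.rstrip("\n").split("\t")
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = attr["ID"]
                genes[gid] = GeneModel(gene_id=gid, chrom=chrom, parts=[],
                                       strand=strand)
            elif ftype in ("CDS", "exon"):
                parent = attr.get("Parent", attr.get("ID", ""))
                parts.setdefault(parent, []).append(
                    (chrom, int(start) - 1, int(end), strand, ftype))
    for gid, plist in parts.items():
        if gid not in genes:
            chrom, s, e, strand, ftype = plist[0]
            genes[gid] = GeneModel(gene_id=gid, chrom=chrom, parts=[],
                                   strand=strand,
                                   kind="gene" if ftype == "CDS" else "tRNA")
        genes[gid].parts = [(s, e) for _c, s, e, _st, _ft in sorted(plist)]
    out = [g for g in genes.values() if g.parts]
    out.sort(key=lambda g: (g.chrom, g.start))
    return out


def extract_cds(genome: list[CircularSequence], genes: list[GeneModel],
                ) -> dict[str, str]:
    """Splice each gene's CDS from the genome, strand-aware; a part with
    end > chromosome length wraps around the origin on circular sequences."""
    seqs = {c.id: (c.seq, c.circular) for c in genome}
    out = {}
    for gene in genes:
        seq, circular = seqs[gene.chrom]
        template = seq + seq if circular else seq
        spliced = "".join(template[s:e] for s, e in gene.parts)
        if gene.strand == "-":
            from mitocharter.sequtil import revcomp
            spliced = revcomp(spliced)
        out[gene.gene_id] = spliced
    return out


def write_manifest(manifest, path) -> None:
    """Truth-manifest TSV: kind, chrom, start, end, strand, payload (the
    remaining fields as key=value pairs joined with ';')."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for row in manifest.to_rows():
            core = {k: row[k] for k in ("kind", "chrom", "start", "end", "strand")}
            payload = ";".join(f"{k}={v}" for k, v in row.items()
                               if k not in core)
            writer.writerow([core["kind"], core["chrom"], core["start"],
                             core["end"], core["strand"], payload])


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
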