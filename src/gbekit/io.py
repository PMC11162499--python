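"""File formats: FASTA/FASTQ via Biopython, GFF3 gene models via gffutils.

Coordinates convert at the boundary: GFF3 is 1-based inclusive on disk,
:class:`~gbekit.genes.GeneModel` is 0-based half-open in memory. Tables are
TSV with a header row and '.' for absent values; summaries are JSON.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genes import GeneModel


def read_fasta(path) -> dict[str, str]:
    """Named sequences in file order; duplicate identifiers are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        warnings.warn(f"no FASTA records found in {path}")
    return out


def write_fasta(records: dict[str, str], path, width: int = 60) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_fastq(path) -> list[str]:
    """Read sequences only; base qualities are ignored by the quantifier."""
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: list[str], path, quality: int = 40, prefix: str = "read") -> None:
    recs = []
    for i, seq in enumerate(reads):
        rec = SeqRecord(Seq(seq), id=f"{prefix}{i}", description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff3_genes(path, sequences: dict[str, str]) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into :class:`GeneModel` objects.

    Each gene's locus sequence is the FASTA record named by its seqid (one
    toy locus per contig). The first mRNA of each gene supplies the exon
    and CDS structure. Features beyond the sequence length or CDS outside
    exons fail validation.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in sequences:
            raise ValueError(f"no sequence for seqid {gene.seqid!r}")
        seq = sequences[gene.seqid]
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parent = mrnas[0] if mrnas else gene
        exons = tuple(
            sorted((f.start - 1, f.end) for f in db.children(parent, featuretype="exon"))
        )
        cds = tuple(
            sorted((f.start - 1, f.end) for f in db.children(parent, featuretype="CDS"))
        )
        for s, e in exons:
            if e > len(seq):
                raise ValueError(
                    f"gene {gene.id}: exon ({s},{e}) beyond sequence length {len(seq)}"
                )
        genes.append(
            GeneModel(
                id=gene.id,
                sequence=seq,
                strand=gene.strand,
                exons=exons,
                cds=cds or None,
            )
        )
    return genes


def write_gff3(genes: list[GeneModel], path) -> None:
    """Write gene/mRNA/exon/CDS features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            L = len(g.sequence)
            fh.write(f"##sequence-region {g.id} 1 {L}\n")
            span = (min(s for s, _ in g.exons) + 1, max(e for _, e in g.exons))
            base = f"{g.id}\tgbekit\t"
            attrs = f"ID={g.id}"
            fh.write(f"{base}gene\t{span[0]}\t{span[1]}\t.\t{g.strand}\t.\t{attrs}\n")
            mrna = f"{g.id}.t1"
            fh.write(
                f"{base}mRNA\t{span[0]}\t{span[1]}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.id}\n"
            )
            for i, (s, e) in enumerate(g.exons):
                fh.write(
                    f"{base}exon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )
            if g.cds:
                order = g.cds if g.strand == "+" else tuple(reversed(g.cds))
                cum = 0
                phases = {}
                for s, e in order:
                    phases[(s, e)] = (3 - cum % 3) % 3
                    cum += e - s
                for i, (s, e) in enumerate(g.cds):
                    fh.write(
                        f"{base}CDS\t{s + 1}\t{e}\t.\t{g.strand}\t{phases[(s, e)]}\t"
                        f"ID={mrna}.cds{i};Parent={mrna}\n"
                    )
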