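"""Readers and writers for FASTA, GFF3, BED6 and the pipeline's TSV tables.

GFF3 is 1-based inclusive on disk and converted to the internal 0-based
half-open convention at this boundary.  Reading uses :mod:`gffutils`
(in-memory database); writing is deterministic so that read -> write ->
read is a fixed point.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    DomainAnnotation,
    GenomeSequence,
    GenomicInterval,
    JunctionCountRecord,
    TranscriptModel,
    ValidationError,
)

logger = logging.getLogger(__name__)


class Gff3ParseError(ValueError):
    """Raised for a malformed GFF3 feature hierarchy."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, GenomeSequence]:
    """Read a (multi-contig) FASTA into GenomeSequence objects keyed by
    contig name."""
    genomes: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genomes[rec.id] = GenomeSequence(rec.id, str(rec.seq))
    return genomes


def write_fasta(path: str | os.PathLike, genomes: Iterable[GenomeSequence]) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.contig_name, description="")
        for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read gene/mRNA/exon/CDS features into TranscriptModels.

    Coordinates are converted from 1-based inclusive to 0-based half-open;
    exons are sorted; TranscriptModel invariants are enforced (a CDS
    outside the exon union raises :class:`ValidationError`).
    """
    text = open(path).read()
    if not any(line.strip() and not line.startswith("#") for line in text.splitlines()):
        logger.warning("GFF3 file %s contains no features", path)
        return []
    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True, merge_strategy="create_unique"
    )
    transcripts: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        parents = list(db.parents(mrna, featuretype="gene"))
        if not parents:
            raise Gff3ParseError(f"mRNA {mrna.id} has no gene parent")
        gene_id = parents[0].id
        exons = sorted(
            db.children(mrna, featuretype="exon"), key=lambda f: f.start
        )
        if not exons:
            raise Gff3ParseError(f"mRNA {mrna.id} has no exon children")
        cds = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not cds:
            raise Gff3ParseError(f"mRNA {mrna.id} has no CDS children")
        intervals = tuple(
            GenomicInterval(mrna.seqid, e.start - 1, e.end, mrna.strand)
            for e in exons
        )
        transcripts.append(
            TranscriptModel(
                transcript_id=mrna.id,
                gene_id=gene_id,
                intervals=intervals,
                cds_start=cds[0].start - 1,
                cds_end=cds[-1].end,
            )
        )
    return transcripts


def _cds_pieces(t: TranscriptModel) -> list[tuple[int, int, int]]:
    """(start, end, phase) of per-exon CDS pieces in genomic order."""
    pieces = []
    for iv in t.intervals:
        s = max(iv.start, t.cds_start)
        e = min(iv.end, t.cds_end)
        if s < e:
            pieces.append((s, e))
    phases = {}
    cum = 0
    ordered = pieces if t.strand == "+" else pieces[::-1]
    for s, e in ordered:
        phases[(s, e)] = (3 - cum % 3) % 3
        cum += e - s
    return [(s, e, phases[(s, e)]) for s, e in pieces]


def write_gff3(path: str | os.PathLike, transcripts: Sequence[TranscriptModel]) -> None:
    """Write gene -> mRNA -> exon/CDS features, 1-based inclusive."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    lines = ["##gff-version 3"]
    for gene_id in sorted(
        by_gene, key=lambda g: (by_gene[g][0].contig, by_gene[g][0].span.start, g)
    ):
        ts = sorted(by_gene[gene_id], key=lambda t: t.transcript_id)
        contig = ts[0].contig
        strand = ts[0].strand
        g_start = min(t.span.start for t in ts)
        g_end = max(t.span.end for t in ts)
        lines.append(
            f"{contig}\tsplicegain\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t"
            f"ID={gene_id}"
        )
        for t in ts:
            lines.append(
                f"{contig}\tsplicegain\tmRNA\t{t.span.start + 1}\t{t.span.end}\t.\t"
                f"{strand}\t.\tID={t.transcript_id};Parent={gene_id}"
            )
            for i, iv in enumerate(t.intervals, 1):
                lines.append(
                    f"{contig}\tsplicegain\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{strand}\t.\tID={t.transcript_id}.exon{i};Parent={t.transcript_id}"
                )
            for i, (s, e, phase) in enumerate(_cds_pieces(t), 1):
                lines.append(
                    f"{contig}\tsplicegain\tCDS\t{s + 1}\t{e}\t.\t{strand}\t{phase}\t"
                    f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}"
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def write_bed6(
    path: str | os.PathLike,
    intervals: Iterable[tuple[GenomicInterval, str, float]],
) -> None:
    """Write (interval, name, score) triples as BED6; scores in [0, 1]
    are scaled to the conventional 0-1000 range."""
    with open(path, "w") as fh:
        for iv, name, score in intervals:
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t"
                f"{int(round(score * 1000))}\t{iv.strand}\n"
            )


def read_bed6(path: str | os.PathLike) -> list[tuple[GenomicInterval, str, float]]:
    out = []
    for line in open(path):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        contig, start, end, name, score, strand = line.rstrip("\n").split("\t")[:6]
        out.append(
            (
                GenomicInterval(contig, int(start), int(end), strand),
                name,
                float(score) / 1000.0,
            )
        )
    return out


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_junction_counts(path: str | os.PathLike) -> list[JunctionCountRecord]:
    """Read the long-format counts table (event_id, sample_id,
    junction_role, junction_index, count) into per-(event, sample)
    records."""
    df = pd.read_csv(path, sep="\t")
    required = {"event_id", "sample_id", "junction_role", "junction_index", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"counts table missing columns {sorted(missing)}")
    records = []
    for (event_id, sample_id), grp in df.groupby(
        ["event_id", "sample_id"], sort=True
    ):
        inc = grp[grp.junction_role == "inc"].sort_values("junction_index")
        skip = grp[grp.junction_role == "skip"].sort_values("junction_index")
        records.append(
            JunctionCountRecord(
                str(event_id),
                str(sample_id),
                tuple(int(c) for c in inc["count"]),
                tuple(int(c) for c in skip["count"]),
            )
        )
    return records


def write_junction_counts(
    path: str | os.PathLike, records: Iterable[JunctionCountRecord]
) -> None:
    rows = []
    for r in records:
        for i, c in enumerate(r.inclusion_counts):
            rows.append((r.event_id, r.sample_id, "inc", i, c))
        for i, c in enumerate(r.skipping_counts):
            rows.append((r.event_id, r.sample_id, "skip", i, c))
    pd.DataFrame(
        rows, columns=["event_id", "sample_id", "junction_role", "junction_index", "count"]
    ).to_csv(path, sep="\t", index=False)


def read_domains(path: str | os.PathLike) -> dict[str, list[DomainAnnotation]]:
    """Read the domains table (gene_id, domain_name, aa_start, aa_end)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[DomainAnnotation]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.gene_id), []).append(
            DomainAnnotation(str(row.domain_name), int(row.aa_start), int(row.aa_end))
        )
    return out


def write_domains(
    path: str | os.PathLike, domains: Mapping[str, Sequence[DomainAnnotation]]
) -> None:
    rows = [
        (gene, d.name, d.aa_start, d.aa_end)
        for gene, ds in domains.items()
        for d in ds
    ]
    pd.DataFrame(
        rows, columns=["gene_id", "domain_name", "aa_start", "aa_end"]
    ).to_csv(path, sep="\t", index=False)


def read_inhibitor_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read the +/-inhibitor abundance table (stage, replicate, treated,
    abundance)."""
    df = pd.read_csv(path, sep="\t")
    required = {"stage", "replicate", "treated", "abundance"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"inhibitor table missing columns {sorted(missing)}")
    return df
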