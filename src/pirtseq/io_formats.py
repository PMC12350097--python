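"""Readers and writers for the standard formats the pipeline touches.

One coordinate convention rules the package: 0-based half-open on the
forward strand. Every reader converts into it at the boundary (GFF3 and
SAM are 1-based inclusive on disk) and every writer converts back out.

FASTA/FASTQ go through Biopython, SAM through pysam, GFF3 through
gffutils; BED6, Artemis userplots and TSV site tables are line formats
written directly.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = frozenset("ACGTN")

SITE_COLUMNS = ["contig", "pos", "orientation", "read_count", "sample"]


@dataclass
class GenomeSeq:
    """A single contig: uppercase A/C/G/T/N sequence plus a circularity flag."""

    contig_id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"contig {self.contig_id!r}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """An annotated CDS interval.

    ``start``/``end`` are 0-based half-open. A model whose length is not a
    multiple of 3 (pseudogenes, annotation artefacts) is kept but flagged
    non-phaseable and excluded from reading-frame classification.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: bad interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def phaseable(self) -> bool:
        return self.length % 3 == 0


@dataclass
class ReadRecord:
    """A sequencing read (or trimmed genomic fragment)."""

    read_id: str
    bases: str
    quals: str | None = None
    sample_tag: str = ""

    def __post_init__(self) -> None:
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(f"read {self.read_id!r}: bases/quals length mismatch")

    def __len__(self) -> int:
        return len(self.bases)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path, circular: bool = False) -> list[GenomeSeq]:
    """Read a (optionally gzipped) FASTA file into :class:`GenomeSeq` records.

    Sequences are uppercased and U mapped to T. Duplicate contig ids and
    empty files are errors.
    """
    genomes: list[GenomeSeq] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
            seen.add(rec.id)
            genomes.append(GenomeSeq(rec.id, str(rec.seq), circular=circular))
    if not genomes:
        raise ValueError(f"no FASTA records in {path}")
    return genomes


def write_fasta(genomes: Iterable[GenomeSeq], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.contig_id, description="") for g in genomes]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a (optionally gzipped) 4-line FASTQ file."""
    with _open_text(path) as fh:
        for title, seq, qual in SeqIO.QualityIO.FastqGeneralIterator(fh):
            yield ReadRecord(title.split()[0], seq.upper(), qual)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = r.quals if r.quals is not None else "I" * len(r.bases)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qual}\n")


def read_annotation(
    path: str | Path,
    format: str = "gff3",
    feature_type: str = "CDS",
    source_label: str = "",
) -> list[GeneModel]:
    """Load gene models from GFF3 or BED6.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; BED is already 0-based half-open. Only
    ``feature_type`` records are retained from GFF3 (frame classification
    is only meaningful on coding intervals).
    """
    if format == "gff3":
        return _read_gff3(path, feature_type, source_label)
    if format == "bed":
        return _read_bed6(path, source_label)
    raise ValueError(f"unknown annotation format {format!r} (expected gff3 or bed)")


def _read_gff3(path: str | Path, feature_type: str, source_label: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for feat in db.features_of_type(feature_type):
        if feat.strand not in {"+", "-"}:
            raise ValueError(f"{path}: unknown strand {feat.strand!r} for feature {feat.id}")
        gene_id = (
            feat.attributes.get("ID", [None])[0]
            or feat.attributes.get("Name", [None])[0]
            or feat.attributes.get("locus_tag", [None])[0]
            or feat.id
        )
        models.append(
            GeneModel(gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand, source_label)
        )
    return models


def _read_bed6(path: str | Path, source_label: str) -> list[GeneModel]:
    models: list[GeneModel] = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{i + 1}: BED6 needs 6 columns, got {len(parts)}")
            chrom, start, end, name, _score, strand = parts[:6]
            models.append(GeneModel(name, chrom, int(start), int(end), strand, source_label))
    return models


def write_annotation_gff3(models: Iterable[GeneModel], path: str | Path,
                          feature_type: str = "CDS") -> None:
    """Write gene models as GFF3 (converting back to 1-based inclusive)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            src = m.source or "pirtseq"
            fh.write(
                f"{m.contig_id}\t{src}\t{feature_type}\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t0\tID={m.gene_id}\n"
            )


def read_sam_alignments(path: str | Path):
    """Stream primary mapped records from a SAM file.

    Yields pysam ``AlignedSegment`` objects (coordinates already 0-based
    through the pysam API). Unmapped, secondary and supplementary records
    are skipped. A record naming a contig absent from the header is an
    error (raised by pysam at parse time).
    """
    import pysam

    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            yield rec


def write_insertion_plot(sites: pd.DataFrame, contig_length: int, path: str | Path) -> None:
    """Write an Artemis userplot: one line per base, two numeric columns
    (forward-orientation read count, reverse-orientation read count).

    All sites must lie on a single contig; a site at or beyond
    ``contig_length`` is an error.
    """
    if len(sites) and sites["contig"].nunique() > 1:
        raise ValueError("insertion plot: sites span multiple contigs")
    fwd = [0] * contig_length
    rev = [0] * contig_length
    for _, row in sites.iterrows():
        pos = int(row["pos"])
        if pos >= contig_length:
            raise ValueError(f"site position {pos} >= contig length {contig_length}")
        if row["orientation"] == "+":
            fwd[pos] += int(row["read_count"])
        else:
            rev[pos] += int(row["read_count"])
    with _open_text(path, "wt") as fh:
        for f, r in zip(fwd, rev):
            fh.write(f"{f} {r}\n")


def write_site_table(sites: pd.DataFrame, path: str | Path) -> None:
    """Write a site table as BED6-compatible TSV
    (chrom, start, end, name=sample, score=read_count, strand=orientation)."""
    with _open_text(path, "wt") as fh:
        for _, row in sites.iterrows():
            fh.write(
                f"{row['contig']}\t{int(row['pos'])}\t{int(row['pos']) + 1}\t"
                f"{row['sample']}\t{int(row['read_count'])}\t{row['orientation']}\n"
            )


def read_site_table(path: str | Path) -> pd.DataFrame:
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, _end, name, score, strand = line.split("\t")[:6]
            rows.append((chrom, int(start), strand, int(score), name))
    return pd.DataFrame(rows, columns=SITE_COLUMNS)
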