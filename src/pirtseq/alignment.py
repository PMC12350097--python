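"""Placement of trimmed genomic fragments and junction extraction.

The junction convention follows the assay: the FIRST base of the trimmed
read marks the transposon insertion site. On the forward strand that is
the leftmost aligned reference base; on the reverse strand it is the
rightmost (the read runs 5'->3' away from the transposon, so its first
base maps to the highest coordinate). The alternative leftmost-for-minus
convention is selectable for comparison with pipelines that use bare POS.

Two routes produce :class:`MappedFragment` records: importing SAM made
by an external mapper (bwa mem in the original protocol), or the
built-in exact-seed mapper, which is sufficient for desk-scale synthetic
genomes and makes the package self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .dna import hamming, revcomp
from .io_formats import GenomeSeq, ReadRecord


@dataclass
class MappedFragment:
    """A uniquely placed genomic fragment.

    ``junction_pos`` is the genome coordinate of the read's first base
    (the insertion site). Non-unique fragments carry ``unique=False``
    and are excluded downstream.
    """

    read_id: str
    contig_id: str
    junction_pos: int
    strand: str
    unique: bool = True
    mismatches: int = 0
    sample_tag: str = ""


def builtin_map(
    fragment: ReadRecord,
    genome: GenomeSeq,
    seed_len: int = 20,
    max_mismatches: int = 2,
) -> MappedFragment | None:
    """Exact-seed, mismatch-extended mapper for desk-scale genomes.

    The first ``seed_len`` bases must occur exactly (on either strand);
    each seed hit is extended over the full fragment allowing up to
    ``max_mismatches`` substitutions. A unique best hit is required:
    tied best hits return ``None`` (multi-mappers are dropped rather than
    randomly placed, so site lists are reproducible).
    """
    frag = fragment.bases
    if len(frag) < seed_len:
        return None
    seq = genome.sequence
    L = len(seq)
    seed = frag[:seed_len]
    flen = len(frag)

    hits: list[tuple[int, int, str]] = []  # (mismatches, junction_pos, strand)

    # Forward strand: fragment aligns left-to-right from the seed hit.
    p = seq.find(seed)
    while p != -1:
        if p + flen <= L:
            mm = hamming(frag, seq[p : p + flen])
            if mm <= max_mismatches:
                hits.append((mm, p, "+"))
        p = seq.find(seed, p + 1)

    # Reverse strand: search the reverse-complemented genome, then map
    # coordinates back. A hit at rc-index q puts the read's first base at
    # genome position L-1-q.
    rc = revcomp(seq)
    p = rc.find(seed)
    while p != -1:
        if p + flen <= L:
            mm = hamming(frag, rc[p : p + flen])
            if mm <= max_mismatches:
                hits.append((mm, L - 1 - p, "-"))
        p = rc.find(seed, p + 1)

    if not hits:
        return None
    hits.sort()
    if len(hits) > 1 and hits[0][0] == hits[1][0]:
        return MappedFragment(
            fragment.read_id, genome.contig_id, hits[0][1], hits[0][2],
            unique=False, mismatches=hits[0][0], sample_tag=fragment.sample_tag,
        )
    mm, pos, strand = hits[0]
    return MappedFragment(
        fragment.read_id, genome.contig_id, pos, strand,
        unique=True, mismatches=mm, sample_tag=fragment.sample_tag,
    )


def map_fragments(
    fragments: Iterable[ReadRecord],
    genome: GenomeSeq,
    seed_len: int = 20,
    max_mismatches: int = 2,
) -> list[MappedFragment]:
    """Map a batch of fragments, keeping only unique placements."""
    out = []
    for frag in fragments:
        m = builtin_map(frag, genome, seed_len, max_mismatches)
        if m is not None and m.unique:
            out.append(m)
    return out


def junction_from_sam(
    rec,
    max_clip: int = 3,
    minus_strand_junction: str = "first_base",
    sample_tag: str = "",
) -> MappedFragment | None:
    """Convert a primary mapped pysam record to a junction coordinate.

    The junction is the first ALIGNED base of the read: soft-clipped
    leading bases never shift it, but a leading clip longer than
    ``max_clip`` (at the read's 5' end — the transposon-proximal end)
    marks the junction as imprecise and the record is discarded.

    ``minus_strand_junction`` selects between the read's-first-base rule
    (``first_base``, default: rightmost aligned base for reverse-strand
    reads) and bare leftmost POS (``leftmost``).
    """
    if minus_strand_junction not in {"first_base", "leftmost"}:
        raise ValueError(f"unknown minus-strand convention {minus_strand_junction!r}")
    cig = rec.cigartuples
    if cig is None or not any(op in (0, 2, 7, 8) for op, _ in cig):
        raise ValueError(f"read {rec.query_name}: CIGAR consumes no reference bases")
    # 5' end of the original read: first op for forward, last op for reverse.
    end_op = cig[-1] if rec.is_reverse else cig[0]
    if end_op[0] == 4 and end_op[1] > max_clip:  # op 4 == soft clip
        return None
    if rec.is_reverse:
        pos = rec.reference_end - 1 if minus_strand_junction == "first_base" \
            else rec.reference_start
        strand = "-"
    else:
        pos = rec.reference_start
        strand = "+"
    return MappedFragment(
        rec.query_name, rec.reference_name, pos, strand,
        unique=True, sample_tag=sample_tag,
    )


def import_sam(path, max_clip: int = 3, minus_strand_junction: str = "first_base",
               sample_tag: str = "") -> list[MappedFragment]:
    """Read a SAM file and extract junctions from every primary mapped record."""
    from .io_formats import read_sam_alignments

    out = []
    for rec in read_sam_alignments(path):
        frag = junction_from_sam(rec, max_clip, minus_strand_junction, sample_tag)
        if frag is not None:
            out.append(frag)
    return out
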