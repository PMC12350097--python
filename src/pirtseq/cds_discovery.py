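"""Discovery of unannotated protein-coding sequences from reporter fusions.

The selected insertion sites are classified against the annotation by
reading frame. In-frame sites inside annotated CDSs are the positive
control; the remaining out-of-frame and intergenic sites are evidence of
unannotated translation. For each such site the maximal stop-free codon
run (the "stop-to-stop" frame) containing the junction is reconstructed,
sites sharing a terminating stop collapse into one candidate CDS, and a
start codon from a prioritized seven-codon set is assigned — where more
than one occurs, the furthest upstream is used (a conservative rule:
positional precedence is authoritative; the seven-codon ordering
documents relative initiation strength only). A candidate additionally
requires its start codon at or 5' of the 5'-most supporting junction,
because a fusion can only report initiation upstream of the junction.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .dna import DEFAULT_START_CODONS, STOP_CODONS, revcomp
from .insertion_analysis import frame_of_site
from .io_formats import GeneModel, GenomeSeq

IN_FRAME = "IN_FRAME"
OUT_OF_FRAME = "OUT_OF_FRAME"
INTERGENIC = "INTERGENIC"

KLASS_INTERGENIC = "INTERGENIC"
KLASS_NESTED_PLUS1 = "NESTED_SAME_SENSE_PLUS1"
KLASS_NESTED_PLUS2 = "NESTED_SAME_SENSE_PLUS2"
KLASS_NESTED_ANTISENSE = "NESTED_ANTISENSE"


@dataclass
class FrameClassification:
    """Verdict for one insertion site against the annotation."""

    site_ref: tuple  # (contig, pos, orientation)
    verdict: str
    host_gene: str | None = None
    host_source: str | None = None


@dataclass
class StopToStopFrame:
    """A maximal stop-free codon run in one frame/strand.

    ``start``/``end`` bound the run's genomic span (half-open), excluding
    both flanking stop codons; ``stop_pos`` is the genome coordinate of
    the terminating stop codon's first (5'-most on its strand) base.
    """

    strand: str
    frame: int
    start: int
    end: int
    stop_pos: int
    wraps: bool = False


@dataclass
class CandidateCDS:
    cds_id: str
    contig_id: str
    strand: str
    frame: int
    orf_start: int
    orf_end: int
    start_pos: int
    start_codon: str
    stop_pos: int
    length_aa: int
    klass: str = KLASS_INTERGENIC
    parent_gene: str | None = None
    supporting_sites: list = field(default_factory=list)
    replicate_support: int = 1

    def span(self) -> tuple[int, int]:
        """Genomic half-open span from the start codon to the stop
        (exclusive of the stop codon)."""
        if self.strand == "+":
            return (self.start_pos, self.stop_pos)
        return (self.stop_pos + 1, self.start_pos + 1)


@dataclass
class DiscoverySummary:
    n_sites_total: int
    n_in_frame: int
    n_oof: int
    n_intergenic: int
    pct_in_frame: float
    pct_oof: float
    pct_intergenic: float
    n_genes_hit: int
    n_candidates: int
    start_codon_freq: dict
    length_median_aa: float
    length_min_aa: int | None
    length_max_aa: int | None
    n_candidates_intergenic: int
    nested_same_sense: int
    nested_plus1: int
    nested_plus2: int
    nested_antisense: int


class GeneIndex:
    """Interval index over phaseable gene models, preserving load order
    (the order encodes annotation-source priority)."""

    def __init__(self, gene_models: Sequence[GeneModel]):
        self.models = list(gene_models)
        self._trees: dict[str, IntervalTree] = {}
        for i, g in enumerate(self.models):
            if not g.phaseable:
                continue
            self._trees.setdefault(g.contig_id, IntervalTree()).addi(g.start, g.end, i)

    def containing(self, contig: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        idx = sorted(iv.data for iv in tree[pos])
        return [self.models[i] for i in idx]


def _in_frame_with(gene: GeneModel, pos: int, junction_offset: int) -> bool:
    if gene.strand == "+":
        return (pos - gene.start + junction_offset) % 3 == 0
    return (gene.end - 1 - pos + junction_offset) % 3 == 0


def classify_site(
    contig: str,
    pos: int,
    orientation: str,
    gene_index: GeneIndex,
    junction_offset: int = 0,
) -> FrameClassification:
    """Classify one site: IN_FRAME / OUT_OF_FRAME / INTERGENIC.

    A host gene is any phaseable CDS containing the position. IN_FRAME
    requires the gene on the reporter's strand with the reporter frame
    continuing the gene's codon phase; an in-frame verdict against ANY
    loaded annotation source wins (a second annotation can rescue sites
    the primary one misses). A site inside genes only on the opposite
    strand or in the wrong phase is OUT_OF_FRAME; inside none, INTERGENIC.
    """
    key = (contig, pos, orientation)
    hosts = gene_index.containing(contig, pos)
    if not hosts:
        return FrameClassification(key, INTERGENIC)
    for g in hosts:  # load order = source priority
        if g.strand == orientation and _in_frame_with(g, pos, junction_offset):
            return FrameClassification(key, IN_FRAME, g.gene_id, g.source)
    same = [g for g in hosts if g.strand == orientation]
    host = min(same or hosts, key=lambda g: g.start)
    return FrameClassification(key, OUT_OF_FRAME, host.gene_id, host.source)


def classify_sites(
    sites: pd.DataFrame,
    gene_models: Sequence[GeneModel],
    junction_offset: int = 0,
) -> list[FrameClassification]:
    """Classify every row of a site table (order preserved)."""
    index = GeneIndex(gene_models)
    return [
        classify_site(row.contig, int(row.pos), row.orientation, index, junction_offset)
        for row in sites.itertuples(index=False)
    ]


def _codon_at(seq: str, p: int, wraps: bool) -> str:
    if not wraps:
        return seq[p : p + 3]
    L = len(seq)
    return (seq + seq)[p : p + 3] if p + 3 > L else seq[p : p + 3]


def _scan_plus(seq: str, frame: int, anchor: int, circular: bool) -> tuple[int, int, bool] | None:
    """Stop-to-stop scan on a plus-strand sequence; returns
    (run_start, stop_codon_start, wraps) or None if no downstream stop."""
    L = len(seq)
    if anchor % 3 != frame % 3:
        raise ValueError(f"anchor {anchor} not congruent with frame {frame}")
    if circular and L % 3 != 0:
        raise ValueError("circular stop-to-stop scan requires contig length divisible by 3")

    # downstream: the codon containing the anchor is included in the run
    stop_pos = None
    if circular:
        n_codons = L // 3
        for k in range(n_codons):
            p = (anchor + 3 * k) % L
            if _codon_at(seq, p, True) in STOP_CODONS:
                stop_pos = p
                break
        if stop_pos is None:
            return None  # stop-free circle in this frame
        # upstream (wrapping): walk back until a stop
        run_start = None
        for k in range(1, n_codons + 1):
            p = (anchor - 3 * k) % L
            if _codon_at(seq, p, True) in STOP_CODONS:
                run_start = (p + 3) % L
                break
        if run_start is None:
            run_start = (stop_pos + 3) % L
        wraps = run_start > stop_pos
        return run_start, stop_pos, wraps

    p = anchor
    while p + 3 <= L:
        if seq[p : p + 3] in STOP_CODONS:
            stop_pos = p
            break
        p += 3
    if stop_pos is None:
        return None
    p = anchor - 3
    run_start = anchor % 3  # first in-frame codon of the contig
    while p >= 0:
        if seq[p : p + 3] in STOP_CODONS:
            run_start = p + 3
            break
        p -= 3
    return run_start, stop_pos, False


def stop_to_stop(
    genome: GenomeSeq,
    strand: str,
    frame: int,
    anchor_pos: int,
    circular: bool | None = None,
) -> StopToStopFrame | None:
    """The maximal stop-free codon run containing ``anchor_pos``.

    ``anchor_pos`` must be a codon start of the given frame on the given
    strand (for '-', frame is anchored at the contig's last base). On a
    linear contig the run is ``None`` if no downstream stop exists; with
    no upstream stop it starts at the contig's first in-frame codon.
    """
    if circular is None:
        circular = genome.circular
    L = len(genome)
    if strand == "+":
        res = _scan_plus(genome.sequence, frame, anchor_pos, circular)
        if res is None:
            return None
        run_start, sp, wraps = res
        return StopToStopFrame("+", frame, run_start, sp, sp, wraps)
    if strand == "-":
        rc = revcomp(genome.sequence)
        res = _scan_plus(rc, frame, L - 1 - anchor_pos, circular)
        if res is None:
            return None
        run_start, sp, wraps = res
        # rc run [run_start, sp) -> genomic span [L - sp, L - run_start)
        return StopToStopFrame("-", frame, (L - sp) % L, (L - run_start - 1) % L + 1,
                               L - 1 - sp, wraps)
    raise ValueError(f"bad strand {strand!r}")


def choose_start(
    genome: GenomeSeq,
    orf: StopToStopFrame,
    max_pos: int,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
) -> tuple[str, int] | None:
    """Pick the candidate's start codon: scan in-frame codons from the
    5' end of the run toward ``max_pos`` (the 5'-most supporting
    junction) and return the first codon in the start set — i.e. the
    furthest-upstream start. ``None`` if no start codon exists at or 5'
    of ``max_pos``.
    """
    codon_set = {c.upper() for c in start_codons}
    L = len(genome)
    if orf.strand == "+":
        seq = genome.sequence
        five_prime = orf.start
        scan_max = max_pos
    else:
        seq = revcomp(genome.sequence)
        five_prime = (L - orf.end) % L if orf.wraps else L - orf.end
        scan_max = L - 1 - max_pos
    dist = (scan_max - five_prime) % L if orf.wraps else scan_max - five_prime
    if dist < 0 or dist % 3 != 0:
        raise ValueError("max_pos is not on the run's codon grid")
    for k in range(dist // 3 + 1):
        p = (five_prime + 3 * k) % L if orf.wraps else five_prime + 3 * k
        codon = _codon_at(seq, p, orf.wraps)
        if codon in codon_set:
            start_genome = p if orf.strand == "+" else L - 1 - p
            return codon, start_genome
    return None


def call_candidates(
    sites: pd.DataFrame,
    classifications: Sequence[FrameClassification],
    genome: GenomeSeq,
    gene_models: Sequence[GeneModel],
    junction_offset: int = 0,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
    require_start_upstream: bool = True,
) -> list[CandidateCDS]:
    """Reconstruct candidate CDSs from OUT_OF_FRAME and INTERGENIC sites.

    Sites sharing (contig, strand, frame, stop_pos) collapse into one
    candidate; the start-codon search is bounded by the 5'-most
    supporting junction unless ``require_start_upstream`` is disabled
    (in which case the whole run is searched). Candidates whose run
    contains no start codon are dropped. ``sites`` is expected to be the
    replicate-filtered table; replicate support is recounted from the
    sample tags carried by the supporting sites.
    """
    L = len(genome)
    groups: dict[tuple, dict] = {}
    for row, cls in zip(sites.itertuples(index=False), classifications):
        if cls.verdict not in {OUT_OF_FRAME, INTERGENIC}:
            continue
        pos, orient = int(row.pos), row.orientation
        j = pos + junction_offset if orient == "+" else pos - junction_offset
        if not (0 <= j < L):
            continue
        rf = frame_of_site(pos, orient, L, junction_offset)
        orf = stop_to_stop(genome, orient, rf.frame, j)
        if orf is None:
            continue
        key = (row.contig, orient, rf.frame, orf.stop_pos)
        g = groups.setdefault(key, {"orf": orf, "junctions": [], "sites": [], "samples": set()})
        g["junctions"].append(j)
        g["sites"].append((row.contig, pos, orient))
        for tag in str(row.sample).split("&"):
            g["samples"].add(tag)

    candidates: list[CandidateCDS] = []
    for (contig, strand, frame, sp), g in groups.items():
        orf = g["orf"]
        if require_start_upstream:
            max_pos = min(g["junctions"]) if strand == "+" else max(g["junctions"])
        else:
            # search the whole run: bound at the last codon before the stop
            max_pos = (sp - 3) % L if strand == "+" else (sp + 3) % L
        picked = choose_start(genome, orf, max_pos, start_codons)
        if picked is None:
            continue
        codon, start_pos = picked
        dist = (sp - start_pos) if strand == "+" else (start_pos - sp)
        length_aa = (dist % L if orf.wraps else dist) // 3
        candidates.append(
            CandidateCDS(
                cds_id="",  # numbered below, in genome order
                contig_id=contig,
                strand=strand,
                frame=frame,
                orf_start=orf.start,
                orf_end=orf.end,
                start_pos=start_pos,
                start_codon=codon,
                stop_pos=sp,
                length_aa=length_aa,
                supporting_sites=sorted(g["sites"]),
                replicate_support=len(g["samples"]),
            )
        )
    candidates.sort(key=lambda c: (c.contig_id, min(c.span()), c.strand, c.frame))
    for i, cand in enumerate(candidates, start=1):
        cand.cds_id = f"CDS{i}"
        classify_candidate(cand, gene_models)
    return candidates


def classify_candidate(
    candidate: CandidateCDS,
    gene_models: Sequence[GeneModel],
    overlap_min: int = 1,
) -> CandidateCDS:
    """Assign the nested/intergenic class and parent gene in place.

    The parent is the phaseable annotated CDS with the largest overlap
    (>= ``overlap_min`` bp of the candidate's start-to-stop span; ties
    go to the 5'-most parent). Same strand implies a nested gene with a
    +1 or +2 frameshift relative to the parent's codon phase; opposite
    strand is antisense; no overlap is intergenic.
    """
    s, e = candidate.span()
    scored = []
    for g in gene_models:
        if g.contig_id != candidate.contig_id or not g.phaseable:
            continue
        ov = min(e, g.end) - max(s, g.start)
        if ov >= overlap_min:
            scored.append((-ov, g.start, g))
    candidate.klass, candidate.parent_gene = KLASS_INTERGENIC, None
    for _negov, _gstart, parent in sorted(scored, key=lambda t: (t[0], t[1])):
        if parent.strand != candidate.strand:
            candidate.klass = KLASS_NESTED_ANTISENSE
            candidate.parent_gene = parent.gene_id
            break
        if parent.strand == "+":
            shift = (candidate.start_pos - parent.start) % 3
        else:
            shift = ((parent.end - 1) - candidate.start_pos) % 3
        if shift == 0:
            # in the parent's own phase: not a nested frame — try the
            # next-best overlapping gene
            warnings.warn(
                f"{candidate.cds_id}: overlaps {parent.gene_id} in its own frame; "
                "skipping as parent"
            )
            continue
        candidate.klass = KLASS_NESTED_PLUS1 if shift == 1 else KLASS_NESTED_PLUS2
        candidate.parent_gene = parent.gene_id
        break
    return candidate


def translate_candidate(genome: GenomeSeq, candidate: CandidateCDS) -> str:
    """Amino-acid sequence from the chosen start to the stop (exclusive)."""
    from Bio.Seq import Seq

    L = len(genome)
    if candidate.strand == "+":
        if candidate.stop_pos >= candidate.start_pos:
            nt = genome.sequence[candidate.start_pos : candidate.stop_pos]
        else:  # wrapped
            nt = (genome.sequence + genome.sequence)[candidate.start_pos : candidate.stop_pos + L]
    else:
        lo, hi = candidate.stop_pos + 1, candidate.start_pos + 1
        if hi > lo:
            nt = revcomp(genome.sequence[lo:hi])
        else:
            nt = revcomp((genome.sequence + genome.sequence)[lo : hi + L])
    return str(Seq(nt).translate(table=11))


def summarize(
    classifications: Sequence[FrameClassification],
    candidates: Sequence[CandidateCDS],
) -> DiscoverySummary:
    """Partition counts/percentages, start-codon usage and length stats.

    Percentages are reported to 2 decimal places with round-half-up.
    """
    n_total = len(classifications)
    n_if = sum(c.verdict == IN_FRAME for c in classifications)
    n_oof = sum(c.verdict == OUT_OF_FRAME for c in classifications)
    n_int = sum(c.verdict == INTERGENIC for c in classifications)
    assert n_if + n_oof + n_int == n_total

    codon_counts: dict[str, int] = {}
    for cand in candidates:
        codon_counts[cand.start_codon] = codon_counts.get(cand.start_codon, 0) + 1
    start_codon_freq = {
        codon: {"count": n, "pct": _pct(n, len(candidates))}
        for codon, n in sorted(codon_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }
    lengths = sorted(c.length_aa for c in candidates)
    return DiscoverySummary(
        n_sites_total=n_total,
        n_in_frame=n_if,
        n_oof=n_oof,
        n_intergenic=n_int,
        pct_in_frame=_pct(n_if, n_total),
        pct_oof=_pct(n_oof, n_total),
        pct_intergenic=_pct(n_int, n_total),
        n_genes_hit=len({c.host_gene for c in classifications if c.verdict == IN_FRAME}),
        n_candidates=len(candidates),
        start_codon_freq=start_codon_freq,
        length_median_aa=float(statistics.median(lengths)) if lengths else float("nan"),
        length_min_aa=lengths[0] if lengths else None,
        length_max_aa=lengths[-1] if lengths else None,
        n_candidates_intergenic=sum(c.klass == KLASS_INTERGENIC for c in candidates),
        nested_same_sense=sum(
            c.klass in {KLASS_NESTED_PLUS1, KLASS_NESTED_PLUS2} for c in candidates
        ),
        nested_plus1=sum(c.klass == KLASS_NESTED_PLUS1 for c in candidates),
        nested_plus2=sum(c.klass == KLASS_NESTED_PLUS2 for c in candidates),
        nested_antisense=sum(c.klass == KLASS_NESTED_ANTISENSE for c in candidates),
    )


def _pct(count: int, total: int) -> float:
    if total == 0:
        return float("nan")
    q = (Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


def write_candidates_gff3(candidates: Iterable[CandidateCDS], path) -> None:
    """Candidates as GFF3 CDS features (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in candidates:
            s, e = c.span()
            attrs = (
                f"ID={c.cds_id};start_codon={c.start_codon};klass={c.klass};"
                f"parent={c.parent_gene or '.'};n_sites={len(c.supporting_sites)};"
                f"replicate_support={c.replicate_support}"
            )
            fh.write(
                f"{c.contig_id}\tpirtseq\tCDS\t{s + 1}\t{e + 3}\t.\t{c.strand}\t0\t{attrs}\n"
            )


def write_candidates_tsv(candidates: Iterable[CandidateCDS], genome: GenomeSeq, path) -> None:
    cols = [
        "cds_id", "contig", "strand", "frame", "start_pos", "start_codon", "stop_pos",
        "length_aa", "klass", "parent_gene", "n_sites", "replicate_support", "protein",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        c.cds_id, c.contig_id, c.strand, c.frame, c.start_pos,
                        c.start_codon, c.stop_pos, c.length_aa, c.klass,
                        c.parent_gene or ".", len(c.supporting_sites),
                        c.replicate_support, translate_candidate(genome, c),
                    ]
                )
                + "\n"
            )
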