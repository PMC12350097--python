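"""Demultiplexing and transposon trimming.

Reads from the assay look like::

    [sample barcode][transposon tail .... segment1 | segment2][genomic DNA]

The barcode is anchored at the 5' end. The transposon tail is located by
a two-step search — a seed segment found by a minimum-mismatch scan, and
a confirmation segment required immediately after it — with one shared
substitution budget (default 4) across both segments. Everything after
the transposon is the genomic fragment whose first base marks the
insertion junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator

from .dna import hamming
from .io_formats import ReadRecord


@dataclass
class BarcodeTable:
    """Sample barcodes anchored at the read 5' end.

    All barcodes must share one length and be pairwise distinct; when a
    mismatch tolerance ``m`` is used the pairwise Hamming distance must
    be >= 2m+1 so that assignment is unambiguous.
    """

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("barcode table is empty")
        self.entries = {k: v.upper() for k, v in self.entries.items()}
        lengths = {len(v) for v in self.entries.values()}
        if len(lengths) != 1:
            raise ValueError(f"barcodes must share one length, got {sorted(lengths)}")
        if len(set(self.entries.values())) != len(self.entries):
            raise ValueError("barcodes are not pairwise distinct")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.entries.values())))

    def min_pairwise_distance(self) -> int:
        if len(self.entries) == 1:
            return self.barcode_length
        return min(hamming(a, b) for a, b in combinations(self.entries.values(), 2))

    def validate_tolerance(self, allowed_mismatches: int) -> None:
        if allowed_mismatches > 0:
            need = 2 * allowed_mismatches + 1
            have = self.min_pairwise_distance()
            if have < need:
                raise ValueError(
                    f"barcode distance {have} too small for tolerance "
                    f"{allowed_mismatches} (need >= {need})"
                )

    @classmethod
    def from_tsv(cls, path) -> "BarcodeTable":
        entries: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                tag, bc = line.split("\t")[:2]
                entries[tag] = bc
        return cls(entries)


@dataclass
class TnQuery:
    """The two-segment transposon query with its shared mismatch budget."""

    segment1: str
    segment2: str
    total_mismatch_budget: int = 4

    def __post_init__(self) -> None:
        self.segment1 = self.segment1.upper()
        self.segment2 = self.segment2.upper()
        if not self.segment1 or not self.segment2:
            raise ValueError("transposon query segments must be non-empty")
        if self.total_mismatch_budget < 0:
            raise ValueError("mismatch budget must be >= 0")

    def __len__(self) -> int:
        return len(self.segment1) + len(self.segment2)


@dataclass
class TnMatch:
    """Location of the transposon end within a read (0-based, exclusive)."""

    read_id: str
    tn_end_offset: int
    mismatches_used: int


@dataclass
class DemuxResult:
    """Per-sample read bins plus bookkeeping counters."""

    bins: dict[str, list[ReadRecord]]
    unassigned: list[ReadRecord]
    n_ambiguous: int = 0

    @property
    def counts(self) -> dict[str, int]:
        out = {tag: len(reads) for tag, reads in self.bins.items()}
        out["unassigned"] = len(self.unassigned)
        return out


def demultiplex(
    reads: Iterable[ReadRecord],
    barcode_table: BarcodeTable,
    allowed_mismatches: int = 0,
) -> DemuxResult:
    """Assign each read to at most one sample by its 5' barcode.

    The barcode is stripped from assigned reads. A read matching two
    barcodes within tolerance is ambiguous and goes to the unassigned
    bin. Bin sizes always sum to the input read count.
    """
    barcode_table.validate_tolerance(allowed_mismatches)
    blen = barcode_table.barcode_length
    result = DemuxResult(bins={tag: [] for tag in barcode_table.entries}, unassigned=[])
    for read in reads:
        if len(read.bases) < blen:
            result.unassigned.append(read)
            continue
        prefix = read.bases[:blen]
        hits = [
            tag
            for tag, bc in barcode_table.entries.items()
            if hamming(prefix, bc) <= allowed_mismatches
        ]
        if len(hits) == 1:
            tag = hits[0]
            result.bins[tag].append(
                ReadRecord(
                    read.read_id,
                    read.bases[blen:],
                    read.quals[blen:] if read.quals is not None else None,
                    sample_tag=tag,
                )
            )
        else:
            if len(hits) > 1:
                result.n_ambiguous += 1
            result.unassigned.append(read)
    return result


def find_transposon(read: ReadRecord, tn_query: TnQuery) -> TnMatch | None:
    """Two-step transposon search with a shared substitution budget.

    Segment 1 is scanned over every read offset; segment 2 must follow
    immediately. The offset minimising the combined Hamming distance
    wins (leftmost on ties) and the match is accepted iff that distance
    is within the total budget. Substitutions only — no indels.
    """
    s1, s2 = tn_query.segment1, tn_query.segment2
    total_len = len(s1) + len(s2)
    bases = read.bases
    if len(bases) < total_len:
        return None
    best_off, best_mm = None, None
    for off in range(len(bases) - total_len + 1):
        mm = hamming(bases[off : off + len(s1)], s1)
        if mm > tn_query.total_mismatch_budget:
            continue  # segment 2 cannot repair an over-budget seed
        mm += hamming(bases[off + len(s1) : off + total_len], s2)
        if best_mm is None or mm < best_mm:
            best_off, best_mm = off, mm
            if mm == 0:
                break
    if best_mm is None or best_mm > tn_query.total_mismatch_budget:
        return None
    return TnMatch(read.read_id, best_off + total_len, best_mm)


def trim_to_genomic(
    read: ReadRecord, tn_match: TnMatch, min_frag_len: int = 20
) -> ReadRecord | None:
    """Return the genomic suffix of a transposon-positive read.

    Fragments shorter than ``min_frag_len`` are discarded (``None``), a
    counted filtering outcome rather than an error.
    """
    frag = read.bases[tn_match.tn_end_offset :]
    if len(frag) < min_frag_len:
        return None
    quals = read.quals[tn_match.tn_end_offset :] if read.quals is not None else None
    return ReadRecord(read.read_id, frag, quals, sample_tag=read.sample_tag)


@dataclass
class TrimStats:
    """Read-conservation log for one sample: every input read lands in
    exactly one of these counters."""

    n_input: int = 0
    n_trimmed: int = 0
    n_tn_negative: int = 0
    n_too_short: int = 0

    def check(self) -> None:
        assert self.n_trimmed + self.n_tn_negative + self.n_too_short == self.n_input


def trim_reads(
    reads: Iterable[ReadRecord],
    tn_query: TnQuery,
    min_frag_len: int = 20,
) -> tuple[list[ReadRecord], TrimStats]:
    """Run ``find_transposon`` + ``trim_to_genomic`` over a read bin."""
    stats = TrimStats()
    fragments: list[ReadRecord] = []
    for read in reads:
        stats.n_input += 1
        match = find_transposon(read, tn_query)
        if match is None:
            stats.n_tn_negative += 1
            continue
        frag = trim_to_genomic(read, match, min_frag_len)
        if frag is None:
            stats.n_too_short += 1
            continue
        stats.n_trimmed += 1
        fragments.append(frag)
    stats.check()
    return fragments, stats
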