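"""End-to-end orchestration: simulate -> demux -> trim -> map -> call ->
intersect -> discover, with recovery scoring against the simulator truth.

This is the convenience layer the examples, CLI and acceptance runs sit
on; each step is the corresponding module function, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from . import cds_discovery, insertion_analysis, read_processing
from .alignment import map_fragments
from .cds_discovery import CandidateCDS, DiscoverySummary, FrameClassification
from .insertion_analysis import ReplicateStats
from .io_formats import ReadRecord
from .read_processing import BarcodeTable, TnQuery
from .simulator import (
    Insertion,
    SimConfig,
    SimTruth,
    apply_selection,
    emit_reads,
    simulate_genome,
    simulate_library,
)


@dataclass
class PipelineResult:
    truth: SimTruth
    library: list
    selections: dict
    sites: dict  # sample -> site table
    shared_sites: pd.DataFrame
    replicate_stats: ReplicateStats
    classifications: list
    candidates: list
    summary: DiscoverySummary
    trim_stats: dict = field(default_factory=dict)

    def frame_chisq_pvalue(self, sample: str = "chlor") -> float:
        """Chi-square p-value for uniformity of the six reporter frames
        in the given sample's site table."""
        counts = insertion_analysis.frame_counts(self.sites[sample], len(self.truth.genome))
        return float(stats.chisquare(list(counts.values())).pvalue)


def process_sample(
    reads: list[ReadRecord],
    genome,
    tn_query: TnQuery,
    sample_tag: str,
    min_frag_len: int = 20,
    seed_len: int = 20,
    max_mismatches: int = 2,
):
    """FASTQ bin -> trimmed fragments -> unique junctions -> site table."""
    fragments, trim_stats = read_processing.trim_reads(reads, tn_query, min_frag_len)
    mapped = map_fragments(fragments, genome, seed_len, max_mismatches)
    sites = insertion_analysis.call_sites(mapped, sample_tag)
    return sites, mapped, trim_stats


def run_simulated_screen(
    config: SimConfig,
    barcode_mismatches: int = 1,
    junction_offset: int = 0,
) -> PipelineResult:
    """Simulate one full experiment and analyse it with the standard
    pipeline.

    One library is drawn and selected twice (the two kanamycin screens);
    the chloramphenicol-selected input pool is sequenced unselected.
    Reads from all three samples are demultiplexed together, per-sample
    junctions are called, the two screens are intersected and candidate
    CDSs discovered against the simulated annotation.
    """
    truth = simulate_genome(config)
    library = simulate_library(truth, config, replicate_id=0)
    sel = {
        "kanA": apply_selection(library, truth, config, screen_id=1),
        "kanB": apply_selection(library, truth, config, screen_id=2),
    }
    reads: list[ReadRecord] = []
    reads += emit_reads(library, truth, config, "chlor", stream_id=0)
    reads += emit_reads([i for i in sel["kanA"] if i.survived], truth, config, "kanA", stream_id=1)
    reads += emit_reads([i for i in sel["kanB"] if i.survived], truth, config, "kanB", stream_id=2)

    demux = read_processing.demultiplex(reads, BarcodeTable(config.barcodes), barcode_mismatches)
    tn_query = TnQuery(config.tn_segment1, config.tn_segment2)
    sites, trim_stats = {}, {}
    for tag, bin_reads in demux.bins.items():
        sites[tag], _, trim_stats[tag] = process_sample(bin_reads, truth.genome, tn_query, tag)

    shared = insertion_analysis.intersect_replicates(sites["kanA"], sites["kanB"])
    rep_stats = insertion_analysis.replicate_correlation(sites["kanA"], sites["kanB"], truth.genes)
    classifications = cds_discovery.classify_sites(shared, truth.genes, junction_offset)
    candidates = cds_discovery.call_candidates(
        shared, classifications, truth.genome, truth.genes, junction_offset
    )
    summary = cds_discovery.summarize(classifications, candidates)
    truth.insertions = {"library": library, **sel}
    return PipelineResult(
        truth=truth,
        library=library,
        selections=sel,
        sites=sites,
        shared_sites=shared,
        replicate_stats=rep_stats,
        classifications=classifications,
        candidates=candidates,
        summary=summary,
        trim_stats=trim_stats,
    )


@dataclass
class RecoveryReport:
    n_hidden_expressed: int
    n_qualifying: int          # expressed hidden CDSs hit in-frame in BOTH screens
    n_recovered: int           # qualifying ones reported with exact (strand, frame, stop)
    recovery_pct: float
    n_unexpected_candidates: int  # candidates matching no planted hidden CDS
    n_unexpressed_reported: int   # planted-but-unexpressed CDSs reported (must be 0)


def score_recovery(result: PipelineResult) -> RecoveryReport:
    """Compare discovered candidates with the simulator's ground truth.

    A hidden CDS qualifies if it is expressed and received at least one
    surviving in-frame fusion in both screens; it counts as recovered if
    a candidate reports its exact (strand, frame, stop position).
    """
    truth = result.truth
    hit_features = {}
    for tag in ("kanA", "kanB"):
        hit_features[tag] = {
            i.feature for i in result.selections[tag] if i.cause == "in_frame_fusion"
        }
    qualifying = [
        h for h in truth.hidden
        if h.expressed and all(h.cds_id in hit_features[t] for t in ("kanA", "kanB"))
    ]
    truth_keys = {h.key(): h.cds_id for h in truth.hidden if h.expressed}
    unexpressed_keys = {h.key() for h in truth.hidden if not h.expressed}
    cand_keys = {(c.strand, c.frame, c.stop_pos) for c in result.candidates}
    n_rec = sum(h.key() in cand_keys for h in qualifying)
    return RecoveryReport(
        n_hidden_expressed=sum(h.expressed for h in truth.hidden),
        n_qualifying=len(qualifying),
        n_recovered=n_rec,
        recovery_pct=100.0 * n_rec / len(qualifying) if qualifying else float("nan"),
        n_unexpected_candidates=sum(k not in truth_keys for k in cand_keys),
        n_unexpressed_reported=len(unexpressed_keys & cand_keys),
    )
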