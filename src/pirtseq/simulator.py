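"""Seeded simulator of a reporter-transposon screen on a toy genome.

The generator emulates the study design end to end: a random genome
carrying annotated, expressed genes; planted "hidden" coding sequences
(intergenic, nested same-sense with a +1/+2 frameshift, or antisense)
that the annotation does not know about; a random transposon insertion
library (one insertion per mutant, both orientations); a lethal
selection step in which a mutant survives only if the promoterless,
start-codon-less resistance reporter is fused in-frame within an
expressed coding sequence 3' of its start codon (or by a rare
spontaneous-resistance event); and junction reads of the form
barcode + transposon tail + genomic flank, with substitution errors.

The same mutant library is screened twice — selection randomness (the
spontaneous-resistance events) is drawn independently per screen — so
requiring a site in both screens removes spontaneous noise at the rate
r^2 * n while keeping deterministic in-frame fusions.

Ground truth (planted features, per-insertion fate, per-read provenance)
is retained so the pipeline's recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .dna import DEFAULT_START_CODONS, SENSE_CODONS, STOP_CODONS, revcomp
from .io_formats import GeneModel, GenomeSeq, ReadRecord

_STOPS = tuple(sorted(STOP_CODONS))

#: Planted start-codon usage: follows the observed frequency ranking of
#: initiation codons (AUG strongest, then GUG, UUG, ...).
DEFAULT_START_WEIGHTS = {
    "ATG": 0.44, "GTG": 0.25, "TTG": 0.11, "CTG": 0.08,
    "ATA": 0.05, "ATT": 0.04, "ATC": 0.03,
}

DEFAULT_BARCODES = {"chlor": "AACCGGTT", "kanA": "CGTTAACG", "kanB": "GTAGCTAC"}

KLASS_BY_MIX_KEY = {
    "intergenic": "INTERGENIC",
    "nested_plus1": "NESTED_SAME_SENSE_PLUS1",
    "nested_plus2": "NESTED_SAME_SENSE_PLUS2",
    "antisense": "NESTED_ANTISENSE",
}


@dataclass
class SimConfig:
    """Study conditions for one simulated screen.

    Lengths are in codons where stated; ``hidden_len_range`` is the
    amino-acid length of planted hidden CDSs (start codon through last
    sense codon, the stop excluded). ``read_len`` is the genomic portion
    of each junction read.
    """

    seed: int
    genome_len: int = 20_000
    gc: float = 0.5
    n_genes: int = 15
    gene_len_range: tuple[int, int] = (100, 300)
    n_hidden: int = 8
    hidden_len_range: tuple[int, int] = (8, 60)
    hidden_class_mix: dict = field(
        default_factory=lambda: {
            "intergenic": 0.40, "nested_plus1": 0.30,
            "nested_plus2": 0.15, "antisense": 0.15,
        }
    )
    expressed_fraction_genes: float = 1.0
    expressed_fraction_hidden: float = 0.75
    n_insertions_per_replicate: int = 5000
    positional_bias: str = "uniform"  # or "edge_biased"
    edge_bias_decay: float = 0.9  # per-codon geometric decay from each CDS end
    spontaneous_resistance_rate: float = 1e-3
    read_len: int = 50
    error_rate: float = 0.002
    barcodes: dict = field(default_factory=lambda: dict(DEFAULT_BARCODES))
    tn_segment1: str = "GCCAACGACTACGCACTAGT"
    tn_segment2: str = "AGATGTGTATAAGAGACAG"
    start_codon_weights: dict = field(default_factory=lambda: dict(DEFAULT_START_WEIGHTS))

    def __post_init__(self) -> None:
        for name in ("gc", "expressed_fraction_genes", "expressed_fraction_hidden",
                     "spontaneous_resistance_rate", "error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.hidden_class_mix.values()) - 1) > 1e-9:
            raise ValueError("hidden_class_mix fractions must sum to 1")
        if self.positional_bias not in {"uniform", "edge_biased"}:
            raise ValueError(f"unknown positional_bias {self.positional_bias!r}")


@dataclass
class HiddenCDS:
    """Ground truth for one planted unannotated coding sequence."""

    cds_id: str
    contig_id: str
    strand: str
    frame: int
    start_pos: int  # genome coord of the start codon's first (5') base
    stop_pos: int   # genome coord of the stop codon's first (5') base
    length_aa: int
    klass: str
    parent_gene: str | None
    expressed: bool

    def key(self) -> tuple:
        return (self.strand, self.frame, self.stop_pos)


@dataclass
class Insertion:
    pos: int
    orientation: str
    cause: str = "none"  # in_frame_fusion | spontaneous | none (set by selection)
    feature: str | None = None

    @property
    def survived(self) -> bool:
        return self.cause != "none"


@dataclass
class SimTruth:
    genome: GenomeSeq
    genes: list[GeneModel]
    gene_expressed: dict[str, bool]
    hidden: list[HiddenCDS]
    insertions: dict = field(default_factory=dict)   # label -> list[Insertion]
    read_provenance: dict = field(default_factory=dict)  # sample -> {read_id: (pos, orient)}

    def fusion_map(self) -> dict[tuple[str, int], str]:
        """(orientation, junction pos) -> feature id, for every position
        where an in-frame reporter fusion into an expressed CDS survives
        selection."""
        out: dict[tuple[str, int], str] = {}
        for g in self.genes:
            if not self.gene_expressed[g.gene_id]:
                continue
            if g.strand == "+":
                positions = range(g.start + 3, g.end - 2, 3)
            else:
                positions = range(g.end - 4, g.start + 1, -3)
            for p in positions:
                out.setdefault((g.strand, p), g.gene_id)
        for h in self.hidden:
            if not h.expressed:
                continue
            if h.strand == "+":
                positions = range(h.start_pos + 3, h.stop_pos + 1, 3)
            else:
                positions = range(h.start_pos - 3, h.stop_pos - 1, -3)
            for p in positions:
                out.setdefault((h.strand, p), h.cds_id)
        return out


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _random_background(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGT"), size=n, p=probs))


def _weighted_start(rng: np.random.Generator, weights: dict[str, float]) -> str:
    codons = list(weights)
    p = np.array([weights[c] for c in codons], dtype=float)
    return str(rng.choice(codons, p=p / p.sum()))


def _random_cds_seq(rng: np.random.Generator, aa: int, start_weights: dict) -> str:
    """start codon + (aa-1) sense codons + stop codon."""
    start = _weighted_start(rng, start_weights)
    body = "".join(rng.choice(SENSE_CODONS, size=aa - 1)) if aa > 1 else ""
    stop = str(rng.choice(_STOPS))
    return start + body + stop


def _overlaps(intervals: list[tuple[int, int]], s: int, e: int, margin: int = 0) -> bool:
    return any(s - margin < ie and is_ - margin < e for is_, ie in intervals)


def _class_counts(mix: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n hidden CDSs over classes."""
    raw = {k: v * n for k, v in mix.items()}
    counts = {k: int(v) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _plant_into(seq: list[str], emb: str, at: int) -> list[str]:
    saved = seq[at : at + len(emb)]
    seq[at : at + len(emb)] = list(emb)
    return saved


def _parent_codons_ok(pseq: list[str], o: int, nt: int) -> bool:
    """No stop codon in the parent's frame across the codons touched by
    an embedded sequence at [o, o+nt) of the parent-strand sequence."""
    k0 = (o // 3) * 3
    k1 = min(len(pseq), -(-(o + nt) // 3) * 3)
    for k in range(k0, k1, 3):
        if "".join(pseq[k : k + 3]) in STOP_CODONS:
            return False
    return True


def simulate_genome(config: SimConfig) -> SimTruth:
    """Generate the toy genome, its annotation and the planted hidden CDSs.

    Deterministic under the config seed. Raises with a diagnostic if a
    feature cannot be placed under the constraints after bounded retries.
    """
    rng = _rng(config.seed, 0)
    L = config.genome_len
    genome = _random_background(rng, L, config.gc)
    contig = "sim_contig"

    genes: list[GeneModel] = []
    occupied: list[tuple[int, int]] = []
    for i in range(config.n_genes):
        for attempt in range(2000):
            codons = int(rng.integers(config.gene_len_range[0], config.gene_len_range[1] + 1))
            nt = 3 * codons
            if nt + 2 >= L:
                continue
            start = int(rng.integers(0, L - nt))
            if _overlaps(occupied, start, start + nt, margin=60):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            cds = "ATG" + "".join(rng.choice(SENSE_CODONS, size=codons - 2)) + str(rng.choice(_STOPS))
            _plant_into(genome, cds if strand == "+" else revcomp(cds), start)
            genes.append(GeneModel(f"gene{i + 1:02d}", contig, start, start + nt, strand, "sim"))
            occupied.append((start, start + nt))
            break
        else:
            raise RuntimeError(
                f"could not place gene {i + 1}/{config.n_genes} in {L} bp "
                f"after 2000 attempts (genome too crowded?)"
            )
    gene_expressed = {
        g.gene_id: bool(rng.random() < config.expressed_fraction_genes) for g in genes
    }

    counts = _class_counts(config.hidden_class_mix, config.n_hidden)
    hidden: list[HiddenCDS] = []
    used_in_parent: dict[str, list[tuple[int, int]]] = {g.gene_id: [] for g in genes}
    hid = 0
    for mix_key in ("intergenic", "nested_plus1", "nested_plus2", "antisense"):
        for _ in range(counts.get(mix_key, 0)):
            hid += 1
            cds_id = f"hidden{hid:02d}"
            if mix_key == "intergenic":
                rec = _plant_intergenic(genome, occupied, config, rng, contig, cds_id)
            else:
                shift = {"nested_plus1": 1, "nested_plus2": 2, "antisense": None}[mix_key]
                rec = _plant_nested(
                    genome, genes, used_in_parent, config, rng, contig, cds_id, shift
                )
            hidden.append(rec)
    for h in hidden:
        h.expressed = bool(rng.random() < config.expressed_fraction_hidden)

    truth = SimTruth(
        genome=GenomeSeq(contig, "".join(genome)),
        genes=genes,
        gene_expressed=gene_expressed,
        hidden=hidden,
    )
    _verify_truth(truth)
    return truth


def _plant_intergenic(genome, occupied, config, rng, contig, cds_id) -> HiddenCDS:
    L = len(genome)
    for attempt in range(2000):
        aa = int(rng.integers(config.hidden_len_range[0], config.hidden_len_range[1] + 1))
        nt = 3 * (aa + 1)
        start = int(rng.integers(0, L - nt))
        if _overlaps(occupied, start, start + nt, margin=12):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        h = _random_cds_seq(rng, aa, config.start_codon_weights)
        _plant_into(genome, h if strand == "+" else revcomp(h), start)
        occupied.append((start, start + nt))
        if strand == "+":
            start_pos, stop_pos = start, start + 3 * aa
            frame = start_pos % 3
        else:
            start_pos, stop_pos = start + nt - 1, start + 2
            frame = (L - 1 - start_pos) % 3
        return HiddenCDS(cds_id, contig, strand, frame, start_pos, stop_pos,
                         aa, "INTERGENIC", None, True)
    raise RuntimeError(f"could not place intergenic hidden CDS {cds_id}")


def _plant_nested(genome, genes, used_in_parent, config, rng, contig, cds_id,
                  shift: int | None) -> HiddenCDS:
    """Plant a hidden CDS inside a gene: same-sense at frameshift
    ``shift`` (1 or 2), or antisense when ``shift`` is None. The embedded
    codons are re-drawn until they leave the parent's frame stop-free."""
    L = len(genome)
    antisense = shift is None
    for attempt in range(4000):
        aa = int(rng.integers(config.hidden_len_range[0], config.hidden_len_range[1] + 1))
        nt = 3 * (aa + 1)
        eligible = [g for g in genes if g.length >= nt + 9]
        if not eligible:
            raise RuntimeError(f"no gene long enough to nest {aa} aa CDS {cds_id}")
        parent = eligible[int(rng.integers(len(eligible)))]
        o_max = parent.length - 3 - nt  # keep clear of the parent stop codon
        if antisense:
            o = int(rng.integers(3, o_max + 1))
        else:
            j = int(rng.integers(1, (o_max - shift) // 3 + 1))
            o = 3 * j + shift
        if _overlaps(used_in_parent[parent.gene_id], o, o + nt, margin=3):
            continue
        pseq = list(
            genome[parent.start : parent.end]
            if parent.strand == "+"
            else revcomp("".join(genome[parent.start : parent.end]))
        )
        h = _random_cds_seq(rng, aa, config.start_codon_weights)
        emb = revcomp(h) if antisense else h
        _plant_into(pseq, emb, o)
        if not _parent_codons_ok(pseq, o, nt):
            continue  # redraw codons / placement
        planted = "".join(pseq)
        _plant_into(genome, planted if parent.strand == "+" else revcomp(planted), parent.start)
        used_in_parent[parent.gene_id].append((o, o + nt))

        # strand-space offset -> genome coordinates
        if not antisense:
            strand = parent.strand
            if parent.strand == "+":
                start_pos, stop_pos = parent.start + o, parent.start + o + 3 * aa
            else:
                start_pos = parent.end - 1 - o
                stop_pos = parent.end - 1 - (o + 3 * aa)
            klass = "NESTED_SAME_SENSE_PLUS1" if shift == 1 else "NESTED_SAME_SENSE_PLUS2"
        else:
            strand = "-" if parent.strand == "+" else "+"
            if parent.strand == "+":
                start_pos = parent.start + o + nt - 1
                stop_pos = parent.start + o + 2
            else:
                start_pos = parent.end - o - nt
                stop_pos = start_pos + 3 * aa
            klass = "NESTED_ANTISENSE"
        frame = start_pos % 3 if strand == "+" else (L - 1 - start_pos) % 3
        return HiddenCDS(cds_id, contig, strand, frame, start_pos, stop_pos,
                         aa, klass, parent.gene_id, True)
    raise RuntimeError(f"could not nest hidden CDS {cds_id} after 4000 attempts")


def _verify_truth(truth: SimTruth) -> None:
    """Internal consistency: annotated genes and hidden bodies are
    stop-free in their own frames and end at their recorded stops."""
    seq = truth.genome.sequence
    for g in truth.genes:
        s = seq[g.start : g.end] if g.strand == "+" else revcomp(seq[g.start : g.end])
        assert s[:3] == "ATG", f"{g.gene_id}: lost start codon"
        assert s[-3:] in STOP_CODONS, f"{g.gene_id}: lost stop codon"
        body = [s[i : i + 3] for i in range(3, len(s) - 3, 3)]
        assert not any(c in STOP_CODONS for c in body), f"{g.gene_id}: internal stop"
    for h in truth.hidden:
        if h.strand == "+":
            s = seq[h.start_pos : h.stop_pos + 3]
        else:
            s = revcomp(seq[h.stop_pos - 2 : h.start_pos + 1])
        assert len(s) == 3 * (h.length_aa + 1)
        assert s[:3] in DEFAULT_START_CODONS, f"{h.cds_id}: start codon lost"
        assert s[-3:] in STOP_CODONS, f"{h.cds_id}: stop codon lost"
        body = [s[i : i + 3] for i in range(0, len(s) - 3, 3)]
        assert not any(c in STOP_CODONS for c in body), f"{h.cds_id}: internal stop"


def simulate_library(truth: SimTruth, config: SimConfig, replicate_id: int = 0) -> list[Insertion]:
    """Draw the unselected mutant library: insertions uniform over
    (position, orientation), deterministic under (seed, replicate_id)."""
    rng = _rng(config.seed, 1, replicate_id)
    n = config.n_insertions_per_replicate
    pos = rng.integers(0, len(truth.genome), size=n)
    orient = rng.choice(list("+-"), size=n)
    return [Insertion(int(p), str(o)) for p, o in zip(pos, orient)]


def _edge_weight(pos: int, feature_span: tuple[int, int], decay: float) -> float:
    lo, hi = feature_span
    i5 = (pos - lo) // 3
    i3 = (hi - 1 - pos) // 3
    return max(decay ** i5, decay ** i3)


def apply_selection(
    insertions: Sequence[Insertion],
    truth: SimTruth,
    config: SimConfig,
    screen_id: int = 0,
) -> list[Insertion]:
    """Kanamycin selection of one screen.

    An insertion survives iff its reporter frame at the junction matches
    an expressed CDS (annotated or hidden) 3' of that CDS's start codon,
    or by a spontaneous-resistance Bernoulli event. Under
    ``edge_biased``, fusion survivors are thinned toward the feature
    extremities. Returns the full list annotated with each insertion's
    fate (survivors are those with ``cause != 'none'``).
    """
    rng = _rng(config.seed, 2, screen_id)
    fusion = truth.fusion_map()
    spans = {g.gene_id: (g.start, g.end) for g in truth.genes}
    for h in truth.hidden:
        s, e = sorted((h.start_pos, h.stop_pos))
        spans[h.cds_id] = (s, e + 3)
    out: list[Insertion] = []
    for ins in insertions:
        feature = fusion.get((ins.orientation, ins.pos))
        cause = "none"
        if feature is not None:
            keep = True
            if config.positional_bias == "edge_biased":
                w = _edge_weight(ins.pos, spans[feature], config.edge_bias_decay)
                keep = rng.random() < w
            if keep:
                cause = "in_frame_fusion"
        if cause == "none" and rng.random() < config.spontaneous_resistance_rate:
            cause = "spontaneous"
            feature = None
        out.append(replace(ins, cause=cause, feature=feature))
    return out


def emit_reads(
    insertions: Sequence[Insertion],
    truth: SimTruth,
    config: SimConfig,
    sample_tag: str,
    stream_id: int = 0,
) -> list[ReadRecord]:
    """Junction reads: barcode + transposon tail + genomic flank.

    The genomic part starts at the insertion position and runs
    ``read_len`` bases in the transposon's orientation (reverse-
    complemented for '-'); it is truncated at the contig end.
    Substitution errors are applied over the whole read at
    ``error_rate``. One read per insertion.
    """
    rng = _rng(config.seed, 3, stream_id)
    seq = truth.genome.sequence
    L = len(seq)
    barcode = config.barcodes[sample_tag]
    tn = config.tn_segment1 + config.tn_segment2
    reads: list[ReadRecord] = []
    provenance: dict[str, tuple[int, str]] = {}
    others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for i, ins in enumerate(insertions):
        if ins.orientation == "+":
            frag = seq[ins.pos : min(L, ins.pos + config.read_len)]
        else:
            frag = revcomp(seq[max(0, ins.pos - config.read_len + 1) : ins.pos + 1])
        bases = list(barcode + tn + frag)
        if config.error_rate > 0:
            errs = np.flatnonzero(rng.random(len(bases)) < config.error_rate)
            for e in errs:
                bases[e] = others.get(bases[e], "A")[int(rng.integers(3))]
        rid = f"{sample_tag}:{i}"
        reads.append(ReadRecord(rid, "".join(bases), "I" * len(bases)))
        provenance[rid] = (ins.pos, ins.orientation)
    truth.read_provenance[sample_tag] = provenance
    return reads
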