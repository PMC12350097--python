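import random

import pytest

from pirtseq.cds_discovery import (
    IN_FRAME,
    INTERGENIC,
    KLASS_INTERGENIC,
    KLASS_NESTED_ANTISENSE,
    KLASS_NESTED_PLUS1,
    KLASS_NESTED_PLUS2,
    OUT_OF_FRAME,
    CandidateCDS,
    FrameClassification,
    GeneIndex,
    call_candidates,
    choose_start,
    classify_candidate,
    classify_site,
    classify_sites,
    stop_to_stop,
    summarize,
    translate_candidate,
)
from pirtseq.dna import DEFAULT_START_CODONS, STOP_CODONS, revcomp
from pirtseq.io_formats import GeneModel, GenomeSeq

from _bruteforce import bf_choose_start, bf_stop_positions, bf_stop_to_stop, rc
from conftest import make_sites


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestClassifySite:
    genes = [GeneModel("geneA", "c1", 100, 130, "+", "primary")]
    index = GeneIndex(genes)

    def test_in_frame_when_phase_matches(self):
        cls = classify_site("c1", 106, "+", self.index)
        assert (cls.verdict, cls.host_gene) == (IN_FRAME, "geneA")

    def test_out_of_frame_one_base_off(self):
        cls = classify_site("c1", 107, "+", self.index)
        assert (cls.verdict, cls.host_gene) == (OUT_OF_FRAME, "geneA")

    def test_opposite_strand_is_out_of_frame(self):
        cls = classify_site("c1", 106, "-", self.index)
        assert cls.verdict == OUT_OF_FRAME

    def test_outside_any_gene_is_intergenic(self):
        cls = classify_site("c1", 50, "+", self.index)
        assert (cls.verdict, cls.host_gene) == (INTERGENIC, None)

    def test_minus_strand_gene_phase(self):
        idx = GeneIndex([GeneModel("geneB", "c1", 100, 130, "-", "primary")])
        assert classify_site("c1", 129, "-", idx).verdict == IN_FRAME  # start codon base
        assert classify_site("c1", 126, "-", idx).verdict == IN_FRAME
        assert classify_site("c1", 125, "-", idx).verdict == OUT_OF_FRAME

    def test_second_annotation_source_rescues_in_frame(self):
        """A site out-of-frame against the primary annotation but
        in-frame against a second source is IN_FRAME, recording the
        rescuing source."""
        models = [
            GeneModel("geneA", "c1", 100, 130, "+", "genbank"),
            GeneModel("geneA2", "c1", 101, 131, "+", "refseq"),
        ]
        idx = GeneIndex(models)
        cls = classify_site("c1", 107, "+", idx)
        assert (cls.verdict, cls.host_source) == (IN_FRAME, "refseq")

    def test_non_phaseable_gene_excluded(self):
        idx = GeneIndex([GeneModel("pseudo", "c1", 100, 131, "+", "primary")])
        assert classify_site("c1", 106, "+", idx).verdict == INTERGENIC

    def test_matches_codon_grid_oracle(self, rng):
        """Verdicts agree with direct codon-grid membership on 200 random
        (gene, site) pairs."""
        for _ in range(200):
            gs = rng.randrange(0, 500)
            glen = 3 * rng.randint(5, 50)
            strand = rng.choice("+-")
            gene = GeneModel("g", "c1", gs, gs + glen, strand)
            idx = GeneIndex([gene])
            pos = rng.randrange(0, 1000)
            orient = rng.choice("+-")
            if strand == "+":
                grid = set(range(gs, gs + glen, 3))
            else:
                grid = set(range(gs + glen - 1, gs - 1, -3))
            inside = gs <= pos < gs + glen
            if inside and orient == strand and pos in grid:
                expected = IN_FRAME
            elif inside:
                expected = OUT_OF_FRAME
            else:
                expected = INTERGENIC
            assert classify_site("c1", pos, orient, idx).verdict == expected


class TestStopToStop:
    def test_hand_traceable_toy(self):
        g = GenomeSeq("c1", "TAAATGAAATGGTGA")
        orf = stop_to_stop(g, "+", 0, 9)
        assert (orf.start, orf.end, orf.stop_pos) == (3, 12, 12)

    def test_no_upstream_stop_starts_at_contig_first_codon(self):
        g = GenomeSeq("c1", "CATGAAATGGTGAAC")
        orf = stop_to_stop(g, "+", 1, 4)
        assert orf.start == 1 and orf.stop_pos == 10

    def test_no_downstream_stop_on_linear_contig(self):
        g = GenomeSeq("c1", "TAAATGAAAATGGAA")
        assert stop_to_stop(g, "+", 0, 9) is None

    def test_anchor_must_be_congruent(self):
        g = GenomeSeq("c1", "TAAATGAAATGGTGA")
        with pytest.raises(ValueError, match="congruent"):
            stop_to_stop(g, "+", 0, 10)

    def test_anchor_on_stop_codon_returns_that_stop(self):
        g = GenomeSeq("c1", "TAAATGAAATGGTGA")
        orf = stop_to_stop(g, "+", 0, 12)
        assert orf.stop_pos == 12 and orf.start == 3

    def test_circular_wraps_across_origin(self):
        # codons AAC TAA TTT AAA, frame 0: only stop is TAA at 3, so the
        # run containing the anchor wraps TTT AAA AAC across the origin
        g = GenomeSeq("c1", "AACTAATTTAAA", circular=True)
        orf = stop_to_stop(g, "+", 0, 0)
        assert (orf.start, orf.stop_pos) == (6, 3)
        assert orf.wraps

    def test_matches_six_frame_enumeration(self, rng):
        """Runs equal brute-force enumeration of maximal stop-free codon
        runs in all six frames on random sequences."""
        for _ in range(15):
            seq = _random_seq(rng, 300)
            g = GenomeSeq("c1", seq)
            stops = bf_stop_positions(seq)
            L = len(seq)
            for strand in "+-":
                s = seq if strand == "+" else rc(seq)
                for a in range(L - 2):
                    frame = a % 3
                    expected = bf_stop_to_stop(stops[(strand, frame)], frame, a, L)
                    anchor = a if strand == "+" else L - 1 - a
                    got = stop_to_stop(g, strand, frame, anchor)
                    if expected is None:
                        assert got is None
                        continue
                    run_start, stop_pos = expected
                    if strand == "+":
                        assert (got.start, got.stop_pos) == (run_start, stop_pos)
                    else:
                        assert (L - got.end, L - 1 - got.stop_pos) == (run_start, stop_pos)


class TestChooseStart:
    def test_furthest_upstream_wins_over_canonical(self):
        # TAA GTG AAA ATG AAA TGA: GTG (pos 3) beats downstream ATG
        g = GenomeSeq("c1", "TAAGTGAAAATGAAATGA")
        orf = stop_to_stop(g, "+", 0, 3)
        assert choose_start(g, orf, 12) == ("GTG", 3)

    def test_none_when_no_start_before_junction(self):
        # run codons before the junction are AAA only
        g = GenomeSeq("c1", "TAAAAAAAAATGAAATGA")
        orf = stop_to_stop(g, "+", 0, 3)
        assert choose_start(g, orf, 6) is None

    def test_minus_strand_agrees_with_plus_on_revcomp(self, rng):
        for _ in range(50):
            seq = _random_seq(rng, 120)
            g = GenomeSeq("c1", seq)
            gm = GenomeSeq("c1", revcomp(seq))
            L = len(seq)
            a = rng.randrange(0, L - 2)
            orf_p = stop_to_stop(gm, "+", a % 3, a)
            orf_m = stop_to_stop(g, "-", a % 3, L - 1 - a)
            assert (orf_p is None) == (orf_m is None)
            if orf_p is None:
                continue
            pick_p = choose_start(gm, orf_p, a)
            pick_m = choose_start(g, orf_m, L - 1 - a)
            if pick_p is None:
                assert pick_m is None
            else:
                assert pick_m == (pick_p[0], L - 1 - pick_p[1])

    def test_matches_bruteforce_scan(self, rng):
        codon_set = set(DEFAULT_START_CODONS)
        for _ in range(100):
            seq = _random_seq(rng, 240)
            g = GenomeSeq("c1", seq)
            a = rng.randrange(0, len(seq) - 2)
            orf = stop_to_stop(g, "+", a % 3, a)
            if orf is None:
                continue
            expected = bf_choose_start(seq, orf.start, a, codon_set)
            assert choose_start(g, orf, a) == expected


def _classify_and_call(genome, genes, site_rows, **kw):
    sites = make_sites(site_rows)
    cls = classify_sites(sites, genes)
    return call_candidates(sites, cls, genome, genes, **kw)


class TestCallCandidates:
    # layout: TAA | GTG AAA ATG AAA CCC | TGA  then padding
    seq = "TAA" + "GTGAAAATGAAACCC" + "TGA" + "ACGTACGTACGTAGCAT"
    genome = GenomeSeq("c1", seq)

    def test_sites_sharing_stop_collapse_to_one_candidate(self):
        cands = _classify_and_call(self.genome, [], [("c1", 6, "+"), ("c1", 15, "+")])
        assert len(cands) == 1
        cand = cands[0]
        assert len(cand.supporting_sites) == 2
        assert (cand.start_codon, cand.start_pos, cand.stop_pos) == ("GTG", 3, 18)
        assert cand.length_aa == 5

    def test_orf_without_start_yields_no_candidate(self):
        g = GenomeSeq("c1", "TAA" + "AAAAAACCCAAACCC" + "TGA" + "ACGT")
        cands = _classify_and_call(g, [], [("c1", 6, "+")])
        assert cands == []

    def test_start_immediately_before_stop_is_one_aa(self):
        g = GenomeSeq("c1", "TAAATGTGAACGTACGT")
        cands = _classify_and_call(g, [], [("c1", 6, "+")])
        assert len(cands) == 1
        assert cands[0].length_aa == 1
        assert translate_candidate(g, cands[0]) == "M"

    def test_start_must_be_upstream_of_junction_unless_disabled(self):
        # junction at the GTG itself: start search limited to <= junction
        cands = _classify_and_call(self.genome, [], [("c1", 9, "+")])
        assert cands[0].start_pos == 3  # GTG upstream of junction is found
        g2 = GenomeSeq("c1", "TAA" + "AAAATGAAAAACCCC".replace("C", "A") + "TGA" + "ACGT")
        # no start at/before junction 3 -> dropped unless start-anywhere
        strict = _classify_and_call(g2, [], [("c1", 3, "+")])
        relaxed = _classify_and_call(g2, [], [("c1", 3, "+")], require_start_upstream=False)
        assert strict == []
        assert len(relaxed) == 1 and relaxed[0].start_codon == "ATG"

    def test_minus_strand_candidate(self):
        g = GenomeSeq("c1", revcomp(self.seq))
        L = len(self.seq)
        cands = _classify_and_call(g, [], [("c1", L - 1 - 6, "-")])
        assert len(cands) == 1
        cand = cands[0]
        assert cand.strand == "-"
        assert (cand.start_pos, cand.stop_pos) == (L - 1 - 3, L - 1 - 18)
        assert cand.length_aa == 5

    def test_in_frame_sites_produce_no_candidates(self):
        genes = [GeneModel("g1", "c1", 3, 21, "+")]
        cands = _classify_and_call(self.genome, genes, [("c1", 6, "+")])
        assert cands == []


class TestClassifyCandidate:
    parent = GeneModel("parent", "c1", 99, 300, "+")

    def _cand(self, start_pos, strand="+", stop_pos=None):
        stop = stop_pos if stop_pos is not None else start_pos + 30
        s, e = (start_pos, stop) if strand == "+" else (stop, start_pos)
        return CandidateCDS(
            "CDSx", "c1", strand, start_pos % 3, s, e, start_pos, "ATG",
            stop, 10,
        )

    def test_plus1_frameshift(self):
        cand = classify_candidate(self._cand(103), [self.parent])
        assert (cand.klass, cand.parent_gene) == (KLASS_NESTED_PLUS1, "parent")

    def test_plus2_frameshift(self):
        cand = classify_candidate(self._cand(104), [self.parent])
        assert cand.klass == KLASS_NESTED_PLUS2

    def test_antisense(self):
        cand = self._cand(200, strand="-", stop_pos=150)
        assert classify_candidate(cand, [self.parent]).klass == KLASS_NESTED_ANTISENSE

    def test_intergenic_without_overlap(self):
        cand = classify_candidate(self._cand(400), [self.parent])
        assert (cand.klass, cand.parent_gene) == (KLASS_INTERGENIC, None)

    def test_largest_overlap_wins(self):
        far = GeneModel("far", "c1", 120, 135, "+")
        cand = classify_candidate(self._cand(103), [far, self.parent])
        assert cand.parent_gene == "parent"


class TestSummarize:
    def test_published_count_percentages(self):
        cls = (
            [FrameClassification(("c1", i, "+"), IN_FRAME, "g") for i in range(5754)]
            + [FrameClassification(("c1", i, "+"), OUT_OF_FRAME, "g") for i in range(272)]
            + [FrameClassification(("c1", i, "+"), INTERGENIC) for i in range(193)]
        )
        s = summarize(cls, [])
        assert (s.pct_in_frame, s.pct_oof, s.pct_intergenic) == (92.52, 4.37, 3.10)
        assert s.n_sites_total == 6219

    def test_single_candidate_full_codon_share(self):
        cand = CandidateCDS("CDS1", "c1", "+", 0, 0, 30, 0, "GTG", 30, 10)
        s = summarize([], [cand])
        assert s.start_codon_freq["GTG"] == {"count": 1, "pct": 100.0}

    def test_odd_count_median(self):
        cands = [
            CandidateCDS(f"C{i}", "c1", "+", 0, 0, 3 * n, 0, "ATG", 3 * n, n)
            for i, n in enumerate([1, 25, 138])
        ]
        s = summarize([], cands)
        assert (s.length_median_aa, s.length_min_aa, s.length_max_aa) == (25, 1, 138)

    def test_partition_completeness(self, rng):
        verdicts = [rng.choice([IN_FRAME, OUT_OF_FRAME, INTERGENIC]) for _ in range(500)]
        cls = [
            FrameClassification(("c1", i, "+"), v, "g" if v != INTERGENIC else None)
            for i, v in enumerate(verdicts)
        ]
        s = summarize(cls, [])
        assert s.n_in_frame + s.n_oof + s.n_intergenic == 500
        assert s.pct_in_frame + s.pct_oof + s.pct_intergenic == pytest.approx(100, abs=0.02)


def test_no_candidate_contains_internal_stop(rng):
    """Re-translation of every candidate from a random-genome discovery
    run contains no internal stop codon."""
    seq = _random_seq(rng, 3000)
    g = GenomeSeq("c1", seq)
    rows = [("c1", rng.randrange(0, 3000), rng.choice("+-")) for _ in range(150)]
    cands = _classify_and_call(g, [], list(dict.fromkeys(rows)))
    assert cands, "expected at least one candidate on a random genome"
    for c in cands:
        aa = translate_candidate(g, c)
        assert "*" not in aa
        assert len(aa) == c.length_aa
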