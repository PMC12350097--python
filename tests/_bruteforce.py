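"""Independent brute-force oracles used by the test suite.

These deliberately take the dumbest correct route (full enumeration,
full scans) and share no code with the package's implementations beyond
the reverse-complement table.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right

_COMP = str.maketrans("ACGT", "TGCA")
_STOPS = {"TAA", "TAG", "TGA"}


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def bf_hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def bf_transposon_decision(read: str, seg1: str, seg2: str, budget: int) -> bool:
    """Accept iff some offset places seg1+seg2 within the total budget."""
    q = seg1 + seg2
    return any(
        bf_hamming(read[o : o + len(q)], q) <= budget
        for o in range(len(read) - len(q) + 1)
    )


def bf_align(frag: str, genome: str, max_mm: int):
    """Full-scan Hamming alignment over every offset of both strands.

    Returns (junction_pos, strand, mismatches) of the unique best hit, or
    None if unmapped or tied.
    """
    hits = []
    L, n = len(genome), len(frag)
    for p in range(L - n + 1):
        mm = bf_hamming(frag, genome[p : p + n])
        if mm <= max_mm:
            hits.append((mm, p, "+"))
    rcg = rc(genome)
    for p in range(L - n + 1):
        mm = bf_hamming(frag, rcg[p : p + n])
        if mm <= max_mm:
            hits.append((mm, L - 1 - p, "-"))
    if not hits:
        return None
    hits.sort()
    if len(hits) > 1 and hits[0][0] == hits[1][0]:
        return None
    return hits[0][1], hits[0][2], hits[0][0]


def bf_stop_positions(seq: str):
    """All six frames' stop-codon start positions, in the coordinates of
    the scanned strand sequence (seq itself for '+', rc(seq) for '-')."""
    out = {}
    for strand, s in (("+", seq), ("-", rc(seq))):
        for frame in range(3):
            out[(strand, frame)] = [
                p for p in range(frame, len(s) - 2, 3) if s[p : p + 3] in _STOPS
            ]
    return out


def bf_stop_to_stop(stops: list[int], frame: int, anchor: int, seq_len: int):
    """Expected maximal stop-free run containing the anchor codon, as
    (run_start, stop_pos) in scanned-strand coordinates; None without a
    downstream stop. The anchor's own codon counts as downstream."""
    i = bisect_left(stops, anchor)
    if i == len(stops):
        return None
    down = stops[i]
    j = bisect_right(stops, anchor - 1)
    up_start = stops[j - 1] + 3 if j > 0 else frame
    return up_start, down


def bf_choose_start(s: str, run_start: int, max_pos: int, codon_set) -> tuple[str, int] | None:
    """First start-set codon scanning 5'->3' from the run start to max_pos."""
    for p in range(run_start, max_pos + 1, 3):
        if s[p : p + 3] in codon_set:
            return s[p : p + 3], p
    return None


def bf_pearson(x, y) -> float:
    """Textbook two-pass Pearson correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5
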