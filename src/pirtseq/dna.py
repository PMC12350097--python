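"""Low-level DNA primitives shared across the package.

Everything here operates on plain uppercase strings; coordinates are
0-based half-open throughout the package.
"""

from __future__ import annotations

from itertools import product

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Bacterial (table 11) stop codons, DNA alphabet.
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: The seven initiation codons searched by default, strongest first
#: (DNA alphabet; the mRNA forms are AUG, GUG, UUG, CUG, AUA, AUU, AUC).
#: Positional precedence (furthest upstream) decides between them; the
#: ordering documents relative initiation strength only.
DEFAULT_START_CODONS: tuple[str, ...] = ("ATG", "GTG", "TTG", "CTG", "ATA", "ATT", "ATC")

#: All 61 sense (non-stop) codons.
SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming: unequal lengths {len(a)} != {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def iter_codons(seq: str, start: int = 0):
    """Yield ``(position, codon)`` for complete codons from ``start``."""
    for p in range(start, len(seq) - 2, 3):
        yield p, seq[p : p + 3]
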