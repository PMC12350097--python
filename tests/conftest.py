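import random
import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _bruteforce oracles

from pirtseq import GeneModel, GenomeSeq


def make_sites(rows, sample="s"):
    """rows: iterable of (contig, pos, orientation[, read_count])."""
    out = []
    for r in rows:
        contig, pos, orient = r[:3]
        count = r[3] if len(r) > 3 else 1
        out.append((contig, pos, orient, count, sample))
    return pd.DataFrame(out, columns=["contig", "pos", "orientation", "read_count", "sample"])


@pytest.fixture
def rng():
    return random.Random(20250924)


@pytest.fixture
def toy_genome():
    # TAA ATG AAA TGG TGA in frame 0, plus trailing padding
    return GenomeSeq("c1", "TAAATGAAATGGTGAACCGTT")


@pytest.fixture
def plus_gene():
    return GeneModel("geneA", "c1", 100, 130, "+", "primary")
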