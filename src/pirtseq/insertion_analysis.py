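"""Unique insertion sites, reporter frames, replicate handling, saturation.

Site tables are pandas DataFrames with columns
``contig, pos, orientation, read_count, sample`` — one row per unique
(contig, pos, orientation) within a sample. The reporter reading frame
of a site is one of six values: (strand, frame mod 3), where frame is
computed from the junction position (plus a configurable global offset,
default 0, accommodating alternative junction conventions such as
correcting for the 9-bp target-site duplication of Tn5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import MappedFragment
from .io_formats import GeneModel, SITE_COLUMNS


@dataclass
class ReporterFrame:
    strand: str
    frame: int


@dataclass
class ReplicateStats:
    pearson_r: float
    n_shared_sites: int
    n_sites_a: int
    n_sites_b: int


def call_sites(mapped_fragments: Iterable[MappedFragment], sample_tag: str) -> pd.DataFrame:
    """Collapse unique-mapped fragments into a site table with read counts."""
    rows = [
        (f.contig_id, f.junction_pos, f.strand)
        for f in mapped_fragments
        if f.unique
    ]
    if not rows:
        return pd.DataFrame(columns=SITE_COLUMNS)
    df = pd.DataFrame(rows, columns=["contig", "pos", "orientation"])
    sites = (
        df.groupby(["contig", "pos", "orientation"], as_index=False)
        .size()
        .rename(columns={"size": "read_count"})
    )
    sites["sample"] = sample_tag
    return sites[SITE_COLUMNS].sort_values(["contig", "pos", "orientation"]).reset_index(drop=True)


def orientation_totals(sites: pd.DataFrame) -> dict[str, int]:
    """Unique-site counts per transposon orientation."""
    out = {"+": 0, "-": 0}
    if len(sites):
        out.update(sites.groupby("orientation").size().to_dict())
    return out


def frame_of_site(pos: int, orientation: str, contig_length: int,
                  junction_offset: int = 0) -> ReporterFrame:
    """Reporter reading frame at an insertion site.

    Forward orientation: frame = (pos + offset) mod 3. Reverse: the
    reporter reads toward lower coordinates, so the frame is anchored at
    the contig's last base: (L - 1 - pos + offset) mod 3.
    """
    if orientation == "+":
        return ReporterFrame("+", (pos + junction_offset) % 3)
    if orientation == "-":
        return ReporterFrame("-", (contig_length - 1 - pos + junction_offset) % 3)
    raise ValueError(f"bad orientation {orientation!r}")


def frame_counts(sites: pd.DataFrame, contig_length: int,
                 junction_offset: int = 0) -> dict[tuple[str, int], int]:
    """Site counts over the six reporter frames."""
    counts: dict[tuple[str, int], int] = {(s, f): 0 for s in "+-" for f in range(3)}
    for _, row in sites.iterrows():
        rf = frame_of_site(int(row["pos"]), row["orientation"], contig_length, junction_offset)
        counts[(rf.strand, rf.frame)] += 1
    return counts


def _per_gene_density(sites: pd.DataFrame, genes: Sequence[GeneModel],
                      weight_by_reads: bool = False) -> np.ndarray:
    dens = np.zeros(len(genes))
    for i, g in enumerate(genes):
        mask = (
            (sites["contig"] == g.contig_id)
            & (sites["pos"] >= g.start)
            & (sites["pos"] < g.end)
        )
        n = sites.loc[mask, "read_count"].sum() if weight_by_reads else mask.sum()
        dens[i] = n / g.length
    return dens


def replicate_correlation(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    genes: Sequence[GeneModel],
    weight_by_reads: bool = False,
) -> ReplicateStats:
    """Pearson correlation of per-gene insertion density between replicates.

    Density is unique sites per bp of gene by default (read-weighted
    density available via ``weight_by_reads``). With fewer than two genes
    of nonzero variance the coefficient is undefined and reported as NaN.
    """
    da = _per_gene_density(sites_a, genes, weight_by_reads)
    db = _per_gene_density(sites_b, genes, weight_by_reads)
    keys_a = set(map(tuple, sites_a[["contig", "pos", "orientation"]].itertuples(index=False)))
    keys_b = set(map(tuple, sites_b[["contig", "pos", "orientation"]].itertuples(index=False)))
    if len(genes) < 2 or np.std(da) == 0 or np.std(db) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(da, db).statistic)
    return ReplicateStats(r, len(keys_a & keys_b), len(keys_a), len(keys_b))


def intersect_replicates(sites_a: pd.DataFrame, sites_b: pd.DataFrame,
                         match_window: int = 0) -> pd.DataFrame:
    """Keep sites identified in BOTH independent screens.

    The default requires an exact (contig, pos, orientation) match —
    base-pair resolution is the point of the assay; ``match_window``
    relaxes this for noisy data by accepting sites in ``b`` within the
    window of a site in ``a`` (the ``a`` coordinate is reported).
    Read counts are summed across replicates. No minimum read threshold
    is applied.
    """
    if len(sites_a) == 0 or len(sites_b) == 0:
        return pd.DataFrame(columns=SITE_COLUMNS)
    if match_window == 0:
        merged = sites_a.merge(
            sites_b, on=["contig", "pos", "orientation"], suffixes=("_a", "_b")
        )
        if len(merged) == 0:
            return pd.DataFrame(columns=SITE_COLUMNS)
        merged["read_count"] = merged["read_count_a"] + merged["read_count_b"]
        merged["sample"] = [
            "&".join(sorted({a, b}))
            for a, b in zip(merged["sample_a"], merged["sample_b"])
        ]
        return merged[SITE_COLUMNS].sort_values(["contig", "pos", "orientation"]).reset_index(drop=True)
    # fuzzy window: match each a-site to the nearest b-site of the same
    # contig/orientation within +/- window
    rows = []
    for (contig, orient), grp_b in sites_b.groupby(["contig", "orientation"]):
        bpos = grp_b["pos"].to_numpy()
        bcount = grp_b["read_count"].to_numpy()
        grp_a = sites_a[(sites_a["contig"] == contig) & (sites_a["orientation"] == orient)]
        for _, row in grp_a.iterrows():
            d = np.abs(bpos - row["pos"])
            j = int(np.argmin(d)) if len(d) else -1
            if j >= 0 and d[j] <= match_window:
                rows.append(
                    (contig, int(row["pos"]), orient,
                     int(row["read_count"]) + int(bcount[j]), str(row["sample"]))
                )
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def pool_replicates(*site_tables: pd.DataFrame, sample_tag: str = "pooled") -> pd.DataFrame:
    """Union of replicate site tables with read counts summed (the
    technical-replicate pooling step, applied explicitly rather than
    implicitly)."""
    cat = pd.concat(list(site_tables), ignore_index=True)
    if len(cat) == 0:
        return pd.DataFrame(columns=SITE_COLUMNS)
    pooled = (
        cat.groupby(["contig", "pos", "orientation"], as_index=False)["read_count"].sum()
    )
    pooled["sample"] = sample_tag
    return pooled[SITE_COLUMNS]


def saturation_curve(
    mapped_fragments: Sequence[MappedFragment],
    step_fractions: Sequence[float],
    seed: int,
) -> pd.DataFrame:
    """Unique sites as a function of reads sampled (rarefaction).

    Fragments are shuffled once with ``seed``; the cumulative unique
    (contig, pos, orientation) count is reported at each fraction. The
    curve is monotone non-decreasing by construction.
    """
    fracs = list(step_fractions)
    if fracs != sorted(fracs) or not all(0 < f <= 1 for f in fracs):
        raise ValueError("step_fractions must be sorted and in (0, 1]")
    keys = [(f.contig_id, f.junction_pos, f.strand) for f in mapped_fragments if f.unique]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    codes, _ = pd.factorize(pd.Series(keys).iloc[order]) if keys else (np.array([]), None)
    # unique count at depth k = number of first occurrences among the first k
    first_seen = np.zeros(len(codes), dtype=bool)
    seen: set[int] = set()
    for i, c in enumerate(codes):
        if c not in seen:
            seen.add(c)
            first_seen[i] = True
    cum_unique = np.cumsum(first_seen)
    rows = []
    for f in fracs:
        k = int(round(f * len(keys)))
        rows.append((k, int(cum_unique[k - 1]) if k > 0 else 0))
    return pd.DataFrame(rows, columns=["reads_sampled", "unique_sites"])
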