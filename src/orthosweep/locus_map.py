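"""Genomic independence analysis of a marker panel.

Loci are point coordinates (the first base of each locus).  A locus is
*isolated* when its nearest neighbour on the same chromosome lies
strictly farther than the independence distance (default 100 kbp);
single-linkage clustering at that distance yields the number of
*potentially independent* loci (one per cluster).  Fixed-width bin
counts (default 500 kbp) are exported for chromosome-map style
visualisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import nan

import pandas as pd

from .io_formats import LocusCoordinate

logger = logging.getLogger(__name__)


@dataclass
class LocusMapParams:
    independence_dist: int = 100_000  # bp
    bin_size: int = 500_000  # bp

    def __post_init__(self) -> None:
        if self.independence_dist <= 0 or self.bin_size <= 0:
            raise ValueError("distances must be positive")


def nearest_neighbor_distances(loci: list[LocusCoordinate]) -> dict[str, float]:
    """Minimum |pos_i - pos_j| per locus over other loci on the same chromosome.

    A locus alone on its chromosome has no neighbour and gets NaN.
    """
    if not loci:
        raise ValueError("no loci")
    out: dict[str, float] = {}
    by_chrom: dict[str, list[LocusCoordinate]] = {}
    for l in loci:
        by_chrom.setdefault(l.chrom, []).append(l)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda l: (l.pos, l.locus_id))
        if len(group) == 1:
            out[group[0].locus_id] = nan
            continue
        for i, l in enumerate(group):
            cands = []
            if i > 0:
                cands.append(l.pos - group[i - 1].pos)
            if i < len(group) - 1:
                cands.append(group[i + 1].pos - l.pos)
            out[l.locus_id] = float(min(cands))
    return out


def independence_summary(
    loci: list[LocusCoordinate], params: LocusMapParams | None = None
) -> tuple[int, int, list[list[str]]]:
    """Isolated-locus count, independent-locus count, and the clusters.

    ``n_isolated`` counts loci whose nearest neighbour is strictly
    farther than the independence distance (a locus without a
    neighbour counts as isolated).  Clusters are single-linkage groups
    joining same-chromosome loci at <= the independence distance;
    ``n_independent`` is the number of clusters.
    """
    params = params or LocusMapParams()
    d = params.independence_dist
    nn = nearest_neighbor_distances(loci)
    n_isolated = sum(1 for v in nn.values() if v != v or v > d)
    clusters: list[list[str]] = []
    by_chrom: dict[str, list[LocusCoordinate]] = {}
    for l in loci:
        by_chrom.setdefault(l.chrom, []).append(l)
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda l: (l.pos, l.locus_id))
        current = [group[0].locus_id]
        for prev, cur in zip(group, group[1:]):
            if cur.pos - prev.pos <= d:
                current.append(cur.locus_id)
            else:
                clusters.append(current)
                current = [cur.locus_id]
        clusters.append(current)
    return n_isolated, len(clusters), clusters


def bin_counts(
    loci: list[LocusCoordinate],
    bin_size: int = 500_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Locus counts per half-open genomic bin [k*bin_size, (k+1)*bin_size).

    A locus with 1-based position p falls in bin floor((p-1)/bin_size).
    Counts always sum to the number of input loci.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    counts: dict[tuple[str, int], int] = {}
    for l in loci:
        if chrom_lengths and l.chrom in chrom_lengths and l.pos > chrom_lengths[l.chrom]:
            logger.warning(
                "locus %s at %s:%d beyond declared chromosome length %d",
                l.locus_id,
                l.chrom,
                l.pos,
                chrom_lengths[l.chrom],
            )
        k = (l.pos - 1) // bin_size
        counts[(l.chrom, k)] = counts.get((l.chrom, k), 0) + 1
    rows = [
        {
            "chrom": chrom,
            "bin_start": k * bin_size,
            "bin_end": (k + 1) * bin_size,
            "count": c,
        }
        for (chrom, k), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end", "count"])
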