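"""Three-step ortholog-cluster filtering ("sweep") with full audit trail.

Each cluster of per-sample CDS passes through, in order:

1. *length filter* — strip gaps, trim terminal N runs, drop sequences
   whose length is not a multiple of three or that contain an internal
   stop codon, then drop sequences whose length deviates from the
   cluster mean by more than ``len_var_pct`` percent (single pass
   against the original mean);
2. *distance filter* — on the codon alignment of the survivors, drop
   every sequence whose mean uncorrected p-distance to the others
   exceeds ``max_mean_dist`` percent (simultaneous pass);
3. *missingness filter* — on the re-aligned survivors, drop rows with
   more than ``max_missing_frac`` of N or gap cells.

Every step is followed by a round of alignment and column trimming, and
every removal is recorded with the step, reason and metric value, so a
run can be audited sequence by sequence.  An occupancy filter across
clusters closes the pipeline.  All threshold comparisons are strict
(a value exactly at the threshold survives).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import mean as _mean

import numpy as np
import pandas as pd

from .codon_align import CodonAlignment, align_cluster, check_and_translate
from .io_formats import OrthologCluster, SequenceRecord

logger = logging.getLogger(__name__)

STEPS = ("prep", "length_set", "distance", "missingness", "occupancy")


@dataclass
class FilterParams:
    """Thresholds controlling the three filter steps plus occupancy.

    Defaults follow the stricter of the published runs: 30% length
    variation, 25% mean distance, 25% missing data, and a minimum of
    30 samples per retained alignment.
    """

    len_var_pct: float = 30.0
    max_mean_dist: float = 25.0
    max_missing_frac: float = 0.25
    min_samples: int = 30
    max_gap_frac: float = 0.2
    min_conservation: float = 0.25
    aligner_cmd: str | None = None
    iterate: bool = False  # re-apply steps 1-2 until a fixed point

    def __post_init__(self) -> None:
        if self.len_var_pct < 0:
            raise ValueError("len_var_pct must be >= 0")
        if not 0 <= self.max_mean_dist <= 100:
            raise ValueError("max_mean_dist must be in [0, 100]")
        if not 0 <= self.max_missing_frac <= 1:
            raise ValueError("max_missing_frac must be in [0, 1]")
        if self.min_samples < 2:
            raise ValueError("min_samples must be >= 2")


@dataclass
class FilterReport:
    """Row-per-record audit trail of a filtering run."""

    rows: list[tuple[str, str, str, str, float]] = field(default_factory=list)
    dispositions: dict[str, tuple[str, int]] = field(default_factory=dict)

    def removed(
        self, cluster_id: str, sample_id: str, step: str, reason: str, metric: float
    ) -> None:
        assert step in STEPS
        self.rows.append((cluster_id, sample_id, step, reason, metric))

    def retained(self, cluster_id: str, sample_id: str) -> None:
        self.rows.append((cluster_id, sample_id, "retained", "", float("nan")))

    def dispose(self, cluster_id: str, status: str, n_final: int) -> None:
        self.dispositions[cluster_id] = (status, n_final)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["cluster_id", "sample_id", "step", "reason", "metric_value"],
        )

    def dispositions_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(cid, st, n) for cid, (st, n) in self.dispositions.items()],
            columns=["cluster_id", "disposition", "final_samples"],
        )

    def removal_step(self, cluster_id: str, sample_id: str) -> str | None:
        """Step at which a record was removed, or None if retained."""
        for cid, sid, step, _, _ in self.rows:
            if cid == cluster_id and sid == sample_id and step != "retained":
                return step
        return None


# ---------------------------------------------------------------------------
# Step 1 — preparation and length-set filter
# ---------------------------------------------------------------------------


def _prep_sequence(seq: str) -> str:
    """Strip alignment gaps and trim leading/trailing runs of N."""
    return seq.replace("-", "").strip("N")


def step1_length_filter(
    cluster: OrthologCluster,
    len_var_pct: float = 30.0,
    report: FilterReport | None = None,
    iterate: bool = False,
) -> list[SequenceRecord]:
    """Prep each CDS, apply ORF checks, then the length-variation rule.

    With a cutoff of c percent, sequences longer than mean*(1+c/100) or
    shorter than mean*(1-c/100) are removed, where the mean is taken
    over the records that survived the prep/ORF checks.  By default a
    single pass against that original mean; with ``iterate`` the mean
    is recomputed and the rule re-applied until a fixed point.
    """
    report = report if report is not None else FilterReport()
    cid = cluster.cluster_id
    prepped: list[SequenceRecord] = []
    for rec in cluster:
        seq = _prep_sequence(rec.sequence)
        if not seq:
            report.removed(cid, rec.sample_id, "prep", "empty_after_prep", 0.0)
            continue
        if len(seq) % 3 != 0:
            report.removed(cid, rec.sample_id, "prep", "not_multiple_of_three", len(seq))
            continue
        status, _ = check_and_translate(seq)
        if status.code == "internal_stop":
            report.removed(
                cid, rec.sample_id, "prep", "internal_stop", float(status.detail or 0)
            )
            continue
        prepped.append(SequenceRecord(rec.sample_id, seq, cid))
    if not prepped:
        return []
    survivors = prepped
    while survivors:
        m = _mean(len(r) for r in survivors)
        lo = m * (1 - len_var_pct / 100.0)
        hi = m * (1 + len_var_pct / 100.0)
        kept = []
        for rec in survivors:
            if len(rec) > hi or len(rec) < lo:
                report.removed(cid, rec.sample_id, "length_set", "length_variation", len(rec))
            else:
                kept.append(rec)
        changed = len(kept) != len(survivors)
        survivors = kept
        if not iterate or not changed:
            break
    return survivors


# ---------------------------------------------------------------------------
# Uncorrected p-distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Pairwise uncorrected p-distances in percent, with site counts.

    Entries with zero compared sites are undefined: the distance is NaN
    and ``compared_sites`` is 0.  Undefined distances are treated as
    exceeding any threshold by the filters.
    """

    ids: list[str]
    values: np.ndarray  # percent, NaN when undefined
    compared_sites: np.ndarray

    def mean_distance(self, i: int) -> float:
        """Mean off-diagonal distance for row i; NaN if any pair undefined."""
        others = [j for j in range(len(self.ids)) if j != i]
        return float(np.mean(self.values[i, others]))


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def pdistance_matrix(aln: CodonAlignment | dict[str, str]) -> DistanceMatrix:
    """Uncorrected pairwise distance: 100 x mismatches / compared sites.

    Sites where either row has a gap or N (or any non-ACGT symbol) are
    excluded from the comparison.
    """
    rows = aln.rows if isinstance(aln, CodonAlignment) else aln
    ids = list(rows)
    if len(ids) < 2:
        raise ValueError("need at least 2 rows for a distance matrix")
    mat = np.frombuffer("".join(rows[i] for i in ids).encode(), dtype=np.uint8).reshape(
        len(ids), -1
    )
    is_base = np.isin(mat, _BASES)
    n = len(ids)
    values = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = is_base[i] & is_base[i + 1 :]
        mismatch = ((mat[i] != mat[i + 1 :]) & both).sum(axis=1)
        comp = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(comp > 0, 100.0 * mismatch / np.maximum(comp, 1), np.nan)
        values[i, i + 1 :] = d
        values[i + 1 :, i] = d
        sites[i, i + 1 :] = comp
        sites[i + 1 :, i] = comp
    return DistanceMatrix(ids, values, sites)


def step2_distance_filter(
    aln: CodonAlignment,
    max_mean_dist: float = 25.0,
    report: FilterReport | None = None,
    cluster_id: str = "",
    iterate: bool = False,
) -> list[str]:
    """Drop sequences whose mean p-distance to the rest exceeds the threshold.

    All per-sequence means are computed from the same matrix and the
    removals happen simultaneously (with ``iterate``, the matrix is
    restricted to the survivors and the pass repeated to a fixed
    point).  An undefined pairwise distance (no shared unambiguous
    sites) counts as exceeding any threshold.
    """
    report = report if report is not None else FilterReport()
    ids = list(aln.rows)
    if len(ids) < 2:
        return ids
    dm = pdistance_matrix(aln)
    index_of = {sid: i for i, sid in enumerate(ids)}
    current = list(ids)
    while len(current) >= 2:
        survivors = []
        for sid in current:
            i = index_of[sid]
            others = [index_of[o] for o in current if o != sid]
            row = dm.values[i, others]
            if np.isnan(row).any() or float(np.mean(row)) > max_mean_dist:
                metric = float(np.nanmean(row)) if not np.isnan(row).all() else float("nan")
                reason = "undefined_distance" if np.isnan(row).any() else "mean_distance"
                report.removed(cluster_id, sid, "distance", reason, metric)
            else:
                survivors.append(sid)
        changed = len(survivors) != len(current)
        current = survivors
        if not iterate or not changed:
            break
    return current


def step3_missingness_filter(
    aln: CodonAlignment,
    max_missing_frac: float = 0.25,
    report: FilterReport | None = None,
    cluster_id: str = "",
) -> list[str]:
    """Drop rows with more than ``max_missing_frac`` N or gap cells (strict)."""
    report = report if report is not None else FilterReport()
    survivors = []
    for sid, row in aln.rows.items():
        frac = (row.count("N") + row.count("-")) / len(row)
        if frac > max_missing_frac:
            report.removed(cluster_id, sid, "missingness", "missing_frac", frac)
        else:
            survivors.append(sid)
    return survivors


# ---------------------------------------------------------------------------
# Cross-cluster statistics and occupancy
# ---------------------------------------------------------------------------


@dataclass
class DistanceStats:
    """Distribution of the per-cluster maximum pairwise distance.

    The published workflow chose the step-2 threshold by inspecting the
    mean, sample SD and median of this distribution (median-anchored
    when the SD is large relative to the mean).
    """

    per_cluster_max: dict[str, float]
    mean: float
    sd: float
    median: float


def distance_threshold_stats(alignments: dict[str, CodonAlignment]) -> DistanceStats:
    """Mean/SD/median of the highest pairwise distance per cluster."""
    maxima: dict[str, float] = {}
    for cid, aln in alignments.items():
        if len(aln.rows) < 2:
            continue
        dm = pdistance_matrix(aln)
        vals = dm.values[np.triu_indices(len(dm.ids), k=1)]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            maxima[cid] = float(vals.max())
    if not maxima:
        raise ValueError("no cluster with >= 2 comparable sequences")
    arr = np.array(list(maxima.values()))
    if arr.size == 1:
        logger.warning("single cluster: SD undefined, reported as 0")
        sd = 0.0
    else:
        sd = float(arr.std(ddof=1))
    return DistanceStats(maxima, float(arr.mean()), sd, float(np.median(arr)))


def occupancy_percent(min_samples: int, total_samples: int) -> int:
    """Occupancy label: 100 * min_samples / total_samples, nearest integer."""
    if min_samples > total_samples:
        raise ValueError("min_samples exceeds the total sample count")
    return round(100 * min_samples / total_samples)


def occupancy_filter(
    alignments: dict[str, CodonAlignment],
    min_samples: int,
    total_samples: int | None = None,
    report: FilterReport | None = None,
) -> tuple[dict[str, CodonAlignment], int]:
    """Keep clusters with at least ``min_samples`` surviving samples.

    Returns the retained alignments and the occupancy percent implied
    by ``min_samples`` out of ``total_samples`` (the union of sample
    ids when not given).
    """
    report = report if report is not None else FilterReport()
    if total_samples is None:
        all_ids: set[str] = set()
        for aln in alignments.values():
            all_ids.update(aln.rows)
        total_samples = len(all_ids)
    occ = occupancy_percent(min_samples, total_samples)
    retained: dict[str, CodonAlignment] = {}
    for cid, aln in alignments.items():
        if len(aln.rows) >= min_samples:
            retained[cid] = aln
            report.dispose(cid, "retained", len(aln.rows))
        else:
            for sid in aln.rows:
                report.removed(cid, sid, "occupancy", "low_occupancy", len(aln.rows))
            report.dispose(cid, "dropped_occupancy", len(aln.rows))
    return retained, occ


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineSummary:
    clusters: int
    total_sites: int
    mean_length: float
    occupancy_pct: int | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "clusters": self.clusters,
                    "total_sites": self.total_sites,
                    "mean_length": self.mean_length,
                    "occupancy_pct": self.occupancy_pct,
                }
            ]
        )


def summarize_alignments(n_clusters: int, total_sites: int) -> PipelineSummary:
    """Bookkeeping identity: mean alignment length = total sites / clusters."""
    if n_clusters <= 0:
        raise ValueError("no clusters")
    return PipelineSummary(n_clusters, total_sites, total_sites / n_clusters)


def filter_cluster(
    cluster: OrthologCluster,
    params: FilterParams,
    report: FilterReport,
    *,
    mark_retained: bool = True,
) -> CodonAlignment | None:
    """Run steps 1-3 (each with an alignment round) on one cluster."""
    cid = cluster.cluster_id

    def _align(cds: dict[str, str]) -> CodonAlignment | None:
        return align_cluster(
            cds,
            max_gap_frac=params.max_gap_frac,
            min_conservation=params.min_conservation,
            aligner_cmd=params.aligner_cmd,
        )

    s1 = step1_length_filter(cluster, params.len_var_pct, report, iterate=params.iterate)
    if not s1:
        report.dispose(cid, "dropped_empty", 0)
        return None
    cds = {r.sample_id: r.sequence for r in s1}
    aln = _align(cds)
    if aln is None:
        for sid in cds:
            report.removed(cid, sid, "prep", "all_columns_trimmed", 0.0)
        report.dispose(cid, "dropped_untrimmable", 0)
        return None

    s2 = step2_distance_filter(aln, params.max_mean_dist, report, cid, iterate=params.iterate)
    if not s2:
        report.dispose(cid, "dropped_empty", 0)
        return None
    if set(s2) != set(aln.rows):
        aln = _align({sid: cds[sid] for sid in s2})
        if aln is None:
            for sid in s2:
                report.removed(cid, sid, "prep", "all_columns_trimmed", 0.0)
            report.dispose(cid, "dropped_untrimmable", 0)
            return None

    s3 = step3_missingness_filter(aln, params.max_missing_frac, report, cid)
    if not s3:
        report.dispose(cid, "dropped_empty", 0)
        return None
    if set(s3) != set(aln.rows):
        aln = _align({sid: cds[sid] for sid in s3})
        if aln is None:
            for sid in s3:
                report.removed(cid, sid, "prep", "all_columns_trimmed", 0.0)
            report.dispose(cid, "dropped_untrimmable", 0)
            return None

    if mark_retained:
        for sid in aln.rows:
            report.retained(cid, sid)
    return aln


def run_pipeline(
    clusters: list[OrthologCluster] | dict[str, OrthologCluster],
    params: FilterParams | None = None,
    *,
    apply_occupancy: bool = True,
) -> tuple[dict[str, CodonAlignment], FilterReport, PipelineSummary]:
    """Filter and align a set of ortholog clusters.

    Returns the final codon alignments keyed by cluster id, the full
    audit report, and the summary (cluster count, total nucleotide
    sites, mean alignment length, occupancy label).
    """
    params = params or FilterParams()
    if isinstance(clusters, dict):
        clusters = list(clusters.values())
    if not clusters:
        raise ValueError("no input clusters")
    report = FilterReport()
    total_samples: set[str] = set()
    for c in clusters:
        total_samples.update(c.sample_ids)
    alignments: dict[str, CodonAlignment] = {}
    for cluster in clusters:
        aln = filter_cluster(cluster, params, report, mark_retained=False)
        if aln is not None:
            alignments[cluster.cluster_id] = aln
    occ = None
    if apply_occupancy and alignments:
        alignments, occ = occupancy_filter(
            alignments, params.min_samples, len(total_samples), report
        )
    else:
        for cid, aln in alignments.items():
            report.dispose(cid, "retained", len(aln.rows))
    for cid, aln in alignments.items():
        for sid in aln.rows:
            report.retained(cid, sid)
    if alignments:
        total_sites = sum(a.column_count for a in alignments.values())
        summary = summarize_alignments(len(alignments), total_sites)
    else:
        summary = PipelineSummary(0, 0, float("nan"))
    summary.occupancy_pct = occ
    return alignments, report, summary
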