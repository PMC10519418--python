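"""Locus-subsampling experiment for sizing a diagnostic marker panel.

Replicate gene-tree subsets of increasing size are drawn (with
replacement, under a per-specimen coverage rule), a species tree is
estimated from each subset, rooted on an outgroup and compared with a
reference species tree via rooted Robinson-Foulds distance and clade
recovery.  The per-size summary (per-clade recovery proportion, RF
median and interquartile range) is the deliverable used to judge where
adding loci stops improving resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .speciestree import greedy_search
from .treestats import clade_recovery, rf_distance, root_on_outgroup

logger = logging.getLogger(__name__)

#: Subset sizes used for the informative-locus panel (10..110 step 10).
PANEL_SIZES = tuple(range(10, 111, 10))
#: Additional sizes used for a large gene-tree collection.
FULLSET_SIZES = tuple(range(200, 1001, 100))


class InfeasibleSubsampleError(RuntimeError):
    """Raised when the coverage rule cannot be satisfied."""


@dataclass
class SubsampleConfig:
    sizes: Sequence[int] = PANEL_SIZES
    replicates: int = 500
    min_coverage: int = 2
    with_replacement: bool = True
    seed: int = 1
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if not self.sizes or any(s < 1 for s in self.sizes):
            raise ValueError("sizes must be positive")
        if self.replicates < 1 or self.min_coverage < 1:
            raise ValueError("replicates and min_coverage must be >= 1")


def draw_subset(
    gene_trees: list[dendropy.Tree] | list[frozenset[str]],
    size: int,
    min_coverage: int = 2,
    with_replacement: bool = True,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 1000,
) -> tuple[list[int], int]:
    """Draw gene-tree indices until every specimen is covered.

    A draw is accepted only when every specimen of the universe (the
    union of all leaf sets) occurs in at least ``min_coverage``
    *distinct* drawn trees; duplicated copies of a tree do not add
    coverage.  Returns (indices, attempts).
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    leafsets = [
        fs if isinstance(fs, frozenset) else frozenset(l.taxon.label for l in fs.leaf_node_iter())
        for fs in gene_trees
    ]
    universe: set[str] = set().union(*leafsets)
    counts = {sp: sum(sp in fs for fs in leafsets) for sp in universe}
    lacking = sorted(sp for sp, c in counts.items() if c < min_coverage)
    if lacking:
        raise InfeasibleSubsampleError(
            f"specimen(s) {lacking} occur in fewer than {min_coverage} gene trees"
        )
    n = len(leafsets)
    if not with_replacement and size > n:
        raise InfeasibleSubsampleError(f"cannot draw {size} of {n} trees without replacement")
    for attempt in range(1, max_attempts + 1):
        idx = rng.choice(n, size=size, replace=with_replacement)
        distinct = set(int(i) for i in idx)
        covered: dict[str, int] = {sp: 0 for sp in universe}
        for i in distinct:
            for sp in leafsets[i]:
                covered[sp] += 1
        if all(c >= min_coverage for c in covered.values()):
            return [int(i) for i in idx], attempt
    raise InfeasibleSubsampleError(
        f"no subset of size {size} satisfied coverage {min_coverage} "
        f"within {max_attempts} attempts"
    )


def _default_estimator(trees: list[dendropy.Tree], rng: np.random.Generator):
    return greedy_search(trees, rng=rng).topology


def run_experiment(
    gene_trees: list[dendropy.Tree],
    config: SubsampleConfig,
    reference_tree: dendropy.Tree,
    outgroup: str,
    reference_clades: list[frozenset[str]],
    estimator: Callable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw, estimate, and compare across all sizes and replicates.

    The reference tree is rooted on the outgroup and the outgroup is
    pruned before comparison; estimated trees are treated the same way.
    Returns (result table, per-size summary).  Fully reproducible from
    (config.seed, config).
    """
    estimator = estimator or _default_estimator
    ref_rooted = root_on_outgroup(reference_tree, outgroup, prune_outgroup=True)
    leafsets = [
        frozenset(l.taxon.label for l in gt.leaf_node_iter()) for gt in gene_trees
    ]
    rows = []
    recovery_rows = []
    for si, size in enumerate(config.sizes):
        for rep in range(config.replicates):
            ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(si, rep))
            rng = np.random.default_rng(ss)
            for _ in range(config.max_attempts):
                idx, attempts = draw_subset(
                    leafsets,
                    size,
                    config.min_coverage,
                    config.with_replacement,
                    rng,
                    config.max_attempts,
                )
                subset = [gene_trees[i] for i in idx]
                est = estimator(subset, rng)
                est_leaves = {l.taxon.label for l in est.leaf_node_iter()}
                if outgroup in est_leaves:
                    break
                logger.warning(
                    "size %d rep %d: outgroup missing from estimate; redrawing", size, rep
                )
            else:
                raise InfeasibleSubsampleError("estimator never produced the outgroup")
            est_rooted = root_on_outgroup(est, outgroup, prune_outgroup=True)
            rf = rf_distance(est_rooted, ref_rooted, mode="rooted", prune_to_common=True)
            rec = clade_recovery(est_rooted, reference_clades)
            rows.append(
                {"size": size, "replicate": rep, "rf": rf, "attempts": attempts}
            )
            recovery_rows.append(rec)
    results = pd.DataFrame(rows)
    rec_mat = pd.DataFrame(
        recovery_rows, columns=[f"clade_{i}" for i in range(len(reference_clades))]
    )
    results = pd.concat([results, rec_mat], axis=1)
    summary = summarize_experiment(results, len(reference_clades))
    return results, summary


def summarize_experiment(results: pd.DataFrame, n_clades: int) -> pd.DataFrame:
    """Per-size, per-clade recovery proportion plus RF median and IQR."""
    out = []
    for size, grp in results.groupby("size"):
        rf_median = float(grp["rf"].median())
        rf_q1 = float(grp["rf"].quantile(0.25))
        rf_q3 = float(grp["rf"].quantile(0.75))
        for i in range(n_clades):
            out.append(
                {
                    "size": int(size),
                    "clade_id": f"clade_{i}",
                    "recovery_prop": float(grp[f"clade_{i}"].mean()),
                    "rf_median": rf_median,
                    "rf_q1": rf_q1,
                    "rf_q3": rf_q3,
                }
            )
    return pd.DataFrame(out)
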