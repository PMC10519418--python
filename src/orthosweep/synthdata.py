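"""Synthetic phylogenomic data with ground truth.

Generates a species tree, multispecies-coalescent (MSC) gene trees,
codon sequences along those gene trees, and injected contaminants
(paralogs, frameshifts, truncations, N-masking) together with a truth
manifest, so the filters, tree statistics and subsampling machinery can
all be exercised without external data.

The MSC here is the textbook one: within each species-tree branch of
length t coalescent units, j lineages coalesce after an exponential
waiting time with rate j(j-1)/2.  For a three-taxon species tree with
internal branch t, the probability that a gene tree matches the species
tree is 1 - (2/3)e^(-t), which the test suite uses as the independent
check of the simulator.

Sequences evolve under a single-rate symmetric nucleotide model
(Jukes-Cantor-like), with any substitution creating an in-frame stop
codon rejected and resampled, so every simulated CDS passes the ORF
checks by construction.  Realism of the substitution process is a
non-goal; the outputs only need the properties the filters assume.

All randomness flows from one seed through per-cluster counter-based
`SeedSequence` streams, so per-cluster outputs do not depend on
iteration order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .codon_align import STOP_CODONS
from .io_formats import OrthologCluster, SequenceRecord

_SENSE_CODONS = sorted(
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
)
_BASES = "ACGT"


@dataclass
class MSCParams:
    """Multispecies-coalescent simulation settings (coalescent units)."""

    n_species: int = 12
    samples_per_species: int = 1
    n_genes: int = 200
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if self.samples_per_species < 1 or self.n_genes < 1:
            raise ValueError("samples_per_species and n_genes must be >= 1")


@dataclass
class ContaminationSpec:
    """Per-record artifact probabilities and effect sizes.

    At most one artifact is applied per record.  Defaults are sized so
    that each artifact decisively violates the filter that targets it
    at the default thresholds: a frameshift breaks the reading frame, a
    50% truncation falls far outside a 30% length-variation band, a
    paralog re-simulated at 2 extra substitutions/site sits near
    saturation (~70% p-distance), and 50% masking doubles the 25%
    missingness threshold.
    """

    p_paralog: float = 0.04
    p_frameshift: float = 0.04
    p_truncate: float = 0.04
    p_mask: float = 0.04
    paralog_extra_divergence: float = 2.0
    mask_frac: float = 0.5
    truncate_frac: float = 0.5

    def __post_init__(self) -> None:
        probs = (self.p_paralog, self.p_frameshift, self.p_truncate, self.p_mask)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must be in [0, 1]")
        if sum(probs) > 1:
            raise ValueError("artifact probabilities sum to more than 1")
        if min(self.paralog_extra_divergence, self.mask_frac, self.truncate_frac) <= 0:
            raise ValueError("effect sizes must be positive")


@dataclass
class TruthManifest:
    """Ground truth of a simulated, possibly contaminated dataset."""

    species_tree: str  # Newick
    rows: pd.DataFrame  # cluster_id, sample_id, artifact, detail

    def artifacts(self, kind: str | None = None) -> pd.DataFrame:
        df = self.rows[self.rows["artifact"] != "none"]
        return df if kind is None else df[df["artifact"] == kind]


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


def simulate_species_tree(
    n_species: int,
    birth_rate: float = 1.0,
    rng: np.random.Generator | int | None = None,
    min_internal_branch: float | None = None,
) -> dendropy.Tree:
    """Yule (pure-birth) species tree with coalescent-unit branch lengths.

    Leaves are labelled sp1..spN and are contemporaneous.  With
    ``min_internal_branch`` every internal branch shorter than the
    given value is stretched to it (the tree is then no longer
    ultrametric in the strict sense, but node ages remain consistent).
    """
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    taxa = dendropy.TaxonNamespace([f"sp{i + 1}" for i in range(n_species)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root.birth_time = 0.0
    active = [root]
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(int(rng.integers(len(active))))
        for _ in range(2):
            child = dendropy.Node()
            child.birth_time = t
            node.add_child(child)
            active.append(child)
        node.split_time = t
    present = t + 1.0
    labels = iter(sorted(taxa, key=lambda tx: tx.label))
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.taxon = next(labels)
            node.edge.length = present - node.birth_time
        elif node is not root:
            node.edge.length = node.split_time - node.birth_time
        else:
            node.edge.length = 0.0
    if min_internal_branch is not None:
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node is root:
                continue
            if node.edge.length < min_internal_branch:
                node.edge.length = min_internal_branch
    return tree


# ---------------------------------------------------------------------------
# Gene trees under the MSC
# ---------------------------------------------------------------------------


def _node_ages(tree: dendropy.Tree) -> dict:
    """Age (time before present) of each node: max root-free path to a leaf."""
    ages: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            ages[node] = max(ages[ch] + (ch.edge.length or 0.0) for ch in node.child_nodes())
    return ages


def simulate_gene_tree(
    species_tree: dendropy.Tree,
    rng: np.random.Generator,
    samples_per_species: int = 1,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """One coalescent gene tree within the species tree (coalescent units)."""
    ages = _node_ages(species_tree)
    ns = taxon_namespace or dendropy.TaxonNamespace()

    def new_leaf(label: str) -> dendropy.Node:
        node = dendropy.Node()
        tx = ns.get_taxon(label)
        node.taxon = tx if tx is not None else ns.new_taxon(label)
        node.age = 0.0
        return node

    def coalesce(lineages: list, t_start: float, t_end: float) -> list:
        """Coalesce within [t_start, t_end] (t_end may be inf)."""
        t = t_start
        lineages = list(lineages)
        while len(lineages) > 1:
            k = len(lineages)
            t = t + rng.exponential(2.0 / (k * (k - 1)))
            if t > t_end:
                break
            i, j = sorted(rng.choice(k, size=2, replace=False))
            a = lineages.pop(j)
            b = lineages.pop(i)
            parent = dendropy.Node()
            parent.age = t
            for ch in (a, b):
                parent.add_child(ch)
                ch.edge.length = t - ch.age
            lineages.append(parent)
        return lineages

    pending: dict = {}
    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if samples_per_species == 1:
                lineages = [new_leaf(label)]
            else:
                lineages = [new_leaf(f"{label}_{k + 1}") for k in range(samples_per_species)]
        else:
            lineages = []
            for ch in node.child_nodes():
                lineages.extend(pending.pop(ch))
        if node.parent_node is None:
            lineages = coalesce(lineages, ages[node], np.inf)
            root = lineages[0]
        else:
            t_end = ages[node] + (node.edge.length or 0.0)
            pending[node] = coalesce(lineages, ages[node], t_end)
    gt = dendropy.Tree(taxon_namespace=ns)
    gt.seed_node = root
    return gt


def simulate_gene_trees(
    species_tree: dendropy.Tree, msc: MSCParams
) -> list[dendropy.Tree]:
    """``msc.n_genes`` independent MSC gene trees, reproducible per seed."""
    ns = dendropy.TaxonNamespace()
    out = []
    for g in range(msc.n_genes):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=msc.seed, spawn_key=(0, g))
        )
        out.append(
            simulate_gene_tree(species_tree, rng, msc.samples_per_species, ns)
        )
    return out


# ---------------------------------------------------------------------------
# Codon sequences
# ---------------------------------------------------------------------------


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    idx = rng.integers(len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _creates_stop(seq: list[str], pos: int, base: str) -> bool:
    cstart = (pos // 3) * 3
    codon = "".join(seq[cstart : cstart + 3])
    codon = codon[: pos - cstart] + base + codon[pos - cstart + 1 :]
    return codon in STOP_CODONS


def evolve_sequence(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Apply Poisson(divergence * length) substitutions, rejecting stops."""
    chars = list(seq)
    n_sub = rng.poisson(divergence * len(chars))
    applied = 0
    while applied < n_sub:
        pos = int(rng.integers(len(chars)))
        base = _BASES[int(rng.integers(4))]
        if base == chars[pos]:
            continue
        if _creates_stop(chars, pos, base):
            continue
        chars[pos] = base
        applied += 1
    return "".join(chars)


def simulate_codon_sequences(
    gene_tree: dendropy.Tree,
    n_codons: int = 300,
    subst_rate: float = 0.01,
    rng: np.random.Generator | int | None = None,
    cluster_id: str = "cluster",
) -> tuple[OrthologCluster, str]:
    """Evolve a CDS of ``n_codons`` sense codons down the gene tree.

    ``subst_rate`` is substitutions per site per coalescent unit.
    Returns the cluster and the root sequence (needed to spawn
    paralogs).  Every output passes the ORF checks by construction.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    root_seq = _random_cds(n_codons, rng)
    seqs: dict = {gene_tree.seed_node: root_seq}
    records = []
    for node in gene_tree.preorder_node_iter():
        if node is gene_tree.seed_node:
            continue
        parent_seq = seqs[node.parent_node]
        seqs[node] = evolve_sequence(parent_seq, subst_rate * (node.edge.length or 0.0), rng)
        if node.is_leaf():
            records.append(SequenceRecord(node.taxon.label, seqs[node], cluster_id))
    records.sort(key=lambda r: r.sample_id)
    return OrthologCluster(cluster_id, records), root_seq


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------


def inject_artifacts(
    clusters: dict[str, OrthologCluster],
    spec: ContaminationSpec,
    rng: np.random.Generator | int | None = None,
    root_seqs: dict[str, str] | None = None,
    species_tree: str = "",
) -> tuple[dict[str, OrthologCluster], TruthManifest]:
    """Corrupt records with at most one artifact each, recording ground truth.

    paralog: the cluster's root sequence re-evolved with
    ``paralog_extra_divergence`` extra substitutions/site (a duplicate
    that split before the cluster's common ancestor); frameshift: one
    base deleted at a random position; truncate: the trailing
    ``truncate_frac`` of codons removed; mask: ``mask_frac`` of
    positions set to N.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    cum = np.cumsum(
        [spec.p_paralog, spec.p_frameshift, spec.p_truncate, spec.p_mask]
    )
    kinds = ["paralog", "frameshift", "truncate", "mask"]
    out: dict[str, OrthologCluster] = {}
    rows = []
    for cid in sorted(clusters):
        cluster = clusters[cid]
        source = (root_seqs or {}).get(cid) or cluster.records[0].sequence
        new_records = []
        for rec in cluster:
            u = rng.random()
            kind = "none"
            for k, threshold in zip(kinds, cum):
                if u < threshold:
                    kind = k
                    break
            seq, detail = rec.sequence, ""
            if kind == "paralog":
                seq = evolve_sequence(source, spec.paralog_extra_divergence, rng)
                detail = f"extra_divergence={spec.paralog_extra_divergence}"
            elif kind == "frameshift":
                pos = int(rng.integers(len(seq)))
                seq = seq[:pos] + seq[pos + 1 :]
                detail = f"deleted_pos={pos}"
            elif kind == "truncate":
                n_codons = len(seq) // 3
                cut = int(round(spec.truncate_frac * n_codons)) * 3
                seq = seq[: len(seq) - cut]
                detail = f"cut_bases={cut}"
                if not seq:
                    seq, kind, detail = rec.sequence, "none", ""
            elif kind == "mask":
                # a contiguous run of whole codons, as an assembly gap would be
                n_codons = len(seq) // 3
                k = min(int(round(spec.mask_frac * n_codons)), max(n_codons - 2, 1))
                # interior run: a terminal N-run would be trimmed and look
                # like a truncation rather than missing data
                start = int(rng.integers(1, n_codons - k)) if n_codons - k > 1 else 0
                seq = seq[: 3 * start] + "N" * (3 * k) + seq[3 * (start + k) :]
                detail = f"masked_codons={k}@{start}"
            new_records.append(SequenceRecord(rec.sample_id, seq, cid))
            rows.append(
                {"cluster_id": cid, "sample_id": rec.sample_id, "artifact": kind, "detail": detail}
            )
        out[cid] = OrthologCluster(cid, new_records)
    manifest = TruthManifest(
        species_tree, pd.DataFrame(rows, columns=["cluster_id", "sample_id", "artifact", "detail"])
    )
    return out, manifest


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    species_tree: dendropy.Tree
    gene_trees: list[dendropy.Tree]
    clusters: dict[str, OrthologCluster]
    root_seqs: dict[str, str]
    manifest: TruthManifest


def simulate_dataset(
    msc: MSCParams | None = None,
    contamination: ContaminationSpec | None = None,
    n_codons: int = 300,
    subst_rate: float = 0.01,
    birth_rate: float = 1.0,
    min_internal_branch: float | None = None,
) -> SimulatedDataset:
    """Species tree -> MSC gene trees -> codon clusters -> artifacts."""
    msc = msc or MSCParams()
    sp_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=msc.seed, spawn_key=(1,))
    )
    species_tree = simulate_species_tree(
        msc.n_species, birth_rate, sp_rng, min_internal_branch
    )
    gene_trees = simulate_gene_trees(species_tree, msc)
    clusters: dict[str, OrthologCluster] = {}
    root_seqs: dict[str, str] = {}
    width = len(str(msc.n_genes))
    for g, gt in enumerate(gene_trees):
        cid = f"cluster{g + 1:0{width}d}"
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=msc.seed, spawn_key=(2, g))
        )
        clusters[cid], root_seqs[cid] = simulate_codon_sequences(
            gt, n_codons, subst_rate, rng, cid
        )
    sp_newick = species_tree.as_string(schema="newick").strip()
    if contamination is None:
        rows = [
            {"cluster_id": cid, "sample_id": r.sample_id, "artifact": "none", "detail": ""}
            for cid in sorted(clusters)
            for r in clusters[cid]
        ]
        manifest = TruthManifest(
            sp_newick,
            pd.DataFrame(rows, columns=["cluster_id", "sample_id", "artifact", "detail"]),
        )
        return SimulatedDataset(species_tree, gene_trees, clusters, root_seqs, manifest)
    art_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=msc.seed, spawn_key=(3,))
    )
    corrupted, manifest = inject_artifacts(
        clusters, contamination, art_rng, root_seqs, sp_newick
    )
    return SimulatedDataset(species_tree, gene_trees, corrupted, root_seqs, manifest)
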