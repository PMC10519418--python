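"""Readers and writers for the formats the toolkit touches.

FASTA files hold one ortholog cluster each (one CDS per sample); Newick
files hold gene trees (one per line) or a single species tree; locus
tables are TSV with a ``locus_id / chrom / pos`` header.  Parsing is
strict: duplicate identifiers, illegal characters and malformed trees
are errors, not warnings, because every downstream filter assumes the
invariants enforced here.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Characters allowed in a sequence after normalisation.
DNA_ALPHABET = frozenset("ACGTN-")

#: IUPAC one-letter nucleotide ambiguity codes collapsed to N on input.
_AMBIGUITY = frozenset("RYSWKMBDHV")


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class SequenceRecord:
    """One sample's CDS within a named ortholog cluster."""

    sample_id: str
    sequence: str
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sample_id or re.search(r"\s", self.sample_id):
            raise FormatError(
                f"sample_id must be a non-empty whitespace-free token, got {self.sample_id!r}"
            )
        if not self.sequence:
            raise FormatError(f"empty sequence for sample {self.sample_id!r}")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"illegal character(s) {sorted(bad)} in sequence for {self.sample_id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class OrthologCluster:
    """An ordered collection of per-sample CDS records for one locus."""

    cluster_id: str
    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sample_id(s) {dup} in cluster {self.cluster_id!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]


@dataclass(frozen=True)
class LocusCoordinate:
    """1-based point coordinate (first position) of a locus in a genome."""

    locus_id: str
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"locus {self.locus_id!r}: pos must be >= 1, got {self.pos}")


def _normalise_sequence(raw: str, *, sample_id: str, line_no: int) -> str:
    """Uppercase, map U->T and IUPAC ambiguity codes to N; reject the rest."""
    seq = raw.upper().replace("U", "T")
    chars = set(seq)
    if chars & _AMBIGUITY:
        logger.warning(
            "sample %s: ambiguity codes %s mapped to N",
            sample_id,
            sorted(chars & _AMBIGUITY),
        )
        seq = re.sub("[" + "".join(_AMBIGUITY) + "]", "N", seq)
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise FormatError(
            f"illegal character(s) {sorted(bad)} in sequence for {sample_id!r} "
            f"(first offending line {line_no})"
        )
    return seq


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _first_bad_line(path: Path, sample_id: str) -> int:
    """Locate the first sequence line of ``sample_id`` containing an illegal char."""
    current = None
    with _open_text(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith(">"):
                current = line[1:].split()[0] if len(line) > 1 else ""
            elif current == sample_id and line:
                seq = line.upper().replace("U", "T")
                seq = re.sub("[" + "".join(_AMBIGUITY) + "]", "N", seq)
                if set(seq) - DNA_ALPHABET:
                    return i
    return -1


def read_fasta(path: str | Path) -> OrthologCluster:
    """Read one ortholog cluster from a FASTA file.

    The header token up to the first whitespace is the sample id (any
    remainder is logged and discarded); the file stem names the cluster.
    Lowercase, ``U`` and IUPAC ambiguity codes are normalised; any other
    character is an error that names the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cluster_id = path.name
    for suffix in (".gz", ".fasta", ".fa", ".fna"):
        if cluster_id.endswith(suffix):
            cluster_id = cluster_id[: -len(suffix)]
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            sample_id = rec.id
            if rec.description != rec.id and rec.description.strip():
                logger.debug("header comment discarded for %s: %r", rec.id, rec.description)
            if sample_id in seen:
                raise FormatError(f"duplicate sample_id {sample_id!r} in {path}")
            seen.add(sample_id)
            try:
                seq = _normalise_sequence(str(rec.seq), sample_id=sample_id, line_no=-1)
            except FormatError:
                raise FormatError(
                    f"illegal character in sequence for {sample_id!r} in {path} "
                    f"(line {_first_bad_line(path, sample_id)})"
                ) from None
            if not seq:
                raise FormatError(f"empty sequence for {sample_id!r} in {path}")
            records.append(SequenceRecord(sample_id, seq, cluster_id))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return OrthologCluster(cluster_id, records)


def write_fasta(cluster_or_rows, path: str | Path, *, width: int = 80) -> None:
    """Write records (an OrthologCluster or a ``{id: seq}`` mapping) as FASTA."""
    if isinstance(cluster_or_rows, OrthologCluster):
        items = [(r.sample_id, r.sequence) for r in cluster_or_rows]
    else:
        items = list(cluster_or_rows.items())
    with open(path, "w") as fh:
        for sid, seq in items:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a single Newick tree from a path or a literal string.

    The parsed shape is kept as written (a basal bifurcation is not
    collapsed); callers decide whether to treat the tree as rooted.
    Duplicate leaf labels and negative branch lengths are errors.
    """
    text = source if isinstance(source, str) and source.lstrip().startswith("(") else None
    try:
        if text is not None:
            tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(path=str(source), schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"malformed Newick: {exc}") from exc
    _validate_tree(tree)
    return tree


def read_newick_list(path: str | Path) -> list[dendropy.Tree]:
    """Read a gene-tree collection: one Newick tree per line."""
    try:
        trees = dendropy.TreeList.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise FormatError(f"malformed Newick in {path}: {exc}") from exc
    out = list(trees)
    for t in out:
        _validate_tree(t)
    return out


def _validate_tree(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(lbl is None for lbl in labels):
        raise FormatError("tree has an unlabeled leaf")
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"duplicate leaf label(s): {dup}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise FormatError(f"negative branch length {edge.length}")


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialise a tree to Newick; write to ``path`` when given."""
    text = tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    text = text.strip() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_newick_list(trees: Iterable[dendropy.Tree], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(
                t.as_string(
                    schema="newick", suppress_rooting=True, unquoted_underscores=True
                ).strip()
                + "\n"
            )


def tree_leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Locus coordinate tables
# ---------------------------------------------------------------------------

LOCUS_COLUMNS = ("locus_id", "chrom", "pos")


def read_locus_table(path: str | Path) -> list[LocusCoordinate]:
    """Read a TSV of locus point coordinates, sorted by (chrom, pos)."""
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "chrom": str})
    missing = set(LOCUS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"locus table missing column(s) {sorted(missing)}")
    if df["locus_id"].duplicated().any():
        dup = sorted(df.loc[df["locus_id"].duplicated(), "locus_id"].unique())
        raise FormatError(f"duplicate locus_id(s): {dup}")
    pos_numeric = pd.to_numeric(df["pos"], errors="coerce")
    if pos_numeric.isna().any() or (pos_numeric % 1 != 0).any():
        raise FormatError("locus table: pos must be integer")
    pos = pos_numeric.astype("int64")
    if (pos < 1).any():
        bad = df.loc[pos < 1, "locus_id"].tolist()
        raise FormatError(f"locus table: pos < 1 for {bad}")
    df = df.assign(pos=pos).sort_values(["chrom", "pos"], kind="mergesort")
    return [
        LocusCoordinate(row.locus_id, row.chrom, int(row.pos))
        for row in df.itertuples(index=False)
    ]


def write_locus_table(loci: Sequence[LocusCoordinate], path: str | Path) -> None:
    pd.DataFrame(
        [(l.locus_id, l.chrom, l.pos) for l in loci], columns=list(LOCUS_COLUMNS)
    ).to_csv(path, sep="\t", index=False)
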