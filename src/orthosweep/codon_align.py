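"""Codon-aware alignment: translate, align proteins, trim, back-translate.

The alignment protocol mirrors the classic TranslatorX-style workflow:
CDS are validated and translated with the standard genetic code, aligned
at the protein level, poorly aligned columns are trimmed, and the kept
columns are mapped back onto the coding DNA one codon per residue, so
the final nucleotide alignment is always in frame.

The built-in aligner is a deterministic progressive aligner (3-mer
distances, UPGMA guide tree, BLOSUM62 profile-profile global alignment
with affine gaps, open -10 / extend -1).  Any external command mapping
FASTA to aligned FASTA can be substituted via ``aligner_cmd``.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .io_formats import SequenceRecord, write_fasta

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)

AA_ORDER = "ARNDCQEGHILKMFPSTWYVX"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

GAP_OPEN = -10.0
GAP_EXTEND = -1.0


def _blosum62_matrix() -> np.ndarray:
    """BLOSUM62 over AA_ORDER (X row/column included), as float64."""
    blosum = substitution_matrices.load("BLOSUM62")
    m = np.zeros((len(AA_ORDER), len(AA_ORDER)))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            m[i, j] = blosum[a][b]
    return m


_BLOSUM = _blosum62_matrix()


@dataclass
class OrfStatus:
    """Outcome of validating a CDS reading frame."""

    code: str  # ok | not_multiple_of_three | internal_stop
    detail: int | None = None  # 1-based codon index of the first offence

    @property
    def ok(self) -> bool:
        return self.code == "ok"


def translate_codon(codon: str) -> str:
    """Standard-code translation; any codon containing N yields X."""
    if "N" in codon:
        return "X"
    return _STANDARD.forward_table.get(codon, "X") if codon not in STOP_CODONS else "*"


def check_and_translate(record: SequenceRecord | str) -> tuple[OrfStatus, str | None]:
    """Validate a gap-free CDS and translate it.

    A single terminal stop codon is allowed and trimmed before
    translation; an in-frame stop anywhere earlier is reported as
    ``internal_stop`` (1-based codon position) and no protein is
    returned.  Codons containing N translate to X.
    """
    seq = record.sequence if isinstance(record, SequenceRecord) else record
    if "-" in seq:
        raise ValueError("check_and_translate expects a gap-free CDS")
    if len(seq) % 3 != 0:
        return OrfStatus("not_multiple_of_three", None), None
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            return OrfStatus("internal_stop", i + 1), None
    if not codons:
        return OrfStatus("internal_stop", 1), None
    protein = "".join(translate_codon(c) for c in codons)
    return OrfStatus("ok"), protein


@dataclass
class ProteinAlignment:
    """Aligned amino-acid rows (equal length), keyed by sample id."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def column_count(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows.values())


@dataclass
class CodonAlignment:
    """In-frame DNA alignment plus the protein columns it derives from."""

    rows: dict[str, str]
    retained_columns: list[int]

    @property
    def column_count(self) -> int:
        """Number of nucleotide columns."""
        return len(next(iter(self.rows.values()))) if self.rows else 0


# ---------------------------------------------------------------------------
# Progressive protein alignment
# ---------------------------------------------------------------------------


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    """Fractional common k-mer distance (MUSCLE-style guide distance)."""
    if len(a) < k or len(b) < k:
        return 1.0
    ka: dict[str, int] = {}
    for i in range(len(a) - k + 1):
        w = a[i : i + k]
        ka[w] = ka.get(w, 0) + 1
    kb: dict[str, int] = {}
    for i in range(len(b) - k + 1):
        w = b[i : i + k]
        kb[w] = kb.get(w, 0) + 1
    shared = sum(min(ka[w], kb[w]) for w in ka.keys() & kb.keys())
    denom = min(len(a), len(b)) - k + 1
    return 1.0 - shared / denom


def _profile(rows: np.ndarray) -> np.ndarray:
    """Column residue-frequency profile; gaps carry no frequency mass."""
    n_rows, n_cols = rows.shape
    prof = np.zeros((n_cols, len(AA_ORDER)))
    for idx in range(len(AA_ORDER)):
        prof[:, idx] = (rows == idx).sum(axis=0)
    return prof / n_rows


try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    njit = lambda *a, **k: (lambda f: f)  # noqa: E731


@njit(cache=False)
def _gotoh_traceback(S, gap_open, gap_extend):  # pragma: no cover - jitted
    """Global affine-gap DP on a precomputed column-score matrix.

    Returns an array of moves (0 diagonal, 1 gap in B/consume A,
    2 gap in A/consume B) in reverse order, and its length.
    """
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in B (A advances)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in A (B advances)
    tb_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    tb_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    tb_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + gap_extend * (i - 1)
        tb_x[i, 0] = 1
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + gap_extend * (j - 1)
        tb_y[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = S[i - 1, j - 1]
            # M: best of the three states diagonally
            best = M[i - 1, j - 1]
            state = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                state = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                state = 2
            M[i, j] = best + s
            tb_m[i, j] = state
            # Ix: gap in B, consume A[i-1]
            open_x = M[i - 1, j] + gap_open
            ext_x = Ix[i - 1, j] + gap_extend
            alt_x = Iy[i - 1, j] + gap_open
            if ext_x >= open_x and ext_x >= alt_x:
                Ix[i, j] = ext_x
                tb_x[i, j] = 1
            elif open_x >= alt_x:
                Ix[i, j] = open_x
                tb_x[i, j] = 0
            else:
                Ix[i, j] = alt_x
                tb_x[i, j] = 2
            # Iy: gap in A, consume B[j-1]
            open_y = M[i, j - 1] + gap_open
            ext_y = Iy[i, j - 1] + gap_extend
            alt_y = Ix[i, j - 1] + gap_open
            if ext_y >= open_y and ext_y >= alt_y:
                Iy[i, j] = ext_y
                tb_y[i, j] = 1
            elif open_y >= alt_y:
                Iy[i, j] = open_y
                tb_y[i, j] = 0
            else:
                Iy[i, j] = alt_y
                tb_y[i, j] = 2
    # choose final state (prefer M on ties, then Ix)
    state = 0
    best = M[n, m]
    if Ix[n, m] > best:
        best = Ix[n, m]
        state = 1
    if Iy[n, m] > best:
        state = 2
    moves = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            prev = tb_m[i, j]
            moves[k] = 0
            i -= 1
            j -= 1
        elif state == 1:
            prev = tb_x[i, j]
            moves[k] = 1
            i -= 1
        else:
            prev = tb_y[i, j]
            moves[k] = 2
            j -= 1
        k += 1
        state = prev
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    return moves, k


def _merge_profiles(rows_a: np.ndarray, rows_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Profile-profile global alignment of two blocks of aligned rows."""
    GAP = len(AA_ORDER)  # gap code in integer rows
    pa = _profile(np.where(rows_a == GAP, -1, rows_a))
    pb = _profile(np.where(rows_b == GAP, -1, rows_b))
    S = pa @ _BLOSUM @ pb.T
    moves, k = _gotoh_traceback(S, GAP_OPEN, GAP_EXTEND)
    moves = moves[:k][::-1]
    n_a, n_b = rows_a.shape[0], rows_b.shape[0]
    out_a = np.empty((n_a, k), dtype=rows_a.dtype)
    out_b = np.empty((n_b, k), dtype=rows_b.dtype)
    ia = ib = 0
    for col, mv in enumerate(moves):
        if mv == 0:
            out_a[:, col] = rows_a[:, ia]
            out_b[:, col] = rows_b[:, ib]
            ia += 1
            ib += 1
        elif mv == 1:
            out_a[:, col] = rows_a[:, ia]
            out_b[:, col] = GAP
            ia += 1
        else:
            out_a[:, col] = GAP
            out_b[:, col] = rows_b[:, ib]
            ib += 1
    return out_a, out_b


def _encode(protein: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, _AA_INDEX["X"]) for c in protein], dtype=np.int8)


def _decode(row: np.ndarray) -> str:
    GAP = len(AA_ORDER)
    return "".join("-" if v == GAP else AA_ORDER[v] for v in row)


def align_proteins(
    proteins: dict[str, str], *, aligner_cmd: str | None = None
) -> ProteinAlignment:
    """Multiple-align protein sequences.

    Progressive alignment over a UPGMA guide tree built from 3-mer
    distances; leaves are processed in lexicographic sample order so the
    result is deterministic.  With ``aligner_cmd`` the sequences are
    piped through an external FASTA-to-FASTA aligner instead.
    """
    if not proteins:
        raise ValueError("no sequences to align")
    if any(not s for s in proteins.values()):
        raise ValueError("empty protein sequence")
    if len(proteins) == 1:
        return ProteinAlignment(dict(proteins))
    if aligner_cmd is not None:
        return _run_external_aligner(proteins, aligner_cmd)

    ids = sorted(proteins)
    from scipy.cluster.hierarchy import linkage

    n = len(ids)
    dists = []
    for i in range(n):
        for j in range(i + 1, n):
            dists.append(_kmer_distance(proteins[ids[i]], proteins[ids[j]]))
    Z = linkage(np.array(dists), method="average")  # UPGMA

    # progressive merge following the linkage tree
    blocks: dict[int, tuple[list[str], np.ndarray]] = {
        i: ([ids[i]], _encode(proteins[ids[i]]).reshape(1, -1)) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(Z):
        ids_a, rows_a = blocks.pop(int(a))
        ids_b, rows_b = blocks.pop(int(b))
        out_a, out_b = _merge_profiles(rows_a, rows_b)
        blocks[n + step] = (ids_a + ids_b, np.vstack([out_a, out_b]))
    (_, (merged_ids, merged_rows)), = blocks.items()
    rows = {sid: _decode(merged_rows[i]) for i, sid in enumerate(merged_ids)}
    return ProteinAlignment({sid: rows[sid] for sid in proteins if sid in rows})


def _run_external_aligner(proteins: dict[str, str], cmd: str) -> ProteinAlignment:
    """Run ``cmd <in.fasta>`` (or cmd reading {in} placeholder) -> aligned FASTA on stdout."""
    from Bio import SeqIO

    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        write_fasta(dict(proteins), fin)
        argv = shlex.split(cmd)
        if "{in}" in argv:
            argv = [a if a != "{in}" else str(fin) for a in argv]
        else:
            argv = argv + [str(fin)]
        proc = subprocess.run(argv, capture_output=True, text=True, check=True)
        fout = Path(tmp) / "out.fasta"
        fout.write_text(proc.stdout)
        rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fout), "fasta")}
    if set(rows) != set(proteins):
        raise RuntimeError("external aligner dropped or renamed sequences")
    return ProteinAlignment(rows)


# ---------------------------------------------------------------------------
# Trimming and back-translation
# ---------------------------------------------------------------------------


def trim_columns(
    aln: ProteinAlignment,
    max_gap_frac: float = 0.2,
    min_conservation: float = 0.25,
) -> tuple[ProteinAlignment, list[int]]:
    """Drop poorly aligned columns.

    A column is retained iff its gap fraction is <= ``max_gap_frac`` and
    the modal residue fraction among non-gap cells is >=
    ``min_conservation``.  X never counts toward the modal residue.
    """
    ids = list(aln.rows)
    n = len(ids)
    retained: list[int] = []
    for j in range(aln.column_count):
        col = [aln.rows[sid][j] for sid in ids]
        gaps = col.count("-")
        if gaps / n > max_gap_frac:
            continue
        residues = [c for c in col if c not in ("-", "X")]
        non_gap = n - gaps
        if non_gap == 0:
            continue
        modal = max((residues.count(r) for r in set(residues)), default=0)
        if modal / non_gap < min_conservation:
            continue
        retained.append(j)
    rows = {sid: "".join(aln.rows[sid][j] for j in retained) for sid in ids}
    return ProteinAlignment(rows), retained


def backtranslate(
    aln: ProteinAlignment, retained: list[int], cds: dict[str, str]
) -> CodonAlignment:
    """Map retained protein columns back onto codons of the original CDS.

    The residue at protein column j corresponds to codon j of the CDS
    counting non-gap cells only; a gap residue maps to ``---``.
    """
    out: dict[str, str] = {}
    for sid, prow in aln.rows.items():
        seq = cds[sid]
        if len(seq) % 3 == 0 and seq[-3:] in STOP_CODONS:
            seq = seq[:-3]
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        ungapped = prow.replace("-", "")
        if len(ungapped) != len(codons):
            raise ValueError(
                f"{sid}: protein length {len(ungapped)} != codon count {len(codons)}"
            )
        # codon index consumed at each protein column
        consumed = np.cumsum([c != "-" for c in prow])
        parts: list[str] = []
        for j in retained:
            if prow[j] == "-":
                parts.append("---")
            else:
                parts.append(codons[consumed[j] - 1])
        out[sid] = "".join(parts)
    return CodonAlignment(out, list(retained))


def align_cluster(
    cds: dict[str, str],
    *,
    max_gap_frac: float = 0.2,
    min_conservation: float = 0.25,
    aligner_cmd: str | None = None,
) -> CodonAlignment | None:
    """One alignment round: translate, align, trim, back-translate.

    ``cds`` must already be gap-free and pass ORF checks.  Returns None
    when trimming removes every column (the cluster is unusable).
    """
    proteins: dict[str, str] = {}
    for sid, seq in cds.items():
        status, prot = check_and_translate(seq)
        if not status.ok:
            raise ValueError(f"{sid}: CDS failed ORF check ({status.code})")
        proteins[sid] = prot
    if len(proteins) == 1:
        (sid, prot), = proteins.items()
        aln = ProteinAlignment({sid: prot})
        retained = list(range(len(prot)))
        return backtranslate(aln, retained, cds)
    aln = align_proteins(proteins, aligner_cmd=aligner_cmd)
    _, retained = trim_columns(aln, max_gap_frac, min_conservation)
    if not retained:
        return None
    return backtranslate(aln, retained, cds)
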