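"""Alignment container, reference numbering, and redundancy/fragment filters.

The analyses downstream (conservation profiling, coevolution detection,
signature classification) all operate on a gapped multiple sequence
alignment whose columns can be addressed in the native numbering of a
chosen reference protein (e.g. *E. coli* ArsC, UniProt P08692).  This
module provides that substrate: reading Pfam-style aligned FASTA or
Stockholm files, mapping alignment columns to reference residue numbers,
and the two pre-filters applied before any column statistic is computed —
removal of fragment sequences and of highly similar (>70% identity)
sequences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import PairwiseAligner

logger = logging.getLogger(__name__)

GAP = "-"
_GAP_CHARS = frozenset("-.")


class AlignmentError(ValueError):
    """Raised when an alignment violates its structural invariants."""


@dataclass
class Alignment:
    """A gapped multiple sequence alignment over one alphabet.

    Records are ``(id, gapped_sequence)`` pairs; every gapped sequence has
    the same length (``n_columns``), ids are unique, and the only gap
    character is ``'-'`` (``'.'`` is normalised on read, lowercase residues
    are uppercased — the Pfam dialect).
    """

    records: list[tuple[str, str]]
    alphabet: str = "protein"  # "protein" | "nucleotide"

    def __post_init__(self) -> None:
        if self.alphabet not in ("protein", "nucleotide"):
            raise AlignmentError(f"unknown alphabet {self.alphabet!r}")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) > 1:
            raise AlignmentError(
                f"ragged alignment: row lengths {sorted(lengths)} differ"
            )
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def sequence(self, record_id: str) -> str:
        for i, s in self.records:
            if i == record_id:
                return s
        raise KeyError(f"no record {record_id!r} in alignment")

    def column(self, index: int) -> str:
        """All residue states of one column, top to bottom."""
        if not 0 <= index < self.n_columns:
            raise IndexError(
                f"column {index} out of range [0, {self.n_columns})"
            )
        return "".join(s[index] for _, s in self.records)

    def subset(self, keep_ids: Iterable[str]) -> "Alignment":
        keep = set(keep_ids)
        return Alignment(
            [(i, s) for i, s in self.records if i in keep], self.alphabet
        )

    def to_array(self) -> np.ndarray:
        """(n_sequences, n_columns) array of single characters."""
        return np.array(
            [list(s) for _, s in self.records], dtype="U1"
        ).reshape(self.n_sequences, self.n_columns)


@dataclass
class ReferenceMap:
    """Bidirectional alignment-column <-> reference-residue-number map.

    Houses all "position 12" / "Arg94" style numbering: ``col_to_ref`` is a
    partial mapping from 0-based alignment columns to 1-based (or any
    offset) reference residue numbers; columns where the reference row is
    gapped are absent.  Numbers strictly increase with column index.
    """

    reference_id: str
    col_to_ref: dict[int, int]
    ref_to_col: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ref_to_col:
            self.ref_to_col = {r: c for c, r in self.col_to_ref.items()}
        cols = sorted(self.col_to_ref)
        refs = [self.col_to_ref[c] for c in cols]
        if any(b <= a for a, b in zip(refs, refs[1:])):
            raise AlignmentError(
                "reference numbers must strictly increase with column index"
            )
        for c, r in self.col_to_ref.items():
            if self.ref_to_col.get(r) != c:
                raise AlignmentError("col_to_ref / ref_to_col are not inverse")

    @property
    def span(self) -> tuple[int, int] | None:
        if not self.col_to_ref:
            return None
        refs = self.col_to_ref.values()
        return (min(refs), max(refs))


@dataclass
class IdentityMatrix:
    """Symmetric pairwise identity fractions for a set of sequences."""

    ids: list[str]
    identity: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.identity, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise AlignmentError("identity matrix shape mismatch")
        if not np.allclose(m, m.T):
            raise AlignmentError("identity matrix must be symmetric")
        if m.size and (m.min() < -1e-12 or m.max() > 1 + 1e-12):
            raise AlignmentError("identity entries must lie in [0, 1]")
        self.identity = m


def _normalise(seq: str) -> str:
    return "".join(GAP if ch in _GAP_CHARS else ch.upper() for ch in seq)


def read_alignment(
    path: str | Path, format: str = "fasta", alphabet: str = "protein"
) -> Alignment:
    """Read an aligned FASTA or Stockholm file into an :class:`Alignment`.

    Stockholm annotation lines (``#=GC`` etc.) are ignored except sequence
    rows.  ``'.'`` gaps are normalised to ``'-'`` and residues uppercased.
    """
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {format!r}")
    path = Path(path)
    try:
        if format == "fasta":
            # AlignIO rejects ragged FASTA with an opaque message; parse
            # records ourselves so the invariant error is ours.
            records = [
                (rec.id, _normalise(str(rec.seq)))
                for rec in SeqIO.parse(str(path), "fasta")
            ]
        else:
            msa = AlignIO.read(str(path), "stockholm")
            records = [(rec.id, _normalise(str(rec.seq))) for rec in msa]
    except AlignmentError:
        raise
    except Exception as exc:  # malformed file
        raise AlignmentError(f"cannot parse {path} as {format}: {exc}") from exc
    if not records:
        raise AlignmentError(f"{path}: no sequences found")
    return Alignment(records, alphabet=alphabet)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as aligned FASTA."""
    with open(path, "w") as fh:
        for rid, seq in aln.records:
            fh.write(f">{rid}\n{seq}\n")


def read_fasta_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Read unaligned FASTA sequences (gap characters stripped)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalise(str(rec.seq)).replace(GAP, "")
        out.append((rec.id, seq))
    return out


def build_reference_map(
    aln: Alignment, reference_id: str, first_residue_number: int = 1
) -> ReferenceMap:
    """Number the non-gap columns of the reference row consecutively.

    Column *i* of the alignment maps to the reference residue number of the
    reference-row character at *i*; gapped reference columns are absent
    from the map.
    """
    ref_row = aln.sequence(reference_id)  # KeyError if absent
    col_to_ref: dict[int, int] = {}
    number = first_residue_number
    for col, ch in enumerate(ref_row):
        if ch != GAP:
            col_to_ref[col] = number
            number += 1
    if not col_to_ref:
        logger.warning(
            "reference row %r is all gaps; reference map is empty", reference_id
        )
    return ReferenceMap(reference_id, col_to_ref)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical residues over columns occupied in BOTH rows.

    The denominator is the number of columns where neither sequence is
    gapped — robust to fragments, which is the point of the 70% filter.
    Returns 0.0 when no column is co-occupied.
    """
    if len(a) != len(b):
        raise AlignmentError(
            f"gapped sequences differ in length ({len(a)} vs {len(b)})"
        )
    both = matches = 0
    for x, y in zip(a, b):
        if x != GAP and y != GAP:
            both += 1
            if x == y:
                matches += 1
    return matches / both if both else 0.0


def identity_matrix(aln: Alignment) -> IdentityMatrix:
    """All-pairs :func:`pairwise_identity` over an alignment."""
    n = aln.n_sequences
    arr = aln.to_array()
    occupied = arr != GAP
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            both = occupied[i] & occupied[j]
            denom = int(both.sum())
            ident = float((arr[i][both] == arr[j][both]).sum()) / denom if denom else 0.0
            m[i, j] = m[j, i] = ident
    return IdentityMatrix(aln.ids, m)


def occupancy(gapped_seq: str) -> float:
    """Fraction of alignment columns carrying a residue."""
    if not gapped_seq:
        return 0.0
    return sum(ch != GAP for ch in gapped_seq) / len(gapped_seq)


def remove_fragments(
    aln: Alignment, min_occupancy: float = 0.5
) -> tuple[Alignment, list[tuple[str, str, float]]]:
    """Drop fragment rows (occupancy below ``min_occupancy``).

    Neither Pfam exports nor the filter's description pin down "fragment";
    occupancy against the alignment width is the operational stand-in.
    Returns the filtered alignment plus a removal report of
    ``(id, reason, statistic)`` rows.
    """
    if not aln.records:
        raise AlignmentError("cannot filter an empty alignment")
    kept, report = [], []
    for rid, seq in aln.records:
        occ = occupancy(seq)
        if occ >= min_occupancy:
            kept.append((rid, seq))
        else:
            report.append((rid, "fragment", occ))
    if not kept:
        warnings.warn("remove_fragments removed every sequence", stacklevel=2)
    return Alignment(kept, aln.alphabet), report


def remove_redundant(
    aln: Alignment, max_identity: float = 0.70
) -> tuple[Alignment, list[tuple[str, str, float]]]:
    """Greedy redundancy filter: drop rows >``max_identity`` to a kept row.

    Scans in input order, keeping a record iff its identity to every
    already-kept record is <= ``max_identity``; the output therefore has
    all pairwise identities <= ``max_identity`` and the operation is
    idempotent.  Input order determines survivors.
    """
    if not aln.records:
        raise AlignmentError("cannot filter an empty alignment")
    kept: list[tuple[str, str]] = []
    report = []
    for rid, seq in aln.records:
        offender = None
        for krid, kseq in kept:
            ident = pairwise_identity(seq, kseq)
            if ident > max_identity:
                offender = (krid, ident)
                break
        if offender is None:
            kept.append((rid, seq))
        else:
            report.append((rid, f"redundant_with:{offender[0]}", offender[1]))
    return Alignment(kept, aln.alphabet), report


def _unaligned_aligner(alphabet: str) -> PairwiseAligner:
    """Semi-global aligner for unaligned sequence identity (match-count scoring)."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    # free end gaps on both sides: identity is assessed over the overlap
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def unaligned_identity(a: str, b: str, alphabet: str = "nucleotide") -> float:
    """Identity fraction from a semi-global pairwise alignment.

    Matches divided by aligned (co-occupied) columns; 0.0 if the overlap is
    empty or either sequence is empty.
    """
    if not a or not b:
        return 0.0
    aligner = _unaligned_aligner(alphabet)
    best = aligner.align(a, b)[0]
    matches = cols = 0
    for (ta, tb), (qa, qb) in zip(*best.aligned):
        cols += tb - ta
        matches += sum(x == y for x, y in zip(a[ta:tb], b[qa:qb]))
    return matches / cols if cols else 0.0


def decrease_redundancy(
    seqs: Sequence[tuple[str, str]],
    max_similarity: float = 0.99,
    min_similarity: float = 0.30,
    alphabet: str = "nucleotide",
) -> tuple[list[tuple[str, str]], list[tuple[str, str, float]]]:
    """Thin a set of unaligned sequences by similarity band (99%/30% defaults).

    Greedy keep-scan in input order over ``(id, sequence)`` pairs: a
    sequence is dropped if its best semi-global identity to an
    already-kept sequence exceeds ``max_similarity`` (near-duplicate) or if
    its best identity to ALL kept sequences falls below ``min_similarity``
    (unrelated outlier).  The first sequence is always kept.  Mirrors the
    role the ExPASy Decrease-Redundancy tool plays in phylogeny
    preparation.
    """
    if not seqs:
        raise AlignmentError("decrease_redundancy needs at least one sequence")
    kept: list[tuple[str, str]] = []
    report = []
    for rid, seq in seqs:
        if not kept:
            kept.append((rid, seq))
            continue
        idents = [unaligned_identity(seq, k, alphabet) for _, k in kept]
        best = max(idents)
        if best > max_similarity:
            partner = kept[int(np.argmax(idents))][0]
            report.append((rid, f"too_similar_to:{partner}", best))
        elif best < min_similarity:
            report.append((rid, "dissimilar_outlier", best))
        else:
            kept.append((rid, seq))
    return kept, report
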