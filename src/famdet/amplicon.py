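"""Amplicon translation, reference-coordinate mapping, and logo statistics.

Clone-library amplicons cover a sub-region of the target domain (the
*arsC* amplicons translate to residues 27–116 of *E. coli* ArsC).  This
module translates nucleotide amplicons, finds the reading frame against a
reference peptide, maps each translated peptide onto the reference's
native residue numbering by semi-global alignment, and summarises the
per-position residue distribution with Bayesian 95% credible intervals —
the numbers behind a sequence-logo figure with error bars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from scipy.stats import beta as beta_dist

from .signatures import MappedPeptide

logger = logging.getLogger(__name__)

_CODE = CodonTable.unambiguous_dna_by_id[1]  # the standard genetic code
_STOPS = set(_CODE.stop_codons)


class TranslationError(ValueError):
    """Internal stop codon under the 'error' stop policy."""


@dataclass
class AmpliconRecord:
    """One amplicon with its chosen frame, peptide, and mapped span."""

    id: str
    nucleotide: str
    frame: int
    peptide: str
    mapped_span: tuple[int, int] | None = None
    states: dict[int, str] | None = None  # reference position -> residue

    def as_mapped_peptide(self) -> MappedPeptide:
        if self.states is None:
            raise ValueError(f"amplicon {self.id} is not mapped")
        return MappedPeptide(self.id, self.states, self.mapped_span)


@dataclass
class LogoMatrix:
    """Per-reference-position residue frequencies with credible intervals.

    ``columns[pos]`` maps residue -> (frequency, ci_low, ci_high);
    ``coverage[pos]`` is the number of peptides carrying a residue there.
    """

    columns: dict[int, dict[str, tuple[float, float, float]]]
    coverage: dict[int, int]
    confidence: float = 0.95


def translate(nt: str, frame: int = 0, stop_policy: str = "truncate") -> str:
    """Translate a nucleotide string in one frame, standard genetic code.

    Codons containing N become 'X' (never resolved, even when synonymous);
    an internal stop truncates the peptide (``truncate``) or raises a
    :class:`TranslationError` naming the codon index (``error``).
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    if stop_policy not in ("error", "truncate"):
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    nt = nt.upper().replace("U", "T")
    if len(nt) < frame + 3:
        raise ValueError("sequence shorter than one codon in this frame")
    bad = set(nt) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in nucleotide sequence: {sorted(bad)}")
    peptide = []
    for i in range(frame, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            peptide.append("X")
        elif codon in _STOPS:
            if stop_policy == "error":
                raise TranslationError(
                    f"stop codon {codon} at codon index {(i - frame) // 3}"
                )
            break
        else:
            peptide.append(_CODE.forward_table[codon])
    return "".join(peptide)


def _peptide_aligner() -> PairwiseAligner:
    """Semi-global peptide aligner: free end gaps on the amplicon side."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # the peptide (query) is a sub-region of the reference (target):
    # end gaps in the peptide row cost nothing
    aligner.end_deletion_score = 0.0
    return aligner


def best_frame(nt: str, reference_peptide: str) -> tuple[int, float]:
    """Reading frame whose translation best aligns to the reference.

    Scores each frame's (stop-truncated) translation by semi-global
    alignment against the reference peptide; ties break toward the lower
    frame.  Raises if every frame translates to an empty peptide.
    """
    if len(nt) < 3:
        raise ValueError("sequence shorter than one codon")
    aligner = _peptide_aligner()
    best: tuple[int, float] | None = None
    for frame in (0, 1, 2):
        if len(nt) < frame + 3:
            continue
        pep = translate(nt, frame, stop_policy="truncate")
        if not pep:
            continue
        score = float(aligner.align(reference_peptide, pep).score)
        if best is None or score > best[1]:
            best = (frame, score)
    if best is None:
        raise TranslationError("every reading frame is stop-only or empty")
    return best


def map_peptide_to_reference(
    peptide: str,
    reference_peptide: str,
    reference_numbering_start: int = 1,
    min_score: float | None = 0.0,
) -> tuple[tuple[int, int] | None, dict[int, str]]:
    """Assign reference residue numbers to a peptide by semi-global alignment.

    Each aligned peptide residue inherits the number of the reference
    residue it sits on (1-based by default, so residue *i* of the
    reference is position ``reference_numbering_start + i``).  Returns the
    (min, max) span of assigned numbers and the per-position residue
    states; deleted reference positions inside the span simply have no
    state.  An alignment scoring below ``min_score`` is declared
    unmappable: span None, empty states.
    """
    if not peptide or not reference_peptide:
        raise ValueError("peptide and reference must be non-empty")
    aligner = _peptide_aligner()
    best = aligner.align(reference_peptide, peptide)[0]
    if min_score is not None and best.score < min_score:
        logger.warning("peptide unmappable (score %.1f < %.1f)", best.score, min_score)
        return None, {}
    states: dict[int, str] = {}
    for (ta, tb), (qa, qb) in zip(*best.aligned):
        for offset in range(tb - ta):
            ref_pos = int(reference_numbering_start + ta + offset)
            states[ref_pos] = peptide[qa + offset]
    if not states:
        return None, {}
    span = (min(states), max(states))
    return span, states


def map_amplicon(
    record_id: str,
    nt: str,
    reference_peptide: str,
    reference_numbering_start: int = 1,
    frame: int | None = None,
    min_score: float | None = 0.0,
) -> AmpliconRecord:
    """Translate one amplicon (auto-selecting the frame unless forced) and map it."""
    if frame is None:
        frame, _ = best_frame(nt, reference_peptide)
    peptide = translate(nt, frame, stop_policy="truncate")
    span, states = (None, {})
    if peptide:
        span, states = map_peptide_to_reference(
            peptide, reference_peptide, reference_numbering_start, min_score
        )
    return AmpliconRecord(record_id, nt, frame, peptide, span, states)


def jeffreys_interval(count: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Equal-tailed Beta(count+1/2, n-count+1/2) credible interval.

    The Jeffreys-prior posterior for a binomial proportion; boundary
    convention ci_low=0 at count=0 and ci_high=1 at count=n keeps the
    interval containing the point estimate.
    """
    if not 0 <= count <= n:
        raise ValueError("need 0 <= count <= n")
    alpha = 1.0 - confidence
    lo = 0.0 if count == 0 else float(beta_dist.ppf(alpha / 2, count + 0.5, n - count + 0.5))
    hi = 1.0 if count == n else float(beta_dist.ppf(1 - alpha / 2, count + 0.5, n - count + 0.5))
    return lo, hi


def residue_distribution(
    mapped_peptides: list[MappedPeptide],
    positions: list[int],
    confidence: float = 0.95,
) -> LogoMatrix:
    """Per-position residue frequencies among covering peptides, with CIs.

    A peptide contributes to a position iff it carries a residue state
    there (a deletion does not).  Positions covered by no peptide are
    emitted with coverage 0 and an empty distribution.
    """
    if not any(
        pep.states.get(pos) for pep in mapped_peptides for pos in positions
    ):
        raise ValueError("no peptide covers any requested position")
    columns: dict[int, dict[str, tuple[float, float, float]]] = {}
    coverage: dict[int, int] = {}
    for pos in positions:
        residues = [
            pep.states[pos] for pep in mapped_peptides if pos in pep.states
        ]
        n = len(residues)
        coverage[pos] = n
        col: dict[str, tuple[float, float, float]] = {}
        for res in sorted(set(residues)):
            count = residues.count(res)
            freq = count / n
            lo, hi = jeffreys_interval(count, n, confidence)
            col[res] = (freq, lo, hi)
        columns[pos] = col
    return LogoMatrix(columns, coverage, confidence)
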