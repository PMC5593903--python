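"""Per-column residue frequency profiles and highly conserved positions.

Conservation here is plain modal-residue frequency — a column is "highly
conserved" when its most frequent residue exceeds a threshold (>80% in the
ArsC/AioA analyses).  Frequencies are fractions of ALL sequences, gapped
rows included in the denominator: a residue absent from half the family
(e.g. the catalytic Cys present in only 54% of ArsC-domain sequences)
reads as not conserved, which is the family-wide prevalence reading the
analysis relies on.  Degenerate codes (B, Z, X) count as their own
symbols.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .alignment import GAP, Alignment, ReferenceMap


@dataclass
class ConservationProfile:
    """Residue frequencies per column, gap fraction reported separately."""

    frequencies: list[dict[str, float]]  # per column, residue -> fraction
    gap_fractions: list[float]
    n_sequences: int

    @property
    def n_columns(self) -> int:
        return len(self.frequencies)

    def top_residue(self, column: int) -> tuple[str, float] | None:
        """Modal residue of a column, or None for an all-gap column."""
        freqs = self.frequencies[column]
        if not freqs:
            return None
        # deterministic tie-break: higher frequency, then alphabetical
        residue = min(freqs, key=lambda r: (-freqs[r], r))
        return residue, freqs[residue]


def column_frequencies(
    aln: Alignment, column: int, ignore_gaps: bool = False
) -> dict[str, float]:
    """Residue -> fraction map for one column.

    By default the denominator is the full number of sequences (gap state
    excluded from the map but counted in the denominator); with
    ``ignore_gaps`` the denominator is the occupied rows only.
    """
    states = aln.column(column)  # IndexError if out of range
    counts = Counter(ch for ch in states if ch != GAP)
    denom = (
        sum(counts.values()) if ignore_gaps else aln.n_sequences
    )
    if denom == 0:
        return {}
    return {r: c / denom for r, c in sorted(counts.items())}


def conservation_profile(
    aln: Alignment, ignore_gaps: bool = False
) -> ConservationProfile:
    """Full per-column frequency profile of an alignment."""
    freqs, gaps = [], []
    n = aln.n_sequences
    for col in range(aln.n_columns):
        states = aln.column(col)
        n_gap = states.count(GAP)
        freqs.append(column_frequencies(aln, col, ignore_gaps=ignore_gaps))
        gaps.append(n_gap / n if n else 0.0)
    return ConservationProfile(freqs, gaps, n)


def conserved_positions(
    aln: Alignment,
    refmap: ReferenceMap,
    threshold: float = 0.80,
    ignore_gaps: bool = False,
) -> list[tuple[int, str, float]]:
    """Columns whose top residue frequency strictly exceeds ``threshold``.

    Reported as ``(reference_position, residue, frequency)`` in reference
    numbering, sorted by reference position; columns outside the reference
    map (gapped in the reference row) are not reportable and are skipped.
    A column at exactly the threshold is NOT reported (strict ``>``).
    """
    profile = conservation_profile(aln, ignore_gaps=ignore_gaps)
    out = []
    for col, ref_pos in sorted(refmap.col_to_ref.items(), key=lambda kv: kv[1]):
        top = profile.top_residue(col)
        if top is None:
            continue
        residue, freq = top
        if freq > threshold:
            out.append((ref_pos, residue, freq))
    return out
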