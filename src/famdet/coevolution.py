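"""Correlated residue-pair detection and coevolved-set assembly.

A residue *event* is a (column, residue) occurrence; two events at
distinct columns are *correlated* when the presence of one raises the
frequency of the other by more than 80% (relative), the association is
supported by a one-sided Fisher exact test at p < 1e-10, and both events
are carried by at least 20% of the sequences.  Correlated pairs are then
assembled into *coevolved sets* — connected components of the pair graph —
which act as subfamily signatures (e.g. the four ArsC-domain sets).

The frequency-increase rule is relative by default: ``f(b|a) > (1 +
min_increase) * f(b)``.  An absolute reading (``f(b|a) - f(b) >
min_increase``) is unsatisfiable for backgrounds above
``min_presence/(1+min_increase)`` under the 20% presence floor, but is
available via ``increase_mode="absolute"`` for comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
from scipy.stats import hypergeom

from .alignment import GAP, Alignment, ReferenceMap


class InvalidPairError(ValueError):
    """Raised when pair statistics are requested for one and the same column."""


@dataclass(frozen=True)
class ResidueEvent:
    """A specific residue at a specific alignment column."""

    column: int
    residue: str
    count: int
    fraction: float
    reference_position: int | None = None

    def label(self) -> str:
        pos = self.reference_position if self.reference_position is not None else f"col{self.column}"
        return f"{self.residue}{pos}"


@dataclass
class CorrelatedPair:
    """Association statistics between two residue events.

    ``relative_increase_ab`` is ``f(b|a)/f(b) - 1`` (how much observing
    *a* raises the frequency of *b*); ``direction`` records which
    direction(s) passed the acceptance rule.
    """

    event_a: ResidueEvent
    event_b: ResidueEvent
    f_a: float
    f_b: float
    f_b_given_a: float
    f_a_given_b: float
    relative_increase_ab: float
    relative_increase_ba: float
    p_value: float
    direction: str = "none"  # "a->b" | "b->a" | "both" | "none"


@dataclass
class CoevolvedSet:
    """One connected component of the correlated-pair graph (>= 2 events)."""

    events: list[ResidueEvent]
    supporting_pairs: list[CorrelatedPair] = field(default_factory=list)

    def labels(self) -> list[str]:
        return [e.label() for e in self.events]


def _row_mask(aln: Alignment, column: int, residue: str) -> list[bool]:
    return [s[column] == residue for _, s in aln.records]


def event_catalog(
    aln: Alignment,
    min_presence: float = 0.20,
    refmap: ReferenceMap | None = None,
) -> list[ResidueEvent]:
    """All (column, residue) events at fraction >= ``min_presence``.

    Gap states are never events.  Fractions are over all sequences.
    Events are ordered by (column, residue).
    """
    if not aln.records:
        raise ValueError("event_catalog needs a non-empty alignment")
    n = aln.n_sequences
    events = []
    for col in range(aln.n_columns):
        states = aln.column(col)
        for residue in sorted(set(states) - {GAP}):
            count = states.count(residue)
            frac = count / n
            if frac >= min_presence:
                ref = refmap.col_to_ref.get(col) if refmap else None
                events.append(ResidueEvent(col, residue, count, frac, ref))
    return events


def fisher_upper_tail(k11: int, count_a: int, count_b: int, n: int) -> float:
    """One-sided Fisher exact p (enrichment): P[X >= k11], X hypergeometric.

    X counts co-occurrences when ``count_b`` rows are drawn among ``n``
    with ``count_a`` marked; this is the upper tail of the 2x2 presence
    table of the two events.
    """
    return float(hypergeom.sf(k11 - 1, n, count_a, count_b))


def pair_statistics(
    aln: Alignment, a: ResidueEvent, b: ResidueEvent
) -> CorrelatedPair:
    """Conditional frequencies, relative increases and Fisher p for a pair."""
    if a.column == b.column:
        raise InvalidPairError(
            f"events at the same column {a.column} are mutually exclusive"
        )
    mask_a = _row_mask(aln, a.column, a.residue)
    mask_b = _row_mask(aln, b.column, b.residue)
    n = aln.n_sequences
    k_a = sum(mask_a)
    k_b = sum(mask_b)
    k_ab = sum(x and y for x, y in zip(mask_a, mask_b))
    f_a, f_b = k_a / n, k_b / n
    f_b_given_a = k_ab / k_a if k_a else 0.0
    f_a_given_b = k_ab / k_b if k_b else 0.0
    inc_ab = f_b_given_a / f_b - 1.0 if f_b else 0.0
    inc_ba = f_a_given_b / f_a - 1.0 if f_a else 0.0
    p = fisher_upper_tail(k_ab, k_a, k_b, n)
    return CorrelatedPair(
        a, b, f_a, f_b, f_b_given_a, f_a_given_b, inc_ab, inc_ba, p
    )


def _passes(
    pair: CorrelatedPair,
    min_increase: float,
    max_p: float,
    increase_mode: str,
) -> str:
    """Direction string if the acceptance rule holds, else 'none'."""
    if not pair.p_value < max_p:
        return "none"
    if increase_mode == "relative":
        ab = pair.relative_increase_ab > min_increase
        ba = pair.relative_increase_ba > min_increase
    elif increase_mode == "absolute":
        ab = (pair.f_b_given_a - pair.f_b) > min_increase
        ba = (pair.f_a_given_b - pair.f_a) > min_increase
    else:
        raise ValueError(f"unknown increase_mode {increase_mode!r}")
    if ab and ba:
        return "both"
    if ab:
        return "a->b"
    if ba:
        return "b->a"
    return "none"


def detect_correlated_pairs(
    aln: Alignment,
    min_presence: float = 0.20,
    min_increase: float = 0.80,
    max_p: float = 1e-10,
    refmap: ReferenceMap | None = None,
    increase_mode: str = "relative",
    require_both_directions: bool = False,
) -> list[CorrelatedPair]:
    """Scan all distinct-column event pairs and keep those passing the rule.

    A pair is reported when both events sit at >= ``min_presence``
    fraction, the frequency increase exceeds ``min_increase`` in at least
    one direction (both, if ``require_both_directions``), and the Fisher
    exact p-value is < ``max_p``.  Output order is deterministic:
    (column_a, residue_a, column_b, residue_b) lexicographic.
    """
    if aln.n_columns < 2:
        raise ValueError("need an alignment with at least 2 columns")
    events = event_catalog(aln, min_presence=min_presence, refmap=refmap)
    out = []
    for a, b in itertools.combinations(events, 2):
        if a.column == b.column:
            continue
        pair = pair_statistics(aln, a, b)
        direction = _passes(pair, min_increase, max_p, increase_mode)
        if direction == "none":
            continue
        if require_both_directions and direction != "both":
            continue
        pair.direction = direction
        out.append(pair)
    return out


def assemble_sets(
    pairs: list[CorrelatedPair], mode: str = "component"
) -> list[CoevolvedSet]:
    """Group correlated pairs into coevolved sets.

    ``component`` (default): connected components of the event graph —
    members of one set need not all be pairwise supported, matching how
    set members are reported jointly.  ``clique``: maximal cliques, the
    stricter alternative.  Singleton events are never emitted.
    """
    graph: nx.Graph = nx.Graph()
    pair_index: dict[frozenset, CorrelatedPair] = {}
    for p in pairs:
        graph.add_edge(p.event_a, p.event_b)
        pair_index[frozenset((p.event_a, p.event_b))] = p
    if mode == "component":
        groups = list(nx.connected_components(graph))
    elif mode == "clique":
        groups = [set(c) for c in nx.find_cliques(graph) if len(c) >= 2]
    else:
        raise ValueError(f"unknown set mode {mode!r}")
    sets = []
    for grp in groups:
        if len(grp) < 2:
            continue
        events = sorted(grp, key=lambda e: (e.column, e.residue))
        support = [
            pair_index[frozenset(pr)]
            for pr in itertools.combinations(events, 2)
            if frozenset(pr) in pair_index
        ]
        sets.append(CoevolvedSet(events, support))
    sets.sort(key=lambda s: (s.events[0].column, s.events[0].residue))
    return sets
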