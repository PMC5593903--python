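"""Residue signatures and subfamily classification.

A signature is a named set of required (and optionally forbidden) residue
events in reference numbering — e.g. the ArsC-domain coevolved set 1
{Arg60, Arg107, Pro108} or the conserved triplet {Arg94, Pro95,
Cys/Gly106}.  Classifying a mapped peptide against a signature yields
``present`` / ``absent`` / ``not_assessable``, the last when a required
position falls outside the peptide's mapped span (amplicons cover only a
sub-region of the domain, so e.g. position 12 is not assessable from a
27–116 amplicon).

The shipped signature tables encode the ArsC-domain sets (sets 1 and 2
required for arsenic resistance; set 3 shared with Spx regulators; set 4
characteristic of the paralogs YffB/YusI) and the 13 conserved
molybdopterin-domain positions.  Position 106 is a two-state discriminator:
Cys106 is the reductase state, Gly106 the Spx state, so the ``conserved``
signature accepts C or G while ``spx_like`` demands G and forbids set 1.
Signatures are data (TSV), not code, so other families can be encoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

_STATUS = ("present", "absent", "not_assessable")


@dataclass
class Signature:
    """Named required/forbidden residue-event sets in reference numbering."""

    name: str
    required_events: list[tuple[int, frozenset[str]]]
    forbidden_events: list[tuple[int, frozenset[str]]] = field(default_factory=list)
    min_required_fraction: float = 1.0

    def __post_init__(self) -> None:
        for pos, allowed in self.required_events + self.forbidden_events:
            if not allowed:
                raise ValueError(
                    f"signature {self.name}: empty residue set at position {pos}"
                )

    @property
    def positions(self) -> set[int]:
        return {p for p, _ in self.required_events} | {
            p for p, _ in self.forbidden_events
        }


@dataclass
class MappedPeptide:
    """A peptide addressable by reference position over a mapped span."""

    id: str
    states: dict[int, str]  # reference position -> residue
    span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.span is None and self.states:
            self.span = (min(self.states), max(self.states))

    def covers(self, position: int) -> bool:
        return self.span is not None and self.span[0] <= position <= self.span[1]


@dataclass
class ClassificationReport:
    """Per-sequence signature statuses and aggregate presence fractions."""

    statuses: dict[str, dict[str, str]]  # seq id -> signature name -> status
    aggregate: dict[str, float]  # signature name -> fraction present among assessable
    n_assessable: dict[str, int]


def parse_signature_tsv(path: str | Path) -> list[Signature]:
    """Load signatures from TSV (signature_name, ref_position, allowed_residues, kind)."""
    rows: dict[str, dict[str, list]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            name, pos, residues, kind = parts
            if kind not in ("required", "forbidden"):
                raise ValueError(f"{path}:{lineno}: unknown kind {kind!r}")
            if name not in rows:
                rows[name] = {"required": [], "forbidden": []}
                order.append(name)
            rows[name][kind].append((int(pos), frozenset(residues.upper())))
    return [
        Signature(name, rows[name]["required"], rows[name]["forbidden"])
        for name in order
    ]


def builtin_signatures(family: str) -> list[Signature]:
    """Shipped signature tables for the supported families.

    ``arsC``: conserved {R94, P95, C/G106}, coevolved sets 1–4, and the
    Spx discriminator (G106 without set 1).  ``aioA``: the 13 conserved
    molybdopterin-domain positions.
    """
    files = {"arsc": "signatures_arsc.tsv", "aioa": "signatures_aioa.tsv"}
    key = family.lower()
    if key not in files:
        raise KeyError(
            f"unknown family {family!r}; supported: {sorted(files)}"
        )
    ref = resources.files("famdet.data").joinpath(files[key])
    with resources.as_file(ref) as path:
        return parse_signature_tsv(path)


def score_sequence(peptide: MappedPeptide, sig: Signature) -> str:
    """Classify one mapped peptide against one signature.

    ``not_assessable`` if any required position lies outside the mapped
    span; otherwise ``present`` iff every required position carries an
    allowed residue and no forbidden event (within span) matches.
    """
    for pos, _ in sig.required_events:
        if not peptide.covers(pos):
            return "not_assessable"
    for pos, allowed in sig.required_events:
        if peptide.states.get(pos) not in allowed:
            return "absent"
    for pos, disallowed in sig.forbidden_events:
        if peptide.covers(pos) and peptide.states.get(pos) in disallowed:
            return "absent"
    return "present"


def classify(
    peptides: list[MappedPeptide], sigs: list[Signature]
) -> ClassificationReport:
    """Classify a set of mapped peptides against a set of signatures.

    Aggregate fractions are taken over assessable sequences only and are
    invariant under permutation of the input.
    """
    if not peptides:
        raise ValueError("classify needs at least one peptide")
    if not sigs:
        raise ValueError("classify needs at least one signature")
    statuses: dict[str, dict[str, str]] = {}
    for pep in peptides:
        statuses[pep.id] = {sig.name: score_sequence(pep, sig) for sig in sigs}
    aggregate, n_assessable = {}, {}
    for sig in sigs:
        calls = [statuses[p.id][sig.name] for p in peptides]
        assessable = [c for c in calls if c != "not_assessable"]
        n_assessable[sig.name] = len(assessable)
        aggregate[sig.name] = (
            assessable.count("present") / len(assessable) if assessable else float("nan")
        )
    return ClassificationReport(statuses, aggregate, n_assessable)
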