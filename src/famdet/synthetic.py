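"""Synthetic families, amplicons and clone libraries with known truth.

Every analysis stage in this package is testable without external
downloads because its inputs can be generated with planted structure: a
protein family composed of functional subfamilies carrying
subfamily-specific residue sets on a shared background (the mechanism —
divergent evolution within one family — that produces coevolved sets),
family-wide conserved columns, gap and fragment contamination, amplicons
covering a sub-region of a reference, and clone libraries with a chosen
OTU abundance distribution.

All generators are pure functions of (spec, seed).  Sequences are drawn
independently — there is no tree-based (phylogenetically correlated)
simulation, mirroring the independence assumption of the column
statistics themselves; see the methods note for what that does and does
not exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import GAP, Alignment

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

# Rounded database amino-acid background ("natural" preset); uniform is the
# default because it maximises the sharpness of planted-signal tests.
NATURAL_FREQUENCIES = {
    "A": 0.083, "C": 0.014, "D": 0.055, "E": 0.067, "F": 0.039,
    "G": 0.071, "H": 0.023, "I": 0.059, "K": 0.058, "L": 0.097,
    "M": 0.024, "N": 0.041, "P": 0.047, "Q": 0.039, "R": 0.055,
    "S": 0.066, "T": 0.053, "V": 0.069, "W": 0.011, "Y": 0.029,
}

# Codons per amino acid, standard code (for reverse translation).
_CODONS: dict[str, list[str]] = {}
_BASES = "TCAG"
_TABLE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _aa in enumerate(_TABLE):
    _codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
    if _aa != "*":
        _CODONS.setdefault(_aa, []).append(_codon)


class SpecError(ValueError):
    """Raised for an infeasible or inconsistent generator specification."""


@dataclass
class FamilySpec:
    """Recipe for a synthetic protein family with planted structure.

    ``subfamilies`` is a list of ``(label, proportion, planted_event_sets)``
    where each planted set is a list of ``(column, residue)`` events every
    member of the subfamily carries (up to ``noise``, the per-event flip
    probability).  ``conserved_columns`` are family-wide
    ``(column, residue, target_frequency)`` plantings.  ``fragment_rate``
    appends extra fragment rows (low occupancy) beyond ``n_sequences`` so
    the planted fractions of the core family are untouched.
    """

    n_sequences: int
    n_columns: int
    subfamilies: list[tuple[str, float, list[list[tuple[int, str]]]]] = field(
        default_factory=list
    )
    conserved_columns: list[tuple[int, str, float]] = field(default_factory=list)
    background: dict[str, float] | None = None  # None = uniform over 20 aa
    gap_rate: float = 0.0
    fragment_rate: float = 0.0
    noise: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_sequences < 1 or self.n_columns < 1:
            raise SpecError("need at least one sequence and one column")
        if self.subfamilies:
            total = sum(p for _, p, _ in self.subfamilies)
            if abs(total - 1.0) > 1e-9:
                raise SpecError(f"subfamily proportions sum to {total}, not 1")
        planted_cols = set()
        for label, _, sets in self.subfamilies:
            seen: dict[int, str] = {}
            for event_set in sets:
                for col, res in event_set:
                    if not 0 <= col < self.n_columns:
                        raise SpecError(f"planted column {col} out of range")
                    if seen.get(col, res) != res:
                        raise SpecError(
                            f"subfamily {label!r} plants two residues at column {col}"
                        )
                    seen[col] = res
                    planted_cols.add(col)
        for col, _, target in self.conserved_columns:
            if not 0 <= col < self.n_columns:
                raise SpecError(f"conserved column {col} out of range")
            if not 0.0 <= target <= 1.0:
                raise SpecError("conserved target frequency must be in [0, 1]")
            if col in planted_cols:
                raise SpecError(
                    f"column {col} is both conserved and subfamily-planted"
                )
        for rate in (self.gap_rate, self.fragment_rate, self.noise):
            if not 0.0 <= rate < 1.0:
                raise SpecError("rates must lie in [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth accompanying a generated dataset."""

    subfamily_of: dict[str, str] = field(default_factory=dict)
    planted_sets: dict[str, list[list[tuple[int, str]]]] = field(default_factory=dict)
    conserved: list[tuple[int, str, float]] = field(default_factory=list)
    fragment_ids: list[str] = field(default_factory=list)
    spans: dict[str, tuple[int, int]] = field(default_factory=dict)
    frames: dict[str, int] = field(default_factory=dict)
    otu_of: dict[str, str] = field(default_factory=dict)


def _background_sampler(spec: FamilySpec, rng: np.random.Generator):
    if spec.background is None:
        symbols = np.array(list(AMINO_ACIDS))
        probs = None
    else:
        symbols = np.array(sorted(spec.background))
        probs = np.array([spec.background[s] for s in symbols])
        probs = probs / probs.sum()

    def draw(size):
        return rng.choice(symbols, size=size, p=probs)

    return draw


def generate_family(spec: FamilySpec) -> tuple[Alignment, TruthRecord]:
    """Generate an alignment with planted subfamily and conservation structure.

    Subfamily sizes are deterministic (largest-remainder rounding of the
    proportions), so planted event fractions are exact at zero noise.
    Conserved columns hit ``round(target * N)`` rows exactly.  Planted and
    conserved residues are *reserved* at their columns: rows not
    designated to carry them never draw them from the background, so the
    truth record describes the generated data exactly.  Gaps are sprinkled
    i.i.d. at ``gap_rate`` over background cells only, never over planted
    cells.  Fragment rows (random windows covering ~30% of columns) are
    appended beyond the core family and recorded in truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_sequences, spec.n_columns
    draw = _background_sampler(spec, rng)
    grid = draw((n, m)).astype("U1")

    # reserved residues per column (planted or conserved): background cells
    # at those columns are redrawn until they avoid them
    reserved: dict[int, set[str]] = {}
    for _, _, sets in spec.subfamilies:
        for event_set in sets:
            for col, res in event_set:
                reserved.setdefault(col, set()).add(res)
    for col, res, _ in spec.conserved_columns:
        reserved.setdefault(col, set()).add(res)
    for col, residues in reserved.items():
        support = set(AMINO_ACIDS if spec.background is None else spec.background)
        if support <= residues:
            raise SpecError(
                f"column {col}: background has no residue outside the reserved set"
            )
        for row in range(n):
            while grid[row, col] in residues:
                grid[row, col] = draw(1)[0]

    if spec.gap_rate > 0:
        gap_mask = rng.random((n, m)) < spec.gap_rate
        grid[gap_mask] = GAP

    truth = TruthRecord(conserved=list(spec.conserved_columns))
    ids = [f"seq{i:05d}" for i in range(n)]

    # subfamily membership: contiguous blocks by largest-remainder counts,
    # then the row order is shuffled at the end for realism
    labels = ["background"] * n
    if spec.subfamilies:
        raw = [p * n for _, p, _ in spec.subfamilies]
        counts = [int(np.floor(x)) for x in raw]
        remainders = np.argsort([c - x for c, x in zip(counts, raw)])
        for idx in remainders[: n - sum(counts)]:
            counts[idx] += 1
        start = 0
        for (label, _, sets), size in zip(spec.subfamilies, counts):
            for row in range(start, start + size):
                labels[row] = label
                for event_set in sets:
                    for col, res in event_set:
                        if spec.noise > 0 and rng.random() < spec.noise:
                            continue
                        grid[row, col] = res
            truth.planted_sets[label] = sets
            start += size

    for col, res, target in spec.conserved_columns:
        k = int(round(target * n))
        rows = rng.permutation(n)[:k]
        grid[rows, col] = res

    order = rng.permutation(n)
    records = [(ids[i], "".join(grid[i])) for i in order]
    truth.subfamily_of = {ids[i]: labels[i] for i in range(n)}

    if spec.fragment_rate > 0:
        n_frag = int(round(spec.fragment_rate * n))
        width = max(1, int(0.3 * m))
        for j in range(n_frag):
            start_col = int(rng.integers(0, m - width + 1))
            body = "".join(draw(width))
            seq = GAP * start_col + body + GAP * (m - start_col - width)
            fid = f"frag{j:04d}"
            records.append((fid, seq))
            truth.fragment_ids.append(fid)
            truth.subfamily_of[fid] = "fragment"

    return Alignment(records, alphabet="protein"), truth


def random_peptide(length: int, seed: int = 0) -> str:
    """Uniform-random peptide (synthetic stand-in for a real reference)."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def arsc_like_reference(seed: int = 7, length: int = 141) -> str:
    """Synthetic ArsC-like reference peptide (NOT the real P08692 sequence).

    A random peptide of the ArsC domain's length carrying the signature
    residues at their reference positions (H8, N9, C12, S15, I22, R60,
    R94, P95, C106, R107, P108), so signature and mapping logic can be
    exercised in reference coordinates.
    """
    pep = list(random_peptide(length, seed))
    for pos, res in {
        8: "H", 9: "N", 12: "C", 15: "S", 22: "I",
        60: "R", 94: "R", 95: "P", 106: "C", 107: "R", 108: "P",
    }.items():
        pep[pos - 1] = res
    return "".join(pep)


def reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    """Random synonymous codon choice for each residue (standard code)."""
    codons = []
    for aa in peptide:
        if aa not in _CODONS:
            raise SpecError(f"cannot reverse-translate residue {aa!r}")
        choices = _CODONS[aa]
        codons.append(choices[int(rng.integers(len(choices)))])
    return "".join(codons)


def generate_amplicons(
    reference_peptide: str,
    region: tuple[int, int],
    n: int,
    substitution_rate: float = 0.0,
    seed: int = 0,
    flank_left: int = 0,
    flank_right: int = 0,
    numbering_start: int = 1,
) -> tuple[list[tuple[str, str]], TruthRecord]:
    """Simulate nucleotide amplicons covering ``region`` of the reference.

    ``region`` is inclusive in reference numbering (``numbering_start``
    based).  Each amplicon reverse-translates the region with random
    synonymous codons, applies i.i.d. substitutions at
    ``substitution_rate``, and prepends/appends random flanking bases.
    Truth records the true span and reading frame (``flank_left mod 3``).
    """
    start, end = region
    lo = numbering_start
    hi = numbering_start + len(reference_peptide) - 1
    if not (lo <= start <= end <= hi):
        raise SpecError(f"region {region} outside reference numbering [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    segment = reference_peptide[start - numbering_start : end - numbering_start + 1]
    records = []
    truth = TruthRecord()
    for i in range(n):
        nt = list(reverse_translate(segment, rng))
        if substitution_rate > 0:
            for pos in range(len(nt)):
                if rng.random() < substitution_rate:
                    nt[pos] = NUCLEOTIDES[int(rng.integers(4))]
        left = "".join(rng.choice(list(NUCLEOTIDES), size=flank_left))
        right = "".join(rng.choice(list(NUCLEOTIDES), size=flank_right))
        rid = f"amp{i:04d}"
        records.append((rid, left + "".join(nt) + right))
        truth.spans[rid] = (start, end)
        truth.frames[rid] = flank_left % 3
    return records, truth


def random_nucleotide(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=length))


def _mutate(seq: str, n_sites: int, rng: np.random.Generator) -> str:
    """Substitute exactly ``n_sites`` distinct positions (never to the same base)."""
    out = list(seq)
    sites = rng.permutation(len(seq))[:n_sites]
    for pos in sites:
        current = out[pos]
        alternatives = [b for b in NUCLEOTIDES if b != current]
        out[pos] = alternatives[int(rng.integers(3))]
    return "".join(out)


def generate_clone_library(
    otu_abundances: list[int],
    within_otu_distance: float = 0.01,
    between_otu_distance: float = 0.10,
    seed: int = 0,
    length: int = 300,
) -> tuple[list[tuple[str, str]], TruthRecord]:
    """Simulate a clone library with a known OTU abundance distribution.

    Each OTU has a centroid derived from a common base sequence by
    substituting ``round(between/2 * length)`` sites, so centroid-centroid
    distances concentrate near ``between_otu_distance``; members
    substitute ``round(within/2 * length)`` sites from their centroid,
    so within-OTU pairwise distances stay near ``within_otu_distance``.
    Substitution-only mutation keeps alignment distances equal to Hamming
    distances.
    """
    if not otu_abundances or any(a < 1 for a in otu_abundances):
        raise SpecError("otu_abundances must be positive integers")
    if not 0.0 <= within_otu_distance < between_otu_distance <= 1.0:
        raise SpecError(
            "need 0 <= within_otu_distance < between_otu_distance <= 1"
        )
    rng = np.random.default_rng(seed)
    base = random_nucleotide(length, rng)
    k_between = max(1, int(round(between_otu_distance / 2 * length)))
    k_within = int(round(within_otu_distance / 2 * length))
    records = []
    truth = TruthRecord()
    for o, abundance in enumerate(otu_abundances):
        centroid = _mutate(base, k_between, rng)
        label = f"otu{o:03d}"
        for j in range(abundance):
            rid = f"{label}_clone{j:03d}"
            records.append((rid, _mutate(centroid, k_within, rng)))
            truth.otu_of[rid] = label
    return records, truth
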