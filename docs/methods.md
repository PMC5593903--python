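# Methods

## Scope and data model

`famdet` analyses a gapped protein multiple sequence alignment (aligned
FASTA or Stockholm; `.` gaps normalised to `-`, residues uppercased) whose
columns are addressed in the native numbering of a chosen reference row.
The reference map numbers the non-gap columns of the reference row
consecutively from a configurable first residue number (1-based by
default); columns gapped in the reference are unaddressable and excluded
from position-level reports. Inserting all-gap columns shifts column
indices but never the reference-number sequence.

## Pre-filters

Two filters precede any column statistic:

- **Fragments** — rows occupying fewer than 50% of alignment columns
  (threshold configurable). Public domain alignments do not define
  "fragment"; occupancy against alignment width is our operational rule.
- **Redundancy** — a greedy scan in input order keeps a row iff its
  identity to every already-kept row is ≤ 0.70. Identity is identical
  residues divided by columns occupied in *both* rows (not alignment
  length, not shorter-sequence length), which keeps the measure meaningful
  for partially overlapping rows. The output satisfies the all-pairs bound
  by construction and the filter is idempotent; input order determines
  which of two mutually redundant rows survives, and is documented as such.

For unaligned nucleotide sets there is a similarity-band filter
(`decrease_redundancy`, defaults 99%/30%): near-duplicates above the upper
bound are dropped, as are outliers whose best identity to everything kept
falls below the lower bound. Identity here comes from a semi-global
pairwise alignment (match 1, mismatch 0, free end gaps), counted over
co-occupied columns.

## Conservation

Per-column residue frequencies use the full sequence count as denominator,
gap state reported separately; a residue carried by half the family reads
50% even if every carrier is unanimous. The `ignore_gaps` toggle switches
to occupied-rows denominators for comparison. "Highly conserved" means the
modal residue frequency strictly exceeds the threshold (default 0.80); a
column at exactly the threshold is not reported. Degenerate codes (B, Z,
X) count as their own symbols.

## Coevolution

Residue events are (column, residue) occurrences at ≥ 20% presence
(`min_presence`). For an ordered pair (a, b) we compute f(b), f(b|a), the
relative increase f(b|a)/f(b) − 1, and a one-sided Fisher exact p-value:
the upper tail P[X ≥ k_ab] of the hypergeometric law for the 2×2 presence
table (scipy's `hypergeom.sf`). A pair is accepted when the relative
increase exceeds 0.80 in at least one direction and p < 10⁻¹⁰.

Choices made where the procedure leaves room:

- **Relative, not absolute, increase.** An absolute reading (f(b|a) − f(b)
  > 0.8) is unsatisfiable whenever f(b) > 0.2/1.8 ≈ 0.11, i.e. for nearly
  all events above the 20% presence floor; only the relative reading is
  generally satisfiable. `increase_mode="absolute"` is available.
- **Either direction suffices** by default; `require_both_directions`
  tightens this. The direction(s) that passed are recorded per pair.
- **No multiple-testing correction**: the 10⁻¹⁰ bar is itself stringent;
  the number of pairs tested is implicit in the event catalog and the pair
  report is complete, so users can correct post hoc if desired.
- **Sets are connected components** of the pair graph, so set members need
  not be pairwise supported; `mode="clique"` gives the stricter reading.
  Events at the same column are never paired (mutually exclusive by
  construction).

## Signatures and classification

Signatures are data (TSV: name, reference position, allowed residues,
required/forbidden), shipped for the ArsC domain (conserved residues,
coevolved sets 1–4, and an Spx-like discriminator: G106 with set 1
forbidden) and for the 13 conserved molybdopterin-domain positions. The
ArsC tables treat position 60 as a two-state marker — R60 belongs to set 1,
N60 to set 4 — mutually exclusive alternatives at one position, which is
exactly how subfamily-specific residues behave. Conserved-position
signatures alone cannot identify AioA among molybdopterin proteins (most
family members share them); the shipped table supports reporting that
fact, not similarity-based identification, which is out of scope.

A peptide is `present` for a signature iff every required position within
its mapped span carries an allowed residue and no forbidden event matches;
`not_assessable` iff any required position lies outside the span (partial
amplicons); `absent` otherwise. Aggregates are fractions among assessable
sequences and are order-invariant; presence is stable under span extension
with unchanged states.

## Amplicon translation and mapping

Translation is codon-by-codon under the standard genetic code. Codons
containing N translate to X unconditionally — we do not resolve synonymous
ambiguity, so an N never silently fabricates a residue call. Internal
stops either truncate (default) or raise, naming the codon index. Reading
frames are chosen by semi-global alignment score of each frame's
translation against the reference peptide (ties to the lower frame); a
primer-known frame can be forced.

Mapping uses semi-global alignment (BLOSUM62, gap open −11 / extend −1,
free end gaps on the amplicon side, the amplicon being a sub-region of the
domain). Each aligned peptide residue inherits its reference residue
number; the span is the (min, max) of assigned numbers; deletions leave
numbers unassigned inside the span. Alignments scoring below a configurable
floor are declared unmappable rather than repaired — frameshifted clones
surface as unmappable, matching how uncurated amplicons should be treated.

Per-position residue distributions are computed over peptides carrying a
state at the position. The 95% interval per residue type is the
equal-tailed credible interval of the Jeffreys posterior
Beta(count + ½, n − count + ½) — the standard "Bayesian confidence"
convention for sequence logos — clamped to 0/1 at empty/full counts so the
interval always contains the point estimate. A uniform prior is a
one-line change (`jeffreys_interval` takes the counts directly).

## OTU clustering and Good's coverage

Pairwise distances are 1 − identity from the semi-global nucleotide
alignment. OTUs come from hierarchical agglomerative clustering
(scipy linkage) cut at the distance cutoff, default 0.03 (= 97% identity)
with furthest-neighbour linkage, the historical DOTUR convention; average
and nearest neighbour are options. Tie-breaks are made deterministic by
sorting members and clusters lexicographically.

Good's coverage is C = (1 − n/N) × 100. The formula is implemented with n
= number of *singleton* OTUs (Good's 1953 estimator); a literal
distinct-OTU reading of "unique OTUs" is available as
`n_definition="distinct_otus"`, but only the singleton reading produces
the 60–85% coverages typical of real clone libraries, so it is the
default.

## Synthetic data generator

The generator emulates the structures the analyses are designed to detect:

- **Families** — i.i.d. background columns (uniform over the 20 amino
  acids by default; a skewed natural-frequency preset exists — uniform
  maximises test sharpness, skew tests robustness), subfamilies assigned
  by largest-remainder rounding so planted fractions are exact, planted
  event sets carried deterministically at zero noise, conserved columns
  hitting round(target·N) rows exactly. Planted and conserved residues are
  *reserved* at their columns: background rows never draw them, so the
  truth record describes the data exactly and boundary p-value fixtures
  behave as constructed. Gaps are sprinkled i.i.d. over background cells;
  fragment rows (random ~30% windows) are appended beyond the core family
  so they perturb nothing but the fragment filter.
- **Amplicons** — a reference sub-region reverse-translated with random
  synonymous codons, i.i.d. substitutions, optional random flanks; truth
  stores span and frame (flank length mod 3). The shipped reference is a
  synthetic ArsC-like peptide (random backbone with the signature residues
  planted at their reference positions) — it is *not* any real protein's
  sequence.
- **Clone libraries** — OTU centroids derived from one base sequence by
  substituting round(between/2 · L) sites, members by round(within/2 · L)
  sites from their centroid; substitution-only mutation keeps alignment
  distances equal to Hamming distances, so within/between distances
  concentrate where the parameters say.

All generators are pure functions of (spec, seed).

**What passing synthetic benchmarks does not show.** Sequences are drawn
independently — there is no phylogenetic correlation, so coevolution
signals caused by shared ancestry rather than function are not modelled
(the column statistics themselves make the same independence assumption).
Real alignments also have correlated gap structure, compositional bias and
alignment errors that the generator does not reproduce. Recovery results
on synthetic data validate the machinery, not database-scale conclusions.

## Problem sizes and numerics

The standard benchmark family is 500 sequences × 100 columns with a 40%
subfamily and 0.95-conserved columns — large enough that the planted
pairs sit far below the 10⁻¹⁰ bar while the whole pipeline runs in
seconds. Oracle comparisons (exhaustive counting for frequencies; exact
rational hypergeometric tails for Fisher) are made at 10⁻¹² relative
tolerance. Fisher p-values use scipy's survival function rather than
factorial ratios for numerical range. Degenerate inputs are defined
rather than left to chance: empty identity denominators return 0,
all-gap columns report an empty distribution with gap fraction 1,
all-gap reference rows yield an empty map with a warning, single-sequence
libraries are one singleton OTU (C = 0).

## Known limitations

- Greedy filters depend on input order (documented, deterministic).
- The frequency-increase rule is the only coevolution statistic; no
  mutual-information or direct-coupling scores.
- Signature classification requires a reference mapping; sequences that
  fail to map are simply not assessable.
- No rarefaction or richness estimators beyond Good's coverage; the wider
  community-ecology pipeline is out of scope.
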