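"""Clone-library OTU clustering and Good's coverage.

Clone libraries are summarised by clustering sequences into operational
taxonomic units (OTUs) at an identity cutoff (97%, i.e. distance 0.03)
with furthest-neighbour hierarchical clustering — the historical DOTUR
convention — and by Good's coverage C = (1 - n/N) x 100, where N is the
library size and n is, under the classical estimator, the number of
singleton OTUs.  A literal "distinct OTUs" reading of n is provided for
comparison; only the singleton reading yields coverages in the ranges
typically reported for environmental clone libraries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .alignment import unaligned_identity

_LINKAGE = {"furthest": "complete", "average": "average", "nearest": "single"}


@dataclass
class OTUTable:
    """A partition of clone sequences into OTUs at one distance cutoff."""

    cutoff: float
    clusters: list[list[str]]  # member ids per OTU

    @property
    def N(self) -> int:
        return sum(len(c) for c in self.clusters)

    @property
    def n_otus(self) -> int:
        return len(self.clusters)

    @property
    def n_singletons(self) -> int:
        return sum(1 for c in self.clusters if len(c) == 1)


@dataclass
class CoverageEstimate:
    """Good's coverage C = (1 - n/N) x 100 with its ingredients."""

    C: float
    n: int
    N: int
    n_definition: str  # "singleton_otus" | "distinct_otus"


def distance_matrix(seqs: list[tuple[str, str]]) -> tuple[list[str], np.ndarray]:
    """Pairwise distances d = 1 - identity from semi-global alignment.

    Symmetric with zero diagonal; identity is matches over co-occupied
    aligned columns.
    """
    if len(seqs) < 2:
        raise ValueError("distance_matrix needs at least two sequences")
    if any(not s for _, s in seqs):
        raise ValueError("empty sequence in input")
    ids = [i for i, _ in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = unaligned_identity(seqs[i][1], seqs[j][1])
            d[i, j] = d[j, i] = 1.0 - ident
    return ids, d


def cluster_otus(
    seqs: list[tuple[str, str]],
    cutoff: float = 0.03,
    method: str = "furthest",
) -> OTUTable:
    """Agglomerative OTU clustering cut at ``cutoff`` distance.

    ``furthest`` (complete linkage, the DOTUR default), ``average`` or
    ``nearest``.  Cluster order and membership order are deterministic:
    members sorted lexicographically, clusters by their smallest id.
    """
    if method not in _LINKAGE:
        raise ValueError(f"unknown linkage {method!r}; choose from {sorted(_LINKAGE)}")
    if not seqs:
        raise ValueError("cluster_otus needs at least one sequence")
    if len(seqs) == 1:
        return OTUTable(cutoff, [[seqs[0][0]]])
    ids, d = distance_matrix(seqs)
    z = linkage(squareform(d, checks=False), method=_LINKAGE[method])
    labels = fcluster(z, t=cutoff, criterion="distance")
    groups: dict[int, list[str]] = {}
    for rid, lab in zip(ids, labels):
        groups.setdefault(int(lab), []).append(rid)
    clusters = sorted((sorted(m) for m in groups.values()), key=lambda c: c[0])
    return OTUTable(cutoff, clusters)


def goods_coverage(
    table: OTUTable, n_definition: str = "singleton_otus"
) -> CoverageEstimate:
    """Good's library coverage from an OTU table.

    With the default (classical) definition n counts singleton OTUs; the
    ``distinct_otus`` alternative counts all OTUs.
    """
    if table.N == 0:
        raise ValueError("cannot compute coverage of an empty library")
    if n_definition == "singleton_otus":
        n = table.n_singletons
    elif n_definition == "distinct_otus":
        n = table.n_otus
    else:
        raise ValueError(f"unknown n_definition {n_definition!r}")
    c = (1.0 - n / table.N) * 100.0
    return CoverageEstimate(c, n, table.N, n_definition)
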