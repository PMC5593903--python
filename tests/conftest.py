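"""Shared fixtures: small hand-built alignments and planted synthetic data."""

from __future__ import annotations

import numpy as np
import pytest

from famdet import Alignment, FamilySpec, generate_family
from famdet.synthetic import AMINO_ACIDS


@pytest.fixture
def tiny_alignment() -> Alignment:
    return Alignment(
        [
            ("ref", "MC-KR"),
            ("s1", "MCAKR"),
            ("s2", "MC-KK"),
            ("s3", "-CAK-"),
        ]
    )


def perfect_association_alignment(n: int) -> Alignment:
    """Two columns; first n/2 rows carry A/W, the rest spread over other residues.

    The only >=20% events are ('A', col 0) and ('W', col 1), co-occurring
    in exactly the same rows — the perfect-association boundary fixture.
    """
    assert n % 2 == 0
    half = n // 2
    others = [aa for aa in AMINO_ACIDS if aa not in "AW"]
    records = []
    for i in range(half):
        records.append((f"on{i}", "AW"))
    for i in range(half):
        res = others[i % len(others)]
        records.append((f"off{i}", res * 2))
    return Alignment(records)


@pytest.fixture
def planted_family():
    """N=500, 100 columns, one 40% subfamily with a planted 3-event set,
    3 conserved columns at 0.95, zero noise."""
    spec = FamilySpec(
        n_sequences=500,
        n_columns=100,
        subfamilies=[
            ("reductase", 0.4, [[(10, "R"), (40, "R"), (41, "P")]]),
            ("background", 0.6, []),
        ],
        conserved_columns=[(5, "C", 0.95), (20, "R", 0.95), (21, "P", 0.95)],
        seed=20260101,
    )
    return generate_family(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_alignment(
    n_seqs: int, n_cols: int, rng: np.random.Generator, gap_rate: float = 0.1
) -> Alignment:
    symbols = list(AMINO_ACIDS)
    records = []
    for i in range(n_seqs):
        chars = rng.choice(symbols, size=n_cols)
        if gap_rate:
            mask = rng.random(n_cols) < gap_rate
            chars = np.where(mask, "-", chars)
        records.append((f"r{i}", "".join(chars)))
    return Alignment(records)
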