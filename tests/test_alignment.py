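"""Alignment I/O, reference numbering, identity and redundancy filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famdet import (
    build_reference_map,
    decrease_redundancy,
    pairwise_identity,
    read_alignment,
    remove_fragments,
    remove_redundant,
)
from famdet.alignment import (
    Alignment,
    AlignmentError,
    identity_matrix,
    unaligned_identity,
)

from conftest import random_alignment


class TestReadAlignment:
    def test_fasta_parse(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nAC-D\n>b\nACED\n")
        aln = read_alignment(p)
        assert aln.n_columns == 4
        assert aln.records == [("a", "AC-D"), ("b", "ACED")]

    def test_stockholm_annotation_skipped(self, tmp_path):
        sto = tmp_path / "a.sto"
        sto.write_text(
            "# STOCKHOLM 1.0\n"
            "a AC.D\n"
            "b ACED\n"
            "#=GC SS_cons ....\n"
            "//\n"
        )
        fa = tmp_path / "a.fasta"
        fa.write_text(">a\nAC-D\n>b\nACED\n")
        assert read_alignment(sto, "stockholm").records == read_alignment(fa).records

    def test_dot_gaps_and_lowercase_normalised(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nac.d\n")
        assert read_alignment(p).records == [("a", "AC-D")]

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACD\n>b\nAC\n")
        with pytest.raises(AlignmentError, match="ragged"):
            read_alignment(p)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(AlignmentError, match="duplicate"):
            Alignment([("a", "AC"), ("a", "AC")])

    def test_malformed_stockholm_names_file(self, tmp_path):
        p = tmp_path / "bad.sto"
        p.write_text("not stockholm at all\n")
        with pytest.raises(AlignmentError, match="bad.sto"):
            read_alignment(p, "stockholm")


class TestReferenceMap:
    def test_gap_skipped(self):
        aln = Alignment([("ref", "M-KC")])
        rm = build_reference_map(aln, "ref", 1)
        assert rm.col_to_ref == {0: 1, 2: 2, 3: 3}
        assert rm.ref_to_col == {1: 0, 2: 2, 3: 3}

    def test_offset_identity(self):
        aln = Alignment([("ref", "ACDEFGHIKL")])
        rm = build_reference_map(aln, "ref", 5)
        assert all(rm.col_to_ref[i] == i + 5 for i in range(10))

    def test_all_gap_reference_is_empty(self):
        aln = Alignment([("ref", "----"), ("x", "ACDE")])
        rm = build_reference_map(aln, "ref")
        assert rm.col_to_ref == {}
        assert rm.span is None

    def test_missing_reference_raises(self, tiny_alignment):
        with pytest.raises(KeyError):
            build_reference_map(tiny_alignment, "nope")

    def test_gap_column_insertion_stability(self, rng):
        """Inserting all-gap columns shifts indices but not the number sequence."""
        aln = random_alignment(5, 12, rng, gap_rate=0.2)
        rm = build_reference_map(aln, "r0")
        widened = Alignment(
            [(rid, s[:4] + "---" + s[4:]) for rid, s in aln.records]
        )
        rm2 = build_reference_map(widened, "r0")
        refs = [rm.col_to_ref[c] for c in sorted(rm.col_to_ref)]
        refs2 = [rm2.col_to_ref[c] for c in sorted(rm2.col_to_ref)]
        assert refs == refs2


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACDE", "ACDF", 0.75),
            ("ACDE", "ACDE", 1.0),
            ("A---", "-CDE", 0.0),  # no co-occupied column
            ("AC--", "ACDE", 1.0),  # fragment: denominator is overlap
        ],
    )
    def test_hand_counts(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            pairwise_identity("AC", "ACD")

    @given(st.text(alphabet="ACDE-", min_size=1, max_size=30).flatmap(
        lambda a: st.tuples(st.just(a),
                            st.text(alphabet="ACDE-", min_size=len(a),
                                    max_size=len(a)))))
    @settings(deadline=None, max_examples=50)
    def test_symmetric_and_gap_column_invariant(self, pair):
        a, b = pair
        assert pairwise_identity(a, b) == pairwise_identity(b, a)
        # inserting a column gapped in both leaves identity unchanged
        assert pairwise_identity(a + "-", b + "-") == pairwise_identity(a, b)


class TestFilters:
    def test_fragment_removed_at_default(self):
        aln = Alignment([("full", "ACDEFGHIKL"), ("frag", "A---------")])
        out, report = remove_fragments(aln)
        assert out.ids == ["full"]
        assert report[0][0] == "frag" and report[0][1] == "fragment"

    def test_threshold_zero_keeps_all(self, tiny_alignment):
        out, _ = remove_fragments(tiny_alignment, min_occupancy=0.0)
        assert out.records == tiny_alignment.records

    def test_redundant_duplicate_dropped(self):
        aln = Alignment([("a", "ACDE"), ("b", "ACDE")])
        out, report = remove_redundant(aln)
        assert out.ids == ["a"]
        assert report[0][:2] == ("b", "redundant_with:a")

    def test_mutually_dissimilar_kept(self):
        aln = Alignment([("a", "AAAA"), ("b", "AACC"), ("c", "CCAA")])
        # all pairwise identities 0.5 <= 0.70
        out, _ = remove_redundant(aln, 0.70)
        assert out.ids == ["a", "b", "c"]

    def test_redundancy_contract_and_idempotence(self, rng):
        """Output has all-pairs identity <= threshold; refiltering is a no-op."""
        templates = [random_alignment(1, 60, rng, 0.0).records[0][1]
                     for _ in range(8)]
        records = []
        for t, tmpl in enumerate(templates):
            for c in range(6):
                seq = list(tmpl)
                for pos in rng.permutation(60)[:6]:  # 90% identity copies
                    seq[pos] = "W"
                records.append((f"t{t}c{c}", "".join(seq)))
        aln = Alignment(records)
        out, _ = remove_redundant(aln, 0.70)
        m = identity_matrix(out).identity
        np.fill_diagonal(m, 0.0)
        assert m.max() <= 0.70 + 1e-12
        again, report = remove_redundant(out, 0.70)
        assert again.records == out.records and not report

    def test_fragment_filter_idempotent(self, rng):
        aln = random_alignment(30, 20, rng, gap_rate=0.4)
        once, _ = remove_fragments(aln)
        twice, report = remove_fragments(once)
        assert twice.records == once.records and not report


class TestDecreaseRedundancy:
    def test_duplicates_collapse(self):
        seqs = [("a", "ACGTACGTAC"), ("b", "ACGTACGTAC"), ("c", "ACGTACGTAC")]
        kept, report = decrease_redundancy(seqs)
        assert [i for i, _ in kept] == ["a"]
        assert len(report) == 2

    def test_outlier_dropped_by_min_similarity(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=60))
        close = []
        for i in range(4):
            seq = list(base)
            for pos in rng.permutation(60)[: 3 + i]:
                seq[pos] = "ACGT"[(("ACGT".index(seq[pos])) + 1) % 4]
            close.append((f"h{i}", "".join(seq)))
        outlier = ("out", "".join(rng.choice(list("ACGT"), size=60)))
        # sanity: the outlier really is below the band
        assert max(unaligned_identity(outlier[1], s) for _, s in close) < 0.85
        kept, report = decrease_redundancy(close + [outlier],
                                           max_similarity=0.99,
                                           min_similarity=0.85)
        assert ("out", "dissimilar_outlier") == report[-1][:2]
        assert all(rid != "out" for rid, _ in kept)

    def test_identity_band_is_noop(self):
        seqs = [("a", "ACGT"), ("b", "TTTT"), ("c", "AAAA")]
        kept, _ = decrease_redundancy(seqs, max_similarity=1.0, min_similarity=0.0)
        assert kept == seqs
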