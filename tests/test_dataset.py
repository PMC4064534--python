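"""Sequence validation, A/C/N categorisation, and dataset I/O."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from solscore.dataset import (
    CategorizationConfig,
    DatasetError,
    ExpressionCategory,
    ExpressionOutcome,
    SequenceError,
    assign_category,
    export_summary,
    read_dataset,
    validate_sequence,
    write_dataset,
)
from solscore.simulate import SynthConfig, generate

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class TestValidateSequence:
    @pytest.mark.parametrize(
        "raw, expected",
        [("acdk", "ACDK"), ("MKKLLPT", "MKKLLPT"), (" mk \n lp ", "MKLP")],
    )
    def test_canonicalisation(self, raw, expected):
        assert validate_sequence("p", raw).residues == expected

    @pytest.mark.parametrize(
        "raw, position", [("AC*K", 3), ("BCD", 1), ("ACDU", 4), ("AC-D", 3)]
    )
    def test_non_standard_residue_rejected_with_position(self, raw, position):
        with pytest.raises(SequenceError, match=f"position {position}"):
            validate_sequence("p", raw)

    def test_empty_rejected(self):
        with pytest.raises(SequenceError):
            validate_sequence("p", "   ")


class TestAssignCategory:
    @pytest.mark.parametrize(
        "expressed, yield_, full, expected",
        [
            (True, 0.5, True, "A"),
            (True, 0.0, True, "C"),
            (True, 0.5, False, "N"),   # truncated product
            (False, 0.0, True, "N"),
            (True, 0.1, True, "C"),    # boundary: exactly the threshold is C
            (True, 0.1000001, True, "A"),
        ],
    )
    def test_rule(self, expressed, yield_, full, expected):
        outcome = ExpressionOutcome(expressed, yield_, full)
        assert assign_category(outcome).value == expected

    @given(
        expressed=st.booleans(),
        yield_=st.floats(0.0, 10.0, allow_nan=False),
        full=st.booleans(),
    )
    def test_partition_exactly_one_category(self, expressed, yield_, full):
        """Every admissible outcome maps to exactly one of A/C/N."""
        if not expressed and yield_ >= 0.1:
            return
        cat = assign_category(ExpressionOutcome(expressed, yield_, full))
        assert cat in (
            ExpressionCategory.SOLUBLE,
            ExpressionCategory.INSOLUBLE,
            ExpressionCategory.NON_EXPRESSED,
        )

    @given(yield_=st.floats(0.001, 5.0), thr=st.floats(0.05, 1.0))
    def test_threshold_monotonicity(self, yield_, thr):
        """Raising the threshold never promotes a record from C to A."""
        outcome = ExpressionOutcome(True, yield_, True)
        low = assign_category(outcome, CategorizationConfig(thr))
        high = assign_category(outcome, CategorizationConfig(thr * 2))
        assert not (low.value == "C" and high.value == "A")

    def test_negative_yield_rejected(self):
        with pytest.raises(DatasetError):
            ExpressionOutcome(True, -0.2, True)

    def test_nonexpressed_with_high_yield_rejected(self):
        with pytest.raises(DatasetError):
            assign_category(ExpressionOutcome(False, 0.5, True))


class TestDatasetIO:
    def test_round_trip_identity(self, tmp_path):
        synth = generate(SynthConfig(n=12, seed=3))
        fasta, tsv = tmp_path / "a.fasta", tmp_path / "a.tsv"
        write_dataset(synth.dataset, fasta, tsv)
        loaded = read_dataset(fasta, tsv)
        assert loaded.ids == synth.dataset.ids
        for orig, back in zip(synth.dataset, loaded):
            assert back.sequence == orig.sequence
            assert back.category == orig.category
            assert back.outcome.expressed == orig.outcome.expressed
            assert back.outcome.full_length == orig.outcome.full_length
            assert back.outcome.soluble_yield == pytest.approx(
                orig.outcome.soluble_yield, rel=1e-5
            )

    def test_orphan_id_raises_join_error(self, tmp_path):
        (tmp_path / "b.fasta").write_text(">s1\nMKLV\n>s2\nMKLW\n")
        (tmp_path / "b.tsv").write_text(
            "id\texpressed\tsoluble_yield\tfull_length\ns1\t1\t0.5\t1\n"
        )
        with pytest.raises(DatasetError, match="s2"):
            read_dataset(tmp_path / "b.fasta", tmp_path / "b.tsv")

    def test_precomputed_categories_taken_verbatim(self, tmp_path):
        (tmp_path / "c.fasta").write_text(">s1\nMKLV\n>s2\nMKLW\n>s3\nMKLY\n")
        (tmp_path / "c.tsv").write_text("id\tcategory\ns1\tA\ns2\tn\ns3\tC\n")
        ds = read_dataset(tmp_path / "c.fasta", tmp_path / "c.tsv")
        assert ds.categories() == ["A", "N", "C"]
        assert all(rec.outcome is None for rec in ds)

    def test_malformed_row_reports_line_number(self, tmp_path):
        (tmp_path / "d.fasta").write_text(">s1\nMKLV\n")
        (tmp_path / "d.tsv").write_text(
            "id\texpressed\tsoluble_yield\tfull_length\ns1\t1\tnot_a_number\t1\n"
        )
        with pytest.raises(DatasetError, match="line 2"):
            read_dataset(tmp_path / "d.fasta", tmp_path / "d.tsv")

    def test_drop_invalid_skips_bad_sequences(self, tmp_path):
        (tmp_path / "e.fasta").write_text(">s1\nMKLV\n>s2\nMKXW\n")
        (tmp_path / "e.tsv").write_text("id\tcategory\ns1\tA\ns2\tC\n")
        ds = read_dataset(
            tmp_path / "e.fasta", tmp_path / "e.tsv", drop_invalid=True
        )
        assert ds.ids == ["s1"]

    def test_export_summary_columns(self, tmp_path):
        synth = generate(SynthConfig(n=5, seed=1))
        out = tmp_path / "summary.tsv"
        export_summary(synth.dataset, out)
        lines = out.read_text().splitlines()
        assert lines[0] == "id\tlength\tcategory"
        assert len(lines) == 6
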