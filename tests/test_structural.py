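"""PEST, coiled-coil, TM and disorder baselines; adapter table contract."""

import math

import numpy as np
import pytest

from solscore.dataset import (
    AminoAcidSequence,
    ExpressionCategory,
    ExpressionDataset,
    ExpressionRecord,
)
from solscore.physchem import KYTE_DOOLITTLE
from solscore.structural import (
    coiled_coil,
    disorder_profile,
    find_pest,
    load_cc_propensities,
    load_external_features,
    tm_segments,
)

from .conftest import random_sequence


def seq(residues: str) -> AminoAcidSequence:
    return AminoAcidSequence(id="t", residues=residues)


class TestFindPest:
    def test_no_depst_means_no_region(self):
        assert find_pest(seq("KLLLLLLLLLLLLLLR")) == []

    def test_all_flanks_means_no_region(self):
        assert find_pest(seq("K" * 16)) == []

    def test_hand_scored_core(self):
        core = "EPSTEEPSTEEP"
        regions = find_pest(seq("K" + core + "R"))
        assert len(regions) == 1
        region = regions[0]
        assert (region.start, region.end) == (2, 13)
        # 100 mole% DEPST; mean KD rescaled to 0-90:
        kd = sum(KYTE_DOOLITTLE[c] for c in core) / len(core)
        expected = 0.55 * 100.0 - 0.5 * (10.0 * kd + 45.0)
        assert region.score == pytest.approx(expected, abs=1e-9)

    def test_flank_concatenation_preserves_core(self):
        core = "EPSTEEPSTEEP"
        inner = find_pest(seq(core))
        outer = find_pest(seq("K" + core + "K"))
        assert len(inner) == len(outer) == 1
        assert inner[0].score == pytest.approx(outer[0].score)
        assert outer[0].end - outer[0].start == inner[0].end - inner[0].start

    def test_short_stretch_excluded(self):
        assert find_pest(seq("K" + "EPSTEEPSTEE" + "R")) == []  # 11 < 12


class TestCoiledCoil:
    def test_short_sequence_all_zero(self):
        profile = coiled_coil(seq("L" * 27))
        assert np.all(profile.scores == 0.0)
        assert profile.segments == ()

    def test_homopolymer_equals_positional_geometric_mean(self):
        # every register permutes the same seven propensities, so the
        # window score reduces to their geometric mean
        table = load_cc_propensities()
        for aa in "LEKG":
            profile = coiled_coil(seq(aa * 40))
            expected = float(np.exp(np.mean(np.log(table[aa]))))
            assert profile.scores.max() == pytest.approx(expected, rel=1e-9)
            assert profile.scores.min() == pytest.approx(expected, rel=1e-9)

    def test_matches_exhaustive_window_register_oracle(self, rng):
        table = load_cc_propensities()
        window = 28
        for trial in range(8):
            s = random_sequence(rng, int(rng.integers(28, 61)))
            n = len(s)
            expected = np.zeros(n)
            for start in range(n - window + 1):
                for reg in range(7):
                    logs = [
                        math.log(table[s.residues[start + j]][(j + reg) % 7])
                        for j in range(window)
                    ]
                    score = math.exp(sum(logs) / window)
                    for j in range(window):
                        expected[start + j] = max(expected[start + j], score)
            got = coiled_coil(s).scores
            assert np.allclose(got, expected, rtol=1e-9)

    def test_raising_threshold_never_lengthens_segments(self):
        s = seq("LEALEGKLEALEGKLEALEGKLEALEGKLEALEGK")
        low = coiled_coil(s, threshold=0.8)
        high = coiled_coil(s, threshold=1.2)
        assert sum(e - s0 + 1 for s0, e in high.segments) <= sum(
            e - s0 + 1 for s0, e in low.segments
        )

    def test_profile_length_equals_sequence_length(self, rng):
        s = random_sequence(rng, 75)
        assert coiled_coil(s).scores.size == len(s)


class TestTmSegments:
    def test_poly_leucine_single_segment(self):
        segs = tm_segments(seq("L" * 25))
        assert segs == [(1, 25)]

    def test_poly_aspartate_none(self):
        assert tm_segments(seq("D" * 40)) == []

    def test_lowering_cutoff_does_not_reduce_coverage(self, rng):
        s = random_sequence(rng, 120)
        covered = lambda segs: {
            i for a, b in segs for i in range(a, b + 1)
        }
        strict = covered(tm_segments(s, cutoff=1.6))
        loose = covered(tm_segments(s, cutoff=1.0))
        assert strict <= loose


class TestDisorder:
    def test_poly_glutamate_fully_disordered(self):
        _, frac = disorder_profile(seq("E" * 50))
        assert frac == 1.0

    def test_poly_tryptophan_fully_ordered(self):
        _, frac = disorder_profile(seq("W" * 50))
        assert frac == 0.0

    def test_fraction_bounded_and_profile_full_length(self, rng):
        s = random_sequence(rng, 90)
        profile, frac = disorder_profile(s)
        assert profile.size == len(s)
        assert 0.0 <= frac <= 1.0


class TestExternalFeatures:
    @pytest.fixture
    def dataset(self):
        records = [
            ExpressionRecord(AminoAcidSequence(f"s{i}", "MKLVAG"), ExpressionCategory.SOLUBLE)
            for i in range(4)
        ]
        return ExpressionDataset(records=records)

    def test_full_join(self, tmp_path, dataset):
        path = tmp_path / "ext.tsv"
        rows = ["id\tfeature\tkind\tvalue"] + [
            f"s{i}\taccessibility\tcontinuous\t{0.1 * i}" for i in range(4)
        ]
        path.write_text("\n".join(rows) + "\n")
        table = load_external_features(path, dataset)
        kind, values = table.features["accessibility"]
        assert kind == "continuous"
        assert len(values) == 4

    def test_missing_ids_logged_not_fatal(self, tmp_path, dataset, caplog):
        path = tmp_path / "ext.tsv"
        path.write_text(
            "id\tfeature\tkind\tvalue\ns0\tsignal_peptide\tbinary\t1\n"
            "s1\tsignal_peptide\tbinary\t0\n"
        )
        with caplog.at_level("WARNING"):
            table = load_external_features(path, dataset)
        assert "2 dataset ids" in caplog.text
        assert len(table.features["signal_peptide"][1]) == 2

    def test_binary_domain_violation(self, tmp_path, dataset):
        path = tmp_path / "ext.tsv"
        path.write_text("id\tfeature\tkind\tvalue\ns0\tss_bond\tbinary\t0.5\n")
        with pytest.raises(ValueError, match="line 2"):
            load_external_features(path, dataset)

    def test_unknown_kind_rejected(self, tmp_path, dataset):
        path = tmp_path / "ext.tsv"
        path.write_text("id\tfeature\tkind\tvalue\ns0\tf\tordinal\t1\n")
        with pytest.raises(ValueError, match="unknown kind"):
            load_external_features(path, dataset)
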