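"""Peptide scoring, the delta-phi sign rule, window scanning, distributions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import amylpot as ap
from amylpot import Label, PeptideDataset, PeptideRecord
from amylpot.io import AMINO_ACIDS, ValidationError, encode_sequence

hexapeptides = st.text(alphabet=AMINO_ACIDS, min_size=6, max_size=6)


def _brute_force_phi(sequence, matrix):
    """Independent oracle: explicit per-position table lookup and sum."""
    return sum(
        matrix.cell(aa, j) for j, aa in enumerate(sequence, start=1)
    )


class TestScorePeptide:
    def test_stviie_worked_example(self, amy_matrix, non_matrix):
        s = ap.score_peptide("STVIIE", amy_matrix, non_matrix)
        assert s.phi_amyloid == pytest.approx(-6.975, abs=5e-4)
        assert s.phi_nonamyloid == pytest.approx(-5.269, abs=5e-4)
        assert s.delta_phi == pytest.approx(-1.706, abs=5e-4)
        assert s.call is Label.AMYLOID

    def test_vqivyk_worked_example(self, amy_matrix, non_matrix):
        s = ap.score_peptide("VQIVYK", amy_matrix, non_matrix)
        assert s.phi_amyloid == pytest.approx(2.290, abs=5e-4)
        assert s.phi_nonamyloid == pytest.approx(1.668, abs=5e-4)
        assert s.delta_phi == pytest.approx(0.622, abs=5e-4)
        assert s.call is Label.NON_AMYLOID

    @given(seq=hexapeptides)
    @settings(max_examples=100, derandomize=True)
    def test_same_matrix_ties_to_non_amyloid(self, amy_matrix, seq):
        s = ap.score_peptide(seq, amy_matrix, amy_matrix)
        assert s.delta_phi == 0.0
        assert s.call is Label.NON_AMYLOID

    @given(seq=hexapeptides)
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetry_on_swap(self, amy_matrix, non_matrix, seq):
        fwd = ap.score_peptide(seq, amy_matrix, non_matrix)
        rev = ap.score_peptide(seq, non_matrix, amy_matrix)
        assert rev.delta_phi == pytest.approx(-fwd.delta_phi, abs=1e-12)

    @given(seq=hexapeptides, pos=st.integers(0, 5),
           new=st.sampled_from(AMINO_ACIDS))
    @settings(max_examples=100, derandomize=True)
    def test_single_substitution_additivity(self, amy_matrix, non_matrix,
                                            seq, pos, new):
        """Changing one residue shifts delta_phi by the cell differential."""
        mutated = seq[:pos] + new + seq[pos + 1:]
        before = ap.score_peptide(seq, amy_matrix, non_matrix).delta_phi
        after = ap.score_peptide(mutated, amy_matrix, non_matrix).delta_phi
        expected_shift = (
            (amy_matrix.cell(new, pos + 1) - non_matrix.cell(new, pos + 1))
            - (amy_matrix.cell(seq[pos], pos + 1)
               - non_matrix.cell(seq[pos], pos + 1))
        )
        assert after - before == pytest.approx(expected_shift, abs=1e-9)

    def test_invalid_sequence_rejected(self, amy_matrix, non_matrix):
        with pytest.raises(ValidationError):
            ap.score_peptide("STVIE", amy_matrix, non_matrix)

    def test_matches_brute_force_lookup(self, amy_matrix, non_matrix):
        rng = np.random.default_rng(5)
        letters = np.array(list(AMINO_ACIDS))
        for _ in range(200):
            seq = "".join(rng.choice(letters, size=6))
            s = ap.score_peptide(seq, amy_matrix, non_matrix)
            assert s.phi_amyloid == pytest.approx(
                _brute_force_phi(seq, amy_matrix), abs=1e-9)
            assert s.phi_nonamyloid == pytest.approx(
                _brute_force_phi(seq, non_matrix), abs=1e-9)


class TestClassifyDataset:
    def test_true_positive(self, amy_matrix, non_matrix):
        ds = PeptideDataset([PeptideRecord("a", "STVIIE", Label.AMYLOID)])
        c = ap.classify_dataset(ds, amy_matrix, non_matrix)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 0, 0)

    def test_false_negative(self, amy_matrix, non_matrix):
        ds = PeptideDataset([PeptideRecord("a", "VQIVYK", Label.AMYLOID)])
        c = ap.classify_dataset(ds, amy_matrix, non_matrix)
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 0, 0, 1)

    def test_swapped_matrices_flip_every_call(self, amy_matrix, non_matrix):
        ds = ap.sample_dataset(ap.GeneratorConfig(
            class_sizes={Label.AMYLOID: 50, Label.NON_AMYLOID: 50}, seed=3))
        fwd = ap.classify_dataset(ds, amy_matrix, non_matrix)
        rev = ap.classify_dataset(ds, non_matrix, amy_matrix)
        # ties (delta=0) are called non-amyloid under both orders; this
        # dataset has none, so every call flips
        deltas = [ap.score_peptide(r.sequence, amy_matrix, non_matrix).delta_phi
                  for r in ds]
        assert all(d != 0 for d in deltas)
        assert (rev.tp, rev.fn) == (fwd.fn, fwd.tp)
        assert (rev.tn, rev.fp) == (fwd.fp, fwd.tn)

    def test_unlabeled_records_rejected(self, amy_matrix, non_matrix):
        ds = PeptideDataset([PeptideRecord("a", "STVIIE", Label.UNLABELED)])
        with pytest.raises(ValueError, match="unlabeled"):
            ap.classify_dataset(ds, amy_matrix, non_matrix)


class TestScanSequence:
    def test_hexapeptide_input_single_window(self, amy_matrix, non_matrix):
        windows = ap.scan_sequence("STVIIE", amy_matrix, non_matrix)
        assert len(windows) == 1
        assert windows[0].start == 0
        assert windows[0].score == ap.score_peptide("STVIIE", amy_matrix,
                                                    non_matrix)

    def test_seven_residues_two_windows(self, amy_matrix, non_matrix):
        windows = ap.scan_sequence("STVIIEA", amy_matrix, non_matrix)
        assert [w.start for w in windows] == [0, 1]
        assert windows[1].sequence == "TVIIEA"
        assert windows[0].start1 == 1

    def test_short_sequence_rejected(self, amy_matrix, non_matrix):
        with pytest.raises(ValueError, match="shorter"):
            ap.scan_sequence("STVIE", amy_matrix, non_matrix)

    def test_windows_match_independent_scoring(self, amy_matrix, non_matrix):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=50))
        windows = ap.scan_sequence(seq, amy_matrix, non_matrix)
        assert len(windows) == 45
        for w in windows:
            assert w.sequence == seq[w.start:w.start + 6]
            assert w.score == ap.score_peptide(w.sequence, amy_matrix,
                                               non_matrix)


class TestEnergyDistribution:
    def test_single_peptide_position_1(self, amy_matrix, non_matrix):
        """STVIIE position 1 differential: -1.036 - (-0.827) = -0.209."""
        ds = PeptideDataset.from_records(
            [PeptideRecord("a", "STVIIE", Label.AMYLOID),
             PeptideRecord("b", "VQIVYK", Label.NON_AMYLOID)]
        )
        dist = ap.energy_differential_distribution(
            ds, amy_matrix, non_matrix, position=1)
        assert dist.cutoff_fractions[Label.AMYLOID] == 1.0  # -0.209 <= -0.2
        assert dist.cutoff == -0.2

    def test_cutoff_is_a_bin_edge(self, amy_matrix, non_matrix):
        ds = ap.sample_dataset(ap.GeneratorConfig(
            class_sizes={Label.AMYLOID: 100, Label.NON_AMYLOID: 100}, seed=4))
        dist = ap.energy_differential_distribution(
            ds, amy_matrix, non_matrix, position=2)
        assert np.isclose(dist.bin_edges, -0.2).any()

    def test_frequencies_sum_to_one(self, amy_matrix, non_matrix):
        ds = ap.sample_dataset(ap.GeneratorConfig(
            class_sizes={Label.AMYLOID: 200, Label.NON_AMYLOID: 300}, seed=9))
        for pos in range(1, 7):
            dist = ap.energy_differential_distribution(
                ds, amy_matrix, non_matrix, position=pos)
            for freqs in dist.class_frequencies.values():
                assert freqs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_amyloid_class_enriched_below_cutoff(self, amy_matrix, non_matrix):
        """Peptides sampled with amyloid bias dominate the favorable tail."""
        ds = ap.sample_dataset(ap.GeneratorConfig(
            class_sizes={Label.AMYLOID: 2000, Label.NON_AMYLOID: 2000},
            seed=21))
        for pos in range(1, 7):
            dist = ap.energy_differential_distribution(
                ds, amy_matrix, non_matrix, position=pos)
            assert (dist.cutoff_fractions[Label.AMYLOID]
                    > dist.cutoff_fractions[Label.NON_AMYLOID])
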