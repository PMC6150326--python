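"""Feature encoders: conservation statistic, PWM scores, SS, AAindex, CKSAAP."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import glypre as g
from glypre.encoders import (
    cksaap_matrix,
    cksaap_pair_index,
    build_layout,
    pairs_from_indices,
    windows_to_ints,
)
from glypre.seqdata_io import AA20, ALPHABET

W = lambda s: g.PeptideWindow(s, relaxed=True)


# ---------------------------------------------------------------------------
# Column frequencies and the conservation statistic


class TestColumnFrequencies:
    def test_uniform_column(self):
        wins = [W(a * 3) for a in AA20]
        np.testing.assert_allclose(g.column_frequencies(wins, 1), 0.05)

    def test_x_excluded_from_denominator(self):
        wins = [W("AAA"), W("AAA"), W("KKK"), W("XXX")]
        freqs = g.column_frequencies(wins, 0)
        assert freqs[AA20.index("A")] == pytest.approx(2 / 3)
        assert freqs[AA20.index("K")] == pytest.approx(1 / 3)

    def test_all_x_column_is_zero(self):
        assert g.column_frequencies([W("XXX")], 1).sum() == 0.0

    def test_ragged_windows_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            g.column_frequencies([W("AAA"), W("AAAAA")], 0)


class TestConservation:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            (np.full(20, 0.05), 0.0),  # random distribution
            (np.eye(20)[0], 19.0),  # pure column
            (0.5 * (np.eye(20)[0] + np.eye(20)[1]), 9.0),  # 50/50 column
        ],
    )
    def test_analytic_values(self, freqs, expected):
        assert g.conservation_M(freqs, 0.05) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=20, max_size=20))
    def test_non_negative_and_zero_only_at_background(self, freqs):
        freqs = np.array(freqs)
        m = g.conservation_M(freqs, 0.05)
        assert m >= 0
        if not np.allclose(freqs, 0.05, atol=1e-13):
            assert m > 0 or np.allclose(freqs, 0.05)


# ---------------------------------------------------------------------------
# PWM


class TestPWM:
    def test_pseudocount_hand_values(self):
        # 4 positives; at column 0: A, A, K, E -> n_A = 2, N = 4.
        pos = [W("AAA"), W("AAA"), W("KAA"), W("EAA")]
        neg = [W("LLL")]
        pwm = g.fit_pwm(pos, neg)
        assert pwm.P[AA20.index("A"), 0] == pytest.approx((2 + 0.05 * 2) / 6)
        # Absent residue never scores zero: (0 + 0.1) / 6.
        assert pwm.P[AA20.index("W"), 0] == pytest.approx(0.1 / 6)

    def test_empty_positives_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            g.fit_pwm([], [W("AAA")])

    @given(st.lists(st.text(alphabet=ALPHABET, min_size=5, max_size=5),
                    min_size=1, max_size=12))
    def test_columns_sum_to_one_with_any_padding(self, strings):
        pwm = g.fit_pwm([W(s) for s in strings], [W("AAAAA")])
        np.testing.assert_allclose(pwm.P.sum(axis=0), 1.0, atol=1e-9)
        assert np.all(pwm.P > 0)


class TestPositionScores:
    @pytest.fixture()
    def pwm(self):
        return g.fit_pwm([W("AAA"), W("AAA"), W("KAA"), W("EAA")],
                         [W("LLL"), W("LLL")])

    def test_background_probability_scores_zero(self):
        P = np.full((20, 1), 0.05)
        pwm = g.PWMModel(1, P, np.array([3.0]), np.array([1.0]), 0.05, 4)
        assert g.encode_position_scores(W("A"), pwm)[0] == pytest.approx(0.0)

    def test_hand_value(self):
        P = np.full((20, 1), 0.05)
        P[0, 0] = 0.35
        P[1:, 0] = (1 - 0.35) / 19
        pwm = g.PWMModel(1, P, np.array([2.5]), np.array([0.5]), 0.05, 4)
        # ln(0.35/0.05) * 2 = 2 ln 7
        assert g.encode_position_scores(W("A"), pwm)[0] == pytest.approx(
            2 * np.log(7))

    def test_padding_scores_zero(self, pwm):
        scores = g.encode_position_scores(W("XAX"), pwm)
        assert scores[0] == 0.0 and scores[2] == 0.0


# ---------------------------------------------------------------------------
# Secondary structure


class TestEncodeSS:
    @pytest.fixture()
    def profile(self):
        probs = np.tile([0.7, 0.2, 0.1], (30, 1))
        probs[5] = [0.1, 0.8, 0.1]
        return g.SSProfile(probs)

    def test_window_27_gives_81_dimensions(self, profile):
        assert g.encode_ss(profile, 14, 27).shape == (81,)

    def test_triples_appear_contiguously(self, profile):
        vec = g.encode_ss(profile, 5, 5)
        np.testing.assert_allclose(vec[6:9], [0.1, 0.8, 0.1])

    def test_out_of_chain_positions_are_zero(self, profile):
        vec = g.encode_ss(profile, 0, 5)
        np.testing.assert_allclose(vec[:6], 0.0)
        assert vec[6:].sum() > 0

    def test_rows_renormalized(self):
        prof = g.SSProfile(np.array([[0.5, 0.3, 0.24]]))  # sums to 1.04
        vec = g.encode_ss(prof, 0, 11)
        mid = vec[15:18]
        assert mid.sum() == pytest.approx(1.0)

    def test_centre_outside_protein_rejected(self, profile):
        with pytest.raises(ValueError, match="outside"):
            g.encode_ss(profile, 30, 5)


# ---------------------------------------------------------------------------
# AAindex encoding


class TestEncodeAAindex:
    def test_length_is_indices_times_window(self, aaindex_table):
        vec = g.encode_aaindex(W("A" * 13), aaindex_table)
        assert vec.shape == (260,)

    def test_all_x_window_encodes_zero(self, aaindex_table):
        assert np.all(g.encode_aaindex(W("X" * 13), aaindex_table) == 0.0)

    def test_single_position_lookup(self):
        values = np.zeros((1, 20))
        values[0, AA20.index("K")] = 1.7
        table = g.AAIndexTable(("SYN1",), values)
        assert g.encode_aaindex(W("K"), table)[0] == 1.7


# ---------------------------------------------------------------------------
# CKSAAP


class TestCKSAAP:
    def test_full_length_2205(self):
        assert g.encode_cksaap_full(W("A" * 25), 4).shape == (2205,)

    def test_441_pair_types_per_gap(self):
        from glypre.encoders import cksaap_pairs
        pairs = cksaap_pairs(4)
        assert len(pairs) == 2205
        assert sum(1 for k, _ in pairs if k == 0) == 441

    def test_alake_gap1_hand_enumeration(self):
        vec = g.encode_cksaap_full(W("ALAKE"), k_max=1)
        block = vec[441:]
        expected = {("A", "A"), ("L", "K"), ("A", "E")}
        for a, b in expected:
            assert block[cksaap_pair_index(0, a + b, 0)] == pytest.approx(1 / 3)
        assert block.sum() == pytest.approx(1.0)
        assert np.count_nonzero(block) == 3

    @given(st.text(alphabet=ALPHABET, min_size=7, max_size=25))
    def test_each_gap_block_is_a_composition(self, s):
        if len(s) % 2 == 0:
            s += "A"
        vec = g.encode_cksaap_full(W(s), 4)
        for k in range(5):
            assert vec[441 * k:441 * (k + 1)].sum() == pytest.approx(1.0)

    def test_ordered_pairs_are_direction_sensitive(self):
        s = "ALAKECDEFGHIK"
        fwd = g.encode_cksaap_full(W(s), 2)
        rev = g.encode_cksaap_full(W(s[::-1]), 2)
        assert not np.allclose(fwd, rev)

    def test_projection_consistency(self):
        s = "ALAKECDEFGHIK"
        full = g.encode_cksaap_full(W(s), 4)
        pairs = [(0, "AL"), (1, "AA"), (4, "XX"), (3, "KE")]
        top = g.encode_cksaap_top(W(s), pairs, 4)
        idx = [cksaap_pair_index(k, p, 4) for k, p in pairs]
        np.testing.assert_array_equal(top, full[idx])

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            g.encode_cksaap_full(W("ALAKE"), k_max=4)

    def test_pair_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="k=7"):
            g.encode_cksaap_top(W("A" * 25), [(7, "AA")], 4)


# ---------------------------------------------------------------------------
# Assembly and layout


def _fitted_parts(aaindex_table):
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list(AA20), 80))
    seq = seq[:40] + "K" + seq[41:]
    prot = g.ProteinRecord("p", seq)
    probs = rng.dirichlet(np.ones(3), size=len(seq))
    profile = g.SSProfile(probs, seq)
    pos = [g.extract_window(prot, 41, 31)]
    neg = [g.extract_window(prot, 41, 31)]
    pwm = g.fit_pwm(pos, neg)
    pairs = pairs_from_indices(range(30), 4)
    return prot, profile, pwm, pairs


class TestAssemble:
    def test_default_configuration_is_402(self, aaindex_table):
        prot, profile, pwm, pairs = _fitted_parts(aaindex_table)
        fv = g.assemble(prot, 41, g.EncoderConfig(), pwm=pwm,
                        table=aaindex_table, profile=profile,
                        selected_pairs=pairs)
        assert len(fv) == 402

    def test_all_windows_11_is_294(self, aaindex_table):
        prot, profile, _, pairs = _fitted_parts(aaindex_table)
        cfg = g.EncoderConfig(window_pssf=11, window_ss=11, window_aaindex=11,
                              window_cksaap=11)
        pwm = g.fit_pwm([g.extract_window(prot, 41, 11)],
                        [g.extract_window(prot, 41, 11)])
        fv = g.assemble(prot, 41, cfg, pwm=pwm, table=aaindex_table,
                        profile=profile, selected_pairs=pairs)
        assert len(fv) == 11 + 33 + 220 + 30 == 294

    def test_layout_block_starts(self, aaindex_table):
        pairs = pairs_from_indices(range(30), 4)
        layout = build_layout(g.EncoderConfig(), aaindex_table.accessions, pairs)
        starts = {b.name: b.start for b in layout.blocks}
        assert starts == {"pssf": 0, "ss": 31, "aaindex": 112, "cksaap": 372}
        assert layout.total_length == 402
        assert layout.labels[0] == "PSSF:pos=-15"
        assert layout.labels[31] == "SS:pos=-13:C"

    @given(s=st.text(alphabet=ALPHABET, min_size=31, max_size=31))
    def test_feature_vectors_are_finite_for_any_window(self, aaindex_table, s):
        """Fuzz: no NaN/Inf from any residue content, including heavy 'X'."""
        seq = s[:15] + "K" + s[16:]
        prot = g.ProteinRecord("p", seq.replace("X", "A") if set(seq) == {"X"} else seq)
        pwm = g.fit_pwm([g.extract_window(prot, 16, 31, relax_center=True)],
                        [g.extract_window(prot, 16, 31, relax_center=True)])
        profile = g.SSProfile(np.tile([0.4, 0.4, 0.2], (len(seq), 1)))
        fv = g.assemble(prot, 16, g.EncoderConfig(), pwm=pwm,
                        table=aaindex_table, profile=profile,
                        selected_pairs=pairs_from_indices(range(30), 4),
                        relax_center=True)
        assert np.all(np.isfinite(fv.values))

    def test_missing_profile_names_group(self, aaindex_table):
        prot, _, pwm, pairs = _fitted_parts(aaindex_table)
        with pytest.raises(ValueError, match="secondary-structure"):
            g.assemble(prot, 41, g.EncoderConfig(), pwm=pwm,
                       table=aaindex_table, profile=None, selected_pairs=pairs)
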