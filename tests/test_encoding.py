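"""Core CGR encoding: recurrences, closed forms, exact digits, edits, k-mers."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cgrmatch.encoding import (
    CgrParams,
    ExactCoordinate,
    UnsupportedConfigError,
    build_bundle,
    build_index,
    closed_form_coordinate,
    decode_sequence,
    kmer_counts,
    left_delete,
    left_insert,
    right_delete,
    right_insert,
)
from cgrmatch.sequences import VERTICES, InvalidSymbolError, SequenceError

from conftest import random_seqs

STD = CgrParams.standard()
CANTOR = CgrParams.cantor()

dna = st.text(alphabet="ACGT", min_size=1, max_size=64)


def exact_value_oracle(seq: str, i: int) -> tuple[Fraction, Fraction]:
    """Direct rational evaluation of the cantor closed form:
    x_i = 2*3^-(i+1) * (1,1) + sum_k 2*3^(k-i-1) y_k."""
    vals = []
    for axis in range(2):
        acc = Fraction(2, 3 ** (i + 1))
        for k in range(1, i + 1):
            acc += 2 * Fraction(3, 1) ** (k - i - 1) * VERTICES[seq[k - 1]][axis]
        vals.append(acc)
    return (vals[0], vals[1])


class TestBuildIndex:
    @pytest.mark.parametrize(
        "seq,params,expected",
        [
            ("AT", STD, (0.625, 0.625)),
            ("TA", STD, (0.375, 0.375)),
            ("GA", STD, (0.375, 0.125)),
        ],
    )
    def test_worked_coordinates(self, seq, params, expected):
        idx = build_index(seq, params)
        assert idx.coordinate(len(seq)) == pytest.approx(expected, abs=1e-15)
        assert idx.coordinate(0) == params.x0

    def test_cantor_exact_digits_and_value(self):
        c = build_index("AT", backend="exact").exact_coordinate(2)
        assert c.digits(1) == "20" and c.digits(2) == "20"
        assert c.value() == (Fraction(20, 27), Fraction(20, 27))

    def test_single_symbol_cantor_closed_form(self):
        assert closed_form_coordinate("A", CANTOR, 1) == pytest.approx((2 / 9, 2 / 9))

    def test_empty_sequence_rejected(self):
        with pytest.raises(SequenceError):
            build_index("")

    def test_invalid_symbol_names_position(self):
        with pytest.raises(InvalidSymbolError, match="position 3"):
            build_index("ACNTG")

    def test_exact_backend_requires_cantor(self):
        with pytest.raises(UnsupportedConfigError):
            build_index("ACGT", STD, backend="exact")

    def test_lowercase_is_uppercased(self):
        assert build_index("acgt").seq == "ACGT"

    def test_closed_form_position_zero_is_x0(self):
        assert closed_form_coordinate("GACGA", STD, 0) == STD.x0

    @pytest.mark.parametrize("params", [STD, CANTOR, CgrParams(r=0.7, x0=(0.1, 0.9))])
    def test_iterative_matches_closed_form(self, params):
        """Eq-by-iteration vs direct summation agree within 1e-12 per axis."""
        for seq in random_seqs(100, 200, seed=11):
            idx = build_index(seq, params)
            for i in (0, 1, len(seq) // 2, len(seq)):
                assert idx.coordinate(i) == pytest.approx(
                    closed_form_coordinate(seq, params, i), abs=1e-12
                )

    def test_exact_digits_equal_rational_closed_form(self):
        """Packed digit construction evaluates to the exact rational sum."""
        for seq in random_seqs(20, 64, seed=12):
            idx = build_index(seq, backend="exact")
            for i in range(len(seq) + 1):
                assert idx.exact_coordinate(i).value() == exact_value_oracle(seq, i)

    def test_float_and_exact_backends_agree(self):
        for seq in random_seqs(20, 40, seed=13):
            f = build_index(seq)
            e = build_index(seq, backend="exact")
            for i in range(len(seq) + 1):
                assert f.coordinate(i) == pytest.approx(e.coordinate(i), abs=1e-12)


class TestBundle:
    def test_members_encode_transformed_strings(self):
        b = build_bundle("GACGA", {"direct", "reverse", "complement", "revcomp"})
        assert b.reverse.seq == "AGCAG"
        assert b.complement.seq == "CTGCT"
        assert b.revcomp.seq == "TCGTC"
        assert b.direct.seq == "GACGA"

    def test_self_reverse_complement(self):
        assert build_bundle("AT", {"revcomp"}).revcomp.seq == "AT"

    def test_complement_example(self):
        assert build_bundle("ACG", {"complement"}).complement.seq == "TGC"


class TestEdits:
    def test_left_delete_example(self):
        x = build_index("GA", STD).coordinate(2)
        assert left_delete(x, "G", 2, STD) == pytest.approx((0.25, 0.25))

    def test_left_delete_single_symbol_recovers_x0(self):
        x = build_index("A", STD).coordinate(1)
        assert left_delete(x, "A", 1, STD) == pytest.approx(STD.x0)

    def test_left_insert_example(self):
        x = build_index("A", STD).coordinate(1)
        assert left_insert(x, "G", 1, STD) == pytest.approx((0.375, 0.125))

    def test_left_insert_into_empty(self):
        assert left_insert(STD.x0, "A", 0, STD) == pytest.approx((0.25, 0.25))

    def test_right_ops_examples(self):
        xg = build_index("G", STD).coordinate(1)
        assert right_insert(xg, "A", STD) == pytest.approx((0.375, 0.125))
        xga = build_index("GA", STD).coordinate(2)
        assert right_delete(xga, "A", STD) == pytest.approx((0.75, 0.25))

    def test_exact_left_delete_drops_low_digit(self):
        at = build_index("AT", backend="exact").exact_coordinate(2)
        t = left_delete(at, "A")
        assert t.digits(1) == "2" and t.digits(2) == "2"
        assert t == ExactCoordinate.encode("T")

    def test_float_round_trips(self, rng):
        """left/right insert-delete are mutual inverses, <= 1e-12 drift."""
        for _ in range(100):
            n = int(rng.integers(1, 60))
            seq = "".join("ACGT"[d] for d in rng.integers(0, 4, n))
            sym = "ACGT"[int(rng.integers(0, 4))]
            x = build_index(seq, STD).coordinate(n)
            assert left_delete(left_insert(x, sym, n, STD), sym, n + 1, STD) == pytest.approx(
                x, abs=1e-12
            )
            assert right_delete(right_insert(x, sym, STD), sym, STD) == pytest.approx(
                x, abs=1e-12
            )

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(dna, st.sampled_from("ACGT"))
    def test_exact_round_trips_bit_equal(self, seq, sym):
        x = ExactCoordinate.encode(seq)
        assert left_delete(left_insert(x, sym), sym) == x
        assert right_delete(right_insert(x, sym), sym) == x

    def test_delete_from_empty_rejected(self):
        with pytest.raises(ValueError):
            left_delete(STD.x0, "A", 0, STD)
        with pytest.raises(ValueError):
            right_delete(ExactCoordinate.encode(""), "A")


class TestDecode:
    def test_manual_digits(self):
        assert decode_sequence(ExactCoordinate.from_digits("20", "20")) == "AT"

    def test_empty(self):
        assert decode_sequence(ExactCoordinate.encode("")) == ""

    def test_malformed_digits_rejected(self):
        with pytest.raises(ValueError, match="digit"):
            ExactCoordinate.from_digits("21", "20")

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=200))
    def test_encode_decode_identity(self, seq):
        assert decode_sequence(ExactCoordinate.encode(seq)) == seq

    def test_index_prefix_decode(self):
        for seq in random_seqs(20, 200, seed=14):
            idx = build_index(seq, backend="exact")
            i = len(seq) // 2
            assert decode_sequence(idx.exact_coordinate(i)) == seq[:i]


class TestKmerCounts:
    def test_worked_example(self):
        idx = build_index("GACGA", STD)
        assert kmer_counts(idx, 2) == {"GA": 2, "AC": 1, "CG": 1}

    def test_homopolymer(self):
        assert kmer_counts(build_index("AAAA", STD), 1) == {"A": 4}

    def test_counts_sum_to_n(self):
        for seq in random_seqs(10, 150, seed=15):
            assert sum(kmer_counts(build_index(seq, STD), 1).values()) == len(seq)

    @pytest.mark.parametrize("m", [1, 2, 3, 4])
    def test_equals_sliding_window(self, m):
        for seq in random_seqs(20, 200, seed=16, min_len=m):
            idx = build_index(seq, STD)
            expected: dict[str, int] = {}
            for i in range(len(seq) - m + 1):
                w = seq[i : i + m]
                expected[w] = expected.get(w, 0) + 1
            assert kmer_counts(idx, m) == expected

    def test_requires_standard_variant(self):
        with pytest.raises(UnsupportedConfigError):
            kmer_counts(build_index("ACGT", CANTOR), 1)

    def test_m_out_of_range(self):
        with pytest.raises(ValueError):
            kmer_counts(build_index("ACGT", STD), 5)


class TestProximityProperty:
    def test_shared_suffix_implies_2L_closeness(self):
        """Standard CGR: an L-shared suffix forces L-inf distance < 2^-L."""
        rngseqs = random_seqs(30, 80, seed=17, min_len=4)
        for s1, s2 in zip(rngseqs[::2], rngseqs[1::2]):
            L = min(len(s1), len(s2)) // 2
            s2 = s2[: len(s2) - L] + s1[len(s1) - L :]  # graft a shared suffix
            i1 = build_index(s1, STD)
            i2 = build_index(s2, STD)
            x1, y1 = i1.coordinate(len(s1))
            x2, y2 = i2.coordinate(len(s2))
            assert max(abs(x1 - x2), abs(y1 - y2)) < 2.0**-L

    def test_converse_fails_on_at_ta(self):
        """AT/TA are within 2^-1 yet share no suffix: closeness is necessary only."""
        a = build_index("AT", STD).coordinate(2)
        b = build_index("TA", STD).coordinate(2)
        d = max(abs(a[0] - b[0]), abs(a[1] - b[1]))
        assert d < 2.0**-1 and "AT"[-1] != "TA"[-1]
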