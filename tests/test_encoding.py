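"""Window matching and density encoding."""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ggapnb import (
    AMINO_ACIDS,
    Feature,
    GGapPattern,
    SequenceRecord,
    admissible_patterns,
    build_vocabulary,
    density,
    encode,
    window_matches,
)
from ggapnb.errors import InvalidArgumentError

from conftest import random_records


def regex_density(sequence: str, feature: Feature) -> float:
    """Independent oracle: overlapping regex matches / window count."""
    pattern = "".join(
        "." if s == "-" else next_res
        for s, next_res in _template_with_residues(feature)
    )
    n_windows = len(sequence) - feature.pattern.width + 1
    if n_windows <= 0:
        return 0.0
    hits = len(re.findall(f"(?=({pattern}))", sequence))
    return hits / n_windows


def _template_with_residues(feature: Feature):
    it = iter(feature.residues)
    for s in feature.pattern.template:
        yield (s, next(it) if s == "x" else None)


class TestWindowMatches:
    def test_gapped_positions_are_wildcards(self):
        f_aa = Feature(GGapPattern("x-x"), ("A", "A"))
        f_ac = Feature(GGapPattern("x-x"), ("A", "C"))
        assert window_matches("ACA", f_aa)
        assert not window_matches("ACA", f_ac)
        assert window_matches("AWC", f_ac)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            window_matches("AC", Feature(GGapPattern("x-x"), ("A", "C")))


class TestDensity:
    @pytest.mark.parametrize(
        "seq,template,residues,expected",
        [
            ("AAAA", "x", ("A",), 1.0),
            ("ACAC", "x-x", ("A", "A"), 0.5),  # windows ACA, CAC
            ("AC", "xxx", ("A", "C", "A"), 0.0),  # shorter than width
            ("ACACAC", "xx", ("A", "C"), 0.6),  # 3 of 5 windows
            ("ACACAC", "xx", ("C", "A"), 0.4),
        ],
    )
    def test_hand_enumerated_examples(self, seq, template, residues, expected):
        feat = Feature(GGapPattern(template), residues)
        assert density(SequenceRecord("s", seq), feat) == pytest.approx(expected)

    def test_density_ignores_record_id(self):
        feat = Feature(GGapPattern("xx"), ("A", "C"))
        assert density(SequenceRecord("a", "ACAC"), feat) == density(
            SequenceRecord("b", "ACAC"), feat
        )


class TestEncode:
    def test_single_residue_pattern_is_composition(self):
        vocab = build_vocabulary([GGapPattern("x")])
        m = encode([SequenceRecord("s", "AAAA")], vocab)
        expected = np.zeros(20)
        expected[0] = 1.0
        np.testing.assert_allclose(m.values[0], expected)

    def test_dipeptide_densities(self):
        vocab = build_vocabulary([GGapPattern("xx")])
        m = encode([SequenceRecord("s", "ACACAC")], vocab)
        ac = vocab.index_of(Feature(GGapPattern("xx"), ("A", "C")))
        ca = vocab.index_of(Feature(GGapPattern("xx"), ("C", "A")))
        assert m.values[0, ac] == pytest.approx(0.6)
        assert m.values[0, ca] == pytest.approx(0.4)
        assert m.values[0].sum() == pytest.approx(1.0)

    def test_row_and_column_order(self, small_vocab):
        recs = [SequenceRecord("a", "ACDEF"), SequenceRecord("b", "KLMNP")]
        m = encode(recs, small_vocab)
        assert m.sample_ids == ["a", "b"]
        assert m.values.shape == (2, len(small_vocab))

    def test_invalid_residue_error_names_record(self, small_vocab):
        with pytest.raises(InvalidArgumentError, match="bad_rec.*'X'"):
            encode([SequenceRecord("bad_rec", "ACXDE")], small_vocab)

    def test_per_pattern_normalization_all_ten_patterns(self, full_vocab):
        rng = np.random.default_rng(11)
        records = random_records(rng, 8, lo=5, hi=50)
        m = encode(records, full_vocab)
        for pattern in full_vocab.patterns:
            sl = full_vocab.pattern_slice(pattern)
            for i, rec in enumerate(records):
                total = m.values[i, sl].sum()
                if len(rec.sequence) >= pattern.width:
                    assert total == pytest.approx(1.0, abs=1e-12)
                else:
                    assert total == 0.0

    def test_entries_within_unit_interval(self, full_vocab):
        rng = np.random.default_rng(3)
        m = encode(random_records(rng, 5), full_vocab)
        assert m.values.min() >= 0.0 and m.values.max() <= 1.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    seq=st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=50),
    data=st.data(),
)
def test_density_equals_regex_oracle(seq, data):
    """Sliding-window counting agrees with an overlapping-regex oracle."""
    pattern = data.draw(st.sampled_from(admissible_patterns()))
    residues = tuple(
        data.draw(
            st.lists(
                st.sampled_from(AMINO_ACIDS),
                min_size=pattern.n_residues,
                max_size=pattern.n_residues,
            )
        )
    )
    feat = Feature(pattern, residues)
    rec = SequenceRecord("h", seq)
    assert density(rec, feat) == pytest.approx(
        regex_density(seq, feat), abs=1e-12
    )


def test_encode_matches_scalar_density(small_vocab):
    """The batch encoder equals per-feature density() on every column."""
    rng = np.random.default_rng(5)
    records = random_records(rng, 3, lo=4, hi=20)
    m = encode(records, small_vocab)
    check_cols = rng.choice(len(small_vocab), size=40, replace=False)
    for i, rec in enumerate(records):
        for c in check_cols:
            assert m.values[i, c] == pytest.approx(
                density(rec, small_vocab[int(c)]), abs=1e-12
            )
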